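"""Generate the synthetic study inputs: four prototype expression clips, the
neutral clip, and trial-level observer responses for the four avatar × view
conditions at the study size (20 participants × 10 repetitions per cell).

Writes prototype trajectory CSVs and the response table under results/.
"""

from pathlib import Path

import xfaces as xf

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    proto_dir = OUT / "prototypes"
    proto_dir.mkdir(exist_ok=True)

    protos = xf.gen_prototype_trajectories(xf.PrototypeSpec(), seed=SEED)
    for name, traj in {**protos.prototypes, "neutral": protos.neutral}.items():
        xf.write_trajectory_csv(traj, proto_dir / f"{name}.csv")
    mf = {k: xf.motion_flow_MF(v).value for k, v in protos.prototypes.items()}
    print("prototype motion flow (MF, coordinate units):")
    for k, v in sorted(mf.items()):
        print(f"  {k:15s} {v:8.1f}")

    grid = xf.build_style_grid(protos.prototypes, steps_per_axis=5)
    pts = sorted({(p.e, p.s) for p in grid.points})
    obs = xf.ObserverConfig(seed=SEED, n_participants=20, n_reps=10)
    resp = xf.gen_observer_responses(pts, obs)
    resp.to_csv(OUT / "responses.csv", index=False)
    print(f"\nwrote {len(resp)} trials over {len(pts)} lattice cells × "
          f"{len(obs.conditions)} conditions → {OUT/'responses.csv'}")


if __name__ == "__main__":
    main()
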