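"""Compute the species-tuning functions D_M(s) and D_H(s) per condition by
marginalizing the fitted discriminant surfaces over the expression axis,
and fit the tanh sigmoid to obtain thresholds θ and steepness ω.

Requires results/responses.csv. Writes results/tuning.tsv.
"""

from pathlib import Path

import pandas as pd

import xfaces as xf

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    resp = pd.read_csv(OUT / "responses.csv")
    conds = sorted(map(tuple, resp[["avatar", "view_deg"]].drop_duplicates().to_numpy()), key=str)
    rows = []
    print("species-tuning fits (θ = threshold, ω/2 = slope at threshold):")
    for cond in conds:
        sub = resp[(resp["avatar"] == cond[0]) & (resp["view_deg"] == cond[1])]
        m = xf.fit_multinomial(sub, ("1", "e", "s"))
        for fit in xf.marginal_tuning(m):
            rows.append(
                {
                    "avatar": cond[0],
                    "view_deg": cond[1],
                    "species": fit.species,
                    "theta": fit.theta,
                    "omega": fit.omega,
                    "steepness_at_threshold": fit.steepness_at_threshold,
                    "degenerate": fit.degenerate,
                }
            )
            print(
                f"  {cond[0]:6s} {cond[1]:>2}°  {fit.species:6s}  "
                f"θ = {fit.theta:.3f}  ω = {fit.omega:+.2f}"
            )
    pd.DataFrame(rows).to_csv(OUT / "tuning.tsv", sep="\t", index=False)
    print(f"wrote tuning table → {OUT/'tuning.tsv'}")


if __name__ == "__main__":
    main()
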