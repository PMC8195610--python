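"""Fit the softmax discriminant model to the simulated responses, per
avatar × view condition, and run the stepwise predictor comparison.

Requires results/responses.csv from 01_simulate.py. Writes the model
coefficient JSON and the stepwise comparison table under results/.
"""

import json
from pathlib import Path

import pandas as pd

import xfaces as xf

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    resp = pd.read_csv(OUT / "responses.csv")
    conds = sorted(map(tuple, resp[["avatar", "view_deg"]].drop_duplicates().to_numpy()), key=str)
    payload = {}
    print("per-condition {1,e,s} discriminant fits:")
    for cond in conds:
        sub = resp[(resp["avatar"] == cond[0]) & (resp["view_deg"] == cond[1])]
        m = xf.fit_multinomial(sub, ("1", "e", "s"))
        payload[f"{cond[0]}_{cond[1]}"] = {
            "beta": m.beta.tolist(),
            "bic": m.bic,
            "accuracy": m.accuracy,
            "log_likelihood": m.log_likelihood,
        }
        print(f"  {cond[0]:6s} {cond[1]:>2}°  accuracy {m.accuracy:.3f}  BIC {m.bic:.0f}")
    (OUT / "models.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    one = resp[(resp["avatar"] == conds[0][0]) & (resp["view_deg"] == conds[0][1])]
    sets = tuple(s for s in xf.DEFAULT_CANDIDATE_SETS if "flow" not in s)
    table, best = xf.stepwise_compare(one, sets)
    table.to_csv(OUT / "stepwise.tsv", sep="\t", index=False)
    print("\nstepwise comparison (first condition):")
    print(table.to_string(index=False))
    print(f"most compact accepted model: {table.attrs['selected']}")


if __name__ == "__main__":
    main()
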