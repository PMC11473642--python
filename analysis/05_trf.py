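"""TRF estimation: lambda search, feature comparison, per-block models.

Writes results/trf_predictions.csv (held-out prediction r per
participant x acoustic feature) and results/trf_feature_tests.json
(pairwise Wilcoxon comparisons at the Bonferroni-corrected threshold).
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, demo_study

from orsound import stats
from orsound.pipeline import FEATURE_KINDS, participant_trf


def main():
    RESULTS.mkdir(exist_ok=True)
    study = demo_study()
    cfg = study["cfg"]
    grid = [10.0**e for e in range(-6, 9, 2)]
    rows = []
    for p in range(cfg.n_participants):
        for kind in FEATURE_KINDS:
            res = participant_trf(study, p, kind, lam_grid=grid, k=4)
            rows.append(dict(participant=p, kind=kind,
                             r=res["prediction"]["r"],
                             lam=res["cv"].best_lambda,
                             lam_modal=res["cv"].modal_lambda()))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "trf_predictions.csv", index=False)

    wide = df.pivot(index="participant", columns="kind", values="r")
    pairs = [("envelope_denoised", "envelope_raw"),
             ("onsets", "envelope_raw"),
             ("envelope_denoised", "onsets")]
    tests = {}
    for a, b in pairs:
        res = stats.wilcoxon_signed_rank(wide[a], wide[b])
        tests[f"{a}_vs_{b}"] = dict(W=res.W, p=res.p, n=res.n_used)
    alpha = stats.bonferroni_alpha(0.05, len(pairs), display=True)
    out = {"alpha_bonferroni": alpha, "tests": tests,
           "mean_r": {k: float(wide[k].mean()) for k in FEATURE_KINDS}}
    (RESULTS / "trf_feature_tests.json").write_text(json.dumps(out,
                                                               indent=2))
    print("Held-out prediction r (mean over participants):")
    for k in FEATURE_KINDS:
        print(f"  {k:18s} {wide[k].mean():.3f}")
    for name, t in tests.items():
        star = "*" if t["p"] < alpha else " "
        print(f"  {name}: W={t['W']:.0f}, p={t['p']:.4f}{star} "
              f"(alpha={alpha})")


if __name__ == "__main__":
    main()
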