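"""Mixed-effects models and stepwise model selection per outcome.

Fits the nested condition / condition+time / condition*time models with
participant random intercepts (linear for ratings, duration and neural
amplitudes; Poisson for counts; cumulative-link for ordinal memory
scores), selects by likelihood ratio, and writes the chosen model and
coefficients per outcome to results/model_selection.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, demo_config

from orsound import stats, synth


def _select(fits):
    chosen, table = stats.lrt_select(fits)
    return {
        "model": chosen.formula_id,
        "method": chosen.method,
        "beta": {k: round(float(v), 4) for k, v in chosen.params.items()},
        "se": {k: round(float(v), 4) for k, v in chosen.se.items()},
        "p": {k: float(v) for k, v in chosen.pvalues.items()},
        "lrt": table.round(4).to_dict(orient="records"),
    }


def main():
    RESULTS.mkdir(exist_ok=True)
    # behavioral models at the full study size
    cfg = demo_config(n_participants=22, n_blocks=28,
                      blocks_per_condition=14)
    truth = synth.default_ground_truth(cfg)
    tab = synth.simulate_behavior(cfg, truth)
    tab["memory_score"] = [stats.memory_score(t, r)
                           for t, r in zip(tab["target"], tab["response"])]

    selection = {}
    for outcome in ("effort", "frustration", "distraction", "duration"):
        selection[outcome] = _select(
            [stats.fit_lmm(tab, outcome, f) for f in (1, 2, 3)])
    for outcome in ("mistakes", "tissue_damage"):
        selection[outcome] = _select(
            [stats.fit_glmm_poisson(tab, outcome, f) for f in (1, 2, 3)])
    selection["memory_score"] = _select(
        [stats.fit_clmm(tab, "memory_score", f) for f in (1, 2)])

    alpha = stats.bonferroni_alpha(0.05, 3, display=True)
    out = {"alpha_bonferroni": alpha, "n_participants": cfg.n_participants,
           "n_blocks": cfg.n_blocks, "selection": selection}
    (RESULTS / "model_selection.json").write_text(json.dumps(out, indent=2))

    print(f"Model selection (alpha = {alpha} per response family):")
    for outcome, d in selection.items():
        beta = d["beta"].get("condition")
        p = d["p"].get("condition")
        star = "*" if (p is not None and p < alpha) else ""
        print(f"  {outcome:14s} model {d['model']} ({d['method']}): "
              f"condition beta={beta:+.3f} p={p:.4f}{star}")


if __name__ == "__main__":
    main()
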