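"""Scoring and mixed-model layer against independent oracles.

Oracles: a brute-force dynamic-programming edit distance, full sign-flip
enumeration for the Wilcoxon test, statsmodels MixedLM for the linear
mixed model, and lme4/lmerTest (via Rscript) for Satterthwaite degrees of
freedom, the Poisson GLMM, and the two-category reduction of the
cumulative-link model.
"""

import itertools
import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orsound import stats, synth


# --------------------------------------------------------------------------
# memory scoring

def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance ('X' never matches)."""
    m, n = len(a), len(b)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            match = a[i - 1] == b[j - 1] and a[i - 1] != "X"
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1,
                          D[i - 1][j - 1] + (0 if match else 1))
    return D[m][n]


LETTERS = list("BCDFHKLMPQST")


class TestMemoryScore:
    def test_perfect_recall(self):
        assert stats.memory_score("BCDFHKLM", "BCDFHKLM") == 1.0

    def test_all_omitted(self):
        assert stats.memory_score("BCDFHKLM", "XXXXXXXX") == 0.0

    def test_single_substitution(self):
        assert stats.memory_score("BCDFHKLM", "BCDFHKLT") == 0.875

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            stats.memory_score("", "B")

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(2000):
            lt = rng.choice([2, 8])
            lr = int(rng.integers(0, 10))
            t = "".join(rng.choice(LETTERS, lt))
            r = "".join(rng.choice(LETTERS + ["X"], lr))
            d = dp_levenshtein(t, r)
            expect = float(np.clip(1 - d / max(len(t), len(r) or 1), 0, 1))
            assert stats.memory_score(t, r) == pytest.approx(expect)

    @given(st.text(alphabet="BCDF", min_size=1, max_size=8),
           st.text(alphabet="BCDFX", min_size=0, max_size=8))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_dp_equivalence_property(self, t, r):
        d = dp_levenshtein(t, r)
        expect = float(np.clip(1 - d / max(len(t), len(r), 1), 0, 1))
        assert stats.memory_score(t, r) == pytest.approx(expect)


# --------------------------------------------------------------------------
# Wilcoxon signed rank

def enumerate_wilcoxon_p(d):
    """Exact two-sided p by enumerating all sign assignments."""
    from scipy.stats import rankdata
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    W = min(w_plus, ranks.sum() - w_plus)
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        wm = ranks.sum() - w
        total += 1
        if min(w, wm) <= W:
            count += 1
    return count / total


class TestWilcoxon:
    def test_all_zero_differences_flagged(self):
        with pytest.warns(UserWarning):
            res = stats.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.flagged and np.isnan(res.p)

    def test_six_positive_differences_exact(self):
        x = np.arange(1.0, 7.0)
        res = stats.wilcoxon_signed_rank(x, np.zeros(6))
        assert res.W == 0
        assert res.p == pytest.approx(2 / 64)

    def test_symmetry_under_swap(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        a = stats.wilcoxon_signed_rank(x, y)
        b = stats.wilcoxon_signed_rank(y, x)
        assert a.W == b.W and a.p == pytest.approx(b.p)

    def test_matches_enumeration_for_all_small_n(self, rng):
        for n in range(5, 9):
            for _ in range(10):
                d = rng.standard_normal(n)
                res = stats.wilcoxon_signed_rank(d, np.zeros(n))
                assert res.method == "exact"
                assert res.p == pytest.approx(enumerate_wilcoxon_p(d))

    def test_matches_scipy_exact(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        for _ in range(20):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            ours = stats.wilcoxon_signed_rank(x, y)
            ref = scipy_wilcoxon(x, y, mode="exact")
            assert ours.W == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue)


class TestBonferroni:
    def test_printed_thresholds(self):
        assert stats.bonferroni_alpha(0.05, 3, display=True) == 0.017
        assert stats.bonferroni_alpha(0.05, 6, display=True) == 0.0083
        assert stats.bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            stats.bonferroni_alpha(0.05, 0)


# --------------------------------------------------------------------------
# mixed models

@pytest.fixture(scope="module")
def behavior_table():
    cfg = synth.SynthConfig(n_participants=22, n_blocks=28,
                            blocks_per_condition=14, seed=5)
    truth = synth.default_ground_truth(cfg)
    tab = synth.simulate_behavior(cfg, truth)
    tab["memory_score"] = [stats.memory_score(t, r)
                           for t, r in zip(tab["target"], tab["response"])]
    return tab


def _run_r(script: str) -> dict:
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    return json.loads(out.stdout.strip().splitlines()[-1])


class TestLMM:
    def test_matches_statsmodels_mixedlm(self, behavior_table):
        import statsmodels.formula.api as smf
        fit = stats.fit_lmm(behavior_table, "effort", 1)
        ref = smf.mixedlm("effort ~ condition", behavior_table,
                          groups=behavior_table["participant"]).fit(reml=True)
        assert fit.params["condition"] == pytest.approx(
            ref.params["condition"], abs=1e-6)
        assert fit.se["condition"] == pytest.approx(
            ref.bse["condition"], abs=1e-6)
        assert fit.var_ri == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                           rel=1e-4)

    def test_matches_lmerTest_satterthwaite(self, behavior_table, tmp_path):
        csv = tmp_path / "tab.csv"
        behavior_table.to_csv(csv, index=False)
        r = _run_r(f"""
suppressMessages(library(lmerTest)); library(jsonlite)
d <- read.csv('{csv}')
m <- lmer(effort ~ condition + (1|participant), data=d, REML=TRUE)
s <- coef(summary(m))
cat(toJSON(list(beta=s['condition','Estimate'], se=s['condition','Std. Error'],
 df=s['condition','df'], p=s['condition','Pr(>|t|)']), digits=12))
""")
        fit = stats.fit_lmm(behavior_table, "effort", 1)
        assert fit.params["condition"] == pytest.approx(r["beta"][0],
                                                        rel=1e-6)
        assert fit.se["condition"] == pytest.approx(r["se"][0], rel=1e-6)
        assert fit.df["condition"] == pytest.approx(r["df"][0], rel=1e-3)
        assert fit.pvalues["condition"] == pytest.approx(r["p"][0], rel=1e-3)

    def test_zero_ri_variance_matches_ols(self, rng):
        n = 400
        tab = pd.DataFrame({
            "participant": np.repeat(np.arange(20), 20),
            "block": np.tile(np.arange(1, 21), 20),
            "condition": rng.integers(0, 2, n),
        })
        tab["y"] = 1.0 + 2.0 * tab["condition"] + rng.standard_normal(n)
        fit = stats.fit_lmm(tab, "y", 1)
        X = np.c_[np.ones(n), tab["condition"]]
        beta_ols = np.linalg.lstsq(X, tab["y"], rcond=None)[0]
        assert fit.var_ri <= 1e-3
        assert np.allclose(fit.params.values, beta_ols, atol=1e-3)

    def test_ri_variance_recovery_at_scale(self, rng):
        n_p, n_b = 40, 30
        tab = pd.DataFrame({
            "participant": np.repeat(np.arange(n_p), n_b),
            "block": np.tile(np.arange(1, n_b + 1), n_p),
            "condition": rng.integers(0, 2, n_p * n_b),
        })
        ri = rng.normal(0, 2.0, n_p)
        tab["y"] = (1.0 + 0.5 * tab["condition"]
                    + ri[tab["participant"]] + rng.standard_normal(len(tab)))
        fit = stats.fit_lmm(tab, "y", 1)
        assert fit.var_ri == pytest.approx(4.0, rel=0.5)
        assert fit.var_resid == pytest.approx(1.0, rel=0.15)

    def test_requires_two_participants(self, behavior_table):
        solo = behavior_table[behavior_table["participant"] == 0]
        with pytest.raises(ValueError):
            stats.fit_lmm(solo, "effort", 1)


class TestGLMMPoisson:
    def test_matches_glmer(self, behavior_table, tmp_path):
        csv = tmp_path / "tab.csv"
        behavior_table.to_csv(csv, index=False)
        r = _run_r(f"""
suppressMessages(library(lme4)); library(jsonlite)
d <- read.csv('{csv}')
g <- glmer(tissue_damage ~ condition + block + (1|participant), data=d,
           family=poisson)
s <- summary(g)$coefficients
cat(toJSON(list(beta=s[,'Estimate'], se=s[,'Std. Error'],
 ll=as.numeric(logLik(g)), v=as.data.frame(VarCorr(g))$vcov), digits=12))
""")
        fit = stats.fit_glmm_poisson(behavior_table, "tissue_damage", 2)
        assert np.allclose(fit.params.values, r["beta"], atol=2e-3)
        assert fit.llf_ml == pytest.approx(r["ll"][0], abs=0.05)
        assert fit.var_ri == pytest.approx(r["v"][0], abs=5e-3)

    def test_constant_rate_intercept_recovery(self, rng):
        n_p, n_b = 30, 28
        tab = pd.DataFrame({
            "participant": np.repeat(np.arange(n_p), n_b),
            "block": np.tile(np.arange(1, n_b + 1), n_p),
            "condition": rng.integers(0, 2, n_p * n_b),
        })
        tab["y"] = rng.poisson(2.0, len(tab))
        fit = stats.fit_glmm_poisson(tab, "y", 1)
        assert fit.params["Intercept"] == pytest.approx(np.log(2.0),
                                                        abs=0.08)

    def test_all_zero_outcome_rejected(self, behavior_table):
        tab = behavior_table.copy()
        tab["zeros"] = 0
        with pytest.raises(ValueError, match="degenerate"):
            stats.fit_glmm_poisson(tab, "zeros", 1)

    def test_non_integer_outcome_rejected(self, behavior_table):
        with pytest.raises(ValueError, match="integer"):
            stats.fit_glmm_poisson(behavior_table, "effort", 1)


class TestCLMM:
    def test_two_categories_reduce_to_mixed_logistic(self, rng, tmp_path):
        n_p, n_b = 20, 28
        rows = []
        for p in range(n_p):
            ri = rng.normal(0, 0.8)
            for b in range(1, n_b + 1):
                cond = (p + b) % 2
                eta = -0.5 + 1.2 * cond + ri
                rows.append(dict(participant=p, block=b, condition=cond,
                                 y=float(rng.uniform() < 1 /
                                         (1 + np.exp(-eta)))))
        tab = pd.DataFrame(rows)
        csv = tmp_path / "bin.csv"
        tab.to_csv(csv, index=False)
        r = _run_r(f"""
suppressMessages(library(lme4)); library(jsonlite)
d <- read.csv('{csv}')
g <- glmer(y ~ condition + (1|participant), data=d, family=binomial, nAGQ=9)
s <- summary(g)$coefficients
cat(toJSON(list(beta=s[,'Estimate'], ll=as.numeric(logLik(g))), digits=12))
""")
        fit = stats.fit_clmm(tab, "y", 1)
        # glmer intercept corresponds to minus the single threshold
        assert -fit.extra["thresholds"][0] == pytest.approx(r["beta"][0],
                                                            abs=1e-3)
        assert fit.params["condition"] == pytest.approx(r["beta"][1],
                                                        abs=1e-3)
        assert fit.llf_ml == pytest.approx(r["ll"][0], abs=1e-3)

    def test_thresholds_strictly_increasing(self, behavior_table):
        fit = stats.fit_clmm(behavior_table, "memory_score", 1)
        th = fit.extra["thresholds"]
        assert all(a < b for a, b in zip(th, th[1:]))

    def test_condition_shift_sign_recovered(self, behavior_table):
        # high load lowers memory scores by construction
        fit = stats.fit_clmm(behavior_table, "memory_score", 1)
        assert fit.params["condition"] < 0
        assert fit.pvalues["condition"] < 0.05


class TestLRT:
    def _fits(self, table, outcome="effort"):
        return [stats.fit_lmm(table, outcome, f) for f in (1, 2, 3)]

    def test_df_between_models_is_one(self, behavior_table):
        fits = self._fits(behavior_table)
        _, tab = stats.lrt_select(fits)
        assert (tab["df"] == 1).all()

    def test_strong_time_effect_selects_larger_model(self, rng):
        n_p, n_b = 20, 28
        tab = pd.DataFrame({
            "participant": np.repeat(np.arange(n_p), n_b),
            "block": np.tile(np.arange(1, n_b + 1), n_p),
            "condition": rng.integers(0, 2, n_p * n_b),
        })
        tab["y"] = (0.5 * tab["condition"] + 0.3 * tab["block"]
                    + rng.standard_normal(len(tab)))
        chosen, _ = stats.lrt_select(self._fits(tab, "y"))
        assert chosen.formula_id >= 2

    def test_non_nested_rejected(self, behavior_table):
        fits = self._fits(behavior_table)
        with pytest.raises(ValueError):
            stats.lrt_select([fits[0], fits[0]])


class TestOrdinalHelpers:
    def test_to_ordinal_codes_sorted_values(self):
        s = pd.Series([0.5, 0.0, 1.0, 0.5])
        codes, values = stats.to_ordinal(s)
        assert np.array_equal(values, [0.0, 0.5, 1.0])
        assert np.array_equal(codes, [1, 0, 2, 1])
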