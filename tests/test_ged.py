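"""GED spatial filters: oracle equivalence, recovery, amplitude extraction."""

import itertools

import numpy as np
import pytest

from orsound import ged, synth
from orsound.preproc import DEFAULT_CHANNELS


LABELS = list(DEFAULT_CHANNELS)


class TestWindowSpec:
    @pytest.mark.parametrize("resp,comp,lo,hi", [
        ("ERP", "N1", 80, 150), ("ERP", "P2", 150, 250),
        ("ERP", "N2", 200, 300),
        ("TRF_ons", "N1", 80, 150), ("TRF_ons", "P2", 150, 250),
        ("TRF_ons", "N2", 200, 300),
        ("TRF_env", "N1", 50, 120), ("TRF_env", "P2", 120, 220),
        ("TRF_env", "N2", 220, 320),
    ])
    def test_search_windows(self, resp, comp, lo, hi):
        spec = ged.WindowSpec(resp, comp)
        assert spec.search_ms == (lo, hi)
        assert spec.half_width_ms == (25.0 if comp == "N1" else 50.0)
        assert spec.polarity == (1 if comp == "P2" else -1)


class TestFindPeak:
    def _response(self, times, lat, amp, pattern):
        bump = amp * np.exp(-0.5 * ((times - lat) / 15.0) ** 2)
        return np.outer(pattern, bump)

    def test_planted_n1_latency_and_channel(self):
        times = np.arange(-200, 601, 8.0)
        pattern = synth.fronto_central_pattern(LABELS, "Cz")
        resp = self._response(times, 100.0, -2.0, pattern)
        spec = ged.WindowSpec("ERP", "N1")
        lat, ch, flagged = ged.find_peak(resp, times, spec)
        assert abs(lat - 100.0) <= 8.0
        assert ch == int(np.argmax(pattern))
        assert not flagged

    def test_flat_response_falls_back_flagged(self):
        times = np.arange(-200, 601, 8.0)
        resp = np.ones((24, times.size)) * 0.5  # wrong polarity everywhere
        lat, ch, flagged = ged.find_peak(resp, times,
                                         ged.WindowSpec("ERP", "N1"))
        assert flagged
        assert 80 <= lat <= 150


class TestCovariances:
    def test_rank1_window_source_in_difference(self, rng):
        times = np.arange(-200, 601, 4.0)
        a = rng.standard_normal(24)
        a /= np.linalg.norm(a)
        noise = 0.1 * rng.standard_normal((24, times.size))
        src = np.zeros(times.size)
        sel = (times >= 75) & (times <= 125)
        src[sel] = 3.0 * rng.standard_normal(sel.sum())
        resp = noise + np.outer(a, src)
        spec = ged.WindowSpec("ERP", "N1")
        S, R = ged.window_covariances(resp, times, 100.0, spec)
        evals, evecs = np.linalg.eigh(S - R)
        top = evecs[:, -1]
        assert abs(np.corrcoef(top, a)[0, 1]) > 0.99

    def test_covariances_symmetric_psd(self, rng):
        times = np.arange(-200, 601, 4.0)
        resp = rng.standard_normal((24, times.size))
        S, R = ged.window_covariances(resp, times, 100.0,
                                      ged.WindowSpec("ERP", "N1"))
        for M in (S, R):
            assert np.allclose(M, M.T)
            assert np.linalg.eigvalsh(M).min() > -1e-10


class TestCleanAndAverage:
    def test_identical_covariances_kept(self, rng):
        S = np.cov(rng.standard_normal((6, 100)))
        Sbar, Rbar, excl = ged.clean_and_average([S] * 10, [S] * 10)
        assert excl == []
        assert np.allclose(Sbar, S)

    def test_scaled_outlier_excluded_jointly(self, rng):
        mats = [np.cov(rng.standard_normal((6, 200))) for _ in range(20)]
        s_list = [m.copy() for m in mats]
        r_list = [m.copy() for m in mats]
        s_list[7] = 100.0 * s_list[7]  # outlier in S only
        Sbar, Rbar, excl = ged.clean_and_average(s_list, r_list)
        assert excl == [7]
        # joint exclusion: participant 7 contributes to neither mean
        assert np.allclose(Rbar, np.mean([r_list[i] for i in range(20)
                                          if i != 7], axis=0))

    def test_minimum_participants(self, rng):
        S = np.eye(3)
        with pytest.raises(ValueError, match="3 participants"):
            ged.clean_and_average([S, S], [S, S])


class TestDecompose:
    def test_identity_pencil_unit_eigenvalues(self):
        f = ged.ged_decompose(np.eye(6), np.eye(6))
        assert np.allclose(f.eigvals, 1.0)

    def test_rank1_pencil_analytic_solution(self, rng):
        R = np.eye(5) + 0.2 * np.ones((5, 5))
        a = rng.standard_normal(5)
        a /= np.linalg.norm(a)
        S = R + 3.0 * np.outer(a, a)
        f = ged.ged_decompose(S, R, shrink=0.01)
        assert abs(np.corrcoef(f.forward[:, 0], a)[0, 1]) >= 0.99

    def test_matches_brute_force_rayleigh_on_3_channels(self, rng):
        S = np.cov(rng.standard_normal((3, 400)))
        R = np.cov(rng.standard_normal((3, 400)))
        f = ged.ged_decompose(S, R, shrink=0.01)
        Rreg = 0.99 * R + 0.01 * np.linalg.eigvalsh(R).mean() * np.eye(3)
        grid = np.linspace(-1, 1, 41)
        best = max(
            (w @ S @ w) / (w @ Rreg @ w)
            for w in (np.array(c) for c in itertools.product(grid, repeat=3))
            if np.linalg.norm(w) > 1e-9
        )
        assert f.eigvals[0] >= best - 1e-3
        w0 = f.eigvecs[:, 0]
        rq = (w0 @ S @ w0) / (w0 @ Rreg @ w0)
        assert abs(rq - f.eigvals[0]) < 1e-8

    def test_permutation_equivariance(self, rng):
        S = np.cov(rng.standard_normal((5, 300)))
        R = np.cov(rng.standard_normal((5, 300)))
        perm = rng.permutation(5)
        f1 = ged.ged_decompose(S, R)
        f2 = ged.ged_decompose(S[np.ix_(perm, perm)], R[np.ix_(perm, perm)])
        assert np.allclose(f1.eigvals, f2.eigvals, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ged.ged_decompose(np.eye(3), np.eye(4))


def _planted_filter(rng, amp=3.0, center="Cz"):
    """Responses with a single planted window source on 24 channels,
    sampled at 500 Hz (the +/-25 ms N1 window needs the fine grid for
    stable window covariances)."""
    times = np.arange(-200, 601, 2.0)
    pattern = synth.fronto_central_pattern(LABELS, center)
    bump = -amp * np.exp(-0.5 * ((times - 100.0) / 15.0) ** 2)
    spec = ged.WindowSpec("ERP", "N1")
    s_list, r_list, responses = [], [], {}
    for p in range(8):
        resp = np.outer(pattern, bump) + 0.3 * rng.standard_normal(
            (24, times.size))
        S, R = ged.window_covariances(resp, times, 100.0, spec)
        s_list.append(S)
        r_list.append(R)
        responses[(p, 0)] = resp
    Sbar, Rbar, _ = ged.clean_and_average(s_list, r_list)
    filt = ged.ged_decompose(Sbar, Rbar)
    grand = np.mean(list(responses.values()), axis=0)
    return filt, spec, grand, times, pattern, responses


class TestSelectAndAmplitudes:
    def test_planted_source_component_one_recovered(self, rng):
        filt, spec, grand, times, pattern, _ = _planted_filter(rng)
        filt = ged.select_component(filt, spec, grand, times, 100.0, LABELS)
        assert filt.chosen == 0
        assert abs(np.corrcoef(filt.topography, pattern)[0, 1]) >= 0.9

    def test_sign_invariance_of_eigenvectors(self, rng):
        filt, spec, grand, times, _, _ = _planted_filter(rng)
        flipped = ged.GEDFilter(filt.s_mean, filt.r_mean,
                                -filt.eigvecs.copy(), filt.eigvals.copy(),
                                filt.shrink, forward=-filt.forward.copy())
        a = ged.select_component(filt, spec, grand, times, 100.0, LABELS)
        b = ged.select_component(flipped, spec, grand, times, 100.0, LABELS)
        assert np.allclose(a.w, b.w)

    def test_component_polarity_enforced(self, rng):
        filt, spec, grand, times, _, _ = _planted_filter(rng)
        filt = ged.select_component(filt, spec, grand, times, 100.0, LABELS)
        comp = filt.w @ grand
        sel = (times >= 75) & (times <= 125)
        assert comp[sel].mean() < 0  # N1 is negative

    def test_second_component_promoted_when_first_implausible(self, rng):
        """Two sources: a stronger artifact-like edge source and a weaker
        fronto-central window source -> component 2 is promoted."""
        times = np.arange(-200, 601, 2.0)
        spec = ged.WindowSpec("ERP", "N1")
        good = synth.fronto_central_pattern(LABELS, "Cz")
        edge = np.zeros(24)
        edge[LABELS.index("T7")] = 1.0  # spatially focal: fails the prior
        bump = -2.0 * np.exp(-0.5 * ((times - 100.0) / 15.0) ** 2)
        sel = (times >= 75) & (times <= 125)
        s_list, r_list = [], []
        responses = {}
        for p in range(8):
            art = np.zeros(times.size)
            art[sel] = 6.0 * rng.standard_normal(sel.sum())
            resp = (np.outer(good, bump) + np.outer(edge, art)
                    + 0.2 * rng.standard_normal((24, times.size)))
            S, R = ged.window_covariances(resp, times, 100.0, spec)
            s_list.append(S)
            r_list.append(R)
            responses[(p, 0)] = resp
        Sbar, Rbar, _ = ged.clean_and_average(s_list, r_list)
        filt = ged.ged_decompose(Sbar, Rbar)
        grand = np.mean(list(responses.values()), axis=0)
        filt = ged.select_component(filt, spec, grand, times, 100.0, LABELS)
        assert filt.chosen == 1
        assert abs(np.corrcoef(filt.topography, good)[0, 1]) >= 0.8

    def test_selector_filter_amplitude_equals_channel_mean(self, rng):
        filt, spec, grand, times, _, responses = _planted_filter(rng)
        c = LABELS.index("Cz")
        unit = np.zeros(24)
        unit[c] = 1.0
        filt.eigvecs[:, 0] = unit
        filt.sign = 1.0
        filt.chosen = 0
        table = ged.component_amplitudes(filt, responses, times, 100.0, spec)
        sel = (times >= 75) & (times <= 125)
        expect = responses[(0, 0)][c, sel].mean()
        got = table.loc[(table.participant == 0) & (table.block == 0),
                        "amplitude"].iloc[0]
        assert got == pytest.approx(expect)

    def test_amplitude_pipeline_linear(self, rng):
        filt, spec, grand, times, _, responses = _planted_filter(rng)
        filt = ged.select_component(filt, spec, grand, times, 100.0, LABELS)
        t1 = ged.component_amplitudes(filt, responses, times, 100.0, spec)
        scaled = {k: 3.0 * v for k, v in responses.items()}
        t2 = ged.component_amplitudes(filt, scaled, times, 100.0, spec)
        assert np.allclose(t2["amplitude"], 3.0 * t1["amplitude"])

    def test_missing_block_yields_na(self, rng):
        filt, spec, grand, times, _, responses = _planted_filter(rng)
        filt = ged.select_component(filt, spec, grand, times, 100.0, LABELS)
        responses[(0, 1)] = None
        table = ged.component_amplitudes(filt, responses, times, 100.0, spec)
        assert table.loc[(table.participant == 0) & (table.block == 1),
                         "amplitude"].isna().all()
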