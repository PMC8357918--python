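"""Consistency statistics: KS-D, Spearman, within/between framework, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from megretest.connectivity import ConnectivityMatrix
from megretest.spectral import PowerSpectrum
from megretest.stats import (StatsError, build_consistency_table,
                             compare_within_between, ks_spectral_distance,
                             paired_t, rm_anova, roiwise_consistency_map,
                             spearman_matrix_consistency)


def _spectrum(masses, band=(0.5, 30.0)):
    masses = np.asarray(masses, dtype=float)
    freqs = band[0] + np.arange(len(masses)) * 0.5
    df = freqs[1] - freqs[0]
    power = masses / (masses.sum() * df)
    return PowerSpectrum(freqs=freqs, power=power, band=band,
                         n_epochs=1, n_rois=90)


def _conn(values, band=(8.0, 13.0)):
    values = np.asarray(values, dtype=float)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, np.nan)
    return ConnectivityMatrix(values=values, band=band, n_epochs=1)


def _random_conn(rng, n=10, band=(8.0, 13.0)):
    v = rng.uniform(0.2, 0.8, (n, n))
    return _conn(v, band)


class TestKsDistance:
    def test_identical_spectra_zero(self):
        p = _spectrum([0.4, 0.3, 0.2, 0.1])
        assert ks_spectral_distance(p, p) == 0.0

    def test_disjoint_mass_one(self):
        p = _spectrum([1.0, 0.0, 0.0, 0.0])
        q = _spectrum([0.0, 0.0, 0.0, 1.0])
        assert ks_spectral_distance(p, q) == pytest.approx(1.0)

    def test_hand_computed_toy_masses(self):
        # CDFs (0.4,0.7,0.9,1.0) vs (0.1,0.3,0.6,1.0): max gap 0.4
        p = _spectrum([0.4, 0.3, 0.2, 0.1])
        q = _spectrum([0.1, 0.2, 0.3, 0.4])
        assert ks_spectral_distance(p, q) == pytest.approx(0.4)

    def test_symmetric_and_bounded(self, rng):
        p = _spectrum(rng.uniform(0, 1, 50))
        q = _spectrum(rng.uniform(0, 1, 50))
        d = ks_spectral_distance(p, q)
        assert 0.0 <= d <= 1.0
        assert d == ks_spectral_distance(q, p)

    def test_grid_mismatch_rejected(self):
        p = _spectrum([0.5, 0.5])
        q = _spectrum([0.3, 0.3, 0.4])
        with pytest.raises(StatsError):
            ks_spectral_distance(p, q)

    def test_approximate_p_value_reported(self):
        p = _spectrum([0.4, 0.3, 0.2, 0.1])
        q = _spectrum([0.1, 0.2, 0.3, 0.4])
        d, pv = ks_spectral_distance(p, q, return_p=True)
        assert d == pytest.approx(0.4) and 0.0 <= pv <= 1.0


class TestSpearmanConsistency:
    def test_identical_matrices(self, rng):
        a = _random_conn(rng)
        assert spearman_matrix_consistency(a, a) == pytest.approx(1.0)

    def test_monotone_transform_invariant(self, rng):
        a = _random_conn(rng)
        b = ConnectivityMatrix(values=a.values**2, band=a.band, n_epochs=1)
        assert spearman_matrix_consistency(a, b) == pytest.approx(1.0)

    def test_reversed_ranks(self, rng):
        a = _random_conn(rng)
        b = ConnectivityMatrix(values=1.0 - a.values, band=a.band, n_epochs=1)
        assert spearman_matrix_consistency(a, b) == pytest.approx(-1.0)

    def test_constant_matrix_rejected(self, rng):
        a = _random_conn(rng)
        b = _conn(np.full((10, 10), 0.5))
        with pytest.raises(StatsError):
            spearman_matrix_consistency(a, b)

    def test_band_mismatch_rejected(self, rng):
        a = _random_conn(rng)
        b = _random_conn(rng, band=(13.0, 30.0))
        with pytest.raises(StatsError):
            spearman_matrix_consistency(a, b)


def _sessions(rng, n_subjects, identical=False):
    sessions = {}
    base_mass = rng.uniform(0.5, 1.5, 60)
    base_conn = rng.uniform(0.2, 0.8, (10, 10))
    for s in range(n_subjects):
        for tp in ("BL", "FU1", "FU2"):
            if identical:
                mass, cv = base_mass, base_conn
            else:
                mass = rng.uniform(0.5, 1.5, 60)
                cv = rng.uniform(0.2, 0.8, (10, 10))
            sessions[(f"S{s}", tp)] = dict(
                spectrum=_spectrum(mass),
                conn={"alpha": _conn(cv),
                      "beta": _conn(cv, band=(13.0, 30.0))})
    return sessions


class TestConsistencyTable:
    def test_counts_for_eight_subjects(self, rng):
        table = build_consistency_table(_sessions(rng, 8))
        for metric in ("ks_d", "spearman_alpha", "spearman_beta"):
            sub = table[table.metric == metric]
            assert (sub.kind == "within").sum() == 24
            assert (sub.kind == "between").sum() == 24

    def test_two_subjects_between_is_single_pair(self, rng):
        sessions = _sessions(rng, 2)
        table = build_consistency_table(sessions)
        row = table[(table.kind == "between") & (table.metric == "ks_d")
                    & (table.subject == "S0") & (table.key == "BL")]
        direct = ks_spectral_distance(sessions[("S0", "BL")]["spectrum"],
                                      sessions[("S1", "BL")]["spectrum"])
        assert row.value.iloc[0] == pytest.approx(direct)

    def test_identical_subjects_give_zero_ks(self, rng):
        table = build_consistency_table(_sessions(rng, 3, identical=True))
        assert (table[table.metric == "ks_d"].value == 0.0).all()

    def test_missing_session_rejected(self, rng):
        sessions = _sessions(rng, 3)
        del sessions[("S1", "FU1")]
        with pytest.raises(StatsError, match="missing"):
            build_consistency_table(sessions)


class TestRmAnova:
    def test_all_equal_values(self):
        res = rm_anova(np.full((8, 3), 0.7))
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_textbook_dfs_for_8_by_3(self, rng):
        res = rm_anova(rng.uniform(0, 1, (8, 3)))
        assert res.df == (2, 14)

    def test_toy_table_with_zero_error(self):
        # hand decomposition: rows (1,2,3),(2,3,4),(3,4,5) -> the condition
        # effect is identical across subjects, SS_error = 0, F = +inf
        res = rm_anova(np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5]], float))
        assert res.statistic == np.inf
        assert res.p == 0.0
        assert res.effect_size == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        values = rng.uniform(0, 1, (8, 3))
        res = rm_anova(values)
        df = pd.DataFrame(dict(
            value=values.ravel(),
            subject=np.repeat(np.arange(8), 3),
            cond=np.tile(np.arange(3), 8)))
        ref = pingouin.rm_anova(data=df, dv="value", within="cond",
                                subject="subject", detailed=True,
                                correction=False)
        assert res.statistic == pytest.approx(ref["F"][0])
        assert res.p == pytest.approx(ref["p_unc"][0])
        eta_ref = ref["SS"][0] / (ref["SS"][0] + ref["SS"][1])
        assert res.effect_size == pytest.approx(eta_ref)

    def test_too_small_rejected(self, rng):
        with pytest.raises(StatsError):
            rm_anova(rng.uniform(0, 1, (1, 3)))


class TestWithinBetweenTest:
    @staticmethod
    def _table(within, between):
        rows = []
        for i, v in enumerate(within):
            rows.append(dict(subject=f"S{i % 8}", kind="within", key="BL-FU1",
                             metric="ks_d", value=v))
        for i, v in enumerate(between):
            rows.append(dict(subject=f"S{i % 8}", kind="between", key="BL",
                             metric="ks_d", value=v))
        return pd.DataFrame(rows)

    def test_df_46_for_eight_subjects(self, rng):
        table = self._table(rng.uniform(0, 1, 24), rng.uniform(0, 1, 24))
        assert compare_within_between(table, "ks_d").df == 46

    def test_identical_groups(self, rng):
        vals = rng.uniform(0, 1, 24)
        res = compare_within_between(self._table(vals, vals), "ks_d")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        within = 0.9 + 0.001 * rng.standard_normal(24)
        between = 0.1 + 0.001 * rng.standard_normal(24)
        res = compare_within_between(self._table(within, between), "ks_d")
        assert res.p < 0.001
        assert res.statistic > 0

    def test_zero_pooled_variance_rejected(self):
        table = self._table(np.full(24, 0.9), np.full(24, 0.1))
        with pytest.raises(StatsError, match="pooled"):
            compare_within_between(table, "ks_d")


class TestPairedT:
    def test_equal_samples(self, rng):
        a = rng.uniform(0, 1, 8)
        res = paired_t(a, a.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_df_is_n_minus_one(self, rng):
        res = paired_t(rng.uniform(0, 1, 8), rng.uniform(0, 1, 8))
        assert res.df == 7

    def test_constant_shift_degenerate(self, rng):
        b = rng.uniform(0, 1, 8)
        with pytest.raises(StatsError, match="degenerate"):
            paired_t(b + 0.3, b)


class TestRoiwiseMap:
    def test_identical_matrices_all_ones(self, rng):
        a = _random_conn(rng, n=20)
        out = roiwise_consistency_map(a, a)
        assert out.shape == (20,)
        assert np.allclose(out, 1.0)

    def test_shuffled_row_localized(self, rng):
        # permutation oracle: shuffling one ROI's connections kills only
        # that ROI's consistency
        a = _random_conn(rng, n=30)
        v = a.values.copy()
        perm = rng.permutation(29)
        keep = np.arange(30) != 7
        v[7, keep] = v[7, keep][perm]
        v[keep, 7] = v[7, keep]
        b = ConnectivityMatrix(values=v, band=a.band, n_epochs=1)
        out = roiwise_consistency_map(a, b)
        assert abs(out[7]) < 0.5
        others = out[np.arange(30) != 7]
        assert others.min() > 0.8
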