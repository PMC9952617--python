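"""Welch tests, differential-peak discovery, Fisher and logistic statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.stats import hypergeom

from sersstroma import (
    DataError,
    WavenumberAxis,
    differential_peaks,
    fisher_exact,
    logistic_or,
    patient_means,
    welch_test,
)
from sersstroma.annotate import TaggedSpectrumTable
from sersstroma.diffstats import PatientSpectrumMatrix


def _table(patient_id, tags, spectra, axis):
    n = len(tags)
    return TaggedSpectrumTable(
        x=np.arange(n), y=np.zeros(n, dtype=int),
        tags=np.asarray(tags, dtype=object),
        spectra=np.asarray(spectra, dtype=float),
        wavenumbers=axis.values, patient_id=patient_id,
    )


class TestPatientMeans:
    def test_single_record_patient_mean_is_that_spectrum(self):
        axis = WavenumberAxis(300, 310, 2)
        spec = np.arange(len(axis), dtype=float)[None, :]
        t = _table("P1", ["cancer_stroma"], spec, axis)
        m = patient_means([t], "stroma", diagnoses={"P1": "IBC"})
        assert np.array_equal(m.values[0], spec[0])

    def test_two_identical_records_mean_is_the_record(self):
        axis = WavenumberAxis(300, 310, 2)
        spec = np.full(len(axis), 3.5)
        t = _table("P1", ["cancer_stroma", "dcis_stroma"], [spec, spec], axis)
        m = patient_means([t], "stroma", diagnoses={"P1": "DCIS"})
        assert np.allclose(m.values[0], spec)

    def test_matches_bruteforce_per_channel_mean(self):
        axis = WavenumberAxis(300, 340, 2)
        rng = np.random.default_rng(4)
        tags = rng.choice(["cancer_stroma", "cancer_nest", "fat"], size=20)
        spectra = rng.random((20, len(axis)))
        t = _table("P1", tags, spectra, axis)
        m = patient_means([t], "stroma", diagnoses={"P1": "IBC"})
        keep = tags == "cancer_stroma"
        expected = np.array([spectra[keep, j].mean() for j in range(len(axis))])
        assert np.allclose(m.values[0], expected)

    def test_patient_without_matching_records_excluded_with_warning(self):
        axis = WavenumberAxis(300, 310, 2)
        t1 = _table("P1", ["cancer_stroma"], np.ones((1, len(axis))), axis)
        t2 = _table("P2", ["fat"], np.ones((1, len(axis))), axis)
        with pytest.warns(RuntimeWarning, match="P2"):
            m = patient_means([t1, t2], "stroma", diagnoses={"P1": "IBC", "P2": "DCIS"})
        assert m.patient_ids == ["P1"]


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_shifted_group_strongly_significant(self):
        res = welch_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p < 0.01 and res.t < 0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 15)
        r1, r2 = welch_test(a, b), welch_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.df == pytest.approx(r2.df)

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            welch_test([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means_convention(self):
        res = welch_test([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_reference_on_thousand_random_instances(self):
        """Agreement with an independent reference implementation to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            na, nb = rng.integers(2, 30, 2)
            a = rng.normal(rng.normal(), abs(rng.normal()) + 0.1, na)
            b = rng.normal(rng.normal(), abs(rng.normal()) + 0.1, nb)
            mine = welch_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert abs(mine.t - ref.statistic) < 1e-10
            assert abs(mine.p - ref.pvalue) < 1e-10
            assert abs(mine.df - ref.df) < 1e-8


def _synthetic_matrix(rng, n_d=14, n_i=32, n_chan=100, effects=None):
    """Patient matrix of iid noise plus optional {channel: diff} effects."""
    wn = 300 + 2.0 * np.arange(n_chan)
    vals = rng.normal(0, 1, (n_d + n_i, n_chan))
    diags = np.array(["DCIS"] * n_d + ["IBC"] * n_i, dtype=object)
    if effects:
        for ch, diff in effects.items():
            vals[:n_d, ch] += diff
    ids = [f"P{i}" for i in range(n_d + n_i)]
    return PatientSpectrumMatrix(vals, ids, diags, wn)


class TestDifferentialPeaks:
    def test_single_injected_band_found_with_direction(self):
        """A strong IBC-elevated Lorentzian band yields one I peak at its center."""
        rng = np.random.default_rng(5)
        n_chan = 200
        wn = 300 + 2.0 * np.arange(n_chan)
        center = 480.0
        profile = 16.0 / ((wn - center) ** 2 + 16.0)
        vals = rng.normal(0, 1, (46, n_chan))
        vals[14:] += 8.0 * profile  # IBC patients elevated
        m = PatientSpectrumMatrix(
            vals, [f"P{i}" for i in range(46)],
            np.array(["DCIS"] * 14 + ["IBC"] * 32, dtype=object), wn)
        rep = differential_peaks(m, alpha=0.05)
        assert rep.n_peaks == 1
        peak = rep.peaks.iloc[0]
        assert abs(peak.wavenumber - center) <= 2.0
        assert peak.dominance == "I"

    def test_null_significant_channel_fraction_near_alpha(self):
        """Type-I control: ~alpha of null channels flagged, 200 replicates."""
        rng = np.random.default_rng(6)
        fractions = []
        for _ in range(200):
            m = _synthetic_matrix(rng, n_d=7, n_i=9, n_chan=100)
            rep = differential_peaks(m, alpha=0.05)
            fractions.append(rep.channels["significant"].mean())
        mean_frac = float(np.mean(fractions))
        # binomial tolerance around alpha
        assert abs(mean_frac - 0.05) < 0.01

    def test_dcis_direction_labelled_d(self):
        rng = np.random.default_rng(7)
        n_chan = 100
        wn = 300 + 2.0 * np.arange(n_chan)
        profile = 16.0 / ((wn - 400.0) ** 2 + 16.0)
        vals = rng.normal(0, 1, (46, n_chan))
        vals[:14] += 8.0 * profile  # DCIS elevated
        m = PatientSpectrumMatrix(
            vals, [f"P{i}" for i in range(46)],
            np.array(["DCIS"] * 14 + ["IBC"] * 32, dtype=object), wn)
        rep = differential_peaks(m)
        assert (rep.peaks["dominance"] == "D").all()

    def test_single_class_matrix_rejected(self):
        rng = np.random.default_rng(8)
        m = _synthetic_matrix(rng, n_d=0, n_i=10)
        with pytest.raises(DataError):
            differential_peaks(m)


def _fisher_p_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_diagonal_table_highly_significant(self):
        or_, p = fisher_exact([[14, 0], [0, 32]])
        assert p < 0.001
        assert p == pytest.approx(_fisher_p_oracle([[14, 0], [0, 32]]), rel=1e-9)

    def test_symmetric_table_is_null(self):
        or_, p = fisher_exact([[5, 5], [5, 5]])
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_metastasis_row_with_empty_class_gives_p_one(self):
        """All 46 patients M0 (14 DCIS vs 32 IBC), none M1: no association."""
        or_, p = fisher_exact([[14, 32], [0, 0]])
        assert p == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 25), min_size=4, max_size=4))
    def test_matches_enumeration_oracle_and_swap_invariance(self, cells):
        table = np.array(cells).reshape(2, 2)
        if table.sum() == 0:
            return
        _, p = fisher_exact(table)
        assert p == pytest.approx(_fisher_p_oracle(table), rel=1e-7, abs=1e-12)
        for swapped in (table[::-1], table[:, ::-1], table.T):
            _, p2 = fisher_exact(swapped)
            assert p2 == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[1, -2], [3, 4]])


class TestLogisticOr:
    def test_null_predictor_ci_covers_one(self):
        """Permuted labels: 95% CI covers OR=1 in >= 90% of 50 replicates."""
        rng = np.random.default_rng(9)
        covered = 0
        for _ in range(50):
            x = rng.normal(0, 1, 200)
            y = rng.permutation(np.repeat([0, 1], 100))
            row = logistic_or(x, y).iloc[0]
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert covered >= 45

    def test_perfect_separation_rejected(self):
        y = np.repeat([0, 1], 20)
        x = y.astype(float)
        with pytest.raises(DataError, match="separation"):
            logistic_or(x, y)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 300)
        logit = 1.5 * x - 0.2
        y = (rng.random(300) < 1 / (1 + np.exp(-logit))).astype(int)
        row = logistic_or(x, y).iloc[0]
        assert row.odds_ratio > 1 and row.p < 0.05

    def test_covariate_adjustment_returns_all_predictors(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 200)
        age = rng.normal(60, 8, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.8 * x)))).astype(int)
        res = logistic_or(x, y, covariates=pd.DataFrame({"age": age}))
        assert list(res.predictor) == ["band", "age"]

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 100)
        y = (rng.random(100) < 0.5).astype(int)
        with pytest.raises(DataError, match="collinear"):
            logistic_or(x, y, covariates=pd.DataFrame({"dup": 2 * x}))
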