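"""Correction-function ensembles: combinatorics, OLS fits, flagging, recovery."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidccs.bias import MatchedPair, MeasuredIon, match_to_library, mean_measured
from lipidccs.correction import (
    CorrectionFunction,
    DegenerateFitError,
    apply_correction,
    correct_dataset,
    eligible_groups,
    enumerate_subsets,
    fit_correction,
    flag_poor_functions,
    n_subsets,
)
from lipidccs.library import LibraryEntry
from lipidccs.lipids import get_adduct, parse_lipid_name


def _pair(name, measured_ccs, reference_ccs, adduct="[M+H]+"):
    species = parse_lipid_name(name, labeled=True)
    return MatchedPair(
        measured=MeasuredIon(
            file_id="f1",
            species=species,
            adduct=get_adduct(adduct),
            measured_mz=700.0,
            rt=5.0,
            ccs_measured=measured_ccs,
        ),
        reference=LibraryEntry(
            species=species,
            adduct=get_adduct(adduct),
            theoretical_mz=700.0,
            dtccs=reference_ccs,
            ccs_rsd=0.2,
            n_detections=3,
        ),
    )


class TestEligibility:
    def test_minimum_of_three_labeled_lipids(self):
        two = [_pair(f"PC 3{i}:0", 260.0 + i, 261.0 + i) for i in (0, 2)]
        three = [_pair(f"PE 3{i}:1", 255.0 + i, 256.0 + i) for i in (0, 2, 4)]
        groups = eligible_groups(two + three)
        assert groups == [("PE", "[M+H]+", 3)]

    def test_empty(self):
        assert eligible_groups([]) == []


class TestSubsetEnumeration:
    @pytest.mark.parametrize("n,expected", [(3, 1), (4, 5), (6, 42), (7, 98)])
    def test_full_enumeration_below_cap(self, n, expected):
        ids = [f"L{i}" for i in range(n)]
        subsets = enumerate_subsets(ids, seed=0)
        assert len(subsets) == expected
        assert len(set(subsets)) == expected  # all distinct
        assert all(3 <= len(s) <= 6 for s in subsets)

    def test_cap_applies_when_space_is_larger(self):
        ids = [f"L{i}" for i in range(10)]  # C(10,3..6) = 792 > 100
        subsets = enumerate_subsets(ids, seed=5)
        assert len(subsets) == 100
        assert len(set(subsets)) == 100

    def test_ensemble_size_formula(self):
        for n in range(3, 15):
            ids = [f"L{i}" for i in range(n)]
            expected = min(100, sum(math.comb(n, k) for k in range(3, min(6, n) + 1)))
            assert len(enumerate_subsets(ids, seed=1)) == expected
            assert n_subsets(n) == sum(math.comb(n, k) for k in range(3, min(6, n) + 1))

    def test_deterministic_for_fixed_seed(self):
        ids = [f"L{i}" for i in range(12)]
        assert enumerate_subsets(ids, seed=11) == enumerate_subsets(ids, seed=11)
        assert enumerate_subsets(ids, seed=11) != enumerate_subsets(ids, seed=12)

    def test_subsets_are_subsets_of_ids(self):
        ids = [f"L{i}" for i in range(9)]
        for s in enumerate_subsets(ids, seed=2):
            assert set(s) <= set(ids)
            assert len(set(s)) == len(s)

    def test_too_few_ids_raises(self):
        with pytest.raises(ValueError):
            enumerate_subsets(["a", "b"])


class TestFitting:
    def test_exact_affine_recovery(self):
        """Three collinear points: ref = 1.02 * meas - 3.0 recovered exactly."""
        xs = [250.0, 260.0, 275.0]
        pairs = [_pair(f"PC 3{i}:0", x, 1.02 * x - 3.0) for i, x in enumerate(xs)]
        fn = fit_correction(pairs)
        assert fn.slope == pytest.approx(1.02, abs=1e-9)
        assert fn.intercept == pytest.approx(-3.0, abs=1e-7)
        assert fn.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_statsmodels_oracle(self):
        """Coefficients equal an independent OLS (statsmodels) on random data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            x = 250.0 + rng.uniform(0, 40, n)
            y = rng.uniform(0.9, 1.1) * x + rng.normal(0, 1.0, n)
            pairs = [
                _pair(f"PC {30 + 2 * i}:0", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))
            ]
            fn = fit_correction(pairs)
            oracle = sm.OLS(y, sm.add_constant(x)).fit()
            assert fn.intercept == pytest.approx(oracle.params[0], rel=1e-9, abs=1e-9)
            assert fn.slope == pytest.approx(oracle.params[1], rel=1e-9)
            assert fn.r_squared == pytest.approx(oracle.rsquared, rel=1e-6, abs=1e-9)

    def test_constant_predictor_is_degenerate(self):
        pairs = [_pair(f"PC 3{i}:0", 250.0, 250.0 + i) for i in range(3)]
        with pytest.raises(DegenerateFitError):
            fit_correction(pairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_residual_is_zero_on_fitting_subset(self, seed):
        """OLS with intercept: signed residuals sum to zero."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        x = 200.0 + rng.uniform(0, 100, n)
        if np.ptp(x) == 0:  # pragma: no cover
            return
        y = 1.01 * x - 2.0 + rng.normal(0, 0.5, n)
        pairs = [_pair(f"PC {30 + 2 * i}:0", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
        fn = fit_correction(pairs)
        residuals = y - (fn.slope * x + fn.intercept)
        assert abs(residuals.mean()) < 1e-8


class TestApplicationAndFlagging:
    def test_identity_function(self):
        fn = CorrectionFunction("PC", "[M+H]+", frozenset("abc"), 1.0, 0.0, 1.0, 3, 1)
        assert apply_correction(fn, 250.0) == 250.0

    def test_affine_application(self):
        fn = CorrectionFunction("PC", "[M+H]+", frozenset("abc"), 1.02, -3.0, 1.0, 3, 1)
        assert apply_correction(fn, 250.0) == pytest.approx(252.0)

    def test_positive_slope_preserves_order(self):
        fn = CorrectionFunction("PC", "[M+H]+", frozenset("abc"), 1.02, -3.0, 1.0, 3, 1)
        assert apply_correction(fn, 250.0) < apply_correction(fn, 251.0)

    @pytest.mark.parametrize(
        "slope,expect_flag", [(2.42, True), (0.46, True), (0.01, True), (1.00, False)]
    )
    def test_slope_flagging(self, slope, expect_flag):
        """The published poor functions (slopes 0.01/0.46/2.42) are flagged."""
        fn = CorrectionFunction("PC", "[M+H]+", frozenset("abc"), slope, 0.0, 1.0, 3, 1)
        (out,) = flag_poor_functions([fn])
        assert out.flagged is expect_flag

    def test_r2_flagging(self):
        fn = CorrectionFunction("PC", "[M+H]+", frozenset("abc"), 1.0, 0.0, 0.5, 3, 1)
        (out,) = flag_poor_functions([fn])
        assert out.flagged and "r2" in out.flag_reason


class TestEndToEnd:
    def test_exact_affine_bias_recovered_by_every_function(self, noise_free_sim):
        """Noise-free bias (1.01, -2.0): every function recovers it exactly
        and every after-correction bias is zero."""
        results = correct_dataset(
            noise_free_sim.measured, noise_free_sim.library, mode="mean", seed=0
        )
        assert results
        for g in results:
            for fn in g.functions:
                assert fn.slope == pytest.approx(1.01, abs=1e-9)
                assert fn.intercept == pytest.approx(-2.0, abs=1e-6)
                assert not fn.flagged
            for b in g.after_biases:
                assert abs(b) < 1e-9

    def test_measured_equals_reference_identity(self, clean_sim):
        """Bias-free measured data yields identity fits and zero bias."""
        ions = [
            MeasuredIon(
                file_id="f1",
                species=e.species,
                adduct=e.adduct,
                measured_mz=e.theoretical_mz,
                rt=5.0,
                ccs_measured=e.dtccs,
            )
            for e in clean_sim.library.entries
        ]
        results = correct_dataset(ions, clean_sim.library, mode="per-file", seed=0)
        for g in results:
            assert all(abs(b) < 1e-9 for b in g.before_biases)
            assert all(abs(b) < 1e-9 for b in g.after_biases)

    def test_noisy_after_bias_vanishes_on_fitting_subset(self, clean_sim):
        """At 0.2% noise each function's mean after-bias over its own fitting
        subset is ~0 (the OLS residuals cancel), and the pooled group mean
        stays within 3 * (0.2% / sqrt(n_standards)) of zero."""
        from lipidccs.bias import ccs_bias_percent
        from lipidccs.correction import apply_correction

        results = correct_dataset(clean_sim.measured, clean_sim.library, mode="mean", seed=0)
        sd = 0.2 / math.sqrt(3)  # averaging over n_files shrinks the noise
        for g in results:
            pairs_by_name = {}
            for lip in g.lipids:
                if lip.labeled:
                    pairs_by_name[lip.lipid_name] = lip
            for fn in g.functions:
                subset_biases = []
                for name in fn.subset_ids:
                    lip = pairs_by_name[name]
                    corrected = apply_correction(fn, lip.ccs_input)
                    ref = lip.ccs_input * (1 + lip.bias_before / 100) ** -1
                    subset_biases.append(ccs_bias_percent(corrected, ref))
                assert abs(statistics.fmean(subset_biases)) < 0.01
            n = len(g.before_biases)
            assert abs(statistics.fmean(g.after_biases)) < 3 * sd / math.sqrt(n)

    def test_unlabeled_lipids_are_corrected_too(self, clean_sim):
        results = correct_dataset(clean_sim.measured, clean_sim.library, mode="mean", seed=0)
        labels = {lip.labeled for g in results for lip in g.lipids}
        assert labels == {True, False}
        for g in results:
            n_usable = sum(not fn.flagged for fn in g.functions)
            for lip in g.lipids:
                assert len(lip.corrected) == n_usable
                assert lip.point_estimate == statistics.median(lip.corrected)

    def test_bitwise_determinism(self, clean_sim):
        r1 = correct_dataset(clean_sim.measured, clean_sim.library, mode="mean", seed=9)
        r2 = correct_dataset(clean_sim.measured, clean_sim.library, mode="mean", seed=9)
        f1 = [(f.slope, f.intercept, f.subset_ids) for g in r1 for f in g.functions]
        f2 = [(f.slope, f.intercept, f.subset_ids) for g in r2 for f in g.functions]
        assert f1 == f2
        c1 = [lip.corrected for g in r1 for lip in g.lipids]
        c2 = [lip.corrected for g in r2 for lip in g.lipids]
        assert c1 == c2

    def test_parameter_recovery_unbiased(self):
        """Fitted slopes/intercepts are unbiased across an ensemble for
        truth slope in [0.95, 1.05], intercept in [-5, 5], 0.2% noise."""
        rng = np.random.default_rng(202)
        slope_err, intercept_err = [], []
        for rep in range(200):
            s = float(rng.uniform(0.95, 1.05))
            b = float(rng.uniform(-5, 5))
            n = int(rng.integers(3, 7))
            x = np.sort(250.0 + rng.uniform(0, 40, n))
            if np.ptp(x) < 1.0:
                continue
            y_true = s * x + b
            y = y_true + rng.normal(0, 0.002 * y_true)
            fn = fit_correction(
                [_pair(f"PC {30 + 2 * i}:0", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
            )
            slope_err.append(fn.slope - s)
            intercept_err.append(fn.intercept - b)
        # mean error within 2 standard errors of zero
        for errs in (np.array(slope_err), np.array(intercept_err)):
            se = errs.std(ddof=1) / math.sqrt(len(errs))
            assert abs(errs.mean()) <= 2 * se
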