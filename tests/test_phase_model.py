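"""Harmonic phase model: centering, DFT decomposition, pooled regression,
amplitude/phase extraction, alignment, bootstrap and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phasemod import phase_model as pm
from phasemod import synthgen
from phasemod.errors import IncompleteDesignError, InvalidInputError

from conftest import make_cohort_from_deltas

PHASES = (0.0, 90.0, 180.0, 270.0)


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

class TestCenterScores:
    def test_worked_example(self):
        cohort = make_cohort_from_deltas([(0.0, 5.0, -2.0, -3.0)])
        cent = pm.center_scores(cohort, "target")
        assert cent["cs_mean"].iloc[0] == pytest.approx(50.0)
        assert cent["delta_cs"].to_numpy() == pytest.approx([0.0, 5.0, -2.0, -3.0])

    def test_constant_scores_center_to_zero(self):
        cohort = make_cohort_from_deltas([(0.0, 0.0, 0.0, 0.0)])
        cent = pm.center_scores(cohort, "target")
        assert np.all(cent["delta_cs"] == 0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(
        st.lists(st.floats(min_value=0, max_value=100), min_size=4, max_size=4),
        min_size=1, max_size=6,
    ))
    def test_per_subject_deltas_sum_to_zero(self, raw_scores):
        rows = []
        for s, scores in enumerate(raw_scores):
            for phase, cs in zip(PHASES, scores):
                rows.append({"subject_id": f"S{s}", "source": "target",
                             "phase_deg": phase, "n_keywords": 100,
                             "n_correct": cs})
        cent = pm.center_scores(pd.DataFrame(rows), "target")
        sums = cent.groupby("subject_id")["delta_cs"].sum()
        assert np.allclose(sums, 0.0, atol=1e-10)

    def test_missing_phase_rejected(self, study_cohort):
        broken = study_cohort[
            ~((study_cohort["subject_id"] == "S01")
              & (study_cohort["phase_deg"] == 90.0)
              & (study_cohort["source"] == "target"))
        ]
        with pytest.raises(IncompleteDesignError):
            pm.center_scores(broken, "target")

    def test_out_of_range_scores_rejected(self, study_cohort):
        broken = study_cohort.copy()
        broken.loc[broken.index[0], "n_correct"] = 200
        with pytest.raises(InvalidInputError):
            pm.validate_scores(broken)


# ---------------------------------------------------------------------------
# DFT decomposition
# ---------------------------------------------------------------------------

class TestDftCoefficients:
    def test_pure_cosine(self):
        c = pm.dft_coefficients([3.0, 0.0, -3.0, 0.0])
        assert c.a0 == pytest.approx(0.0, abs=1e-12)
        assert c.a1 == pytest.approx(1.5 + 0j, abs=1e-12)
        assert c.a2 == pytest.approx(0.0, abs=1e-12)
        assert c.A1 == pytest.approx(3.0)
        assert c.phi1_deg == pytest.approx(0.0, abs=1e-10)

    def test_zero_vector(self):
        c = pm.dft_coefficients([0.0, 0.0, 0.0, 0.0])
        assert c.a0 == 0 and c.a1 == 0 and c.a2 == 0 and c.A1 == 0

    def test_mixed_harmonics(self):
        c = pm.dft_coefficients([1.0, 2.0, -1.0, -2.0])
        assert c.a0 == pytest.approx(0.0, abs=1e-12)
        assert c.a1 == pytest.approx(0.5 - 1.0j, abs=1e-12)
        assert c.a2 == pytest.approx(0.0, abs=1e-12)
        assert c.A1 == pytest.approx(np.sqrt(5), abs=1e-12)
        assert c.B1 == pytest.approx(2.0) and c.B2 == pytest.approx(1.0)

    def test_conjugate_symmetry(self):
        c = pm.dft_coefficients([4.0, -1.0, 2.5, -5.5])
        assert c.a3 == np.conj(c.a1)

    def test_inverse_relation_reproduces_input(self):
        delta = np.array([4.0, -1.0, 2.5, -5.5])
        c = pm.dft_coefficients(delta)
        phases = np.radians(PHASES)
        recon = (c.a0 + c.a1 * np.exp(1j * phases)
                 + c.a2 * np.exp(2j * phases) + c.a3 * np.exp(3j * phases))
        assert np.allclose(recon.imag, 0.0, atol=1e-12)
        assert np.allclose(recon.real, delta, atol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidInputError):
            pm.dft_coefficients([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# amplitude and phase extraction
# ---------------------------------------------------------------------------

class TestAmplitudePhase:
    @pytest.mark.parametrize("b1,b2,a1,phi1", [
        (0.0, 3.0, 3.0, 0.0),       # target-envelope pattern: peak at 0 deg
        (0.0, -1.6, 1.6, 180.0),    # distractor pattern: peak at 180 deg
        (2.0, 1.0, np.sqrt(5), np.degrees(np.arctan2(2, 1))),
    ])
    def test_known_mappings(self, b1, b2, a1, phi1):
        A1, p1 = pm.amplitude_phase(b1, b2)
        assert A1 == pytest.approx(a1)
        assert p1 == pytest.approx(phi1)

    def test_cosine_form_reproduces_sine_cosine_sum(self):
        b1, b2 = 2.0, 1.0
        A1, phi1 = pm.amplitude_phase(b1, b2)
        phis = np.radians(PHASES)
        model = A1 * np.cos(phis - np.radians(phi1))
        direct = b1 * np.sin(phis) + b2 * np.cos(phis)
        assert np.allclose(model, direct, atol=1e-12)
        assert np.allclose(model, [1.0, 2.0, -1.0, -2.0], atol=1e-12)


# ---------------------------------------------------------------------------
# harmonic regression
# ---------------------------------------------------------------------------

class TestFitHarmonic:
    def test_exact_cosine_cohort(self):
        deltas = [3.0 * np.cos(np.radians(PHASES))] * 6
        fit = pm.fit_harmonic(pm.center_scores(make_cohort_from_deltas(deltas),
                                               "target"), "ols")
        est = fit.coef["estimate"]
        assert est["B2"] == pytest.approx(3.0, abs=1e-10)
        assert est["B1"] == pytest.approx(0.0, abs=1e-10)
        assert est["A2"] == pytest.approx(0.0, abs=1e-10)
        assert est["A0"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_mixed_harmonics_cohort_matches_dft(self):
        deltas = [(1.0, 2.0, -1.0, -2.0)] * 5
        fit = pm.fit_harmonic(pm.center_scores(make_cohort_from_deltas(deltas),
                                               "target"), "ols")
        est = fit.coef["estimate"]
        assert est["B1"] == pytest.approx(2.0, abs=1e-10)
        assert est["B2"] == pytest.approx(1.0, abs=1e-10)
        assert est["A2"] == pytest.approx(0.0, abs=1e-10)

    def test_dft_regression_equivalence_on_noisy_cohorts(self):
        for seed in range(10):
            scores = synthgen.generate_cohort(synthgen.CohortParams(seed=seed))
            cent = pm.center_scores(scores, "distractor")
            fit = pm.fit_harmonic(cent, "ols")
            mean_delta = (cent.groupby("phase_deg")["delta_cs"].mean()
                          .reindex(list(PHASES)).to_numpy())
            c = pm.dft_coefficients(mean_delta)
            est = fit.coef["estimate"]
            assert est["A0"] == pytest.approx(c.a0, abs=1e-8)
            assert est["B1"] == pytest.approx(c.B1, abs=1e-8)
            assert est["B2"] == pytest.approx(c.B2, abs=1e-8)
            assert est["A2"] == pytest.approx(c.a2, abs=1e-8)

    def test_single_subject_fit_interpolates(self):
        cohort = make_cohort_from_deltas([(4.0, -1.0, 2.5, -5.5)])
        cent = pm.center_scores(cohort, "target")
        fit = pm.fit_harmonic(cent, "ols")
        X = pm.harmonic_design(cent["phase_deg"].to_numpy(), aligned=False)
        resid = cent["delta_cs"].to_numpy() - X @ fit.coef["estimate"].to_numpy()
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_intercept_vanishes_on_centered_cohorts(self, centered_target):
        fit = pm.fit_harmonic(centered_target, "ols")
        assert abs(fit.coef.loc["A0", "estimate"]) < 1e-10

    def test_fdr_adjustment_monotone(self, centered_target):
        fit = pm.fit_harmonic(centered_target, "ols")
        raw = fit.coef["p_raw"].to_numpy()
        adj = fit.coef["p_fdr"].to_numpy()
        assert np.all(adj >= raw - 1e-15)
        # BH preserves the ordering of the p-values
        assert np.array_equal(np.argsort(raw), np.argsort(adj, kind="stable"))

    def test_robust_close_to_ols_without_outliers(self):
        # bisquare has ~95% Gaussian efficiency: agreement is statistical,
        # not exact, at the binomial noise level of the study design
        diffs = []
        for seed in range(20):
            cent = pm.center_scores(
                synthgen.generate_cohort(synthgen.CohortParams(seed=seed)),
                "target")
            fo = pm.fit_harmonic(cent, "ols")
            fr = pm.fit_harmonic(cent, "robust")
            diffs.append(np.max(np.abs(fo.coef["estimate"].to_numpy()
                                       - fr.coef["estimate"].to_numpy())))
        assert np.mean(diffs) < 0.35
        assert np.max(diffs) < 1.0

    def test_robust_matches_ols_exactly_at_low_noise(self):
        params = synthgen.CohortParams(seed=0, n_keywords=100_000, subject_sd=0.0)
        cent = pm.center_scores(synthgen.generate_cohort(params), "target")
        fo = pm.fit_harmonic(cent, "ols")
        fr = pm.fit_harmonic(cent, "robust")
        assert np.allclose(fo.coef["estimate"], fr.coef["estimate"], atol=0.02)

    def test_aligned_fit_has_no_a2_term(self, study_cohort):
        aligned = pm.align_to_best_phase(study_cohort, "target")
        fit = pm.fit_harmonic(aligned, "ols", aligned=True)
        assert list(fit.coef.index) == ["A0", "B1", "B2"]
        assert fit.aligned


# ---------------------------------------------------------------------------
# best-phase alignment
# ---------------------------------------------------------------------------

class TestAlignment:
    def test_worked_example(self):
        cohort = make_cohort_from_deltas([(0.0, 5.0, -2.0, -3.0)])
        best = pm.best_phase_per_subject(cohort, "target")
        assert best.iloc[0] == 90.0
        aligned = pm.align_to_best_phase(cohort, "target")
        vals = aligned.set_index("phase_deg")["delta_cs"]
        assert vals[90.0] == pytest.approx(-2.0)   # absolute 180
        assert vals[180.0] == pytest.approx(-3.0)  # absolute 270
        assert vals[270.0] == pytest.approx(0.0)   # absolute 0

    def test_flat_scores_tie_break_to_zero(self):
        cohort = make_cohort_from_deltas([(0.0, 0.0, 0.0, 0.0)])
        assert pm.best_phase_per_subject(cohort, "target").iloc[0] == 0.0

    def test_phase_locked_cohort_recovers_shape_exactly(self):
        # every subject peaks at its own phase with an identical shape
        shape = 4.0 * np.cos(np.radians(PHASES))
        deltas = [np.roll(shape, k) for k in range(4)]
        cohort = make_cohort_from_deltas(deltas)
        aligned = pm.align_to_best_phase(cohort, "target")
        fit = pm.fit_harmonic(aligned, "ols", aligned=True)
        assert fit.r2 == pytest.approx(1.0)
        # every subject contributes the same aligned values (0, -4, 0), and
        # the saturated three-parameter fit interpolates them exactly
        per_phase = aligned.groupby("phase_deg")["delta_cs"].agg(["nunique", "first"])
        assert (per_phase["nunique"] == 1).all()
        assert per_phase["first"].to_numpy() == pytest.approx([0.0, -4.0, 0.0])
        X = pm.harmonic_design(aligned["phase_deg"].to_numpy(), aligned=True)
        resid = aligned["delta_cs"].to_numpy() - X @ fit.coef["estimate"].to_numpy()
        assert np.allclose(resid, 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# bootstrap r2 comparison
# ---------------------------------------------------------------------------

class TestBootstrapCompare:
    def test_deterministic_under_seed(self, centered_target):
        a = pm.bootstrap_r2_compare(centered_target, n_boot=100, seed=3)
        b = pm.bootstrap_r2_compare(centered_target, n_boot=100, seed=3)
        assert a.p == b.p
        assert np.array_equal(a.r2_ols, b.r2_ols)

    def test_outliers_favor_robust(self, centered_target):
        dirty = synthgen.inject_outliers(centered_target, 0.10, 30.0, seed=7)
        comp = pm.bootstrap_r2_compare(dirty, n_boot=300, seed=1)
        assert comp.p < 0.01
        assert comp.r2_robust.mean() > comp.r2_ols.mean()

    def test_clean_gaussian_not_extreme(self):
        rng = np.random.default_rng(42)
        rows = []
        for s in range(18):
            vals = rng.normal(0, 4, 4)
            vals -= vals.mean()
            for ph, v in zip(PHASES, vals):
                rows.append({"subject_id": f"S{s}", "phase_deg": ph,
                             "delta_cs": v, "cs_mean": 50.0})
        comp = pm.bootstrap_r2_compare(pd.DataFrame(rows), n_boot=300, seed=1)
        assert comp.p > 0.001
        assert abs(comp.r2_robust.mean() - comp.r2_ols.mean()) < 0.02


# ---------------------------------------------------------------------------
# amplitude comparison and sham ANOVA
# ---------------------------------------------------------------------------

class TestComparisons:
    def test_identical_cohorts_give_null_difference(self, centered_target):
        comp = pm.compare_amplitudes(centered_target, centered_target,
                                     n_boot=100, seed=0)
        assert comp.diff == 0.0
        assert comp.p == pytest.approx(1.0)

    def test_known_amplitude_difference_recovered(self):
        scores = synthgen.generate_cohort(synthgen.CohortParams(seed=5))
        comp = pm.compare_amplitudes(
            pm.center_scores(scores, "target"),
            pm.center_scores(scores, "distractor"),
            method="ols", n_boot=400, seed=2,
        )
        assert abs(comp.diff - 1.4) < 2 * comp.se_diff

    @staticmethod
    def _three_group_table(noise):
        rows = []
        for src, phase in (("target", 0.0), ("distractor", 180.0),
                           ("sham", np.nan)):
            for s, v in enumerate(noise[src]):
                rows.append({"subject_id": f"S{s}", "source": src,
                             "phase_deg": phase, "n_keywords": 100,
                             "n_correct": 50 + v})
        return pd.DataFrame(rows)

    def test_sham_anova_identical_groups(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 4, 18)
        res = pm.compare_to_sham(self._three_group_table(
            {"target": v, "distractor": v, "sham": v}))
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)
        assert res.df_between == 2 and res.df_within == 51

    def test_sham_anova_detects_separation(self):
        rng = np.random.default_rng(1)
        res = pm.compare_to_sham(self._three_group_table(
            {"target": rng.normal(20, 0.5, 18),
             "distractor": rng.normal(0, 0.5, 18),
             "sham": rng.normal(0, 0.5, 18)}))
        assert res.p < 1e-6

    def test_sham_anova_unequal_groups_rejected(self, study_cohort):
        broken = study_cohort[study_cohort["subject_id"] != "S01"
                              ].copy()
        sham_back = study_cohort[(study_cohort["subject_id"] == "S01")
                                 & (study_cohort["source"] == "sham")]
        broken = pd.concat([broken, sham_back])
        with pytest.raises(IncompleteDesignError):
            pm.compare_to_sham(broken)
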