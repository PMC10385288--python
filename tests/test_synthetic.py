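"""Generator contracts: determinism, invariants, planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metabfuse import synthetic as syn


class TestLibrary:
    def test_deterministic_given_seed(self):
        a = syn.make_library(5, seed=1)
        b = syn.make_library(5, seed=1)
        assert [s.metabolite_id for s in a] == [s.metabolite_id for s in b]
        assert [s.peaks for s in a] == [s.peaks for s in b]

    def test_centers_avoid_reference_window(self):
        for sig in syn.make_library(50, seed=7):
            for c, h, w in sig.peaks:
                assert 0.2 < c < 10.0
                assert not (6.45 <= c <= 6.58)
                assert h > 0 and 0.0005 < w < 0.02

    def test_unique_ids(self):
        ids = [s.metabolite_id for s in syn.make_library(10, seed=3)]
        assert len(set(ids)) == 10

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            syn.make_library(0, seed=1)


class TestConcentrations:
    def test_unknown_affected_metabolite_raises(self, small_library):
        design = syn.StudyDesign([("A", 4), ("B", 4)], {"g": {"A": 0, "B": 1}}, seed=0)
        eff = syn.EffectSpec(affected={"nope": ("g", 1.0)})
        with pytest.raises(KeyError):
            syn.simulate_concentrations(design, small_library, eff)

    def test_deterministic_and_positive(self, small_library):
        design = syn.StudyDesign([("A", 4), ("B", 4)], {"g": {"A": 0, "B": 1}}, seed=5)
        t1 = syn.simulate_concentrations(design, small_library, syn.EffectSpec())
        t2 = syn.simulate_concentrations(design, small_library, syn.EffectSpec())
        pd.testing.assert_frame_equal(t1.concentrations, t2.concentrations)
        assert (t1.concentrations > 0).all().all()

    def test_null_type_one_error_near_alpha(self):
        """With no planted effects, a two-sample t-test on one metabolite
        rejects at the nominal 5% rate (Monte Carlo over 1000 seeds)."""
        lib = syn.make_library(1, seed=0)
        rejections = 0
        n_rep = 1000
        for s in range(n_rep):
            design = syn.StudyDesign(
                [("A", 8), ("B", 8)], {"g": {"A": 0, "B": 1}}, seed=s
            )
            truth = syn.simulate_concentrations(design, lib, syn.EffectSpec(), sigma=0.3)
            x = np.log(truth.concentrations["M01"].to_numpy())
            _, p = sps.ttest_ind(x[:8], x[8:])
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.02

    def test_planted_effect_magnitude(self):
        """Arm-mean log difference lands within 3 SE of the planted 1.0."""
        lib = syn.make_library(3, seed=2)
        design = syn.StudyDesign([("A", 8), ("B", 8)], {"g": {"A": 0, "B": 1}}, seed=9)
        eff = syn.EffectSpec(affected={"M01": ("g", 1.0)})
        truth = syn.simulate_concentrations(design, lib, eff, sigma=0.3)
        logc = np.log(truth.concentrations["M01"].to_numpy())
        diff = logc[8:].mean() - logc[:8].mean()
        se = 0.3 * np.sqrt(2 / 8)
        assert abs(diff - 1.0) < 3 * se

    def test_effect_recovered_in_most_replicates(self):
        """Planted 1.0 log-unit effect at sigma 0.3, n=8/arm is detected
        (t-test p < 0.05) in at least 95 of 100 seeded replicates."""
        lib = syn.make_library(2, seed=4)
        eff = syn.EffectSpec(affected={"M01": ("g", 1.0)})
        hits = 0
        for s in range(100):
            design = syn.StudyDesign(
                [("A", 8), ("B", 8)], {"g": {"A": 0, "B": 1}}, seed=s
            )
            truth = syn.simulate_concentrations(design, lib, eff, sigma=0.3)
            x = truth.concentrations["M01"].to_numpy()
            _, p = sps.ttest_ind(x[:8], x[8:])
            hits += p < 0.05
        assert hits >= 95


class TestRenderSpectra:
    def test_noise_free_single_peak_is_lorentzian_plus_reference(self):
        lib = [syn.SpectralSignature("M01", [(2.0, 1.0, 0.003)])]
        design = syn.StudyDesign([("A", 3)], {"g": {"A": 0}}, seed=1)
        truth = syn.simulate_concentrations(design, lib, syn.EffectSpec(), sigma=0.0)
        spectra = syn.render_spectra(
            truth, lib, jitter_ppm=0.0, noise_sd=0.0, nuisance=False, seed=0
        )
        s = spectra[0]
        conc = truth.concentrations.iloc[0, 0]
        expected = conc / (1 + ((s.ppm - 2.0) / 0.003) ** 2) + 5.0 / (
            1 + ((s.ppm - 6.5) / 0.002) ** 2
        )
        np.testing.assert_allclose(s.intensity, expected, atol=1e-12)

    def test_reference_apex_within_jitter_bound(self, two_arm_truth):
        lib, truth = two_arm_truth
        spectra = syn.render_spectra(
            truth, lib, jitter_ppm=0.02, noise_sd=0.0, nuisance=False, seed=5
        )
        for s in spectra:
            win = (s.ppm > 6.3) & (s.ppm < 6.7)
            apex = s.ppm[win][np.argmax(s.intensity[win])]
            assert abs(apex - 6.5) <= 0.02 + 1e-9

    def test_doubling_concentration_doubles_apex(self):
        lib = [syn.SpectralSignature("M01", [(3.0, 0.8, 0.002)])]
        design = syn.StudyDesign([("A", 3)], {"g": {"A": 0}}, seed=1)
        truth = syn.simulate_concentrations(design, lib, syn.EffectSpec(), sigma=0.0)
        doubled = syn.SyntheticTruth(
            truth.concentrations * 2, truth.metadata, truth.affected, truth.effects, 1
        )
        kw = dict(jitter_ppm=0.0, noise_sd=0.0, nuisance=False, seed=0)
        s1 = syn.render_spectra(truth, lib, **kw)[0]
        s2 = syn.render_spectra(doubled, lib, **kw)[0]
        i = int(np.argmin(np.abs(s1.ppm - 3.0)))
        ref = 5.0 / (1 + ((3.0 - 6.5) / 0.002) ** 2)
        assert s2.intensity[i] - ref == pytest.approx(2 * (s1.intensity[i] - ref), rel=1e-9)

    def test_rejects_bad_grid_step(self, two_arm_truth):
        lib, truth = two_arm_truth
        with pytest.raises(ValueError):
            syn.render_spectra(truth, lib, grid_step_ppm=0.0)


class TestRenderMS:
    def test_qc_rows_identical_without_drift_or_noise(self, two_arm_truth):
        _, truth = two_arm_truth
        df = syn.render_ms_table(truth, drift=("none", 0), technical_cv=0.0, seed=0)
        qc = df[df["is_qc"]].drop(columns=["sample_id", "injection_order", "is_qc"])
        assert np.allclose(qc.to_numpy(), qc.to_numpy()[0], rtol=1e-12)

    def test_linear_drift_halves_last_qc(self, two_arm_truth):
        _, truth = two_arm_truth
        df = syn.render_ms_table(truth, drift=("linear", -0.5), technical_cv=0.0, seed=0)
        qc = df[df["is_qc"]].drop(columns=["sample_id", "injection_order", "is_qc"])
        ratio = qc.iloc[-1] / qc.iloc[0]
        first, last = df["injection_order"].iloc[0], df["injection_order"].iloc[-1]
        qc_last = df.loc[df["is_qc"], "injection_order"].iloc[-1]
        expected = 1 - 0.5 * (qc_last - first) / (last - first)
        np.testing.assert_allclose(ratio.to_numpy(), expected, rtol=1e-10)

    def test_qc_count_rule(self):
        """40 study samples at qc_every=5: one leading QC + one per block."""
        lib = syn.make_library(3, seed=0)
        design = syn.StudyDesign([("A", 20), ("B", 20)], {"g": {"A": 0, "B": 1}}, seed=0)
        truth = syn.simulate_concentrations(design, lib, syn.EffectSpec())
        df = syn.render_ms_table(truth, qc_every=5, seed=0)
        assert int(df["is_qc"].sum()) == 9
        assert len(df) == 49

    def test_randomized_order_covers_all_samples(self, two_arm_truth):
        _, truth = two_arm_truth
        df = syn.render_ms_table(truth, seed=3)
        study = df.loc[~df["is_qc"], "sample_id"]
        assert sorted(study) == sorted(truth.concentrations.index)
        assert df["injection_order"].is_unique

    def test_unknown_drift_shape_rejected(self, two_arm_truth):
        _, truth = two_arm_truth
        with pytest.raises(ValueError):
            syn.render_ms_table(truth, drift=("wiggle", 0.1))

    def test_deterministic(self, two_arm_truth):
        _, truth = two_arm_truth
        pd.testing.assert_frame_equal(
            syn.render_ms_table(truth, seed=8), syn.render_ms_table(truth, seed=8)
        )


class TestEffectSpec:
    def test_bad_block_name_rejected(self):
        with pytest.raises(ValueError):
            syn.EffectSpec(block_assignment={"M01": "sideways"})

    def test_block_visibility_partitions_metabolites(self, small_library):
        design = syn.StudyDesign([("A", 4)], {"g": {"A": 0}}, seed=0)
        eff = syn.EffectSpec(
            block_assignment={"M01": "nmr_only", "M02": "ms_only", "M03": "both"}
        )
        truth = syn.simulate_concentrations(design, small_library, eff)
        assert "M01" in truth.nmr_metabolites() and "M01" not in truth.ms_metabolites()
        assert "M02" in truth.ms_metabolites() and "M02" not in truth.nmr_metabolites()
        assert "M03" in truth.nmr_metabolites() and "M03" in truth.ms_metabolites()
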