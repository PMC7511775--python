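"""Synthetic cohort generator: Poisson placement, geometry, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from immunotopo import SimParams, generate_cohort, mann_whitney_u
from immunotopo.simulate import (default_class_intensity, generate_core,
                                 write_cohort)


def _single_class_intensity(panel="P1", cls="NK", tumor=0.0, stroma=100.0):
    """All rates zero except one class, to isolate the placement process."""
    intensity = default_class_intensity()
    for pn, classes in intensity.items():
        for c in classes:
            classes[c] = {"tumor": 0.0, "stroma": 0.0}
    intensity[panel][cls] = {"tumor": tumor, "stroma": stroma}
    return intensity


class TestPoissonPlacement:
    def test_rate_and_dispersion_match_homogeneous_poisson(self):
        """At 100 cells/mm² in an all-stroma core (area π/4 mm²), counts
        over many cores have mean ≈ rate·area and variance ≈ mean."""
        params = SimParams(
            n_tumor_nests=0,
            class_intensity=_single_class_intensity(stroma=100.0),
        )
        rng = np.random.default_rng(202)
        counts, area = [], None
        for i in range(150):
            cells, geom, _ = generate_core(params, "caseX", i, rng)
            counts.append(len(cells))
            area = geom["stroma_area_mm2"]
        counts = np.asarray(counts, dtype=float)
        expected = 100.0 * area
        assert counts.mean() == pytest.approx(expected, rel=0.05)
        # index of dispersion ~ 1 for a Poisson process
        assert 0.7 <= counts.var(ddof=1) / counts.mean() <= 1.3

    def test_cells_stay_inside_core_and_compartment(self):
        params = SimParams(seed=4)
        rng = np.random.default_rng(7)
        cells, geom, _ = generate_core(params, "caseY", 0, rng)
        R = params.core_radius
        r = np.hypot(cells["x_um"] - R, cells["y_um"] - R)
        assert (r <= R + 1e-6).all()
        assert set(cells["compartment"]) <= {"tumor", "stroma"}


class TestGeometry:
    def test_compartment_areas_sum_to_core_area(self):
        """Grid-integrated tumor + stroma equals the analytic disc area to
        within the discretization error of the 2 μm pitch."""
        params = SimParams(seed=9)
        rng = np.random.default_rng(9)
        _, geom, _ = generate_core(params, "caseZ", 0, rng)
        total = geom["tumor_area_mm2"] + geom["stroma_area_mm2"]
        analytic = math.pi * (params.core_radius / 1000.0) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_no_nests_means_no_tumor_and_no_cancer_cells(self):
        params = SimParams(n_tumor_nests=0)
        rng = np.random.default_rng(3)
        cells, geom, truth = generate_core(params, "caseW", 0, rng)
        assert geom["tumor_area_mm2"] == 0.0
        assert (cells["compartment"] == "stroma").all()
        assert "cancer" not in set(truth["true_label"])

    def test_benign_core_tumor_free(self):
        params = SimParams()
        rng = np.random.default_rng(5)
        cells, geom, truth = generate_core(params, "caseB", 0, rng,
                                           tissue_type="benign")
        assert geom["tissue_type"] == "benign"
        assert geom["tumor_area_mm2"] == 0.0
        assert "cancer" not in set(truth["true_label"])


class TestIntensities:
    def test_signature_markers_bimodal(self, small_cohort):
        """Cells truly labelled NK (CD3−CD56+NKp46+) show high CD56/NKp46
        and low CD3 intensity; the two modes are well separated."""
        truth = small_cohort.cell_truth
        cells = small_cohort.cells
        nk_ids = set(truth.loc[(truth["panel"] == "P1")
                               & (truth["true_label"] == "NK"), "cell_id"])
        nk = cells[cells["cell_id"].isin(nk_ids)]
        assert len(nk) > 20
        pos = np.log(np.concatenate([nk["int_CD56"], nk["int_NKp46"]]))
        neg = np.log(nk["int_CD3"].to_numpy(dtype=float))
        assert pos.mean() - neg.mean() > 1.5
        assert np.median(pos) > np.median(neg)

    def test_every_cell_has_truth_row(self, small_cohort):
        merged = small_cohort.cells.merge(
            small_cohort.cell_truth, on=["cell_id", "core_id", "case_id",
                                         "panel"], how="left")
        assert merged["true_label"].notna().all()


class TestCohort:
    def test_deterministic_given_seed(self):
        params = SimParams(n_cases=4, cores_per_case=1, seed=31)
        a = generate_cohort(params)
        b = generate_cohort(SimParams(n_cases=4, cores_per_case=1, seed=31))
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(a.case_truth, b.case_truth)

    def test_seed_changes_output(self):
        a = generate_cohort(SimParams(n_cases=4, cores_per_case=1, seed=31))
        c = generate_cohort(SimParams(n_cases=4, cores_per_case=1, seed=32))
        assert not a.cells.equals(c.cells)

    def test_written_files_byte_identical_across_runs(self, tmp_path):
        params = SimParams(n_cases=3, cores_per_case=1, seed=13)
        pa = write_cohort(generate_cohort(params), tmp_path / "a")
        pb = write_cohort(generate_cohort(params), tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_clinical_only_cohort(self):
        cohort = generate_cohort(SimParams(n_cases=25, cores_per_case=0,
                                           benign_case_fraction=0.0, seed=6))
        assert len(cohort.cells) == 0
        assert len(cohort.geometry) == 0
        assert len(cohort.clinical) == 25
        assert len(cohort.case_truth) == 25

    def test_benign_core_count(self, small_cohort, small_params):
        geo = small_cohort.geometry
        n_benign = (geo["tissue_type"] == "benign").sum()
        expected = round(small_params.benign_case_fraction
                         * small_params.n_cases)
        assert n_benign == expected
        # benign cores come on top of the malignant ones
        per_case = geo.groupby("case_id").size()
        assert set(per_case) <= {small_params.cores_per_case,
                                 small_params.cores_per_case + 1}


class TestSurvivalGeneration:
    def test_null_betas_give_exchangeable_survival(self):
        """With all coefficients zero the latent group carries no survival
        information: a rank test on the uncensored times is non-significant."""
        cohort = generate_cohort(SimParams(
            n_cases=600, cores_per_case=0, benign_case_fraction=0.0,
            betas={}, admin_censor_months=1e9, seed=21))
        truth = cohort.case_truth
        t = truth["uncensored_time"].to_numpy()
        high = truth["high_infiltration"].to_numpy()
        res = mann_whitney_u(t[high], t[~high])
        assert res.p > 0.01

    def test_protective_beta_lengthens_survival(self):
        cohort = generate_cohort(SimParams(
            n_cases=600, cores_per_case=0, benign_case_fraction=0.0,
            betas={"high_infiltration": math.log(0.5)},
            admin_censor_months=1e9, seed=22))
        truth = cohort.case_truth
        t = truth["uncensored_time"].to_numpy()
        high = truth["high_infiltration"].to_numpy()
        assert np.median(t[high]) > np.median(t[~high])

    def test_event_flag_consistent_with_censoring(self, small_cohort):
        clin = small_cohort.clinical
        cap = small_cohort.params.admin_censor_months
        assert (clin.loc[~clin["event"], "os_months"] == cap).all()
        assert (clin.loc[clin["event"], "os_months"] <= cap).all()


class TestParamValidation:
    def test_rejects_absurd_rate(self):
        intensity = default_class_intensity()
        intensity["P1"]["NK"]["stroma"] = 1e7
        with pytest.raises(ValueError, match="1e6|cells per core"):
            SimParams(class_intensity=intensity)

    def test_rejects_inverted_intensity_modes(self):
        with pytest.raises(ValueError, match="logmean"):
            SimParams(marker_pos_logmean=0.5, marker_neg_logmean=3.0)
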