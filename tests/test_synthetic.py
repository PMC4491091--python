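"""Planted-template generator: templates, precision repair, HRF design,
subject/group simulation, volume rendering."""

import numpy as np
import pytest

from synconn.connectivity import partial_corr_matrix
from synconn.regions import RegionCatalog, RegionDefinition, VoxelGrid, extract_roi_series, build_sphere_mask, voxel_to_mni
from synconn.synthetic import (
    HRFParams,
    SimulationConfig,
    TemplateSpec,
    double_gamma_hrf,
    hrf_convolve,
    leveled_template,
    normal_template,
    other_template,
    precision_from_partials,
    render_volumes,
    simulate_group,
    simulate_subject,
    template_matrix,
)


class TestTemplates:
    def test_normal_template_levels(self, catalog):
        pc = template_matrix(normal_template(), catalog)
        off = pc[~np.eye(14, dtype=bool)]
        within = off[np.isclose(off, np.tanh(0.18))]
        between = off[np.isclose(off, np.tanh(0.002))]
        assert len(within) == 2 * 27 and len(between) == 2 * 64

    def test_leveled_uniform(self, catalog):
        pc = template_matrix(leveled_template(0.052), catalog)
        off = pc[~np.eye(14, dtype=bool)]
        assert np.allclose(off, np.tanh(0.052))

    def test_other_preserved_edges(self, catalog):
        pc = template_matrix(other_template(), catalog)
        for (a, b), z in (
            (("L_F3op/F3t", "L_IPS"), 0.22),
            (("L_LPMC", "L_AG"), 0.28),
            (("L_F3t", "L_F3O"), 0.25),
        ):
            i, j = catalog.index(a), catalog.index(b)
            assert pc[i, j] == pytest.approx(np.tanh(z))
        # a non-preserved pair sits at the abnormal baseline
        i, j = catalog.index("L_F3op/F3t"), catalog.index("R_LPMC")
        assert pc[i, j] == pytest.approx(np.tanh(0.052))

    def test_unknown_preserved_edge_rejected(self, catalog):
        spec = TemplateSpec(
            scenario="other", preserved_edges=((("nope", "L_IPS"), 0.2),)
        )
        with pytest.raises(ValueError, match="not in catalog"):
            template_matrix(spec, catalog)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            TemplateSpec(scenario="weird")


class TestPrecisionFromPartials:
    def test_two_node_identity(self):
        pc = np.array([[0.0, 0.5], [0.5, 0.0]])
        omega, lam = precision_from_partials(pc)
        assert lam == 1.0
        assert np.allclose(omega, [[1.0, -0.5], [-0.5, 1.0]])
        # for two nodes the partial equals the marginal correlation
        cov = np.linalg.inv(omega)
        marg = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert marg == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "spec_fn", [normal_template, lambda: leveled_template(0.045),
                    lambda: leveled_template(0.052), other_template]
    )
    def test_paper_templates_need_no_shrinkage(self, catalog, spec_fn):
        pc = template_matrix(spec_fn(), catalog)
        omega, lam = precision_from_partials(pc)
        assert lam == 1.0
        assert np.linalg.eigvalsh(omega)[0] > 0
        # implied partials equal the planted ones
        d = np.sqrt(np.diag(omega))
        implied = -omega / np.outer(d, d)
        off = ~np.eye(14, dtype=bool)
        assert np.allclose(implied[off], pc[off], atol=1e-12)

    def test_infeasible_uniform_is_shrunk(self):
        pc = np.full((14, 14), 0.9)
        np.fill_diagonal(pc, 0.0)
        omega, lam = precision_from_partials(pc)
        assert lam < 1.0
        assert np.linalg.eigvalsh(omega)[0] >= 1e-6 - 1e-9
        d = np.sqrt(np.diag(omega))
        implied = -omega / np.outer(d, d)
        assert implied[0, 1] == pytest.approx(lam * 0.9, abs=1e-6)

    def test_asymmetric_rejected(self):
        pc = np.zeros((3, 3))
        pc[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            precision_from_partials(pc)


class TestHRF:
    def test_no_onsets_all_zero(self):
        reg = hrf_convolve([], 100, 2.0)
        assert not reg.any()

    def test_single_event_peak_latency(self):
        # BOLD response to a 6-s boxcar peaks 6-10 s after onset
        reg = hrf_convolve([20.0], 200, 2.0)
        peak_s = np.argmax(reg) * 2.0 - 20.0
        assert 6.0 <= peak_s <= 10.0

    def test_linearity_of_nonoverlapping_events(self):
        both = hrf_convolve([20.0, 160.0], 200, 2.0)
        a = hrf_convolve([20.0], 200, 2.0)
        b = hrf_convolve([160.0], 200, 2.0)
        assert np.allclose(both, a + b, atol=1e-12)

    def test_negative_onset_rejected(self):
        with pytest.raises(ValueError, match="negative onset"):
            hrf_convolve([-1.0], 100, 2.0)

    def test_hrf_shape(self):
        h = double_gamma_hrf(0.5, HRFParams())
        assert np.max(h) == pytest.approx(1.0)
        assert np.min(h) < 0  # undershoot present


class TestSimulateSubject:
    def test_deterministic_given_seed(self, catalog):
        pc = template_matrix(normal_template(), catalog)
        omega, _ = precision_from_partials(pc)
        cfg = SimulationConfig(n_runs=2, n_volumes_per_run=50)
        a = simulate_subject(omega, cfg, seed=11, region_names=catalog.names)
        b = simulate_subject(omega, cfg, seed=11, region_names=catalog.names)
        for ra, rb in zip(a.runs, b.runs):
            assert ra.data.equals(rb.data)

    def test_no_onsets_equals_zero_amplitude(self, catalog):
        pc = template_matrix(normal_template(), catalog)
        omega, _ = precision_from_partials(pc)
        base = SimulationConfig(n_runs=1, n_volumes_per_run=50, event_onsets_s=())
        amp0 = SimulationConfig(n_runs=1, n_volumes_per_run=50, task_amplitude=0.0)
        a = simulate_subject(omega, base, seed=3)
        b = simulate_subject(omega, amp0, seed=3)
        assert np.allclose(a.runs[0].data.to_numpy(), b.runs[0].data.to_numpy())

    def test_sample_covariance_matches_inverse_precision(self):
        pc = np.zeros((5, 5))
        pc[0, 1] = pc[1, 0] = 0.3
        omega, _ = precision_from_partials(pc)
        cfg = SimulationConfig(
            n_runs=1,
            n_volumes_per_run=100_000,
            task_amplitude=0.0,
            drift_amplitude=0.0,
            gain_range=(1.0, 1.0),
        )
        sub = simulate_subject(omega, cfg, seed=5)
        sample = np.cov(sub.runs[0].data.to_numpy(), rowvar=False)
        assert np.allclose(sample, np.linalg.inv(omega), atol=0.02)

    def test_non_pd_precision_rejected(self):
        bad = np.array([[1.0, -2.0], [-2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            simulate_subject(bad, SimulationConfig(), seed=0)


class TestSimulateGroup:
    def test_seven_subjects_distinct_seeds_shared_template(self, catalog):
        cfg = SimulationConfig(n_subjects=7, n_runs=1, n_volumes_per_run=30)
        subjects, meta = simulate_group(
            normal_template(), cfg, catalog, master_seed=1, group="Normal"
        )
        assert len(subjects) == 7
        assert meta["shrinkage_lambda"] == 1.0
        first_rows = {tuple(s.runs[0].data.iloc[0]) for s in subjects}
        assert len(first_rows) == 7  # distinct streams
        assert np.allclose(
            np.array(meta["template_z"])[0, 1],
            0.18,
            atol=1e-12,
        )

    def test_single_subject_group(self, catalog):
        cfg = SimulationConfig(n_subjects=1, n_runs=1, n_volumes_per_run=30)
        subjects, _ = simulate_group(other_template(), cfg, catalog, master_seed=2)
        assert len(subjects) == 1

    def test_reruns_bit_identical(self, catalog):
        cfg = SimulationConfig(n_subjects=2, n_runs=2, n_volumes_per_run=40)
        a, _ = simulate_group(normal_template(), cfg, catalog, master_seed=9)
        b, _ = simulate_group(normal_template(), cfg, catalog, master_seed=9)
        for sa, sb in zip(a, b):
            for ra, rb in zip(sa.runs, sb.runs):
                assert ra.data.equals(rb.data)

    def test_end_to_end_recovery_normal(self, catalog):
        from synconn.pipeline import analyze_group
        from synconn.preprocess import PreprocessConfig
        from synconn.group_stats import summarize_networks

        cfg = SimulationConfig()
        subjects, _ = simulate_group(normal_template(), cfg, catalog, master_seed=17)
        _, _, summary = analyze_group(subjects, catalog, PreprocessConfig(), "Normal")
        assert np.mean(summary.within_values) == pytest.approx(0.18, abs=0.02)
        assert np.mean(summary.between_values) == pytest.approx(0.002, abs=0.02)


class TestRenderVolumes:
    @pytest.fixture
    def two_region_catalog(self):
        return RegionCatalog(
            [
                RegionDefinition("a", "1", "L", (-12.0, 0.0, 0.0), "I"),
                RegionDefinition("b", "1", "R", (12.0, 0.0, 0.0), "II"),
            ]
        )

    @pytest.fixture
    def small_grid(self):
        return VoxelGrid.isotropic((17, 11, 11), 3.0, origin_mni=(-24, -15, -15))

    def _subject(self, catalog, n=20):
        pc = np.zeros((2, 2))
        omega, _ = precision_from_partials(pc)
        cfg = SimulationConfig(n_runs=1, n_volumes_per_run=n)
        return simulate_subject(omega, cfg, seed=4, region_names=catalog.names)

    def test_zero_noise_round_trip_exact(self, two_region_catalog, small_grid):
        sub = self._subject(two_region_catalog)
        img = render_volumes(
            sub, two_region_catalog, small_grid, background_noise_sd=0.0
        )[0]
        for region in two_region_catalog:
            mask = build_sphere_mask(region.mni, 6.0, small_grid)
            series = extract_roi_series(img, mask)
            expected = sub.runs[0].data[region.name].to_numpy()
            assert np.allclose(series, expected, atol=1e-3)  # float32 storage

    def test_default_noise_high_correlation(self, two_region_catalog, small_grid):
        sub = self._subject(two_region_catalog, n=40)
        img = render_volumes(sub, two_region_catalog, small_grid)[0]
        for region in two_region_catalog:
            mask = build_sphere_mask(region.mni, 6.0, small_grid)
            series = extract_roi_series(img, mask)
            expected = sub.runs[0].data[region.name].to_numpy()
            assert np.corrcoef(series, expected)[0, 1] > 0.99

    def test_overlapping_spheres_rejected(self, small_grid):
        close = RegionCatalog(
            [
                RegionDefinition("a", "1", "L", (-3.0, 0.0, 0.0), "I"),
                RegionDefinition("b", "1", "R", (3.0, 0.0, 0.0), "II"),
            ]
        )
        sub = self._subject(close)
        with pytest.raises(ValueError, match="overlapping"):
            render_volumes(sub, close, small_grid)

    def test_grid_too_small_rejected(self, two_region_catalog):
        tiny = VoxelGrid.isotropic((3, 3, 3), 3.0, origin_mni=(100, 100, 100))
        sub = self._subject(two_region_catalog)
        with pytest.raises(ValueError):
            render_volumes(sub, two_region_catalog, tiny)

    def test_extraction_from_full_catalog_rendering(self, catalog, mni_grid):
        """Round trip through NIfTI on the real 14-region catalog."""
        pc = template_matrix(normal_template(), catalog)
        omega, _ = precision_from_partials(pc)
        cfg = SimulationConfig(n_runs=1, n_volumes_per_run=10)
        sub = simulate_subject(omega, cfg, seed=6, region_names=catalog.names)
        img = render_volumes(sub, catalog, mni_grid, background_noise_sd=0.0)[0]
        from synconn.regions import extract_catalog_series

        extracted = extract_catalog_series(img, catalog, mni_grid)
        assert np.allclose(
            extracted.to_numpy(), sub.runs[0].data.to_numpy(), atol=1e-3
        )
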