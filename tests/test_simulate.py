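"""Unit tests for the synthetic checkerboard generator."""

import numpy as np
import pytest

from synbias import (
    HillParams,
    PRESETS,
    SimulationConfig,
    base2_doses,
    config_from_presets,
    generate_checkerboard,
    generate_extreme_dataset,
    hill_viability,
    preset,
)


class TestPresets:
    def test_vinorelbine_plateau_near_20(self):
        assert preset("vinorelbine_like").emax == pytest.approx(20.0)
        assert preset("gemcitabine_like").emax == pytest.approx(20.0)

    def test_celecoxib_negative_plateau(self):
        assert preset("celecoxib_like").emax < 0

    def test_inactive_flat(self):
        p = preset("inactive")
        d = np.geomspace(0.01, 100, 50)
        np.testing.assert_allclose(hill_viability(p, d), 100.0)

    def test_carboplatin_midpoint_near_top_of_range(self):
        from synbias.simulate import PRESET_TOP_DOSES

        p = preset("carboplatin_like")
        top = PRESET_TOP_DOSES["carboplatin_like"]
        # ec50 in the top quarter of the range: the curve cannot approach
        # its plateau within the tested concentrations.
        assert top / 4 <= p.ec50 <= top
        assert hill_viability(p, top) > 20.0

    def test_unknown_preset_names_valid_ones(self):
        with pytest.raises(ValueError, match="celecoxib_like"):
            preset("aspirin_like")

    def test_all_presets_valid(self):
        for name in PRESETS:
            p = preset(name)
            assert p.emin > 0


class TestBase2Doses:
    def test_length_and_top(self):
        d = base2_doses(200.0, 9)
        assert d.size == 9
        assert d[-1] == 200.0

    def test_ratio_two(self):
        d = base2_doses(16.0, 5)
        np.testing.assert_allclose(d[1:] / d[:-1], 2.0)

    def test_invalid_top(self):
        with pytest.raises(ValueError):
            base2_doses(0.0)


class TestSimulationConfig:
    def test_rejects_decreasing_doses(self, simple_params):
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(
                row_params=simple_params, col_params=simple_params,
                row_doses=[4.0, 2.0, 1.0, 0.5], col_doses=[1.0, 2.0, 4.0, 8.0],
            )

    def test_rejects_bad_offset_shape(self, simple_params):
        with pytest.raises(ValueError, match="shape"):
            SimulationConfig(
                row_params=simple_params, col_params=simple_params,
                row_doses=base2_doses(16.0, 9), col_doses=base2_doses(16.0, 9),
                interaction_offset=np.zeros((3, 3)),
            )

    def test_rejects_unknown_null_model(self, simple_params):
        with pytest.raises(ValueError, match="null model"):
            SimulationConfig(
                row_params=simple_params, col_params=simple_params,
                row_doses=base2_doses(16.0, 9), col_doses=base2_doses(16.0, 9),
                null_model="zip",
            )


class TestGenerateCheckerboard:
    def test_determinism(self):
        cfg = config_from_presets("indomethacin_like", "gemcitabine_like", seed=42)
        a = generate_checkerboard(cfg)
        b = generate_checkerboard(cfg)
        np.testing.assert_array_equal(a.viability, b.viability)

    def test_different_seeds_differ(self):
        a = generate_checkerboard(
            config_from_presets("indomethacin_like", "gemcitabine_like", seed=1)
        )
        b = generate_checkerboard(
            config_from_presets("indomethacin_like", "gemcitabine_like", seed=2)
        )
        assert not np.array_equal(a.viability, b.viability)

    def test_shape_and_zero_axis(self):
        ds = generate_checkerboard(
            config_from_presets("indomethacin_like", "gemcitabine_like")
        )
        assert ds.viability.shape == (4, 10, 10)
        assert ds.row_doses[0] == 0.0 and ds.col_doses[0] == 0.0

    def test_bliss_half_effect_cell(self, simple_params):
        # Both drugs at their midpoint: Bliss expects 50*50/100 = 25.
        cfg = SimulationConfig(
            row_params=simple_params,
            col_params=HillParams(100.0, 0.0, 0.5, 1.0),
            row_doses=np.array([0.5, 1.0, 2.0, 4.0]),
            col_doses=np.array([0.125, 0.25, 0.5, 1.0]),
            null_model="bliss", noise_sd=0.0,
        )
        ds = generate_checkerboard(cfg)
        i = 1 + 1  # row dose 1.0 == ec50_row
        j = 1 + 2  # col dose 0.5 == ec50_col
        assert ds.viability[0, i, j] == pytest.approx(25.0)

    def test_hsa_with_inactive_partner(self, simple_params):
        cfg = SimulationConfig(
            row_params=simple_params, col_params=preset("inactive"),
            row_doses=base2_doses(16.0, 9), col_doses=base2_doses(16.0, 9),
            null_model="hsa", noise_sd=0.0,
        )
        ds = generate_checkerboard(cfg)
        expected = hill_viability(simple_params, ds.row_doses)
        for j in range(ds.col_doses.size):
            np.testing.assert_allclose(ds.viability[0, :, j], expected, atol=1e-9)

    def test_offset_injects_synergy(self, simple_params):
        off = np.full((9, 9), 10.0)
        base = SimulationConfig(
            row_params=simple_params, col_params=simple_params,
            row_doses=base2_doses(16.0, 9), col_doses=base2_doses(16.0, 9),
            noise_sd=0.0,
        )
        with_off = base.with_(interaction_offset=off)
        a = generate_checkerboard(base)
        b = generate_checkerboard(with_off)
        np.testing.assert_allclose(
            a.viability[:, 1:, 1:] - b.viability[:, 1:, 1:], 10.0
        )
        # single-agent axes untouched
        np.testing.assert_allclose(a.viability[:, 0, :], b.viability[:, 0, :])

    def test_clip_keeps_range(self):
        cfg = config_from_presets(
            "celecoxib_like", "vinorelbine_like", clip_observations=True, seed=0
        )
        ds = generate_checkerboard(cfg)
        assert ds.viability.min() >= 0.0
        assert ds.viability.max() <= 100.0

    def test_noise_free_unclipped_within_plateaus(self, simple_params):
        cfg = SimulationConfig(
            row_params=simple_params, col_params=simple_params,
            row_doses=base2_doses(16.0, 9), col_doses=base2_doses(16.0, 9),
            noise_sd=0.0,
        )
        ds = generate_checkerboard(cfg)
        assert ds.viability.min() >= 0.0 - 1e-12
        assert ds.viability.max() <= 100.0 + 1e-12

    def test_replicate_mean_converges_to_truth(self):
        cfg = config_from_presets(
            "indomethacin_like", "gemcitabine_like", n_replicates=400, seed=11
        )
        ds = generate_checkerboard(cfg)
        assert np.max(np.abs(ds.mean_viability() - ds.truth)) < 1.0


class TestExtremeDataset:
    def test_synergistic_combination_cells_zero(self, simple_params, plateau_params):
        ds = generate_extreme_dataset(
            "synergistic", simple_params, plateau_params,
            base2_doses(16.0, 9), base2_doses(2.0, 9),
        )
        np.testing.assert_array_equal(ds.viability[:, 1:, 1:], 0.0)

    def test_antagonistic_combination_cells_100(self, simple_params, plateau_params):
        ds = generate_extreme_dataset(
            "antagonistic", simple_params, plateau_params,
            base2_doses(16.0, 9), base2_doses(2.0, 9),
        )
        np.testing.assert_array_equal(ds.viability[:, 1:, 1:], 100.0)

    def test_single_agent_axes_follow_curves(self, simple_params, plateau_params):
        rd, cd = base2_doses(16.0, 9), base2_doses(2.0, 9)
        ds = generate_extreme_dataset("synergistic", simple_params, plateau_params, rd, cd)
        np.testing.assert_allclose(
            ds.viability[0, :, 0], hill_viability(simple_params, ds.row_doses)
        )
        np.testing.assert_allclose(
            ds.viability[0, 0, :], hill_viability(plateau_params, ds.col_doses)
        )

    def test_bad_direction(self, simple_params):
        with pytest.raises(ValueError, match="direction"):
            generate_extreme_dataset(
                "maximal", simple_params, simple_params,
                base2_doses(16.0, 9), base2_doses(16.0, 9),
            )
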