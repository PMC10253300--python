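"""Unit tests for normalization, regime shifts, and the fixture panel."""

import numpy as np
import pytest

from synbias import (
    CONVENTIONS,
    analyze_panel,
    analyze_regime,
    fit_single_agents,
    fixture_panel,
    generate_extreme_dataset,
    normalization_constants,
    normalize_score,
    regime_shift_analysis,
    run_full_analysis,
    separation_statistic,
    surface,
)
from synbias.scoring import score_checkerboard


class TestNormalizationConstants:
    def test_signs(self, noisy_bliss_dataset):
        ds = noisy_bliss_dataset
        fr, fc = fit_single_agents(ds, "unconstrained")
        for model in ("hsa", "loewe", "bliss"):
            for conv in CONVENTIONS:
                c = normalization_constants(
                    fr, fc, ds.row_doses_pos, ds.col_doses_pos, model, conv
                )
                assert c.s_syn > 0
                assert c.s_ant < 0

    def test_extremes_normalize_to_unit(self, noisy_bliss_dataset):
        # Scoring the extreme dataset against the same surface and
        # normalizing with its own constants must give exactly +-1.
        ds = noisy_bliss_dataset
        fr, fc = fit_single_agents(ds, "unconstrained")
        c = normalization_constants(
            fr, fc, ds.row_doses_pos, ds.col_doses_pos, "bliss", "mean"
        )
        surf = surface("bliss", fr, fc, ds.row_doses_pos, ds.col_doses_pos)
        for direction, target in (("synergistic", 1.0), ("antagonistic", -1.0)):
            extreme = generate_extreme_dataset(
                direction, fr.params, fc.params, ds.row_doses_pos, ds.col_doses_pos
            )
            raw = score_checkerboard(extreme, surf).mean_score
            assert normalize_score(raw, c) == target

    def test_unknown_convention(self, noisy_bliss_dataset):
        ds = noisy_bliss_dataset
        fr, fc = fit_single_agents(ds, "unconstrained")
        with pytest.raises(ValueError, match="convention"):
            normalization_constants(
                fr, fc, ds.row_doses_pos, ds.col_doses_pos, "bliss", "median"
            )


class TestNormalizeScore:
    def test_zero_maps_to_zero(self, noisy_bliss_dataset):
        ds = noisy_bliss_dataset
        fr, fc = fit_single_agents(ds, "unconstrained")
        c = normalization_constants(
            fr, fc, ds.row_doses_pos, ds.col_doses_pos, "bliss", "mean"
        )
        assert normalize_score(0.0, c) == 0.0

    def test_sign_and_order_preserved(self, noisy_bliss_dataset):
        ds = noisy_bliss_dataset
        fr, fc = fit_single_agents(ds, "unconstrained")
        c = normalization_constants(
            fr, fc, ds.row_doses_pos, ds.col_doses_pos, "bliss", "mean"
        )
        raws = [-10.0, -1.0, 0.0, 1.0, 10.0]
        norms = [normalize_score(r, c) for r in raws]
        assert norms == sorted(norms)
        assert all(np.sign(n) == np.sign(r) for n, r in zip(norms, raws))

    def test_out_of_range_errors(self, noisy_bliss_dataset):
        ds = noisy_bliss_dataset
        fr, fc = fit_single_agents(ds, "unconstrained")
        c = normalization_constants(
            fr, fc, ds.row_doses_pos, ds.col_doses_pos, "bliss", "mean"
        )
        with pytest.raises(ValueError, match="outside"):
            normalize_score(c.s_syn * 2, c)


class TestAnalyzeRegime:
    def test_returns_all_conventions(self, noisy_bliss_dataset):
        fits, result, per_conv = analyze_regime(
            noisy_bliss_dataset, "bliss", "unconstrained"
        )
        assert set(per_conv) == set(CONVENTIONS)
        for conv in CONVENTIONS:
            raw, norm, constants = per_conv[conv]
            assert -1.0 <= norm <= 1.0
            assert constants.convention == conv

    def test_noise_free_null_normalized_zero(self, noisefree_bliss_dataset):
        _, result, per_conv = analyze_regime(
            noisefree_bliss_dataset, "bliss", "unconstrained"
        )
        assert abs(per_conv["mean"][1]) < 1e-6
        assert abs(per_conv["weighted"][1]) < 1e-6


class TestRegimeShift:
    def test_fields_consistent(self, noisy_bliss_dataset):
        shift = regime_shift_analysis(noisy_bliss_dataset, model="bliss")
        assert shift.raw_shift == pytest.approx(
            shift.raw["constrained"] - shift.raw["unconstrained"]
        )
        assert shift.flip == (
            shift.classification["constrained"] != shift.classification["unconstrained"]
        )

    def test_flip_fixture(self):
        # Noise-free Loewe-null board with a small uniform synergy offset:
        # the two regimes land on opposite sides of the additive band.
        from synbias import config_from_presets, generate_checkerboard

        cfg = config_from_presets(
            "celecoxib_like", "gemcitabine_like", null_model="loewe",
            noise_sd=0.0, seed=0, clip_observations=True,
            interaction_offset=np.full((9, 9), 2.5),
        )
        ds = generate_checkerboard(cfg)
        shift = regime_shift_analysis(ds, model="loewe", convention="mean")
        assert shift.flip
        assert shift.classification["constrained"] == "additive"
        assert shift.classification["unconstrained"] == "synergistic"


class TestPanel:
    def test_panel_composition(self):
        panel = fixture_panel(seed=0)
        assert len(panel) == 6
        directions = [d for _, d, _ in panel]
        assert directions.count("synergistic") == 3
        assert directions.count("antagonistic") == 3

    def test_panel_deterministic(self):
        a = fixture_panel(seed=1)
        b = fixture_panel(seed=1)
        for (_, _, da), (_, _, db) in zip(a, b):
            np.testing.assert_array_equal(da.viability, db.viability)

    def test_separation_statistic(self):
        assert separation_statistic([0.5, 0.6], [-0.5, -0.4]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            separation_statistic([], [0.1])

    def test_analyze_panel_directions_separate(self):
        panel = fixture_panel(seed=0)
        out = analyze_panel(panel, model="bliss", regime="unconstrained")
        for conv in CONVENTIONS:
            assert out[conv]["separation"] > 0
            ranking = out[conv]["ranking"]
            assert len(ranking) == 6


class TestFullAnalysis:
    def test_report_covers_all_cells(self, noisy_bliss_dataset):
        analysis = run_full_analysis(noisy_bliss_dataset)
        assert len(analysis.results) == 6  # 3 models x 2 regimes
        assert len(analysis.normalized) == 12
        assert len(analysis.shifts) == 6
        d = analysis.to_dict()
        assert set(d["scores"]) == {"hsa", "loewe", "bliss"}
        for model in d["scores"]:
            for regime in ("constrained", "unconstrained"):
                for conv in CONVENTIONS:
                    cell = d["scores"][model][regime][conv]
                    assert set(cell) == {"raw", "normalized", "classification"}

    def test_report_deterministic(self, noisy_bliss_dataset):
        import json

        a = run_full_analysis(noisy_bliss_dataset, seed=0)
        b = run_full_analysis(noisy_bliss_dataset, seed=0)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )
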