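"""Score normalization against extreme matrices and fitting-regime bias.

Raw matrix scores are not comparable across scoring conventions, so they
are normalized against the scores of two simulated yardstick matrices on
the same dose grid and single-agent curves: a fully synergistic one (0%
viability at every combination cell) and a fully antagonistic one (100%
everywhere). Dividing a raw score by the direction-matched extreme score
maps the yardsticks to exactly +1 and -1 while preserving sign and order.

The regime-shift analysis runs the identical pipeline twice — the two
runs differ only in how the single-agent curves were fitted (plateaus
pinned at 100/0 versus a free lower plateau) — and reports how much
the matrix score and its synergistic/additive/antagonistic classification
move between regimes. This isolates curve fitting as the source of any
disagreement, every other stage being shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import REGIMES, HillFit, fit_curve
from .scoring import (
    DEFAULT_ALPHA,
    DEFAULT_RAW_THRESHOLDS,
    SynergyResult,
    classify,
    score_checkerboard,
)
from .simulate import (
    CheckerboardDataset,
    config_from_presets,
    generate_checkerboard,
    generate_extreme_dataset,
)
from .surfaces import MODELS, surface

__all__ = [
    "CONVENTIONS",
    "DEFAULT_NORM_THRESHOLDS",
    "NormalizationConstants",
    "RegimeShift",
    "FullAnalysis",
    "fit_single_agents",
    "normalization_constants",
    "normalize_score",
    "analyze_regime",
    "regime_shift_analysis",
    "separation_statistic",
    "fixture_panel",
    "analyze_panel",
    "run_full_analysis",
]

CONVENTIONS = ("mean", "weighted")
# Additive band on normalized scores (the raw-score analogue is +-5).
DEFAULT_NORM_THRESHOLDS = (-0.05, 0.05)


def fit_single_agents(
    dataset: CheckerboardDataset, regime: str
) -> tuple[HillFit, HillFit]:
    """Fit both single-agent curves of a checkerboard under one regime."""
    row_doses, row_viab = dataset.single_agent("row")
    col_doses, col_viab = dataset.single_agent("col")
    return (
        fit_curve(row_doses, row_viab, regime=regime),
        fit_curve(col_doses, col_viab, regime=regime),
    )


@dataclass
class NormalizationConstants:
    """Scores of the two extreme yardstick matrices for one (model, convention)."""

    model: str
    convention: str
    s_syn: float  # score of the fully synergistic extreme, > 0
    s_ant: float  # score of the fully antagonistic extreme, < 0
    row_doses: np.ndarray
    col_doses: np.ndarray
    fits: tuple[HillFit, HillFit]


def normalization_constants(
    fit1: HillFit,
    fit2: HillFit,
    row_doses,
    col_doses,
    model: str,
    convention: str,
    alpha: float = DEFAULT_ALPHA,
    clip: bool = True,
) -> NormalizationConstants:
    """Score the extreme matrices built on the given fits and dose grid.

    The extremes reuse the *fitted* single-agent curves (per regime), so
    the constants are consistent with the machinery that produced the raw
    score being normalized. Noise-free construction makes them
    deterministic; significance uses the degenerate t-test limit, under
    which every nonzero-delta cell is significant and the two conventions
    coincide on the extremes.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    surf = surface(model, fit1, fit2, row_doses, col_doses, clip=clip)
    scores = {}
    for direction in ("synergistic", "antagonistic"):
        extreme = generate_extreme_dataset(
            direction, fit1.params, fit2.params, row_doses, col_doses
        )
        res = score_checkerboard(extreme, surf, method="t_test", alpha=alpha)
        scores[direction] = res.score(convention)
    s_syn, s_ant = scores["synergistic"], scores["antagonistic"]
    if not (s_syn > 0 and s_ant < 0):
        raise ValueError(
            "extreme datasets do not separate "
            f"(s_syn={s_syn:.4g}, s_ant={s_ant:.4g}); are both drugs inactive?"
        )
    return NormalizationConstants(
        model=model, convention=convention, s_syn=s_syn, s_ant=s_ant,
        row_doses=np.asarray(row_doses, float), col_doses=np.asarray(col_doses, float),
        fits=(fit1, fit2),
    )


def normalize_score(raw: float, constants: NormalizationConstants) -> float:
    """Map a raw matrix score into [-1, 1] via the direction-matched extreme.

    Non-negative raw scores divide by the synergistic constant, negative
    ones by the magnitude of the antagonistic constant, so the extremes
    map to exactly +-1. A result outside [-1, 1] (beyond tolerance)
    indicates the constants were built on a different grid or fits and is
    an error.
    """
    norm = raw / constants.s_syn if raw >= 0 else raw / abs(constants.s_ant)
    if abs(norm) > 1 + 1e-6:
        raise ValueError(
            f"normalized score {norm:.4g} outside [-1, 1]: constants do not "
            "match the scored grid/fits"
        )
    return float(norm)


@dataclass
class RegimeShift:
    """Raw/normalized scores and classifications of one dataset under both regimes."""

    model: str
    convention: str
    raw: dict  # regime -> raw score
    normalized: dict  # regime -> normalized score
    classification: dict  # regime -> label (on normalized score)
    raw_shift: float  # constrained - unconstrained
    normalized_shift: float
    flip: bool  # classification changes between regimes


def analyze_regime(
    dataset: CheckerboardDataset,
    model: str,
    regime: str,
    method: str = "t_test",
    alpha: float = DEFAULT_ALPHA,
    b: int = 1000,
    seed: int = 0,
    clip: bool = True,
    fits: tuple[HillFit, HillFit] | None = None,
) -> tuple[tuple[HillFit, HillFit], SynergyResult, dict]:
    """Fit -> surface -> score -> normalize for one (model, regime).

    Returns the fits, the :class:`~synbias.scoring.SynergyResult`, and a
    dict mapping convention to (raw, normalized, constants).
    """
    if fits is None:
        fits = fit_single_agents(dataset, regime)
    fit_r, fit_c = fits
    surf = surface(
        model, fit_r, fit_c, dataset.row_doses_pos, dataset.col_doses_pos, clip=clip
    )
    result = score_checkerboard(
        dataset, surf, method=method, alpha=alpha, b=b, seed=seed, regime=regime
    )
    per_convention = {}
    for convention in CONVENTIONS:
        constants = normalization_constants(
            fit_r, fit_c, dataset.row_doses_pos, dataset.col_doses_pos,
            model, convention, alpha=alpha, clip=clip,
        )
        raw = result.score(convention)
        per_convention[convention] = (raw, normalize_score(raw, constants), constants)
    return fits, result, per_convention


def regime_shift_analysis(
    dataset: CheckerboardDataset,
    model: str = "bliss",
    convention: str = "mean",
    method: str = "t_test",
    alpha: float = DEFAULT_ALPHA,
    b: int = 1000,
    seed: int = 0,
    clip: bool = True,
    norm_thresholds: tuple[float, float] = DEFAULT_NORM_THRESHOLDS,
) -> RegimeShift:
    """Quantify how the fitting regime alone moves one matrix score.

    The full chain (fit, reference surface, per-point deltas, significance,
    matrix score, normalization) runs once per regime; only the
    single-agent fits differ. ``flip`` is raised when the classification
    of the normalized score changes between regimes.
    """
    raw, normalized, labels = {}, {}, {}
    for regime in REGIMES:
        _, _, per_conv = analyze_regime(
            dataset, model, regime, method=method, alpha=alpha, b=b, seed=seed, clip=clip
        )
        r, n, _ = per_conv[convention]
        raw[regime] = r
        normalized[regime] = n
        labels[regime] = classify(n, norm_thresholds)
    return RegimeShift(
        model=model,
        convention=convention,
        raw=raw,
        normalized=normalized,
        classification=labels,
        raw_shift=raw["constrained"] - raw["unconstrained"],
        normalized_shift=normalized["constrained"] - normalized["unconstrained"],
        flip=labels["constrained"] != labels["unconstrained"],
    )


def separation_statistic(syn_scores, ant_scores) -> float:
    """Distance between designated synergistic and antagonistic score sets.

    Mean normalized score of the synergistic set minus mean of the
    antagonistic set; computed per convention on identical inputs to ask
    which convention spreads the two directions further apart.
    """
    syn = np.asarray(list(syn_scores), dtype=float)
    ant = np.asarray(list(ant_scores), dtype=float)
    if syn.size == 0 or ant.size == 0:
        raise ValueError("need at least one dataset per direction")
    return float(syn.mean() - ant.mean())


def fixture_panel(
    seed: int = 0,
    row: str = "indomethacin_like",
    col: str = "gemcitabine_like",
    noise_sd: float = 5.0,
    n_replicates: int = 4,
) -> list[tuple[str, str, CheckerboardDataset]]:
    """Six seeded checkerboards: three synergistic and three antagonistic.

    Each fixture injects a strong 4x4 interaction block at the high-dose
    corner (|offset| 15-45 % viability, spaced widely so the panel has an
    unambiguous strength ordering) over a faint opposite-signed
    background (2 %) that stays within well noise — so a plain average is
    diluted by many indistinguishable-from-noise cells while a
    significance-gated score is not. Stands in for a panel of drug pairs
    spanning clear synergy to clear antagonism.

    Returns (name, direction, dataset) triples; directions are
    ``"synergistic"`` or ``"antagonistic"``.
    """
    base = config_from_presets(row, col, noise_sd=noise_sd, n_replicates=n_replicates)
    shape = (base.row_doses.size, base.col_doses.size)
    panel = []
    magnitudes = (15.0, 30.0, 45.0)
    for k, mag in enumerate(magnitudes):
        for sign, direction in ((1.0, "synergistic"), (-1.0, "antagonistic")):
            offset = np.full(shape, -sign * 2.0)
            offset[-4:, -4:] = sign * mag
            cfg = base.with_(
                interaction_offset=offset,
                seed=int(seed) * 12 + 2 * k + (0 if sign > 0 else 1),
            )
            name = f"{direction[:3]}_block{int(mag)}"
            panel.append((name, direction, generate_checkerboard(cfg)))
    return panel


def analyze_panel(
    panel,
    model: str = "bliss",
    regime: str = "unconstrained",
    method: str = "t_test",
    alpha: float = DEFAULT_ALPHA,
    b: int = 1000,
    seed: int = 0,
) -> dict:
    """Normalized scores, separation and rank order per convention on a panel.

    Returns ``{convention: {"scores": {name: normalized}, "separation":
    float, "ranking": [names best-to-worst]}}``.
    """
    per_conv = {c: {"scores": {}} for c in CONVENTIONS}
    directions = {}
    for name, direction, dataset in panel:
        directions[name] = direction
        _, _, conv_scores = analyze_regime(
            dataset, model, regime, method=method, alpha=alpha, b=b, seed=seed
        )
        for convention in CONVENTIONS:
            per_conv[convention]["scores"][name] = conv_scores[convention][1]
    for convention in CONVENTIONS:
        scores = per_conv[convention]["scores"]
        syn = [s for n, s in scores.items() if directions[n] == "synergistic"]
        ant = [s for n, s in scores.items() if directions[n] == "antagonistic"]
        per_conv[convention]["separation"] = separation_statistic(syn, ant)
        per_conv[convention]["ranking"] = sorted(scores, key=scores.get, reverse=True)
    return per_conv


@dataclass
class FullAnalysis:
    """Everything the pipeline computes for one dataset."""

    dataset: CheckerboardDataset
    fits: dict  # regime -> (fit_row, fit_col)
    results: dict  # (model, regime) -> SynergyResult
    normalized: dict  # (model, regime, convention) -> float
    classifications: dict  # (model, regime, convention) -> label
    shifts: dict  # (model, convention) -> RegimeShift
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Deterministic, JSON-serializable report."""
        out = {
            "schema_version": 1,
            "row_drug": self.dataset.row_drug,
            "col_drug": self.dataset.col_drug,
            "settings": self.settings,
            "fits": {
                regime: {
                    "row": fr.to_record(self.dataset.row_drug),
                    "col": fc.to_record(self.dataset.col_drug),
                }
                for regime, (fr, fc) in sorted(self.fits.items())
            },
            "scores": {},
            "shifts": {},
        }
        for (model, regime), res in sorted(self.results.items()):
            entry = out["scores"].setdefault(model, {}).setdefault(regime, {})
            entry["mean"] = {
                "raw": res.mean_score,
                "normalized": self.normalized[(model, regime, "mean")],
                "classification": self.classifications[(model, regime, "mean")],
            }
            entry["weighted"] = {
                "raw": res.weighted_score,
                "normalized": self.normalized[(model, regime, "weighted")],
                "classification": self.classifications[(model, regime, "weighted")],
            }
        for (model, convention), shift in sorted(self.shifts.items()):
            out["shifts"].setdefault(model, {})[convention] = {
                "raw_shift": shift.raw_shift,
                "normalized_shift": shift.normalized_shift,
                "classification": dict(shift.classification),
                "flip": shift.flip,
            }
        return out


def run_full_analysis(
    dataset: CheckerboardDataset,
    models=MODELS,
    regimes=REGIMES,
    method: str = "t_test",
    alpha: float = DEFAULT_ALPHA,
    b: int = 1000,
    seed: int = 0,
    clip: bool = True,
    norm_thresholds: tuple[float, float] = DEFAULT_NORM_THRESHOLDS,
    raw_thresholds: tuple[float, float] = DEFAULT_RAW_THRESHOLDS,
) -> FullAnalysis:
    """Run every model x regime x convention combination on one dataset.

    Deterministic for a fixed dataset and seed; the seed only feeds the
    bootstrap significance method.
    """
    fits = {regime: fit_single_agents(dataset, regime) for regime in regimes}
    results, normalized, classifications = {}, {}, {}
    for model in models:
        for regime in regimes:
            _, result, per_conv = analyze_regime(
                dataset, model, regime, method=method, alpha=alpha, b=b,
                seed=seed, clip=clip, fits=fits[regime],
            )
            results[(model, regime)] = result
            for convention in CONVENTIONS:
                raw, norm, _ = per_conv[convention]
                normalized[(model, regime, convention)] = norm
                classifications[(model, regime, convention)] = classify(norm, norm_thresholds)
    shifts = {}
    if set(REGIMES) <= set(regimes):
        for model in models:
            for convention in CONVENTIONS:
                raw = {r: results[(model, r)].score(convention) for r in REGIMES}
                norm = {r: normalized[(model, r, convention)] for r in REGIMES}
                labels = {r: classifications[(model, r, convention)] for r in REGIMES}
                shifts[(model, convention)] = RegimeShift(
                    model=model, convention=convention, raw=raw, normalized=norm,
                    classification=labels,
                    raw_shift=raw["constrained"] - raw["unconstrained"],
                    normalized_shift=norm["constrained"] - norm["unconstrained"],
                    flip=labels["constrained"] != labels["unconstrained"],
                )
    settings = {
        "models": list(models), "regimes": list(regimes), "method": method,
        "alpha": alpha, "bootstrap_resamples": b, "seed": seed, "clip": clip,
        "norm_thresholds": list(norm_thresholds), "raw_thresholds": list(raw_thresholds),
    }
    return FullAnalysis(
        dataset=dataset, fits=fits, results=results, normalized=normalized,
        classifications=classifications, shifts=shifts, settings=settings,
    )
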