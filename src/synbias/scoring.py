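"""Point-by-point synergy deltas, significance, and matrix-level scores.

The delta at a combination cell is the reference-model expectation minus
the observed mean viability, so positive deltas mean the cells died more
than the null model predicts (synergy) and negative deltas mean
antagonism. Per-cell significance comes from either a one-sample t-test
or a replicate bootstrap, both against zero delta at a flat alpha with
no multiple-testing correction by default.

Two matrix-level conventions are provided:

* ``mean_score`` — the plain average delta over all combination cells;
* ``weighted_score`` — a significance-gated signed sum: only cells whose
  delta is individually significant contribute, divided by the total
  number of combination cells. It credits synergistic points and
  penalizes antagonistic ones while ignoring cells indistinguishable from
  noise, and reduces exactly to the plain mean when every cell is
  significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import CheckerboardDataset
from .surfaces import ReferenceSurface

__all__ = [
    "SynergyResult",
    "delta_surface",
    "point_significance",
    "mean_score",
    "weighted_score",
    "classify",
    "score_checkerboard",
]

SIGNIFICANCE_METHODS = ("t_test", "bootstrap")
DEFAULT_ALPHA = 0.05
# Default additive band on raw scores (% viability); the normalized analogue
# is +-0.05. A symmetric small band around zero: scores inside it are called
# additive.
DEFAULT_RAW_THRESHOLDS = (-5.0, 5.0)

_ZERO_VAR_EPS = 1e-9


@dataclass
class SynergyResult:
    """Per-point deltas plus matrix-level scores for one (model, regime) run."""

    model: str
    regime: str
    delta: np.ndarray  # (R, C), expected - observed mean; positive = synergy
    replicate_delta: np.ndarray  # (n_rep, R, C)
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float
    mean_score: float
    weighted_score: float
    classification: str
    significance_method: str = "t_test"
    surface: ReferenceSurface | None = None

    def score(self, convention: str) -> float:
        if convention == "mean":
            return self.mean_score
        if convention == "weighted":
            return self.weighted_score
        raise ValueError(f"unknown convention {convention!r}; expected 'mean' or 'weighted'")


def delta_surface(
    dataset: CheckerboardDataset, surface: ReferenceSurface
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-minus-observed viability at every combination cell.

    Returns ``(delta, replicate_delta)`` with ``delta`` the (R, C) grid
    against the replicate mean and ``replicate_delta`` the per-replicate
    version retained for significance testing. The zero-dose axes are not
    compared — they are single-agent data, not combinations.
    """
    for name, ds_d, surf_d in (
        ("row", dataset.row_doses_pos, surface.row_doses),
        ("col", dataset.col_doses_pos, surface.col_doses),
    ):
        if ds_d.size != surf_d.size or not np.allclose(ds_d, surf_d, rtol=1e-9, atol=0):
            raise ValueError(
                f"{name} dose grids differ between dataset and surface: "
                f"{ds_d.tolist()} vs {np.asarray(surf_d).tolist()}"
            )
    observed = dataset.combination_viability()
    replicate_delta = surface.expected[None, :, :] - observed
    return surface.expected - observed.mean(axis=0), replicate_delta


def point_significance(
    replicate_delta: np.ndarray,
    method: str = "t_test",
    b: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided per-cell p-values for delta != 0 across replicates.

    ``t_test`` is a one-sample Student t of the replicate deltas against
    zero; zero-variance cells (noise-free fixtures) take the degenerate
    limit p = 0 when the mean delta is nonzero and p = 1 otherwise.
    ``bootstrap`` resamples replicates with replacement ``b`` times per
    cell and reports the two-sided tail proportion of resampled mean
    deltas crossing zero, floored at 1/b; it is seeded and reproducible.
    A single replicate supports no inference: p = 1 with a warning.
    """
    if method not in SIGNIFICANCE_METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {SIGNIFICANCE_METHODS}"
        )
    d = np.asarray(replicate_delta, dtype=float)
    n = d.shape[0]
    if n < 2:
        warnings.warn("single replicate: no per-point inference possible, p = 1")
        return np.ones(d.shape[1:])
    if method == "t_test":
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_1samp(d, 0.0, axis=0).pvalue
        degenerate = sd <= _ZERO_VAR_EPS
        p = np.where(degenerate, np.where(np.abs(mean) > _ZERO_VAR_EPS, 0.0, 1.0), p)
        return p
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b,) + d.shape)
    resampled = np.take_along_axis(d[None, ...], idx, axis=1).mean(axis=1)
    frac_le = (resampled <= 0).mean(axis=0)
    frac_ge = (resampled >= 0).mean(axis=0)
    return np.clip(2.0 * np.minimum(frac_le, frac_ge), 1.0 / b, 1.0)


def mean_score(delta: np.ndarray) -> float:
    """Plain average delta over all combination cells (% viability)."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty delta grid")
    return float(delta.mean())


def weighted_score(delta: np.ndarray, significant: np.ndarray) -> float:
    """Significance-gated signed sum of deltas over the number of cells.

    Non-significant cells contribute zero; with every cell significant
    this equals :func:`mean_score` exactly.
    """
    delta = np.asarray(delta, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    if delta.shape != significant.shape:
        raise ValueError("delta and significance grids must share a shape")
    if delta.size == 0:
        raise ValueError("empty delta grid")
    return float(delta[significant].sum() / delta.size)


def classify(score: float, thresholds: tuple[float, float] = DEFAULT_RAW_THRESHOLDS) -> str:
    """Label a matrix score as synergistic / additive / antagonistic.

    Strict inequalities: a score exactly at a threshold stays additive.
    """
    t_ant, t_syn = thresholds
    if not (t_ant < 0 < t_syn):
        raise ValueError("thresholds must satisfy t_ant < 0 < t_syn")
    if score > t_syn:
        return "synergistic"
    if score < t_ant:
        return "antagonistic"
    return "additive"


def score_checkerboard(
    dataset: CheckerboardDataset,
    surface: ReferenceSurface,
    method: str = "t_test",
    alpha: float = DEFAULT_ALPHA,
    b: int = 1000,
    seed: int = 0,
    thresholds: tuple[float, float] = DEFAULT_RAW_THRESHOLDS,
    regime: str | None = None,
) -> SynergyResult:
    """Run delta -> significance -> matrix scores for one dataset/surface pair."""
    delta, replicate_delta = delta_surface(dataset, surface)
    pvalues = point_significance(replicate_delta, method=method, b=b, seed=seed)
    significant = pvalues < alpha
    m = mean_score(delta)
    if regime is None:
        regime = getattr(surface.source_fits[0], "regime", "unknown")
    return SynergyResult(
        model=surface.model,
        regime=regime,
        delta=delta,
        replicate_delta=replicate_delta,
        pvalues=pvalues,
        significant=significant,
        alpha=alpha,
        mean_score=m,
        weighted_score=weighted_score(delta, significant),
        classification=classify(m, thresholds),
        significance_method=method,
        surface=surface,
    )
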