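"""Synthetic checkerboard viability datasets with known ground truth.

Emulates 384-well checkerboard combination assays: two drugs on base-2
dilution series (9 concentrations each by default) plus single-agent rows
and columns and an untreated control, 4 replicate plates, i.i.d. Gaussian
well noise on % viability. Combination truth is generated under one of the
three reference null models (HSA / Loewe / Bliss), optionally shifted by a
per-cell interaction offset (positive = injected synergy), so every
downstream stage can be tested against an exactly known surface.

Single-agent presets cover the archetypes that stress checkerboard
analysis software in characteristic ways:

* ``celecoxib_like`` — high-potency and very steep; its true lower plateau
  sits below 0% so that observed (clipped-at-0) data drop faster than any
  4PL bounded in [0, 100] can follow;
* ``vinorelbine_like`` / ``gemcitabine_like`` — antiproliferative drugs
  plateauing near 20% viability;
* ``carboplatin_like`` — midpoint near the top of its soluble range, so
  the in-range curve never approaches its plateau;
* ``indomethacin_like`` — an ordinary full-range cytotoxic curve;
* ``inactive`` — flat 100% viability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import HillParams, hill_viability
from . import surfaces as _surfaces

__all__ = [
    "PRESETS",
    "PRESET_TOP_DOSES",
    "SimulationConfig",
    "CheckerboardDataset",
    "preset",
    "base2_doses",
    "config_from_presets",
    "generate_checkerboard",
    "generate_extreme_dataset",
]

PRESETS: dict[str, HillParams] = {
    # emin, emax, ec50 (µM), hill slope
    "celecoxib_like": HillParams(100.0, -20.0, 20.0, 3.0),
    "indomethacin_like": HillParams(100.0, 0.0, 150.0, 1.5),
    "vinorelbine_like": HillParams(100.0, 20.0, 0.03, 1.4),
    "gemcitabine_like": HillParams(100.0, 20.0, 0.05, 1.0),
    "carboplatin_like": HillParams(100.0, 0.0, 15.0, 1.2),
    "inactive": HillParams(100.0, 100.0, 1.0, 1.0),
}

# Top concentration (µM) of the default 9-point base-2 series per preset,
# bracketing each preset's midpoint within a realistic soluble range.
PRESET_TOP_DOSES: dict[str, float] = {
    "celecoxib_like": 200.0,
    "indomethacin_like": 1000.0,
    "vinorelbine_like": 0.1,
    "gemcitabine_like": 2.0,
    "carboplatin_like": 20.0,
    "inactive": 100.0,
}


def preset(name: str) -> HillParams:
    """Ground-truth 4PL parameters for a named single-agent archetype."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        ) from None


def base2_doses(top: float, n: int = 9) -> np.ndarray:
    """Ascending base-2 dilution series ending at ``top`` (length ``n``)."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    return top / 2.0 ** np.arange(n - 1, -1, -1, dtype=float)


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic checkerboard experiment.

    ``interaction_offset`` (R x C, % viability) is subtracted from the null
    surface at combination cells before noise and clipping, so positive
    entries inject synergy. ``clip_observations`` models the assay floor
    and ceiling by clipping emitted wells into [0, 100]; it is off by
    default so that the generative model is exactly the stated null.
    """

    row_params: HillParams
    col_params: HillParams
    row_doses: np.ndarray
    col_doses: np.ndarray
    null_model: str = "bliss"
    interaction_offset: np.ndarray | None = None
    noise_sd: float = 5.0
    n_replicates: int = 4
    clip_observations: bool = False
    seed: int = 0
    row_drug: str = "drug_row"
    col_drug: str = "drug_col"
    units: str = "uM"

    def __post_init__(self):
        for name in ("row_doses", "col_doses"):
            d = np.asarray(getattr(self, name), dtype=float)
            if d.ndim != 1 or d.size < 2:
                raise ValueError(f"{name} must be a 1-d sequence of length >= 2")
            if np.any(d <= 0) or np.any(np.diff(d) <= 0):
                raise ValueError(f"{name} must be strictly increasing and positive")
            object.__setattr__(self, name, d)
        if self.null_model not in _surfaces.MODELS:
            raise ValueError(
                f"unknown null model {self.null_model!r}; expected one of {_surfaces.MODELS}"
            )
        shape = (self.row_doses.size, self.col_doses.size)
        off = self.interaction_offset
        off = np.zeros(shape) if off is None else np.asarray(off, dtype=float)
        if off.shape != shape:
            raise ValueError(f"interaction_offset must have shape {shape}, got {off.shape}")
        object.__setattr__(self, "interaction_offset", off)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def config_from_presets(row: str, col: str, **changes) -> SimulationConfig:
    """Convenience config from two preset names with their default dose grids."""
    cfg = SimulationConfig(
        row_params=preset(row),
        col_params=preset(col),
        row_doses=base2_doses(PRESET_TOP_DOSES[row]),
        col_doses=base2_doses(PRESET_TOP_DOSES[col]),
        row_drug=row,
        col_drug=col,
    )
    return cfg.with_(**changes) if changes else cfg


@dataclass
class CheckerboardDataset:
    """Replicate % viability over a (row-drug x column-drug) dose grid.

    Dose axes carry an explicit zero at index 0, so the viability tensor
    has shape (n_replicates, R+1, C+1); position (0, 0) is the untreated
    control (100% up to noise), row/column 0 hold the single-agent data,
    and indices >= 1 the combination cells.
    """

    row_drug: str
    col_drug: str
    row_doses: np.ndarray  # (R+1,), row_doses[0] == 0
    col_doses: np.ndarray  # (C+1,)
    viability: np.ndarray  # (n_replicates, R+1, C+1)
    units: str = "uM"
    truth: np.ndarray | None = field(default=None, repr=False)  # noise-free surface, if known
    config: SimulationConfig | None = field(default=None, repr=False)

    def __post_init__(self):
        self.row_doses = np.asarray(self.row_doses, dtype=float)
        self.col_doses = np.asarray(self.col_doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        for name, d in (("row_doses", self.row_doses), ("col_doses", self.col_doses)):
            if d[0] != 0 or np.any(d < 0) or np.count_nonzero(d == 0) != 1:
                raise ValueError(f"{name} must carry exactly one zero dose, at index 0")
            if np.any(np.diff(d) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        expect = (self.row_doses.size, self.col_doses.size)
        if self.viability.ndim != 3 or self.viability.shape[1:] != expect:
            raise ValueError(
                f"viability must have shape (n_replicates, {expect[0]}, {expect[1]})"
            )

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[0]

    @property
    def row_doses_pos(self) -> np.ndarray:
        """Positive (combination-axis) row doses."""
        return self.row_doses[1:]

    @property
    def col_doses_pos(self) -> np.ndarray:
        return self.col_doses[1:]

    def mean_viability(self) -> np.ndarray:
        return self.viability.mean(axis=0)

    def single_agent(self, axis: str) -> tuple[np.ndarray, np.ndarray]:
        """Single-agent (doses, viability (n_rep, n_doses)) for ``"row"`` or ``"col"``.

        Includes the zero dose, whose observations anchor curve-fit
        initialization but are excluded from the fit itself.
        """
        if axis == "row":
            return self.row_doses, self.viability[:, :, 0]
        if axis == "col":
            return self.col_doses, self.viability[:, 0, :]
        raise ValueError("axis must be 'row' or 'col'")

    def combination_viability(self) -> np.ndarray:
        """Replicate viability at combination cells only, (n_rep, R, C)."""
        return self.viability[:, 1:, 1:]


def _true_surface(config: SimulationConfig, full_row: np.ndarray, full_col: np.ndarray) -> np.ndarray:
    """Noise-free expected viability over the full grid (zero doses included).

    Uses the same reference-surface formulas as the analysis path, so a
    dataset generated under model M with zero offset and zero noise is an
    exact fixed point of an analysis under M.
    """
    kwargs = {"tol": 1e-9} if config.null_model == "loewe" else {}
    surf = _surfaces.surface(
        config.null_model, config.row_params, config.col_params, full_row, full_col, **kwargs
    )
    truth = surf.expected.copy()
    truth[1:, 1:] -= config.interaction_offset
    return truth


def generate_checkerboard(config: SimulationConfig) -> CheckerboardDataset:
    """Simulate one checkerboard experiment from a :class:`SimulationConfig`.

    Deterministic for a fixed config (including seed): identical configs
    yield bit-identical tensors.
    """
    full_row = np.concatenate(([0.0], config.row_doses))
    full_col = np.concatenate(([0.0], config.col_doses))
    truth = _true_surface(config, full_row, full_col)
    rng = np.random.default_rng(config.seed)
    obs = truth[None, :, :] + rng.normal(
        0.0, config.noise_sd, size=(config.n_replicates, full_row.size, full_col.size)
    )
    if config.clip_observations:
        obs = np.clip(obs, 0.0, 100.0)
    return CheckerboardDataset(
        row_drug=config.row_drug, col_drug=config.col_drug,
        row_doses=full_row, col_doses=full_col, viability=obs,
        units=config.units, truth=truth, config=config,
    )


def generate_extreme_dataset(
    direction: str,
    row_params: HillParams,
    col_params: HillParams,
    row_doses,
    col_doses,
    n_replicates: int = 4,
    row_drug: str = "drug_row",
    col_drug: str = "drug_col",
    units: str = "uM",
) -> CheckerboardDataset:
    """Noise-free all-or-nothing combination matrix used as a score yardstick.

    Single-agent rows and columns follow the noise-free 4PL curves; every
    combination cell (both doses positive) is exactly 0% viability
    (``direction="synergistic"``) or exactly 100% (``"antagonistic"``),
    replicated identically. Normalizing a real matrix's score by the score
    of these extremes maps "maximal synergy" to +1 and "maximal
    antagonism" to -1.
    """
    if direction not in ("synergistic", "antagonistic"):
        raise ValueError(
            f"unknown direction {direction!r}; expected 'synergistic' or 'antagonistic'"
        )
    rd = np.asarray(row_doses, dtype=float)
    cd = np.asarray(col_doses, dtype=float)
    if np.any(rd <= 0) or np.any(cd <= 0) or np.any(np.diff(rd) <= 0) or np.any(np.diff(cd) <= 0):
        raise ValueError("dose grids must be strictly increasing and positive")
    full_row = np.concatenate(([0.0], rd))
    full_col = np.concatenate(([0.0], cd))
    grid = np.empty((full_row.size, full_col.size))
    grid[:, 0] = hill_viability(row_params, full_row)
    grid[0, :] = hill_viability(col_params, full_col)
    grid[1:, 1:] = 0.0 if direction == "synergistic" else 100.0
    obs = np.repeat(grid[None, :, :], n_replicates, axis=0)
    return CheckerboardDataset(
        row_drug=row_drug, col_drug=col_drug,
        row_doses=full_row, col_doses=full_col, viability=obs, units=units,
    )
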