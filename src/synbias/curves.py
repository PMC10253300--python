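"""Four-parameter logistic (4PL / Hill) concentration-response curves.

The model is

    v(d) = emax + (emin - emax) / (1 + (d / ec50)**h)

with ``v`` the % viability relative to untreated control, ``d`` the
concentration, ``emin`` the zero-dose plateau (near 100 for data normalized
to control), ``emax`` the infinite-dose plateau (which may fall below 0 for
drugs whose observed curve is steeper than any 0-100-bounded logistic),
``ec50`` the curve midpoint and ``h`` the Hill slope.

Everything downstream (fitting, reference surfaces, the Loewe solver and
the synthetic-data generator) evaluates curves through this module, so the
forward model and its closed-form inverse live in exactly one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillParams",
    "UnreachableEffect",
    "hill_viability",
    "hill_inverse",
    "absolute_ec50",
]


class UnreachableEffect(ValueError):
    """Raised when a target viability lies at or below the curve's lower plateau.

    The Loewe solver consumes this condition as an infinite-dose sentinel
    (the drug's dose-equivalence term vanishes); other callers see an error.
    """


@dataclass(frozen=True)
class HillParams:
    """Parameters of a 4PL viability curve.

    Attributes
    ----------
    emin : float
        % viability at zero dose (upper plateau, ~100 for control-normalized
        data).
    emax : float
        % viability at infinite dose (lower plateau). May be negative for
        overshoot archetypes whose observed, clipped data are steeper than
        any curve bounded in [0, 100].
    ec50 : float
        Midpoint concentration, in the same units as the dose grid. > 0.
    h : float
        Hill slope, > 0.
    """

    emin: float
    emax: float
    ec50: float
    h: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.h > 0):
            raise ValueError(f"Hill slope h must be > 0, got {self.h}")

    @property
    def is_active(self) -> bool:
        """Whether the curve actually decreases (emin > emax)."""
        return self.emin > self.emax + 1e-9


def hill_viability(params: HillParams, dose) -> np.ndarray | float:
    """Evaluate the 4PL curve at one or more non-negative doses.

    ``dose = 0`` returns exactly ``emin``; ``dose -> inf`` approaches
    ``emax``. Negative doses raise ``ValueError``.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / params.ec50) ** params.h, 0.0)
    v = params.emax + (params.emin - params.emax) / (1.0 + ratio)
    return float(v) if np.isscalar(dose) or np.ndim(dose) == 0 else v


def hill_inverse(params: HillParams, target: float, *, unreachable: str = "raise") -> float:
    """Dose at which the curve crosses ``target`` % viability (closed form).

    Defined for ``emax < target <= emin`` on an active curve. ``target ==
    emin`` maps to dose 0. ``target > emin`` is an error (above the zero-dose
    effect). ``target <= emax`` is below the reachable range: raises
    :class:`UnreachableEffect` by default, or returns ``inf`` when
    ``unreachable="inf"`` (the Loewe dose-equivalence limit).
    """
    if not params.is_active:
        raise ValueError("inverse requires an active curve (emin > emax)")
    if target > params.emin:
        raise ValueError(
            f"target {target} exceeds the zero-dose viability emin={params.emin}"
        )
    if target == params.emin:
        return 0.0
    if target <= params.emax:
        if unreachable == "inf":
            return math.inf
        raise UnreachableEffect(
            f"target {target} at or below the lower plateau emax={params.emax}"
        )
    # (d/ec50)^h = (emin - v)/(v - emax)
    ratio = (params.emin - target) / (target - params.emax)
    return params.ec50 * ratio ** (1.0 / params.h)


def absolute_ec50(params: HillParams) -> float | None:
    """Dose where the curve crosses 50% viability in absolute terms.

    Distinct from the relative midpoint ``ec50`` whenever the plateaus are
    not exactly 100 and 0. Returns ``None`` when the curve never crosses 50
    within its plateau range.
    """
    if not params.is_active:
        return None
    if not (params.emax < 50.0 < params.emin):
        return None
    return hill_inverse(params, 50.0)
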