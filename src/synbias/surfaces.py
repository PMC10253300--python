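"""Expected-viability reference surfaces: HSA, Bliss and Loewe.

Each surface maps two single-agent 4PL curves onto a checkerboard dose
grid and states what the combination viability *should* be if the drugs
did not interact, under one of the three classical null models:

* HSA (highest single agent): the combination matches the stronger drug,
  i.e. the minimum of the two single-agent viabilities;
* Bliss independence: survival fractions multiply;
* Loewe additivity: dose equivalence — the expected effect E solves
  ``d1/D1(E) + d2/D2(E) = 1`` where ``Dk(E)`` is the dose of drug k alone
  producing E.

Surfaces are always computed from fitted (or ground-truth) curves, never
from raw single-agent observations: curve fitting is exactly the channel
through which the two fitting regimes produce diverging synergy calls,
and it must flow through these surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .curves import HillParams, hill_inverse, hill_viability

__all__ = ["ReferenceSurface", "hsa_surface", "bliss_surface", "loewe_surface", "surface"]

MODELS = ("hsa", "loewe", "bliss")

_ACTIVE_EPS = 1e-9


@dataclass
class ReferenceSurface:
    """Expected % viability over a (row-drug x column-drug) dose grid."""

    model: str
    row_doses: np.ndarray
    col_doses: np.ndarray
    expected: np.ndarray  # (R, C) % viability
    source_fits: tuple  # the two HillFit (or HillParams) the surface was built from
    clip_policy: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def _params_of(fit_or_params) -> HillParams:
    return getattr(fit_or_params, "params", fit_or_params)


def _check_converged(fit) -> None:
    if getattr(fit, "converged", True) is False:
        raise ValueError("surface requires converged fits")


def _margins(fit1, fit2, row_doses, col_doses, clip: bool):
    p1, p2 = _params_of(fit1), _params_of(fit2)
    v1 = np.atleast_1d(hill_viability(p1, np.asarray(row_doses, dtype=float)))
    v2 = np.atleast_1d(hill_viability(p2, np.asarray(col_doses, dtype=float)))
    if clip:
        v1, v2 = np.clip(v1, 0.0, 100.0), np.clip(v2, 0.0, 100.0)
    return v1, v2


def hsa_surface(fit1, fit2, row_doses, col_doses, clip: bool = True) -> ReferenceSurface:
    """Highest-single-agent surface: minimum viability of the two drugs."""
    _check_converged(fit1), _check_converged(fit2)
    v1, v2 = _margins(fit1, fit2, row_doses, col_doses, clip)
    expected = np.minimum.outer(v1, v2)
    return ReferenceSurface(
        model="hsa", row_doses=np.asarray(row_doses, float),
        col_doses=np.asarray(col_doses, float), expected=expected,
        source_fits=(fit1, fit2), clip_policy={"clip_single_agents": clip},
    )


def bliss_surface(fit1, fit2, row_doses, col_doses, clip: bool = True) -> ReferenceSurface:
    """Bliss independence surface: product of single-agent survival fractions.

    Bliss presumes fractional effects; fitted viabilities are clipped into
    [0, 100] before the product by default. With ``clip=False`` a negative
    lower plateau propagates into the product — this is precisely where a
    constrained and an unconstrained fit of an overshooting drug diverge —
    and the out-of-range condition is recorded in ``clip_policy`` rather
    than raised.
    """
    _check_converged(fit1), _check_converged(fit2)
    v1, v2 = _margins(fit1, fit2, row_doses, col_doses, clip)
    expected = np.multiply.outer(v1, v2) / 100.0
    policy = {"clip_single_agents": clip}
    if not clip and (np.any(v1 < 0) or np.any(v2 < 0) or np.any(v1 > 100) or np.any(v2 > 100)):
        policy["out_of_range_margins"] = True
    return ReferenceSurface(
        model="bliss", row_doses=np.asarray(row_doses, float),
        col_doses=np.asarray(col_doses, float), expected=expected,
        source_fits=(fit1, fit2), clip_policy=policy,
    )


def _loewe_cell(d1: float, d2: float, p1: HillParams, p2: HillParams, tol: float) -> float:
    """Solve the Loewe interaction index for one dose pair.

    The index g(E) = d1/D1(E) + d2/D2(E) is monotone increasing in viability
    E (weaker effects need smaller dose equivalents); the root of g(E) = 1
    is bracketed between the reachable plateaus and found by Brent's method.
    Unreachable effects contribute a vanishing term (D = inf).
    """
    active = [p for p in (p1, p2) if p.is_active]
    hi = min(p.emin for p in active)
    # Effects below one drug's plateau are still reachable by the other:
    # that drug's index term simply vanishes (D = inf). The bracket
    # bottoms at the lower plateau of the two.
    lo = min(p.emax for p in active)

    def g(E: float) -> float:
        total = 0.0
        for d, p in ((d1, p1), (d2, p2)):
            if d <= 0 or not p.is_active:
                continue
            D = hill_inverse(p, E, unreachable="inf")
            if D == 0.0:
                return math.inf
            total += d / D
        return total - 1.0

    eps = max(1e-12, (hi - lo) * 1e-12)
    e_lo, e_hi = lo + eps, hi - eps
    g_lo = g(e_lo)
    if g_lo >= 0.0:
        # Doses exceed what is needed for the strongest reachable effect.
        return lo
    g_hi = g(e_hi)
    if g_hi <= 0.0:
        # Doses too small for any appreciable joint effect.
        return hi
    return brentq(g, e_lo, e_hi, xtol=min(tol, 1e-8) * 1e-2, maxiter=200)


def loewe_surface(
    fit1, fit2, row_doses, col_doses, tol: float = 1e-6, clip: bool = True
) -> ReferenceSurface:
    """Loewe additivity surface via the implicit dose-equivalence equation.

    Requires at least one active curve. When a drug cannot reach the probed
    effect its dose-equivalent is treated as infinite (its index term
    vanishes), which keeps the solver defined for partial-effect drugs.
    Cells where no bracketed root exists (e.g. both drugs inactive) fall
    back to the no-effect viability and are flagged.

    With ``clip`` set (default) the solved expected viability is clipped
    into [0, 100]; fitted curves with plateaus outside that range (a free
    lower plateau below 0, or an upper plateau slightly above 100) would
    otherwise yield unphysical expectations.
    """
    _check_converged(fit1), _check_converged(fit2)
    p1, p2 = _params_of(fit1), _params_of(fit2)
    if not (p1.is_active or p2.is_active):
        rd, cd = np.asarray(row_doses, float), np.asarray(col_doses, float)
        expected = np.full((rd.size, cd.size), min(p1.emin, p2.emin))
        if clip:
            expected = np.clip(expected, 0.0, 100.0)
        return ReferenceSurface(
            model="loewe", row_doses=rd, col_doses=cd, expected=expected,
            source_fits=(fit1, fit2), clip_policy={"tol": tol, "clip_expected": clip},
            flags={"no_active_curve": True},
        )
    rd = np.atleast_1d(np.asarray(row_doses, dtype=float))
    cd = np.atleast_1d(np.asarray(col_doses, dtype=float))
    expected = np.empty((rd.size, cd.size))
    for i, d1 in enumerate(rd):
        for j, d2 in enumerate(cd):
            contributors = [
                (d, p) for d, p in ((d1, p1), (d2, p2)) if d > 0 and p.is_active
            ]
            if len(contributors) == 2:
                expected[i, j] = _loewe_cell(d1, d2, p1, p2, tol)
            elif len(contributors) == 1:
                d, p = contributors[0]
                expected[i, j] = hill_viability(p, d)
            else:
                # No active drug at a positive dose: no-effect viability.
                expected[i, j] = min(hill_viability(p1, d1), hill_viability(p2, d2))
    if clip:
        expected = np.clip(expected, 0.0, 100.0)
    return ReferenceSurface(
        model="loewe", row_doses=rd, col_doses=cd, expected=expected,
        source_fits=(fit1, fit2), clip_policy={"tol": tol, "clip_expected": clip},
    )


def surface(model: str, fit1, fit2, row_doses, col_doses, **kwargs) -> ReferenceSurface:
    """Dispatch to one of the three reference models by name."""
    if model == "hsa":
        return hsa_surface(fit1, fit2, row_doses, col_doses, **kwargs)
    if model == "bliss":
        return bliss_surface(fit1, fit2, row_doses, col_doses, **kwargs)
    if model == "loewe":
        return loewe_surface(fit1, fit2, row_doses, col_doses, **kwargs)
    raise ValueError(f"unknown reference model {model!r}; expected one of {MODELS}")
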