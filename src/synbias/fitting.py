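"""Single-agent concentration-response fitting under two regimes.

The two regimes reproduce the two fitting philosophies found in popular
checkerboard-analysis software:

* ``constrained`` — the curve is forced to span the full effect range:
  plateaus pinned at 100% (zero dose) and 0% (infinite dose) viability,
  leaving only the midpoint and slope free;
* ``unconstrained`` — the lower plateau is free (may fall below 0), while
  the upper plateau is softly anchored near the control level (80-120).

The divergence between the two on drugs whose observed curve is steeper
than any 0-100-bounded logistic is the bias mechanism this package
quantifies downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curves import HillParams, absolute_ec50, hill_inverse, hill_viability

__all__ = ["HillFit", "ResidualProfile", "fit_curve", "predict", "inverse_dose", "residual_profile"]

REGIMES = ("constrained", "unconstrained")

H_BOUNDS = (0.05, 20.0)  # keeps the closed-form inverse numerically stable
_FLAT_TOL = 1e-6


@dataclass
class HillFit:
    """A fitted 4PL curve with its regime tag and diagnostics."""

    params: HillParams
    regime: str
    rmse: float
    residuals: np.ndarray  # signed, observed - fitted, one per (dose, replicate)
    converged: bool
    absolute_ec50: float | None
    doses: np.ndarray = field(default=None, repr=False)  # positive doses used in the fit
    flat: bool = False

    def to_record(self, drug: str | None = None) -> dict:
        """JSON-serializable summary of the fit."""
        rec = {
            "regime": self.regime,
            "emin": self.params.emin,
            "emax": self.params.emax,
            "ec50": self.params.ec50,
            "h": self.params.h,
            "rmse": self.rmse,
            "absolute_ec50": self.absolute_ec50,
            "converged": self.converged,
            "flat": self.flat,
        }
        if drug is not None:
            rec["drug"] = drug
        return rec


def _pack_viability(doses, viability):
    """Normalize inputs to (doses[k], table[replicate, k]) and split off dose 0."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.shape[1] != d.size:
        raise ValueError(f"viability has {y.shape[1]} dose columns, expected {d.size}")
    pos = d > 0
    zero_obs = y[:, ~pos].ravel()
    return d[pos], y[:, pos], zero_obs


def fit_curve(doses, viability, regime: str = "unconstrained") -> HillFit:
    """Least-squares 4PL fit of replicate-level viability data.

    Parameters
    ----------
    doses
        Concentration per column; any zero-dose entries are excluded from
        the fit itself but their observations anchor the emin initialization.
    viability
        % viability, shape (n_replicates, n_doses) or (n_doses,).
    regime
        ``"constrained"`` or ``"unconstrained"`` (see module docstring).

    The fit is run from a multi-start grid (ec50 initialized at each dose
    decade spanned by the data, Hill slope at {0.5, 1, 2, 4}) on raw
    replicate points with plain least squares; the best-RMSE converged start
    wins, ties broken by the lower slope. All-flat data return a flagged
    flat fit rather than failing.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    d, y, zero_obs = _pack_viability(doses, viability)
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct positive doses")
    y_flat = y.ravel()
    d_flat = np.tile(d, y.shape[0])

    level = float(np.mean(y_flat))
    if float(np.std(y_flat)) < _FLAT_TOL and (
        zero_obs.size == 0 or abs(float(np.mean(zero_obs)) - level) < _FLAT_TOL
    ):
        # Degenerate flat data: no slope information at all.
        emin = min(max(level, 0.0), 100.0) if regime == "constrained" else level
        p = HillParams(emin=max(emin, 1e-9), emax=emin, ec50=float(np.median(d)), h=H_BOUNDS[0])
        fitted = hill_viability(p, d_flat)
        res = y_flat - fitted
        return HillFit(
            params=p, regime=regime, rmse=float(np.sqrt(np.mean(res**2))),
            residuals=res, converged=True, absolute_ec50=absolute_ec50(p),
            doses=d, flat=True,
        )

    emin0 = float(np.mean(zero_obs)) if zero_obs.size else float(np.max(y_flat))
    emax0 = float(np.min(y_flat))

    log_ec50_lo = math.log(d.min()) - math.log(1e3)
    log_ec50_hi = math.log(d.max()) + math.log(1e3)
    if regime == "constrained":
        # The curve is forced to span the full 0-100% viability range: both
        # plateaus pinned (emin = 100, emax = 0), only midpoint and slope
        # fitted. This is what makes the regime systematically misfit drugs
        # whose observed data decline early or never reach full effect.
        lb = np.array([log_ec50_lo, H_BOUNDS[0]])
        ub = np.array([log_ec50_hi, H_BOUNDS[1]])

        def unpack(theta):
            log_ec50, h = theta
            return 100.0, 0.0, math.exp(log_ec50), h

        def make_start(ec50_0, h0):
            return np.array([math.log(ec50_0), h0])
    else:
        # theta = (emin, emax, log_ec50, h); lower plateau free below zero.
        lb = np.array([80.0, -500.0, log_ec50_lo, H_BOUNDS[0]])
        ub = np.array([120.0, 120.0, log_ec50_hi, H_BOUNDS[1]])

        def unpack(theta):
            emin, emax, log_ec50, h = theta
            return emin, emax, math.exp(log_ec50), h

        def make_start(ec50_0, h0):
            emin = min(max(emin0, 80.0), 120.0)
            emax = min(max(emax0, -499.0), emin - 1.0)
            return np.array([emin, emax, math.log(ec50_0), h0])

    def fun(theta):
        emin, emax, ec50, h = unpack(theta)
        pred = emax + (emin - emax) / (1.0 + (d_flat / ec50) ** h)
        return pred - y_flat

    # ec50 starts: each power of 10 spanned by the dose range, plus geometric mean.
    lo_dec, hi_dec = math.floor(math.log10(d.min())), math.ceil(math.log10(d.max()))
    ec50_starts = [10.0**k for k in range(lo_dec, hi_dec + 1)]
    ec50_starts.append(math.sqrt(d.min() * d.max()))

    candidates = []
    failures = []
    for ec50_0 in ec50_starts:
        for h0 in (0.5, 1.0, 2.0, 4.0):
            x0 = np.clip(make_start(ec50_0, h0), lb, ub)
            try:
                sol = least_squares(fun, x0, bounds=(lb, ub), method="trf", xtol=1e-10)
            except Exception as exc:  # pragma: no cover - scipy internal failure
                failures.append((ec50_0, h0, repr(exc)))
                continue
            if not sol.success:
                failures.append((ec50_0, h0, sol.message))
                continue
            emin, emax, ec50, h = unpack(sol.x)
            rmse = float(np.sqrt(np.mean(sol.fun**2)))
            candidates.append((rmse, h, HillParams(emin, emax, ec50, h), -sol.fun))
    if not candidates:
        raise RuntimeError(f"4PL fit failed from every start; diagnostics: {failures}")

    best_rmse = min(c[0] for c in candidates)
    rmse, _, p, resid = min(
        (c for c in candidates if c[0] <= best_rmse + 1e-9), key=lambda c: c[1]
    )
    return HillFit(
        params=p, regime=regime, rmse=rmse, residuals=resid, converged=True,
        absolute_ec50=absolute_ec50(p), doses=d,
    )


def predict(fit: HillFit, dose):
    """Evaluate a converged fit at non-negative dose(s)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return hill_viability(fit.params, dose)


def inverse_dose(fit: HillFit, target: float, *, unreachable: str = "raise") -> float:
    """Dose producing ``target`` % viability under a converged, active fit.

    Raises :class:`~synbias.curves.UnreachableEffect` (or returns ``inf``
    with ``unreachable="inf"``) for targets at or below the lower plateau.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    return hill_inverse(fit.params, target, unreachable=unreachable)


@dataclass
class ResidualProfile:
    """Signed fit bias (fitted - observed) split around the absolute EC50."""

    per_dose: np.ndarray  # mean fitted - observed at each positive dose
    doses: np.ndarray
    below_ec50: float  # mean over doses strictly below the pivot
    above_ec50: float  # mean over doses strictly above the pivot
    pivot: float
    pivot_is_absolute: bool  # False when the curve never crosses 50% viability


def residual_profile(fit: HillFit, doses, viability) -> ResidualProfile:
    """Per-dose mean signed residuals of a fit on its own data.

    Residuals here are oriented fitted - observed, so a positive value
    means the fitted curve sits above the data. The summary averages the
    per-dose residuals below and above the absolute EC50 (falling back,
    flagged, to the relative midpoint when the fitted curve never crosses
    50% viability).
    """
    d, y, _ = _pack_viability(doses, viability)
    fitted = hill_viability(fit.params, d)
    per_dose = fitted - y.mean(axis=0)
    if fit.absolute_ec50 is not None:
        pivot, is_abs = fit.absolute_ec50, True
    else:
        pivot, is_abs = fit.params.ec50, False
    below = d < pivot
    above = d > pivot
    return ResidualProfile(
        per_dose=per_dose,
        doses=d,
        below_ec50=float(per_dose[below].mean()) if below.any() else math.nan,
        above_ec50=float(per_dose[above].mean()) if above.any() else math.nan,
        pivot=pivot,
        pivot_is_absolute=is_abs,
    )
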