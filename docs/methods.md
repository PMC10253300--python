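# Methods

This document records the model, the numerics, and the design decisions
behind `synbias`. Everything here is implemented in `src/synbias/` and
exercised by `tests/`; `scripts/acceptance.py` recomputes the headline
quantities.

## Dose–response model

Single-agent response is the four-parameter logistic (4PL / Hill)
curve in viability units (% of untreated control, 100 = no effect):

```
v(d) = Emax + (Emin − Emax) / (1 + (d / EC50)^h)
```

with `Emin` the zero-dose plateau, `Emax` the high-dose plateau, `EC50`
the half-way dose between the plateaus, and `h` the Hill slope. The
closed-form inverse maps a viability back to a dose; effects outside
the open plateau interval are unreachable, and callers choose whether
that is an error, `NaN`, or an infinite dose (`hill_inverse`).

Two EC50 notions are kept distinct:

- **relative EC50** — the fitted midpoint parameter;
- **absolute EC50** — the dose where the curve crosses 50% viability,
  obtained from the inverse. For full-range curves the two coincide;
  for partial-effect or overshooting curves they do not. Residual
  diagnostics pivot on the absolute EC50 because "above/below half
  kill" is the operationally meaningful split.

## Dual fitting regimes

`fit_curve(doses, viability, regime=...)` fits the 4PL by bounded
nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) on the replicate-level data, multistarted over a grid of
EC50 decades and slopes `h ∈ {0.5, 1, 2, 4}` with the best solution
kept. Zero-dose wells anchor the initialization but are excluded from
the fit. The two regimes are:

- **`constrained`** — both plateaus pinned: `Emin = 100`, `Emax = 0`;
  only `(EC50, h)` are free (EC50 is fitted in log space). The curve is
  forced to span the full 0–100% range.
- **`unconstrained`** — all four parameters free, with
  `Emin ∈ [80, 120]` (the untreated control is measured, so the top
  plateau may only wander within assay noise) and `Emax ∈ [−500, 120]`
  (the bottom plateau may sit below full kill, as steep compounds'
  normalized viability often does).

Why pinning rather than a narrow box for the constrained regime: with
any freedom at all in `Emax`, least-squares stationarity lets the
bottom plateau absorb the mean of the floor-censored data (observations
clipped at 0% have a positive mean), which erases precisely the misfit
this regime is meant to exhibit. Pinning makes the constrained regime a
faithful "full-range" fitter: on data whose true curve overshoots, its
signed residuals are positive below the absolute EC50 and negative
above it, and its RMSE exceeds the unconstrained fit's (see
`residual_profile` and `tests/test_acceptance.py::test_4`).

Flat, inactive data (no crossing, no slope information) are flagged
(`HillFit.flat`) and represented by an inactive curve rather than a
spurious fit.

## Reference surfaces

All three references are computed **from the fitted curves only** —
never from the raw combination wells — so the only thing that differs
between regimes downstream is the pair of single-agent fits.

- **HSA** (highest single agent): `E(d1, d2) = min(v1(d1), v2(d2))`.
- **Bliss** (independence): on kill fractions, multiplicativity of
  survival: `E = v1 · v2 / 100`.
- **Loewe** (dose additivity): `E` solves the interaction index
  equation `d1/D1(E) + d2/D2(E) = 1`, where `Di(E)` is drug *i*'s dose
  equivalent for effect `E` from the inverse Hill curve.

### Loewe solver

The index `g(E) = d1/D1(E) + d2/D2(E)` is monotone in viability
(weaker effects need smaller dose equivalents), so the root is
bracketed and found with Brent's method. Two bracket subtleties:

- the bracket **top** is `min(Emin)` of the active curves (no joint
  effect can be weaker than the weaker zero-dose plateau);
- the bracket **bottom** is `min(Emax)`, not `max(Emax)`: effects below
  one drug's plateau are still reachable — that drug's dose equivalent
  is infinite and its index term simply vanishes, leaving the other
  drug to satisfy the equation alone. (Using `max(Emax)` silently
  truncates the surface wherever one drug has a partial effect.)

Doses beyond the strongest reachable effect return the lower plateau;
doses too small for any appreciable effect return the upper plateau.
Inactive partners reduce exactly to the single-agent curve. The solver
is validated two ways: the sham test (a drug combined with itself must
reproduce its own curve at the summed dose, max error ~1e-12) and a
grid-scan oracle that resolves the index equation by brute force on a
100,000-point effect grid over random curve pairs (worst disagreement
< 0.1% viability; `loewe_max_index_residual` ~1e-9).

### Clipping policy

Fitted curves can predict viability outside [0, 100] (unconstrained
`Emax < 0`, `Emin > 100`). By default (`clip=True`) the single-agent
margins entering HSA/Bliss are clipped into [0, 100], and the Loewe
output surface is likewise clipped. This guarantees the structural
stringency ordering — pointwise `bliss ≤ hsa` and `loewe ≤ hsa` — for
any fits (clipping is monotone and commutes with `min`; the unclipped
Loewe solution never exceeds the smaller single-agent margin). Setting
`clip=False` exposes the raw fitted surfaces; every surface records its
`clip_policy`.

## Scoring

For a dataset with replicate tensor `obs` and reference surface `E`:

- **delta grid**: `delta(i, j) = E(i, j) − mean obs(i, j)`, in %
  viability, **positive = synergy** (cells killed beyond the
  expectation).
- **per-point significance**: one-sample t-test of the replicate
  deltas against 0 (default), or a seeded bootstrap of the replicate
  mean (tail proportion, floored at 1/B). Zero-variance cells use the
  degenerate limit: p = 0 if the mean delta is nonzero, else 1.
  Significance is `p < alpha`, default `alpha = 0.05`.
- **matrix scores**: `mean_score` is the plain average of delta over
  all combination cells; `weighted_score` sums only significant deltas
  and divides by the full cell count. The weighted convention is a
  noise gate: diffuse sub-noise structure is excluded, concentrated
  real structure is kept (on the six-fixture panel it separates
  designated synergistic from antagonistic datasets more widely than
  the mean, with identical rank ordering).
- **classification**: synergistic / additive / antagonistic with a
  symmetric additive band, ±5 raw (% viability) or ±0.05 normalized.
  The band width is a deliberate, recorded default ("small symmetric
  band"), not an estimated quantity.

## Normalization against extremes

Raw scores depend on the dose grid and the drugs' potencies, so they
are not comparable across experiments. `synbias` normalizes against
the two **extreme matrices** built on the same fitted curves and dose
grid: single-agent axes follow the fits, and every combination cell is
exactly 0% (maximal synergy) or exactly 100% (maximal antagonism)
viability. Scoring these against the same reference surface gives
constants `s_syn > 0 > s_ant`; a raw score `s` maps to

```
normalized = s / s_syn        if s ≥ 0
           = s / |s_ant|      otherwise
```

so the extremes themselves land exactly on +1 and −1, and 0 is a fixed
point. Constants are computed per regime (each regime's own fits build
its own yardstick) and per convention. Note the two denominators sum
to 100% viability for full-range fits — a useful identity: a
classification flip across the ±0.05 normalized band always requires a
raw score gap of at least 5% viability.

## Simulator

`generate_checkerboard(config)` produces replicate viability tensors
over a 9×9 base-2 dilution grid plus single-agent axes and the
untreated anchor:

1. the **true surface** is the chosen null model (HSA / Loewe / Bliss)
   applied to the true generating curves, using the same clipped
   reference formulas as the analysis path — so a zero-offset,
   zero-noise dataset is an exact fixed point of an analysis under the
   same model (the assay cannot report beyond full kill, so true
   surfaces do not extend below 0%);
2. a per-cell **interaction offset** (in % viability; positive injects
   synergy) is subtracted at combination cells;
3. i.i.d. Gaussian noise (default `sd = 5`) is added per replicate
   (default 4);
4. optionally (`clip_observations=True`) the emitted wells are clipped
   into [0, 100], modelling the assay floor and ceiling.

Drug archetypes (`PRESETS`, doses via `PRESET_TOP_DOSES`):

| preset | Emin | Emax | EC50 | h | character |
|---|---|---|---|---|---|
| `celecoxib_like` | 100 | −20 | 20 | 3.0 | steep, overshoots below 0 |
| `indomethacin_like` | 100 | 0 | 150 | 1.5 | shallow, full range |
| `vinorelbine_like` | 100 | 20 | 0.03 | 1.4 | potent, partial (≈20% survivors) |
| `gemcitabine_like` | 100 | 20 | 0.05 | 1.0 | potent, partial, shallow |
| `carboplatin_like` | 100 | 0 | 15 | 1.2 | full range, mid-grid EC50 |
| `inactive` | 100 | 100 | — | — | no effect |

The `celecoxib_like` parameters were calibrated once, against the
qualitative behavior the archetype must exhibit (constrained-fit
residual sign pattern, RMSE ordering, positive additive-board score
shift), and then frozen; they were not adjusted against test outcomes
afterwards.

## Bias analysis

- `regime_shift_analysis` runs the identical chain (fit → surface →
  score → normalize → classify) under both regimes; only the
  single-agent fits differ. It reports raw and normalized scores per
  regime, `raw_shift = constrained − unconstrained`, and a `flip` flag
  when the classifications disagree.
- The **flip mechanism** worth knowing about: on boards dosed far past
  full kill with floor-clipped observations, floored wells have mean
  `sd/√(2π)` (the mean of a half-censored Gaussian) rather than 0. The
  unconstrained fit absorbs that into a small positive `Emax`; the
  pinned constrained fit cannot, and reads the same wells as
  antagonism. Over a grid that is mostly floored this gap exceeds the
  5%-viability flip threshold, and a small uniform synergy offset
  positions the two regimes on opposite sides of the additive band —
  antagonistic under `constrained`, synergistic under `unconstrained`,
  on identical wells (`examples/regime_bias.py`).
- `fixture_panel` + `analyze_panel` provide a six-dataset panel (three
  synergistic, three antagonistic block fixtures over faint
  opposite-signed backgrounds) and a `separation_statistic` comparing
  how widely each scoring convention spreads the two directions.

## Limitations

- The 4PL is the only single-agent model; biphasic or non-monotone
  responses are out of scope.
- Loewe requires at least one active fitted curve; two inactive drugs
  return the flat no-effect surface with a flag.
- Per-point significance treats cells independently; no multiple-
  testing correction is applied (the weighted score is a gate, not an
  inference procedure).
- The simulator's noise is i.i.d. Gaussian per well; plate effects,
  edge effects, and dose-dependent variance are not modelled.
- Normalization constants depend on the fitted curves, so normalized
  scores inherit fit uncertainty; extremes are noise-free by design.
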