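"""Reading/writing checkerboard CSV formats, reports and heatmaps.

Two CSV dialects are supported:

* ``wide_grid`` — one file per replicate; the first column carries the
  row-drug concentrations, the header row the column-drug concentrations
  (both including the zero dose), each cell a % viability.
* ``long_table`` — a single file, one row per well, with columns
  ``block_id, drug_row, drug_col, conc_row, conc_col, response,
  conc_unit, replicate``.

Viability is stored as percent of untreated control (0-100 scale).
Fraction-scale input (everything <= 1.5) is rejected with a message
rather than silently rescaled. Concentrations stay in their native units;
no conversion is performed.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CheckerboardDataset

__all__ = [
    "LONG_COLUMNS",
    "read_checkerboard",
    "write_checkerboard",
    "write_report",
    "plot_heatmap",
    "plot_fit",
]

DIALECTS = ("wide_grid", "long_table")
LONG_COLUMNS = [
    "block_id", "drug_row", "drug_col", "conc_row", "conc_col",
    "response", "conc_unit", "replicate",
]


def _check_scale(values: np.ndarray) -> None:
    if np.nanmax(values) <= 1.5:
        raise ValueError(
            "responses look fraction-scaled (max <= 1.5); supply % viability "
            "on the 0-100 scale instead"
        )


def _require_zero_axis(doses: np.ndarray, axis: str) -> None:
    if not np.any(doses == 0):
        raise ValueError(f"single-agent data required: no zero dose on the {axis} axis")


def write_checkerboard(dataset: CheckerboardDataset, path, dialect: str = "long_table") -> list[Path]:
    """Serialize a dataset; returns the file(s) written.

    ``long_table`` writes one CSV at ``path``. ``wide_grid`` writes one
    CSV per replicate named ``<stem>_rep<k><suffix>`` next to ``path``.
    """
    path = Path(path)
    if dialect == "long_table":
        rows = []
        for r in range(dataset.n_replicates):
            for i, ci in enumerate(dataset.row_doses):
                for j, cj in enumerate(dataset.col_doses):
                    rows.append((
                        "block1", dataset.row_drug, dataset.col_drug, ci, cj,
                        dataset.viability[r, i, j], dataset.units, r + 1,
                    ))
        pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)
        return [path]
    if dialect == "wide_grid":
        written = []
        for r in range(dataset.n_replicates):
            df = pd.DataFrame(
                dataset.viability[r],
                index=dataset.row_doses,
                columns=dataset.col_doses,
            )
            df.index.name = "conc"
            out = path.with_name(f"{path.stem}_rep{r + 1}{path.suffix or '.csv'}")
            df.to_csv(out)
            written.append(out)
        return written
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_wide(paths, row_drug: str, col_drug: str, units: str) -> CheckerboardDataset:
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    replicates = []
    ref_rows = ref_cols = None
    for path in paths:
        raw = pd.read_csv(path, index_col=0)
        try:
            rows = raw.index.to_numpy(dtype=float)
            cols = np.asarray([float(c) for c in raw.columns])
            values = raw.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
        if np.unique(rows).size != rows.size or np.unique(cols).size != cols.size:
            raise ValueError(f"duplicate concentration labels in {path}")
        # Canonical order is ascending; a shuffled file is sorted, values
        # permuted to match.
        ri, cj = np.argsort(rows), np.argsort(cols)
        rows, cols, values = rows[ri], cols[cj], values[np.ix_(ri, cj)]
        if ref_rows is None:
            ref_rows, ref_cols = rows, cols
        elif not (np.array_equal(rows, ref_rows) and np.array_equal(cols, ref_cols)):
            raise ValueError(f"replicate {path} has a different dose grid")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(f"non-numeric or missing cell in {path} at grid position ({i}, {j})")
        replicates.append(values)
    _require_zero_axis(ref_rows, "row")
    _require_zero_axis(ref_cols, "column")
    viability = np.stack(replicates)
    _check_scale(viability)
    return CheckerboardDataset(
        row_drug=row_drug, col_drug=col_drug, row_doses=ref_rows,
        col_doses=ref_cols, viability=viability, units=units,
    )


def _read_long(path) -> CheckerboardDataset:
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long_table file {path} lacks columns {missing}")
    for col in ("conc_row", "conc_col", "response"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric {col} at data row {bad} of {path}")
        df[col] = coerced
    if df["block_id"].nunique() != 1:
        raise ValueError("expected a single block per file")
    dupes = df.duplicated(subset=["conc_row", "conc_col", "replicate"])
    if dupes.any():
        rec = df[dupes].iloc[0]
        raise ValueError(
            f"duplicate well (conc_row={rec.conc_row}, conc_col={rec.conc_col}, "
            f"replicate={rec.replicate}) in {path}"
        )
    row_doses = np.sort(df["conc_row"].unique())
    col_doses = np.sort(df["conc_col"].unique())
    _require_zero_axis(row_doses, "row")
    _require_zero_axis(col_doses, "column")
    reps = np.sort(df["replicate"].unique())
    if len(df) != reps.size * row_doses.size * col_doses.size:
        raise ValueError(
            f"{path} is not a complete grid: {len(df)} wells, expected "
            f"{reps.size} x {row_doses.size} x {col_doses.size}"
        )
    ri = {c: i for i, c in enumerate(row_doses)}
    cj = {c: j for j, c in enumerate(col_doses)}
    rk = {r: k for k, r in enumerate(reps)}
    viability = np.full((reps.size, row_doses.size, col_doses.size), np.nan)
    for rec in df.itertuples(index=False):
        viability[rk[rec.replicate], ri[rec.conc_row], cj[rec.conc_col]] = rec.response
    _check_scale(viability)
    return CheckerboardDataset(
        row_drug=str(df["drug_row"].iloc[0]), col_drug=str(df["drug_col"].iloc[0]),
        row_doses=row_doses, col_doses=col_doses, viability=viability,
        units=str(df["conc_unit"].iloc[0]),
    )


def read_checkerboard(
    path, dialect: str = "long_table", row_drug: str = "drug_row",
    col_drug: str = "drug_col", units: str = "uM",
) -> CheckerboardDataset:
    """Parse a checkerboard dataset from CSV.

    ``path`` is one file for ``long_table``, or one file / list of files
    (one per replicate) for ``wide_grid``; drug names and units for the
    wide dialect come from the keyword arguments since the grid does not
    carry them.
    """
    if dialect == "long_table":
        return _read_long(path)
    if dialect == "wide_grid":
        return _read_wide(path, row_drug, col_drug, units)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def plot_heatmap(delta: np.ndarray, row_doses, col_doses, path, title: str = "") -> Path:
    """Render a delta grid as a diverging heatmap (blue = synergy, red = antagonism)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    limit = max(1.0, float(np.abs(delta).max()))
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    # RdBu maps high values to blue, so positive deltas (synergy) are blue.
    im = ax.imshow(delta, cmap="RdBu", vmin=-limit, vmax=limit, origin="lower", aspect="auto")
    ax.set_xticks(range(len(col_doses)), [f"{c:g}" for c in col_doses], rotation=45)
    ax.set_yticks(range(len(row_doses)), [f"{c:g}" for c in row_doses])
    ax.set_xlabel("column-drug concentration")
    ax.set_ylabel("row-drug concentration")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="expected - observed viability (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_fit(dataset: CheckerboardDataset, axis: str, fits, path) -> Path:
    """Observed single-agent points (mean +- SD) with fitted curves overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .curves import hill_viability

    doses, viab = dataset.single_agent(axis)
    pos = doses > 0
    d, y = doses[pos], viab[:, pos]
    fig, ax = plt.subplots(figsize=(5.2, 4.0))
    ax.errorbar(d, y.mean(axis=0), yerr=y.std(axis=0, ddof=1) if y.shape[0] > 1 else None,
                fmt="o", color="k", capsize=3, label="observed")
    grid = np.geomspace(d.min() / 2, d.max() * 2, 200)
    for fit in fits:
        ax.plot(grid, hill_viability(fit.params, grid), label=fit.regime)
    ax.set_xscale("log")
    ax.set_xlabel(f"concentration ({dataset.units})")
    ax.set_ylabel("% viability")
    ax.set_title(dataset.row_drug if axis == "row" else dataset.col_drug)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_report(analysis, outdir, figures: bool = True) -> dict:
    """Write a full-analysis report: JSON + per-surface CSV grids + heatmaps.

    The JSON body is deterministic for a fixed input (sorted keys, no
    timestamps; run metadata that may vary lives in a separate sidecar).
    The output directory's writability is checked before anything is
    written, so a bad path never leaves a partial report behind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
    except OSError as exc:
        raise OSError(f"report path {outdir} is not writable: {exc}") from exc
    finally:
        if probe.exists():
            probe.unlink()

    written = {"json": outdir / "report.json", "surfaces": [], "figures": []}
    (outdir / "report.json").write_text(
        json.dumps(analysis.to_dict(), sort_keys=True, indent=2) + "\n"
    )
    dataset = analysis.dataset
    for (model, regime), res in sorted(analysis.results.items()):
        stem = f"{model}_{regime}"
        if res.surface is not None:
            df = pd.DataFrame(
                res.surface.expected, index=dataset.row_doses_pos,
                columns=dataset.col_doses_pos,
            )
            df.index.name = "conc"
            surf_path = outdir / f"surface_{stem}.csv"
            df.to_csv(surf_path)
            written["surfaces"].append(surf_path)
        if figures:
            fig_path = outdir / f"delta_{stem}.png"
            plot_heatmap(
                res.delta, dataset.row_doses_pos, dataset.col_doses_pos,
                fig_path, title=f"{model.upper()} / {regime}",
            )
            written["figures"].append(fig_path)
    return written
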