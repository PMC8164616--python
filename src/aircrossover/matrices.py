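"""Association matrices: 18 strata x 15 lags grids of significance markers.

For each (disease chapter, pollutant) a binary matrix marks the cells whose
fitted slope is positive and statistically significant (p below threshold,
strictly).  Summing the 12 chapter matrices cellwise gives a 0-12 frequency
grid per pollutant: how many disease groups show a positive association at
each (stratum, lag).  Counting summaries mirror the per-pollutant totals,
per-stratum row totals over the 15 lags, the per-pollutant maximum row and
percentage rows; the persistence ratio compares association counts at two
significance thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import enumerate_patient_strata

logger = logging.getLogger(__name__)

N_STRATA = 18
N_LAGS = 15
STRATA_LABELS = tuple(s.label for s in enumerate_patient_strata())


class MatrixError(ValueError):
    pass


@dataclass
class AssociationMatrix:
    """An 18 x 15 integer grid (strata rows in canonical order, lags 0-14).

    Binary for a single chapter (cells in {0, 1}); summed over chapters the
    cells range 0..n_chapters.
    """

    pollutant_id: str
    values: np.ndarray
    chapter_id: str | None = None
    n_chapters: int = 1
    row_labels: tuple = STRATA_LABELS
    lags: tuple = tuple(range(N_LAGS))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.row_labels), len(self.lags)):
            raise MatrixError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.row_labels)}, {len(self.lags)})")
        if self.values.min() < 0 or self.values.max() > self.n_chapters:
            raise MatrixError(
                f"cells must lie in [0, {self.n_chapters}]")

    def total(self) -> int:
        return int(self.values.sum())

    def row_totals(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=1), index=list(self.row_labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels),
                            columns=[f"lag{l}" for l in self.lags])


def build_binary_matrix(results: dict, pollutant_id: str,
                        chapter_id: str | None = None,
                        p_threshold: float = 0.05,
                        row_labels: tuple = STRATA_LABELS,
                        lags: tuple = tuple(range(N_LAGS))
                        ) -> AssociationMatrix:
    """Binary matrix from a {(stratum label, lag): ModelResult} grid.

    A cell is 1 iff the model converged, the slope is positive and the
    p-value is strictly below the threshold (p exactly at the threshold is
    not significant); a missing or non-converged result contributes 0 and is
    logged so fit failures are not silently absorbed.
    """
    vals = np.zeros((len(row_labels), len(lags)), dtype=int)
    n_failed = 0
    for i, label in enumerate(row_labels):
        for j, lag in enumerate(lags):
            res = results.get((label, lag))
            if res is None or not res.converged:
                n_failed += res is not None
                continue
            if res.beta > 0 and res.p_value < p_threshold:
                vals[i, j] = 1
    if n_failed:
        logger.warning("%s/%s: %d non-converged cells set to 0",
                       pollutant_id, chapter_id, n_failed)
    return AssociationMatrix(pollutant_id, vals, chapter_id=chapter_id,
                             n_chapters=1, row_labels=row_labels, lags=lags)


def sum_matrices(matrices: list[AssociationMatrix],
                 expected: int = 12) -> AssociationMatrix:
    """Cellwise sum of the per-chapter binary matrices for one pollutant.

    With the full design this sums exactly 12 chapter matrices (cells 0-12);
    ``expected`` lets reduced designs sum their configured chapter count.
    """
    if len(matrices) != expected:
        raise MatrixError(f"expected {expected} matrices, got {len(matrices)}")
    pid = matrices[0].pollutant_id
    shape = matrices[0].values.shape
    for m in matrices:
        if m.pollutant_id != pid:
            raise MatrixError("matrices must share a pollutant")
        if m.values.shape != shape:
            raise MatrixError("matrices must share a shape")
    total = np.sum([m.values for m in matrices], axis=0)
    return AssociationMatrix(pid, total, chapter_id=None,
                             n_chapters=len(matrices),
                             row_labels=matrices[0].row_labels,
                             lags=matrices[0].lags)


def count_summaries(summed: dict[str, AssociationMatrix]) -> pd.DataFrame:
    """Counting summary across pollutants (columns) with rows:

    * the 18 per-stratum totals over the 15 lags,
    * ``Maximum`` -- the largest per-stratum total,
    * ``Total`` -- the sum of all cells (positive associations),
    * ``% of cells tested`` -- Total / (18*15*n_chapters) * 100,
    * ``% cells nonzero`` -- share of the 270 (stratum, lag) cells with at
      least one associated chapter.

    The two percentage rows are reported side by side because published
    summaries of this design are ambiguous about the denominator of their
    percentage row.
    """
    cols = {}
    for pid, m in summed.items():
        rows = m.row_totals()
        rows.loc["Maximum"] = rows.max()
        rows.loc["Total"] = m.total()
        denom = m.values.size * m.n_chapters
        rows.loc["% of cells tested"] = round(100.0 * m.total() / denom, 1)
        rows.loc["% cells nonzero"] = round(
            100.0 * float((m.values > 0).mean()), 1)
        cols[pid] = rows
    return pd.DataFrame(cols)


def persistence_ratio(count_p05: int, count_p001: int) -> float:
    """Percentage of p<0.05 associations persisting at p<0.001: 100 b / a.

    Undefined (NaN) when no associations exist at the looser threshold.
    """
    if count_p05 < 0 or count_p001 < 0:
        raise ValueError("counts must be non-negative")
    if count_p001 > count_p05:
        raise ValueError("p<0.001 count cannot exceed p<0.05 count")
    if count_p05 == 0:
        return float("nan")
    return 100.0 * count_p001 / count_p05


def export_heatmap(matrix: AssociationMatrix, path_base) -> None:
    """Write the matrix as CSV and as a green-to-red heatmap image.

    The colour ramp is linear in the cell value with the number printed in
    each cell, so the figure carries the same information as the CSV.
    """
    from pathlib import Path
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path_base = Path(path_base)
    df = matrix.to_frame()
    df.rename_axis("stratum").to_csv(path_base.with_suffix(".csv"))

    fig, ax = plt.subplots(figsize=(9, 6.5))
    vmax = max(matrix.n_chapters, 1)
    im = ax.imshow(matrix.values, cmap="RdYlGn_r", vmin=0, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(len(matrix.lags)), [str(l) for l in matrix.lags])
    ax.set_yticks(range(len(matrix.row_labels)), matrix.row_labels,
                  fontsize=8)
    ax.set_xlabel("lag (days)")
    title = matrix.pollutant_id
    if matrix.chapter_id:
        title += f" / {matrix.chapter_id}"
    ax.set_title(title)
    for i in range(matrix.values.shape[0]):
        for j in range(matrix.values.shape[1]):
            ax.text(j, i, str(matrix.values[i, j]), ha="center", va="center",
                    fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path_base.with_suffix(".png"), dpi=150)
    plt.close(fig)


def read_matrix_csv(path, pollutant_id: str,
                    n_chapters: int = 12) -> AssociationMatrix:
    df = pd.read_csv(path, index_col=0)
    lags = tuple(int(c.removeprefix("lag")) for c in df.columns)
    return AssociationMatrix(pollutant_id, df.to_numpy(),
                             n_chapters=n_chapters,
                             row_labels=tuple(df.index), lags=lags)
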