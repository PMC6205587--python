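"""Cell tables, pseudotime handling and trajectory-resolved summaries.

Pseudotime is an *input*: any external trajectory algorithm that assigns
each cell a scalar progression score can feed this package; the score is
normalized to [0, 1] here.  Marker trends are Gaussian-filter weighted
averages along pseudotime; phase binning, per-phase pairwise DREMI
matrices and their cross-condition correlations support consistency
analyses across replicates and days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._filters import gaussian_weighted_average, silverman_sigma_1d
from .conditional import dremi_from_data


@dataclass
class CellTable:
    """Cells × markers expression (arcsinh units) with optional pseudotime."""

    expression: pd.DataFrame
    pseudotime: np.ndarray | None = None
    condition: str | None = None

    def __post_init__(self):
        if not isinstance(self.expression, pd.DataFrame):
            self.expression = pd.DataFrame(self.expression)
        if self.expression.columns.duplicated().any():
            dupes = self.expression.columns[self.expression.columns.duplicated()].tolist()
            raise ValueError(f"duplicated marker name(s): {dupes}")
        if not np.all(np.isfinite(self.expression.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")
        if self.pseudotime is not None:
            t = np.asarray(self.pseudotime, dtype=float)
            if t.shape != (len(self.expression),):
                raise ValueError(f"pseudotime length {t.shape} does not match {len(self.expression)} cells")
            if not np.all(np.isfinite(t)) or t.min() < 0 or t.max() > 1:
                raise ValueError("pseudotime must be finite and within [0, 1]")
            self.pseudotime = t

    @property
    def n_cells(self) -> int:
        return len(self.expression)

    @property
    def markers(self) -> list:
        return list(self.expression.columns)

    def marker(self, name: str) -> np.ndarray:
        if name not in self.expression.columns:
            raise KeyError(f"marker {name!r} not in table (have {self.markers})")
        return self.expression[name].to_numpy(dtype=float)

    def require_pseudotime(self) -> np.ndarray:
        if self.pseudotime is None:
            raise ValueError("this operation requires per-cell pseudotime")
        return self.pseudotime

    def subset(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        return CellTable(
            expression=self.expression.loc[mask].reset_index(drop=True),
            pseudotime=None if self.pseudotime is None else self.pseudotime[mask],
            condition=self.condition,
        )


def normalize_pseudotime(raw, invert: bool = False) -> np.ndarray:
    """Affine map of raw trajectory scores onto [0, 1]; optionally inverted."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi <= lo:
        raise ValueError("pseudotime scores are constant; cannot normalize")
    t = (raw - lo) / (hi - lo)
    return 1.0 - t if invert else t


@dataclass
class TrendCurve:
    """Gaussian-weighted average marker level at fixed pseudotime bins."""

    t_values: np.ndarray
    values: np.ndarray
    marker: str
    sigma: float = field(default=np.nan)

    def rescaled01(self) -> "TrendCurve":
        lo, hi = self.values.min(), self.values.max()
        if hi <= lo:
            raise ValueError("constant trend cannot be rescaled to [0, 1]")
        return TrendCurve(self.t_values, (self.values - lo) / (hi - lo), self.marker, self.sigma)


def marker_trend(cells: CellTable, marker: str, n_bins: int = 256,
                 sigma: float | None = None, rescale: bool = False) -> TrendCurve:
    """Marker trend along pseudotime: 256 equally spaced bin centers,
    Gaussian-filter weighted average of the marker at each center.

    The filter width defaults to Silverman's 1D rule on the pseudotime
    values; weights are normalized to sum 1 per bin.
    """
    t = cells.require_pseudotime()
    y = cells.marker(marker)
    if sigma is None:
        sigma = silverman_sigma_1d(t)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    values = gaussian_weighted_average(centers, t, y, sigma)
    curve = TrendCurve(t_values=centers, values=values, marker=marker, sigma=sigma)
    return curve.rescaled01() if rescale else curve


def phase_bin(cells: CellTable) -> np.ndarray:
    """Four-phase grouping at pseudotime 0.25 / 0.5 / 0.75.

    Returns group labels 1-4; boundaries belong to the upper group
    (t = 0.25 is Group 2), so every cell lands in exactly one group.
    """
    t = cells.require_pseudotime()
    return np.digitize(t, [0.25, 0.5, 0.75], right=False) + 1


def pairwise_dremi_matrix(cells: CellTable, markers=None, bins: int = 64,
                          epsilon: float = 0.0, min_cells: int = 100) -> pd.DataFrame:
    """2D-DREMI for every ordered marker pair (regulator → response).

    Rows are regulators, columns responses; the diagonal is NaN.  DREMI
    is directional, so the matrix is not symmetric.  A table smaller
    than ``min_cells`` raises (per-phase groups can be tiny).
    """
    markers = list(markers) if markers is not None else cells.markers
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    if cells.n_cells < min_cells:
        raise ValueError(f"only {cells.n_cells} cells; need >= {min_cells}")
    out = pd.DataFrame(np.nan, index=markers, columns=markers)
    for xm in markers:
        for ym in markers:
            if xm == ym:
                continue
            out.loc[xm, ym] = dremi_from_data(cells.marker(xm), cells.marker(ym),
                                              bins=bins, epsilon=epsilon).value
    return out


def score_correlation(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> float:
    """Pearson correlation of two score sets over matched off-diagonal pairs."""
    a = np.asarray(matrix_a, dtype=float).ravel()
    b = np.asarray(matrix_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("score sets must be matched element-wise")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError(f"need >= 3 paired finite scores, got {int(keep.sum())}")
    return float(stats.pearsonr(a[keep], b[keep]).statistic)
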