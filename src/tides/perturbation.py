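"""Perturbation-based validation and driver-edge ranking.

If TIDES correctly reports when an edge X -> Z is strong, acutely
inhibiting X should depress Z most at those pseudotimes: the *impact
curve* (control trend minus perturbed trend of Z) should track the TIDES
curve.  :func:`match_curves` aligns the two by cross-correlation.
Candidate driver edges are ranked by the sum of a 3D-DREMI on
(T, X) -> Y and 2D-DREMIs on X -> Y and T -> Y, averaged over
replicates.  Threshold gating of cells into epithelial / transitional /
mesenchymal classes supports long-term perturbation readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .conditional import dremi3d_from_data, dremi_from_data
from .trajectory import CellTable, TrendCurve


@dataclass
class ImpactCurve:
    """Control-minus-perturbed trend of a target marker (arcsinh units)."""

    t_values: np.ndarray
    values: np.ndarray
    target: str

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_values.shape != self.values.shape:
            raise ValueError("t_values and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("impact values must be finite")


def impact_curve(control_trend: TrendCurve, perturbed_trend: TrendCurve) -> ImpactCurve:
    """Pointwise difference control - perturbed of a target marker's trend."""
    if control_trend.marker != perturbed_trend.marker:
        raise ValueError(f"trends are for different markers: "
                         f"{control_trend.marker!r} vs {perturbed_trend.marker!r}")
    if (control_trend.t_values.shape != perturbed_trend.t_values.shape
            or not np.allclose(control_trend.t_values, perturbed_trend.t_values)):
        raise ValueError("trends are on different pseudotime grids")
    return ImpactCurve(t_values=control_trend.t_values.copy(),
                       values=control_trend.values - perturbed_trend.values,
                       target=control_trend.marker)


@dataclass(frozen=True)
class MatchResult:
    lag_bins: int
    lag_time: float
    r: float


def _minmax01(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("constant curve; min-max normalization undefined")
    return (v - lo) / (hi - lo)


def match_curves(tides_curve, impact: ImpactCurve, max_lag: float = 0.25) -> MatchResult:
    """Best cross-correlation alignment of a TIDES curve and an impact curve.

    Both curves are min-max normalized to [0, 1]; the impact curve is
    linearly resampled onto the TIDES pseudotime grid if the grids
    differ.  Correlation is computed on the overlapping region only (no
    wrap-around) at every integer-bin shift within ±``max_lag`` (a
    fraction of the axis); the shift maximizing the correlation is
    selected and the Pearson r at that shift returned.
    """
    a_t, a = tides_curve.t_values, _minmax01(np.asarray(tides_curve.scores, float))
    b = np.asarray(impact.values, float)
    if impact.t_values.shape != a_t.shape or not np.allclose(impact.t_values, a_t):
        b = np.interp(a_t, impact.t_values, b)
    b = _minmax01(b)
    n = a.size
    max_shift = int(round(max_lag * n))
    if n - max_shift < n // 2:
        max_shift = n - n // 2  # keep overlap >= half the axis
    best = None
    for lag in range(-max_shift, max_shift + 1):
        if lag >= 0:
            x, y = a[lag:], b[: n - lag]
        else:
            x, y = a[: n + lag], b[-lag:]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(stats.pearsonr(x, y).statistic)
        if best is None or r > best[1]:
            best = (lag, r)
    if best is None:
        raise ValueError("no lag produced a defined correlation")
    dt = float(np.mean(np.diff(a_t)))
    return MatchResult(lag_bins=best[0], lag_time=best[0] * dt, r=best[1])


# ---------------------------------------------------------------------------
# Gating

_OPS = {"<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}


@dataclass
class GateSpec:
    """Ordered threshold gates over markers; first matching class wins.

    ``classes`` maps class name -> list of (marker, op, threshold)
    conditions, all of which must hold; cells matching no class fall in
    ``fallback``.  The default reproduces the epithelial / mesenchymal /
    transitional gates used for EMT heterogeneity (Vimentin < 2
    epithelial; E-cadherin < 2.5 and Vimentin > 4 mesenchymal).
    """

    classes: dict = field(default_factory=lambda: {
        "epithelial": [("Vimentin", "<", 2.0)],
        "mesenchymal": [("E-cadherin", "<", 2.5), ("Vimentin", ">", 4.0)],
    })
    fallback: str = "transitional"

    @classmethod
    def from_dict(cls, d: dict) -> "GateSpec":
        classes = {name: [(m, op, float(th)) for m, op, th in conds]
                   for name, conds in d.get("classes", {}).items()}
        return cls(classes=classes, fallback=d.get("fallback", "transitional"))

    def classify(self, cells: CellTable) -> np.ndarray:
        labels = np.full(cells.n_cells, self.fallback, dtype=object)
        unassigned = np.ones(cells.n_cells, dtype=bool)
        for name, conds in self.classes.items():
            match = np.ones(cells.n_cells, dtype=bool)
            for marker, op, threshold in conds:
                if op not in _OPS:
                    raise ValueError(f"unknown comparator {op!r}")
                match &= _OPS[op](cells.marker(marker), threshold)
            sel = match & unassigned
            labels[sel] = name
            unassigned &= ~match
        return labels


def gate_fractions(cells: CellTable, gates: GateSpec | None = None) -> pd.DataFrame:
    """Per-class cell counts and fractions under a gate specification."""
    gates = gates or GateSpec()
    labels = gates.classify(cells)
    order = list(gates.classes) + [gates.fallback]
    counts = pd.Series(labels).value_counts().reindex(order, fill_value=0)
    return pd.DataFrame({"count": counts, "fraction": counts / cells.n_cells})


# ---------------------------------------------------------------------------
# Driver-edge ranking


@dataclass
class EdgeScore:
    """Combined evidence that X drives Y along the trajectory."""

    edge: tuple
    dremi3d: float
    dremi2d_xy: float
    dremi2d_ty: float
    replicate_scores: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def combined(self) -> float:
        return self.dremi3d + self.dremi2d_xy + self.dremi2d_ty


def rank_edges(cells_per_replicate, markers=None, target_set=None, bins: int = 64,
               epsilon: float = 0.0, base: float = 2.0) -> list:
    """Rank ordered edges by 3D-DREMI((T,X)->Y) + 2D-DREMI(X->Y) + 2D-DREMI(T->Y).

    Component scores are averaged across replicates; edges are sorted by
    the combined score descending with a deterministic tie-break on the
    edge label.  ``bins`` defaults to 64 per axis to keep full-panel
    scans (k·(k-1) 3D densities per replicate) fast.
    """
    replicates = list(cells_per_replicate)
    if len(replicates) < 1:
        raise ValueError("need at least one replicate")
    markers = list(markers) if markers is not None else replicates[0].markers
    targets = list(target_set) if target_set is not None else markers

    per_edge = {(x, y): {"d3": [], "xy": [], "ty": [], "comb": []}
                for x in markers for y in targets if x != y}
    for cells in replicates:
        t = cells.require_pseudotime()
        ty_cache = {y: dremi_from_data(t, cells.marker(y), bins=bins,
                                       epsilon=epsilon, base=base).value
                    for y in targets}
        for x in markers:
            xv = cells.marker(x)
            for y in targets:
                if x == y:
                    continue
                yv = cells.marker(y)
                d3 = dremi3d_from_data(t, xv, yv, bins=bins, epsilon=epsilon, base=base).value
                xy = dremi_from_data(xv, yv, bins=bins, epsilon=epsilon, base=base).value
                rec = per_edge[(x, y)]
                rec["d3"].append(d3)
                rec["xy"].append(xy)
                rec["ty"].append(ty_cache[y])
                rec["comb"].append(d3 + xy + ty_cache[y])

    scores = [EdgeScore(edge=edge, dremi3d=float(np.mean(r["d3"])),
                        dremi2d_xy=float(np.mean(r["xy"])), dremi2d_ty=float(np.mean(r["ty"])),
                        replicate_scores=np.asarray(r["comb"]))
              for edge, r in per_edge.items()]
    return sorted(scores, key=lambda s: (-s.combined, s.edge))


def ranking_frame(scores) -> pd.DataFrame:
    """Tabular view of a ranking for text export."""
    return pd.DataFrame([{
        "source": s.edge[0], "target": s.edge[1], "combined": s.combined,
        "dremi3d": s.dremi3d, "dremi2d_xy": s.dremi2d_xy, "dremi2d_ty": s.dremi2d_ty,
    } for s in scores])
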