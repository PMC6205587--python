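"""Trajectory Interpolated DREMI Scores (TIDES).

A 3D conditional density p(z | t, y) — pseudotime first conditioning
axis — is sliced at fixed pseudotime locations by linear interpolation
between grid planes; each slice is denoised and scored with 2D-DREMI,
giving edge strength as a continuous function of pseudotime.  The
discrete comparator (:func:`binned_dremi_baseline`) recomputes DREMI in
overlapping pseudotime windows of cells and is expected to miss fast
transient couplings that TIDES resolves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._filters import (gaussian_weighted_average, silverman_sigma_1d,
                       value_distance_weighted_average)
from .conditional import (EMPTY_COLUMN_FRACTION, ConditionalDensity,
                          conditional_density, dremi, rescale_denoise)
from .density import diffusion_kde
from .trajectory import CellTable

DEFAULT_EPSILON = 0.9


@dataclass
class TidesCurve:
    """Edge strength (2D-DREMI, bits) at fixed pseudotime locations."""

    t_values: np.ndarray
    scores: np.ndarray
    edge: tuple = ("", "")
    smoothing_sigma: float | None = None

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.t_values.shape != self.scores.shape:
            raise ValueError("t_values and scores must have equal length")
        if np.any(np.diff(self.t_values) <= 0):
            raise ValueError("t_values must be strictly increasing")
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t_values, "score": self.scores})


def tides_slice(cond3d: ConditionalDensity, t: float,
                epsilon: float = DEFAULT_EPSILON) -> ConditionalDensity:
    """Fixed-pseudotime slice of a rescaled 3D conditional, then denoise.

    Linear interpolation between the two bounding pseudotime planes of
    both the conditional values and the conditioning-cell masses; the
    result is a 2D conditional (y-columns × z) in denoised state (or
    rescaled state when epsilon = 0).  ``t`` must lie within the grid's
    pseudotime range; no extrapolation.
    """
    if cond3d.n_cond_axes != 2:
        raise ValueError("tides_slice needs a 3D conditional (two conditioning axes)")
    if cond3d.state != "rescaled":
        raise ValueError(f"tides_slice expects a rescaled conditional, got {cond3d.state!r}")
    t_centers = cond3d.cond_centers[0]
    half_bin = 0.5 * (t_centers[1] - t_centers[0])
    if not (t_centers[0] - half_bin <= t <= t_centers[-1] + half_bin):
        raise ValueError(f"t = {t} outside the grid pseudotime range "
                         f"[{t_centers[0] - half_bin}, {t_centers[-1] + half_bin}]")
    tc = np.clip(t, t_centers[0], t_centers[-1])
    i = int(np.clip(np.searchsorted(t_centers, tc, side="right") - 1, 0, len(t_centers) - 2))
    w = (tc - t_centers[i]) / (t_centers[i + 1] - t_centers[i])

    values = (1.0 - w) * cond3d.values[i] + w * cond3d.values[i + 1]
    mass = (1.0 - w) * cond3d.column_mass[i] + w * cond3d.column_mass[i + 1]
    total = mass.sum()
    empty = (mass < EMPTY_COLUMN_FRACTION * mass.mean()) if total > 0 else np.ones_like(mass, bool)

    values = values.copy()
    if epsilon > 0:
        values[values < epsilon] = 0.0
    names = None if cond3d.axis_names is None else cond3d.axis_names[1:]
    return ConditionalDensity(
        values=values, column_mass=mass / total if total > 0 else mass,
        empty=empty | (values.sum(axis=-1) <= 0),
        z_centers=cond3d.z_centers, cond_centers=(cond3d.cond_centers[1],),
        state="denoised" if epsilon > 0 else "rescaled", epsilon=epsilon,
        axis_names=names,
    )


def rescaled_conditional_3d(cells: CellTable, source: str, target: str,
                            bins: int = 128, tail_trim: int = 50) -> ConditionalDensity:
    """Rescaled p(target | T, source) from a cell table with pseudotime.

    ``tail_trim`` cells are dropped from the right tail of the source
    (conditioning) marker so its dynamic range stays well populated.
    """
    from .io import trim_right_tail

    cells.require_pseudotime()
    if tail_trim:
        cells = trim_right_tail(cells, source, tail_trim)
    t, x, z = cells.pseudotime, cells.marker(source), cells.marker(target)
    for name, v in ((source, x), (target, z)):
        if v.std() <= 0:
            raise ValueError(f"marker {name!r} is constant; density is degenerate")
    pts = np.column_stack([t, x, z])
    joint = diffusion_kde(pts, m=bins, axis_names=("pseudotime", source, target))
    cond = conditional_density(joint, response_axis=2)
    return rescale_denoise(cond, epsilon=0.0)  # rescaled, not yet denoised


def _slice_score(cond3d, t, epsilon, base):
    sl = tides_slice(cond3d, t, epsilon=epsilon)
    try:
        return dremi(sl, base=base).value
    except ValueError:  # < 2 scoreable columns after denoise
        return 0.0


def tides_curve(cells: CellTable, source: str, target: str, n_locations: int | None = None,
                bins: int = 128, epsilon: float = DEFAULT_EPSILON, tail_trim: int = 50,
                min_cells: int = 500, base: float = 2.0) -> TidesCurve:
    """Raw TIDES curve for one edge.

    Builds the 3D density of (pseudotime, source, target), rescales the
    conditional, slices it at ``n_locations`` (default 2 × bins) equally
    spaced pseudotimes across the observed range, and scores each slice
    with 2D-DREMI at the given epsilon.
    """
    if cells.n_cells < min_cells:
        raise ValueError(f"only {cells.n_cells} cells; need >= {min_cells} for a stable 3D density")
    if n_locations is None:
        n_locations = 2 * bins
    cond3d = rescaled_conditional_3d(cells, source, target, bins=bins, tail_trim=tail_trim)
    t = cells.require_pseudotime()
    t_lo = max(cond3d.cond_centers[0][0], float(t.min()))
    t_hi = min(cond3d.cond_centers[0][-1], float(t.max()))
    locations = np.linspace(t_lo, t_hi, n_locations)
    scores = np.array([_slice_score(cond3d, tl, epsilon, base) for tl in locations])
    return TidesCurve(t_values=locations, scores=scores, edge=(source, target))


def smooth_curve(curve: TidesCurve, sigma: float | None = None,
                 mode: str = "time") -> TidesCurve:
    """Gaussian-filter smoothing of a TIDES curve along pseudotime.

    Weights decay with pseudotime distance and are normalized to sum 1
    at each location (constants are preserved; end windows truncate and
    renormalize).  ``sigma`` defaults to Silverman's 1D rule on the
    pseudotime locations.  ``mode="literal"`` instead weights by distance
    between score *values* — a value-adaptive variant kept only for
    comparison.
    """
    if curve.t_values.size < 3:
        raise ValueError("need at least 3 points to smooth")
    if sigma is None:
        sigma = silverman_sigma_1d(curve.t_values)
    if mode == "time":
        smoothed = gaussian_weighted_average(curve.t_values, curve.t_values, curve.scores, sigma)
    elif mode == "literal":
        smoothed = value_distance_weighted_average(curve.t_values, curve.t_values, curve.scores, sigma)
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")
    return replace(curve, scores=np.clip(smoothed, 0.0, None), smoothing_sigma=sigma)


def average_tides(curves) -> TidesCurve:
    """Pointwise mean of TIDES curves sharing a pseudotime grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].t_values
    for c in curves[1:]:
        if c.t_values.shape != t0.shape or not np.allclose(c.t_values, t0):
            raise ValueError("curves are on different pseudotime grids")
    scores = np.mean([c.scores for c in curves], axis=0)
    sources = sorted({c.edge[0] for c in curves})
    targets = sorted({c.edge[1] for c in curves})
    edge = ("+".join(sources), "+".join(targets))
    return TidesCurve(t_values=t0.copy(), scores=scores, edge=edge,
                      smoothing_sigma=curves[0].smoothing_sigma)


def binned_dremi_baseline(cells: CellTable, source: str, target: str, n_bins: int = 5,
                          overlap: float = 0.5, bins: int = 128,
                          epsilon: float = 0.0, min_cells: int = 100,
                          base: float = 2.0) -> pd.DataFrame:
    """Discrete comparator: 2D-DREMI in overlapping pseudotime windows.

    The pseudotime range is covered by ``n_bins`` windows whose centers
    partition it; each window is widened to width w0 / (1 - overlap)
    (overlap = 0 gives a disjoint partition).  A fresh 2D density is fit
    per window, scored with the package's standard 2D-DREMI settings.
    Windows with fewer than ``min_cells`` cells are flagged (score NaN),
    not scored.
    """
    from .conditional import dremi_from_data

    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    t = cells.require_pseudotime()
    lo, hi = float(t.min()), float(t.max())
    w0 = (hi - lo) / n_bins
    width = w0 / (1.0 - overlap)
    rows = []
    for i in range(n_bins):
        center = lo + (i + 0.5) * w0
        in_win = (t >= center - width / 2) & (t < center + width / 2)
        if i == n_bins - 1:  # closed right edge for the last window
            in_win |= t == hi
        n = int(in_win.sum())
        if n < min_cells:
            rows.append({"center": center, "score": np.nan, "n_cells": n, "flagged": True})
            continue
        sub = cells.subset(in_win)
        score = dremi_from_data(sub.marker(source), sub.marker(target),
                                bins=bins, epsilon=epsilon, base=base).value
        rows.append({"center": center, "score": score, "n_cells": n, "flagged": False})
    return pd.DataFrame(rows)
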