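"""Conditional densities, DREMI scores and DREVI surfaces.

A joint density on a 2D or 3D mesh is turned into the conditional
distribution of a response variable Z given the remaining one or two
axes.  DREMI (conditional-Density Resampled Estimate of Mutual
Information) is mutual information computed after each conditioning
column is rescaled to peak 1 and thresholded (denoised), with every
non-empty column weighted equally — so sparsely populated regions of the
regulator's dynamic range count as much as dense ones.  DREVI renders
the conditional mean of Z over the conditioning plane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .density import DensityGrid

#: a conditioning cell is "empty" when its marginal mass falls below this
#: fraction of the *mean* column mass.  Diffusion spreads a little mass
#: everywhere, so a purely numerical floor would keep columns supported by
#: no data at all; those columns are smoothing artifacts and, under the
#: uniform column weighting DREMI uses, would dominate the score with
#: noise.
EMPTY_COLUMN_FRACTION = 0.05


@dataclass
class ConditionalDensity:
    """p(z | conditioning cell) on a mesh.

    ``values`` has the conditioning axes first and the response axis
    last, shape (m_cond..., m_z).  ``column_mass`` is the (normalized)
    marginal of the conditioning cells; ``empty`` marks cells excluded
    from all downstream sums.
    """

    values: np.ndarray
    column_mass: np.ndarray
    empty: np.ndarray
    z_centers: np.ndarray
    cond_centers: tuple
    state: str = "raw"            # raw | rescaled | denoised
    epsilon: float | None = None
    axis_names: tuple | None = None

    @property
    def n_cond_axes(self) -> int:
        return self.values.ndim - 1

    @property
    def n_nonempty(self) -> int:
        return int((~self.empty).sum())


def conditional_density(joint: DensityGrid, response_axis: int = -1) -> ConditionalDensity:
    """Normalize a joint density by the marginal over the response axis.

    p(z_k | cell) = p(cell, z_k) / sum_k p(cell, z_k).  Cells whose
    marginal falls below ``EMPTY_COLUMN_FRACTION`` of the mean column
    mass are flagged empty and excluded from downstream weighting.
    """
    if joint.ndim not in (2, 3):
        raise ValueError(f"joint density must have 2 or 3 axes, got {joint.ndim}")
    response_axis = response_axis % joint.ndim
    vals = np.moveaxis(joint.values, response_axis, -1)
    marginal = vals.sum(axis=-1)
    total = marginal.sum()
    if total <= 0:
        raise ValueError("joint density has no mass")
    empty = marginal < EMPTY_COLUMN_FRACTION * marginal.mean()
    if empty.all():
        raise ValueError("all conditioning columns are empty")
    safe = np.where(empty, 1.0, marginal)
    cond = vals / safe[..., None]
    cond[empty] = 0.0

    axes = [i for i in range(joint.ndim) if i != response_axis]
    names = None
    if joint.axis_names:
        names = tuple(joint.axis_names[i] for i in axes) + (joint.axis_names[response_axis],)
    return ConditionalDensity(
        values=cond,
        column_mass=marginal / total,
        empty=empty,
        z_centers=joint.axis_centers(response_axis),
        cond_centers=tuple(joint.axis_centers(i) for i in axes),
        axis_names=names,
    )


def rescale_denoise(cond: ConditionalDensity, epsilon: float = 0.9) -> ConditionalDensity:
    """Rescale each column to maximum 1, then zero entries below epsilon.

    epsilon = 0 keeps everything (pure rescale); epsilon = 1 keeps only
    the column maxima.  The input must be in the raw state.
    """
    if cond.state != "raw":
        raise ValueError(f"expected a raw conditional, got state {cond.state!r}")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    peaks = cond.values.max(axis=-1)
    safe = np.where(peaks > 0, peaks, 1.0)
    scaled = cond.values / safe[..., None]
    scaled[scaled < epsilon] = 0.0
    state = "rescaled" if epsilon == 0 else "denoised"
    return replace(cond, values=scaled, state=state, epsilon=epsilon)


@dataclass(frozen=True)
class DremiScore:
    """Mutual information on the resampled conditional, with components."""

    value: float
    h_z: float
    h_z_given: float
    base: float = 2.0
    n_columns: int = 0


def dremi(cond: ConditionalDensity, base: float = 2.0) -> DremiScore:
    """DREMI of a (rescaled/denoised) conditional density.

    Columns are renormalized to proper distributions and weighted
    uniformly across non-empty conditioning cells; the z-marginal is the
    mean column of that resampled joint.  Score = H(Z) - H(Z | cond) in
    the given log base, clipped at 0.
    """
    if cond.state == "raw":
        raise ValueError("dremi expects a rescaled or denoised conditional; call rescale_denoise first")
    flat = cond.values.reshape(-1, cond.values.shape[-1])
    col_sums = flat.sum(axis=1)
    keep = (~cond.empty.ravel()) & (col_sums > 0)
    if keep.sum() < 2:
        raise ValueError(f"need at least 2 non-empty columns, got {int(keep.sum())}")
    cols = flat[keep] / col_sums[keep, None]

    log = np.log2 if base == 2.0 else (lambda x: np.log(x) / np.log(base))

    def entropy(p):
        p = p[p > 0]
        return float(-(p * log(p)).sum())

    marginal = cols.mean(axis=0)
    h_z = entropy(marginal)
    h_z_given = float(np.mean([entropy(c) for c in cols]))
    value = max(h_z - h_z_given, 0.0)
    return DremiScore(value=value, h_z=h_z, h_z_given=h_z_given, base=base,
                      n_columns=int(keep.sum()))


@dataclass
class DreviSurface:
    """Conditional-mean surface E(z | x_i, y_j) over the conditioning plane."""

    values: np.ndarray
    cond_centers: tuple
    smoothing_span: int
    axis_names: tuple | None = None


def _fill_nearest(values: np.ndarray, empty: np.ndarray) -> np.ndarray:
    if not empty.any():
        return values
    idx = ndimage.distance_transform_edt(empty, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def _moving_average(a: np.ndarray, span: int, axis: int) -> np.ndarray:
    """Box filter with truncated (renormalized) windows at the ends."""
    kernel = np.ones(span)
    num = ndimage.convolve1d(a, kernel, axis=axis, mode="constant", cval=0.0)
    den = ndimage.convolve1d(np.ones(a.shape[axis]), kernel, mode="constant", cval=0.0)
    shape = [1] * a.ndim
    shape[axis] = a.shape[axis]
    return num / den.reshape(shape)


def drevi_surface(cond: ConditionalDensity, smoothing_span: int = 20) -> DreviSurface:
    """Conditional mean of Z per conditioning cell, box-smoothed along both axes.

    Uses the raw (pre-denoise) conditional; empty cells are filled from
    their nearest non-empty neighbor before smoothing.
    """
    if cond.n_cond_axes != 2:
        raise ValueError("drevi_surface needs two conditioning axes")
    if cond.state != "raw":
        raise ValueError("drevi_surface uses the raw conditional density")
    if smoothing_span > min(cond.values.shape[:2]):
        raise ValueError(f"smoothing span {smoothing_span} exceeds grid size {cond.values.shape[:2]}")
    surface = (cond.values * cond.z_centers).sum(axis=-1)
    surface = _fill_nearest(surface, cond.empty)
    if smoothing_span > 1:
        surface = _moving_average(surface, smoothing_span, axis=0)
        surface = _moving_average(surface, smoothing_span, axis=1)
    return DreviSurface(values=surface, cond_centers=cond.cond_centers,
                        smoothing_span=smoothing_span, axis_names=cond.axis_names)


def dremi_from_data(x, z, bins: int = 128, epsilon: float = 0.0, base: float = 2.0,
                    ranges=None) -> DremiScore:
    """2D-DREMI of response z given regulator x, from raw observations.

    The default epsilon = 0 scores the rescaled conditional without
    further thresholding: with a smooth density and uniform column
    weighting the score is then well calibrated (near 0 for independent
    markers).  Harsher denoising is available via ``epsilon``.
    """
    from .density import diffusion_kde

    pts = np.column_stack([np.asarray(x, float), np.asarray(z, float)])
    joint = diffusion_kde(pts, m=bins, ranges=ranges)
    cond = rescale_denoise(conditional_density(joint, response_axis=1), epsilon)
    return dremi(cond, base=base)


def dremi3d_from_data(t, x, z, bins: int = 128, epsilon: float = 0.0, base: float = 2.0,
                      ranges=None) -> DremiScore:
    """3D-DREMI of response z given (t, x), from raw observations."""
    from .density import diffusion_kde

    pts = np.column_stack([np.asarray(t, float), np.asarray(x, float), np.asarray(z, float)])
    joint = diffusion_kde(pts, m=bins, ranges=ranges)
    cond = rescale_denoise(conditional_density(joint, response_axis=2), epsilon)
    return dremi(cond, base=base)
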