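"""Seeded generators for every input the analysis modules consume.

The generators emulate a cytometry-like EMT continuum on an arcsinh-like
positive scale: cells carry a uniform pseudotime, phenotype markers
follow smooth monotone trends (an E-cadherin-like decrease, a
Vimentin-like increase), and designated regulator -> target pairs are
coupled with a strength g(t) that is modulated along pseudotime —
constant, exponentially decaying (the strong-but-transient case) or
unimodal.  Paired control / perturbed tables share every random draw so
the true impact of inhibiting an edge is exactly effect_scale · g(t)
times the regulator's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import CellTable


# ---------------------------------------------------------------------------
# Coupling shapes g(t) >= 0 on [0, 1]


@dataclass(frozen=True)
class Coupling:
    """Parametrized edge-strength profile g(t)."""

    kind: str            # constant | decaying | unimodal
    height: float = 1.0
    rate: float = 0.15   # decaying: e-folding scale in pseudotime units
    peak: float = 0.5    # unimodal: location of maximum coupling
    width: float = 0.15  # unimodal: Gaussian width

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.height)
        if self.kind == "decaying":
            return self.height * np.exp(-t / self.rate)
        if self.kind == "unimodal":
            return self.height * np.exp(-0.5 * ((t - self.peak) / self.width) ** 2)
        raise ValueError(f"unknown coupling kind {self.kind!r}")


def constant_coupling(height: float = 1.0) -> Coupling:
    return Coupling("constant", height=height)


def decaying_coupling(rate: float = 0.15, height: float = 1.0) -> Coupling:
    return Coupling("decaying", height=height, rate=rate)


def unimodal_coupling(peak: float = 0.5, width: float = 0.15, height: float = 1.0) -> Coupling:
    return Coupling("unimodal", peak=peak, width=width, height=height)


@dataclass(frozen=True)
class EdgeModulationSpec:
    """How a target responds to a regulator along pseudotime.

    target = base trend + g(t) · link(regulator) + noise, with
    ``link`` either the identity or a saturating sigmoid of the
    regulator level.
    """

    coupling: Coupling = field(default_factory=decaying_coupling)
    noise_sd: float = 0.15
    link: str = "linear"

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.link not in ("linear", "sigmoidal"):
            raise ValueError(f"unknown link {self.link!r}")

    def apply_link(self, x: np.ndarray) -> np.ndarray:
        if self.link == "linear":
            return x
        return 3.0 / (1.0 + np.exp(-(x - 2.0) / 0.5))


# ---------------------------------------------------------------------------
# Point clouds


def simulate_gaussian3d(n: int, mean: float = 0.5, variance: float = 0.3,
                        seed: int = 0) -> np.ndarray:
    """Isotropic 3D Gaussian point cloud (per-axis mean and variance)."""
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, np.sqrt(variance), size=(n, 3))


def gaussian3d_density(points, mean: float = 0.5, variance: float = 0.3) -> np.ndarray:
    """Closed-form density of the benchmark Gaussian at given points."""
    pts = np.asarray(points, dtype=float)
    quad = ((pts - mean) ** 2).sum(axis=-1) / variance
    return np.exp(-0.5 * quad) / (2.0 * np.pi * variance) ** 1.5


# ---------------------------------------------------------------------------
# Transient edge (T, X, Y triple)


def simulate_transient_edge(n: int, spec: EdgeModulationSpec | None = None,
                            seed: int = 0) -> CellTable:
    """Cells with a pseudotime-modulated X -> Y edge.

    T ~ U(0, 1); X is drawn from a fixed half-normal-like marginal
    (scale 1.5, so its spread does not depend on T); Y = g(T) · link(X)
    + noise.  The default decaying coupling gives the
    strong-but-transient case: X and Y are tightly related early in
    pseudotime and decouple as T grows.
    """
    if n < 500:
        raise ValueError(f"need n >= 500 for a stable edge simulation, got {n}")
    spec = spec or EdgeModulationSpec()
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, n)
    x = np.abs(rng.normal(0.0, 1.5, n))
    y = spec.coupling(t) * spec.apply_link(x) + rng.normal(0.0, spec.noise_sd, n)
    table = pd.DataFrame({"X": x, "Y": y})
    return CellTable(expression=table, pseudotime=t)


# ---------------------------------------------------------------------------
# EMT-like marker panels

_TREND_SHAPES = ("decreasing", "increasing", "flat")


@dataclass
class PanelSpec:
    """Generative recipe for an EMT-like marker panel.

    ``markers`` maps name -> trend shape; ``couplings`` maps ordered
    (source, target) pairs to an EdgeModulationSpec.  Trend markers
    sweep ~4 arcsinh units through a smooth sigmoid in pseudotime with
    ``trend_noise_sd`` residual noise; flat markers sit at a constant
    mean with the larger ``flat_sd`` spread so they can act as
    regulators with T-independent variance.
    """

    n_cells: int = 5000
    markers: dict = field(default_factory=lambda: {
        "E-cadherin": "decreasing", "Vimentin": "increasing", "CD44": "increasing",
    })
    couplings: dict = field(default_factory=dict)
    trend_noise_sd: float = 0.35
    flat_sd: float = 1.0
    flat_mean: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 100:
            raise ValueError(f"n_cells must be >= 100, got {self.n_cells}")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        for shape in self.markers.values():
            if shape not in _TREND_SHAPES:
                raise ValueError(f"unknown trend shape {shape!r}; expected one of {_TREND_SHAPES}")
        for (src, tgt) in self.couplings:
            if src not in self.markers or tgt not in self.markers:
                raise ValueError(f"coupled pair ({src}, {tgt}) not declared in markers")


def _trend_mean(shape: str, t: np.ndarray, spec: PanelSpec) -> np.ndarray:
    # sigmoid switch plus a linear drift so the mean is strictly monotone
    # over the whole trajectory, not flat in the pre/post-transition tails
    s = 1.0 / (1.0 + np.exp(-(t - 0.5) / 0.12))
    if shape == "decreasing":
        return 0.3 + 3.0 * (1.0 - s) + 1.0 * (1.0 - t)
    if shape == "increasing":
        return 0.3 + 3.0 * s + 1.0 * t
    return np.full_like(t, spec.flat_mean)


def _generate_panel(spec: PanelSpec, inhibited_edge=None, effect_scale: float = 0.0):
    """Shared generator: all random draws are made identically regardless
    of the inhibition arguments, so control and perturbed tables differ
    only through the inhibited edge's coupled contribution."""
    rng = np.random.default_rng(spec.seed)
    t = rng.uniform(0.0, 1.0, spec.n_cells)
    base = {}
    for name, shape in spec.markers.items():
        sd = spec.flat_sd if shape == "flat" else spec.trend_noise_sd
        base[name] = _trend_mean(shape, t, spec) + rng.normal(0.0, sd, spec.n_cells)
    values = dict(base)
    for (src, tgt), mod in spec.couplings.items():
        contribution = mod.coupling(t) * mod.apply_link(base[src])
        if inhibited_edge == (src, tgt):
            contribution = contribution * (1.0 - effect_scale)
        values[tgt] = values[tgt] + contribution + rng.normal(0.0, mod.noise_sd, spec.n_cells)
    table = pd.DataFrame({name: values[name] for name in spec.markers})
    return CellTable(expression=table, pseudotime=t)


def simulate_emt_panel(spec: PanelSpec):
    """EMT-like panel plus a ground-truth record of trends and couplings."""
    cells = _generate_panel(spec)
    t_grid = np.linspace(0.0, 1.0, 256)
    ground_truth = {
        "trends": dict(spec.markers),
        "couplings": {f"{s}->{g}": mod for (s, g), mod in spec.couplings.items()},
        "coupling_curves": {f"{s}->{g}": (t_grid, mod.coupling(t_grid))
                            for (s, g), mod in spec.couplings.items()},
    }
    return cells, ground_truth


def simulate_perturbation(spec: PanelSpec, inhibited_edge: tuple,
                          effect_scale: float, seed: int | None = None):
    """Paired control / perturbed panels for an acute edge inhibition.

    The perturbed table is identical to the control except the target of
    ``inhibited_edge`` loses ``effect_scale`` × g(t) × link(source) of
    its coupled contribution, so the true impact curve is proportional
    to g(t).  With effect_scale = 0 the two tables are bit-identical.
    """
    if inhibited_edge not in spec.couplings:
        raise ValueError(f"edge {inhibited_edge} is not a declared coupling")
    if seed is not None:
        spec = PanelSpec(n_cells=spec.n_cells, markers=dict(spec.markers),
                         couplings=dict(spec.couplings), trend_noise_sd=spec.trend_noise_sd,
                         flat_sd=spec.flat_sd, flat_mean=spec.flat_mean, seed=seed)
    control = _generate_panel(spec)
    control.condition = "control"
    perturbed = _generate_panel(spec, inhibited_edge=inhibited_edge, effect_scale=effect_scale)
    perturbed.condition = "perturbed"
    return control, perturbed


def planted_edge_panel(n_markers: int = 8, coupling: Coupling | None = None,
                       n_cells: int = 5000, seed: int = 0):
    """Panel of flat, independent markers with exactly one planted edge.

    The planted regulator M1 drives M2 with a pseudotime-modulated
    coupling (default unimodal at t = 0.5); every other marker is
    independent noise.  Used for driver-edge recovery experiments.
    """
    if n_markers < 3:
        raise ValueError("need at least 3 markers")
    names = [f"M{i+1}" for i in range(n_markers)]
    mod = EdgeModulationSpec(coupling=coupling or unimodal_coupling(height=1.5))
    spec = PanelSpec(n_cells=n_cells, markers={n: "flat" for n in names},
                     couplings={(names[0], names[1]): mod}, seed=seed)
    return simulate_emt_panel(spec) + ((names[0], names[1]),)
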