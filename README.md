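# tides

**Time-varying edge strength along a pseudotime trajectory, from static
single-cell snapshots.**

Mass cytometry measures dozens of proteins in each of many thousands of
cells, but destroys the cells in doing so: there is no way to watch a
signaling relationship change over time in any one cell. When a cell
population spans a continuous transition — here the epithelial-to-
mesenchymal transition (EMT) — an external trajectory algorithm can
order the cells along a pseudotime axis T ∈ [0, 1], and the *variation
across cells* can then stand in for time. This package quantifies how
the statistical coupling between a regulator X and a target Z changes
continuously along that trajectory.

It is aimed at systems biologists analyzing CyTOF (or similar
cells × markers) data with a per-cell pseudotime already in hand, and at
methodologists who want a fast, tested 1–3D density-estimation and
conditional-information stack.

## Method

Everything rests on a fast kernel density estimate. The data histogram
(B bins per axis, B a power of 2) is taken as the initial condition of
the heat equation ∂f/∂t = ½∇²f with Neumann boundaries; evolving the
DCT coefficients by `exp(−k²π²t/2)` per axis for time t = h² and
inverting gives a Gaussian KDE in O(NB + B^d log B). Bandwidths follow
Silverman's rule, h_j = (4/(5n))^{1/7} σ_j.

From a 3D density p̂(T, X, Z) on a 128³ mesh:

- **Conditional density** — p̂(z_k | t_i, x_j) = p̂(t_i, x_j, z_k) / Σ_k p̂(t_i, x_j, z_k).
- **DREVI** — the conditional-mean surface E(Z | t_i, x_j) = Σ_k z_k p̂(z_k | t_i, x_j).
- **DREMI** — each conditioning column is rescaled to peak 1,
  optionally thresholded at ε, renormalized, and weighted *uniformly*
  across populated columns; the score is
  I_c = H_c(Z) − H_c(Z | T, X) in bits, so sparse and dense regions of
  the regulator's dynamic range contribute equally.
- **TIDES** — the rescaled 3D conditional is sliced at 256 fixed
  pseudotimes by linear interpolation, each slice denoised at ε = 0.9
  and scored with 2D-DREMI, yielding edge strength as a curve over T
  (Gaussian-filter smoothed).
- **Driver ranking** — each ordered pair (X, Z) is scored with
  3D-DREMI((T, X)→Z) + 2D-DREMI(X→Z) + 2D-DREMI(T→Z), averaged over
  replicates and sorted.
- **Perturbation validation** — the *impact curve* of a target
  (control trend minus trend under acute inhibition of its regulator)
  is aligned to the TIDES curve by lag-searched cross-correlation.

A seeded synthetic-data module generates every input the pipeline
consumes — benchmark Gaussian clouds, EMT-like marker panels,
transiently coupled edges, and paired control/perturbed conditions whose
true inhibition effect scales with the generative coupling — so the
whole stack is exercisable and testable end to end without any
measured dataset.

## Worked example

`examples/03_tides_curve.py` simulates 5000 cells with a
strong-but-transient X → Y edge (coupling decays with e-folding scale
0.15 in pseudotime) and compares TIDES with windowed DREMI:

```
smoothed TIDES: first-quartile mean 2.38 bits, last-quartile mean 0.46 bits (ratio 5.2)
windowed-DREMI comparator maxima: 0.53 bits vs TIDES peak 2.69 bits
curve written to tides_curve.csv (columns t, score)
```

TIDES resolves the transient: the edge carries ~2.4 bits of information
early in the trajectory and ~0.5 bits late. The comparator — DREMI
recomputed in five overlapping pseudotime windows — pools coupled and
uncoupled cells within each wide window and never reaches a fifth of
the TIDES peak, which is exactly the failure mode fixed-binning has on
transient relationships.

The other examples cover density estimation against a brute-force
oracle (`01`), DREMI/DREVI for one edge (`02`), impact-curve validation
(`04`, Pearson r = 0.993 between TIDES and the simulated inhibition
impact), driver-edge ranking (`05`, the planted edge tops all 55
spurious pairs), and gating plus the config-driven pipeline (`06`).

A thin CLI wraps the same functions:
`tides simulate | preprocess | kde | dremi | tides | rank | validate | gate | pipeline`
(see `tides --help`).

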