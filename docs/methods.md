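# Methods

This note records the statistical model behind `curvhdr`, the defaults and
the reasoning behind them, the numerical choices that matter, and what the
synthetic fixtures do and do not demonstrate.

## Model and assumptions

Events $x_1,\dots,x_n \in \mathbb{R}^d$, $d \in \{1,2,3\}$, are treated as
an i.i.d. sample from a smooth density $f$. Cell populations of interest
are assumed to be **modal regions** of $f$: neighbourhoods of local maxima.
Two consequences follow. First, structure that is not modal (ridges from
spillover, smears from debris) is deliberately not gated. Second, the
boundary of the sample support is genuinely curved after smoothing, so
saturation rails and hard instrument limits *do* produce detectable
curvature (see "Boundary behaviour" below).

All density work happens on asinh-transformed, per-channel standardised
coordinates. The asinh transform is linear near zero and logarithmic in
the tails, which makes cytometry channels roughly Gaussian per population;
standardisation (mean 0, sd 1, `ddof=1`) justifies the single-parameter
bandwidth matrix $h^2 I$ used by the curvature phase.

## Pipeline stages and defaults

| parameter | default | units | why |
|---|---|---|---|
| `tau` | 0.1 | probability | gate keeps the ~90%-mass HDR of each subset; the one knob users should tune |
| `growth_factor` G | $2^d$ | ratio | doubles the region per dimension before the HDR refit |
| `alpha` | 0.05 | probability | curvature-test significance level; results are insensitive to small values |
| `h_curv` | $[4/\{(d+6)n\}]^{1/(d+8)}$ | standardized sd | optimal Hessian-estimation bandwidth for a standard normal target; approximately the largest bandwidth worth using on standardized data |
| `debris_threshold` | 0.01 | fraction of n | an exact per-channel min/max value repeated by > 1% of events is a detector rail, not a cell |
| curvature grid | 151/axis (d ≤ 2), 51 (d = 3) | nodes | fine enough that contour placement error ≪ gate size |
| HDR grid | 101/axis (d ≤ 2), 21 (d = 3) | nodes | local per-subset grids; 21³ keeps the trivariate refit fast |
| grid padding | 3.7 × bandwidth | standardized sd | Gaussian tails beyond 3.7 h are numerically negligible |
| `adjustment` | `hochberg` | — | multiplicity control over in-support grid nodes; `pointwise` is available and is what calibration simulations use |
| `min_region_nodes` | 3 | nodes | suppresses single-node noise components |
| density floor | $10^{-3}\,\max\hat f$ | density | below it the plug-in covariance of the Hessian is unreliable; such nodes are never flagged |

### Curvature significance

The Hessian of the KDE is estimated by convolving linearly binned counts
with the analytic second derivatives of the Gaussian kernel — never by
finite-differencing $\hat f$. At each node the half-vectorised Hessian is
referred to its estimated sampling covariance
$\hat\Sigma(x) = \hat f(x) R/(n h^{d+4})$, where $R$ is the matrix of
integrated products of the Gaussian kernel's second derivatives. For the
Gaussian kernel $R$ is known in closed form through the moments of
$N(0, I/2)$: with $c_0 = (2\sqrt\pi)^{-d}$, diagonal-vs-diagonal entries
are $\tfrac34 c_0$ (same axis) or $\tfrac14 c_0$ (different axes), matched
off-diagonal entries are $\tfrac14 c_0$, and everything else vanishes by
symmetry. The Wald statistic is compared with the
$\chi^2_{d(d+1)/2}$ critical value, and a node is flagged only when the
estimated Hessian is also negative definite. Interior calibration was
checked by simulation: on uniform-box noise, nodes further than $3h$ from
the data boundary reject at well under the nominal pointwise level (the
negative-definiteness requirement makes the test conservative).

### Boundary behaviour

A uniform or truncated sample has a density discontinuity at its support
boundary; after smoothing, a band of width ~2–3 bandwidths inside the
boundary has real, strongly significant negative curvature, and about half
of that band also appears negative definite. The curvature test therefore
flags support boundaries *by design of the statistic*, and a pure-noise
sample yields boundary gates rather than an empty gate. This is inherent
to curvature-based modal detection; the intended remedy is composition
with rectangle gates (`intersect_rectangle` / `--rect`), which is exactly
how boundary debris is excluded in practice.

### Region growth

Convex hulls are grown by "rolling": edge midpoints (2D) or triangular
face centroids (3D) are offset $2r$ along the outward normals and the
offset points are re-hulled, with $r$ found by bisection (bracket
expanded from the region diameter) until the area/volume ratio is within
0.5% of $G$. One deliberate refinement: the hull is taken over the offset
points **union the input vertices**. For regions with many vertices — the
usual case for contour-extracted regions — this is identical to hulling
the offsets alone; for very coarse regions (a triangle at $G = 2$) the
offsets-only polygon provably fails to contain its input, and including
the input vertices restores the containment guarantee without affecting
the bisection (the ratio is still continuous and increasing from 1).

### HDR refit

Each grown region's events get their own KDE with **two-stage diagonal
plug-in bandwidths**: per axis, the integrated density-derivative
functional ladder $\psi_8^{NR} \to \hat\psi_6 \to \hat\psi_4$ (normal
reference start, optimal pilot bandwidths, binned double-sum evaluation),
then the diagonal AMISE solved in closed form under a product-density
approximation (cross $\psi_{2,2}$ terms dropped):
$h_j = t/c_j^{1/4}$ with $c_j = \hat\psi_{4,j}\prod_{k\ne j}\hat R_k$ and
$t = [R(K)^d \prod_j c_j^{1/4}/m]^{1/(d+4)}$. This scales as
$m^{-1/(d+4)}$ and, for Gaussian data, lands within a few percent of the
exact normal-reference optimum. If any functional comes out with the
wrong sign, the normal-scale rule $\hat\sigma_j[4/\{(d+2)m\}]^{1/(d+4)}$
is used instead.

The HDR level is the $\lceil \tau m\rceil$-th smallest of the density
values interpolated at the subset points — a deterministic order
statistic, exactly enumerable at small $m$, with no interpolation
convention to choose. Subsets with fewer than 10 events, or degenerate
along an axis (e.g. a saturation rail that survived debris removal), are
dropped with a logged warning.

### Membership and units

Gates are fitted in standardized space and reported in original units;
polygon edges and mesh faces are densified before the nonlinear
back-transform so the mapped boundary tracks the curved image of the gate.
Membership is **purely geometric in original units**: debris influences
gate placement but not gate membership, overlapping components count an
event once, and re-applying a saved gate to the same events reproduces the
membership bit-for-bit. Regions are reported per-component (not merged)
for interpretability; holes inside a component are filled (cavity contours
are discarded), since a gate with an interior exclusion is not a meaningful
cytometry object.

## Contouring and containment

Regions are extracted from grids by linear interpolation of level
crossings ($d=1$), marching squares ($d=2$) and marching cubes ($d=3$),
each on a zero-padded field so every contour closes; connected components
are found on the flag grid (face connectivity) before contouring.
Point-in-polygon uses an even-odd crossing-number test with boundary
points counted inside (gates are closed sets, so events printed exactly on
a rectangle bound have deterministic membership). Point-in-polyhedron uses
a randomized-direction ray-parity test: one shared ray per batch, with any
point whose ray grazes a vertex/edge or near-parallel face retested under
a fresh seeded direction. Both are validated in the tests against
independent oracles (prepared winding-number predicates and convex
half-space checks).

## Synthetic fixtures

The generator draws a Gaussian mixture in raw channel units, a uniform
debris background over the sample box, and exact-value saturation
pile-ups; layouts are designed on the asinh scale and mapped through
`sinh` with local-Jacobian covariance scaling. Fixture F2's banana
population is a 6-component Gaussian arc — one *labelled* population whose
modal region is non-convex, exercising the shape-unrestricted character of
the gates.

What passing fixture tests show: the pipeline separates well-separated
modal populations, respects the HDR mass convention out of sample, and
recovers non-convex population shapes. What they do not show: robustness
to spillover/compensation artefacts, autofluorescence, doublets, or
populations overlapping heavily in all channels — none of which the
generator emulates.

Problem sizes used throughout the tests and the acceptance script
(n = 4000–20000 events, 100 replicates for calibration runs) were chosen
so each check's Monte-Carlo error is several times smaller than its
tolerance while the whole suite stays interactive.

## Known limitations

- Dimensions above 3 are out of scope (the statistic generalises; the
  geometry layer does not).
- No compensation/spillover handling, logicle/biexponential transforms,
  or doublet discrimination; apply those upstream if needed.
- Rectangle intersection in 3D is membership-level (the clip box is
  recorded on the gate) rather than mesh CSG.
- The HDR bandwidth selector is diagonal; strongly rotated, elongated
  subsets would benefit from a full bandwidth matrix.
- Support boundaries are flagged as curvature regions (see "Boundary
  behaviour"); compose with rectangle gates when the sample has hard
  limits inside the recorded range.
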