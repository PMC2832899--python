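# curvhdr

Automatic and semi-automatic **gating** of flow cytometry samples in 1–3
dimensions, combining *significant high negative curvature* detection with
*highest density region* (HDR) refinement.

## The problem

A flow cytometer records, per cell, forward/side scatter and several
fluorescence intensities — point clouds of 10⁴–10⁵ events in channel space.
Analysis subsets these events geometrically ("gates") to isolate cell
populations, which usually sit at **modal regions** of the event density.
Manual gating is slow and subjective; this package draws the gates
automatically and reports event membership, so high-throughput panels can be
processed without per-sample hand work.

## The method

For events $x_1,\dots,x_n \in \mathbb{R}^d$ ($d \le 3$) assumed drawn from a
smooth density $f$:

1. Remove saturation pile-ups at the channel rails; apply the
   skew-reducing transform $\sinh^{-1}$; standardise each channel.
2. On a regular grid, estimate $\hat f$ by a binned Gaussian kernel density
   estimate with bandwidth matrix $h_{\mathrm{curv}}^2 I$,
   $h_{\mathrm{curv}} = [4/\{(d+6)n\}]^{1/(d+8)}$, and estimate the Hessian
   $\widehat{\nabla^2 f}$ by convolving the binned counts with the
   analytically differentiated kernel.
3. Flag grid nodes where the Wald statistic
   $W(x) = \operatorname{vech}\hat H(x)^\top \hat\Sigma(x)^{-1}
   \operatorname{vech}\hat H(x)$, with plug-in covariance
   $\hat\Sigma(x) = \hat f(x)\, R /(n h^{d+4})$, exceeds the
   $\chi^2_{d(d+1)/2}$ critical value **and** $\hat H(x)$ is negative
   definite — statistically significant local-maximum curvature.
4. Extract the $S$ flagged regions (intervals / polygons / triangle
   meshes), replace each by its convex hull, and grow each hull by
   circle/sphere rolling until its area/volume is $G = 2^d$ times larger.
5. For the events inside each grown region, refit a KDE with two-stage
   diagonal plug-in bandwidths and keep the level-$\tau$ HDR
   $R_\tau = \{x : \hat f(x) \ge f_\tau\}$, where $f_\tau$ is the
   $\lceil \tau m \rceil$-th smallest density value at the subset points —
   so $R_{0.1}$ carries about 90% of the subset's probability mass.
6. The gate is the union of the HDR components, mapped back to original
   units; membership is purely geometric, so a saved gate re-applied to the
   same events reproduces it exactly. Axis-aligned rectangles can be
   intersected with any gate ("rectangle-curvHDR") to cut away boundary
   debris.

$\tau$ (default 0.1) is the main tuning knob; $G$, $\alpha = 0.05$ and
$h_{\mathrm{curv}}$ rarely need changing. See `docs/methods.md` for
assumptions, numerical choices and limitations.

## Worked example

Simulate the canonical bivariate fixture (two Gaussian populations plus a
banana-shaped arc, 2% uniform debris, 1% saturation pile-up) and gate it:

```bash
curvhdr simulate --fixture f2 --out f2.csv
curvhdr gate --input f2.csv --channels FL1-H,FL2-H --tau 0.1 \
        --out-gate f2_gate.json --out-membership f2_membership.csv
```

The run record printed to stdout (abbreviated):

```json
{"tau": 0.1, "growth_factor": 4.0, "alpha": 0.05,
 "h_curv": 0.3913142541087896, "transform": "asinh",
 "n_input": 6000, "n_debris": 61, "n_retained": 5939,
 "S": 3, "n_components": 3, "n_members": 5289}
```

Reading it: 61 events sat exactly on a saturated channel rail and were
excluded from gate placement; the curvature test found `S = 3` significant
modal regions; each produced one HDR component (`n_components = 3`), and
5289 of the 6000 events fall inside the final gate. `f2_gate.json` stores
the gate geometry in original channel units; `f2_membership.csv` holds one
row per event. The same gate can be re-applied to another sample with
`curvhdr apply --input other.csv --gate f2_gate.json`.

In this sample the component covering the arc population is genuinely
non-convex (its area is about two thirds of its convex hull's area) —
gates are not restricted to ellipses or any parametric shape.

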