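"""Seedable synthetic flow-like samples with known ground truth.

Real list-mode data mix several modal cell populations of unequal size and
covariance with a diffuse uniform "debris" background and saturation
pile-up at the detector rails.  The generator draws from exactly that
structure so every pipeline stage is testable offline: a Gaussian mixture
in raw channel units, uniform debris over the sample bounds, and
exact-value pile-ups on saturated channels.

Canonical fixtures (seeds fixed here):

* F1 — univariate bimodal fluorescence channel,
* F2 — bivariate three-population sample whose third population is a
  banana-shaped arc (a 6-component Gaussian arc) to exercise non-convex
  nonparametric gates,
* F3 — trivariate two-population sample with a heavy debris background.

Cluster layouts are designed on the asinh scale (where populations are
roughly Gaussian, as on a cytometer's log-like display) and mapped to raw
units through ``sinh``, with covariances scaled by the local Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .preprocess import EventTable

__all__ = [
    "SampleSpec",
    "simulate_sample",
    "gate_recovery_score",
    "fixture_f1",
    "fixture_f2",
    "fixture_f3",
]

LABEL_DEBRIS = -1
LABEL_SATURATION = -2


@dataclass(frozen=True)
class SampleSpec:
    """Recipe for one synthetic sample.

    ``clusters`` is a list of ``(weight, mean, cov)`` in raw channel units;
    weights are renormalised to the non-debris, non-saturated share.
    ``saturation`` maps channel index -> (fraction, pile-up value).
    """

    d: int
    n: int
    clusters: tuple
    debris_fraction: float = 0.0
    saturation: dict = field(default_factory=dict)
    channel_names: tuple[str, ...] | None = None
    bounds: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d not in (1, 2, 3) or self.n < 1:
            raise ValidationError("need d in 1..3 and n >= 1")
        if not self.clusters:
            raise ValidationError("at least one cluster is required")
        if not 0 <= self.debris_fraction < 1:
            raise ValidationError("debris_fraction must lie in [0, 1)")
        sat_total = sum(f for f, _ in self.saturation.values())
        if self.debris_fraction + sat_total >= 1:
            raise ValidationError("debris + saturation fractions must sum below 1")
        for w, mean, cov in self.clusters:
            cov = np.atleast_2d(np.asarray(cov, float))
            if w <= 0:
                raise ValidationError("cluster weights must be positive")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValidationError("cluster covariance not positive definite") from exc

    def names(self) -> tuple[str, ...]:
        if self.channel_names:
            return tuple(self.channel_names)
        return tuple(f"FL{j + 1}-H" for j in range(self.d))

    def box(self) -> np.ndarray:
        """Debris bounding box: cluster means +- 4 sd per axis, or override."""
        if self.bounds is not None:
            return np.asarray(self.bounds, float)
        los, his = [], []
        for _, mean, cov in self.clusters:
            mean = np.atleast_1d(np.asarray(mean, float))
            sd = np.sqrt(np.diag(np.atleast_2d(np.asarray(cov, float))))
            los.append(mean - 4 * sd)
            his.append(mean + 4 * sd)
        return np.stack([np.min(los, axis=0), np.max(his, axis=0)], axis=1)


def simulate_sample(spec: SampleSpec) -> tuple[EventTable, np.ndarray]:
    """Draw one sample; labels give the source of each event.

    Labels: cluster index ``0..K-1``, ``-1`` debris, ``-2`` saturated.
    Deterministic per ``spec.seed``; rows are shuffled so event order
    carries no information about the source.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for w, _, _ in spec.clusters], float)
    sat_items = sorted(spec.saturation.items())
    sat_fracs = np.array([f for _, (f, _) in sat_items])
    cluster_share = 1.0 - spec.debris_fraction - sat_fracs.sum()
    probs = np.concatenate(
        [cluster_share * weights / weights.sum(), [spec.debris_fraction], sat_fracs]
    )
    counts = rng.multinomial(spec.n, probs)
    k = len(spec.clusters)

    def draw_mixture(m: int) -> np.ndarray:
        comp = rng.choice(k, size=m, p=weights / weights.sum())
        out = np.empty((m, spec.d))
        for i, (w, mean, cov) in enumerate(spec.clusters):
            sel = comp == i
            if sel.any():
                out[sel] = rng.multivariate_normal(
                    np.atleast_1d(mean), np.atleast_2d(cov), size=int(sel.sum())
                )
        return out

    blocks, labels = [], []
    for i, (w, mean, cov) in enumerate(spec.clusters):
        m = counts[i]
        if m:
            blocks.append(
                rng.multivariate_normal(np.atleast_1d(mean), np.atleast_2d(cov), size=m)
            )
            labels.append(np.full(m, i))
    m_debris = counts[k]
    if m_debris:
        box = spec.box()
        blocks.append(rng.uniform(box[:, 0], box[:, 1], size=(m_debris, spec.d)))
        labels.append(np.full(m_debris, LABEL_DEBRIS))
    for j, (ch, (frac, value)) in enumerate(sat_items):
        m = counts[k + 1 + j]
        if m:
            ev = draw_mixture(m)
            ev[:, ch] = value
            blocks.append(ev)
            labels.append(np.full(m, LABEL_SATURATION))
    values = np.vstack(blocks)
    labels = np.concatenate(labels)
    perm = rng.permutation(len(values))
    table = EventTable(values[perm], spec.names(), "original")
    return table, labels[perm]


def gate_recovery_score(result, labels: np.ndarray) -> dict[int, tuple[float, float]]:
    """Per-cluster (capture, contamination) of a gating result.

    Each gate component is assigned to the cluster providing the majority
    of its member events; components assigned to the same cluster pool
    their membership.  ``capture`` is the fraction of the cluster's events
    inside its assigned component union; ``contamination`` is the fraction
    of that union's members coming from anywhere else (other clusters,
    debris, saturation).
    """
    labels = np.asarray(labels)
    clusters = sorted(int(c) for c in np.unique(labels) if c >= 0)
    union: dict[int, np.ndarray] = {}
    for mask in result.component_masks:
        inside = labels[mask]
        if inside.size == 0:
            continue
        real = inside[inside >= 0]
        target = (
            int(np.bincount(real).argmax()) if real.size else LABEL_DEBRIS
        )
        if target < 0:
            continue
        union[target] = union.get(target, np.zeros_like(mask)) | mask
    scores = {}
    for c in clusters:
        mask = union.get(c)
        cluster_ev = labels == c
        if mask is None or not mask.any():
            scores[c] = (0.0, 0.0)
            continue
        capture = float((mask & cluster_ev).sum() / cluster_ev.sum())
        contamination = float((mask & ~cluster_ev).sum() / mask.sum())
        scores[c] = (capture, contamination)
    return scores


# ---------------------------------------------------------------------------
# canonical fixtures (asinh-scale designs mapped to raw units)
# ---------------------------------------------------------------------------

def _raw_cluster(weight: float, mean_t, sd_t) -> tuple:
    """Map an asinh-scale (mean, per-axis sd) design to raw-unit moments."""
    mean_t = np.atleast_1d(np.asarray(mean_t, float))
    sd_t = np.atleast_1d(np.asarray(sd_t, float))
    mean_raw = np.sinh(mean_t)
    jac = np.cosh(mean_t)
    cov_raw = np.diag((jac * sd_t) ** 2)
    return (weight, mean_raw, cov_raw)


def fixture_f1(n: int = 8000, seed: int = 101) -> SampleSpec:
    """F1: univariate bimodal fluorescence with debris and rail pile-up."""
    clusters = (
        _raw_cluster(0.60, [6.0], [0.22]),
        _raw_cluster(0.40, [8.0], [0.30]),
    )
    return SampleSpec(
        d=1,
        n=n,
        clusters=clusters,
        debris_fraction=0.02,
        saturation={0: (0.02, 30000.0)},
        channel_names=("SSC-H",),
        seed=seed,
    )


def fixture_f2(n: int = 6000, seed: int = 202) -> SampleSpec:
    """F2: bivariate, three populations, one a non-convex banana arc.

    The arc is a 6-component Gaussian chain along a circular segment on the
    asinh scale; it reads as a single non-convex modal region and exercises
    the nonparametric (shape-unrestricted) character of the gates.
    """
    clusters = [
        _raw_cluster(0.28, [5.5, 5.0], [0.25, 0.25]),
        _raw_cluster(0.22, [8.2, 5.2], [0.30, 0.35]),
    ]
    cx, cy, radius = 6.8, 8.3, 1.1
    for theta in np.linspace(np.deg2rad(195), np.deg2rad(345), 6):
        clusters.append(
            _raw_cluster(
                0.50 / 6,
                [cx + radius * np.cos(theta), cy + radius * np.sin(theta)],
                [0.16, 0.16],
            )
        )
    return SampleSpec(
        d=2,
        n=n,
        clusters=tuple(clusters),
        debris_fraction=0.02,
        saturation={0: (0.01, 30000.0)},
        channel_names=("FL1-H", "FL2-H"),
        seed=seed,
    )


F2_ARC_COMPONENTS = range(2, 8)  # cluster indices forming the banana arc


def f2_merged_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse the six F2 arc sub-components into one banana label (2)."""
    out = labels.copy()
    out[np.isin(labels, list(F2_ARC_COMPONENTS))] = 2
    return out


def fixture_f3(n: int = 6000, seed: int = 303) -> SampleSpec:
    """F3: trivariate two-population sample over a heavy debris background."""
    clusters = (
        _raw_cluster(0.5, [5.5, 5.5, 5.5], [0.30, 0.30, 0.30]),
        _raw_cluster(0.4, [7.5, 7.0, 6.3], [0.30, 0.35, 0.30]),
    )
    return SampleSpec(
        d=3,
        n=n,
        clusters=clusters,
        debris_fraction=0.10,
        channel_names=("FSC-H", "SSC-H", "FL2-H"),
        seed=seed,
    )
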