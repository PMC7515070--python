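"""Synthetic measures and RR-like surrogates with known multifractal spectra.

Deterministic base-``b`` multiplicative cascades are the natural oracle
for a direct spectrum estimator: splitting mass recursively among ``b``
sub-intervals with fixed weights ``(p_1 ... p_b)`` produces a measure
whose singularity spectrum has the exact closed form

    alpha(q) = sum_i mu~_i ln(1/p_i) / ln b,
    f(q)     = sum_i mu~_i ln(1/mu~_i) / ln b,
    mu~_i    = p_i**q / sum_j p_j**q,

against which every estimate can be checked. Randomizing the weight
assignment per node scrambles the ordering of the cascade (making it
look irregular, like a heartbeat series) while provably leaving the
multiset of box masses at every level — and hence the spectrum —
unchanged.

RR-like surrogate cohorts emulate the two empirical classes: a
``healthy_like`` profile with a broad, right-skewed spectrum and a
``chf_like`` profile whose spectrum narrows (and whose vertex curvature
grows) with a severity parameter, standing in for worsening heart
failure. They are synthetic: amplitude statistics are not physiological,
only the multifractal structure is controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .spectrum import QGrid
from .tachogram import BoxMeasure, Tachogram

__all__ = [
    "CascadeSpec",
    "AnalyticSpectrum",
    "make_cascade",
    "analytic_spectrum",
    "make_rr_surrogate",
    "make_cohort",
    "HEALTHY_WEIGHTS",
]

#: base-4 weights of the healthy-like surrogate. The two small weights
#: (ratio 1.5) let q = -10 explore most of the right tail while the two
#: large weights (ratio 1.19) leave the left tail barely explored, so the
#: spectrum on the standard q grid is broad (delta_alpha ~ 0.8) and right
#: skewed (r ~ 1.3) with its curvature maximum at the vertex (q = 0) —
#: extreme weight ratios would instead saturate alpha(q) inside |q| <= 10
#: and blow up the finite-difference curvature in the tails.
HEALTHY_WEIGHTS = (0.38, 0.32, 0.18, 0.12)

#: fraction of the healthy weight spread removed at severity 1; the
#: remaining spread sets the chf-like spectrum width (~0.35 at severity 1,
#: roughly 3x narrower, hence ~10x the vertex curvature).
_SEVERITY_SHRINK = 0.65

#: memory guard: cascades no longer than 2**22 cells.
_MAX_CELLS = 2**22


@dataclass(frozen=True)
class CascadeSpec:
    """Parameters of a base-``b`` multiplicative cascade.

    ``weights`` must be ``base`` positive reals summing to one;
    ``levels`` is the recursion depth m (output length ``base**m``).
    ``randomize`` shuffles the weight assignment independently at every
    node, seeded for reproducibility.
    """

    base: int
    weights: tuple[float, ...]
    levels: int
    randomize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base < 2:
            raise ValueError("base must be >= 2")
        if len(self.weights) != self.base:
            raise ValueError("need exactly `base` weights")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {w.sum()!r}, not 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base**self.levels > _MAX_CELLS:
            raise ValueError(
                f"cascade of {self.base}**{self.levels} cells exceeds the "
                f"{_MAX_CELLS} guard"
            )


@dataclass(frozen=True)
class AnalyticSpectrum:
    """Closed-form spectrum of a cascade on a q grid.

    ``r_exact`` follows the same conventions as the estimator's shape
    metrics: endpoints of the (truncated) q grid for alpha_min/alpha_max
    and the f-maximizer for alpha_0.
    """

    q: np.ndarray
    alpha_exact: np.ndarray
    f_exact: np.ndarray
    alpha_min_exact: float   # -log_b(max weight), the q -> +inf limit
    alpha_max_exact: float   # -log_b(min weight), the q -> -inf limit
    alpha0_exact: float
    r_exact: float

    def vertex_curvature(self) -> float:
        """|f''(alpha)| at the vertex, by central differences on the grid.

        The slope vanishes at the vertex, so this equals the curvature K
        there up to O(h^2).
        """
        i0 = int(np.argmax(self.f_exact))
        a, f = self.alpha_exact, self.f_exact
        if not 0 < i0 < a.size - 1:
            raise ValueError("vertex not interior to the grid")
        h1 = a[i0] - a[i0 - 1]
        h2 = a[i0 + 1] - a[i0]
        d2 = 2.0 * (f[i0 - 1] * h2 - f[i0] * (h1 + h2) + f[i0 + 1] * h1) \
            / (h1 * h2 * (h1 + h2))
        return abs(d2)


def make_cascade(spec: CascadeSpec) -> BoxMeasure:
    """Construct the cascade measure iteratively.

    Starts from unit mass and, at each of ``levels`` generations, splits
    every cell's mass among ``base`` children by the weights — in fixed
    order, or per-node shuffled order when ``randomize`` is set.
    """
    w = np.asarray(spec.weights, dtype=float)
    masses = np.ones(1)
    rng = np.random.default_rng(spec.seed) if spec.randomize else None
    for _ in range(spec.levels):
        if rng is None:
            masses = np.multiply.outer(masses, w).ravel()
        else:
            rows = np.tile(w, (masses.size, 1))
            rows = rng.permuted(rows, axis=1)
            masses = (masses[:, None] * rows).ravel()
    # renormalize away accumulated rounding (sum drifts ~1e-14 at deep m)
    masses /= masses.sum()
    return BoxMeasure(p=masses, base=spec.base, m=spec.levels)


def analytic_spectrum(spec: CascadeSpec,
                      qgrid: QGrid | None = None) -> AnalyticSpectrum:
    """Exact (alpha(q), f(q)) curves of a cascade on a q grid."""
    qgrid = qgrid or QGrid()
    q = qgrid.values
    logw = np.log(np.asarray(spec.weights, dtype=float))
    lw = np.outer(q, logw)
    lw -= lw.max(axis=1, keepdims=True)
    mu = np.exp(lw)
    mu /= mu.sum(axis=1, keepdims=True)
    lnb = np.log(spec.base)
    alpha = -(mu @ logw) / lnb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = -np.einsum("ij,ij->i", mu, np.where(mu > 0, np.log(mu), 0.0)) / lnb
    fmax = f.max()
    ties = np.flatnonzero(f >= fmax - 1e-12)
    i0 = int(ties[np.argmin(np.abs(q[ties]))])
    alpha0 = float(alpha[i0])
    d_right = float(alpha[0]) - alpha0
    d_left = alpha0 - float(alpha[-1])
    r_exact = d_right / d_left if d_left > 1e-9 else float("inf")
    return AnalyticSpectrum(
        q=q, alpha_exact=alpha, f_exact=f,
        alpha_min_exact=float(-logw.max() / lnb),
        alpha_max_exact=float(-logw.min() / lnb),
        alpha0_exact=alpha0, r_exact=r_exact,
    )


def _profile_weights(profile: str, severity: float) -> np.ndarray:
    if profile not in ("healthy_like", "chf_like"):
        raise ValueError(f"unknown surrogate profile {profile!r}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    w = np.asarray(HEALTHY_WEIGHTS, dtype=float)
    if profile == "chf_like":
        # pull toward the uniform split: narrower spectrum, spikier vertex
        u = np.full_like(w, 1.0 / w.size)
        w = u + (1.0 - _SEVERITY_SHRINK * severity) * (w - u)
    return w / w.sum()


def make_rr_surrogate(profile: Literal["healthy_like", "chf_like"],
                      severity: float = 1.0, length_m: int = 16,
                      seed: int = 0, weight_jitter: float = 0.05,
                      mean_rr_s: float = 0.8) -> Tachogram:
    """A seeded RR-like tachogram with controlled multifractal structure.

    Builds a randomized base-4 cascade of ``2**length_m`` cells
    (``length_m`` must be even, at most 22) from the profile's weight set
    — perturbed per subject by a small log-normal jitter so cohorts have
    between-subject variance — then scales the measure by a constant so
    the mean interval is ``mean_rr_s`` seconds. Pure scaling is the only
    map under which spectrum estimation (which renormalizes) is exactly
    invariant, so the surrogate's spectrum is the cascade's. First half
    of the recording is tagged asleep, second half awake.
    """
    if length_m % 2 != 0:
        raise ValueError("length_m must be even (base-4 cascade)")
    if length_m > 22:
        raise ValueError("length_m must be <= 22")
    rng = np.random.default_rng(seed)
    w = _profile_weights(profile, severity)
    if weight_jitter > 0:
        w = w * np.exp(weight_jitter * rng.standard_normal(w.size))
        w = w / w.sum()
    cascade_seed = int(rng.integers(0, 2**31 - 1))
    spec = CascadeSpec(base=4, weights=tuple(w), levels=length_m // 2,
                       randomize=True, seed=cascade_seed)
    p = make_cascade(spec).p
    rr = p * (mean_rr_s * p.size)
    # same sequential cumsum the Tachogram time axis uses, so the awake
    # window's end matches t[-1] bit for bit
    total = float(np.cumsum(rr)[-1])
    condition = "healthy" if profile == "healthy_like" else "chf"
    return Tachogram(
        rr=rr,
        subject_id=f"synthetic-{profile}-{seed}",
        condition=condition,
        state_windows=[("asleep", 0.0, total / 2.0),
                       ("awake", total / 2.0, total)],
    )


def make_cohort(profile: Literal["healthy_like", "chf_like"], n: int,
                seed: int = 0, severity: float = 1.0,
                length_m: int = 16, **kwargs) -> list[Tachogram]:
    """n independent surrogate subjects with reproducible per-subject seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
    return [
        make_rr_surrogate(profile, severity=severity, length_m=length_m,
                          seed=s, **kwargs)
        for s in seeds
    ]
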