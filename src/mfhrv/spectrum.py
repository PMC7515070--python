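"""Direct (Chhabra-Jensen) estimation of the multifractal spectrum f(alpha).

Given a normalized measure on a base-``b`` support, the method covers the
support with boxes of relative size ``L = b**-n``, forms the one-parameter
family of q-warped box weights

    mu_i(q, L) = P_i(L)**q / sum_j P_j(L)**q,

and estimates, by least squares over a range of box sizes,

    f(q)     = slope of  sum_i mu_i log mu_i   versus log L,
    alpha(q) = slope of  sum_i mu_i log P_i    versus log L.

Plotting f(q) against alpha(q) traces the downward-concave singularity
spectrum directly, without a Legendre transform. ``q > 1`` magnifies the
densest (most singular) regions of the measure, ``q < 1`` the sparsest,
and ``q = 1`` reproduces the measure itself.

All powers are taken in log space (max-shifted before exponentiation) so
that |q| = 10 on box masses of order 1e-6 neither overflows nor
underflows. Logs are natural; slopes against log L are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .tachogram import BoxMeasure

__all__ = [
    "QGrid",
    "ScaleGrid",
    "SpectrumPoint",
    "MultifractalSpectrum",
    "box_probabilities",
    "mu_family",
    "scaling_sums",
    "spectrum_point",
    "compute_spectrum",
]

SPECTRUM_CSV_COLUMNS = ["q", "alpha", "f", "r2_alpha", "r2_f",
                        "stderr_alpha", "stderr_f"]


@dataclass(frozen=True)
class QGrid:
    """Uniform grid of moment orders q.

    Defaults span q = -10 ... 10 in steps of 0.1, i.e. 201 values with 0
    and 1 on the grid.
    """

    q_min: float = -10.0
    q_max: float = 10.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0 or self.q_max <= self.q_min:
            raise ValueError("need q_min < q_max and step > 0")
        span = (self.q_max - self.q_min) / self.step
        if abs(span - round(span)) > 1e-9:
            raise ValueError("step must divide the q range exactly")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.q_max - self.q_min) / self.step)) + 1
        return np.linspace(self.q_min, self.q_max, n)

    def __len__(self) -> int:
        return int(round((self.q_max - self.q_min) / self.step)) + 1

    def index_of(self, q: float) -> int:
        """Index of the grid point closest to ``q``."""
        return int(np.argmin(np.abs(self.values - q)))


@dataclass(frozen=True)
class ScaleGrid:
    """Box-size levels entering the scaling fits.

    Level ``n`` partitions a measure of length ``base**m`` into ``base**n``
    boxes of relative side ``L = base**-n``, each holding ``base**(m-n)``
    samples. Valid levels are ``1 <= n <= m - 1`` (at least ``base`` boxes
    and at least ``base`` samples per box); the default uses all of them.
    """

    base: int
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.base < 2:
            raise ValueError("base must be >= 2")
        if len(self.levels) < 1 or any(n < 1 for n in self.levels):
            raise ValueError("levels must be positive integers")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("duplicate levels")

    @classmethod
    def default_for(cls, measure: BoxMeasure) -> "ScaleGrid":
        if measure.m < 2:
            raise ValueError("measure too short for any scaling fit")
        return cls(base=measure.base, levels=tuple(range(1, measure.m)))

    @property
    def log_sizes(self) -> np.ndarray:
        """log L = -n log b for each level."""
        return -np.asarray(self.levels, dtype=float) * np.log(self.base)

    def validate_for(self, measure: BoxMeasure) -> None:
        if self.base != measure.base:
            raise ValueError("scale grid base does not match the measure")
        if max(self.levels) > measure.m - 1:
            raise ValueError(
                f"level {max(self.levels)} out of range for m={measure.m} "
                "(need 1 <= n <= m-1)"
            )


@dataclass(frozen=True)
class SpectrumPoint:
    """One (q, alpha, f) point with its regression diagnostics."""

    q: float
    alpha: float
    f: float
    r2_alpha: float
    r2_f: float
    stderr_alpha: float
    stderr_f: float


@dataclass
class MultifractalSpectrum:
    """The estimated singularity spectrum on a q grid.

    Stored as parallel arrays ordered by q; ``points`` iterates them as
    :class:`SpectrumPoint` records. ``alpha`` is non-increasing in q for
    exact cascades; empirical series may show small inversions, which are
    flagged in ``alpha_monotone`` but are not fatal.
    """

    q: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    r2_alpha: np.ndarray
    r2_f: np.ndarray
    stderr_alpha: np.ndarray
    stderr_f: np.ndarray
    base: int
    levels: tuple[int, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        for name in ("q", "alpha", "f", "r2_alpha", "r2_f",
                     "stderr_alpha", "stderr_f"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.q.size == self.alpha.size == self.f.size):
            raise ValueError("q, alpha, f must have equal length")
        if not np.all(np.isfinite(self.alpha)) or not np.all(np.isfinite(self.f)):
            raise ValueError("non-finite spectrum values")

    def __len__(self) -> int:
        return int(self.q.size)

    @property
    def points(self) -> Iterator[SpectrumPoint]:
        for i in range(len(self)):
            yield SpectrumPoint(
                q=float(self.q[i]), alpha=float(self.alpha[i]),
                f=float(self.f[i]), r2_alpha=float(self.r2_alpha[i]),
                r2_f=float(self.r2_f[i]),
                stderr_alpha=float(self.stderr_alpha[i]),
                stderr_f=float(self.stderr_f[i]),
            )

    @property
    def alpha_monotone(self) -> bool:
        """True when alpha is non-increasing in q (tolerance 1e-6/step)."""
        return bool(np.all(np.diff(self.alpha) <= 1e-6))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "q": self.q, "alpha": self.alpha, "f": self.f,
            "r2_alpha": self.r2_alpha, "r2_f": self.r2_f,
            "stderr_alpha": self.stderr_alpha, "stderr_f": self.stderr_f,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_curve(cls, alpha: Sequence[float], f: Sequence[float],
                   q: Sequence[float] | None = None,
                   source_id: str = "curve") -> "MultifractalSpectrum":
        """Wrap an externally supplied (alpha, f) curve (e.g. an analytic
        spectrum or a test shape) in the spectrum container."""
        alpha = np.asarray(alpha, dtype=float)
        f = np.asarray(f, dtype=float)
        if q is None:
            q = np.arange(alpha.size, dtype=float)
        q = np.asarray(q, dtype=float)
        z = np.zeros_like(alpha)
        return cls(q=q, alpha=alpha, f=f, r2_alpha=z + 1.0, r2_f=z + 1.0,
                   stderr_alpha=z, stderr_f=z, base=0, levels=(),
                   source_id=source_id)


def box_probabilities(measure: BoxMeasure, n: int) -> np.ndarray:
    """Total mass P_i(L) in each of the ``base**n`` boxes at level ``n``."""
    if not 1 <= n <= measure.m - 1:
        raise ValueError(f"level n={n} out of range 1..{measure.m - 1}")
    return measure.p.reshape(measure.base**n, -1).sum(axis=1)


def mu_family(P: Sequence[float], q: float) -> np.ndarray:
    """The q-warped normalized weights mu_i = P_i**q / sum_j P_j**q.

    Zero-mass boxes are excluded (the 0*log 0 -> 0 convention); the
    returned array covers the positive boxes only and sums to one.
    Computed in log space so extreme q on tiny masses stays finite.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("box masses must be non-negative")
    P = P[P > 0]
    if P.size == 0:
        raise ValueError("all boxes have zero mass")
    logw = q * np.log(P)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def scaling_sums(measure: BoxMeasure, q: float,
                 scales: ScaleGrid) -> list[tuple[float, float]]:
    """Per-scale numerators (S_f, S_alpha) for one q.

    ``S_f = sum_i mu_i log mu_i`` (an entropy, always <= 0) and
    ``S_alpha = sum_i mu_i log P_i``; their slopes versus log L over the
    scale grid give f(q) and alpha(q).
    """
    scales.validate_for(measure)
    out: list[tuple[float, float]] = []
    for n in scales.levels:
        P = box_probabilities(measure, n)
        P = P[P > 0]
        logP = np.log(P)
        logw = q * logP
        shift = logw.max()
        w = np.exp(logw - shift)
        Z = w.sum()
        mu = w / Z
        logmu = logw - shift - np.log(Z)
        out.append((float(mu @ logmu), float(mu @ logP)))
    return out


def _ols_slopes(y: np.ndarray, x: np.ndarray):
    """Vectorized OLS of each row of ``y`` on ``x``.

    Returns (slope, r2, stderr) arrays. A perfectly collinear fit gets
    r2 = 1 and stderr 0; with exactly two scales stderr is reported as 0.
    """
    k = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("degenerate regression: all log L equal")
    slope = (y @ xc) / sxx
    ym = y.mean(axis=1)
    resid = y - ym[:, None] - np.outer(slope, xc)
    ss_res = np.einsum("ij,ij->i", resid, resid)
    ss_tot = np.einsum("ij,ij->i", y - ym[:, None], y - ym[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    dof = max(k - 2, 1)
    stderr = np.sqrt(np.maximum(ss_res, 0.0) / dof / sxx)
    return slope, r2, stderr


def _scaling_matrices(measure: BoxMeasure, qvals: np.ndarray,
                      scales: ScaleGrid):
    """S_f and S_alpha for every (q, level) pair, shape (nq, nlevels)."""
    nq, nl = qvals.size, len(scales.levels)
    S_f = np.empty((nq, nl))
    S_a = np.empty((nq, nl))
    for j, n in enumerate(scales.levels):
        P = box_probabilities(measure, n)
        P = P[P > 0]
        logP = np.log(P)
        logw = np.outer(qvals, logP)
        shift = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - shift)
        Z = w.sum(axis=1, keepdims=True)
        mu = w / Z
        logmu = logw - shift - np.log(Z)
        S_f[:, j] = np.einsum("ij,ij->i", mu, logmu)
        S_a[:, j] = mu @ logP
    return S_f, S_a


def spectrum_point(measure: BoxMeasure, q: float,
                   scales: ScaleGrid) -> SpectrumPoint:
    """Estimate alpha(q) and f(q) for a single moment order."""
    if len(scales.levels) < 3:
        raise ValueError("need at least 3 scales for a meaningful fit")
    S_f, S_a = _scaling_matrices(measure, np.asarray([q], dtype=float), scales)
    x = scales.log_sizes
    f, r2_f, se_f = _ols_slopes(S_f, x)
    a, r2_a, se_a = _ols_slopes(S_a, x)
    return SpectrumPoint(q=float(q), alpha=float(a[0]), f=float(f[0]),
                         r2_alpha=float(r2_a[0]), r2_f=float(r2_f[0]),
                         stderr_alpha=float(se_a[0]), stderr_f=float(se_f[0]))


def compute_spectrum(measure: BoxMeasure, qgrid: QGrid | None = None,
                     scales: ScaleGrid | None = None,
                     source_id: str = "") -> MultifractalSpectrum:
    """Estimate the full multifractal spectrum over a q grid.

    Under the defaults (q = -10 ... 10 step 0.1, all valid box levels)
    the result has exactly 201 points. Each q is fitted independently.
    """
    qgrid = qgrid or QGrid()
    scales = scales or ScaleGrid.default_for(measure)
    scales.validate_for(measure)
    if len(scales.levels) < 3:
        raise ValueError("need at least 3 scales for a meaningful fit")
    qvals = qgrid.values
    S_f, S_a = _scaling_matrices(measure, qvals, scales)
    x = scales.log_sizes
    f, r2_f, se_f = _ols_slopes(S_f, x)
    alpha, r2_a, se_a = _ols_slopes(S_a, x)
    return MultifractalSpectrum(
        q=qvals, alpha=alpha, f=f, r2_alpha=r2_a, r2_f=r2_f,
        stderr_alpha=se_a, stderr_f=se_f,
        base=measure.base, levels=tuple(scales.levels), source_id=source_id,
    )
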