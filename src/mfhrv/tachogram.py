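"""Reading, validating and segmenting RR-interval series (tachograms).

An RR tachogram is the ordered sequence of intervals between successive
heartbeats, typically extracted from a 24 h Holter ECG recording. This
module turns plain-text RR files into :class:`Tachogram` objects, cuts out
fixed-duration asleep/awake segments, and converts a tachogram into the
normalized singular measure on a dyadic (or base-``b``) support that the
multifractal estimator operates on.

File format: one RR interval per line, in seconds or milliseconds, with an
optional leading cumulative-time column and ``#`` comments. Binary Holter
formats (e.g. WFDB annotation files) are out of scope; convert them to this
text form first (``rdann -r rec -a atr`` piped through an RR-difference
step, or any HRV toolbox export).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Tachogram",
    "BoxMeasure",
    "read_rr",
    "read_sidecar",
    "extract_segment",
    "filter_artifacts",
    "to_measure",
]

Condition = Literal["healthy", "chf", "unknown"]
NYHA_CLASSES = ("none", "I", "II", "III", "III-IV", "IV")
STATE_LABELS = ("asleep", "awake")

#: raw values whose median exceeds this are taken to be milliseconds;
#: physiologic RR intervals never exceed 10 s.
_MS_MEDIAN_THRESHOLD = 10.0


@dataclass
class Tachogram:
    """An ordered RR-interval series with subject metadata.

    Parameters
    ----------
    rr
        RR intervals in seconds; every value must be positive and finite.
    subject_id
        Free-text subject identifier.
    condition
        ``"healthy"``, ``"chf"`` or ``"unknown"``.
    nyha
        NYHA functional class of a CHF patient (``"none"`` if not graded).
    state_windows
        Optional ``(label, start_s, end_s)`` triples marking asleep/awake
        periods on the cumulative-time axis. Windows must not overlap and
        must lie within the recording.
    """

    rr: np.ndarray
    subject_id: str = "unknown"
    condition: Condition = "unknown"
    nyha: str = "none"
    state_windows: list[tuple[str, float, float]] | None = None
    t: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1 or self.rr.size == 0:
            raise ValueError("tachogram needs a 1-D, non-empty RR sequence")
        if not np.all(np.isfinite(self.rr)) or np.any(self.rr <= 0):
            bad = np.flatnonzero(~np.isfinite(self.rr) | (self.rr <= 0)) + 1
            raise ValueError(
                f"non-positive or non-finite RR at positions {bad.tolist()[:10]}"
            )
        # cumulative time: t[0] = 0, t[i] = t[i-1] + rr[i-1]
        self.t = np.concatenate(([0.0], np.cumsum(self.rr)))
        if self.nyha not in NYHA_CLASSES:
            raise ValueError(f"unknown NYHA class {self.nyha!r}")
        if self.state_windows:
            self._check_windows()

    def _check_windows(self) -> None:
        total = float(self.t[-1])
        tol = 1e-9 * max(1.0, total)
        wins = sorted(self.state_windows, key=lambda w: w[1])
        for label, start, end in wins:
            if label not in STATE_LABELS:
                raise ValueError(f"unknown state label {label!r}")
            if not (0.0 <= start < end <= total + tol):
                raise ValueError(
                    f"window {label}={start}:{end} outside recording [0, {total:.1f}]"
                )
        for (_, _, e0), (_, s1, _) in zip(wins, wins[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("state windows overlap")

    @property
    def n_beats(self) -> int:
        return int(self.rr.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1])


@dataclass(frozen=True)
class BoxMeasure:
    """A normalized singular measure on a base-``b`` support.

    ``p`` holds ``base**m`` non-negative masses summing to one — the RR
    series normalized by its total, or a synthetic cascade. Every box
    partition of the analysis nests exactly in this support.
    """

    p: np.ndarray
    base: int
    m: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if self.base < 2:
            raise ValueError("base must be >= 2")
        if p.size != self.base**self.m:
            raise ValueError(f"length {p.size} is not {self.base}^{self.m}")
        if np.any(p < 0):
            raise ValueError("measure has negative mass")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"measure sums to {p.sum()!r}, not 1")

    def __len__(self) -> int:
        return int(self.p.size)


def read_rr(path: str | Path, units: Literal["s", "ms", "auto"] = "auto",
            sidecar: str | Path | None = "auto") -> Tachogram:
    """Read a plain-text RR file into a :class:`Tachogram` (seconds).

    Each non-comment line holds either one value (an RR interval) or two
    (cumulative time, RR interval); only the RR column is used, the time
    axis is rebuilt from the intervals. ``units="auto"`` infers
    milliseconds when the median raw value exceeds 10.

    If ``sidecar="auto"`` and ``<path>.meta`` exists it is read for
    subject metadata and state windows (see :func:`read_sidecar`).
    """
    path = Path(path)
    values: list[float] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (1, 2):
                raise ValueError(f"{path}: line {lineno}: expected 1 or 2 values")
            values.append(float(parts[-1]))
            lines.append(lineno)
    if not values:
        raise ValueError(f"{path}: no samples")
    rr = np.asarray(values, dtype=float)
    if units == "auto":
        units = "ms" if np.median(rr) > _MS_MEDIAN_THRESHOLD else "s"
    if units == "ms":
        rr = rr / 1000.0
    bad = np.flatnonzero(~np.isfinite(rr) | (rr <= 0))
    if bad.size:
        where = [lines[i] for i in bad[:10]]
        raise ValueError(f"{path}: non-positive RR on line(s) {where}")

    meta: dict = {}
    if sidecar == "auto":
        candidate = path.with_name(path.name + ".meta")
        if candidate.exists():
            meta = read_sidecar(candidate)
    elif sidecar is not None:
        meta = read_sidecar(sidecar)
    return Tachogram(rr=rr, **meta)


def read_sidecar(path: str | Path) -> dict:
    """Parse a key-value sidecar config.

    Recognized lines: ``subject_id=...``, ``condition=healthy|chf|unknown``,
    ``nyha=I|II|III|III-IV|IV|none`` and state windows as
    ``asleep=start_s:end_s`` / ``awake=start_s:end_s`` (repeatable).
    """
    meta: dict = {}
    windows: list[tuple[str, float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in STATE_LABELS:
                start, _, end = value.partition(":")
                windows.append((key, float(start), float(end)))
            elif key in ("subject_id", "condition", "nyha"):
                meta[key] = value
            else:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
    if windows:
        meta["state_windows"] = windows
    return meta


def extract_segment(tg: Tachogram, label: Literal["asleep", "awake"],
                    duration_s: float = 21600.0) -> Tachogram:
    """Cut the first qualifying fixed-duration segment of a given state.

    Scans the tachogram's state windows carrying ``label`` in temporal
    order; from the first window whose span covers ``duration_s``, returns
    the sub-tachogram of the smallest prefix of beats (starting at the
    first beat inside the window) whose summed RR reaches ``duration_s``.
    The default of 21 600 s is a six-hour segment. Raises if no window
    provides a continuous period of the requested length — such recordings
    are excluded from segment-level analyses.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    windows = [w for w in (tg.state_windows or []) if w[0] == label]
    for _, start, end in sorted(windows, key=lambda w: w[1]):
        if end - start < duration_s:
            continue
        i0 = int(np.searchsorted(tg.t, start, side="left"))
        if i0 >= tg.n_beats:
            continue
        cum = np.cumsum(tg.rr[i0:])
        j = int(np.searchsorted(cum, duration_s, side="left"))
        if j >= cum.size or tg.t[i0] + cum[j] > end + 1e-9:
            continue
        rr = tg.rr[i0 : i0 + j + 1]
        return Tachogram(
            rr=rr.copy(),
            subject_id=tg.subject_id,
            condition=tg.condition,
            nyha=tg.nyha,
            state_windows=[(label, 0.0, float(rr.sum()))],
        )
    raise ValueError(
        f"{tg.subject_id}: no continuous {label} period of {duration_s:.0f} s"
    )


def filter_artifacts(tg: Tachogram, rr_range: tuple[float, float] = (0.2, 4.0),
                     max_jump: float = 0.2) -> Tachogram:
    """Drop physiologically implausible beats (optional; off by default).

    Removes RR values outside ``rr_range`` seconds and beats differing
    from their predecessor by more than ``max_jump`` (fractional). The
    default analysis pipeline applies no artifact rejection.
    """
    rr = tg.rr
    keep = (rr >= rr_range[0]) & (rr <= rr_range[1])
    prev = np.concatenate(([rr[0]], rr[:-1]))
    keep &= np.abs(rr - prev) <= max_jump * prev
    keep[0] = rr_range[0] <= rr[0] <= rr_range[1]
    if not np.any(keep):
        raise ValueError("artifact filter removed every beat")
    return replace_rr(tg, tg.rr[keep])


def replace_rr(tg: Tachogram, rr: Sequence[float]) -> Tachogram:
    """Return a copy of ``tg`` with a new RR sequence (windows dropped)."""
    return Tachogram(
        rr=np.asarray(rr, dtype=float),
        subject_id=tg.subject_id,
        condition=tg.condition,
        nyha=tg.nyha,
        state_windows=None,
    )


def to_measure(tg: Tachogram, base: int = 2) -> BoxMeasure:
    """Normalize a tachogram into a singular measure on a base-``b`` support.

    The series is truncated to its largest leading block of length
    ``base**m`` (padding would inject artificial singularities) and each
    RR is divided by the block sum, so the measure partitions exactly into
    ``base**n`` boxes at every level ``n <= m``. Requires at least 16
    beats (two dyadic partition levels of at least two samples each); a
    useful spectrum needs far more. The result is invariant to rescaling
    the RR series by any positive constant.
    """
    if base < 2:
        raise ValueError("base must be >= 2")
    n = tg.n_beats
    # floor of 16 samples = base^4 boxes-within-boxes for the dyadic default
    min_n = max(base**2, 16)
    if n < min_n:
        raise ValueError(f"series too short: {n} < {min_n} samples")
    m = int(math.floor(math.log(n) / math.log(base) + 1e-12))
    length = base**m
    block = tg.rr[:length]
    return BoxMeasure(p=block / block.sum(), base=base, m=m)
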