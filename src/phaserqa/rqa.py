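"""Multidimensional recurrence quantification over circular phase.

Relative phase is circular, and a naive recurrence threshold on raw angles
sees 359deg and 1deg as 358deg apart.  Analysing the unit-circle
coordinates (cos psi, sin psi) as one two-dimensional signal fixes this:
the Euclidean distance between two phase points is the chord
``2*sin(|delta psi|/2)``, so with the default radius of 1 two taps recur
exactly when their circular phase difference is at most
``2*arcsin(1/2) = 60deg``.

Defaults reproduce the analysis configuration: a single embedding
dimension (the 2-D signal needs no phase-space reconstruction), unit
delay, no phase-space normalisation, radius 1, no z-scoring.  Diagonal
line statistics use a Theiler window of 1 (line of identity excluded) and
minimum line length 2; %REC is the full-matrix recurrence density
including the LOI, matching common MdRQA implementations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .phase import PhaseSeries

NORMS = ("none", "euclidean", "maximum", "minimum")

REGION_LABELS = ("r1", "r2", "r3")


@dataclass(frozen=True)
class RQAParams:
    """Recurrence-analysis parameters.

    emb, delay, norm, radius and zscore mirror the five standard MdRQA
    parameters (EMB, DEL, NORM, RAD, ZSCORE); lmin and theiler fix the
    line-counting conventions.
    """

    emb: int = 1
    delay: int = 1
    norm: str = "none"
    radius: float = 1.0
    zscore: bool = False
    lmin: int = 2
    theiler: int = 1

    def __post_init__(self) -> None:
        if self.emb < 1:
            raise ValueError("emb must be a positive integer")
        if self.delay < 1:
            raise ValueError("delay must be a positive integer")
        if self.norm not in NORMS:
            raise ValueError(f"norm must be one of {NORMS}, got {self.norm!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")

    @classmethod
    def from_file(cls, path: Path | str) -> "RQAParams":
        """Load parameters from a YAML or JSON config; missing keys keep
        their defaults, unknown keys raise."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of parameter names")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "emb": self.emb,
            "delay": self.delay,
            "norm": self.norm,
            "radius": self.radius,
            "zscore": self.zscore,
            "lmin": self.lmin,
            "theiler": self.theiler,
        }


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary recurrence matrix of an embedded series."""

    matrix: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=bool)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("recurrence matrix must be square")
        mat = mat.copy()
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "n", int(mat.shape[0]))

    def to_text(self) -> str:
        """Dense 0/1 grid, one row per line."""
        return "\n".join("".join("1" if v else "0" for v in row) for row in self.matrix)

    def to_pairs(self) -> List[Tuple[int, int]]:
        """Sparse (i, j) list of recurrent cells."""
        ii, jj = np.nonzero(self.matrix)
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass(frozen=True)
class RQAMetrics:
    """%REC, %DET and MAXL for one (sub-)recurrence plot.

    ``None`` marks an undefined metric (too few points, or no recurrent
    points off the line of identity); it is never coerced to 0.
    """

    rec: Optional[float]
    det: Optional[float]
    maxl: Optional[int]
    n: int

    @property
    def is_missing(self) -> bool:
        return self.rec is None


def _missing_metrics(n: int) -> RQAMetrics:
    return RQAMetrics(rec=None, det=None, maxl=None, n=n)


def embed(signal, emb: int, delay: int) -> np.ndarray:
    """Time-delay embedding of a (possibly multidimensional) signal.

    emb = 1 returns the signal unchanged (as a 2-D array); emb > 1 stacks
    delayed copies so each point carries emb*d coordinates, shortening the
    series to ``len - (emb-1)*delay`` points.
    """
    arr = np.asarray(signal, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("signal must be 1-D or 2-D (time x dimensions)")
    if emb < 1 or delay < 1:
        raise ValueError("emb and delay must be positive integers")
    n_out = arr.shape[0] - (emb - 1) * delay
    if n_out < 1:
        raise ValueError(
            f"series of length {arr.shape[0]} too short for emb={emb}, delay={delay}"
        )
    if emb == 1:
        return arr
    return np.hstack([arr[k * delay : k * delay + n_out] for k in range(emb)])


def _normalize_phase_space(points: np.ndarray, norm: str) -> np.ndarray:
    """Rescale phase-space points by their mean/max/min point norm."""
    if norm == "none":
        return points
    lengths = np.linalg.norm(points, axis=1)
    if norm == "euclidean":
        scale = float(np.mean(lengths))
    elif norm == "maximum":
        scale = float(np.max(lengths))
    elif norm == "minimum":
        nonzero = lengths[lengths > 0]
        scale = float(np.min(nonzero)) if nonzero.size else 0.0
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if scale == 0.0:
        return points
    return points / scale


def distance_matrix(embedded: np.ndarray, norm: str = "none") -> np.ndarray:
    """Pairwise Euclidean distances between embedded points, after the
    optional phase-space rescaling named by ``norm``."""
    pts = np.asarray(embedded, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    pts = _normalize_phase_space(pts, norm)
    return cdist(pts, pts)


def recurrence_plot(distances: np.ndarray, radius: float) -> RecurrencePlot:
    """Threshold a distance matrix: recurrent iff distance <= radius.

    The threshold is inclusive, which makes the 60deg boundary case of the
    default configuration deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dist = np.asarray(distances, dtype=float)
    return RecurrencePlot(matrix=dist <= radius, n=dist.shape[0])


def percent_recurrence(rp: RecurrencePlot) -> Optional[float]:
    """Recurrence density over the full matrix (LOI included), percent."""
    if rp.n < 2:
        return None
    return 100.0 * float(np.count_nonzero(rp.matrix)) / float(rp.n * rp.n)


def _run_lengths(line: np.ndarray) -> List[int]:
    if line.size == 0:
        return []
    padded = np.concatenate(([0], line.astype(np.int8), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return (ends - starts).tolist()


def diagonal_line_lengths(rp: RecurrencePlot, theiler: int = 1) -> List[int]:
    """Lengths of all maximal diagonal runs outside the Theiler band.

    Diagonals at offsets |k| >= max(1, theiler) are scanned; both symmetric
    halves are counted.  The line of identity never contributes.
    """
    lengths: List[int] = []
    lo = max(1, theiler)
    for k in range(lo, rp.n):
        lengths.extend(_run_lengths(np.diagonal(rp.matrix, offset=k)))
        lengths.extend(_run_lengths(np.diagonal(rp.matrix, offset=-k)))
    return lengths


def percent_determinism(
    line_lengths: Sequence[int], lmin: int = 2
) -> Optional[float]:
    """Share of off-LOI recurrent points lying on diagonals of length >=
    lmin, percent; ``None`` when there are no off-LOI recurrent points."""
    total = sum(line_lengths)
    if total == 0:
        return None
    on_lines = sum(l for l in line_lengths if l >= lmin)
    return 100.0 * on_lines / total


def maxline(line_lengths: Sequence[int]) -> int:
    """Longest diagonal run off the line of identity (0 when none)."""
    return max(line_lengths, default=0)


def _signal_from(series) -> np.ndarray:
    if isinstance(series, PhaseSeries):
        return np.column_stack([series.x, series.y])
    arr = np.asarray(series, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def mdrqa(
    series, params: RQAParams = RQAParams()
) -> Tuple[Optional[RecurrencePlot], RQAMetrics]:
    """Full recurrence analysis of a phase series (or raw 2-D signal).

    Returns the recurrence plot and its metrics.  Series shorter than 2
    points after embedding yield ``(None, missing metrics)``.
    """
    signal = _signal_from(series)
    min_len = (params.emb - 1) * params.delay + 2
    if signal.shape[0] < min_len:
        return None, _missing_metrics(max(0, signal.shape[0] - (params.emb - 1) * params.delay))
    if params.zscore:
        sd = signal.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        signal = (signal - signal.mean(axis=0)) / sd
    embedded = embed(signal, params.emb, params.delay)
    rp = recurrence_plot(distance_matrix(embedded, params.norm), params.radius)
    lengths = diagonal_line_lengths(rp, params.theiler)
    metrics = RQAMetrics(
        rec=percent_recurrence(rp),
        det=percent_determinism(lengths, params.lmin),
        maxl=maxline(lengths),
        n=rp.n,
    )
    return rp, metrics


def region_metrics(
    series: PhaseSeries,
    regions: np.ndarray,
    params: RQAParams = RQAParams(),
) -> Dict[str, RQAMetrics]:
    """Region-based analysis: metrics per phase region r1/r2/r3.

    The taps of each region are extracted in original order and analysed
    as their own series with the same parameters; synchronous taps are
    excluded entirely.  A region with fewer than ``max(2, lmin)`` taps
    yields missing metrics rather than zeros.
    """
    regions = np.asarray(regions)
    if regions.shape[0] != len(series):
        raise ValueError("region assignment is not aligned with the series")
    min_points = max(2, params.lmin)
    out: Dict[str, RQAMetrics] = {}
    for label in REGION_LABELS:
        idx = np.flatnonzero(regions == label)
        if idx.size < min_points:
            out[label] = _missing_metrics(int(idx.size))
            continue
        sub = np.column_stack([series.x[idx], series.y[idx]])
        _, metrics = mdrqa(sub, params)
        out[label] = metrics
    return out
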