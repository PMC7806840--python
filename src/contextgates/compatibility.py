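"""Pairwise gate compatibility and cross-context shape similarity.

Two inverters A -> B compose correctly when A's output bands land inside
B's input bands: A's low-output band (below OL_A) must sit below B's
low-input threshold IL_B, and A's high-output band (above OH_A) above B's
high-input threshold IH_B — concretely IL_B > OL_A and IH_B < OH_A. The
margin is summarized by the log-ratio score

    score(A, B) = min( ln(IL_B / OL_A), ln(OH_A / IH_B) )

which is positive iff the pair is compatible, and larger when the bands
nest with more room to spare.

Shape similarity between two characterizations (typically the same gate in
two contexts) is 1 minus the discrete Fréchet distance between the two
curves after log-transforming and min-max normalizing each curve's axes to
the unit square, making it a pure comparison of curve shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .core import GateContext
from .errors import DataError
from .hill import Thresholds, is_operational
from .standardization import Characterization


@dataclass(frozen=True)
class CompatibilityEdge:
    """Scored ordered pair: can ``source`` drive ``target``?"""

    source: GateContext
    target: GateContext
    score: float
    compatible: bool


@dataclass(frozen=True)
class SimilarityResult:
    """Shape similarity of two normalized transfer-function curves."""

    curve_a: GateContext
    curve_b: GateContext
    frechet: float
    similarity: float


def compatibility_score(
    a: Thresholds,
    b: Thresholds,
    source: GateContext | None = None,
    target: GateContext | None = None,
) -> CompatibilityEdge:
    """Score the ordered pairing A -> B of two *operational* gates.

    Compatibility requires a strictly positive score; a score of exactly 0
    (coincident thresholds) is not compatible.
    """
    if not is_operational(a) or not is_operational(b):
        raise ValueError("compatibility is defined only for operational inverter pairs")
    score = float(min(np.log(b.IL / a.OL), np.log(a.OH / b.IH)))
    return CompatibilityEdge(
        source=source,
        target=target,
        score=score,
        compatible=score > 0,
    )


@dataclass
class CompatibilityTable:
    """All scored ordered pairs over a gate-context library."""

    edges: list[CompatibilityEdge]
    nodes: list[GateContext]
    n_compatible: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "source": e.source.label,
                    "target": e.target.label,
                    "score": e.score,
                    "compatible": e.compatible,
                }
                for e in self.edges
            ]
        )


def compatibility_matrix(
    library: Iterable[tuple[GateContext, Thresholds]],
    context_filter: Callable[[GateContext], bool] | None = None,
    exclude_same_family: bool = True,
) -> CompatibilityTable:
    """Score every ordered pair of operational, filter-passing devices.

    Self-pairs are never scored. Pairs whose two devices share a repressor
    family are scored but marked incompatible when ``exclude_same_family``
    (the default): in a chain the repressor of one step is the input of
    the next, so a family cannot drive its own cognate promoter.
    """
    entries = [
        (gc, t)
        for gc, t in library
        if is_operational(t) and (context_filter is None or context_filter(gc))
    ]
    nodes = [gc for gc, _ in entries]
    edges: list[CompatibilityEdge] = []
    for i, (gi, ti) in enumerate(entries):
        for j, (gj, tj) in enumerate(entries):
            if i == j:
                continue
            e = compatibility_score(ti, tj, source=gi, target=gj)
            if exclude_same_family and gi.repressor_family == gj.repressor_family:
                e = CompatibilityEdge(source=gi, target=gj, score=e.score, compatible=False)
            edges.append(e)
    return CompatibilityTable(
        edges=edges,
        nodes=nodes,
        n_compatible=sum(e.compatible for e in edges),
    )


def discrete_frechet(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete Fréchet distance between two 2D point sequences.

    Classic dynamic program over monotone couplings with the Euclidean
    point metric: the minimum over couplings of the maximum paired
    distance. Symmetric; zero iff the sequences are identical.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.size == 0 or q.size == 0:
        raise ValueError("point sequences must be non-empty")
    if p.shape[1] != 2 or q.shape[1] != 2:
        raise ValueError("points must be 2D")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    m, n = d.shape
    ca = np.empty((m, n))
    ca[0, 0] = d[0, 0]
    for j in range(1, n):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, m):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, n):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def _normalize_curve(points: np.ndarray, label: str) -> np.ndarray:
    if np.any(points <= 0):
        raise DataError(f"curve {label} has non-positive points; log transform undefined")
    logged = np.log(points)
    lo, hi = logged.min(axis=0), logged.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        raise DataError(f"curve {label} is degenerate along one axis (zero range)")
    return (logged - lo) / span


def similarity(
    a: Characterization,
    b: Characterization,
    joint_normalization: bool = False,
) -> SimilarityResult:
    """Shape similarity of two transfer functions.

    Each curve is log-transformed and min-max normalized to the unit
    square per curve and per axis (so absolute scale and log-offsets drop
    out and only shape remains), then compared by discrete Fréchet
    distance; similarity = 1 - distance. With ``joint_normalization`` both
    curves share one min-max frame, retaining relative position.
    """
    pa = np.asarray(a.points, dtype=float)
    pb = np.asarray(b.points, dtype=float)
    if joint_normalization:
        both = np.vstack([pa, pb])
        if np.any(both <= 0):
            raise DataError("curves have non-positive points; log transform undefined")
        logged = np.log(both)
        lo, hi = logged.min(axis=0), logged.max(axis=0)
        span = hi - lo
        if np.any(span == 0):
            raise DataError("curves are degenerate along one axis (zero range)")
        na = (np.log(pa) - lo) / span
        nb = (np.log(pb) - lo) / span
    else:
        na = _normalize_curve(pa, a.gate_context.label)
        nb = _normalize_curve(pb, b.gate_context.label)
    dist = discrete_frechet(na, nb)
    return SimilarityResult(
        curve_a=a.gate_context,
        curve_b=b.gate_context,
        frechet=dist,
        similarity=1.0 - dist,
    )


def similarity_matrix(chars: list[Characterization], **kwargs) -> pd.DataFrame:
    """Square table of pairwise similarities (e.g. one gate across contexts)."""
    labels = [c.gate_context.label for c in chars]
    mat = np.ones((len(chars), len(chars)))
    for i in range(len(chars)):
        for j in range(i + 1, len(chars)):
            s = similarity(chars[i], chars[j], **kwargs).similarity
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=labels, columns=labels)
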