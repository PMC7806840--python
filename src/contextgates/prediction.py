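"""Cross-context prediction by an optimal affine map in log-log space.

If context change acted uniformly on every gate, the characterization of a
single reference gate in a source and a target context would determine a
transformation carrying *any* gate's source curve onto its target curve.
The transformation space used here is the 2D affine maps (2x2 matrix plus
translation) acting on (log input, log output) points — pure translations
in log space correspond to fold-changes along either RPU axis — fitted by
minimizing the L1 loss between the transformed source curve and the true
target curve. The map found for the reference gate is then applied to the
other gates; large prediction errors on them reveal that the context
effect is gate-specific ("nonlinear"), which is exactly what heterogeneous
context perturbations produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .standardization import Characterization


@dataclass(frozen=True)
class AffineMap2D:
    """Affine transformation of log-log characterization points."""

    matrix: tuple[tuple[float, float], tuple[float, float]]
    translation: tuple[float, float]
    loss: float

    @property
    def A(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return points @ self.A.T + self.t


def _log_points(c: Characterization) -> np.ndarray:
    pts = np.asarray(c.points, dtype=float)
    if np.any(pts <= 0):
        raise ValueError(
            f"characterization {c.gate_context.label} has non-positive points; "
            "log-space mapping undefined"
        )
    return np.log(pts)


def _l1(params: np.ndarray, P: np.ndarray, Q: np.ndarray, with_translation: bool) -> float:
    A = params[:4].reshape(2, 2)
    t = params[4:6] if with_translation else np.zeros(2)
    return float(np.abs(P @ A.T + t - Q).sum())


def fit_affine(
    source: Characterization,
    target: Characterization,
    allow_translation: bool = True,
) -> AffineMap2D:
    """Optimal affine map from one gate's source-context curve to its target.

    Points are paired by index (the two characterizations must be sampled
    at the same inducer levels) and mapped to (log input, log output). The
    six affine parameters minimize the summed L1 deviation. Multi-start:
    identity, centroid-aligning translation, and the closed-form
    least-squares affine fit; the best L1 objective wins. With
    ``allow_translation=False`` only the 2x2 matrix is fitted.
    """
    if len(source) != len(target):
        raise ValueError("source and target must be sampled at the same levels (paired points)")
    if len(source) < 3:
        raise ValueError("affine fitting needs at least 3 points")
    P = _log_points(source)
    Q = _log_points(target)

    if np.allclose(P, P[0]):
        warnings.warn("degenerate source curve (all points identical); returning centroid translation")
        t = Q.mean(axis=0) - P.mean(axis=0)
        loss = float(np.abs(P + t - Q).sum())
        return AffineMap2D(
            matrix=((1.0, 0.0), (0.0, 1.0)),
            translation=(float(t[0]), float(t[1])),
            loss=loss,
        )

    starts = [np.concatenate([np.eye(2).ravel(), np.zeros(2)])]
    centroid = np.concatenate([np.eye(2).ravel(), Q.mean(axis=0) - P.mean(axis=0)])
    starts.append(centroid)
    # closed-form L2 affine fit as a warm start for the L1 objective
    X = np.column_stack([P, np.ones(len(P))])
    coef, *_ = np.linalg.lstsq(X, Q, rcond=None)
    starts.append(np.concatenate([coef[:2].T.ravel(), coef[2]]))

    best = None
    for x0 in starts:
        if not allow_translation:
            x0 = x0.copy()
            x0[4:] = 0.0
        res = minimize(
            _l1,
            x0=x0,
            args=(P, Q, allow_translation),
            method="Powell",
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    A = best.x[:4].reshape(2, 2)
    t = best.x[4:6] if allow_translation else np.zeros(2)
    return AffineMap2D(
        matrix=tuple(tuple(float(v) for v in row) for row in A),
        translation=(float(t[0]), float(t[1])),
        loss=float(best.fun),
    )


def predict(map: AffineMap2D, gate_source: Characterization) -> Characterization:
    """Apply a fitted context map to another gate's source characterization.

    The map acts in log space and the result is exponentiated back to RPU.
    If the transformed inputs come out unordered (a reflecting map), the
    points are re-sorted by input with a warning.
    """
    P = _log_points(gate_source)
    mapped = np.exp(map(P))
    order = np.argsort(mapped[:, 0])
    if not np.array_equal(order, np.arange(len(mapped))):
        warnings.warn("transformed inputs were re-sorted to restore input ordering")
        mapped = mapped[order]
    return Characterization(
        gate_context=gate_source.gate_context,
        inputs=tuple(mapped[:, 0]),
        outputs=tuple(mapped[:, 1]),
        iptg_levels=gate_source.iptg_levels,
    )


def prediction_error(predicted: Characterization, measured: Characterization) -> float:
    """Mean per-point L1 deviation between two curves, in log space.

    A constant log-offset delta applied to all outputs (inputs unchanged)
    yields an error of exactly delta.
    """
    if len(predicted) != len(measured):
        raise ValueError("predicted and measured curves must have paired points")
    dP = _log_points(predicted) - _log_points(measured)
    return float(np.abs(dP).sum(axis=1).mean())
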