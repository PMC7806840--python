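"""Repressive Hill model: fitting, evaluation, and operational thresholds.

A genetic inverter's transfer function is modelled by the 4-parameter
repressive Hill equation

    h(x) = ymin + (ymax - ymin) * k^n / (k^n + x^n)

with floor ``ymin``, ceiling ``ymax``, half-repression input ``k`` and
cooperativity ``n`` (all activities in RPU). Following common practice for
gate characterization, ``ymin`` and ``ymax`` are pinned to the minimum and
maximum of the corrected data and only (k, n) are fitted, by least squares
on logarithmic residuals (errors in fold-change, not absolute RPU).

Digital thresholds derive from the fit: a high output means above
OH = ymax/2 and a low output below OL = 2*ymin. The input thresholds IL
and IH are where the curve crosses OH and OL:

    IL = (k^n * ymax / (ymax - 2*ymin))^(1/n)      [h(IL) = OH]
    IH = (k^n * (ymax - 2*ymin) / ymin)^(1/n)      [h(IH) = OL]

A gate is *operational* iff OH > OL and IH > IL, which for ymin > 0 is
equivalent to a dynamic range ymax/ymin > 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import GateContext
from .errors import DataError
from .standardization import Characterization


@dataclass(frozen=True)
class HillFit:
    """Fitted parameters of one gate-context's repressive Hill response."""

    ymin: float
    ymax: float
    k: float
    n: float
    residual: float
    converged: bool

    def __post_init__(self) -> None:
        if not (self.ymax >= self.ymin >= 0):
            raise ValueError("require ymax >= ymin >= 0")
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Digital output/input thresholds of a fitted gate.

    IL and IH are ``None`` when the closed forms are undefined
    (ymax <= 2*ymin or ymin = 0), in which case the gate is
    non-operational.
    """

    OL: float
    OH: float
    IL: float | None
    IH: float | None
    operational: bool


def hill_eval(fit: HillFit, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted response at input ``x`` (RPU); h(0) = ymax."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("input RPU must be non-negative")
    kn = fit.k**fit.n
    out = fit.ymin + (fit.ymax - fit.ymin) * kn / (kn + x**fit.n)
    return float(out) if out.ndim == 0 else out


def _log_residuals(params: np.ndarray, x: np.ndarray, y: np.ndarray, ymin: float, ymax: float) -> np.ndarray:
    log_k, log_n = params
    # extreme optimizer excursions may overflow to inf; the resulting ratio
    # limits (0 or 1) are valid, so suppress the intermediate warnings
    with np.errstate(over="ignore", divide="ignore"):
        k, n = np.exp(log_k), np.exp(log_n)
        kn_over = 1.0 / (1.0 + (x / k) ** n)  # k^n/(k^n + x^n)
    h = ymin + (ymax - ymin) * kn_over
    return np.log(h) - np.log(y)


def fit_hill(
    c: Characterization,
    floor: float | None = None,
    n_k_starts: int = 8,
) -> HillFit:
    """Fit (k, n) of the repressive Hill model to one characterization.

    Outputs at or below zero (clipped during standardization) are replaced
    by a floor — ``max(1e-4, smallest positive output / 10)`` by default —
    so the logarithmic residuals are defined. The optimizer is multi-start:
    ``least_squares`` in (log k, log n) from a log-spaced grid of k across
    the input range crossed with n in {0.5, 1, 2, 4}; the best residual
    wins, deterministically. A perfectly flat response short-circuits to
    ymin = ymax (it will be flagged non-operational downstream).
    """
    x = np.asarray(c.inputs, dtype=float)
    y = np.asarray(c.outputs, dtype=float)
    if len(x) < 6:
        raise DataError("fitting requires at least 6 points")
    positive = y[y > 0]
    if positive.size == 0:
        raise DataError("all outputs are non-positive; nothing to fit on a log scale")
    if floor is None:
        floor = max(1e-4, positive.min() / 10.0)
    y = np.maximum(y, floor)
    ymin, ymax = float(y.min()), float(y.max())
    if ymax == ymin:
        return HillFit(ymin=ymin, ymax=ymax, k=float(np.exp(np.mean(np.log(x[x > 0])))) if np.any(x > 0) else 1.0,
                       n=1.0, residual=0.0, converged=True)

    x_pos = x[x > 0]
    k_grid = np.geomspace(x_pos.min(), x_pos.max(), n_k_starts)
    best = None
    for k0 in k_grid:
        for n0 in (0.5, 1.0, 2.0, 4.0):
            try:
                res = least_squares(
                    _log_residuals,
                    x0=[np.log(k0), np.log(n0)],
                    args=(x, y, ymin, ymax),
                    method="lm",
                    xtol=1e-12,
                    ftol=1e-12,
                )
            except Exception:
                continue
            cost = float(np.sum(res.fun**2))
            if best is None or cost < best[0] - 1e-15:
                best = (cost, res)
    if best is None:
        return HillFit(ymin=ymin, ymax=ymax, k=1.0, n=1.0, residual=float("inf"), converged=False)
    cost, res = best
    k, n = np.exp(res.x)
    return HillFit(
        ymin=ymin,
        ymax=ymax,
        k=float(k),
        n=float(n),
        residual=cost,
        converged=bool(res.success),
    )


def thresholds(fit: HillFit, require_converged: bool = True) -> Thresholds:
    """Derive OL/OH/IL/IH and the operational flag from a fit.

    The closed forms require ymax > 2*ymin and ymin > 0; otherwise IL/IH
    are undefined and the gate is non-operational. A non-converged fit is
    never operational when ``require_converged`` (the default): a gate the
    model fits poorly should not be used as a circuit part.
    """
    OL = 2.0 * fit.ymin
    OH = fit.ymax / 2.0
    if fit.ymin <= 0 or fit.ymax <= 2.0 * fit.ymin:
        return Thresholds(OL=OL, OH=OH, IL=None, IH=None, operational=False)
    kn = fit.k**fit.n
    IL = (kn * fit.ymax / (fit.ymax - 2.0 * fit.ymin)) ** (1.0 / fit.n)
    IH = (kn * (fit.ymax - 2.0 * fit.ymin) / fit.ymin) ** (1.0 / fit.n)
    operational = OH > OL and IH > IL and (fit.converged or not require_converged)
    return Thresholds(OL=OL, OH=OH, IL=float(IL), IH=float(IH), operational=operational)


def is_operational(t: Thresholds) -> bool:
    """True iff the gate separates its digital bands: OH > OL and IH > IL."""
    if t.IL is None or t.IH is None:
        return False
    return t.OH > t.OL and t.IH > t.IL


def fits_to_csv(
    records: list[tuple[GateContext, HillFit, Thresholds]],
    path: str | Path,
) -> Path:
    """Serialize fits and thresholds, one row per gate-context."""
    rows = []
    for gc, fit, t in records:
        rows.append(
            {
                "gate": gc.gate_name,
                "backbone": gc.backbone,
                "host": gc.host,
                "ymin": fit.ymin,
                "ymax": fit.ymax,
                "k": fit.k,
                "n": fit.n,
                "residual": fit.residual,
                "converged": fit.converged,
                "OL": t.OL,
                "OH": t.OH,
                "IL": t.IL,
                "IH": t.IH,
                "operational": t.operational,
            }
        )
    path = Path(path)
    pd.DataFrame.from_records(rows).to_csv(path, index=False)
    return path
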