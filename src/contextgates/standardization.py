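"""Relative Promoter Units (RPU) and transfer-function assembly.

Raw median fluorescence depends on instrument gain, reporter maturation
and context; dividing out two in-context controls removes this:

    RPU = (<YFP> - <YFP>_auto) / (<YFP>_standard - <YFP>_auto)

where ``<YFP>_auto`` is the median of an autofluorescence-only control and
``<YFP>_standard`` the median of a constitutive reference construct. By
construction the autofluorescence control reads 0 RPU and the standard
reads 1 RPU, and the quantity is invariant to affine rescaling of the
fluorescence axis (gain changes cancel).

A gate-context's *characterization* is then the ordered list of (input
RPU, output RPU) points measured across the inducer ladder, with input RPU
supplied by the sensor calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GateContext, repressor_family  # noqa: F401  (re-exported)
from .cytometry import SampleSummary
from .errors import DataError
from .synthetic_data import SensorMap

#: Minimum number of inducer levels for a usable characterization.
MIN_LEVELS = 6


def rpu(yfp: float, yfp_auto: float, yfp_std: float, clip_negative: bool = True) -> float:
    """Convert a median fluorescence to Relative Promoter Units.

    Raises :class:`DataError` if the standard does not exceed the
    autofluorescence control (an unusable standard). Negative results are
    clipped to 0 with a warning unless ``clip_negative=False``.
    """
    if yfp_std <= yfp_auto:
        raise DataError(
            f"standardization control ({yfp_std}) must exceed the autofluorescence "
            f"control ({yfp_auto}); standard is unusable"
        )
    value = (yfp - yfp_auto) / (yfp_std - yfp_auto)
    if value < 0 and clip_negative:
        warnings.warn(f"negative RPU {value:.4g} clipped to 0", stacklevel=2)
        return 0.0
    return value


@dataclass(frozen=True)
class Characterization:
    """Ordered (input RPU, output RPU) points of one transfer function."""

    gate_context: GateContext
    inputs: tuple[float, ...]
    outputs: tuple[float, ...]
    iptg_levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.outputs):
            raise ValueError("inputs and outputs must have equal length")
        if len(self.inputs) < 2:
            raise ValueError("a characterization needs at least 2 points")
        arr_in = np.asarray(self.inputs)
        arr_out = np.asarray(self.outputs)
        if not (np.all(np.isfinite(arr_in)) and np.all(np.isfinite(arr_out))):
            raise ValueError("RPU values must be finite")
        if np.any(np.diff(arr_in) <= 0):
            raise ValueError("input RPU values must be strictly increasing")
        if np.any(arr_out < 0):
            raise ValueError("output RPU values must be non-negative")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (input, output) pairs."""
        return np.column_stack([self.inputs, self.outputs])


def build_characterization(
    summaries: dict[float, SampleSummary],
    controls: tuple[SampleSummary, SampleSummary],
    sensor: SensorMap,
    gate_context: GateContext,
    clip_negative: bool = True,
) -> Characterization:
    """Assemble one gate-context's transfer function from sample medians.

    ``summaries`` maps each IPTG level (µM) to that sample's summary (a
    mapping, or an iterable of (iptg, summary) pairs); ``controls`` are the
    (autofluorescence, standard) summaries measured in the *same* context.
    At least six inducer levels are required for the curve to cover the
    response up to saturation.
    """
    pairs = list(summaries.items()) if hasattr(summaries, "items") else list(summaries)
    levels = [float(iptg) for iptg, _ in pairs]
    if len(set(levels)) != len(levels):
        raise DataError("duplicate IPTG levels in sample summaries")
    if len(levels) < MIN_LEVELS:
        raise DataError(
            f"characterization needs at least {MIN_LEVELS} inducer levels, got {len(levels)}"
        )
    auto, std = controls
    if auto is None or std is None:
        raise DataError(f"missing control sample for context of {gate_context.label}")
    rows = []
    for iptg, summary in pairs:
        x = sensor.input_at(iptg)
        y = rpu(
            summary.median_fluorescence,
            auto.median_fluorescence,
            std.median_fluorescence,
            clip_negative=clip_negative,
        )
        rows.append((x, y, float(iptg)))
    rows.sort(key=lambda r: r[0])
    return Characterization(
        gate_context=gate_context,
        inputs=tuple(r[0] for r in rows),
        outputs=tuple(r[1] for r in rows),
        iptg_levels=tuple(r[2] for r in rows),
    )


def characterizations_to_csv(chars: list[Characterization], path: str | Path) -> Path:
    """Long-form CSV: gate, backbone, host, iptg_uM, input_rpu, output_rpu."""
    records = []
    for c in chars:
        gc = c.gate_context
        iptg = c.iptg_levels or (float("nan"),) * len(c)
        for x, y, lvl in zip(c.inputs, c.outputs, iptg):
            records.append(
                {
                    "gate": gc.gate_name,
                    "backbone": gc.backbone,
                    "host": gc.host,
                    "iptg_uM": lvl,
                    "input_rpu": x,
                    "output_rpu": y,
                }
            )
    path = Path(path)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
    return path


def characterizations_from_csv(path: str | Path) -> list[Characterization]:
    df = pd.read_csv(path)
    chars = []
    for (gate, backbone, host), grp in df.groupby(["gate", "backbone", "host"], sort=True):
        grp = grp.sort_values("input_rpu")
        chars.append(
            Characterization(
                gate_context=GateContext(gate_name=gate, backbone=backbone, host=host),
                inputs=tuple(grp["input_rpu"]),
                outputs=tuple(grp["output_rpu"]),
                iptg_levels=tuple(grp["iptg_uM"]),
            )
        )
    return chars
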