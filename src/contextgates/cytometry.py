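"""Event-level cytometry processing: gating and per-sample medians.

The raw observable for every sample is a table of single-cell events with
forward scatter (FSC, a proxy for cell size), side scatter (SSC) and one
fluorescence channel (FL1, the YFP reporter). Because the median
fluorescence of a sample shifts with the cell-size distribution, samples
are compared at a common cell size: a density gate keeps the densest
scatter region, and the sample median is then taken over events whose
forward scatter falls in a narrow window around a pooled reference value
("size-conditioned median"). A plain median is available as a fallback by
passing an infinite window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

#: Default CSV column names for the three channels.
DEFAULT_CHANNELS = {"fsc": "FSC", "ssc": "SSC", "fluorescence": "FL1"}


@dataclass
class EventTable:
    """Per-event scatter and fluorescence values for one sample.

    Fluorescence may be negative (instrument baseline subtraction) but
    scatter values must be strictly positive.
    """

    fsc: np.ndarray
    ssc: np.ndarray
    fluorescence: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        n = len(self.fsc)
        if n < 1:
            raise DataError("event table must contain at least one event")
        if len(self.ssc) != n or len(self.fluorescence) != n:
            raise DataError("FSC, SSC and FL1 channels must have equal length")
        for name, chan in (("FSC", self.fsc), ("SSC", self.ssc), ("FL1", self.fluorescence)):
            if not np.all(np.isfinite(chan)):
                raise DataError(f"non-finite values in channel {name}")
        if np.any(self.fsc <= 0) or np.any(self.ssc <= 0):
            raise DataError("scatter channels must be strictly positive")

    def __len__(self) -> int:
        return len(self.fsc)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": np.arange(len(self)),
                "FSC": self.fsc,
                "SSC": self.ssc,
                "FL1": self.fluorescence,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        """Write events as CSV plus a JSON metadata sidecar (same stem)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.metadata, indent=1, sort_keys=True))
        return path


@dataclass(frozen=True)
class SampleSummary:
    """Median fluorescence of one sample after gating and size conditioning."""

    median_fluorescence: float
    n_events_used: int
    scatter_reference: float
    gating_coverage: float

    def __post_init__(self) -> None:
        if not (0 < self.gating_coverage <= 1):
            raise ValueError("gating_coverage must be in (0, 1]")


def read_events(
    path: str | Path,
    format: str = "csv",
    channels: dict | None = None,
) -> EventTable:
    """Read an event table from disk.

    ``channels`` maps the logical names ``fsc``/``ssc``/``fluorescence`` to
    column names in the file (defaults: FSC, SSC, FL1). A JSON sidecar next
    to the file, if present, supplies the sample metadata.
    """
    path = Path(path)
    if format == "fcs":
        raise FormatError(
            "FCS reading is not available in this build; export events as CSV "
            "(columns FSC, SSC, FL1) instead"
        )
    if format != "csv":
        raise ValueError(f"unknown event format {format!r}; expected 'csv'")
    if not path.exists():
        raise FormatError(f"no such event file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"event file {path} contains no events")
    chans = dict(DEFAULT_CHANNELS)
    chans.update(channels or {})
    for logical, column in chans.items():
        if column not in df.columns:
            raise FormatError(f"event file {path} is missing channel column {column!r} ({logical})")
    sidecar = path.with_suffix(".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EventTable(
        fsc=df[chans["fsc"]].to_numpy(),
        ssc=df[chans["ssc"]].to_numpy(),
        fluorescence=df[chans["fluorescence"]].to_numpy(),
        metadata=metadata,
    )


def scatter_gate(
    events: EventTable,
    coverage: float = 0.5,
    bins: int = 64,
    log_scale: bool = False,
) -> EventTable:
    """Density-gate events on the (FSC, SSC) plane.

    A 2D histogram (``bins`` x ``bins``) is built over the scatter plane and
    the densest bins are included greedily until at least a ``coverage``
    fraction of events is retained, mimicking an auto-gate drawn around the
    densest population. Ties between equally dense bins are broken by bin
    index, so the gate is deterministic. ``coverage=1`` keeps every event.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    if coverage == 1.0:
        return events
    x = np.log10(events.fsc) if log_scale else events.fsc
    y = np.log10(events.ssc) if log_scale else events.ssc
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, bins - 1)
    flat = counts.ravel()
    # stable sort on negated counts: densest first, ties by bin index
    order = np.argsort(-flat, kind="stable")
    needed = coverage * len(events)
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, needed - 1e-9)) + 1
    keep_bins = np.zeros(bins * bins, dtype=bool)
    keep_bins[order[:k]] = True
    mask = keep_bins[ix * bins + iy]
    return EventTable(
        fsc=events.fsc[mask],
        ssc=events.ssc[mask],
        fluorescence=events.fluorescence[mask],
        metadata=dict(events.metadata),
    )


def size_conditioned_median(
    events: EventTable,
    scatter_reference: float,
    window_halfwidth: float,
    min_events: int = 100,
) -> SampleSummary:
    """Median fluorescence of events near a reference cell size.

    Only events with forward scatter inside
    ``[reference - halfwidth, reference + halfwidth]`` contribute, which
    removes the dependence of the sample median on the sample's cell-size
    distribution. Pass ``window_halfwidth=math.inf`` for a plain median.
    """
    if window_halfwidth <= 0:
        raise ValueError("window_halfwidth must be positive")
    if math.isinf(window_halfwidth):
        mask = np.ones(len(events), dtype=bool)
    else:
        mask = np.abs(events.fsc - scatter_reference) <= window_halfwidth
    n_used = int(mask.sum())
    if n_used < max(1, min_events):
        raise DataError(
            f"only {n_used} events fall in the scatter window "
            f"[{scatter_reference - window_halfwidth:.3g}, "
            f"{scatter_reference + window_halfwidth:.3g}] "
            f"(minimum {min_events}); widen the window"
        )
    return SampleSummary(
        median_fluorescence=float(np.median(events.fluorescence[mask])),
        n_events_used=n_used,
        scatter_reference=float(scatter_reference),
        gating_coverage=n_used / len(events),
    )


def choose_scatter_reference(samples: list[EventTable], bins: int = 64) -> float:
    """Mode of the pooled forward-scatter distribution.

    All samples that will be compared against each other should share one
    reference so their size-conditioned medians are taken at the same cell
    size. Returns the center of the fullest histogram bin (first such bin
    on ties).
    """
    if not samples:
        raise DataError("cannot choose a scatter reference from an empty sample list")
    pooled = np.concatenate([s.fsc for s in samples])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(pooled, bins=bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))
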