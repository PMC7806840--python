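"""Synthetic gate libraries and cytometry-like event generation.

This module stands in for the study's flow-cytometry dataset: it draws a
library of genetic inverters with known (ground-truth) repressive Hill
parameters, perturbs them per context (backbone x host), and renders each
gate-context x inducer-level sample as a table of single-cell events with

* log-normal cell-to-cell variability on the construct signal,
* cell-size (forward scatter) correlated fluorescence,
* additive autofluorescence background,

plus the two control samples every context needs: an autofluorescence-only
plasmid and a constitutive reference standard whose activity defines
1 RPU. Because the truth is known, every downstream stage (gating, RPU
standardization, Hill fitting, thresholds, compatibility, depth, and
prediction) can be tested end to end without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import BACKBONES, HOSTS, GateContext
from .cytometry import EventTable

#: Inducer ladder (µM IPTG) used to sweep the input axis.
IPTG_LEVELS = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 70.0, 100.0, 150.0, 200.0, 500.0, 1000.0)

#: Repressor families of the inverter library (CELLO-derived part set).
FAMILIES = (
    "AmtR", "AmeR", "BM3R1", "BetI", "HlyIIR", "IcaRA",
    "LitR", "LmrA", "PhlF", "PsrA", "QacR", "SrpR",
)


@dataclass(frozen=True)
class GateTruth:
    """Generating parameters of one inverter's repressive Hill response.

    ``functional=False`` marks a gate-context that lost its NOT logic (e.g.
    a gate that tolerates only low copy number cloned into a high-copy
    backbone); such devices emit a flat response at ``ymin_true``.
    """

    gate_name: str
    repressor_family: str
    ymin_true: float
    ymax_true: float
    k_true: float
    n_true: float
    functional: bool = True

    def __post_init__(self) -> None:
        if not (self.ymax_true > self.ymin_true > 0):
            raise ValueError("require ymax_true > ymin_true > 0")
        if self.k_true <= 0 or self.n_true <= 0:
            raise ValueError("k_true and n_true must be positive")

    def response(self, x: float | np.ndarray) -> float | np.ndarray:
        """True output (RPU) at input ``x`` (RPU); flat when non-functional."""
        if not self.functional:
            return np.broadcast_to(self.ymin_true, np.shape(x)).astype(float) if np.ndim(x) else self.ymin_true
        x = np.asarray(x, dtype=float)
        kn = self.k_true**self.n_true
        out = self.ymin_true + (self.ymax_true - self.ymin_true) * kn / (kn + x**self.n_true)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ContextSpec:
    """Phenomenological effect of one backbone x host context.

    Context acts multiplicatively on the floor, ceiling and half-repression
    point of a gate's response and additively on its cooperativity; a
    non-``viable`` context flattens the gate entirely.
    """

    backbone: str
    host: str
    ymax_factor: float = 1.0
    ymin_factor: float = 1.0
    k_factor: float = 1.0
    n_shift: float = 0.0
    viable: bool = True

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.host not in HOSTS:
            raise ValueError(f"unknown host {self.host!r}")
        if min(self.ymax_factor, self.ymin_factor, self.k_factor) <= 0:
            raise ValueError("context factors must be positive")

    def apply(self, base: GateTruth) -> GateTruth:
        """Context-perturbed truth for ``base``; may come out non-functional."""
        ymin = base.ymin_true * self.ymin_factor
        ymax = base.ymax_true * self.ymax_factor
        n = base.n_true + self.n_shift
        functional = base.functional and self.viable and ymax > ymin and n > 0
        if not functional:
            # degenerate parameters are replaced by a flat-at-floor device
            ymax = max(ymax, ymin * 1.0001)
            n = max(n, 0.1)
        return replace(
            base,
            ymin_true=ymin,
            ymax_true=ymax,
            k_true=base.k_true * self.k_factor,
            n_true=n,
            functional=functional,
        )


@dataclass(frozen=True)
class SensorMap:
    """Input sensor calibration: IPTG concentration -> input promoter activity.

    The input promoter (pTac/LacI) converts the external inducer into an
    input RPU; characterizations are plotted in RPU-RPU space using this
    map for the x axis.
    """

    iptg_levels: tuple[float, ...]
    input_rpu: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.iptg_levels) != len(self.input_rpu):
            raise ValueError("iptg_levels and input_rpu must have the same length")
        rpu = np.asarray(self.input_rpu)
        if np.any(rpu < 0):
            raise ValueError("input RPU values must be non-negative")
        if np.any(np.diff(rpu) <= 0):
            raise ValueError("input_rpu must be strictly increasing with IPTG")

    def input_at(self, iptg: float) -> float:
        try:
            i = self.iptg_levels.index(float(iptg))
        except ValueError:
            raise ValueError(f"IPTG level {iptg} µM is not in the sensor map {self.iptg_levels}") from None
        return self.input_rpu[i]

    @classmethod
    def default(
        cls,
        iptg_levels: tuple[float, ...] = IPTG_LEVELS,
        basal: float = 0.003,
        saturating: float = 8.0,
        km: float = 60.0,
        hill: float = 1.7,
    ) -> "SensorMap":
        """Activating Hill response of the pTac sensor over the inducer ladder."""
        iptg = np.asarray(iptg_levels, dtype=float)
        rpu = basal + (saturating - basal) * iptg**hill / (km**hill + iptg**hill)
        return cls(tuple(iptg.tolist()), tuple(float(v) for v in rpu))


@dataclass(frozen=True)
class NoiseModel:
    """Event-level noise and instrument parameters.

    ``sigma_lognormal`` is the log-space SD of cell-to-cell variability on
    the construct signal (median-unbiased: the multiplier has median 1);
    ``size_coupling`` is the exponent linking *absolute* forward scatter to
    fluorescence (1 = proportional to cell size), so samples grown to a
    different cell-size distribution (``scatter_mean``) shift their raw
    medians — the artefact size-conditioning removes; ``gain`` converts
    RPU to fluorescence a.u. for a cell at ``size_reference`` scatter.
    """

    sigma_lognormal: float = 0.25
    autofluorescence_mean: float = 150.0
    scatter_mean: float = 5.0e4
    scatter_sigma: float = 0.35
    size_coupling: float = 1.0
    size_reference: float = 5.0e4
    gain: float = 2000.0

    def __post_init__(self) -> None:
        if self.sigma_lognormal < 0 or self.scatter_sigma < 0:
            raise ValueError("noise SDs must be non-negative")
        if min(self.gain, self.scatter_mean, self.size_reference) <= 0 or self.autofluorescence_mean < 0:
            raise ValueError("gain, scatter_mean and size_reference must be positive, autofluorescence non-negative")


#: Default 7-context panel: pAN is E. coli-only; broad-host-range pSEVA
#: vectors carry the gates into the second E. coli strain and P. putida.
def default_contexts(rng: np.random.Generator | None = None) -> list[ContextSpec]:
    """The seven study contexts, with randomized per-context perturbations.

    With ``rng=None`` the factors are all 1 (identity contexts).
    """
    pairs = [
        ("pAN", "EcDH5a"),
        ("pSEVA221", "EcDH5a"),
        ("pSEVA221", "EcCC118lpir"),
        ("pSEVA231", "EcCC118lpir"),
        ("pSEVA221", "PpKT2440"),
        ("pSEVA231", "PpKT2440"),
        ("pSEVA251", "PpKT2440"),
    ]
    specs = []
    for backbone, host in pairs:
        if rng is None:
            specs.append(ContextSpec(backbone=backbone, host=host))
        else:
            specs.append(
                ContextSpec(
                    backbone=backbone,
                    host=host,
                    ymax_factor=float(np.exp(rng.normal(0.0, 0.4))),
                    ymin_factor=float(np.exp(rng.normal(0.0, 0.3))),
                    k_factor=float(np.exp(rng.normal(0.0, 0.3))),
                    n_shift=float(rng.normal(0.0, 0.3)),
                )
            )
    return specs


@dataclass(frozen=True)
class LibraryEntry:
    """One gate-context device with its generating truth."""

    gate_context: GateContext
    truth: GateTruth


def _gate_names(n_gates: int) -> list[tuple[str, str]]:
    """(gate_name, family) pairs; >12 gates reuse families as variants."""
    names = []
    for i in range(n_gates):
        fam = FAMILIES[i % len(FAMILIES)]
        variant = i // len(FAMILIES) + 1
        names.append((f"{fam}-{fam[0]}{variant}", fam))
    return names


def make_library(
    n_gates: int,
    contexts: list[ContextSpec],
    seed: int,
    nonviable: list[tuple[str, str]] | None = None,
) -> list[LibraryEntry]:
    """Draw a gate library and instantiate it in every context.

    Base Hill parameters are drawn once per gate (seeded, deterministic)
    from ranges typical of characterized repressor gates: dynamic ranges of
    10-100x (so gates are operational and their output bands can nest
    inside other gates' input bands), half-repression points of 0.05-0.18
    RPU — well inside the sensor sweep, so the inducer ladder covers the
    response up to saturation as the measurement protocol requires — and
    cooperativities between 2.3 and 3.0. Each context's factors are then
    applied to every gate.

    ``nonviable`` lists (gate_name, backbone) combinations that fail to
    yield a functional device (e.g. gates not tolerated on a high-copy
    backbone); those entries are emitted flat and flagged non-functional.
    """
    if n_gates < 1:
        raise ValueError("n_gates must be at least 1")
    if not contexts:
        raise ValueError("at least one context is required")
    rng = np.random.default_rng(seed)
    nonviable = nonviable or []
    entries: list[LibraryEntry] = []
    for gate_name, fam in _gate_names(n_gates):
        ratio = float(np.exp(rng.uniform(np.log(10.0), np.log(100.0))))
        ymax = float(np.exp(rng.uniform(np.log(1.5), np.log(6.0))))
        base = GateTruth(
            gate_name=gate_name,
            repressor_family=fam,
            ymin_true=ymax / ratio,
            ymax_true=ymax,
            k_true=float(np.exp(rng.uniform(np.log(0.05), np.log(0.18)))),
            n_true=float(rng.uniform(2.3, 3.0)),
        )
        for ctx in contexts:
            truth = ctx.apply(base)
            if (gate_name, ctx.backbone) in nonviable:
                truth = replace(truth, functional=False)
            gc = GateContext(gate_name=gate_name, backbone=ctx.backbone, host=ctx.host)
            entries.append(LibraryEntry(gate_context=gc, truth=truth))
    return entries


def _draw_events(
    rng: np.random.Generator,
    signal_rpu: float,
    n_events: int,
    noise: NoiseModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FSC, SSC and FL1 arrays for a constant underlying signal (RPU)."""
    fsc = noise.scatter_mean * np.exp(noise.scatter_sigma * rng.standard_normal(n_events))
    ssc = 0.6 * fsc * np.exp(0.5 * noise.scatter_sigma * rng.standard_normal(n_events))
    size_factor = (fsc / noise.size_reference) ** noise.size_coupling
    construct = (
        noise.gain
        * size_factor
        * signal_rpu
        * np.exp(noise.sigma_lognormal * rng.standard_normal(n_events))
    )
    auto = noise.autofluorescence_mean * np.exp(
        noise.sigma_lognormal * rng.standard_normal(n_events)
    )
    return fsc, ssc, auto + construct


def simulate_events(
    truth: GateTruth,
    sensor: SensorMap,
    iptg: float,
    n_events: int,
    noise: NoiseModel,
    seed: int,
) -> EventTable:
    """Render one gate sample at one inducer level as an event table.

    The expected fluorescence of an event is
    ``autofluorescence + gain * (FSC/size_reference)^size_coupling * h(x)``
    where ``h`` is the gate's true response and ``x`` the sensor's input
    RPU at ``iptg``. With ``sigma_lognormal=0`` and ``size_coupling=0``
    every event takes exactly that value.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    x = sensor.input_at(iptg)
    rng = np.random.default_rng(seed)
    fsc, ssc, fl1 = _draw_events(rng, float(truth.response(x)), n_events, noise)
    return EventTable(
        fsc=fsc,
        ssc=ssc,
        fluorescence=fl1,
        metadata={
            "role": "gate",
            "gate": truth.gate_name,
            "iptg_uM": float(iptg),
        },
    )


def simulate_controls(
    context: ContextSpec,
    n_events: int,
    noise: NoiseModel,
    seed: int,
) -> tuple[EventTable, EventTable]:
    """Autofluorescence and reference-standard samples for one context.

    The autofluorescence sample carries no construct signal; the standard
    sample expresses the reporter constitutively at exactly 1 RPU, so after
    standardization the standard reads 1 and the autofluorescence control
    reads 0 by construction.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    rng = np.random.default_rng(seed)
    meta = {"backbone": context.backbone, "host": context.host, "iptg_uM": 0.0}
    fsc, ssc, fl1 = _draw_events(rng, 0.0, n_events, noise)
    auto = EventTable(fsc=fsc, ssc=ssc, fluorescence=fl1, metadata={**meta, "role": "auto"})
    fsc, ssc, fl1 = _draw_events(rng, 1.0, n_events, noise)
    std = EventTable(fsc=fsc, ssc=ssc, fluorescence=fl1, metadata={**meta, "role": "standard"})
    return auto, std
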