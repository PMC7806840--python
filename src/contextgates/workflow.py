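"""End-to-end orchestration: events -> medians -> RPU -> fits -> analyses.

A single :class:`RunConfig` carries every stage parameter (with defaults
matching the package's documented choices) and a seed; :func:`run_pipeline`
then either simulates a synthetic study or loads event CSVs from disk, and
produces characterizations, Hill fits and thresholds, the compatibility
table, per-gate cross-context similarity matrices, the chain-depth report
under a set of context policies, and the cross-context prediction report.
All randomness derives from the config seed, so a rerun with the same
config reproduces every number bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chains import depth_by_context_policy
from .compatibility import CompatibilityTable, compatibility_matrix, similarity_matrix
from .core import GateContext
from .cytometry import (
    EventTable,
    SampleSummary,
    choose_scatter_reference,
    read_events,
    scatter_gate,
    size_conditioned_median,
)
from .errors import DataError
from .hill import HillFit, Thresholds, fit_hill, fits_to_csv, thresholds
from .prediction import fit_affine, predict, prediction_error
from .standardization import Characterization, build_characterization, characterizations_to_csv
from .synthetic_data import (
    ContextSpec,
    NoiseModel,
    SensorMap,
    default_contexts,
    make_library,
    simulate_controls,
    simulate_events,
)

#: The paper-style three-panel policy set: one backbone in one host, any
#: backbone in that host, and every context in the library.
def three_panel_policies(backbone: str = "pSEVA221", host: str = "EcCC118lpir"):
    return [
        (f"{backbone}+{host}", lambda gc, b=backbone, h=host: gc.backbone == b and gc.host == h),
        (f"any-backbone+{host}", lambda gc, h=host: gc.host == h),
        ("all-contexts", None),
    ]


@dataclass
class RunConfig:
    """Every knob of the pipeline in one serializable object."""

    seed: int = 1
    # synthetic study design
    n_gates: int = 20
    randomize_contexts: bool = True
    nonviable: list[tuple[str, str]] = field(default_factory=list)
    n_events: int = 5000
    noise: NoiseModel = field(default_factory=NoiseModel)
    # input mode: directory of event CSVs (with JSON sidecars) instead of simulation
    events_dir: str | None = None
    # cytometry
    gating_coverage: float = 0.5
    use_size_conditioning: bool = True
    window_relative: float = 0.1  # scatter window halfwidth as a fraction of the reference
    min_window_events: int = 100
    # fitting / scoring
    fit_floor: float | None = None
    exclude_same_family: bool = True
    # policies and prediction
    policy_backbone: str = "pSEVA221"
    policy_host: str = "EcCC118lpir"
    prediction_source: tuple[str, str] = ("pSEVA221", "EcCC118lpir")  # (backbone, host)
    prediction_target: tuple[str, str] = ("pSEVA221", "EcDH5a")
    reference_gate: str | None = None  # None -> first operational gate alphabetically
    outdir: str | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["noise"] = NoiseModel(**d["noise"])
        d["nonviable"] = [tuple(x) for x in d["nonviable"]]
        d["prediction_source"] = tuple(d["prediction_source"])
        d["prediction_target"] = tuple(d["prediction_target"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Bundle of every stage output of one pipeline run."""

    characterizations: list[Characterization]
    fits: list[tuple[GateContext, HillFit, Thresholds]]
    compatibility: CompatibilityTable
    similarity: dict[str, pd.DataFrame]
    depth_report: list[dict]
    prediction_report: pd.DataFrame
    n_functional: int

    @property
    def n_compatible(self) -> int:
        return self.compatibility.n_compatible


def _summarize(
    events: EventTable,
    reference: float,
    config: RunConfig,
) -> SampleSummary:
    if config.use_size_conditioning:
        hw = max(config.window_relative * reference, 1e-9)
        min_events = min(config.min_window_events, len(events))
        # widen the window geometrically until it holds enough events; the
        # widest window degrades gracefully to the plain median
        while True:
            try:
                return size_conditioned_median(events, reference, hw, min_events=min_events)
            except DataError:
                hw *= 2.0
                if hw > reference + events.fsc.max():
                    return size_conditioned_median(events, reference, math.inf, min_events=1)
    return size_conditioned_median(events, reference, math.inf, min_events=1)


def _simulate_samples(config: RunConfig):
    """Yield (context, gate-context, truth, {iptg: gated events}, controls)."""
    contexts = default_contexts(
        np.random.default_rng(config.seed + 1) if config.randomize_contexts else None
    )
    library = make_library(config.n_gates, contexts, seed=config.seed, nonviable=config.nonviable)
    sensor = SensorMap.default()
    seed_rng = np.random.default_rng(config.seed + 2)
    by_context: dict[tuple[str, str], dict] = {}
    for ctx in contexts:
        key = (ctx.backbone, ctx.host)
        auto_ev, std_ev = simulate_controls(
            ctx, config.n_events, config.noise, seed=int(seed_rng.integers(2**31))
        )
        by_context[key] = {"ctx": ctx, "auto": auto_ev, "std": std_ev, "gates": {}}
    for entry in library:
        gc = entry.gate_context
        samples = {}
        for iptg in sensor.iptg_levels:
            samples[iptg] = simulate_events(
                entry.truth,
                sensor,
                iptg,
                config.n_events,
                config.noise,
                seed=int(seed_rng.integers(2**31)),
            )
        by_context[(gc.backbone, gc.host)]["gates"][gc] = samples
    n_functional = sum(e.truth.functional for e in library)
    return by_context, sensor, n_functional


def load_event_samples(events_dir: str | Path):
    """Read event CSVs (with JSON sidecars) into the pipeline's sample layout.

    Sidecar metadata must provide role (gate/auto/standard), backbone,
    host, and for gate samples the gate name and iptg_uM. Raises
    :class:`DataError` naming any context that lacks a control sample.
    """
    events_dir = Path(events_dir)
    by_context: dict[tuple[str, str], dict] = {}
    for path in sorted(events_dir.glob("*.csv")):
        table = read_events(path)
        meta = table.metadata
        key = (meta.get("backbone"), meta.get("host"))
        if key[0] is None or key[1] is None:
            raise DataError(f"event file {path} lacks backbone/host metadata")
        slot = by_context.setdefault(
            key, {"ctx": ContextSpec(backbone=key[0], host=key[1]), "auto": None, "std": None, "gates": {}}
        )
        role = meta.get("role", "gate")
        if role == "auto":
            slot["auto"] = table
        elif role == "standard":
            slot["std"] = table
        else:
            gc = GateContext(gate_name=meta["gate"], backbone=key[0], host=key[1])
            slot["gates"].setdefault(gc, {})[float(meta["iptg_uM"])] = table
    if not by_context:
        raise DataError(f"no event CSV files found in {events_dir}")
    for key, slot in by_context.items():
        for role in ("auto", "std"):
            if slot[role] is None:
                raise DataError(
                    f"context {key[0]}/{key[1]} lacks its "
                    f"{'autofluorescence' if role == 'auto' else 'standardization'} control"
                )
    return by_context


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the analysis bundle."""
    if config.events_dir is not None:
        by_context = load_event_samples(config.events_dir)
        sensor = SensorMap.default()
        n_functional = -1  # unknown for externally supplied data
    else:
        by_context, sensor, n_functional = _simulate_samples(config)

    characterizations: list[Characterization] = []
    for key in sorted(by_context):
        slot = by_context[key]
        gated = {
            "auto": scatter_gate(slot["auto"], config.gating_coverage),
            "std": scatter_gate(slot["std"], config.gating_coverage),
        }
        gated_gates = {
            gc: {iptg: scatter_gate(ev, config.gating_coverage) for iptg, ev in samples.items()}
            for gc, samples in slot["gates"].items()
        }
        pool = [gated["auto"], gated["std"]] + [
            ev for samples in gated_gates.values() for ev in samples.values()
        ]
        reference = choose_scatter_reference(pool)
        controls = (
            _summarize(gated["auto"], reference, config),
            _summarize(gated["std"], reference, config),
        )
        for gc in sorted(gated_gates):
            summaries = {
                iptg: _summarize(ev, reference, config) for iptg, ev in gated_gates[gc].items()
            }
            characterizations.append(
                build_characterization(summaries, controls, sensor, gc)
            )
        slot.clear()  # release event memory context by context

    fits = []
    for c in characterizations:
        f = fit_hill(c, floor=config.fit_floor)
        fits.append((c.gate_context, f, thresholds(f)))

    library = [(gc, t) for gc, _, t in fits]
    compat = compatibility_matrix(library, exclude_same_family=config.exclude_same_family)

    # shape similarity of each gate across its contexts (positive outputs only)
    sim: dict[str, pd.DataFrame] = {}
    floored = [
        Characterization(
            gate_context=c.gate_context,
            inputs=c.inputs,
            outputs=tuple(max(v, 1e-4) for v in c.outputs),
            iptg_levels=c.iptg_levels,
        )
        for c in characterizations
    ]
    by_gate: dict[str, list[Characterization]] = {}
    for c in floored:
        by_gate.setdefault(c.gate_context.gate_name, []).append(c)
    for gate, curves in sorted(by_gate.items()):
        if len(curves) < 2:
            continue
        try:
            sim[gate] = similarity_matrix(curves)
        except DataError:
            continue  # flat curves have a degenerate (zero-range) axis

    policies = three_panel_policies(config.policy_backbone, config.policy_host)
    try:
        depth_report = depth_by_context_policy(compat, policies, max_chains=1000)
    except DataError:
        depth_report = []

    prediction_report = _prediction_report(characterizations, fits, config)

    result = PipelineResult(
        characterizations=characterizations,
        fits=fits,
        compatibility=compat,
        similarity=sim,
        depth_report=depth_report,
        prediction_report=prediction_report,
        n_functional=n_functional,
    )
    if config.outdir is not None:
        _write_bundle(result, config)
    return result


def _prediction_report(
    characterizations: list[Characterization],
    fits: list[tuple[GateContext, HillFit, Thresholds]],
    config: RunConfig,
) -> pd.DataFrame:
    """Fit the reference-gate context map and score it on every other gate."""
    src_b, src_h = config.prediction_source
    tgt_b, tgt_h = config.prediction_target
    floored = {}
    for c in characterizations:
        gc = c.gate_context
        floored[(gc.gate_name, gc.backbone, gc.host)] = Characterization(
            gate_context=gc,
            inputs=c.inputs,
            outputs=tuple(max(v, 1e-4) for v in c.outputs),
            iptg_levels=c.iptg_levels,
        )
    operational = {gc.gate_name for gc, _, t in fits if t.operational}
    gates_in_both = sorted(
        {
            g
            for (g, b, h) in floored
            if b == src_b and h == src_h and (g, tgt_b, tgt_h) in floored
        }
    )
    if not gates_in_both:
        return pd.DataFrame(columns=["gate", "is_reference", "error"])
    reference = config.reference_gate
    if reference is None:
        candidates = [g for g in gates_in_both if g in operational] or gates_in_both
        reference = candidates[0]
    if reference not in gates_in_both:
        raise DataError(f"reference gate {reference} not characterized in both contexts")
    ctx_map = fit_affine(
        floored[(reference, src_b, src_h)], floored[(reference, tgt_b, tgt_h)]
    )
    rows = []
    for g in gates_in_both:
        predicted = predict(ctx_map, floored[(g, src_b, src_h)])
        err = prediction_error(predicted, floored[(g, tgt_b, tgt_h)])
        rows.append({"gate": g, "is_reference": g == reference, "error": err})
    return pd.DataFrame.from_records(rows)


def reproduce_counts(
    library: list[tuple[GateContext, Thresholds]],
    policies: list[tuple[str, object]],
    exclude_same_family: bool = True,
) -> pd.DataFrame:
    """Compatible-pair counts and max depth per context policy.

    The paper-style layout: one row per policy, counts non-decreasing as
    policies are relaxed by set inclusion.
    """
    rows = []
    for name, pred in policies:
        table = compatibility_matrix(
            library, context_filter=pred, exclude_same_family=exclude_same_family
        )
        if table.nodes:
            report = depth_by_context_policy(table, [(name, None)], max_chains=1)
            depth = report[0]["max_depth"]
        else:
            depth = 0
        rows.append(
            {
                "policy": name,
                "n_devices": len(table.nodes),
                "n_compatible_pairs": table.n_compatible,
                "max_depth": depth,
            }
        )
    return pd.DataFrame.from_records(rows)


def _write_bundle(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    written.append(characterizations_to_csv(result.characterizations, outdir / "characterizations.csv"))
    written.append(fits_to_csv(result.fits, outdir / "fits.csv"))
    p = outdir / "compatibility.csv"
    result.compatibility.to_dataframe().to_csv(p, index=False)
    written.append(p)
    for gate, df in result.similarity.items():
        p = outdir / f"similarity_{gate}.csv"
        df.to_csv(p)
        written.append(p)
    p = outdir / "depth_report.json"
    p.write_text(
        json.dumps(
            [
                {
                    **{k: v for k, v in row.items() if k != "chains"},
                    "chains": [[n.label for n in ch.nodes] for ch in row["chains"][:50]],
                }
                for row in result.depth_report
            ],
            indent=1,
        )
    )
    written.append(p)
    p = outdir / "prediction_report.csv"
    result.prediction_report.to_csv(p, index=False)
    written.append(p)
    manifest = {
        "config": json.loads(config.to_json()),
        "outputs": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in written
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
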