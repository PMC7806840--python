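# contextgates

Quantitative analysis of genetic NOT gates (inverters) across molecular
contexts: plasmid backbone × host strain. A genetic inverter — a repressor
plus its cognate promoter driving a fluorescent reporter — behaves
differently depending on the vector copy number and the cell that carries
it. This package treats each *gate-context* pairing as its own device and
provides the full pipeline from single-cell cytometry events to
circuit-level conclusions:

1. **Cytometry** — density gating on the scatter plane and
   *size-conditioned* medians (fluorescence medians taken at a common
   forward-scatter value, removing cell-size artefacts).
2. **Standardization** — Relative Promoter Units,
   `RPU = (⟨YFP⟩ − ⟨YFP⟩_auto) / (⟨YFP⟩_std − ⟨YFP⟩_auto)`,
   using in-context autofluorescence and constitutive-reference controls.
3. **Hill characterization** — the repressive Hill model
   `h(x) = ymin + (ymax − ymin)·kⁿ/(kⁿ + xⁿ)` fitted by least squares on
   logarithmic residuals with `ymin`/`ymax` pinned to the data extremes,
   and the digital thresholds
   `OL = 2·ymin`, `OH = ymax/2`,
   `IL = (kⁿ·ymax/(ymax − 2·ymin))^(1/n)`,
   `IH = (kⁿ·(ymax − 2·ymin)/ymin)^(1/n)`;
   a gate is *operational* iff `OH > OL` and `IH > IL` (equivalently
   `ymax > 4·ymin`).
4. **Compatibility** — ordered pairs A→B scored by
   `min(ln(IL_B/OL_A), ln(OH_A/IH_B))`; positive means A's output bands
   nest inside B's input bands. Shape similarity of two characterizations
   is `1 − d_F` where `d_F` is the discrete Fréchet distance between the
   log-transformed, per-axis min-max-normalized curves.
5. **Chains** — maximum layered-circuit depth: the longest path in the
   compatibility graph in which no repressor family repeats, computed
   exactly by dynamic programming over (node, used-family-set) states.
6. **Prediction** — cross-context portability probed by the optimal affine
   map (L1 loss, log-log space) between one reference gate's curves in two
   contexts, applied to the rest of the library.

A first-class **synthetic-data generator** emulates the study design — 20
inverters × 7 backbone/host contexts, a 13-level IPTG ladder, log-normal
cell-to-cell noise, cell-size-coupled fluorescence, autofluorescence and
reference-standard controls, and per-context Hill-parameter perturbations
(including non-functional flat gates) — so every stage is testable against
known ground truth without any external data.

## Worked example

```python
from contextgates import RunConfig, run_pipeline

result = run_pipeline(RunConfig(n_gates=8, n_events=2000, seed=42))
gc, fit, t = result.fits[0]
print(gc.label, fit, t)
```

prints (abridged):

```
device: EcDH5a(pAN::AmeR-A1)
fit: ymin=0.567 ymax=6.384 k=0.113 n=2.62 residual=0.00279
thresholds: OL=1.135 OH=3.192 IL=0.122 IH=0.264 operational=True
compatible pairs: 881
policy pSEVA221+EcCC118lpir: 8 devices, max depth 5
policy any-backbone+EcCC118lpir: 16 devices, max depth 6
policy all-contexts: 56 devices, max depth 6
```

Reading this: the AmeR inverter on the pAN backbone in *E. coli* DH5α has
an ~11-fold dynamic range (0.57→6.4 RPU), half-repression at 0.11 RPU
input, and is operational; 881 ordered device pairs in the 8-gate
synthetic library can be wired output→input, and the deepest layered chain
grows from 5 to 6 gates as the backbone and host restrictions are relaxed
— the central effect the analysis quantifies. The per-gate prediction
report in `result.prediction_report` shows the reference gate's context
map fitting itself well (error 0.04 in log-RPU) while transferring poorly
to other gates (errors 0.3–0.75): context effects are gate-specific.

The same stages are scriptable from the shell via the `contextgates` CLI
(`simulate`, `preprocess`, `fit`, `score`, `similarity`, `chains`,
`predict`, `reproduce`).

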