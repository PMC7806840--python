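# Methods

## The model

Each genetic inverter is summarized by the repressive Hill response

    h(x) = ymin + (ymax − ymin) · kⁿ / (kⁿ + xⁿ)

mapping input promoter activity x (RPU) to output promoter activity
(RPU): `ymax` is the unrepressed ceiling, `ymin` the fully repressed
floor, `k` the input at half repression and `n` the cooperativity. The
model assumes a monotone decreasing dose-response; devices that are not
inverters (flat or non-monotone responses) are fitted anyway but excluded
from downstream scoring by the operational criterion. A *gate-context*
(one insert × one backbone × one host) is the unit of analysis: the same
insert in two contexts is two devices with two fits.

## Standardization (RPU)

Median sample fluorescence is converted to Relative Promoter Units as
`(yfp − auto) / (std − auto)` with the autofluorescence-only and
constitutive-standard controls measured in the same context. Note that the
commonly printed one-line form of this equation omits the parenthesis
around the numerator; the subtraction of the autofluorescence median from
the sample median *before* division is the standard definition and is what
this package implements. RPU is invariant to affine rescaling of the
fluorescence axis, which is the point: instrument gain and day effects
cancel. Negative post-subtraction values are clipped to zero with a
warning by default (`clip_negative=False` retains them); log-residual
fitting then floors clipped outputs at `max(1e−4, smallest positive
output / 10)`.

## Cytometry

Events are density-gated on the (FSC, SSC) plane: a 64×64 2D histogram,
greedy inclusion of the densest bins until the requested coverage
(default 50%) is reached, ties broken by bin index for determinism.
Because median fluorescence tracks cell size, samples are compared at a
common size: the median is taken over events whose forward scatter lies
within a window (default ±10% of the reference) around the mode of the
pooled FSC histogram of all samples being compared. A plain median is the
`window_halfwidth=inf` degenerate case, and the pipeline widens the window
geometrically if it holds fewer than the minimum event count (default
100). Conditioning uses FSC; SSC conditioning and log-scale gating are
config options. No compensation, doublet discrimination or bead
calibration is attempted.

## Thresholds and compatibility

From a fit, `OL = 2·ymin`, `OH = ymax/2`, and IL/IH are the closed-form
inputs where the curve crosses OH and OL respectively (the curve is
decreasing, so the *low* input threshold corresponds to the *high* output
threshold). The forms require `ymax > 2·ymin` and `ymin > 0`; otherwise
IL/IH are undefined and the gate is non-operational. For `ymin > 0`,
`OH > OL ∧ IH > IL` is algebraically equivalent to `ymax > 4·ymin`; the
test suite verifies both the closed forms (against bracketed root finding)
and this equivalence on random parameter sweeps. Non-converged fits are
treated as non-operational by default (`require_converged=False` to
disable): a device the model describes poorly should not be wired into a
circuit.

The pair score `min(ln(IL_B/OL_A), ln(OH_A/IH_B))` is positive iff A's
output bands nest strictly inside B's input bands; score exactly 0
(coincident thresholds) is not compatible. The score is not a metric and
only its sign and ordering are meaningful. At the matrix level, pairs
sharing a repressor family are excluded from the compatible count by
default (a repressor cannot feed its own cognate promoter in a chain);
`exclude_same_family=False` reports the unexcluded count. Pairs are
ordered — (A,B) and (B,A) are distinct, since composition is directional.

## Similarity

Two characterizations are compared as shapes: log-transform both axes,
min-max normalize each curve's axes to [0,1] independently (per-curve, so
fold-changes and offsets drop out and only shape remains; a joint
normalization frame is available behind a flag), then similarity =
1 − discrete Fréchet distance. The Fréchet DP is the classic
coupling-minimax with Euclidean point metric, validated against exhaustive
enumeration of monotone couplings. Flat curves have a zero-range axis and
are rejected rather than silently normalized.

## Chains

The strictly-positive-score pairs form a directed graph; circuit depth is
the length in gates of the longest path in which no repressor family
repeats. With F families this bounds depth at F, and makes the search
tractable: `longest(v, S)` (deepest chain from node v with family set S
consumed) is memoized over (node, family-bitmask) states, exact for any
graph density, and all maximal chains are then enumerated by following
only DP-optimal edges (optionally capped). Depth counts gates, not
connections. Chains carry annotations for multicellular feasibility — the
number of host switches and the backbone multiset per host — but these are
reported, not used as search constraints.

## Prediction

Cross-context portability is probed with the most charitable linear
hypothesis: a full 2D affine map (2×2 matrix + translation, 6 parameters)
acting on (log input, log output) points, fitted on a single reference
gate by minimizing the summed L1 deviation between its transformed
source-context curve and its measured target-context curve, then applied
to every other gate. Pure axis translations in log space (fold-changes)
are a subspace of this family, and a matrix-only mode exists. The L1
objective is non-smooth, so the optimizer (Powell) is multi-started from
the identity, the centroid-aligning translation, and the closed-form
least-squares affine fit, with the best objective kept; loss is computed
in log-RPU (a linear-space option is a flag). Prediction error is the mean
per-point L1 deviation in log space. The designed behaviour pair: if every
gate feels the same affine context effect, the reference map transfers
with near-zero error; if effects are gate-specific, no single map can —
the heterogeneous fixture asserts the worst gate exceeds the reference
error by a configured margin (0.1 log-RPU).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: 20 inverters (12 repressor
families + 8 promoter variants) × 7 backbone-host contexts (pAN and
pSEVA221 in *E. coli* DH5α; pSEVA221/231 in *E. coli* CC118λpir;
pSEVA221/231/251 in *P. putida* KT2440), a 13-level IPTG ladder
(0–1000 µM), 30k-event-scale samples, and the two per-context controls.
Defaults, with rationale:

- **Gate parameters**: `ymax` 1.5–6 RPU, dynamic range 10–100×
  (`ymin = ymax/ratio`), `k` 0.05–0.18 RPU, `n` 2.3–3.0, drawn
  log-uniformly (linearly for n) per gate. These are the ranges of
  characterized repressor gate libraries; the dynamic-range and `k` ranges
  jointly ensure (i) most gates are operational, (ii) output bands can
  nest inside input bands so single-context compatibility is non-trivial,
  and (iii) the inducer ladder saturates both ends of every response —
  the measurement protocol's own requirement, and a precondition for the
  data-pinned `ymin`/`ymax` convention to be unbiased.
- **Sensor**: an activating Hill map from IPTG to input RPU (basal 0.003,
  saturating 8 RPU, Km 60 µM, cooperativity 1.7) evaluated at the 13
  ladder concentrations.
- **Noise**: multiplicative log-normal on the construct signal
  (σ = 0.25 default, median-unbiased) plus additive autofluorescence
  (mean 150 a.u. with the same log-normal jitter); forward scatter is
  log-normal (σ = 0.35) and fluorescence scales with absolute cell size
  as `(FSC/size_reference)^coupling` (coupling 1 by default), so samples
  grown to different sizes shift their raw medians — the artefact
  size-conditioning removes. Reporter gain is 2000 a.u./RPU at the
  reference size.
- **Context effects**: multiplicative factors on `ymin`, `ymax`, `k`
  (log-normal, σ 0.3–0.4) and an additive shift on `n` (σ 0.3) per
  context; non-viable gate-backbone combinations (e.g. five gates on the
  high-copy pSEVA251) emit a flat response at the floor, giving the
  140-device / 135-function layout.

Not emulated: growth, burden or resource-competition mechanisms (context
effects are phenomenological), instrument compensation, calibration-bead
drift, bimodal populations, or any distributional detail of the real
cytometry data beyond "roughly log-normal around a size-coupled median" —
the published analysis reports only medians, so the event-level noise
model is a stand-in, not a claim about the real data. Passing tests
demonstrate that the *pipeline* is correct and self-consistent under these
conditions, not that the real dataset would yield identical counts.

## Numerical choices

- Hill fitting: (k, n) optimized in log space by Levenberg–Marquardt
  least squares on log residuals, multi-started from an 8-point
  log-spaced k grid × n ∈ {0.5, 1, 2, 4}; best residual wins,
  deterministically. Perfectly flat data short-circuit to `ymin = ymax`.
  Optimizer failure on all starts returns `converged=False` rather than
  raising.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); a pipeline rerun with the same config is
  bit-identical, and the run manifest records every parameter and output
  hash.
- Ties in density gating and scatter-mode selection break by bin index;
  returned chains are ordered lexicographically by node index.
- Scale choices for the default runs: the shipped validation script uses
  5000 events per sample for the 20×7 study and 10,000 events for the
  noisy-recovery experiment — large enough that median-based statistics
  are stable, small enough to run comfortably on a laptop.

## Design notes and open points

- The input-sensor calibration must be supplied (the pTac map is not
  restated by the characterization itself); the generator's default map
  plays that role for synthetic runs.
- Whether the original analysis conditioned on FSC, SSC or both is not
  specified; FSC is used here, SSC via config.
- Whether negative post-subtraction RPUs were clipped or retained
  originally is unknown; clipping is the default, retention a flag.
- FCS files are not read directly; events enter as CSV (plus a JSON
  metadata sidecar). The deposited-dataset harness
  (`scripts/reproduce_figshare.py`) documents where an FCS-to-CSV
  conversion plugs in.
- With all 7 contexts the published analyses report a maximum depth of 11
  in one place and 12 in another; this package reports whatever the
  search computes for the data given to it — the repressor-family bound
  (≤ 12 for 12 families) is asserted, the exact value is not adjudicated.
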