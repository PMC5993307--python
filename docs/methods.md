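# Methods

## Model

The package treats the five co-varying elements of the hemoglobin signal
at one voxel — measured ΔD (deoxyHb) and ΔO (oxyHb), and dependent
ΔT = ΔD + ΔO, ΔE = ΔD − ΔO, ΔS (saturation) — as a single finite-state
system. Because resting-state signals oscillate about their temporal
means, each component reduces naturally to a binary above/below-mean
variable; the joint sign pattern is the state. Geometrically the five
zero lines pass through the origin of the (ΔD, ΔO) plane and carve it
into ten sectors, so only 10 of the 2⁵ = 32 conceivable sign patterns
are realizable. State labels 1–10 run counter-clockwise from the sector
[180°, 225°) (all concentrations below mean, saturation above); labels
j and j+5 are antipodal.

The dynamics are modeled as a semi-Markov network: a voxel stays in a
state for a variable dwell and then jumps to a different state. Only
direct transitions are counted; the dwell preceding each one is recorded,
giving a lag-resolved 10×10×N count accumulator and matching accumulators
of each component's change across the transition and of its value at the
pre- and post-transition frames. All estimators (P, τ, k, φ, m, k·φ,
k·m, pre/post amplitudes, V = k/P, asymmetries) are deterministic ratios
of accumulator sums; formulas are in the module docstrings and README.

### Assumptions

- Samples are deviations from the per-voxel temporal mean. Linear
  detrending (the only preprocessing applied, on by default) enforces
  this while removing instrumental drift; it is a projection, hence
  idempotent.
- The state definition ignores amplitude (distance from the origin) and
  history beyond the current state; amplitudes enter only through the
  flux-type coefficients.
- Maps are averaged over voxels and time: coefficients characterize the
  whole tissue volume, not localized events.
- First-order kinetics are a *finding to be checked*, not an assumption:
  the occupancy relation V = K·diag(PᵀΤ) holds exactly for a semi-Markov
  process whose observed transitions and dwells are counted from the same
  series (up to edge effects from uncounted final runs), and its
  discrepancy on real data measures departure from first-order behavior.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| S₀ | % | 85 | typical mean tissue saturation; sets the ΔS line at tan⁻¹(85/15) ≈ 80.0° |
| T₀ | mol/L | 1e-4 | baseline total Hb; scales ΔS amplitude only, never state assignment |
| sampling rate | Hz | 1.8 | frame clock used to convert frame⁻¹ rates to s⁻¹ |
| max stored lag N | frames | 60 | ample for dwell spectra at this frame rate; the accumulator grows automatically if a longer dwell occurs, so no transition is ever dropped |
| saturation mode | — | linearized | the first-order form (100/T₀)(ΔO − (S₀/100)ΔT) is the form whose zero set is the straight demarcation line; the exact ratio form is available by flag for amplitude studies |

## Numerical and design choices

- **Boundary convention.** Sector membership bins θ = atan2(ΔO, ΔD) into
  half-open arcs [lower, upper) anchored at the five boundary angles.
  This is deterministic and total: a sample exactly on a line joins the
  sector counter-clockwise of it, and exactly one of ten states results.
  Real-valued data hit boundaries with probability zero, so the choice is
  inconsequential for measured series but keeps synthetic edge cases
  well-defined. The origin (0, 0) has no direction and maps to the
  sentinel 0, excluded from all counting.
- **Degenerate S₀ = 50.** At exactly S₀ = 50 the ΔS line coincides with
  the ΔE line (ΔS ∝ −ΔE) and only 8 sign patterns are realizable. The
  geometry is implemented as-is; the realizability sweep reports 8 there
  and 10 at every non-degenerate S₀.
- **Undefined labels.** A run of label 0 severs the scan: no transition
  is recorded into, out of, or across it. Runs reaching the end of a
  series are likewise never counted (their successor is unobserved).
- **Missing cells.** Transition types never observed yield NaN (not 0)
  for τ, k, φ and derived maps — 1/τ is undefined and zero-imputation
  would bias group means. P uses 0 for unobserved cells, which is its
  correct probability estimate. Similarity indices, regressions and
  group averages exclude NaN cells pairwise.
- **nRMSD** includes the square root, as the name implies:
  √(Σ(α−β)² / [(Σα²+Σβ²)/2]), ranging 0 (equality) to 2 (negation).
- **t-score contrast** uses the (n−1)-denominator SD over the three
  unaffected-breast pairings — the small-sample convention.
- **Student (pooled) t-tests**, not Welch, for the group-difference maps;
  two-sided p-values; cells analyzed independently with no
  multiple-testing correction.
- **AUC** uses the rank-sum identity with midrank ties, cancer as the
  positive class; maps store the raw oriented value, with a fold option
  (max(AUC, 100−AUC)) for reports where only discriminability matters.
- **Mass-action regression.** Within one accumulator the identity
  post − pre = φ holds exactly cell-wise, so regressing φ on its own
  accumulator's amplitude difference returns slope 1 identically.
  Slopes below 1 can only arise when flux and amplitude maps are averaged
  across subjects or groups before fitting — cross-subject averaging of
  ratios breaks the identity. The regression therefore takes its three
  inputs independently and makes no attempt to reproduce any particular
  group-level slope.
- **Z metric.** Right-tumor subjects are corrected with the non-cancer
  reference means before differencing, so that the tumor-bearing side
  plays the same role as a left tumor; with a symmetric reference the
  correction collapses to the plain relative difference. Zero
  denominators yield NaN cells.

## The synthetic generator

`SimulationConfig` emulates the study conditions: ~7.5 minutes of
resting-state data at 1.8 Hz (810 frames) per breast, micromolar
amplitude scale (radius 2 µM, SD 0.5 µM), S₀ = 85 %. Its embedded jump
chain favors transitions between circularly nearby states (exponential
decay with distance, scale 1.5 states), echoing the banded structure of
observed probability maps; per-(f, i) mean dwells span 1.05–1.6 frames in
a fixed deterministic pattern, chosen so that recovered rate constants
span the ~1.2–1.75 s⁻¹ range reported for breast tissue and every cell
has a distinct recoverable value. Dwells are geometric — the
discrete-time analogue of first-order kinetics — so the occupancy model
holds by construction and parameter recovery has closed-form Monte-Carlo
error bars. Amplitudes are drawn uniformly in direction within each
label's sector, inset by a 1 % margin of sector width so that state
assignment round-trips exactly despite float rounding, with
positive-truncated normal radii. Disease is a pair of multipliers on the
tumor side: dwell < 1 (elevated rate constants, the elevated-metabolism
phenotype) and amplitude > 1 (angiogenesis). Cohorts default to the
2:1 left:right tumor laterality mix of the motivating study design.
Randomness flows from one seed through `SeedSequence` spawn keys per
subject/breast/voxel, so outputs are bit-reproducible and independent of
execution order.

What the generator does **not** emulate: spatial correlation between
voxels, tomographic blurring, physiological oscillations (cardiac,
respiratory, vasomotion), history-dependent dwells, amplitude–state
coupling beyond the sector constraint, or inter-subject variability
beyond sampling noise. Passing tests therefore demonstrate correctness of
the estimators and the internal consistency of the methodology on
first-order data — not that real breast tissue is first-order, which is
an empirical claim the pipeline is designed to *measure* via the
occupancy-model discrepancy.

## Problem sizes used in the checks

The automated checks run at sizes where Monte-Carlo error is small but
desk-scale: parameter recovery at 200 voxels × 2,000 frames (~3×10⁵
transitions; 3-SE bands per cell), the first-order occupancy check at 50
voxels × 10⁵ frames, counting-oracle equivalence on 1,000 random
sequences, t-test size on 10⁴ null draws, and cohort diagnostics at
9–18 cancer / 8–45 non-cancer subjects with 8–12 voxels × 300–400 frames
per breast.

## Known limitations

- Clinical tomography data are not distributed with the package; all
  shipped analyses run on the synthetic generator.
- The occupancy model check on a single series uses P and τ estimated
  from that same series, so it validates internal consistency and the
  counting algebra; an external test of first-order behavior needs
  independent replicates.
- Cells never visited in short series propagate NaN into derived maps;
  group averaging skips them, which slightly reweights small cohorts.
- The exact (non-linearized) saturation mode curves the ΔS zero set, so
  its sign can disagree with the sector label very far from the origin;
  the linearized mode is authoritative for state assignment.
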