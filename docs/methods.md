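# Methods

## Scope and model

`seroscreen` analyses case/control seroreactivity measured two ways: a
discovery arm on dual-channel proteome microarrays (IgG and IgM read from
separate fluorescence channels of the same array) and a validation arm on
indirect ELISA plates. The statistical object in both arms is the same: a
per-marker score whose distribution in cases is a *responder mixture* —
only a fraction of patients seroconvert against any given antigen — so the
screen is built around positive-call rates at a specificity-constrained
cutoff rather than around mean shifts alone.

## Microarray preprocessing

1. **Spot SNR.** Each spot contributes SNR = F/B, the ratio of foreground
   to local background intensity (dimensionless, > 0). Spots with B ≤ 0
   are dropped individually with a warning; a protein missing all usable
   replicates on an array is reported missing, and proteins missing from
   any array are dropped so downstream matrices have no holes.
2. **Duplicate collapsing.** The arithmetic mean of the (normally two)
   replicate-spot SNRs is the protein's SNR on that array. Collapsing is
   order-invariant and tolerates non-standard replicate counts.
3. **Median scaling.** Each array (column) is multiplied by a constant so
   its median equals the grand median of the raw matrix. The grand median
   as the target keeps the output on the raw SNR scale and treats arrays
   symmetrically; the operation preserves within-array ranks and ratios
   and is exactly idempotent (all columns have equal length, so the pooled
   median of median-equalized columns is that shared median). Each isotype
   is normalized separately — the two channels have different dynamic
   ranges. Implemented as a scikit-learn transformer (`MedianScaler`).
4. **Negativity filter.** A protein is excluded from an isotype's screen
   when its SNR is ≤ 4 (IgG) or ≤ 5 (IgM) — inclusive — in *every* sample
   of both groups. The thresholds are stated on the raw SNR scale, so the
   filter is applied before normalization by default (`negativity_on`
   switches this). The filter is applied per isotype; a `joint` mode
   (exclude only when both isotype conditions hold) is available because
   the prose rule admits either reading.

## Screening statistics

For each retained protein × isotype, computed on normalized SNRs:

- **Cutoff.** Candidate cutoffs are the midpoints between adjacent
  distinct pooled values plus one point above the maximum (which satisfies
  any specificity constraint vacuously, so a cutoff always exists). Among
  candidates with specificity ≥ 0.90, the one maximizing Youden's
  J = sensitivity + specificity − 1 is returned; ties go to the higher
  (more specific) cutoff, consistent with the specificity-first design.
  "Discriminant ability" could equally be operationalized as accuracy;
  both are implemented (`cutoff_objective`), J is the default.
- **Direction-symmetric cutoffs.** A cutoff with ≥ 90 % specificity
  against HC caps the HC positive ratio at 10 %, which makes the Down
  criterion "HC positive ratio > 30 %" unsatisfiable at that cutoff. A
  marker elevated in controls is simply the mirror problem, so the Down
  criteria are evaluated at a cutoff whose specificity reference is RC.
  Each reported marker carries the cutoff of the direction it was
  evaluated under; group exchange therefore maps Up ↔ Down exactly.
- **Positive ratio** = fraction of a group strictly above the cutoff;
  **fold change** = mean(RC)/mean(HC); **p** from a two-sided t-test.
  Welch's unequal-variance flavor is the default — seroreactive
  distributions are variance-heterogeneous almost by construction
  (responder mixtures) — with Student's pooled test available
  (`t_test`). Zero variance in both groups with equal means returns p = 1
  by convention.
- **Labels.** Up iff RC ratio > 0.30, HC ratio < 0.10, FC ≥ 1.5, p < 0.05;
  Down iff HC ratio > 0.30, RC ratio < 0.10, FC < 2/3, p < 0.05.
  Comparison operators follow the stated criteria exactly (strict ratios
  and p, inclusive FC ≥ 1.5). Everything else is Unchanged, sub-flagged
  `ratio_consistent_fc_or_p_fail` when a direction's ratio pattern held
  but FC or p did not. Markers with undefined FC (zero control mean,
  impossible for valid SNRs but possible for arbitrary scores) are
  excluded from Up/Down. No multiple-testing correction enters the
  labels; an informational Benjamini–Hochberg q column is emitted.

## Random-forest ranking

Up markers are ranked by a bagged classification forest: 500 trees
(default), bootstrap rows, mtry = ⌊√p⌋ features per split — conventional
defaults, since no study-specific values exist. Importances follow the
classic definitions: MDA is the mean over trees of the out-of-bag accuracy
drop after permuting one feature within the OOB rows, *unscaled* (not
divided by its SE); MDG is the per-tree total Gini impurity decrease from
splits on the feature, averaged over trees (non-negative by construction).
The forest bookkeeping (bootstraps, OOB sets, batched permutation
predictions, aggregation) is implemented here over scikit-learn's CART
learner; a single integer seed makes the output bit-identical. Feature
subsampling is positional (the tree backend's `max_features`), so
importance tables are guaranteed reproducible for a fixed column order,
not invariant to column permutation.

## ELISA arm

Plate SNR = (mean positive-control OD − mean negative-control OD)/mean
negative-control OD; plates with SNR < 1 (configurable) fail QC and their
samples are reported missing. The per-sample score applies the same
control-relative normalization, (OD − mean neg)/mean neg: the study design
defines only the plate-level control statistic, and this choice extends
its intent to samples, removes plate offsets, and is invariant to
proportional plate rescaling (raw ODs are available via `raw=True`). AUC
is the concordant-pair probability with half-credit ties, computed via
midranks; cutoffs reuse the screening rule. Panels combine marker scores
by an in-sample logistic fit (linear predictor as panel score; the
reported AUC is therefore optimistic, and the report says so) with an
OR-rule alternative — positive iff any marker exceeds its own cutoff;
perfect separation in the logistic fit falls back to the OR rule with a
warning. A single-marker panel passes the score through unchanged.

## Synthetic cohorts

Defaults mirror the emulated study regime: 32 arrays (16 RC / 16 HC),
19,500 proteins × 2 duplicates × 2 channels; ELISA 72 RC / 66 HC on
96-well plates with 3 positive and 3 negative control wells.

Per protein and isotype, baseline log-SNR ~ Normal(0.3, 0.4) across
proteins with within-protein between-sample SD 0.3 — chosen so that the
bulk of proteins fall below the negativity thresholds in all 32 samples,
as on real arrays where most of the proteome is seronegative, while a
reactive tail survives the filter. Planted markers sit at a reactive
baseline (log-SNR 1.1): an antigen that elicits a measurable response is
by definition above the detection floor. Responders (a Bernoulli fraction
`prevalence` of the reactive group — RC for Up markers, HC for Down
markers) are shifted by `effect_size` × 0.3 in log-SNR. Arrays carry
multiplicative LogNormal(0, 0.15) scale factors that deliberately stress
the median normalization (set the SD to 0 to disable); duplicate spots
multiply in LogNormal(0, 0.1) noise; backgrounds are LogNormal around 200
intensity units and F = SNR·B. Histone H3/H4 spots are emitted as
high-signal positive controls, BSA/biotinylated BSA as negative controls.
ELISA sample ODs are baseline 0.2 + effect (RC responders only) +
Normal(0, 0.05) read noise, with groups interleaved across plates so no
plate is group-confounded, as a designed validation run would randomize.

What the generator does *not* emulate: spatial/print-tip artifacts,
scanner saturation, flagged spots, cross-reactivity structure between
related antigens, batch effects beyond a scalar per-array factor, and
plate edge effects. Passing recovery tests therefore demonstrates that the
statistics behave as specified under the assumed data regime, not that the
pipeline is robust to every failure mode of real arrays.

`generate_marker_stats_table` additionally builds a synthetic per-marker
statistics table (cutoff, positive rates, FC, p) with a requested class
composition, used to exercise the count-check path when no published
per-marker table is distributed with the package.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down cohorts — 120–300 proteins
per array rather than 19,500 — which leaves every statistical mechanism
(negativity filtering, cutoff search, classification, recovery scoring)
identical while keeping the suite fast; the per-protein computations are
independent, so protein count affects only multiplicity. Recovery is
measured over 20 seeded replicates at the planted regime of a 3 SD
log-SNR effect and 0.6 prevalence; at substantially weaker/rarer effects
(≈ 1.5 SD, 40 % prevalence) the expected responder count sits at the
30 %-ratio boundary and the positive-ratio criterion itself caps
attainable sensitivity — a property of the screening definition, not of
the implementation (see the monotonicity test).

Normalization equality is asserted to 1e-9 relative (measured ≈ 1e-16);
Welch p-values agree with an independent implementation to 1e-6 relative
(measured ≈ 1e-15). Cutoff ties break toward the higher cutoff;
positive calls are strictly greater-than throughout, so values exactly at
a cutoff are negative calls. All RNG flows through
`numpy.random.default_rng` seeded from a single integer per run.

## Known limitations

- Which specific antigens are markers cannot be re-derived without the
  original arrays; the package reproduces the *method*, and its validation
  is oracle- and recovery-based.
- The logistic panel score is fit and evaluated in-sample; treat panel
  AUCs as upper estimates.
- The GPR dialect reader covers tab-separated tables with a one-line
  header and configurable per-wavelength F/B columns, not full ATF
  headers or morphology flags; all spots are used (no flag handling).
- MDA's permutation test is the classic per-tree OOB procedure; with very
  few OOB samples per tree (tiny cohorts) individual-tree accuracies are
  coarse, which is why rank stability, not raw MDA magnitude, is the
  tested guarantee.
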