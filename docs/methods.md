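# Methods

## Statistical model

### Moderated t-test against a spatial reference

Protein abundances are modelled on the log2 scale. For a two-group
contrast (e.g. Cav1-NT vs NES-NT) with group sizes n₁, n₂ and pooled
residual variance s²_g on d_g = n₁ + n₂ − 2 degrees of freedom, the
per-protein variance is assumed exchangeable across proteins: σ²_g
follows a scaled inverse-χ² prior with hyperparameters (d₀, s₀²). The
posterior variance `s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` replaces
s²_g in the t-statistic, which then carries d₀ + d_g degrees of
freedom. This is the standard empirical-Bayes moderation used for
small-n proteomics designs (here n = 3 per group).

The hyperparameters are estimated by moment matching on
z_g = log s²_g, whose marginal under the model is a location-shifted
log-F: `E[z] = log s₀² + ψ(d_g/2) − log(d_g/2) − ψ(d₀/2) + log(d₀/2)`
and `Var[z] = ψ′(d_g/2) + ψ′(d₀/2)`, with ψ, ψ′ the digamma and
trigamma functions. The trigamma equation is inverted by Newton
iteration. When the observed spread of log-variances does not exceed
the χ² sampling spread the excess is non-positive and d₀ is infinite;
it is reported capped at 10⁶ and the posterior variance pins to s₀².
The implementation is cross-checked against Bioconductor limma
(`fitFDist`/`eBayes`) on a shared matrix in the test suite, agreeing
to 4+ significant digits.

Design choices, and why:

- **Per-contrast two-group tests rather than one four-group linear
  model.** Group-specific missingness (a protein fully absent under
  HYPO, say) then invalidates only the affected contrast instead of
  the whole protein row. The prior for the condition-vs-NES family is
  fit once on the pooled contrast variances so all three contrasts
  shrink toward the same prior.
- **Two-sided p combined with a one-directional logFC > 0 filter**
  (strict inequalities), the volcano-plot convention for "enriched".
- **Proteins with < 2 present values in either group are flagged
  `testable = False`** and excluded from calls rather than given
  p = 0. With the optional imputation enabled they become testable;
  both modes are reported, never mixed silently.

### Missing values

A raw intensity of 0 in the MaxQuant dialect means "not identified"
and is mapped to missing at read time; the replicate-presence rule
("identified in three out of three replicates of at least one
sample") is therefore a presence rule, evaluated per (bait, condition)
group — the only reading consistent with a triplicate design.
Imputation, when requested, is the Perseus-style per-sample
down-shifted normal: missing values in column *s* are drawn from
`N(μ_s − 1.8·σ_s, (0.3·σ_s)²)` over the observed values of that
column. It is **off by default**: the enrichment calls should not
depend on imputed numbers unless the analyst opts in, since the
original processing pipeline does not document an imputation step.

### Classification and z-profiles

Enrichment calls for NT, HYPO, REC form 2³ membership patterns, kept
as a full partition (eight raw categories) so any coarser reading —
"HYPO-exclusive", "co-recovered = NT∩REC ∪ NT∩HYPO∩REC" — can be
reconstructed without re-testing. Z-score profiles are computed per
protein row over the Cav1 samples (or condition means), sample sd with
ddof = 1; rows with fewer than two distinct present values are
undefined and emitted as NA.

### Over-representation

The hypergeometric upper tail `P(X ≥ k)` for overlap k between a query
and a gene set, both intersected with a stated universe, BH-adjusted
across sets. The default universe is the detected proteome (all
proteins surviving the presence filter), not the genome: conditioning
on detectability avoids the abundance bias of whole-genome
backgrounds. Accession matching is case-insensitive and exact; fuzzy
ID mapping is deliberately out of scope.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; they emulate the structure of the real data, not its exact
parameters (the deposited dataset does not state within-replicate
variance or detection limits).

**LFQ matrices.** Four groups (Cav1-NT/HYPO/REC, NES-NT) × 3
replicates. Per protein: baseline log2 intensity ~ N(27, 2²) (a
typical MaxQuant LFQ scale), plus a class effect per condition, plus
N(0, 0.5²) replicate noise. Planted classes and their log2 enrichments
over NES: `core_caveolar` (NT 3, HYPO 0, REC 3 — the caveolar-coat
pattern: enriched at rest and after recovery, lost under shock),
`nt_rec_specific` (2, 0, 2), `hypo_specific` (0, 2, 0),
`hypo_rec_specific` (0, 2, 2), `background` (all 0). Class fractions
(2/2/5/1/90 %) roughly mirror the reported interactome proportions.
Missingness is MNAR by left-censoring at a log2 detection limit of 24
(≈ 1.3 % of values at these settings); an optional MCAR dropout rate
exists for robustness tests. What this does **not** emulate: shared
peptide evidence between proteins, intensity-dependent variance,
batch effects, or correlated contaminant structure — a pass here
shows the statistics and set logic are correct, not that real data
will be as well behaved.

**Polarized cells.** Elliptical masks; intensity steps at the minor
axis so the rear-half mean is exactly `rear_fold` times the front-half
mean before noise (a linear ramp variant exists for profile tests).
Default geometry centres the ellipse on half-integer pixel
coordinates so the two halves have exactly equal pixel counts and the
planted fold is recovered exactly in the noise-free case. Noise:
Poisson (shot-noise-like) or additive Gaussian.

**PLA images.** Isotropic Gaussian dots (radius 2 px, amplitude 200
on background 10) at centres drawn by rejection sampling inside the
mask with a pairwise minimum separation, capped at 10,000 attempts;
centres are kept one dot-footprint clear of the mask edge.

**Migration tracks.** 2-D persistent random walk: the velocity is a
stationary Ornstein–Uhlenbeck process with RMS speed S (default
0.4 µm/min, the observed translocation rate of migrating RPE1 cells)
and persistence time P (default 10 min, a plausible scale for
epithelial cells; the source study does not report one). Velocity and
frame displacement are sampled from their **exact joint Gaussian**
(integrated-OU) transition, so the ensemble MSD matches the Fürth
form at the sampled lags with no time-discretisation bias; the
near-ballistic regime (dt ≪ P) uses a series expansion of the
displacement variance to avoid catastrophic cancellation. Default
sampling: 5-min frames, 61 frames (5 h), matching typical time-lapse
settings.

## Imaging quantification

- Polarity axis: principal axis of the mask's second moments; the
  rear pole is the brighter half's pole unless a manual rear hint is
  given. Masks with axis ratio < 1.05 are rejected as ambiguous
  without a hint.
- Equal-size rear/front regions: mask pixels ranked by axis
  coordinate; the extreme ⌊N/2⌋ pixels at each end form the regions,
  guaranteeing equal counts.
- Line scans: in-mask pixels within half the line width (default
  50 px) of the axis, binned at 1 px along the axis; quadrant means
  average raw pixels within four equal fractions of the pole-to-pole
  span, ordered rear → front.
- PLA dots: Gaussian smoothing (σ = 1 px), threshold at in-mask
  mean + 4·sd (the original ImageJ recipe is not published; the rule
  and k are configurable), 8-connected components, area window
  3–400 px, assignment by centroid. Two dots closer than the
  smoothing scale merge into one component — tunable via σ, and the
  reason the dot-count guarantees are stated at ≥ 10× dot radius
  separation.
- Background is subtracted (floored at 0) before every intensity
  ratio; the rear index is scale-invariant by construction.

## Motility statistics

Speed defaults to path length / duration of the frame-to-frame
polyline; the mean instantaneous step speed is also reported because
tracking packages differ on the convention. Note the finite-sampling
bias: at frame intervals comparable to P the step speed
underestimates the instantaneous speed (characterised, not hidden, in
the tests — at dt → 0 the mean step speed converges to the Rayleigh
mean S·√π/2). MSD pools all overlapping ordered pairs per lag across
tracks; tracks shorter than 3 frames are excluded with a logged
count. The Fürth fit uses bounded least squares; a persistence
estimate at the 10⁴ min upper bound flags the ballistic regime where
P is unidentifiable.

## Problem sizes and numerical choices

Validation runs use 1,500–2,000 proteins, 50 noisy image replicates,
and 200 tracks × 61 frames — sizes at which the Monte-Carlo error of
each checked quantity is small against its tolerance (e.g. the
background false-classification rate is estimated over three pooled
2,000-protein experiments because a single experiment leaves ~0.006
sampling noise on a ~0.064 rate). BH ties resolve by the standard
cumulative-minimum step-up. All generators are bit-reproducible for a
fixed seed; pipeline outputs embed the config hash and seed and
re-runs are byte-identical (plots excluded).

## Known limitations

- No peptide-level modelling, normalisation between samples (LFQ is
  assumed pre-normalised), or multi-factor designs beyond
  bait × condition.
- Category counts from real deposited data can shift slightly under a
  different moderated-t configuration (single linear model vs pairwise
  contrasts, imputation on/off); both knobs are exposed.
- Image analysis expects masks as inputs (or synthetic); there is no
  cell segmentation, deconvolution or 3-D support.
- The network stage consumes database exports as files; accession
  normalisation is exact-match only.
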