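# Methods

This note documents the models and contracts implemented in `spliceaxis`:
what each stage computes, the choices made where the field offers several
defensible definitions, and what the synthetic cohort does and does not
emulate.

## Local AS events and PSI

Events are *local two-form contrasts* derived from annotated transcript
structures (the transcript-set formulation used by TPM-based quantifiers,
as opposed to junction-read PSI).  For each gene, all transcripts are
indexed by their exons and introns (an intron is the junction pair
`(donor-exon end, acceptor-exon start)`), and seven patterns are
enumerated:

| type | pattern | inclusion form |
| --- | --- | --- |
| SE | cassette exon with both flanking junctions vs the flank-to-flank junction, boundaries shared | cassette present |
| RI | unspliced exon spanning exactly the two exons another transcript splits (outer boundaries shared) | intron retained |
| A5/A3 | two introns sharing one boundary whose alternative-boundary exons **overlap**; donor-side variation is 5' on `+` and 3' on `-` | shorter intron (longer exon) |
| AF/AL | two introns sharing one boundary whose alternative exons do **not** overlap and are genuine terminal exons of their transcripts (first/last strand-relative) | alternative exon with the smaller start coordinate |
| MX | two non-overlapping cassette exons with identical flanks that never co-occur in one transcript | genomically left cassette |

Sites with more than two alternatives are emitted as pairwise two-form
events, keeping PSI a ratio of two forms.  Events are deduplicated by a
canonical id, `gene;TYPE:chrom:<coordinates>:strand`, and transcript sets
are containment sets (every transcript carrying the pattern).  The
overlap rule that separates A5/A3 from AF/AL is evaluated at the set level
(any exon pair across the two boundary groups), which makes classification
a function of the intron pair rather than of a particular transcript pair.

Two geometric facts are asserted as properties: flipping a gene's strand
alone swaps A5↔A3 and AF↔AL, and flipping the strand while mirroring all
coordinates leaves every classification unchanged (the two operations
compose to the identity).

A deliberately naive second implementation
(`events_reference.enumerate_events_pairwise`) re-derives all events by
exhaustive comparison of every ordered transcript pair with containment
scans over all transcripts.  It shares no logic with the production
generator and serves as its oracle; the suite requires event-for-event
agreement (type, coordinates, transcript sets) on randomly generated
mixed-strand toy genes.

**PSI.** For inclusion-form TPM sum `a` and exclusion-form sum `b`, PSI is
`a/(a+b)`, undefined when `a+b < 1e-3` TPM (this avoids 0/0 while leaving
expression filtering to the downstream TPM > 1 threshold).  Numerically the
minority form is computed as the ratio and the majority form as its
complement, so the PSIs of an event and its mirrored event sum to exactly
1.0 in IEEE double arithmetic — the naive ratio pair is off by one ulp in a
noticeable fraction of cells.

## Differential splicing

A comparison contrasts tumor samples carrying a genomic flag against tumor
samples without it (the shipped `comparisons.yaml` enumerates 18 such
flags: the five IgH translocations, hyperdiploidy, 1q gain and
amplification, del(17p), del(13q), mutation flags for DIS3/TENT5C/TP53/
SF3B1 plus the SF3B1 hotspot subset, and the three biallelic states; the
complement-of-case control arm is this package's documented assumption).
Per event: dPSI = difference of arm means (missing PSI excluded pairwise,
at least 3 non-missing values per arm), two-sided Mann–Whitney U p-value,
and a pass flag requiring |dPSI| > 0.10, mean event TPM (over both arms)
> 1, and raw p < 0.05.  No multiple-testing correction is applied by
default — the raw-p triple filter is the reproduced contract — but a
Benjamini–Hochberg switch is available.

**Normal-cell subtraction.** An event is called cell-type specific, and
removed, when both arms deviate from the normal-panel mean PSI by more
than 0.10 *in the same direction* — a tumor-wide shift rather than a
subgroup effect.  Events with no quantifiable normal PSI are retained with
a warning.  This rule is interpretive: it is the simplest operationalization
of "remove events that separate tumor from normal rather than subgroup
from subgroup".

Sample structure is visualized by UMAP (fixed seed, library defaults for
neighbors/min_dist) over the top-variance events (default top 1%), with
per-event mean imputation used for the embedding only.

## Pathway activity and splicing frequency

Pathway activity per sample is the mean z-score of member genes'
log2(TPM+1); the cohort is cut at tertiles into high/mid/low (thresholds
config-exposed).  Gene sets ship as a GMT fixture (NHEJ with 13 genes
including XRCC4 and LIG4, HR, MMEJ, their union, and a spliceosome set
including the Hsp70-family genes HSPA1A/HSPA1B/HSPA6/HSPA8/HSPA1L); the
file is user-replaceable since curated pathway databases are licensed and
drift across versions.

*Splicing frequency* has no standard operational definition; here it is
the per-sample count of events whose PSI deviates from the cohort median
by more than 0.10 among events expressed (event TPM > 1) in that sample.
Burden comparisons between activity groups use a one-sided Mann–Whitney U
test on these per-sample counts; abnormality enrichment uses Fisher's
exact test, reporting the odds ratio with a Haldane +0.5 correction when
any cell is zero (the p-value always comes from the exact enumeration of
the uncorrected table); SV-count comparisons report group means, a
one-sided MWU, and a Kolmogorov–Smirnov normality p per group
(diagnostic, not gating).

## Survival and risk modeling

Events are dichotomized at their mean PSI; values equal to the mean go to
the "above" group (documented tie-break), missing values are excluded, and
degenerate splits skip the event.  Kaplan–Meier curves and the k-sample
logrank test come from lifelines, as does the Cox partial-likelihood fit
(Efron tie handling); Harrell's C-index is computed on the linear
predictor.  Constant covariates are an error, perfect collinearity and
fewer than five events per covariate produce warnings.

The composite risk model screens the top-200-variance events among those
expressed (event TPM > 1) in at least half the samples — "expressed" needs
an operational cut — dichotomizes them, adds the clinical covariates, and
runs backward elimination: drop the largest Wald p ≥ 0.05, refit, repeat.
Because ~200 candidates against ~600 patients is unstable, a univariate
pre-screen (p < 0.2, disableable) and a hard cap of n/3 candidates guard
the initial fit; every candidate, clinical included, is eliminable, and an
empty final model is a valid outcome (C-index reported as 0.5).  Samples
with missing PSI for a dichotomized candidate are mean-imputed in the
design (they carry no signal for that marker).  Unfavorable markers
(HR > 1) feed the accumulation tiers: 0–2 markers low, 3–4 medium, ≥5
high risk, with KM/logrank across tiers.

## Splicing-factor networks

For each subgroup, all (SF gene, event) pairs are tested over the
subgroup's case samples (within-subgroup by default; correlating across
all samples is a config switch) with Spearman correlation of log2(TPM+1)
expression against PSI on pairwise-complete observations; pairs with fewer
than 10 paired samples or a constant side are skipped.  Edges require
|ρ| > 0.3.  The 69-gene SF panel is a synthetic placeholder list of
well-known splicing factors (the original panel is external); it is
user-replaceable via `--sf-list`.  Exports are Cytoscape-compatible
node/edge TSVs; cross-subgroup consistency reports edges present in ≥2 or
all networks with per-network ρ and sign agreement.

## The synthetic cohort

The generator emulates the *statistical structure* the analysis assumes,
not myeloma biology:

* **Cohort**: 598 tumors + 5 normal plasma-cell samples by default.
  Primary subtypes are mutually exclusive with population frequencies
  t(11;14) 15%, t(4;14) 12%, t(14;16) 3%, t(14;20) 2%, t(6;14) 1%,
  hyperdiploid 57%; 1q gain 30% / amp 10% (exclusive); del(13q)
  co-occurs with t(4;14) at 95%; biallelic flags imply the mutation;
  TP53/TENT5C abnormalities are enriched in latent-high samples so the
  enrichment stage has signal.  Flag fractions are realized as exact
  counts with random placement.
* **PSI**: per-event baseline Uniform(0.25, 0.75); planted subgroup
  effects shift the target mean on the PSI scale (toward the farther
  boundary), and observed PSI is `sigmoid(logit(target) + N(0, sd))` with
  sd 0.25 by default.  A configurable fraction of events (8%) carries a
  tumor-wide +0.25 shift against the normal baseline to exercise the
  normal filter.  The 1q pair plants the same events at 0.1 (gain) and
  0.3 (amp), mirroring effect escalation.
* **NHEJ coupling**: a latent per-sample activity factor `a ~ N(0,1)`
  raises NHEJ gene expression by 1 log2 unit per sd (up to ~4-fold across
  the cohort) and, through a correlated factor
  `s = ρ·a + √(1−ρ²)·ε` with ρ = 0.7, sets each sample's probability
  (0.02–0.6) of deviating on each of 200 frequency-responsive events by
  ±0.3 PSI.  The noise levels were chosen by an identifiability
  calculation: with 13 NHEJ genes at 0.2 log2 expression noise the
  activity score correlates ≈0.99 with `a` (tertile labels recoverable at
  ≥95%), and with PSI noise 0.25 the deviation-count measurement
  attenuates the planted ρ by ≈5–10%, keeping the estimate within ±0.1.
* **Expression**: gene log2(TPM+1) is Normal with per-gene means
  N(5, 1); transcript TPMs of an event gene are the gene TPM split by the
  true PSI, so transcript sums reproduce gene TPM exactly.  Planted
  SF–event couplings tie an SF gene's expression to a target event's
  realized logit-PSI at Spearman ≈0.6 (targets are drawn from the
  frequency-responsive events, which carry the real cross-sample
  variance).
* **Outcomes**: survival is exponential with log-hazard additive in
  marker flags (defaults: NHEJ-high log 1.7, Double-Hit log 2, del(17p)
  log 1.6, amp1q log 1.5, t(4;14)/t(14;16) log 1.3), administratively
  censored at a 7-year horizon; OS uses half the PFS hazard.  SV counts
  are negative binomial (dispersion 2) with mean 87 in NHEJ-high samples
  and 19 otherwise.

Everything planted is recorded in a `GroundTruth` ledger (planted events
per subgroup, cell-type-specific events, per-sample true deviation counts,
latent NHEJ tertiles, SF couplings, marker hazards), and all outputs are
byte-identical under a fixed seed (independent seed streams per stage).

What the generator does **not** emulate: linkage between genomic flags
beyond the few rules above, read-level noise and mapping artifacts,
isoform complexity beyond two forms per gene, batch effects, non-
proportional hazards, and informative censoring.  Passing tests therefore
demonstrate that the pipeline recovers known structure of this form — not
that it would be well-calibrated against all features of real cohorts.

## Problem sizes and numerical conventions

The test and validation suites run at deliberately modest scales chosen to
keep each property measurable: oracle equivalence on 50 random toy genes;
differential recovery at 30 vs 30 samples with 504 events and 50 planted;
type-I calibration over 2030 null events; coupling recovery at n = 300;
Cox recovery over 100 simulation seeds at n = 598 with ~40% events;
backward elimination over 20 planted and 10 null replicates at n = 500;
tier ordering at n = 600; network recovery at n = 200 with a 40×50
independent-pair null at n = 24; and two full default-scale pipeline runs
compared byte-for-byte.

Numerical conventions, in one place: genomic coordinates are 1-based
inclusive throughout; matrices are features × samples, tab-separated,
`NA` for missing; PSI needs ≥1e-3 TPM across both forms; comparisons need
≥3 non-missing PSI per arm; dichotomization sends ties above; event-id
sorting breaks all remaining ties deterministically; per-stage seeds are
derived from the master seed via CRC-tagged seed sequences and logged in
the run manifest.
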