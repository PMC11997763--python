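# Methods

`ese-scan` classifies hormone-responsive target genes and their regulatory
elements from four data layers: differential transcription, receptor /
coactivator ChIP co-binding, chromatin accessibility (FAIRE) and histone
acetylation (H3K27Ac).  The biological setting is the ecdysone (20E)
response in *Drosophila* larval tissues: depleting the hormone (the
"treatment" / HS condition, versus the NHS control) reduces transcription
of 20E-activated genes, and the elements driving them — sites co-bound by
the ecdysone receptor EcR and the CBP/Nejire acetyltransferase, here called
ecdysone-sensitive elements (ESEs) — lose receptor binding, accessibility
and acetylation.  The pipeline turns those observations into a reproducible
classification procedure; the synthetic generator provides a labeled
experiment of the same design so every stage can be validated without any
external data.

## Coordinates and windows

All internal coordinates are 0-based half-open; GFF3/GTF converts on read,
BED and bedGraph pass through verbatim.  The window vocabulary:

| window | definition | used for |
|---|---|---|
| locus flank | locus padded ±5 kb, clamped at 0 | target/ESE locus assignment |
| TSS response window | 500 bp strand-aware downstream of a TSS | responsive-TSS counts |
| proximal zone | summit within ±250 bp of a TSS, boundary inclusive | proximal/distal split |
| summit window | ±250 bp around a summit (500 bp total) | EcR/CBP/FAIRE scores |
| acetylation window | ±500 bp around a summit (1000 bp total) | H3K27Ac scores and clustering |

Flanks are not clipped at neighbouring genes (no clipping rule is defined
for the assay); a peak overlapping two flanked loci counts for both.

## Differential transcription

Counts are scaled with median-of-ratios size factors (reference: per-feature
geometric mean over features with all-positive counts; total-count fallback
otherwise), log2-transformed with a 0.5 pseudocount, and tested per feature
with a moderated t-statistic: pooled two-group residual variances are shrunk
toward a scaled inverse-chi-square prior fitted by moments on the
log-variances (the limma `squeezeVar` construction, implemented here), and
the t reference distribution gains the prior degrees of freedom.  With two
replicates per condition a plain per-feature Welch test has ~2 residual df:
its detection power for even a ~6-fold planted effect on negative-binomial
counts (dispersion 0.1) is only 30–40% after multiplicity control, so
variance moderation is a requirement of the design, not a refinement.
`method="welch"` retains the unmoderated test.  Gene-level calls use
|log2FC| ≥ 1.5 with Benjamini–Hochberg adjusted P ≤ .05 ("FC ≥ |1.5|" is
read on the log2 scale, the DESeq2-style convention; the threshold is
configurable).  Genes *down* under depletion are the hormone-**activated**
set; *up* genes the hormone-**suppressed** set.  NB dispersion estimation
and GLM fitting are deliberately out of scope — this stage is the
pipeline's filter, not its contribution.

Responsive TSSs use the same machinery on 500-bp downstream-window counts
but threshold on the **raw** p-value (the TSS-level criterion is stated
without adjustment), after deduplicating TSSs shared by transcripts.

## Targets and elements

A DE gene is a **primary** target when its locus ±5 kb contains ≥1 EcR
peak.  ESE calling intersects each EcR peak with every overlapping CBP peak
(≥1 bp, half-open semantics), merges overlapping intersection footprints by
union (one regulatory region should not be double-counted), and keeps
footprints overlapping ≥1 flanked activated primary locus.  The summit is
the EcR summit when inside the footprint, else the footprint midpoint.

Activity classification is 2-way agglomerative clustering (Ward linkage,
Euclidean — the standard default, as the linkage is otherwise
unconstrained) on one scalar per element: log1p of the replicate-mean,
input-subtracted H3K27Ac in the ±500 bp summit window, floored at 0 before
the log.  Input is subtracted (not ratioed) for H3K27Ac and FAIRE;
ChIP-factor scores are ratios to input with a stabiliser ε = 0.25 of the
background unit.  k = 2 is fixed: the procedure defines exactly an
active/poised dichotomy.  Elements are sorted before clustering so labels
are invariant to input order.  Clustering operates on the scalar window
level rather than a multi-bin signal shape; at realistic bimodality
(several-fold separation between acetylation modes) the scalar is
sufficient and keeps the cut interpretable.

## Differential windows

Per-element, per-assay scores in the fixed windows above are compared
between conditions with a paired t-test across replicate pairs on log2
scores (pairing by replicate index; a paired design is used throughout),
plus a five-way call: **down** (log2FC control-over-treatment ≥ 1, p ≤
.05), **up** (≤ −1), **flat**, and the peak-presence overrides **absent**
(no peak in either condition) and **acquired** (peak only under treatment).
The fold-change threshold "FC ≥ |1|" is read as |log2FC| ≥ 1, i.e. 2-fold.
A 0.25 pseudo-signal precedes the log2 so subtractive scores of 0 remain
finite.  No NB model is re-fit behind these calls: with n = 2 replicates
the operational output (window FC + paired p against fixed thresholds) is
the reproducible quantity, and the calling engine is pluggable.

Metaprofiles are per-offset medians with standard errors (sd/√n across
anchors), strand-flipped so positive offsets are downstream.  The single FC
printed per panel is the ratio of condition-level means of per-anchor
window means, with the paired t across anchors; per-anchor FCs are also
emitted.  PCA on window-score matrices (samples × regions, region-centered)
uses a full SVD.

## The synthetic experiment

The generator emulates the study design: two tissues (SG, BR) × two
conditions (NHS control, HS depletion) × 2 replicates.  Defaults, chosen
once to match the design scale: 500 genes (60 activated, 50 suppressed) on
a 2 × 6 Mb genome (2–10 kb loci, ≥12 kb gaps — the geometry needed for
±5 kb flanks not to bridge neighbouring loci), NB counts with dispersion
0.1 over a log-normal baseline (median ~200 counts, σ = 1), planted
|log2FC| = 2.5, ~Poisson(3, min 1) co-bound elements per activated locus
with a 0.24 proximal placement probability, an active fraction of 0.4, and
HS multiplying local coverage at affected summits by 0.5.  Tracks are
Gaussian bumps (sd 150 bp) on a flat background 1.0 with i.i.d.
multiplicative log-normal bin noise (sd 0.2, mean 1); input tracks are
background only.  Acetylation amplitudes are bimodal log-normal with an
order-of-magnitude separation between active and poised modes — the
operative constraint is only that modes are ≥4-fold apart.  Three child RNG
streams (annotation, labels, counts, tracks) hang off the master seed so
any one artifact regenerates independently.

What the generator does *not* model, and hence what green tests do not
show about real data: fragment-level read sampling and GC/mappability
bias, replicate-level batch effects (replicates differ only by noise, the
simplest structure satisfying the paired-test assumptions), promoter
acetylation independent of planted elements, overlapping or nested gene
models, and brain-tissue coverage tracks (the brain arm exists only as a
tissue-bias structure in the count matrices).  The realized proximal share
of planted elements runs somewhat below the nominal 0.24 because each TSS
can host at most one proximal element under the ≥1.2 kb spacing rule.

One deliberate consequence of the planted-effect construction: multiplying
local *coverage* by 0.5 moves ratio-to-input chip scores by exactly the
calling threshold (log2FC = 1), where expected recall is ~50% by symmetry,
while subtractive FAIRE/H3K27Ac scores move by *more* than 2-fold (the
input is unchanged).  Recovery of planted drops is therefore assessed on
the subtractive assays; chip-ratio calls at exactly-threshold effects are
reported but not used as a sensitivity benchmark.

## Numerical choices

* ε = 0.25 in ratio scores; 0.25 pseudo-signal before log2 of window
  scores; 0.5 pseudocount before log2 of scaled counts.
* Zero-variance features: p = 1 under the unmoderated test; under
  moderation they borrow the prior variance.
* Ties at the proximal boundary (exactly ±250 bp) are proximal; percent
  figures round half-up.
* Clipped windows at chromosome starts shrink (logged); clipped profile
  anchors are dropped, not padded, to avoid edge bias.
* All outputs are written with stable ordering and fixed float formatting,
  so a rerun from the same inputs is byte-identical.

## Validation summary

The test suite checks each primitive against an independent oracle
(per-base expansion for window means and scores, O(n²) scans for interval
overlap, the literal step-up definition for BH, closed-form t for the
paired test), verifies type-I error of both tests on null simulations, and
measures planted-structure recovery at the default design (DE sensitivity
and FDR, activity-label agreement, down-call sensitivity, directional
active-vs-poised fold-change structure).  `scripts/acceptance.py`
recomputes all of these from scratch; the problem sizes it uses (500-gene
design, 100 null simulations per test, 1000 oracle cases) keep a full run
under a minute on one core.
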