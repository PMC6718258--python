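# Methods

## Feature model

A panel is an ordered list of microsatellite target intervals (BED,
0-based half-open). Indel calls are extracted from VCF 4.x records
(1-based positions): every length-changing ALT of a (possibly
multi-allelic) record becomes one call with signed
`length_delta = len(ALT) − len(REF)`; symbolic ALTs, breakends and
spanning deletions are skipped because their length change is
undefined. A call is assigned to the locus whose padded interval
`[start+1−pad, end+pad]` contains its position; the default padding of
2 bp absorbs the left-alignment ambiguity of homopolymer indels.
Coordinate conversion between the two conventions happens exactly once,
in the VCF reader.

Per locus, alleles are **deduplicated by signed length**: `n_peaks` is
the number of distinct deltas and `mean_indel_length` the unweighted
mean of those distinct deltas. Two readings of "number of peaks" are
possible (count of distinct indel lengths vs total allele count); the
distinct-length reading is used because a "peak" mirrors a distinct
fragment length in the PCR-chromatogram analogy, and the mean is taken
over the same deduplicated set for consistency. Read-support weighting
is deliberately not used. A locus with no calls contributes (0, 0.0)
so every sample maps to a fixed-length vector; `callable_loci` (loci
with ≥ 1 call) feeds sample QC instead.

The locus-prevalence filter retains loci whose fraction of samples with
`n_peaks ≥ 1` is **strictly greater** than the threshold (default 0.8),
matching the "> 80 %" selection that reduced a wider candidate set to
the 29-locus panel.

## Classifier

Training runs Lloyd's k-means (k = 3, Euclidean) with 25 seeded
random-observation initializations, keeping the lowest within-cluster
sum of squares; scikit-learn's `KMeans` is the engine (its random init
draws observations, and empty clusters are re-seeded at far points,
matching the documented fallback). Each converged cluster is named by
the majority gold-standard label of its members, normal tissue counting
toward MSS; a model is valid only if exactly one cluster is MSS-named
(two MSI-H clusters + one MSS/normal cluster), otherwise training fails
with a per-cluster composition diagnostic. k = 3 reflects the wide
spread of MSI-H samples, which one centroid cannot cover.

No feature scaling is applied before clustering or distance
computation: both feature families live on comparable small magnitudes,
and the decision statistic is meant to be read in raw feature units so
that τ = 3.0 keeps its calibrated meaning. A z-scoring flag exists for
experimentation and is off by default.

Classification computes `D = d(x, c_MSS) − d(x, c_MSI-H*)` with
`c_MSI-H*` the **nearer** of the two MSI-H centroids. Cluster indices
from k-means are arbitrary under re-seeding, so anchoring D to a fixed
"cluster 1" would be irreproducible; the literal fixed-cluster variant
remains available via `msih_reference="first"`. The inconclusive zone
is the **open** interval `−τ < D < τ` (exactly ±τ is conclusive);
`D ≥ τ` → MSI-H, `D ≤ −τ` → MSS. Nearest-centroid ties break to the
lower cluster index; an MSS/MSI-H tie necessarily lies inside the
inconclusive zone. Degenerate inputs (fewer distinct rows than k, or
k > n) abort training rather than emit a meaningless model.

## Marker discovery

Candidates are keyed by (chrom, pos, REF, ALT, homopolymer repeat
number); the repeat number is the maximal single-base run starting at
the base after the variant anchor when a reference FASTA is supplied,
else the `HRUN` INFO tag, else 0. It participates only in the key —
no numeric threshold is applied to it. The association test is a
two-sided Fisher's exact test (scipy) on carriers among MSI-H positives
vs the MSI-L ∪ MSS negatives; the test suite checks it against an
exhaustive hypergeometric-enumeration oracle. The filter retains
candidates with p < 1e−4, carriage in at least `ceil(0.8 · n_pos)`
positives (the generalization of "at least 6 of 7"), **zero MSS
carriers** (MSI-L carriage does not disqualify — the exclusion clause
names MSS only), and ALT string length 5–7 bp ("alt allele length"
reads as the ALT string's length, not |delta|). No multiple-testing
correction is applied; the procedure is a raw-p screen by design.

## Performance metrics and QC

Inconclusive calls are tallied separately and excluded from TP/FP/TN/FN;
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN) and accuracy (TP+TN)/(TP+FP+TN+FN) therefore describe
conclusive calls, with inconclusive/total reported alongside. A ratio
with zero denominator is reported absent, never as 0. Percent
formatting rounds half-up to whole percents (95.83 % → 96 %).
Reproducibility uses Pearson's r. NTC contamination thresholds are
mean + 2 × sample SD (n−1 denominator; the denominator convention is a
package choice) of replicate library concentration (nM) and length
(bp). Sample QC requires a minimum number of callable loci (default
24 of 29); run-level sequencer metrics (cluster PF %, % ≥ Q30, mapped
read %) are accepted as pre-computed numbers and compared against
configured thresholds.

## Synthetic-data generator

The generator works at the indel-allele level — the caller never sees
reads, so read-level simulation would add nothing it consumes. Depth
is emitted as a constant `DP` INFO field (default 500×) for filter
tests.

Defaults (one set of study conditions, fixed up front):

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 29 | panel size |
| `mss_peak_rate` | 0.4 | mean stutter alleles per locus, MSS/normal |
| `mss_deltas` | {−1} | MSS stutter allele lengths (bp) |
| `msih_peak_rate` | 3.0 | mean distinct alleles per unstable locus |
| `msih_fraction_unstable` | 0.8 | fraction of loci unstable in an MSI-H sample |
| `msih_delta_mean` | −4.0 bp | mean signed indel length at unstable loci |
| `msih_delta_sd` | 1.5 bp | spread of indel lengths |
| `msih_severity_range` | [0.6, 1.4] | per-sample scaling of rate and mean |
| `detect_floor` | 0.025 | dilution fraction at which allele retention saturates |

Unstable-locus allele counts are truncated Poisson (≥ 1); distinct
lengths are rounded normals excluding 0. The per-sample severity
factor makes the MSI-H group an elongated cloud rather than a ball,
which is what makes a two-cluster MSI-H representation the natural
k-means solution and mirrors the heterogeneity of real MSI-H tumors.
Dilution mixing retains each MSI-H-specific allele with probability
`min(1, f / detect_floor)` — a detection-probability rule that
reproduces the qualitative limit-of-detection transition (flat D down
to the floor, then decay into the inconclusive zone) without read
resampling. WES-like catalogs plant homopolymer insertions (ALT length
5–7) carried by 6–7 of 7 MSI-H exomes and no MSI-L/MSS exome, among
background indels carried label-independently; planted MSI-L carriage
is kept at zero because a single MSI-L carrier already lifts the
two-sided Fisher p above 1e−4 in the 7-vs-21 design, which would make
exact recovery ill-posed.

All randomness flows from one top-level seed via
`numpy.random.SeedSequence` spawning (one child stream per sample /
fraction), so outputs are byte-identical under a fixed seed and
sub-streams are independent.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: FFPE deamination artifacts and read-level
error; locus-specific allele spectra (loci are exchangeable, so
between-sample feature correlation across loci is uninformative, unlike
real BAT-25/BAT-26 spectra); partially unstable MSI-L tumors on the
panel; and real inter-assay nuisance variation (operator, day, batch).
Conclusions about separability and thresholds on real cohorts require
real gold-standard data.

## Problem sizes

The test suite and the acceptance script use the cohort compositions
the method was designed around: 94-sample training cohorts
(22 MSI-H / 25 MSS / 47 normal), 28-sample WES catalogs
(7 / 7 / 14) with 12 planted markers and 500 background indels, and
20-replicate dilution series over fractions 1 → 0.01. Three replicate
seeds are used wherever a stochastic quantity is asserted.

## Known limitations

* The decision statistic's τ = 3.0 is meaningful only in unscaled
  feature units; enabling z-scoring changes its scale and would require
  re-deriving τ.
* With a manifest whose truth labels do not yield a two-MSI-H/one-MSS
  majority structure, training refuses rather than relabels — cohort
  composition is the user's responsibility.
* Homopolymer repeat numbers default to 0 when neither a reference nor
  an `HRUN` tag is available, which can merge candidates that a
  reference would distinguish.
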