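# Methods

`repdx` implements a peripheral-blood biomarker workflow for patients with
advanced solid tumors receiving anti-PD-1/PD-L1 therapy: TCR-beta
repertoire diversity at baseline and on treatment, pre/post repertoire
dynamics, a soluble receptor/ligand (sRL) panel with a checkpoint-protein
fold-change signature, and stratification of clinical outcomes.  This note
records the models, the parameters that matter, the design choices made
where the design was genuinely open, and what the synthetic cohort does and
does not establish.

## Repertoire representation

A repertoire is a clonotype abundance table: one row per unique
(CDR3 nucleotide sequence, V gene, J gene) triple with a read count and a
frequency.  Allele suffixes (`*01`, `*02`, ...) are stripped before identity
comparison because allele-level calls are unstable across aligners; rows
that collide after stripping are merged by summing counts.  Frequencies are
always recomputed from counts on read, so a stale frequency column in an
input file cannot leak through.

Frequency thresholding ("dominant clones") keeps clones with frequency
**strictly greater** than the threshold, computed against the full
repertoire.  The filtered table carries both the original
(`frequency_full`) and the renormalized (`frequency`) vector: entropy of a
sub-distribution requires a proper distribution, so all diversity
statistics downstream use the renormalized one, but the original is kept so
the alternative convention can be evaluated.

## Diversity statistics

* **Shannon–Wiener index**: `H = -sum p_i ln p_i` over (renormalized) clone
  frequencies.  The *effective number of clones* `exp(H)` (order-1 Hill
  number) is exposed as a variant and is what the pipeline uses for the
  dominant-clone comparison: reported Shannon values in this literature are
  on the effective-number scale (tens to hundreds), which ln-entropy of a
  few hundred dominant clones cannot reach.
* **D10/D20/D50**: rank clones by frequency descending; `k` is the smallest
  prefix whose cumulative frequency reaches 10/20/50% of reads; the index
  is `100 k / richness`.  Low D50 means an oligoclonal repertoire.  Ties at
  the cumulative boundary are broken deterministically (count descending,
  then CDR3 lexicographic) and the cumulative comparison uses a `1e-12`
  tolerance, so the index is reproducible across platforms.
* **Top-k abundance**: cumulative frequency of the k most frequent clones
  (k = 10 in the pipeline).

## Pre/post dynamics

* **Jaccard index** on clonotype identity sets measures turnover; an
  optional frequency floor restricts it to dominant clones (default: all
  clones).
* **Pearson similarity** correlates clone frequencies aligned on identity.
  Defaults are log-transformed frequencies over the shared-clone
  intersection — the least assumption-laden choice; a union scope with
  pseudo-frequency `1/(2 * total_reads)` is available for zero-fill.
* **Expansion testing**: for each clonotype present in either sample with
  combined count >= `min_count` (default 10, to suppress singleton noise),
  the 2x2 table `[[pre_count, pre_rest], [post_count, post_rest]]` is
  tested with a two-sided Fisher's exact test (two-sided by summation of
  tables with probability <= observed, the standard convention).
  Adjustment across clones is Benjamini–Hochberg by default; a
  Storey-type positive-FDR estimator (pi0 from the p > 0.5 fraction) is
  available behind `fdr="storey"` for fidelity to pFDR-style workflows.
  Direction compares pre/post frequencies; exact ties get no direction and
  are never significant.
* **Shared expanded clones** groups significant expansions across patients
  by CDR3 amino-acid sequence (public clones) or full nucleotide identity.
* **Similarity vs covariates** uses Spearman rank correlation for numeric
  covariates (elapsed weeks) and a two-sided rank-sum test for two-level
  covariates (therapy arm).

## Gene usage

Usage profiles are read-frequency-weighted by default (clone-proportion
weighting available) at the V, J, or paired V–J level, with V–J usage
marginalizing exactly to the V and J profiles.  Between-group comparison is
a per-segment two-sided rank-sum test, exact for combined n <= 20,
asymptotic with tie correction otherwise; p-values are nominal by default
(segment counts are modest) with an optional BH column.

## Soluble receptor/ligand panel

The panel vocabulary is fixed at 30 analytes: 14 soluble cytokine
receptors and 16 soluble immune-checkpoint proteins; a normalization map
absorbs spelling variants (alpha/a, hyphens).  Bead-panel QC drops
analytes whose %CV exceeds 10 (inclusive at exactly 10%).

* **Baseline comparison**: per-analyte two-sided rank-sum between benefit
  groups, with the percent difference of medians.
* **Fold change**: `log2(post/pre)` per analyte; nonpositive concentrations
  are skipped with a warning.
* **Signature discovery**: pairwise Pearson correlation of fold changes
  across patients, average-linkage hierarchical clustering on `1 - r`, tree
  cut at cophenetic distance `1 - min_r` with `min_r = 0.6`.  This is an
  operational surrogate for "average within-cluster correlation >= 0.6":
  the scipy tree cut bounds the cluster's cophenetic merge height rather
  than re-averaging the final within-cluster correlations; on block-
  structured data the two agree.  Clusters are returned largest-first.
* **Signature scoring**: (i) mean over member analytes after per-analyte
  z-scoring across the cohort (cohort mean exactly 0; missing values
  imputed at the member median, logged); (ii) a rank-based single-sample
  enrichment score in the ssGSEA convention — genes ranked by expression
  descending, weighted in-set CDF (weight exponent 0.25 on the rank
  statistic) minus uniform out-of-set CDF, summed over ranks, optionally
  normalized by the cohort score range.  The weight exponent and range
  normalization follow that method's published convention.
* **Direction groups**: patients are labeled by the sign of the signature
  score change; on the z scale the difference is used (log-ratios are
  undefined for negative scores), zero changes are excluded with a warning.
* The packaged 17-member checkpoint signature ships with a co-stimulatory
  (12 members) / co-inhibitory (5 members) split.  The split membership is
  a curated assumption (the grouping is standard immunology but no
  authoritative partition exists for the soluble forms) and is
  config-editable.

## Outcomes

* **Durable clinical benefit (DCB)**: PR or SD with survival strictly
  greater than 6 months; everything else NDB.  Which survival column feeds
  the rule is configurable (default overall survival; the choice between
  OS and PFS is genuinely open and documented as such).
* **Group comparison**: two-sided Mann–Whitney, exact null for combined
  n <= 20 without ties.
* **ROC / Youden**: AUC by the rank-sum identity `U/(n1*n2)` with midrank
  ties; candidate cutoffs are midpoints between adjacent distinct scores
  (plus sentinels), classification is `score >= cutoff`, and the Youden
  cutoff maximizes sensitivity + specificity - 1 with ties broken toward
  higher specificity.  Midpoint reporting makes the cutoff stable under
  small perturbations of the observed scores.
* **Survival**: Kaplan–Meier per group (lifelines) and the two-group
  log-rank test with a 1-df chi-square p.
* **Combined classifier**: *favorable* = D50 at/above the Youden cutoff
  AND signature change <= 0; *unfavorable* = below the cutoff AND change
  > 0; otherwise *mixed*.  DCB rates are compared between favorable and all
  other patients by Fisher's exact test.

## Synthetic cohort generator

The generator exists so every stage is testable end to end without patient
data.  Defaults are the study conditions the pipeline is built around:
31 patients, 35% DCB, 24 paired samples, 14 single-agent; on-treatment
sampling at a median of ~9 weeks (lognormal, clipped to 3–36).

* **Clone frequencies**: Zipf with exponent 1.1 over 1,000 clones by
  default (lognormal sigma 1.5 as an alternative), per-patient lognormal
  jitter (sd 0.25), multinomial reads at depth 100,000.  The DCB group's
  distribution is flattened by an exponent solved numerically so that the
  dominant-clone (frequency > 0.1%) effective diversity is 2.78x the NDB
  group's in expectation; when a configuration is too small to reach the
  target the flattest admissible exponent is used.
* **Dynamics**: sub-dominant clones survive to the post sample with
  probability `persistence^(weeks/9)` (DCB 0.8, NDB 0.9 at nine weeks —
  benefiting patients remodel more, giving them the lower Jaccard);
  combination therapy scales the turnover exponent by 1.5.  Dominant
  clones always persist but the top-10 decay by a group factor (NDB 0.85,
  DCB 1.0), reproducing the loss of dominant-clone abundance in
  non-benefiting patients.  Dropped clones are replaced by novel clones
  entering near the sampling detection floor (so clone influx does not
  masquerade as statistically significant expansion).  Truly expanded
  clones (27 per DCB patient, 18 per NDB patient) are drawn from surviving
  sub-dominant clones and multiplied by the expansion factor (10 by
  default) before renormalization; the set is returned as ground truth.
  Every clone also drifts by a small time-scaled lognormal factor (sd 0.1
  at nine weeks).  Three fixed *public* clonotypes are present in every
  patient and expand with group-dependent probability (DCB 0.6, NDB 0.25),
  producing the shared-expanded-clone table.
* **Panel**: log-normal baseline concentrations (per-analyte means fixed,
  between-patient sd 0.3 log2 units).  Signature members share a latent
  factor on the log2 fold change giving pairwise correlation ~0.6
  (configurable); the NDB group's latent factor is shifted by +1.2, so the
  checkpoint signature rises on treatment in non-benefiting patients.
  DCB baselines carry +5.04% (sIL-2Ra) and +11.52% (sCD27) shifts;
  sRAGE and sCD27 are globally upregulated on treatment (+0.5 log2);
  baseline sCD30 is coupled to the patient's standardized D50.
* **Clinical**: RECIST response and OS are drawn consistently with the DCB
  rule (the generated label always equals `classify_dcb` applied to the
  table); PR probability increases with standardized D50 within each
  group.  PFS is exponential with log-hazard linear in standardized D50
  (-0.8 per SD) and uniform censoring on 6–36 months.

**What the generator does not emulate**: germline V(D)J recombination
statistics and CDR3 length/motif biology; realistic repertoire richness
(patients have ~10^5 clones, the default is 10^3, so absolute Jaccard and
detected-expansion counts are on a compressed scale); sequencing error and
UMI artifacts; assay-range censoring in the bead panel; correlated
competing risks.  Passing tests therefore demonstrate the statistical
machinery is correct and calibrated, not that effect sizes transfer to
real cohorts.

## Problem sizes in the checks

The null-calibration and recovery checks use problem sizes chosen to make
their Monte Carlo error small relative to the bands they assert: expansion
false positives pooled over 200 resampled pairs (1,000 clones at depth
10^5); ROC calibration on 100 null cohorts of 50 patients at reduced depth
(300 clones, 30,000 reads — the D50 statistic is insensitive to the extra
depth); diversity-ratio recovery from 100 repertoires per group; signature
membership recovery and expansion power over 100 generator seeds.  The
acceptance script repeats these with 30–60 replicates, which is enough for
the reported rates to be stable to a few percent.

## Known limitations

* The effective-number transform reproduces the *scale* of published
  Shannon values; the exact transform used upstream of such values is not
  derivable from the statistics alone.
* With heavy ties the exact rank-sum null (used for combined n <= 20)
  ignores the tie structure; this matches the usual exact-test convention
  but can be conservative.
* The Storey pFDR estimator uses a single lambda (0.5) rather than the
  smoothed lambda grid; with thousands of clones the difference is
  negligible.
* The tree-cut signature discovery can split one generating block into
  nested clusters at small n; membership recovery is only claimed at
  n ~ 200 patients.
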