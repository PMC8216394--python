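# repdx

Peripheral-blood biomarker analysis for immune-checkpoint-inhibitor (ICI)
therapy: TCR-beta repertoire diversity, pre/post-treatment repertoire
dynamics, and soluble immune-checkpoint protein signatures, linked to
clinical outcome.

Only a minority of patients benefit from anti-PD-1/PD-L1 therapy, and
tissue biopsies are hard to obtain repeatedly.  `repdx` implements the
statistics behind a blood-based alternative, for analysts working with
AIRR-seq clonotype tables and multiplex bead-panel data:

* **Diversity** — Shannon–Wiener index `H = -Σ p_i ln p_i` of the clone
  frequency distribution, optionally restricted to dominant clones
  (frequency > 0.1% or 1%) and transformed to the effective clone number
  `exp(H)`; the D10/D20/D50 indexes (minimum percentage of distinct
  clonotypes covering 10/20/50% of reads).  Low D50 = oligoclonal.
* **Dynamics** — Jaccard overlap and Pearson frequency correlation between
  paired pre/post repertoires; top-10 clone persistence; per-clone
  expansion calls by two-sided Fisher's exact test on
  `[[n_pre, N_pre−n_pre], [n_post, N_post−n_post]]` with FDR control
  (Benjamini–Hochberg or a Storey-type positive-FDR estimate); clones
  expanded in multiple patients.
* **Gene usage** — V/J/V–J segment usage profiles and rank-sum group
  comparison.
* **Soluble panel** — %CV QC, baseline group comparison, log2 fold
  changes, correlation-clustered fold-change signatures, signature scores
  (mean of z-scored members, and a rank-based single-sample enrichment
  score in the ssGSEA convention), signature direction groups.
* **Outcomes** — durable-clinical-benefit classification (PR/SD surviving
  > 6 months), ROC with the Youden-index cutoff (AUC via the rank-sum
  identity), Kaplan–Meier + log-rank stratification, and a combined
  D50 + signature classifier.
* **Synthetic cohorts** — a generator producing clonotype tables, analyte
  panels and censored survival with controllable group effects, so the
  whole pipeline is testable end to end (`repdx.simulate`).

## Worked example

Generate a synthetic 31-patient cohort and run the analyses:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_baseline_diversity.py
python analysis/06_outcome_stratification.py
```

which prints (seed 1):

```
 single_agent | dominant-clone effective Shannon: DCB median 88.61 vs NDB 35.77 (ratio 2.48, rank-sum p = 0.0020)
 single_agent | D50: DCB median 7.50 vs NDB 1.30 (ratio 5.77, rank-sum p = 0.0056)
...
ROC: AUC 0.950; Youden cutoff D50 >= 4.62 (sensitivity 100.0%, specificity 88.2%)
PFS: log-rank p = 0.0141 (median inf vs 4.5 months)
OS: log-rank p = 0.0081 (median 19.7 vs 4.9 months)
combined classifier groups: {'unfavorable': 9, 'favorable': 8, 'mixed': 7}
DCB rate, favorable vs rest (Fisher): p = 0.0001
```

Patients with durable benefit carry a more even dominant-clone repertoire
at baseline (the effective-diversity ratio is the generator's 2.78
condition, recovered within sampling noise); on treatment, the D50 index
separates responders (AUC ≈ 0.95) and the Youden split stratifies both
progression-free and overall survival.  The remaining analysis scripts
(`03`–`05`) cover repertoire dynamics, V/J usage, and the soluble-panel
signature.

The same steps are available from the library:

```python
from repdx import SimulationConfig, simulate_cohort, run_pipeline
summary = run_pipeline(simulate_cohort(SimulationConfig(seed=1)))
```

or the CLI (`repdx simulate`, `repdx diversity`, `repdx dynamics`,
`repdx run`).  Input formats: AIRR Rearrangement TSV (junction,
junction_aa, v_call, j_call, duplicate_count) or a simple five-column TSV;
clinical CSV; analyte-panel CSV (patients × 30 named analytes, pg/mL).

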