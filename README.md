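# metpanel

Count-rule gene expression / methylation marker panels for predicting distant
metastasis in clear cell renal cell carcinoma (ccRCC).

About 30% of ccRCC patients develop distant metastases, and predicting which
localized tumors will metastasize drives decisions about lymphadenectomy and
adjuvant therapy. `metpanel` implements a tissue-based molecular predictor
built on two complementary marker families measured in the same tumor sample:

* **Expression loss** of four HIF1-target genes — *CA9*, *NDUFA4L2*, *EGLN3*,
  *BHLHE41* — quantified by real-time PCR as relative expression
  (RQ = 2<sup>−ΔΔCt</sup>, tumor vs. paired normal tissue, GAPDH-normalized);
* **Promoter hypermethylation** of five miRNA genes — *MIR125B-1*, *MIR137*,
  *MIR375*, *MIR193A*, *MIR34B/C* — quantified by quantitative
  methylation-specific PCR as a methylation index
  (MI = 100·2<sup>−Ct_M</sup>/(2<sup>−Ct_M</sup>+2<sup>−Ct_U</sup>), percent).

Each marker is binarized into an *event* at a per-marker ROC cutoff
(expression: RQ ≤ cutoff; methylation: MI > cutoff), and a sample is called
high metastatic potential by a k-of-m count rule: ≥3 of 4 expression events,
≥4 of 5 methylation events, or ≥6 of 9 combined events. The package covers
the whole pipeline:

1. **Quantification** — raw Ct tables → RQ and MI, with bisulfite-conversion
   QC via an unconverted-template *ACTB* control;
2. **Marker screening** — per-marker group medians, two-sided Mann–Whitney U
   test, Benjamini–Hochberg FDR (within modality families), univariate
   logistic regression (Wald, with separation detection);
3. **ROC analysis** — direction-aware empirical ROC, AUC with DeLong 95% CI
   and test vs. 0.5, Youden-J optimal cutoff with specificity-favoring
   tie-break;
4. **Panels** — k-of-m count-rule calls with full diagnostic performance:
   confusion counts, sensitivity/specificity/PPV/NPV with exact
   Clopper–Pearson CIs, and the AUC of the ordinal event count;
5. **Synthetic cohorts** — the study's per-sample data are unreleased, so a
   calibrated generator (31 metastatic / 49 non-metastatic samples,
   published group medians, dispersions solved to match published
   single-marker AUCs) provides realistic test inputs, including raw Ct
   tables that round-trip through quantification exactly.

The count-rule panel is also exposed as a scikit-learn classifier
(`CountRulePanelClassifier`) whose `fit` learns Youden cutoffs and whose
`decision_function` returns the event count, so it composes with sklearn
pipelines and model selection.

## Worked example

```python
from metpanel import (SimulationConfig, simulate_cohort, screen_markers,
                      roc_summary, builtin_panels, call_events,
                      classify_count_rule, panel_performance)

cohort = simulate_cohort(SimulationConfig(seed=1))   # 31 met / 49 nonmet
summary, results = roc_summary(cohort)
print(summary[["marker", "auc", "cutoff_rule", "sensitivity", "specificity"]]
      .head(5).round(3).to_string(index=False))

cutoffs = {m: r.cutoff for m, r in results.items()}
panel = builtin_panels(cutoffs)["combined"]          # 6-of-9 rule
events, n_excl = call_events(cohort, panel)
pred, counts = classify_count_rule(events, panel.k_events)
perf = panel_performance(pred, counts, events["outcome"].to_numpy(),
                         "combined", n_excl)
print(f"combined 6-of-9 panel: sens {perf.sensitivity:.2f}%  "
      f"spec {perf.specificity:.2f}%  NPV {perf.npv:.2f}%  "
      f"PPV {perf.ppv:.2f}%  count-score AUC {perf.auc_count_score:.3f}")
```

prints

```
   marker   auc cutoff_rule  sensitivity  specificity
      CA9 0.817    ≤28.8522       74.194       81.633
 NDUFA4L2 0.862    ≤21.8679       83.871       83.673
    EGLN3 0.781     ≤8.3885       87.097       69.388
  BHLHE41 0.715     ≤2.1034       67.742       71.429
MIR125B-1 0.843    >49.7846       90.323       73.469
combined 6-of-9 panel: sens 87.10%  spec 97.96%  NPV 92.31%  PPV 96.43%  count-score AUC 0.986
```

Single markers reach AUCs around 0.7–0.86; combining all nine through the
6-of-9 count rule lifts performance to ~87% sensitivity and ~98% specificity
on this synthetic cohort — the same qualitative gain the panel is designed to
deliver. A negative combined test carries a ~92% probability of no
metastasis (NPV).

The same pipeline runs from the shell:

```bash
metpanel run --simulate --seed 1 --out results/
metpanel simulate --seed 1 --emit-raw-ct --out data/      # cohort + raw Ct
metpanel quantify --ct data/ct_records.csv --out data/wide.csv
metpanel associate --cohort data/cohort.csv --out stats.tsv
```

## Layout

```
src/metpanel/
  registry.py   published study reference values + dispersion calibration
  simulate.py   synthetic cohort and raw-Ct generator
  quantify.py   Ct -> RQ / MI, conversion QC
  stats.py      Mann-Whitney, BH-FDR, logistic screening
  roc.py        ROC curves, DeLong CIs, Youden cutoffs
  panel.py      count-rule panels, performance, sklearn classifier
  io.py, cli.py CSV/TSV I/O, pipeline, `metpanel` CLI
docs/methods.md model and design notes
```
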