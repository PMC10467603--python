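# prognosig

Prognostic gene-expression signature discovery and recurrence scoring for
stage II colorectal cancer.

About 20% of stage II colorectal cancer patients relapse within five years
of surgery, yet adjuvant chemotherapy helps only a few percent — so the
clinical question is *which* patients carry the risk.  `prognosig`
implements a complete discovery-and-validation pipeline for
expression-based risk stratification of these patients:

1. **Screen** — for every gene and every cohort, dichotomize expression at
   the cut-off c maximizing the standardized log-rank statistic
   |z| = |O₁−E₁|/√V over admissible splits (maximally selected rank
   statistic, `minprop` 0.1), test the split against relapse-free survival
   (RFS), and keep genes significant with a consistent direction in at
   least 4 of 6 cohorts.
2. **Score** — assign each tumor an integer recurrence score
   RS = Σ_g 1[x_g > c_g] (unfavorable genes) + Σ_g 1[x_g < c_g]
   (favorable genes), ranging 0..|signature|; classify high/low risk at
   the score's own optimal cut-off.
3. **Refine** — beam search over gene subsets: keep the B most significant
   k-gene combinations (log-rank p of the score classifier), extend each
   by one gene, repeat, and select the size k* at the significance peak.
4. **Evaluate** — Kaplan–Meier curves, hazard ratios, multivariate Cox
   models (pT, grade, MSI), ROC/AUC with Youden operating points, 10-year
   risk-of-recurrence GLM curves, pT-stratified KM, and head-to-head
   comparison against the 7-gene Oncotype DX colon score
   (RS_U = 0.15·(BGN+FAP+INHBA)/3 − 0.3·(MYBL2+KI67+MYC)/3 + 0.15·GADD45B).

It also ships NanoString nCounter-style normalization (positive-control
and housekeeping geometric-mean scaling, <10 counts/sample gene filter,
RLE/PCA outlier QC) for validation panels, the published 15-gene signature
definition (9 unfavorable: BET1L, CD2BP2, CD40LG, JUP, KCND2, SNAPC5,
TMEM86B, TRIP10, ZNF785; 6 favorable: ATOH1, FAM173B, GGT6, MTF1, TBC1D3H,
UNC13B), and a synthetic-data generator that plants known prognostic
structure so the whole pipeline is testable offline.  See
`docs/methods.md` for the statistical details.

## Worked example

Simulate a small three-cohort study with 4 unfavorable + 3 favorable
planted genes among 40, screen it, refine the hits, and evaluate the
selected signature on the pooled cohort:

```bash
cat > config.yaml <<EOF
n_cohorts: 3
n_samples: 120
n_genes: 40
n_unfavorable: 4
n_favorable: 3
EOF
prognosig simulate --config config.yaml --seed 7 --out data
prognosig screen   --data data --min-cohorts 2 --out screen
prognosig refine   --data data --screen screen/screen.tsv --beam 100 --max-k 6 --out refine
prognosig evaluate --data data --signature refine/signature.json --out eval
```

which prints:

```
wrote 3 cohorts to data
screened 40 genes: {'excluded': 24, 'unfavorable': 9, 'favorable': 7}
selected 6-gene signature: FAV000, NULL0018, UNFAV000, UNFAV001, UNFAV002, UNFAV003
beam-6gene on pooled (RFS): HR=9.34, logrank p=8e-46, AUC=0.825
```

Reading the output: the screen keeps 16 of 40 genes (all 7 planted genes
plus some false positives — per-gene p values are selection-inflated by
the cut-off optimization, and with `--min-cohorts 2` of 3 the replication
filter is mild); the beam search then concentrates the signal, selecting
five planted genes plus one passenger.  On the pooled cohort the 6-gene
score splits patients into high/low risk groups whose relapse hazards
differ 9.3-fold.  Every stage writes a `manifest.json` with config, seed
and checksums, so reruns are verifiable byte-for-byte.

The same machinery is available as a library, scikit-learn style:

```python
from prognosig import RecurrenceScoreClassifier, Signature

clf = RecurrenceScoreClassifier(signature=Signature.packaged("15gene"))
clf.fit(X, y)                 # X: samples × genes, y: (time, event)
scores = clf.decision_function(X)   # integer recurrence scores, 0..15
risk = clf.predict(X)               # 1 = high risk
```

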