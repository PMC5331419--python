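# arqsar

QSAR modelling toolkit for steroidal androgen-receptor (AR) antagonists:
genetic-algorithm descriptor selection over multiple linear regression
(GA-MLR), rigorous internal/external validation, a leverage-based
applicability domain, virtual-screening ranking with a frozen published
model, and MM/GBSA binding-free-energy bookkeeping.

It is written for computational medicinal chemists who build linear QSAR
models on molecular-descriptor tables (DRAGON-style numeric matrices) and
need the full modelling workflow — curation, variable selection, validation,
domain checking, screening — as tested, scriptable Python rather than a GUI
package.

## The model

Given a training set of n compounds with activities y (pIC50, the negative
log molar IC50) and a curated descriptor matrix X, the workflow searches for
a small multiple-linear-regression model

    pIC50 = b0 + b1 x1 + ... + bp xp

by a genetic algorithm over descriptor subsets of fixed size p, scored by
the Friedman lack-of-fit statistic

    LOF = SSE / (1 - (c + d p)/n)^2,     c = p + 1, d = 0.5,

which penalises SSE by model size. Candidate models are then validated
internally (R², RMSE, leave-one-out Q²(LOO) via the exact hat-matrix
shortcut, leave-many-out Q²(LMO), Y-scrambling) and externally on held-out
compounds via Q²F1, Q²F2, Q²F3 and Lin's concordance correlation
coefficient (CCC).

Predictions are trusted only inside the model's applicability domain,
defined by the leverage h = x̃(X̃ᵀX̃)⁻¹x̃ᵀ (intercept-augmented design) with
warning cutoff h\* = 3(p+1)/n — the Williams plot (h vs standardized
residual) for labelled compounds and the Insubria graph (h vs predicted
activity) for unlabelled screening candidates.

The package ships the published four-descriptor AR-antagonist model

    pIC50 = −2.89·IC5 + 1.01·GATS5e − 3.17·DISPp − 12.99·HATS3u + 27.13

together with its 38-compound activity table, the 110-compound PubChem
screening table, and the per-complex MM/GBSA energy terms of the four
docked AR complexes, all as plain-text package data. Computing descriptors
from structures is out of scope: descriptor tables are consumed as numbers.

## Worked example

```python
from arqsar import (load_published_data, external_metrics, leverage_cutoff,
                    rank_complexes, results_from_predictions, top_hits)

fx = load_published_data()
train, pred = fx.split_frame("train"), fx.split_frame("pred_a")
m = external_metrics(pred.pic50_exp.to_numpy(), pred.pic50_pred.to_numpy(),
                     train.pic50_exp.to_numpy())
print(f"Q2_F1={m['q2_f1']:.3f}  Q2_F2={m['q2_f2']:.3f}  "
      f"Q2_F3={m['q2_f3']:.3f}  CCC={m['ccc']:.3f}")
print(f"h* = {leverage_cutoff(fx.eq4_model.p, fx.eq4_model.n_train):.3f}")

hits = top_hits(results_from_predictions(
    fx.table4.compound_id, fx.table4.pic50_pred, fx.table4.ad_flag), k=3)
print(f"best inside AD: {hits.best_inside_ad.compound_id} "
      f"(pIC50 {hits.best_inside_ad.predicted_pic50:.2f})")
print(f"best overall:   {hits.best_overall[0].compound_id} "
      f"(pIC50 {hits.best_overall[0].predicted_pic50:.2f})")
for t in rank_complexes(fx.table5):
    print(f"{t.complex_id:>14s}  dG_bind = {t.dG_bind:7.2f} kcal/mol")
```

prints

```
Q2_F1=0.736  Q2_F2=0.727  Q2_F3=0.874  CCC=0.890
h* = 0.517
best inside AD: CID_70128824 (pIC50 7.37)
best overall:   CID_70126881 (pIC50 7.90)
  CID_70126881  dG_bind =  -41.61 kcal/mol
  CID_70127147  dG_bind =  -33.06 kcal/mol
  CID_70128824  dG_bind =  -31.86 kcal/mol
    Compound 4  dG_bind =  -22.69 kcal/mol
```

The external statistics recomputed from the 2-decimal activity table agree
with the published 0.739 / 0.731 / 0.876 / 0.891 to rounding; h\* is the
published 0.517. Among the 110 screening candidates, CID_70128824 is the
most active compound inside the structural domain (predicted pIC50 7.37,
above the best experimental training compound at 6.77), while CID_70126881
(7.90) and CID_70127147 (7.76) score higher still but sit outside the
domain, so their predictions are extrapolations. The MM/GBSA binding free
energies of the four docked complexes rank in the same order as the
predicted activities.

## Command line

Every stage is a subcommand of `arqsar` (`simulate`, `curate`, `fit`,
`validate`, `ad`, `screen`, `gbsa`), and `arqsar run` chains
curate → GA-MLR fit → validation → applicability domain → screening with a
manifest. All stages are deterministic under `--seed`.

```
arqsar --seed 7 --out-dir out simulate --correlated-pairs 5 --screen-outliers 26
arqsar --seed 7 --out-dir out run
```

Because real descriptor tables are proprietary, the `simulate` subcommand
(and the `arqsar.synthetic` module) generates descriptor/activity data with
the same statistical shape — 29 training / 7 external / 110 screening rows,
358 columns, a planted 4-descriptor linear signal, near-duplicate column
pairs, and screening rows constructed inside and outside the training
leverage domain — so the whole pipeline is exercisable end to end.

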