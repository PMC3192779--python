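# receptorsig

Multi-gene expression signatures for calling estrogen receptor (ER),
progesterone receptor (PR) and ERBB2 (HER2) status in breast tumor gene
expression profiles.

Public repositories hold thousands of breast tumor microarray profiles, but
the clinical receptor status established by IHC/FISH is often missing from
the deposited metadata, limiting their reuse for biomarker and target
discovery. `receptorsig` implements a pipeline that derives a multi-probe-set
*signature* predictive of a receptor's status from a training cohort with
known clinical labels, and then calls the status of unlabeled cohorts:

1. **Rank** every probe set by the Spearman rank correlation ρ between its
   expression vector and the binary clinical status (mid-ranks for ties;
   negative = 0, positive = 1).
2. **Sweep** a grid of correlation cutoffs *c*; each candidate signature is
   the probe sets with |ρ| ≥ *c* (candidates are nested: a higher cutoff
   selects a subset of a lower one).
3. **Call** each sample's status for each candidate by k-means clustering
   (k = 2, Euclidean, 25 seeded restarts) of the samples in signature space;
   the cluster whose centroid scores higher under
   score = mean(sign(ρᵢ) · centroidᵢ) is the positive cluster.
4. **Select** the cutoff maximizing sensitivity + specificity against the
   clinical labels. If the sweep is flat (every cutoff performs identically)
   a second training cohort resolves the choice; ties break toward the
   larger cutoff (smaller signature).
5. **Validate** on independent cohorts — clustering is re-run per cohort,
   only the signature transfers — reporting accuracy, sensitivity,
   specificity, PPV, NPV, a two-sided Fisher exact p, and cross-dataset
   95% t-intervals.

The literature baseline is also included: a single marker probe set
(e.g. 205225_at/ESR1 for ER) called by fitting a two-component Gaussian
mixture to its bimodal expression distribution with EM and assigning samples
to the higher-mean component by posterior probability.

A synthetic-data generator plants known marker structure (bimodal marker
probes tracking a latent state, background probes, label noise emulating
imperfect clinical assays) so the whole pipeline is testable with exact
ground truth and a closed-form expected operating point.

## Worked example

Derive a signature from two planted synthetic training cohorts (300 samples,
12 positively + 8 negatively tracking markers at effect size Δ/σ = 3,
2000 background probes, 5% label noise) and validate on a third:

```python
import receptorsig as rs

shape = dict(n_samples=300, n_pos_markers=12, n_neg_markers=8,
             n_background=2000, delta=3.0, sigma=1.0, label_noise=0.05)
e1, c1, truth = rs.generate(rs.SyntheticConfig(seed=42, **shape))
e2, c2, _    = rs.generate(rs.SyntheticConfig(seed=500042, **shape))

model = rs.SignatureDiscovery(e1, c1, e2, c2)
res = model.fit(cutoff_grid=rs.default_grid(0.20, 0.60, 0.10), seed=1)
print(res.summary())
```

```
Receptor signature discovery (ER)
========================================================
training samples        300
probes ranked           2020
cutoff grid             0.20 .. 0.60  (5 points)
selected cutoff         0.60  (secondary training set used: primary sweep flat)
signature size          20 probe sets
best probe (signed rho) SYN_000003  rho=0.74
--------------------------------------------------------
training performance (vs clinical status):
  accuracy     94.33 %
  sensitivity  97.19 %
  specificity  90.16 %
  PPV          93.51 %
  NPV          95.65 %
  Fisher p    7.22e-61
```

The derived 20-probe signature is exactly the planted marker set. On clean
planted data the sweep is flat — every cutoff that isolates the markers
performs identically — so the model transparently falls back to the second
training cohort, and the larger-cutoff tie-break picks the most parsimonious
signature. Training sensitivity/specificity sit at the ceiling imposed by
the 5% label noise (the analytic operating point is 95%/95%), not at 100%:
the clustering recovers the molecular state almost perfectly, and the
residual "errors" are the flipped clinical labels. Validation on a fresh
cohort behaves the same:

```python
ev, cv, _ = rs.generate(rs.SyntheticConfig(seed=777, **shape))
rep = res.evaluate(ev, cv)
# acc=93.33% sens=96.17% spec=88.89% ppv=93.12% npv=93.69% fisher_p=2.22e-56
```

Evaluating a published validation table (the 24-gene ER signature on the
286-sample GSE2034 cohort) reproduces the reported percentages:

```python
from receptorsig.published_tables import VALIDATION_TABLES
print(rs.metrics(VALIDATION_TABLES[("ER", "GSE2034", "signature")]).to_text())
```

```
tp      183
fp      9
tn      68
fn      26
accuracy        87.76
sensitivity     87.56
specificity     88.31
ppv     95.31
npv     72.34
fisher_p        7.51724e-34
```

i.e. of 209 clinically ER-positive tumors the signature calls 183 positive
(sensitivity 87.56%), of 77 negative tumors it calls 68 negative
(specificity 88.31%), and the association is far beyond chance.

The same workflow is available from the shell:

```sh
receptorsig simulate --out train --seed 42
receptorsig simulate --out train2 --seed 500042
receptorsig derive --expr train/expression.tsv --clinical train/clinical.tsv \
    --expr2 train2/expression.tsv --clinical2 train2/clinical.tsv \
    --grid 0.2,0.6,0.1 --seed 1 --out run
receptorsig evaluate --signature run/signature.tsv \
    --expr valid/expression.tsv --clinical valid/clinical.tsv --out run_eval
```

## Packaged signatures

The three published signatures ship as TSV fixtures (24-gene ER at cutoff
0.43, 35 probe sets; 14-gene ERBB2 at 0.35, 19 probe sets; 51-gene PR at
0.38, 61 probe sets) loadable with `rs.load_published_signature("ER")`. The
files carry the published coefficients; per-row probe-set IDs use
gene-symbol placeholders (see `receptorsig/signatures/`) except the probe
IDs that are public (205225_at, 203497_at, 219197_s_at). Re-deriving the
real signatures requires the original GEO cohorts (GSE3494, GSE2034,
GSE7390, GSE2603, GSE20271, GSE20194, GSE16446, GSE9195) after fRMA
normalization, which this package does not download or perform.

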