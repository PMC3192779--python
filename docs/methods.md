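# Methods

## The problem and the model

Breast tumor cohorts profiled on Affymetrix GeneChips (HG-U133A: 22,283
probe sets) carry a clinical receptor status — ER, PR or ERBB2 — established
by protein-level (IHC, enzymatic immunoassay, ligand binding) or DNA-level
(FISH) assays. The package derives, from a training cohort with known
status, a *signature*: the set of probe sets whose Spearman rank correlation
with the binary status exceeds a cutoff in absolute value, each retained
with its signed coefficient. Status of any cohort is then called by 2-means
clustering of the samples in the signature's probe space.

The method makes three substantive assumptions:

* **Monotone association.** Informative probes are monotonically related to
  status, so Spearman correlation (Pearson on mid-ranks, average ranks for
  ties, status encoded negative = 0 / positive = 1) is the right ranking
  statistic. Probes with zero rank variance have undefined correlation and
  are excluded explicitly rather than silently scored 0.
* **Two-population structure.** In signature space the cohort splits into a
  receptor-positive and a receptor-negative clump, recoverable by Euclidean
  k-means with k = 2 on the (log-scale, already normalized) expression
  values. No per-probe standardization is applied: inputs are assumed on a
  common log scale (the shape of fRMA output), and rescaling would distort
  the relative weight of strongly bimodal probes.
* **Per-cohort calling.** Absolute intensity levels are not comparable
  enough across cohorts and platforms to transfer centroids; clustering is
  re-run on every cohort and only the signature (the probe list and signs)
  transfers from training to validation.

## Signature selection

Candidates are swept over a cutoff grid (default granularity 0.01; any
strictly increasing grid is accepted). Selection uses |ρ| ≥ c, which admits
anti-correlated probes — the ERBB2 and PR signatures genuinely contain
negative blocks — and guarantees nesting: the signature at a higher cutoff
is a subset of that at a lower one. Each candidate is scored by calling the
training samples and computing sensitivity + specificity against the
clinical labels; the maximizing cutoff wins.

Two edge rules matter in practice:

* **Flat sweeps.** When the summed metric varies by less than 0.5
  percentage points across the grid (at a few hundred samples, less than a
  one-sample change in either metric), the training set cannot discriminate
  between cutoffs and a second training cohort is required; its sweep then
  decides. This is not an exotic corner: on well-separated data every
  cutoff that isolates the informative probes performs identically, so the
  fallback is the expected path for clean cohorts, and the error message
  says exactly that.
* **Ties.** Equal maxima break toward the larger cutoff, i.e. the smaller
  signature — parsimony as the explicit tie-break. Combined with the flat
  fallback this makes the whole selection deterministic.

Cluster orientation — which cluster is "positive" — uses the sign-weighted
centroid mean, score = mean over entries of sign(ρ)·centroid coordinate.
For an all-positive signature this reduces to "the high-expression cluster
is positive"; with negative entries it generalizes to "high on positively
correlated probes and low on negatively correlated ones". An exact score
tie is surfaced as an error rather than resolved arbitrarily. k-means uses
25 seeded restarts keeping the lowest within-cluster sum of squares, making
calls bit-reproducible for a fixed seed.

## The single-probe EM baseline

The comparison method calls status from one probe set's bimodal intensity
distribution: a two-component univariate Gaussian mixture with unequal
variances, fitted by EM (initialized from a seeded 2-means split; stopped
at log-likelihood gain < 1e-8 or 500 iterations; full likelihood trace
recorded and checked non-decreasing). A variance floor of 1e-4
(log-intensity²) prevents degenerate spikes on replicated values; hitting
it is flagged on the fit. Samples are assigned to the higher-mean component
when its posterior is ≥ 0.5, the boundary itself counting as positive; for
equal variances this is exactly the weighted-midpoint intensity threshold.
Unequal variances are the default because positive and negative intensity
modes in receptor data have visibly different spreads. Externally supplied
single-probe calls (e.g. bimodality calls distributed with a cohort's
metadata) can be used instead of fitting by supplying them as a
clinical-table-shaped file.

## Evaluation battery

Positive means clinically receptor-positive throughout. From the 2×2
confusion matrix: accuracy = 100(tp+tn)/n, sensitivity = 100·tp/(tp+fn),
specificity = 100·tn/(tn+fp), PPV = 100·tp/(tp+fp), NPV = 100·tn/(tn+fn);
a zero denominator flags that metric undefined (NaN) without affecting the
others. Association is tested with the two-sided Fisher exact test summing
hypergeometric probabilities of all tables at most as likely as the
observed one (the R `fisher.test` convention; scipy implements it, and the
test suite checks it against a full-enumeration oracle). Cross-dataset
uncertainty for a metric is the t-interval mean ± t₀.₉₇₅,ₙ₋₁·sd/√n over the
per-dataset values, deliberately unclamped — with three datasets an upper
bound above 100% is a legitimate and informative outcome. Signature vs
baseline comparisons use a two-sided t-test, paired by dataset by default
(the same cohorts evaluated under both methods); identical vectors make the
paired test degenerate and raise rather than fabricating a p-value.

One labeling caveat is worth documenting for users reconciling against
published tables of this kind: reported sensitivity/specificity pairs
occasionally swap the conventional roles (the reporting orientation of the
2×2 table is easy to transpose). The package always computes the
conventional definitions and reports the raw confusion matrix alongside, so
any such discrepancy is visible rather than hidden.

## Synthetic data and what it shows

The generator plants k = k⁺ + k⁻ marker probes (positively and negatively
tracking a latent Bernoulli(prevalence) state via a mean shift ±Δ),
background probes N(baseline, σ²), and clinical labels equal to the state
flipped with probability ε. Defaults (300 samples, prevalence 0.6, 12 + 8
markers, 2000 background probes, Δ/σ = 3, ε = 0.05, baseline 7 on the log₂
intensity scale) mirror a few-hundred-sample cohort with a dominant
receptor-positive class, strong marker separation, and the few-percent
clinical-assay discordance that motivates transcriptional status calling in
the first place.

An ideal midpoint threshold on the sign-aligned marker mean separates the
classes at d = Δ√k/σ, so its expected sensitivity and specificity are

    (1 − ε)·Φ(d/2) + ε·(1 − Φ(d/2)),

which the package exposes as `expected_operating_point` and uses as the
recovery oracle: label noise, not clustering error, sets the performance
ceiling (95% at the defaults). Passing tests on this generator demonstrate
that the pipeline recovers planted monotone mean-shift structure and hits
its analytic operating point; they do not exercise real-data complications
— correlated background genes, batch structure, heavy-tailed intensities,
platform differences, or markers with unequal effect sizes — and results on
real cohorts depend on those.

## Numerical and design choices

* Ranking is vectorized mid-rank Pearson; values are clipped to [-1, 1]
  against floating-point overshoot and checked against `scipy.spearmanr`
  to 1e-12 in tests.
* Empty selections during a sweep produce an explicit n_probes = 0 point
  with NaN metrics; they are never silently dropped, and `choose_optimal`
  ignores them.
* Cross-dataset duplicate removal is by exact sample-identifier match
  against a caller-supplied ID list; how duplicates were identified is
  cohort-specific curation, not something the package can infer.
* The best single probe is the maximal *signed* ρ (ties lexicographic),
  matching how the reference probe sets for ER/ERBB2/PR were chosen; an
  |ρ|-maximal variant would differ only for signatures dominated by
  negative correlations.
* Worked-example study sizes: the acceptance script runs planted recovery
  at 50 seeds × (300 samples × 2,020 probes, two training cohorts, grid
  0.20–0.60 step 0.10) and operating points on three 500-sample cohorts —
  sizes at which the binomial noise on a percentage is a fraction of the
  tolerances used, while the whole script completes in well under a minute.

## Known limitations

* Cross-platform application is by shared probe-set ID only; no remapping.
  Signatures derived on one platform measurably lose specificity on
  another, as the PR case shows.
* The flat-sweep tolerance (0.5 pp) and the k-means restart count (25) are
  pragmatic constants; pathological cohorts straddling the tolerance could
  flip between the one- and two-training-set paths.
* The EM baseline assumes a genuinely bimodal marker; on unimodal inputs it
  converges to an arbitrary split of one mode (the variance floor keeps it
  finite but not meaningful).
* The generator's homoscedastic, independent-probe model is the minimal
  structure for consistency of both predictors, chosen deliberately;
  conclusions about robustness to correlated noise require a richer
  simulator.
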