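# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## RPPA normalization

Input is an analyte-by-sample intensity matrix (raw linear scale) with
optional per-analyte annotations (`species`, `is_phospho`). Processing
is annotation-driven; no analyte counts are hard-coded.

* **Species filter.** Antibodies raised against the host species give
  unspecific signal in xenograft material and are removed before
  normalization. Unannotated analytes are kept and logged rather than
  guessed at.
* **log2 transform.** `log2(value + offset)` with offset defaulting to
  0 and an explicit error on non-positive cells — no silent
  pseudo-count. Missing readings propagate as missing.
* **Bidirectional median-centering.** Exactly one row (antibody) pass
  followed by one column (sample) pass, no iteration to convergence.
  The column pass runs on the row-centered matrix, so output column
  medians are exactly zero while row medians retain only the
  perturbation introduced by the column pass. The median of an
  even-length vector is the mean of the two central order statistics
  (the conventional definition). Missing cells are ignored when
  medians are computed and propagated unchanged; a row or column with
  no observed value at all is an error, not an imputation target.

## Pathway activity score

PAS is a plain signed sum — no averaging by set size, no weighting:
`PAS(s) = Σ positives − Σ negatives` over normalized log2 values.
Consequences worth knowing: PAS is linear in the matrix, invariant to
analytes outside the set, and its magnitude grows with set size, so
scores are comparable across samples within one pathway but not
across pathways of different sizes.

* An empty realized intersection (no set member present in the matrix)
  is an error; PAS never silently returns 0.
* Under `missing_policy="skip"`, missing member readings are omitted
  from that sample's sum and the event is logged; the default policy
  errors instead, because a sum over differing member subsets is not
  comparable across samples.
* ΔPAS ties (`delta == 0`) are classified **Down**, so Up strictly
  means an increase; ties are measure-zero on real data.
* The shipped SRC-family regulator set in the paired generator (SRC,
  FYN, LYN, YES1 positive; SRC pY527 negative, the autoinhibitory
  site) is a synthetic stand-in assembled for testing, not a curated
  transcription of any published regulator table; real analyses should
  supply their own signed gene-set file. Replicate antibodies against
  the same protein are treated as distinct analytes (no averaging).

## Gated two-group comparison

Shapiro-Wilk runs per group at level alpha (default 0.05); the Welch
*t*-test (unequal variances, two-sided) is used when **both** groups
pass, otherwise the two-sided Mann-Whitney *U*. Triggering on either
group's rejection is the conservative reading of a "data not normal →
rank test" rule. Groups need n ≥ 3 (the Shapiro minimum). Under both
normal and lognormal nulls the empirical type-I error at alpha 0.05
stays within [0.035, 0.065] (1000 replicates, asserted in the tests).

## Survival stratification and comparison

* **Quantile convention.** Per-gene thresholds use the
  linear-interpolation quantile (numpy default) between order
  statistics; the comparator is strictly `>`. With 40 distinct values
  and q = 0.75 this yields exactly 10 High samples. Reproducing any
  published High/Low split can be sensitive to this convention —
  nearest-rank or exclusive-interpolation quantiles shift thresholds
  by up to one order statistic.
* **Union rule.** `combine="any"` implements "High in at least one
  panel gene"; the High fraction is therefore monotone in panel size.
* **Kaplan-Meier.** Standard product-limit estimator; at tied times,
  events are counted before censorings leave the risk set. The median
  is the smallest event time with S(t) ≤ 0.5 and is undefined when S
  never reaches 0.5.
* **Log-rank.** Hypergeometric variance with tie correction;
  chi-square = (O₁−E₁)²/V on 1 df. The reported hazard ratio is the
  O/E (Pike) ratio (O₁/E₁)/(O₀/E₀), chosen because it derives directly
  from the log-rank table. **Known attenuation:** when nearly every
  subject has an event and the true ratio is far from 1, the O/E ratio
  is biased toward the null — on simulated cohorts with true HR 3,
  n = 400 and essentially complete follow-up, the median estimate is
  ≈ 2.5, while a Cox proportional-hazards fit on the same data
  recovers 3.0 (both measured in the test suite). When an unbiased
  estimate matters, fit a proportional-hazards model; the O/E ratio is
  reported for its transparency and direct link to the test.
* Disease-free-interval tables without a censor flag are treated as
  all-events; supply `event=False` records for censored subjects.

## Growth efficacy

Caliper volume V = W²·L·0.5 with validation that width ≤ length.
The inclusion window is half-open (60, 200] mm³ at the treatment-start
day and is a configuration parameter, since palpable-at-implantation
and at-treatment windows differ between protocols. AUC uses the
trapezoid rule on the measured days of the **relative**-volume curve
(start = 1); an absolute-volume AUC can be computed by integrating
`GrowthSeries.volumes` directly, but relative AUC is the default
because it is invariant to absolute-size rescaling and matches
relative-tumor-volume reporting. Series ending before the requested
end day are integrated to their last measurement and flagged — never
extrapolated; tumors outside the window are reported excluded, never
silently dropped.

## Network hubs

The confidence filter (≥ 0.9, "highest confidence" convention) and the
gene restriction are applied **before** degrees are counted, mirroring
a retrieval-then-filter workflow; the hub threshold is strict
(degree > 2). Degrees are simple-graph degrees (duplicate pairs
collapse to the maximum confidence; self-loops are rejected). The
degree threshold counts edges within the restricted subgraph, not
against the full interaction database. Top-n DEG selection filters
padj < 0.05 first, ranks by |LFC| descending, and breaks ties by gene
id for determinism.

## Synthetic generators

All generators are pure functions of `(config.seed, parameters)`; each
draws from a named substream (`seed`, stream-id pairs fed to numpy's
`default_rng`), so adding a generator never perturbs another's draws.
Defaults are chosen to mirror the study designs the stages serve:

* **RPPA** (`gen_rppa`): 100 analytes × 6 samples/group,
  antibody-effect SD 1.0, sample-effect SD 0.5, noise SD 0.25 log2
  units, planted shift 1.0 on a 5-positive/1-negative pathway, 10%
  mouse antibodies. `value = 2^(μ_a + ν_s + δ + ε)` — exactly the
  location-effect structure the bidirectional centering removes.
* **Survival** (`gen_survival`): n = 40 (a typical metastatic-cohort
  TNBC subset), true HR 3.2, baseline hazard 0.0066/month (exponential
  median ≈ 105 months for the Low group), censor rate 0.001/month
  (near-complete follow-up: disease-free-interval cohorts of
  metastatic patients observe essentially all events), High fraction
  0.6 (a union-of-three-genes prevalence). High labels are drawn
  first, then one panel gene per High sample is shifted +3 log2 units,
  so truth labels are exact by construction. Times are rounded to 0.1
  month to exercise tie handling.
* **Growth** (`gen_growth`): 7 animals/arm, growth rate 0.05/day
  (control tripling in ≈ 3 weeks), twice-weekly caliper schedule over
  3 weeks, lognormal start volumes resampled into the inclusion
  window, 5% multiplicative measurement noise, treatment multiplier
  0.5 (a growth-halving agent). Calipers are back-computed at aspect
  ratio 1.3 so W²·L·0.5 reproduces the simulated volume exactly.
* **Paired** (`gen_paired`): 10 patients, 6 responders, shift 2.0 log2
  units per regulator, 2 screening-only samples. Pathway-member values
  are carried from pre to post unchanged except for the responder
  shift, so Up/Down truth is exact rather than noise-flipped;
  background analytes are redrawn with noise.
* **Edges** (`gen_edges`): 60 genes, 3 hubs of degree 5 at confidence
  0.95 over disjoint leaves, background pairs below the 0.9 floor —
  non-hub high-confidence degree is ≤ 1 by construction.

What the generators deliberately do **not** emulate: real marginal
distributions (RPPA intensity heavy tails, fkpm dispersion),
between-antibody correlation, proportional-hazards violations,
Gompertzian growth deceleration, or scale-free network topology.
Passing tests therefore demonstrate that the estimators and filters
are implemented correctly under their own assumptions — not that those
assumptions hold in any particular clinical dataset.

## Problem sizes in the test and acceptance runs

Simulation-based checks use 100–1000 replicates at cohort sizes
40–400: large enough that Monte-Carlo error is well inside each
asserted band (e.g. a 1000-replicate null rejection rate has standard
error ≈ 0.007), small enough to run interactively.

## Known limitations

* The O/E hazard-ratio attenuation described above.
* `stratify` requires complete expression rows for panel genes;
  imputation is out of scope.
* The log-rank implementation covers exactly two groups (df = 1);
  multi-group trend tests are not provided.
* Differential expression and moderated linear-model protein testing
  are consumed as input tables, not reimplemented.
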