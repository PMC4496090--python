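# Methods

## The model

`glycograph` analyses how lifestyle changes and genetic predisposition
jointly drive 12-month changes in glycaemic traits, using a chain-graph
(graphical Markov) model estimated by *sequences of regressions*.

Variables are arranged in ordered boxes reflecting the order of exposure,
rightmost = intrinsic, leftmost = final responses:

```
outcomes | Δweight | Δsatfat, Δsteps | arm | age, sex, country, GPS
```

* **outcomes** — log final/baseline ratios of HOMA-IR, HOMA-B, fasting
  glucose and HbA1c.  On the log scale a 12-month change is a ratio:
  `Δlog y = ln(y_12 / y_0)`, 0 meaning no change.  The four outcomes are
  interrelated but analysed separately, each with its own selected model;
  they share one box and are never regressed on one another.
* **Δweight** (kg, negative = loss), **Δsatfat** (percentage points of
  total energy from saturated fat), **Δsteps** (thousands of steps/day);
  Δsatfat and Δsteps are stacked (same box, mutually unrelated).
* **arm** — randomised treatment (SC standard care, CP commercial
  programme).  Because assignment is randomised it is a *source-only*
  node: no regression is fitted for it.
* **intrinsic** — age (years), sex, country (UK/AU/DE), and the T2DM
  genetic predisposition score (GPS): the unweighted count of risk alleles
  over the retained SNP panel (range 0 to 2 × panel size).

Each modelled response is fitted by OLS on *all* variables strictly to its
right (categorical variables dummy-coded against a reference: female, UK,
SC).  The explanatory set is then pruned by backward elimination: the term
whose removal has the largest partial-F p value is dropped while that p
value exceeds `selection_alpha` (default 0.05); dummy blocks move as a
whole.  Prespecified, clinically motivated interactions (GPS × Δweight,
Δweight × Δsatfat, arm × Δweight, arm × Δsatfat for each outcome) are then
screened by nested F-tests against the selected model and added greedily
when significant, with their main effects forced in (hierarchy principle).

The graph is read off the selected models: a directed edge (arrow) for
every retained term with p < `edge_alpha` (default 0.10, a deliberately
more liberal display threshold), annotated `coefficient (SE), p`;
interaction terms are drawn as dashed edges from a product pseudo-node.
Rightmost-box pairs are tested marginally (Pearson t-test, one-way F, or
chi-square, by type) and connected by undirected lines when associated at
`edge_alpha`.  A missing edge states conditional independence given the
selected explanatory sets.  No multiplicity adjustment is applied across
models: each displayed test addresses a distinct, individually
interpretable association.

Path-based prediction evaluates a fitted outcome model at a covariate
profile (for example, mean Δweight and Δsatfat with GPS at its lower or
upper quartile) and exponentiates the linear predictor into a
final/baseline ratio; `100·(ratio − 1)` is the percent change.

## Genotype QC and the predisposition score

* SNPs with call rate < 0.95 are excluded; individuals with ≥ 3 missing
  genotypes are excluded (both configurable).
* Hardy–Weinberg equilibrium is tested per SNP with the log
  likelihood-ratio chi-square (G) test, 1 df:
  `G = 2 Σ O ln(O/E)` with expectations from the ML allele frequency; the
  exclusion cut-off is Bonferroni-corrected, `alpha / m` with `m`
  defaulting to the pre-QC panel size (0.05/25 = 0.002).  Monomorphic SNPs
  are reported as degenerate but never auto-excluded.
* LD between same-locus SNPs is reported as composite r²: the squared
  Pearson correlation of allele counts over complete pairs (phase-free).
* Sporadic missing genotypes are mean-imputed per SNP (preserving the
  observed mean exactly) before scoring; the GPS is the (optionally
  weighted, by default unweighted) allele-count sum.
* VCF/PLINK-raw ingestion re-orients dosages to the panel's risk allele.
  Strand flips of A/T and C/G SNPs are undetectable, so for those SNPs an
  orientation that would require the other-allele labelling (exactly what
  a flip produces) is a hard error rather than a guess.

## Trait derivation

* HOMA indices use the closed-form HOMA1 equations,
  `HOMA-IR = G·I/22.5` and `HOMA-B = 20·I/(G − 3.5)` % with insulin in
  µU/mL (pmol/L ÷ 6.0 by default).  This is a deliberate deviation from
  the HOMA2 computer model, which has no published closed form; per-index
  multiplicative calibration factors (default 1.0) let users rescale
  toward HOMA2 output, and precomputed `homa_*` columns, when present in
  the phenotype table, are used verbatim.  HOMA-B is undefined (missing,
  record retained) at glucose ≤ 3.5 mmol/L.
* Saturated fat: `%E = 100 · g · 37 kJ/g / energy`; energy accepted in kJ
  or kcal with an explicit unit flag.  NSP ≈ 0.75 × AOAC fibre.
* Steps: the 7-day pedometer diary is averaged over non-missing days,
  requiring ≥ 4 of 7 by default (full weeks are the ideal; real diaries
  have gaps).  Changes are expressed in thousands of steps/day.
* HbA1c is carried in mmol/mol; an NGSP-%-to-IFCC converter is provided
  for ingestion only.
* Derivation is complete-case on the required baseline/12-month fields,
  with per-record exclusion reasons logged.

## Numerical choices

* **Centred products.** Interaction columns are built from mean-centred
  continuous components (sample means of the response's complete-case
  set, stored on the fit and reused at prediction time).  This is a pure
  reparametrisation — the model span, RSS and interaction tests are
  unchanged — but it keeps products near-orthogonal to their main
  effects.  Without it, a product such as GPS × Δweight (raw GPS mean
  ≈ 21) is ≈ 0.99-collinear with Δweight and a spuriously screened-in
  interaction can mask a genuine main effect.  Main-effect coefficients
  are therefore effects at the interaction partners' means, matching the
  fixed-mean-covariate style of the interaction depictions.
* Complete cases per response are fixed from the response's *full*
  right-hand variable set so every nested comparison runs on identical
  rows; per-model n is reported.
* Elimination ties are broken towards the smaller minimum |t| within the
  term, then lexicographically; screening ties towards the smaller p,
  then name.  Both make the procedure fully deterministic.
* Rank-deficient designs raise a collinearity error naming the aliased
  columns (pivoted-QR diagnosis).  Intercept-only models are legal
  fixed points of selection.  Zero response variance makes R² undefined
  (error), monomorphic SNPs make LD undefined (error).
* DOT output is assembled deterministically (sorted nodes and edges,
  fixed label formats) so identical runs are byte-identical.

## The synthetic-cohort generator

No deposited data exist for the emulated trial, so the generator is a
first-class module producing cohorts with the causal structure the
analysis assumes, plus a queryable ground truth (every edge, coefficient
and noise draw).  Generation order: age ~ N(49.3, 12.6²); sex (86.8%
female); country (UK 0.4 / AU 0.3 / DE 0.3); genotypes binomial(2, f) under
HWE with per-SNP risk-allele frequencies drawn once uniformly from
[0.2, 0.8] (the published panel frequencies are not public) and ~1% MCAR
missingness; GPS by mean-imputed summation; randomised arm (50% CP); then
the lifestyle and outcome equations, each linear in its parents plus
Gaussian noise (log scale for outcomes).

Planted defaults follow the published trial results where printed:

| edge | value | origin |
|---|---|---|
| arm → Δsatfat | −1.13 %E | printed |
| arm → Δweight | −3.53 kg | printed |
| Δsatfat → Δweight | 0.20 kg/%E | printed |
| Δsteps → Δweight | −0.18 kg/1000 steps | printed (as "0.18 g", read as kg) |
| GPS → baseline glucose / HbA1c / HOMA-B | 0.04 mM, 0.21 mmol/mol, −1.30 % per allele | printed |
| GPS → Δlog HOMA-IR | −0.0225 | from the printed quartile predictions (−7% at GPS 20, −15% at GPS 24) |
| GPS → Δlog glucose | −0.00476 | from the printed quartile predictions (+0.05%, −1.84%) |

The remaining slopes, intercepts and residual SDs are package defaults,
calibrated analytically (never against test outcomes) to three published
summaries: the variance-explained band of the outcome models (≈ 7–18%),
Table-level baseline means/SDs, and the qualitative interaction patterns
(diet quality matters more at smaller weight loss; weight loss moves
HOMA-B only in the CP arm; HbA1c gains from satfat reduction only under
CP).  The calibration targeted an effective per-term noncentrality ≥ 4.5
at n = 2000 in the final true model, computed from the true design
covariance, so that the default configuration is a strong-signal setting
in which structure recovery is informative.  Sex/country shifts on
Δsatfat (male +0.8, DE −1.0, AU −0.4 %E) and small age/country effects on
the outcomes are of realistic magnitude for multi-centre dietary data.

Consistency of the raw table: month-12 glucose, HbA1c, HOMA-IR and HOMA-B
reproduce the planted log-ratios exactly, and insulin_12 is reconstructed
so the closed-form HOMA-IR ratio equals the planted one
(`I_12 = I_0 · exp(Δlog IR − Δlog glucose)`).  HOMA-B is carried as its
own column pair: the closed form ties HOMA-B to the same two primitives as
HOMA-IR, so all four outcomes cannot be simultaneously consistent with
two measured quantities — mirroring the fact that the emulated study took
HOMA values from the HOMA2 computer model rather than the closed form.

What the generator does **not** emulate: LD between panel SNPs,
population structure, informative dropout (attrition is
completely-at-random), laboratory between-centre assay differences,
dietary under-reporting, or negative step counts in extreme tails.
Passing recovery tests therefore show that the engine recovers the
assumed data-generating structure at realistic effect sizes and n — not
that the original trial's estimates are reproduced, which is impossible
without its private data.

## Problem sizes used

Structure/parameter recovery is benchmarked at n = 2000 per cohort — the
strong-signal scaling of the ~353-participant study — with 200 replicates
in the test suite and 100 in `scripts/acceptance.py`; both report mean
edge TPR, the per-edge recovery minimum, the spurious-edge rate
(eligible-pair denominator) and coefficient RMSE/2-SE coverage.  The
deterministic exclusion-cascade and SNP-QC fixtures reproduce the
published marginal counts (772 → 442 → 402 → 370 → 353; 25 → 21 SNPs)
exactly and run in well under a second.

## Known limitations

* Backward elimination explores one path through the model space; the
  search strategy of the original analysis is unpublished.  An exhaustive
  best-subset search is deliberately out of scope for > 12 terms.
* The symmetric (rightmost-box) associations are tested marginally, not
  conditionally on the other box members; the original choice is
  unstated.
* The GPS-quartile predictions and variance-explained figures computed on
  synthetic cohorts land near the published values by construction of the
  generator defaults; they are illustrations of the machinery, not
  replications.
* HOMA1 output differs from HOMA2 in level (roughly half for IR at normal
  glucose); log-*ratios* are far less sensitive to the index family, which
  is why the outcomes are defined on ratios.
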