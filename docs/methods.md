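# Methods

## Model

`cmbnet` models 18 categorical variables describing US adults as a
discrete Bayesian network: a directed acyclic graph G plus one conditional
probability table (CPT) per node, factorizing the joint distribution as
P(X | G, Θ) = ∏ᵢ P(Xᵢ | pa(Xᵢ)). The variables sit in six knowledge
tiers, in descending order: non-modifiable socio-demographics (age band,
gender, ethno-racial group), modifiable socio-demographics (education,
income as a federal-poverty-level ratio band, employment), social
determinants of health (household food security, health insurance,
routine healthcare site), behavioral factors (DASH-diet accordance,
physical activity, alcohol use, smoking status), the four secondary
cardiometabolic drivers (ABCD, DBCD, HBCD, LBCD; each staged 0–4), and
the overall CMBCD category (Stage 0 / Stage 1 / Stage 2–4).

## Clinical staging

Each driver is staged 0 (no disease, no risk factors), 1 (risk factors),
2 (pre-disease), 3 (disease), 4 (pre-disease or disease with
complications). Stage semantics are fixed; the numeric cut-offs live in a
`StagingRuleSet` value object (YAML-overridable) with defaults from
standard clinical categories: BMI 25/30 kg/m² (overweight/obesity), FPG
100/126 mg/dL and HbA1c 5.7/6.5 % (ADA pre-diabetes/diabetes), SBP
120/130 and DBP 80 mmHg (elevated/hypertension), LDL 130/160, TG 150/200,
HDL < 40 mg/dL (borderline/high lipids). A recorded history of clinical
CVD (congestive heart failure, coronary artery disease, heart attack,
stroke) counts as a complication for every driver. The overall CMBCD
category follows a three-case rule on (CVD history, driver stages); the
one combination the rule does not cover — CVD history with all drivers at
stage 0 — is classified Stage 2–4 (history dominates) with a warning, so
the map is total. Continuous fields are banded closed-on-the-left (age
[20,40), [40,60), [60,∞); FPL ratio [0,1), [1,2), [2,4), [4,∞); alcohol 0
/ (0,3] / (3,14] / (14,∞) drinks per week), so band edges partition each
domain.

Exclusions mirror the study design: records with any missing model
variable, age under 20, pregnancy, or type 1 diabetes are dropped; the
tally attributes each record to the first applicable criterion in that
order.

## Constrained structure learning

Search runs over DAGs by greedy hill-climbing: from the whitelist-only
graph, repeatedly apply the best strictly score-improving single-arc
addition, deletion, or reversal, subject to the constraint system — no
blacklisted arc may be added, no whitelisted arc deleted or reversed, and
every move must keep the graph acyclic. The blacklist encodes the tier
ordering (no arc into a strictly higher tier), protects the
non-modifiable demographics from incoming arcs, and forbids direct
ethno-racial → driver/CMBCD arcs; the whitelist mandates the driver
hierarchy (default ABCD→DBCD, ABCD→HBCD, ABCD→LBCD, DBCD→HBCD,
DBCD→LBCD — adiposity as the most proximal driver — configurable) and the
four driver→CMBCD arcs. Within-tier arcs are unconstrained in both
directions.

The default score is BIC: for node i with rᵢ levels and qᵢ parent
configurations, Σⱼₖ Nᵢⱼₖ ln(Nᵢⱼₖ/Nᵢⱼ) − ½ ln(N) qᵢ(rᵢ−1), with
0·ln(0/·) ≡ 0 and N the post-exclusion record count. BIC is
penalty-parameter-free and decomposable, which the move evaluation
exploits through a family-score cache; BDeu (imaginary sample size
configurable) is available as an option. Tie-breaking among equal-gain
moves is lexicographic by (operation: add < delete < reverse, source,
target), making the search bit-reproducible; gains must exceed 1e-9 to
count as improvements, which guards against floating-point cycling.
No random restarts or tabu list are used by default.

## Bootstrap averaging and the significance threshold

Structure confidence comes from nonparametric bootstrap: B (default 200)
resamples of size n with replacement, each relearned with the same
constraints; an adjacency's strength is its inclusion fraction across
replicates, with a separate orientation frequency among inclusions.
Replicate b draws its resample from the RNG stream `SeedSequence([seed,
b])`, so tables are reproducible and replicates independent of B.

The significance threshold minimizes the L1 distance between the
empirical CDF of observed strengths and an idealized two-point CDF that
puts mass only on {0, 1}: for candidate t, the idealized CDF places
P(0) = share of strengths ≤ t. Because the objective is piecewise linear
between observed values, searching candidates at {0} ∪ observed strengths
is exact; the smallest minimizer is returned and arcs strictly above it
are significant. The consensus network takes all significant adjacencies,
orients each by majority direction (ties point to the lower tier, then
lexicographically), and inserts them in decreasing strength order,
skipping any arc that would close a cycle or violate constraints — so the
output is acyclic and constraint-valid by construction and always
contains the whitelist.

## Parameters and inference

CPTs are fitted from complete data either by maximum likelihood (rows
with zero support become uniform and are flagged) or as a Dirichlet
posterior mean with total imaginary sample size `iss` split uniformly
over the table, i.e. (Nₖ + iss/(q·r)) / (N_row + iss/q). The pipeline
default is `bayes` with iss = 1: the study fitted parameters without
priors, but pure MLE produces zero cells that make likelihood-weighting
evidence weights degenerate; `mle` remains available to mirror the
original exactly.

Conditional queries use likelihood weighting: forward samples in
topological order with evidence nodes clamped, each sample weighted by
the product of the evidence values' conditional probabilities given the
sampled parents. Results report the effective sample size (Σw)²/Σw² and
warn below 1,000. The study-scale default of 10⁷ samples per query is
available; the pipeline and CLI default to 10⁵, which is accurate to
roughly ±0.005 per probability and keeps desk-scale runs fast. Two exact
routines back the approximate path: full-joint enumeration (capped at 10⁶
configurations) and variable-elimination marginals with a min-degree
ordering, which handle any network whose treewidth is modest — including
the 18-node default.

## The synthetic generator

`default_calibrated_bn()` emulates the composite NHANES-like study
population of 29,078 complete adult records. Its DAG contains the four
published mediating pathways from ethno-racial group to ABCD (via diet;
via education → smoking → diet; via education → physical activity; via
education → income → alcohol → smoking → diet), the mandated driver
arcs, and tier-respecting demographic/SDOH dependencies (27 arcs total).
Initial CPTs tilt each node's target marginal by a linear combination of
parent-level scores with plausible effect signs (e.g. DASH-accordant diet
lowers adiposity stage); calibration then iteratively rescales CPT
columns by target/current exact marginals (computed by variable
elimination) and renormalizes rows until every marginal matches the
published summary-table percentage to within 1e-7 — typically a handful
of sweeps, with a hard cap of 500 and a diagnostic error listing any
offending marginals on failure.

Only the marginals are published, so dependence strengths are free
parameters; they are set strong enough that for every true arc some pair
of parent configurations differing only in that parent has CPT rows at
total variation ≥ 0.15 (asserted in the test suite), giving
structure-recovery experiments real signal. Consequences to keep in mind:
the generator is **not** a reproduction of the study's estimated networks
or query values; it emulates neither survey design (strata, clusters,
weights) nor the real data's dependence magnitudes. Passing recovery
tests show the learning stack recovers *this kind* of tiered categorical
dependence structure at these sample sizes — not that it would recover
the real survey's network.

Randomness: one root seed per operation; `forward_sample` and
`inject_missingness` derive child generators via
`SeedSequence([seed, tag])` with fixed per-operation tags, and pipeline
queries derive per-query seeds the same way, so every artifact is
reproducible from the seeds recorded in the run manifest.

## Problem sizes used in the checks

The packaged checks run at the sizes the analysis itself prescribes where
feasible: calibration sampling at n = 29,078; consensus recovery at
n = 29,078 with B = 50 bootstrap replicates; five-node skeleton recovery
at n = 20,000 over 20 seeds; CPT recovery at n = 50,000; inference-oracle
agreement at 10⁶ likelihood-weighting samples on twenty ≤ 6-node models.
CPT recovery is asserted on parent configurations whose observed support
N_row satisfies 3·√(0.25/N_row) ≤ 0.02 (N_row ≥ 5,625): rows rarer than
that cannot be estimated to the 0.02 tolerance by any method, since
binomial sampling noise alone exceeds it.

## Design choices and limitations

- Adjacency-based strength bookkeeping (inclusion of either orientation)
  with separate direction frequencies follows standard averaged-network
  practice; thresholding directed arcs instead is selectable by building
  the strength list from directed entries.
- Stratified runs drop the stratification variable rather than keeping a
  constant node: a constant node has a degenerate family score and no
  interpretable arcs. Strata smaller than a configurable minimum (default
  100 records) are skipped with a warning.
- Behavioral-impact queries report exactly 0 when a stratum's DAG has no
  directed path from the behavior to the outcome, since the conditional
  distribution then cannot depend on the behavior; this avoids reporting
  Monte Carlo noise as an effect.
- The uncovered CMBCD cell, the staging cut-offs, and the driver
  hierarchy are documented defaults, all configurable; alternative
  published rule sets can be dropped in verbatim via YAML/config.
- Exact inference at 18 nodes is limited to marginals (variable
  elimination); conditional queries at that scale go through likelihood
  weighting. MAP queries, latent-variable structures, CPDAGs,
  survey-weighted estimation, and EM for missing data are out of scope —
  incomplete records are excluded, as in the study design.
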