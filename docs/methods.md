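# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic benchmark does and does not
establish.

## Differential expression: the RVM moderated t-test

For a feature with pooled two-sample variance $s^2$ on $d = n_1 + n_2 - 2$
degrees of freedom, the precision $\sigma^{-2}$ is given a Gamma$(a, b)$
prior (shape $a$, scale $b$), under which the marginal law of the observed
variance is $s^2 a b \sim F(d, 2a)$. The hyperparameters are fitted once
per cohort by maximizing $\sum_i [\log(ab) + \log f_F(a b s_i^2; d, 2a)]$
over $(\log a, \log b)$ with L-BFGS-B, box-bounded to
$a \in [10^{-4}, 10^5]$: with near-constant observed variances the
likelihood is flat in the $a \to \infty$ direction, whose limit is a
degenerate (maximally informative) prior, so the boundary solution is the
correct limit rather than a failure; a Nelder–Mead polish handles
line-search breakdowns in that flat region. The posterior-mean variance
$\tilde s^2 = (d s^2 + 2/b)/(d + 2a)$ enters the t statistic with
$d + 2a$ degrees of freedom. The exact hyperparameter-fitting procedure is
this package's reconstruction of the named method, not a verbatim
published algorithm. With `prior=None` the statistic reduces to the
classical pooled t exactly (regression-tested at 1e-12), and the fitted
moderation vanishes appropriately as $a \to 0$.

The test is unpaired by design even where cohorts contain matched pairs,
because real multi-cohort compositions are unbalanced; pairing information
is carried through the sample sheet for users who need it.

Gating thresholds (defaults, configurable per class): mRNA/lncRNA
$|\mathrm{FC}| > 2 \wedge p < 0.05$; miRNA
$|\mathrm{FC}| > 1.5 \wedge p < 0.05 \wedge \mathrm{FDR} < 0.05$. "FC" is
the signed fold change $\pm 2^{|\Delta \log_2|}$, so "FC > 2" reads as
$|\mathrm{FC}| > 2$ (down-regulated features carry negative values).
FDR gating uses Benjamini–Hochberg. A literal quantity
$1 - N_k/T$ — with $N_k$ the number of p-values strictly below the
$k$-th smallest among $T$ — is also computed (`legacy_fdr`) because some
legacy array pipelines report it; its terms are ambiguous in the
literature, our reading is documented here, and it never gates by default.

Cross-cohort intersection keeps a feature iff it is significant with the
same direction in all cohorts (or `min_cohorts`); conflicting directions
are logged and dropped.

## Enrichment

Two-sided Fisher exact p-values come from the hypergeometric law of the
2×2 table (set membership × flagged status); the χ² option applies the
continuity correction and falls back to Fisher whenever an expected cell
is below 5. $R_e$ is the in-set flagged fraction over the array-wide one;
it is undefined (reported missing) for sets with no members in the
universe. The universe defaults to the whole array rather than the DE
pool — enrichment then asks "do DE genes concentrate here?" against the
platform background — and is configurable. The downstream "functional"
gene pool is the intersection semantics: a DE gene must sit in at least
one significant GO term AND at least one significant pathway
(p < 0.05 and FDR < 0.05 for the term).

## Signal network

Relation tables are directed and weighted; parallel rows between the same
pair collapse to one edge with summed weight (relations repeat across
pathway maps). Connectivity $K_i$ sums weights on the undirected
projection; in/outdegree are counted on the directed graph. Relative
betweenness is computed on the undirected, unweighted projection because
its $2/((n-1)(n-2))$ normalizer is the undirected Freeman normalization;
$\sigma_{st}(v)$ counts the vertex strictly interior, disconnected pairs
contribute zero, and $n < 3$ networks report 0 with a warning. Whether the
field's "degree" is weighted is ambiguous ("connection strengths" suggests
weights), so both the weighted $K_i$ and unweighted in/outdegree are
reported. Hub ranking sorts descending with a feature-id tie-break for
determinism.

## Target prediction

External predictors are replaced by a bespoke, deterministic seed matcher
on the canonical site classes, because remote tools cannot be called
reproducibly offline and their parameter settings are rarely recorded. The
scan anchors on the 6mer core (reverse complement of seed nt 2–7) and
upgrades by the m8 match and the A1 anchor, so each locus is reported once
at its highest class. Coordinates are 0-based, half-open, target 5'→3';
U is normalized to T on input. The whole supplied sequence is scanned
(pass 3'UTRs to restrict). The "consensus of two tools" semantics is kept
by intersecting two threshold parameterizations (default 7mer-m8 vs 8mer).
No free-energy or context scoring in v1; seed classes suffice for
planted-truth recovery and the site tables carry coordinates for rescoring.

## ceRNA assembly

Edges require, jointly: sequence-predicted pairing, opposite DE
directions, $r < 0$, and $p < 0.05$ on tumor samples only (validation
collections are tumor cohorts; an all-samples option exists). The
correlation gate is uncorrected by default to mirror common pairwise
practice, with a BH option. The positive lncRNA–mRNA correlation is
computed and reported on every triplet but not required by default — it is
an observed consequence of genuine sponging rather than a definition — and
can be enforced with `require_positive_lnc_m`. Triplets are all
(lncRNA, mRNA) combinations through a shared miRNA. The two
direction-stratified sub-networks partition nodes exactly.

## Clinical validation

Median splits assign ties at the median to the low group — an arbitrary
but documented rule that makes splits reproducible; constant vectors are
an error. Kaplan–Meier uses the product-limit estimator; the two-group
log-rank statistic is $\chi^2_1$. Cox fits use the partial likelihood
with Efron tie handling; "multivariate" enters the covariates with
univariate $p < 0.05$ (a forward-entry rule chosen where the literature is
silent; configurable). ROC labels are event-at-end-of-follow-up status —
the simplest classifier reading; time-dependent ROC is out of scope. AUC
is the Mann–Whitney statistic with half-credit ties and equals the
trapezoidal area of the empirical curve identically. The default
confidence interval is Hanley–McNeil normal; an `exact-binomial` option
treats the concordant-pair count as binomial (Clopper–Pearson), which is
conservative because pairs are not independent. "Binomial exact" CIs are
under-specified in the applied literature; the choice here is the
package's own.

## Synthetic data: what it emulates, and what it does not

The generator emulates multi-cohort tumor/normal log2 expression with
Gaussian noise (defaults: three cohorts of 33 tumors + 8 normals,
mirroring a ~99/24 design; noise SD 1.0 log2 units), a `de_fraction` of
10% truly shifted features, and a planted mean shift of
`effect_log2fc = 3.0` (8-fold). The effect default is deliberately large:
screen survivors that intersect across several small cohorts at
$|FC| > 2 \wedge p < 0.05$ in every cohort are precisely the
large-effect genes (reported top fold changes in such studies run 30–90×),
and sponge-driven variance inflation (below) makes small effects
undetectable under intersection — a property, not a bug, of the design.

Each planted triplet draws a latent per-tumor-sample activity
$m \sim \mathcal N(0,1)$; the miRNA adds $+m$, and the lncRNA and mRNA add
$-s\,m$ with sponge strength $s$ (default 2), producing negative
miRNA–partner and positive lncRNA–mRNA correlations on top of the DE
shifts. Triplet members are disjoint across triplets so cross-triplet
correlations stay null. Planted (miRNA, target) pairs carry one embedded
8mer site (configurable class) at a random interior position; all other
transcripts are scrubbed of every miRNA's 6mer core, so decoys carry no
canonical site and seed-match recall of planted pairs is exactly 1.
Survival times are exponential with hazard
$\lambda_0 e^{\sum \beta_f z_f}$ ($\lambda_0 = \ln 2/30$ per month, i.e.
30-month baseline median; $z$ standardized tumor expression; default one
harmful lncRNA at $\beta = 0.7$), censored administratively at the
empirical $(1-\text{censor fraction})$ quantile.

Not modelled: probe-level effects, batch effects, heavy-tailed or
count-based noise, copy-number confounding, correlated gene programs
beyond the planted triplets, non-proportional hazards, or informative
censoring. Passing the recovery suites therefore demonstrates correctness
of the inference machinery under its own assumptions — sign conventions,
gate logic, calibration — not robustness to the full messiness of real
cohorts.

## Pipeline and reproducibility

Stages run in dependency order, each writing under its own directory; a
SHA-256 manifest covers every output, and two runs with the same seed are
bitwise identical (asserted in tests). One global seed fans out to
per-stage seeds by hashing the stage name (kept below $2^{31}$), so a
stage's stream does not depend on which stages ran before it. Disabling
the enrichment stage routes all intersected DE genes into the ceRNA
stage. A stage failure raises an error naming the stage and leaves
completed stages' outputs intact. Applied thresholds are logged per stage
for audit.

## Problem sizes in the test and acceptance suites

Suites use downsized designs chosen to keep statistical properties
measurable while the full run stays desk-scale: null calibration pools
three replicates of 10,000 features at 20+20 samples; planted-effect
recovery uses ten replicates of 2,000 features at a 1.5-log2 effect;
ceRNA recovery uses the 800/200/100-feature default panel with 100 tumor
samples and ten triplets; Cox coverage uses 100 replicates of n = 500.
The Fisher oracle in the test suite enumerates every 2×2 table with
N ≤ 60 (deduplicated by table symmetry); the acceptance script samples
2,000 of them.

## Known limitations

- The RVM reconstruction assumes a common $d$ across features (complete
  matrices); missing-data designs fall back to row dropping at read time.
- The seed matcher ignores site accessibility, conservation, and
  supplementary 3' pairing; ranked scoring would need those.
- The legacy FDR quantity (`legacy_fdr`) is reported for comparability
  only; its definition in legacy pipelines is ambiguous.
- Multivariate Cox uses single-pass forward entry, not stepwise selection
  with re-checking.
- Correlograms and KM curves are returned as data (DataFrames/step
  functions); plotting is left to the caller.
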