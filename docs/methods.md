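# Methods

`survmdr` detects gene-gene interactions associated with a right-censored
survival phenotype by multifactor dimensionality reduction (MDR): the
3^k genotype cells of a k-SNP combination are collapsed into a binary
high/low-risk attribute, the attribute is scored by cross-validation,
and the best-scoring combination over all C(p, k) candidates is
reported.  This note records the models, the numerical choices, what the
simulator emulates, and the known limits of both.

## Null survival models and risk scores

All six method variants start from a *covariates-only* null model — SNPs
never enter a regression — and reduce each subject to a scalar risk
score:

* **Cox null model.**  The partial likelihood is maximized by
  Newton-Raphson with Breslow handling of ties (convergence when the
  largest Newton step falls below 1e-8, at most 100 iterations, explicit
  failure naming the iteration count otherwise).  With no covariates the
  fit degenerates to the Nelson-Aalen estimator; constant covariate
  columns are dropped with coefficient 0.  The baseline cumulative
  hazard is the Breslow estimator at the fitted coefficients, which
  guarantees the martingale residuals
  `delta_i - Lambda0(t_i) exp(z_i'g)` sum to zero exactly.  Subject
  times beyond the last event use the flat extrapolation of the step
  function.
* **AFT null models.**  `log t = mu + z'g + sigma eps` with standard
  normal errors (log-normal family) or standard minimum-extreme-value
  errors (Weibull family); censored subjects contribute the log survival
  function — deliberately the *naive* residual, with no Buckley-James
  style adjustment, because the methods' sensitivity to censoring is
  exactly the behaviour under study.  The uncensored log-normal MLE is
  computed in closed form (OLS coefficients, variance divisor n), so the
  standardized residuals have mean 0 and mean square 1 to machine
  precision; the censored likelihoods are maximized by BFGS with an
  analytic gradient on (mu, g, log sigma).  A scale collapsing below
  1e-8, or conditionally constant log-times, is an explicit failure.

Scores carry one orientation contract: **larger score = shorter-than-
expected survival = higher risk**.  Martingale residuals already satisfy
it; standardized AFT residuals are negated.  Two transforms serve the
robustified variants: *discretized* scores (case = strictly positive
oriented score, i.e. negative raw residual; exact zeros are controls, a
deterministic tie rule for an event of probability ~0) and *winsorized*
scores (clipped into `[lower, upper]` on the oriented scale; default
±2.0, surfaced as a parameter because any such threshold is a judgment
call that should be visible and tunable).

Residuals are computed once on the full dataset and the cross-validation
machinery splits subjects afterwards.  Since the null model is SNP-free,
refitting it inside each training fold would not change what the
genotype search sees, while multiplying cost by the number of splits.

## Cell classification and scoring

For one SNP combination, each subject maps to the base-3 cell index of
its genotype tuple.  On the training folds only:

| method | cell is high risk iff | split score |
|--------|----------------------|-------------|
| cox, aft, raft | sum of cell scores > 0 | balanced accuracy |
| daft | cell case/control ratio > overall ratio (cross-multiplied, so a case-only cell is high) | balanced accuracy |
| qcox, qaft | cell mean > overall training mean (strict) | pooled two-sample t |

Balanced accuracy is measured against the subject-level pseudo
case/control status defined by each subject's own score sign — the
discretization rule applied to the method's residual.  This reduces
exactly to the original MDR score for the discretized variant and gives
all sum-based variants a consistent score.  An evaluation side with no
cases (or no controls) contributes the chance level 0.5, keeping the
score defined on small test folds without favouring models that empty a
class.  The t statistic is the pooled-variance two-sample t of high
minus low subjects; sentinels keep the ranking total (empty group →
-inf so the model cannot win; zero pooled variance → +inf when means
differ, 0 when they coincide).

Cross-validation is 5-fold repeated 10 times: subjects are shuffled per
repeat (seeded) and cut into contiguous blocks, with no stratification
by event status.  Cells empty in training predict low risk in testing —
the conservative, deterministic MDR convention.  Per split the best
combination is the training-score argmax (ties: lexicographically first
combination); the overall winner maximizes the mean testing score, with
ties broken by cross-validation consistency (how often the combination
won its split) and then lexicographic order.  The same selection rule is
applied to all six variants; CVC-based and candidate-restricted
selection were measured to give indistinguishable detection power, so
the simplest uniform rule was kept.

All per-cell aggregates are matrix products of fold masks against a cell
membership indicator, shared across methods that use the same score
vector; one dataset x all 190 pairs x 50 splits x all six methods costs
about 0.2 s on one CPU core.

## The simulator

Cohorts mirror a balanced two-group design: a 3x3 penetrance table
`f[i,j] = P(high risk | g1 = i, g2 = j)` over two causal SNPs (shared
MAF, HWE) defines a latent binary risk status; 200 high-risk and 200
low-risk subjects are sampled, causal-pair genotypes drawn conditional
on status by Bayes' rule (`P(g|high) = p_g f_g / K`), the other 18 of 20
SNPs drawn as independent HWE noise at the same MAF (configurable), and
the causal positions randomized.  Heritability is the variance-explained
definition `h2 = sum p_ij (f_ij - K)^2 / (K (1 - K))`.

**Penetrance tables** are sampled to emulate searched two-locus
epistasis model archives: draw a prevalence K ~ U(0.05, 0.5), maximize
the HWE-weighted deviation variance subject to *exactly zero*
single-locus marginal penetrance deviations and the [0,1] box (SLSQP
from a random start; different starts give the distinct vertices that
play the role of "models" within a grid cell), then scale the deviations
to hit the target h2 exactly.  Candidates are accepted only when the
target is within the table's frontier and at least half of it, keeping
the corner-like, many-extreme-cell structure of searched models.  Two
properties motivated this design over naive i.i.d. cell sampling: (i)
i.i.d. tables carry most of their risk variance in single-locus
marginals, so the "interaction" is detectable through either SNP alone
and pair-level power collapses; (ii) the maximum pure-epistasis h2 is a
sharp function of prevalence and MAF (about 0.12 at K = 0.1, MAF 0.2),
so feasible tables at the study's h2 grid necessarily couple K to h2.

**Survival times** depend on genotype only through the latent status:
log-normal `log T = -(beta s + gamma z) + eps`, `eps ~ N(0,1)`; Weibull
the same with standard minimum-extreme-value errors; Cox
`T = -log(U) / exp(beta s + gamma z)` (unit exponential baseline).
Defaults `beta = 1`, `gamma in {0, 1}`, one standard-normal covariate
independent of all SNPs.  The negative AFT sign/positive hazard sign
makes high risk mean stochastically shorter survival in all three
models.  **Censoring** is uniform `C ~ U(0, c*)`, independent of
everything, with `c*` solved by root bracketing so the expected censored
fraction `E[min(T/c*, 1)]` over a 20 000-subject reference sample of the
configuration's marginal time distribution equals the target (0, 0.3 or
0.5); calibration is marginal (one bound per configuration), not
per-dataset.

What the simulator does **not** emulate: linkage disequilibrium,
genotyping error or missingness, covariates correlated with genotype,
informative censoring, and any direct genotype effect on survival beyond
the binary status.  Passing power tests therefore demonstrate method
behaviour under clean, status-mediated epistasis — not performance on
real cohort data.

## Power and false-detection estimation

Power at one grid cell is the fraction of simulated datasets whose
overall best model is *exactly* the unordered causal pair (not merely a
pair containing one causal SNP); pooled across fresh penetrance models
within the cell, with per-model counts retained because model-to-model
spread is large.  Failed null-model fits count as non-hits and are
reported — silently dropping them would bias power upward.  False
detection uses the same pipeline on null cohorts (constant table
`f = K`), where the randomly designated pair should be chosen at the
chance level `1/C(20,2) = 1/190 ≈ 0.0053`; base cohorts are re-censored
at each censoring level rather than resimulated, so a (MAF, censoring)
grid costs one simulation per dataset.  Binomial CIs are Wilson
intervals.

Problem sizes: the bundled acceptance runs use 1000 null datasets per
(MAF, censoring) setting pooled over the six methods, and the study's
own 5 models x 100 datasets per power cell; the test suite uses 200 null
datasets per setting.  Both are choices of measurement precision —
method orderings need the larger replication to rise above Monte Carlo
noise, since methods share cohorts and their hit indicators are highly
correlated.

## Known limitations

* The published study's exact 40 penetrance models are not available;
  regenerated models reproduce its method *orderings* (the robustified
  AFT variants beat AFT under moderate censoring, the t-statistic
  variants beat their sum-based parents, AFT-family power collapses as
  censoring grows while qCox degrades most slowly) but several absolute
  power levels sit below the printed values at any generator consistent
  with the stated design (status-mediated effect size 1.0, unit-variance
  errors, heritability grid).  An analytic bound on the cell-to-score
  separation shows the printed near-saturated values (e.g. qCox 0.95
  under 50% censoring) would require near-deterministic genotype-to-risk
  assignment, which the stated heritabilities do not permit.
* The exact scoring statistic of the earlier sum-based survival MDR
  publications is not restated in the study; the pseudo-status balanced
  accuracy defined above is this engine's definition.
* Search is plain enumeration; k > 3 is legal but slow.  No permutation
  p-values for the selected model are provided.
* Only right censoring, time-fixed covariates and complete genotypes
  after subject dropping are supported.
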