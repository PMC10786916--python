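# Methods

## Model

The cooperation-and-punishment model is a joint multinomial processing tree
over two trees per condition, split by the partner's programmed decision.
Parameters per condition: cooperation *C*, moral punishment *P*_Moral
(cooperating participant punishes a defecting partner), hypocritical
punishment *P*_Hypocritical (after mutual defection), antisocial punishment
*P*_Antisocial (defecting participant punishes a cooperating partner), and
an unspecific punishment bias *b*.  The mutual-cooperation cell has no
specific punishment process and identifies *b* alone; every other cell
punishes with probability `P + (1 − P)·b`.  All parameters are
probabilities in [0, 1]; boundary values are legal inputs and the
log-likelihood uses the 0·ln 0 = 0 convention.

Punishment is binary in the model: any investment (1–3 points) counts as
"punished".  Graded amounts exist only in the simulator, which is where the
payoff ledger lives.  The category enumeration is frozen (partner-defects
tree first; within a tree cooperate/punish, cooperate/none, defect/punish,
defect/none) and used by all file formats.  The structure can be exported
as an EQN-style text file (`cooppunish.to_eqn`): one line per branch with
the product of parameter terms, `1-x` denoting a complement — the format
most MPT tools read.

## Estimation

Counts are pooled over participants into per-condition aggregates
(standard aggregate MPT fitting; the model yields group-level parameters).
The likelihood is product-multinomial conditional on the tree totals, which
are fixed by the partner schedule.  Fitting maximises the log-likelihood on
the logit scale with L-BFGS-B and 5 starts by default: the first start is
the closed-form estimator (below), the rest are uniform draws on
[0.02, 0.98]; convergence tolerance 1e−10 on the objective.  An infinite
objective (a zero-probability category with observations) is replaced by a
large finite penalty so the line search can back off.

Goodness of fit is G² = 2(ln L_saturated − ln L_model), with the saturated
model at the observed tree-conditional frequencies; df = Σ_trees 3 − (free
parameters), so the two-condition base model has df 2.  Equality
restrictions merge two free-parameter indices — across conditions for the
same parameter, or across parameter names (the moral-vs-antisocial test) —
and are assessed by ΔG² with 1 df; negative ΔG² below 1e−8 in magnitude is
clamped to 0.  Boundary estimates are reported at the boundary with a flag;
df is left unchanged.

Closed-form oracle: for an unrestricted condition the likelihood factorises
into a cooperation binomial and four conditional punish-rate binomials, so
Ĉ is the overall cooperation rate, b̂ the punish rate under mutual
cooperation, and each specific parameter (r − b̂)/(1 − b̂) for its cell's
punish rate r, clipped to [0, 1].  The optimizer is required (and tested)
to agree with this to 1e−6 whenever the unclipped values are interior.

Standard errors come from the inverse observed information (central-
difference Hessian on the probability scale, step 1e−5).  When an estimate
is on the boundary or the information matrix is singular, a parametric
bootstrap (200 draws by default) supplies the SEs and the result records
the fallback.

## Inference statistics

p-values are central chi-square survival probabilities.  Cohen's
w = √(statistic/N) with N the **total decision count** (participants ×
analysed trials) — the only convention consistent with treating pooled
decisions as the multinomial observations, and the one used throughout.
Power uses the noncentral chi-square with λ = N·w²; sensitivity (minimal
detectable w at a target power) inverts the power function by Brent
bracketing to machine tolerance, with the degenerate target-equals-α case
returning w = 0.  The sensitivity analysis defaults to df = 1, the df of
every restriction test in the battery.

## Simulator

The generator emulates the two-condition base-rate experiment: each
participant plays 25 analysed one-shot Prisoner's Dilemma trials against
programmed partners who cooperate in exactly 60% (cooperating-majority) or
40% (defecting-majority) of their trials, in shuffled order; a
Bernoulli-per-trial schedule is available for non-integer rates.
Participant cooperation is Bernoulli(*C*) independent of the scheduled
partner move; punishment follows the cell's branch probability; the
investment given punishment is uniform on {1, 2, 3} points, fining the
partner 10/20/30.  In the bilateral variant the partner always fines the
participant's unilateral defection by a uniform 10/20/30 points.  Payoffs
are +10/+10 for mutual cooperation, 0/0 for mutual defection, +20/−10 for
unilateral defection; balances start at a 150-point endowment, may go
negative, and carry no bankruptcy rule.  Presets encode the two studied
designs: 278/266 participants with partner punishment, and 250/245 without.

What the generator does **not** emulate: training trials, learning or
trial-order effects, partner identity (faces), dropout/exclusion pipelines,
and any dependence of decisions across trials beyond the fixed parameters.
Passing recovery and calibration tests therefore show that the pipeline is
correct under the model's own assumptions, not that real participants
satisfy them; in particular the uniform punishment-investment distribution
is an assumption, invisible to the binary-punishment model.

## Validation studies and problem sizes

* Optimizer vs closed form: 10 random interior datasets of 4000 decisions
  per tree; worst absolute discrepancy ~1e−9 (tolerance 1e−6).
* Parameter recovery: 200 replications of the full simulate → aggregate →
  fit pipeline at 500 participants × 25 trials; mean absolute error per
  parameter must stay below 0.02.
* Null calibration: 500 counts-level replications (multinomial draws per
  tree, the distribution the likelihood assumes) under a model whose C is
  equal across conditions; the base-model G² mean must sit within 3 SEs of
  its df and the C-restriction type-I error within Monte-Carlo error of
  α = 0.05.
* Generator consistency: one condition at 4000 participants × 25 trials
  (10⁵ decisions); every tree-conditional category frequency within 3
  binomial SEs of the model probability.

These sizes keep the whole suite at about a minute while leaving the
Monte-Carlo error small relative to every tested margin.

## Design choices and limitations

* The battery reports unadjusted p-values per test, matching the standard
  reporting convention for MPT restriction batteries; Bonferroni/Holm
  columns are available but off by default.
* Report formatting rounds G² to 2 dp, p to 3 dp, w to 2 dp; JSON always
  retains full precision.
* Per-participant heterogeneity (hierarchical MPT), Bayesian estimation,
  and information-criterion model selection are out of scope; with strong
  heterogeneity the aggregate G² can overreject even when the process
  model is right.
* Fitting third-party trial exports requires a user-supplied column
  mapping onto the documented trial-table header (`cooppunish.io.read_trials`).
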