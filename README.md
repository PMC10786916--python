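# cooppunish

Multinomial processing-tree (MPT) modelling of cooperation and costly
punishment in the Prisoner's Dilemma, with the complete inferential pipeline
around it: maximum-likelihood fitting, G² goodness of fit, ΔG² equality-
restriction tests, Cohen's w effect sizes, noncentral-chi-square power and
sensitivity analysis, and a trial-level simulator of the two-condition
base-rate experiment the model is designed for.

## The problem

Do people punish defection, or do they punish whatever deviates from the
majority?  In a one-shot Prisoner's Dilemma with a costly punishment option,
raw punishment rates confound several processes: a cooperator fining a
defector (moral punishment), a defector fining a fellow defector
(hypocritical punishment), a defector fining a cooperator (antisocial
punishment), and an outcome-blind tendency to punish anyone.  The
cooperation-and-punishment MPT model separates these processes from
categorical trial outcomes.

## The model

Trials are split into two trees by the partner's programmed decision.  The
participant cooperates with probability *C* (independent of the partner's
move, which is revealed simultaneously).  In each outcome cell the
participant punishes through a cell-specific process or, failing that,
through an unspecific bias *b*:

| cell (participant, partner) | P(punish) |
|---|---|
| cooperate, defect  | *P*<sub>Moral</sub> + (1 − *P*<sub>Moral</sub>)·*b* |
| defect, defect     | *P*<sub>Hypocritical</sub> + (1 − *P*<sub>Hypocritical</sub>)·*b* |
| defect, cooperate  | *P*<sub>Antisocial</sub> + (1 − *P*<sub>Antisocial</sub>)·*b* |
| cooperate, cooperate | *b* |

Eight categories per condition (2 trees × participant decision × punished
or not), fitted by maximising the product-multinomial likelihood pooled
over participants.  The two-condition base model (a cooperating-majority
condition with 60% partner cooperation and a defecting-majority condition
with 40%) has 4 trees × 3 free category probabilities − 10 parameters =
2 df.  Hypotheses are tested by equating a parameter pair across conditions
and comparing fits: ΔG² = G²(restricted) − G²(base), χ²(1) under the null,
with effect size w = √(ΔG²/N) where N is the total decision count.

## Worked example

```sh
cooppunish simulate --preset exp1 --seed 20240112 --out trials.tsv
cooppunish aggregate trials.tsv --out counts.tsv
cooppunish report counts.tsv --seed 11
```

or equivalently `python analysis/01_simulate_experiments.py` followed by
`python analysis/02_fit_battery.py`, which prints:

```
exp1: base model G²(2) = 0.27, p = 0.876
  C                        ΔG²(1) =  270.04, p = 0.000, w = 0.14
  pMoral                   ΔG²(1) =   28.84, p = 0.000, w = 0.05
  pHypocritical            ΔG²(1) =   21.28, p = 0.000, w = 0.04
  pMoral=pAntisocial       ΔG²(1) =  480.67, p = 0.000, w = 0.19
  pAntisocial              ΔG²(1) =    9.98, p = 0.002, w = 0.03
  b                        ΔG²(1) =    0.10, p = 0.749, w = 0.00
```

The data were simulated from known parameters (544 participants × 25
trials; *C* = 0.70 vs 0.56 across conditions), so the battery reads as:
the base model fits (p = 0.876, as it must — the generator is the model);
cooperation, moral, hypocritical and antisocial punishment genuinely differ
between conditions and are detected; moral punishment of defection far
exceeds antisocial punishment of cooperation (w = 0.19); and the punishment
bias, equal by construction, is correctly not rejected.  The `power` and
`sensitivity` subcommands cover the design's sensitivity: at N = 13600
decisions the minimal detectable effect at power 0.95 is w = 0.03.

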