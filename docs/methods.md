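# Methods

## Model

Two controllers value the same two-step decision tree. Outcomes are coded
as signed values r = −(shocks delivered), so avoidance is value
maximisation. Both controllers share one learning rate α.

**Model-free SARSA.** Q_MF(s, a) is updated by the outcome prediction
error OPE = r + Q_MF(s′, a′) − Q_MF(s, a) with ΔQ_MF = α·OPE. The
first-stage transition carries no outcome (r = 0) and bootstraps on the
*chosen* second-stage pair (on-policy); the terminal update has no
bootstrap term. Because only experienced outcomes drive it, this system
cannot re-evaluate coins when the goal rule changes — in specific-goal
blocks its targets effectively jump from trial to trial.

**Model-based FORWARD learner.** A transition model T(s, a, s′) over each
pair's two configured successors is updated by the state prediction error
SPE = 1 − T(s, a, s_observed), ΔT = α·SPE, with the unobserved successor
rescaled multiplicatively so rows stay stochastic (with two successors
this is simply the complement). Q_MB is recomputed by exact backward
induction, Q_MB(s, a) = Σ_s′ T(s, a, s′)·[r + max_a′ Q_MB(s′, a′)]; since
shocks occur only at outcome states, r enters through the terminal
values. On every trial the displayed goal sets the terminal values before
planning (backward-planning devaluation): under a specific goal the
matching coin keeps −(face value) and all others become −4; under the
flexible rule all coins keep face values.

**Reliabilities.** The model-free reliability derives from an estimator Ω
of the absolute OPE, ΔΩ = η(|OPE| − Ω), as χ_MF = max(0, 1 − Ω/Ω_max):
perfect outcome prediction gives χ_MF = 1. The model-based reliability is
an exponentially weighted rate (same η) of transitions whose SPE fell
below the threshold ω ("counted as zero"), so χ_MB = 1 when every recent
transition was well predicted. Both reliabilities update after every
observed transition/outcome — twice per trial each.

**Arbitration.** The mixture weight follows a two-state dynamical system,
p_MB ← p_MB + τ_MF→MB·(1 − p_MB) − τ_MB→MF·p_MB, with logistic rates
τ_MF→MB = A_MF→MB·σ(B·(χ_MB − χ_MF)) and
τ_MB→MF = bias_MF·A_MB→MF·σ(B·(χ_MF − χ_MB)). The fixed bias_MF > 1
favours habitual control when reliabilities are equal. The weight updates
once per trial, after the outcome. Choices at both stages are softmax in
the integrated values Q = p_MB·Q_MB + p_MF·Q_MF with inverse temperature
β.

The rate functions' exact arguments are a design choice: we use logistics
of the signed reliability *difference* with a shared fixed steepness B and
two free amplitudes. An alternative parameterisation (each rate a logistic
of the other controller's reliability alone) exists in the antecedent
reward-learning literature; the difference form was chosen because it
keeps the two amplitudes as the only free rate parameters while making the
equilibrium weight an explicit monotone function of χ_MB − χ_MF.

## Per-trial algorithm (shared by simulation and likelihood replay)

1. Set terminal values from the displayed goal; recompute Q_MB.
2. First choice by softmax on Q at the root (weight w = p_MB frozen at
   trial start).
3. Observe the first transition; SPE update of T (+ χ_MB update);
   recompute Q_MB.
4. Second choice by softmax on Q at the reached state.
5. First-stage SARSA update (r = 0, bootstrap on the chosen pair)
   (+ χ_MF update).
6. Observe the outcome transition; SPE update (+ χ_MB); deliver shocks
   under the goal rule; terminal SARSA update (+ χ_MF).
7. One weight update of p_MB.

Simulation samples actions and transitions; likelihood replay forces the
observed ones through the same compiled loop, which guarantees that
fitting replays exactly the generative process (a test asserts that
replaying a simulated session reproduces its latent trace bit for bit).
The negative log-likelihood sums −log P(observed action) over both stages
of included trials, with a floor of 1e-12 per choice against softmax
saturation.

## Parameters

| parameter | meaning | default | range searched |
|---|---|---|---|
| α | learning rate of both value systems | 0.25 | [0.01, 1] |
| η | reliability-estimator learning rate | 0.3 | [0.01, 1] |
| ω | zero-SPE threshold (MB reliability) | 0.5 | [0.01, 0.99] |
| A_MF→MB | MF→MB transition-rate amplitude | 0.7 | [0.01, 1] |
| A_MB→MF | MB→MF transition-rate amplitude | 0.5 | [0.01, 1] |
| β | softmax inverse temperature | 2.5 | [0.01, 20] |
| B | rate-function steepness (fixed) | 10 | — |
| bias_MF | habitual bias on the MB→MF rate (fixed) | 1.5 | — |
| Ω_max | |OPE| at which χ_MF reaches 0 (fixed) | 4 | — |

Ω_max equals the maximum attainable |OPE| in this task: outcomes of at
most 4 shocks occur only at the terminal transition and the first-stage
update is a pure bootstrap, so Q_MF ∈ [−4, 0] and |OPE| ≤ 4. A larger
bound would compress χ_MF into the upper half of its range and make the
arbitrator insensitive to outcome prediction failures.

Default agent parameters are the package's reference study conditions.
They were chosen, by piloting the simulator during model design, to place
the arbitrator in its responsive range so the generator expresses the
phenomena the task is built to elicit: ω = 0.5 counts a transition as
predicted exactly when the observed successor was the more-expected one,
which separates converged low-uncertainty rows (SPE ≈ 0.1) from
high-uncertainty rows (SPE ≈ 0.5); η = 0.3 integrates reliabilities over
roughly three recent events, fast enough to track 3–7-trial blocks;
α = 0.25 is a moderate human-scale learning rate; β = 2.5 gives decisive
but stochastic choices for value gaps of order 1 shock; and amplitudes
0.7/0.5 allow within-block controller switching, with the MF→MB amplitude
larger to offset the habitual bias. Under these conditions mean p_MB is
higher in specific-goal than flexible-goal blocks, model-based control
dominates mainly in specific/low-uncertainty blocks (roughly a quarter to
a third of trials have p_MB > 0.5), and model-free control dominates
flexible and high-uncertainty blocks.

**Initialisation.** Q_MF = 0, T uniform, terminal values at face value,
Ω = 0 (χ_MF = 1), zero-SPE rate 0.5, p_MB = 0.5. Simulated subjects run
the 100-trial training session first, so experimental sessions start from
experience-shaped values rather than hand-set ones. During training the
displayed coin magnitudes drive learning (r = −face value) while
delivered shocks are recorded as 0.

## Fitting

Per-subject maximum likelihood. The search runs Nelder–Mead in a
scaled-logit transform of the box bounds above (function tolerance 1e-6,
at most 2,000 evaluations per restart), from independent uniform random
starting points; restart k draws its start from a deterministic child of
the master seed, so enlarging the restart set keeps earlier starts
nested. The `mf_only` and `mb_only` variants pin p_MB at 0 or 1, which
makes η, ω and the amplitudes likelihood-irrelevant; those variants
therefore optimise only (α, β). Training-session choices are replayed for
state evolution but excluded from the likelihood by default, as are
penalising (no-response) trials. Pooled fitting is available by
concatenating subjects' logs; group statistics are computed from
per-subject fits, which is what the between-group tests require.

## Synthetic data: what it does and does not emulate

The generator reproduces the task design — tree layout, 0.9/0.1 and
0.5/0.5 transitions, coin magnitudes {0, 1, 2, 4} with red = 0 and
grey = 4, goal devaluation, randomised 48-block schedules with 3–5 / 5–7
trial blocks, the 100-trial training session — and produces behaviour
from the arbitration model itself (or MF-only, MB-only, ideal, random
agents). The default successor layout is fixed so that, in the flexible
condition, the optimal first-stage action is the same under both
uncertainty levels while the optimal second-stage action flips; this
mirrors the structure the stage-wise analyses probe. Penalising trials
are optional random-choice trials flagged for exclusion; response times,
inter-trial intervals, fatigue, pain habituation and any physiological
component of real subjects are not modelled. Tests passing on synthetic
cohorts therefore validate the pipeline's internal consistency
(simulation → fitting → analysis), not claims about human parameter
values.

## Numerical choices and scale

The trial loop is compiled with numba and shared verbatim between
simulation and replay. Softmax probabilities are computed
overflow-safely; at extreme β the disfavoured action's probability can
round to 0 at double precision, which the likelihood floor absorbs.
Backward induction is exact (it agrees with exhaustive expectimax
enumeration to 1e-10 over random instances). Ideal-agent ties break in
fixed action order (LEFT first). Transition-row renormalisation keeps row
sums at 1 to within accumulated rounding (< 1e-10 over 10,000 updates).
Reference problem sizes — 15–20 subjects, 48 blocks plus training per
subject, 10–20 optimisation restarts — run in tens of seconds on one CPU
core; the recovery study (15 subjects × 20 restarts × 6 parameters) takes
about half a minute.

## Known limitations

* η and the two amplitudes recover weakly from single-subject data at
  this scale (true-vs-recovered rank correlations around 0.3, versus
  ≈ 0.9 for α and β); conclusions about those parameters need pooled or
  hierarchical designs.
* χ_MB is an exponentially weighted zero-SPE rate; a Bayesian posterior
  over zero-SPE counts is a defensible alternative reading and would add
  no free parameter, but was not implemented.
* The arbitration weight updates once per trial; within-trial arbitration
  (e.g. different weights at the two stages of one trial) is not
  expressible.
* Values persist across blocks and conditions (no reset), matching
  continuous sessions; paradigms with explicit breaks may need a reset
  option.
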