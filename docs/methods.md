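# Methods

## Model

The cooperation-and-punishment model is a joint multinomial processing tree
over two independent multinomials per experimental group: the trials on which
the (preprogrammed) partner defected and the trials on which the partner
cooperated.  Each tree has four observable categories — participant
{cooperate, defect} × {punished, not punished} — and the eight category
probabilities are products of five branch probabilities (C, P_Moral,
P_Hypocritical, P_Antisocial, b), listed in `punishmpt.model`.  Punishment is
binarized: any positive punishment investment counts as "punished", the
magnitude is treated as irrelevant to the latent punishment decision.

Assumptions worth keeping in mind:

- **Simultaneity / independence.** The same C appears in both trees because
  the participant cannot condition on the partner's simultaneous choice.
  The marginal cooperation probability per tree is therefore exactly C.
- **One latent process per trial.** An outcome-specific punishment process is
  consulted first; only if it does not fire can the unspecific bias b produce
  punishment.  The bias is the only punishment path after mutual cooperation.
- **Homogeneity.** All participants in a group share one parameter vector;
  the model describes aggregate frequencies, not individual differences.
- **Independence across trials and participants**, as in any product-
  multinomial MPT analysis.

## Estimation

Per group the likelihood is a product of two multinomials; groups are fitted
jointly so that cross-group equality constraints (implemented by collapsing
the constrained cells onto one free parameter, with union-find so overlapping
constraints chain) can be imposed.  Maximization proceeds in two stages:

1. **Log-odds stage.** L-BFGS-B on the logit scale of every free parameter,
   from a central start plus `n_restarts` (default 10) seeded uniform random
   starts; tolerance 1e-10 on the log-likelihood.  The transform keeps every
   iterate strictly inside the unit cube.
2. **Bounded polish.** A final L-BFGS-B run on the probability scale with
   box bounds [0, 1], started from the stage-1 optimum and run essentially to
   gradient convergence.  This stage exists because a logit parametrization
   can approach but never attain boundary maxima (e.g. a punishment rate
   whose MLE is exactly 0), and because the likelihood has shallow ridges
   where a punishment parameter trades off against the bias b; the projected
   steps traverse both.

Gradients are analytic throughout (the category probabilities are low-order
polynomials with a hand-coded Jacobian).  Fits are deterministic given the
options, including the seed for the restart draws.  Non-convergence of every
restart is flagged on the result, never silently dropped.

Goodness of fit is G² = 2 Σ obs·ln(obs/exp) over all groups, trees and
categories; observed zero cells contribute exactly 0 and expected counts are
floored at 1e-12 inside the logarithm.  The reference distribution is a
central χ² with df = 6·(groups) − (free parameters): each group contributes
two multinomials with three free category probabilities each.  Nested tests
report ΔG² = G²(restricted) − G²(base), clipped to 0 when within 1e-6 below
zero (optimizer noise); a larger negative value raises an error instead of
being reported.  p-values are upper-tail central χ² without continuity
correction.  Cohen's effect size w = √(ΔG²/N) uses N = the total number of
test decisions of **all** groups in the fitted model, not only the compared
groups — the convention validated in the test suite against the full set of
reported (ΔG², w) pairs from both study designs (N = 4060 and N = 33620).

Standard errors are square roots of the diagonal of the inverse expected
Fisher information at the estimate, computed analytically on the probability
scale.  Estimates within 1e-6 of a bound are reported as-is with an
undefined (NaN) standard error rather than jittered; the interior block of
the information matrix is still inverted for the remaining parameters.

## Power analysis

For a χ²-family test with effect size w on N observations the noncentrality
is λ = w²·N, and power is the mass of the noncentral χ²(df, λ) above the
central critical value at α.  N counts *observations*: participants × test
decisions per participant (20 under the default schedule).  This convention
reproduces both reference planning numbers — a minimal detectable w that
rounds to 0.06 for 203 participants at power 0.95, and a required sample of
1625 participants for w = 0.02 — and is therefore the package default.
Sensitivity analysis inverts the power function by bisection on w ∈ [0, 1]
to 1e-8; the a-priori mode searches integers by doubling, bisecting, then a
final linear scan, and returns the smallest n meeting the target (the test
suite checks n passes and n − 1 fails).  The df of the a-priori reference
computation is not uniquely pinned down by the planning description it
mirrors; df = 1 (a single pairwise parameter comparison) reproduces the
reference value and is the default.

## Synthetic data

`simulate_trials` emulates the study structure: 26 rounds per participant,
the first 6 training, and a half-cooperating / half-defecting partner
schedule presented in random order.  The published description fixes only
the 13/13 overall split; the default schedule resolves it as 3/3 in training
and 10/10 in the test phase (so every participant contributes exactly 10
decisions to each tree), and both splits are configurable.  Participant
behavior follows the model's branch process exactly; punished trials draw an
investment uniformly from 1..max (9 cents-variant, 3 points-variant), which
affects payoff bookkeeping only.  The points-variant option `punish_back`
adds the partner's counter-punishment of unilateral participant defection
(uniform 1–3), again for payoff realism only.  Randomness is keyed per
(seed, group index, participant index), so growing a group never reshuffles
earlier participants, and identical seeds give byte-identical logs.

What the generator does **not** emulate: individual differences (participants
are homogeneous within group), sequential dependencies (no learning or
reciprocity dynamics across rounds), emotion ratings, and reaction times.
Passing recovery tests therefore certify the estimation machinery under a
correctly specified aggregate model — they do not certify robustness to
participant heterogeneity in real data.

The recovery harness (`parameter_recovery`) runs simulate → aggregate → fit
per replicate and reports per-parameter bias, RMSE, and coverage of nominal
95% Wald intervals (replicates with an undefined SE for a parameter are
excluded from that parameter's coverage denominator and visible in the
per-replicate table).  The shipped validation uses an interior truth
(C = 0.6, P_Moral = 0.4, P_Hypocritical = 0.2, P_Antisocial = 0.1, b = 0.1)
with 200 participants × 500 replicates — large enough for coverage to be
estimated to about ±1 percentage point while the whole study runs in about a
minute — plus a 100-replicate two-group study checking that a true P_Moral
difference of 0.15 dominates all null comparisons.

## Pipeline conventions

Aggregation excludes training trials, rejects duplicate (participant, trial)
keys, unknown value codes and missing columns with row-level diagnostics, and
fails on logs without a test phase.  Ingestion of foreign trial-log dialects
goes exclusively through a user-editable `ColumnMapping` (column names plus
decision/phase value codes); no external schema is hard-coded.  Reports
round for display the way the reporting style conventionally does — G²/ΔG²
to two decimals, p to three, w to two, round-half-up, with "< 0.01" /
"< 0.001" shown when a positive value would display as zero — while the JSON
report keeps full precision.  Comparisons are reported unadjusted for
multiplicity, matching the analysis style the package mirrors.

## Known limitations

- No hierarchical / latent-trait extension: parameter heterogeneity within a
  group biases no parameter of the aggregate model only under specific
  conditions; use the recovery harness with per-participant jitter (not
  implemented) before trusting aggregate estimates on strongly heterogeneous
  populations.
- Wald intervals and SEs are asymptotic; they degrade near boundaries (where
  the package reports NaN rather than pretending otherwise).
- The ΔG² reference distribution is the usual asymptotic χ²; no bootstrap or
  exact small-sample calibration is provided.
- Only the fixed two-tree model is implemented — this is not a general MPT
  compiler.
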