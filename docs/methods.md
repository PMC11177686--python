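# Methods

## Model structure

A discrete-time cohort Markov model with three health states —
progression-free survival (PFS), progressed disease (PD), death — a
1-month cycle and a 10-year horizon (120 cycles, configurable). The
whole cohort starts in PFS; PD cannot revert to PFS; death is absorbing.
Propagation is the left product of the occupancy row vector with the
3×3 transition matrix, so every trace row sums to 1 to machine
precision, PFS occupancy is non-increasing and death occupancy
non-decreasing by construction.

## Transition probabilities from medians

Under a constant hazard, the per-cycle event probability implied by a
median time-to-event *m* (months) is `1 − 0.5**(1/m)`, identical to
`1 − exp(−ln2/m)`. The three hazards map as:

| transition | median used |
|---|---|
| PFS → PD | median PFS |
| PFS → death | median OS |
| PD → death | median OS − median PFS (post-progression) |

This mapping is the unique one under which all ten published baseline
probabilities of the glioblastoma comparison (both arms) are reproduced
at two decimals from the four arm medians — including the BEV+LOM
PFS-stay value 0.77, which equals the full-precision complement 0.7745
rounded. The *printed* rounded row 0.77/0.15/0.07 sums to 0.99; when
such externally supplied rows are loaded (precision mode `fixture`),
the stay probability is recomputed as the complement of the exit
probabilities (0.78 here) and the repair is recorded as a provenance
note — exit probabilities carry the clinical signal and are never
rescaled. Exit masses above 1 are a hard error. Infinite medians are
accepted and map to probability 0, so degenerate no-event arms can be
expressed in synthetic configurations.

The default precision mode (`derived`) uses full-precision derived
probabilities; the printed two-decimal table is retained in the fixture
for comparison runs and as the source of the one-way sensitivity limits.

## Accrual and discounting

Cycle *t* (t = 1..N) accrues the state membership at cycle *t*; cycle 0,
the decision point, accrues nothing. The optional half-cycle correction
(`half_cycle: true`, default off) instead accrues the average of each
cycle's entry and exit occupancy. Utilities are per-year weights divided
by 12 per monthly cycle; costs are per-cycle per-state amounts; death
accrues zero cost and zero utility and there is no one-time terminal
cost. Both streams are discounted with the continuous-equivalent monthly
factor `(1 + r)**(−t/12)` at an annual rate r = 0.05 — smooth, standard,
and exact at annual boundaries.

An analytic oracle (`expected_state_time_closed_form`) computes the same
discounted person-time per state from closed-form occupancy expressions
— `PFS(t) = p**t`, `PD(t) = f·(q**t − p**t)/(q − p)` (or `f·t·p**(t−1)`
when the stay probabilities coincide) — entirely independently of the
trace recursion; the test suite requires agreement to 1e-9 on random
chains, including discounting.

## Economic comparison

Increments are intervention minus comparator. The ICER is reported as
the signed ratio ΔC/ΔE with signed-infinity conventions at ΔE = 0;
dominance ("dominant": at least as cheap and more effective;
"dominated": the mirror) replaces the ICER as the decision statistic
when the increments favor opposite arms. Net monetary benefit
NMB = λ·QALYs − cost is reported per arm; the decision at threshold λ is
cost-effective iff the intervention dominates or ΔE > 0 with ICER < λ,
which coincides with the incremental-NMB sign whenever ΔE > 0.

## Base case: sign of the QALY increment

With the derived matrix, expected discounted person-time is ≈3.37
months in PFS and ≈4.90 in PD for BEV+LOM versus ≈1.22 and ≈8.48 for
LOM. The monotherapy arm's much longer post-progression sojourn —
mechanical consequence of its 7.1-month post-progression median versus
4.9 for the combination (8.6 − 1.5 vs 9.1 − 4.2) — outweighs the
combination's progression-free gain at utilities 0.89/0.74, so the QALY
increment is **negative** (≈ −0.061) and the combination is dominated:
costlier by ≈$10,980 and less effective. This is a property of the
median-derived transition matrix itself, not of any accrual convention:
the same sign obtains undiscounted, with or without half-cycle
correction, and with the published two-decimal probabilities in place of
the derived ones. Published per-state QALY splits for this comparison
that show the opposite sign are not reproducible from the same
transition matrix under any cycle-accounting convention we identified,
and are treated as non-binding references. The headline decision — the
combination is not cost-effective at $35,906/QALY — is unaffected and,
if anything, strengthened by dominance.

## Sensitivity analysis

**One-way (tornado).** Each parameter is set to its low and high bound
in turn, everything else at base, and the full pipeline re-run.
Probability parameters take the published lower/upper limits; cost and
utility parameters, which have no published ranges, get ±20% (utilities
clamped at 1). Bounds that push a PFS row's exit mass above 1 are
rescaled proportionally to validity and flagged on the row, never
silently dropped. Because the base-case ICER is negative (dominated),
ICER spans mix signs and do not rank parameters meaningfully; rows
therefore carry both the signed ICERs and the incremental NMB at the
configured WTP, and the tornado is sorted by NMB span — the robust
ordering when dominance occurs.

**Probabilistic.** 1,000 Monte-Carlo iterations (configurable). The
published text names no distributions, so the package uses standard CEA
practice: Beta for probabilities and utilities, moment-matched to the
base value with the low/high range read as a 95% interval
(SD = (high − low)/3.92; infeasible matches fall back to
uniform(low, high) with a warning), and Gamma for costs with mean = base
and SD = 25% of the mean (configurable `cost_sd_fraction`). Exit
probabilities are sampled independently and the stay probability
renormalized; draws whose exit mass exceeds 1 are rejected and resampled
with the rejection count reported. Draws are reproducible given the
seed, which is mandatory for every stochastic entry point. The CEAC
reports, per λ on a 0–150,000 grid in 1,500-unit steps (101 points,
covering both the $35,906 threshold and the US$100k–150k oncology
range), the fraction of draws with positive incremental NMB. With this
fixture the curve is essentially flat at zero: ~100% of draws are not
cost-effective at $35,906/QALY, and among the minority of draws with a
positive QALY increment the 5th-percentile ICER is on the order of
$100,000/QALY.

## Synthetic data

`generate_trial_arm` draws patient-level exponential progression times
(median = the arm's median PFS) and post-progression survival times
(median = median OS − median PFS), OS being their sum — exactly the
constant-hazard structure the transition derivation assumes, so
parameter-recovery tests are well-posed. No censoring is simulated: the
model consumes only medians, and censoring would add nothing testable
at this level. `estimate_medians` takes the sample median of the
progression times and of the *post-progression* times, reconstructing
the OS median additively; the raw sample median of the OS times would
not do, because the median of a sum of exponentials exceeds the sum of
the medians, which would bias the PD→death hazard low. What the
generator does **not** emulate: censoring and dropout, Kaplan–Meier
median estimation, non-constant (e.g. Weibull) hazards, correlated
progression and survival times, or patient-level cost heterogeneity —
so passing recovery tests demonstrate internal consistency of the
median→probability chain, not robustness to real-trial features.

`generate_random_config` draws structurally valid two-arm
configurations uniformly within constraint intervals (defaults keep
derived exit masses below 1: median PFS ≥ 1 month, post-progression gap
≥ 0.5 months); pinning every interval reproduces the packaged fixture.

## Fixture cost inputs

Unit prices are published; per-administration arithmetic is not, so the
fixture assembles per-cycle costs under documented, overridable
defaults: 65 kg body weight, 1.72 m² body surface area, bevacizumab
10 mg/kg every 2 weeks (3 administrations per 6-week trial cycle,
whole 100 mg vials at $209.50), lomustine 90 (combination) or 110
(monotherapy) mg/m² per 6-week cycle capped at 200 mg in whole 40 mg
capsules at $3.25, with 6-week costs rescaled to the monthly model cycle
by 30.4375/42. Adding the per-cycle adverse-reaction management and
medical-examination fees gives PFS costs of $3,665.95 (BEV+LOM) and
$470.85 (LOM) per cycle. The PD-state (second-line) cost is a
configured input, set to one temozolomide unit plus monthly imaging and
labs ($227.03, both arms). No headline quantity depends on these
assembly choices; `markovcea.config.fixture_drug_costs` exposes the
arithmetic and the test suite checks the fixture file against it.

## Numerical choices and degenerate inputs

- Row-stochasticity is enforced at 1e-12; accrual identities
  (totals = sum of per-state components) at 1e-9.
- Equal PFS/PD stay probabilities switch the PD occupancy formula to its
  `f·t·p**(t−1)` limit (guard at |q − p| ≤ 1e-12).
- ΔE and ΔC within 1e-12 of zero are treated as ties ("equivalent"); a
  zero QALY increment with nonzero cost reports a signed-infinite ICER
  with a dominance annotation.
- The acceptance script and all stochastic tests use explicit seeds;
  identical seeds give bit-identical draw sequences.
- Problem sizes: 120-cycle traces throughout; 1,000 iterations for the
  PSA; n = 5,000 patients per synthetic arm for recovery tests (order
  statistics put the median's sampling error well inside the ±0.02
  acceptance band); 100–1,000 random chains for property suites.

## Known limitations

- Two strategies only; no efficiency frontier, EVPI or budget impact.
- Constant hazards and a time-invariant transition matrix; no cure
  fraction, no adverse-event state (AE management enters as a per-cycle
  cost), no terminal-care cost.
- PSA distributions and dosing arithmetic are reconstructions under
  documented defaults, since the source analysis does not state them;
  scatter-level results are reproducible in distribution only.
- All monetary inputs are taken as USD; currency conversion is out of
  scope.
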