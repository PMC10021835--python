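# Methods

## Model structure

The model is an individual-level (first-order Monte Carlo) state-transition
microsimulation of women of reproductive age in India. Women enter at age
14 and are followed for 35 annual cycles (ages 14–49). Four health states
carry the utilities: non-pregnant (1.0), pregnant (0.99), history of
hysterectomy (0.94) and dead (0). At entry a woman has a history of
hysterectomy with probability 0.017 (she then remains in the 0.94 state and
can never become pregnant) and otherwise starts non-pregnant with one prior
cesarean section (CS) at the strategy-specific history-of-CS prevalence
(0.172 national, 0.128 rural, 0.282 urban).

Each cycle a non-pregnant woman becomes pregnant with probability 0.0654
(India's fertility rate expressed as an annual pregnancy probability). A
pregnancy is carried to term and resolved *within the cycle* by a delivery
episode: first an access draw (probability that she delivers in a facility
with comprehensive emergency obstetric care, CEmOC — 0.502/0.472/0.557 by
arm), then one of two decision trees.

**With access.** In order: (1) antepartum absolute indication — placenta
previa and placenta accreta at prior-CS-dependent probabilities, plus a
general antepartum indication (0.0362) — leading to an antepartum CS, with
previa→PPH 0.2111, accreta→PPH 0.6 and hysterectomy 0.765, and
antepartum-indication mortality 0.00323; (2) otherwise a non-indicated
antepartum CS at the calibrated probability; (3) otherwise labor: a woman
with a prior CS chooses elective repeat CS versus trial of labor (TOLAC)
per the prior-CS table; TOLAC resolves as a multinomial over uterine
rupture (0.0169; → PPH 0.314, hysterectomy 0.0819, intrapartum-indication
mortality 0.0025, costed as a CS), intrapartum CS (0.739), non-indicated
intrapartum CS (calibrated), or VBAC; a woman without prior CS faces an
absolute intrapartum indication (0.144, mortality 0.0025) or the calibrated
non-indicated intrapartum CS, else a vaginal delivery with PPH 0.009
(mortality 0.006) and hysterectomy 0.0003; (4) every other CS can be
complicated by emergency hysterectomy (0.0027); (5) every peripartum
hysterectomy leads to ICU admission with probability 0.357 and ICU
mortality 0.2165, and routes the survivor to the post-hysterectomy state;
(6) episode cost = delivery-mode cost (vaginal 153.70, CS 745.66, 2016 USD)
plus event costs (PPH incl. transfusion 79.89, hysterectomy 2241.42, ICU
1172.50). With access, neonatal survival is 100 %. Antepartum and
intrapartum absolute indications are mutually exclusive (antepartum
evaluated first).

**Without access.** Every delivery is vaginal and costed at the vaginal
price only; transfusion, hysterectomy and ICU care are unavailable. An
absolute indication (antepartum or intrapartum) is fatal to the neonate.
The unmet intrapartum indication (obstructed labor) additionally risks
uterine rupture (0.0169, → PPH 0.314), fistula (0.0001), incontinence
(0.0011) and stroke (0.0015). PPH is tallied but untreatable; its
mortality uses the without-access value (0.0006). Indication mortalities
(0.00323 antepartum, 0.0025 intrapartum) apply as printed.

Utilities use a half-cycle convention: each cycle credits the average of
the utility of the state occupied during the cycle and the utility at
cycle exit, so a woman who dies during delivery earns half the pregnancy
utility that cycle and nothing afterwards. Discounting (off by default, as
the source analysis used none; 3 % available by config) weights cycle
*t* by (1+r)^-(t-1). Costs are one-time episode amounts credited in full
in their cycle.

## Engines

`run_cohort` simulates each woman individually. Every (seed, woman, cycle)
triple seeds its own NumPy substream and the episode tree consumes one
uniform per decision in fixed order, so runs are bitwise reproducible and
strategies can be compared with common random numbers.

`expected_value` computes the same quantities exactly: the delivery tree
is enumerated analytically (the simulation and the enumeration execute the
*same* tree code through an abstract chooser, so the leaf set cannot
drift), and the cohort distribution over {non-pregnant × prior-CS count
0–5, post-hysterectomy, dead} is propagated cycle by cycle. Prior-CS
counts above 5 reuse the top row of the prior-CS table; the table itself
tops out at "3+". The exact engine is the verification oracle for the
Monte Carlo engine (agreement within 4 standard errors is enforced in the
test suite) and the evaluator used by calibration and the deterministic
sensitivity sweeps, which are therefore free of Monte Carlo jitter.

## Parameters

All parameters live in `src/cemocsim/data/parameters.csv` (id, baseline,
family, params, units): probabilities with beta distributions, costs
(2016 USD) with gamma distributions, utilities with uniform distributions.
Two near-duplicate PPH-mortality rows (0.006 with access, 0.0006 without,
with identical printed betas) are kept as distinct parameters exactly as
published. The published utility values come without ranges; the shipped
uniforms are symmetric about the baselines (pregnant 0.98–1.00,
post-hysterectomy 0.89–0.99) and the non-pregnant and dead utilities are
point masses.

PSA draws every parameter independently from its distribution, except the
trial-of-labor node (uterine rupture / intrapartum CS / non-indicated
intrapartum CS / VBAC complement), whose branch probabilities are
standardized and drawn jointly from a Dirichlet. Its concentrations are
the branch baselines scaled by the smallest effective sample size
(α+β) among the sibling betas, which preserves every printed branch mean;
using the printed alphas directly as one concentration vector would not,
because their effective sample sizes differ by two orders of magnitude.
Any node whose independently drawn siblings sum above one is renormalized
proportionally with a warning, so every sampled model is well-formed.
Calibrated non-indicated CS probabilities are held at their
baseline-calibrated values across PSA draws.

### Prior-CS table

The probabilities of previa, accreta and elective repeat CS by number of
prior cesareans are a config input (`data/prior_cs.csv`) with documented
defaults:

| prior CS | previa | accreta | elective repeat |
|---|---|---|---|
| 0 | 0.0006 | 0.0004 | — |
| 1 | 0.0013 | 0.0012 | 0.60 |
| 2 | 0.0022 | 0.0025 | 0.85 |
| 3+ | 0.0040 | 0.0060 | 0.95 |

Previa/accreta rise with each prior CS (the clinical dose-response) and
are anchored so that the count-weighted averages under the national arm's
prior-CS mix reproduce the published marginal previa/accreta event rates
(~0.5 and ~0.4 per 10,000 women per year). The elective-repeat default of
0.60 after one CS matches the reported contemporary TOLAC share in India
(~34 % of prior-CS deliveries attempt labor), rising for higher counts.
Users with the exact supplementary values can substitute their own CSV.

## Calibration

Non-indicated CS probabilities are not observed; they are estimated by
sweeping (p_antepartum, p_intrapartum) along a regular grid that holds
their published baseline ratio 0.0094 : 0.018, evaluating the achieved CS
rate — cesarean deliveries per full-term pregnancy — with the exact
engine at the full 35-cycle horizon, and selecting the grid point
minimizing |achieved − target| (default grid step 0.001, tolerance 0.005).
Because the achieved rate is monotone in the swept probability, a coarse
pass at 10× the step followed by a fine pass around the coarse optimum
selects the same point as the full fine grid. A target at or below the
indicated-only floor forces both probabilities to zero (the rural
assumption that no CS are performed without indication) and flags the
result as floor-constrained.

Under the shipped parameters the indicated-only floors are 18.2 %
(national arm), 15.5 % (rural) and 24.7 % (urban): the national and rural
targets lie below their floors, so those arms run non-indicated-free at
their floor rates, while the urban arm calibrates exactly to 28.2 %.

## Reporting units

Cohort tallies are converted to events per 10,000 women **per year**
(lifetime tally / horizon — the unit of the published event tables, whose
pregnancy count of ~646 per 10,000 women corresponds to one year of the
0.0654 annual pregnancy probability), extrapolated to a reference female
population (default 3.25×10⁸, recovered from the published per-10k /
national pairs), and to maternal deaths per 100,000 and neonatal deaths
per 1,000 live births. Rates with zero live births in the denominator are
reported as undefined, never as zero.

## Sensitivity analyses

One-way sweeps default to ±50 % of baseline, clipped to the units-legal
range (the published ranges are not printed); each grid value rebuilds the
parameter set with the single substitution and recomputes the frontier on
the exact engine. The two-way analysis calibrates a custom strategy for
every (access, CS-rate) grid cell — floor-infeasible cells are labelled,
not dropped — and reports the cost/QALY surface with finite-difference
gradients at the cell of interest. PSA defaults to 1,000 draws × 2,000
Monte Carlo women (scaled down from the base-case cohort; the exact
evaluator is available as a faster per-draw alternative) and reports the
frequency with which each arm is optimal at the willingness-to-pay
threshold of $1,939.61 per QALY (India's 2017 GDP per capita).

## What the synthetic fixtures do and do not show

`random_parameter_table` emits registry-dialect CSVs with probabilities
feasible at every decision node, log-uniform costs in [10, 5000] and
utilities in [0.5, 1]; the test suite uses them to verify structural
invariants (leaf-probability conservation, tally conservation, engine
agreement) across the whole parameter space, not just at the published
values. `degenerate_scenarios` pins closed forms: zero fertility (QALY =
horizon exactly), certain uncomplicated pregnancy (two-leaf cost form),
unmet certain indication (all neonatal deaths, undefined mortality
ratios), certain first-delivery death (QALY = half the pregnancy utility).
Passing these shows the machinery is correct under the model's
assumptions; it cannot show that the tree wiring matches the original
(unpublished) tree figure, nor that real Indian cohort data would follow
the model.

## Numerical and design choices

- Horizon 35 cycles by default (49 − 14); cohort 10,000 women; seeds are
  explicit everywhere and results are bitwise reproducible.
- Uterine rupture under access is managed surgically: counted as a
  cesarean and costed at the CS price (the stated cost equivalence).
- PPH transfusion cost applies only with access; without access the PPH
  event is tallied but uncosted beyond the vaginal delivery.
- The model tallies a single neonatal-death counter (no separate
  stillbirth state).
- Strategy access probabilities default to the parameter-table values
  (0.502/0.472/0.557); the slightly different prose values
  (0.4958/0.4719/0.5574) can be supplied via a custom strategy table.
- The general antepartum indication (0.0362) is additive to the
  prior-CS-table previa/accreta risks, with previa/accreta drawn first.
- ICU admission is reachable only through peripartum hysterectomy, the
  only ICU-entry probability available.
- ICERs are reported to 2 decimals; full precision is kept internally.

## Known limitations

- The decision-tree wiring is reconstructed from the published parameter
  list and assumption text; the original tree figure is not available, so
  event rates that depend on fine wiring (notably neonatal mortality
  without access, which here follows every unmet absolute indication) can
  differ substantially from the published table values.
- Between-arm QALY differences are of order 10⁻³ QALY per woman —
  below Monte Carlo resolution at 10,000 women. Frontier composition from
  Monte Carlo output is therefore noise-dominated; use `expected_value`
  for dominance and ICER statements. Because the model charges no QALY
  loss for neonatal deaths (out of scope) and access carries in-model
  mortality through the ICU pathway, higher access does not raise maternal
  QALYs here, and the low-access/low-CS rural arm dominates on
  cost-effectiveness grounds.
- No background (non-obstetric) mortality, no neonatal QALYs, no sepsis,
  abortion, antenatal or late-postpartum complications; the model covers
  labor, delivery and the immediate postpartum period only.
- Costs are consumed already standardized to 2016 USD; no currency or
  inflation machinery is included.
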