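# Methods

## Scope and intent

`sitsim` simulates the population dynamics of a generic fly-like insect
pest under three scenarios — no control, sterile-male release (SIT), and
sterile males carrying a biocide (boosted SIT) — to ask when the biocide
makes the release programme cheaper (fewer males) or rescues it where
plain sterility fails. The model is deliberately generic: no space, no
resource competition, no seasonality, a single release. Immature mortality
is folded into the fecundity parameter `F`, which counts recruits that
reach maturity, not eggs laid.

## State and scheduling

Individuals are stored as a structure of numpy arrays (one array per state
variable) rather than one object per insect; the uncontrolled runs reach
30,000–60,000 agents and a vectorized daily step keeps a full
three-scenario replicate under a second. The per-day schedule runs eight
processes in fixed order (development, disease progression, release, lek
transmission, mating/laying with vertical transmission, horizontal
transmission, senescence); all processes read frozen start-of-process
state, so same-day chains (e.g. a male contaminated in today's lek
infecting a female through today's mating) cannot occur except where the
schedule orders them (lek precedes mating). Ages increment at the end of
the day and the strict tests `age > Timmature` (maturity) and
`age > Tgeneration` (death) give each individual exactly `Tgeneration`
days of life; the spec-style alternative (death check before the age
increment) would leave agents one day older than the lifespan inside a
step, violating the age-coherence invariant we assert after every step.

## Randomness and seed matching

One `numpy.random.Generator` (PCG64) per replicate drives every draw, in
scheduled order. Draws are only consumed when the affected agents exist
and the probability is informative (`0 < p < 1`); since no contaminated
agent exists before the release, the control, SIT and boosted runs of one
seed consume identical streams up to the release day — which is what makes
re-simulation from the same seed an exact stand-in for state checkpointing
and gives day-for-day matched trajectories before the release. The same
gating makes a boosted run with `Ph = Pv = Pc = 0, Virulence = 0`
bit-identical in population terms to the SIT run (the only difference is
the inert "contaminated" label on released males).

Replicate seeds are derived by SHA-256 hashing of the base seed with the
pest-cell values (`F`, `Csterile`, `Csperm`); biocide parameters do not
enter the hash, so all biocide combinations within a pest cell share
initial conditions, grid rows are unchanged when axes gain values, and the
control run and SIT sweep — which biocide parameters cannot influence —
are computed once per cell and reused.

## Reproduction

Females perform `Nmating` lifetime matings at ages spread evenly across
the adult span: threshold *k* is `Timmature + ⌊(k−1)(Tgeneration −
Timmature)/Nmating⌋`, and a female attempts her *k*-th mating (at most one
per day) on the first day with a mature male present on which her age
exceeds threshold *k* and she has completed *k* − 1 matings. Delayed
opportunities are retried daily — in particular, founders initialized
mature catch up on their schedule at one mating per day. Partner choice
uses the cumulative-probability method over male competitiveness; males
serve any number of females per day. The mating history needed by all
three sperm-competition regimes is kept as a sufficient statistic (first
partner status, last partner status, fertile count, total count) instead
of an explicit 0/1 list. Fractional clutch expectations (the `share`
regime, or `F` not divisible by `Nmating`) are realized by stochastic
rounding — floor plus a Bernoulli(remainder) extra recruit — which
preserves the expected growth rate that the expected-generations formula
assumes. Offspring sex is an independent fair coin per recruit.

## Biocide

Three routes: horizontal at mating (`Ph`, either direction, evaluated on
pre-mating health after the day's reproduction), vertical to the clutch of
a contaminated mother (`Pv`), and a pooled daily lek event contaminating
each healthy adult male with probability `Pc` whenever at least one
contaminated adult male exists (leks are male aggregations; females and
immatures are not exposed). The lethal time `LT` is a fraction of the
adult phase, so `Tcontamination = round(LT·(Tgeneration − Timmature))`
days (floor one day) and the clocks of vertically contaminated immatures
stay frozen at zero until maturation. At the end of the window the
individual dies with probability `Virulence` or heals with no immunity;
re-contamination restarts the clock. Released inoculated males obey the
same clock and virulence as any contaminated individual.

## Scenario protocol and the success metric

The uncontrolled run stops when the total population first reaches
`NX = nx_multiplier·N0` (day `t+1`, hard cap 50 lifespans); the release
day `t` is the first day an adult of generation `nbGeneration − 1`
exists, with a fallback (flagged in the output) to the latest generation's
first maturation day if that generation never matures in time. Released
males enter freshly mature (age `Timmature + 1`) with competitiveness
`Csterile`.

`N(t+1)` — the quantity compared against the success threshold
`0.5·NX` — counts **every living individual, including released sterile
males still alive on that day**. This literal reading of "population size"
is a substantive choice: at low fecundity (`F = 6`) the released cohort
dies of old age before `t+1` and SIT behaves classically
(monotone in ratio), whereas at high fecundity (`F = 45`) the window
between release and assessment is shorter than the sterile males' lifespan,
so large releases inflate the count while the post-release surge of newly
maturing wild males dilutes the sterile mating share — making `N(t+1)`
non-monotone in the ratio with a minimum near `0.5·NX`. That is precisely
the regime where SIT can fail at every ratio up to 20, and where a biocide
whose lethal window elapses before `t+1` (short `LT`) can rescue the
programme by removing the inoculated males from the count and killing
contaminated wild adults. With a long lethal window (`LT ≥ 0.5`,
i.e. ≥ 20 days) no biocide death can precede `t+1` at high fecundity and
boosted SIT is distributionally identical to SIT there.

The gain uses the printed convention `G = (ratio_SIT − ratio_SIT_b) /
(ratio_SIT + ratio_SIT_b)`, with `G = 1` when only SIT fails; the
symmetric `G = −1` is assigned when only boosted SIT fails, and replicates
where both fail are excluded from mean G (but counted in the failure
fractions).

## Defaults and problem sizes

Defaults follow the canonical parameter table: `N0 = 30`,
`Tgeneration = 60` d, `Pimmature = 33` % (so `Timmature = 20` d),
`Nmating = 3`, `Cwild = 1`, `NX = 30,000`, ratio sweep 1–20, success at
`0.5·NX`, 50 replicates per combination in the full factorial
(6,480 combinations: `Ph ∈ {0.1, 0.25, 0.5}`, `Pv ∈ {0, 0.25, 0.5}`,
`LT ∈ {0.1, 0.25, 0.5, 0.75, 0.9}`, `Virulence ∈ {0.25, 0.5, 0.75, 1}`,
`Pc ∈ {0, 0.25}`, `F ∈ {6, 45}`, `Csterile ∈ {0.5, 1, 2}`, three sperm
regimes). The test suite reproduces the protocol at reduced scale — the
pest-trait grid at 6 replicates per cell and the rescue experiment at the
full 50 replicates — sizes chosen so the whole suite completes in about a
minute; statistical assertions carry correspondingly generous tolerances,
noted per test.

## What the generator does and does not emulate

The synthetic populations realize exactly the stated life histories:
uniform founder ages on `[0, Tgeneration)` (the distribution's support is
not pinned down elsewhere; this is the assumption), alternating founder
sexes for an exact 1:1 ratio, stochastic offspring sex, and deterministic
mating-age thresholds. Real populations add mortality before senescence,
density dependence, seasonality, dispersal and measurement error — none of
which are modelled — so passing tests demonstrate internal consistency of
the protocol and its statistics, not field-level forecasting skill.
Because whole cohorts share thresholds, generations are more synchronized
than in nature (and than under stochastic daily mating); quantitative
margins that sit close to the `0.5·NX` threshold (notably which
high-fecundity cells fail and how often) are sensitive to this
synchronization, while the qualitative structure — failures confined to
high fecundity, rescue requiring a lethal window shorter than the
release-to-assessment gap, gains increasing with transmission — is not.

## Numerical choices and degenerate inputs

Durations round half-up to whole days; the lethal window floors at one
day. `F = 2` is rejected (the expected-generations formula divides by
`ln F − ln 2`), as are odd `N0`, out-of-range probabilities, and
`Nmating` larger than the adult span in days. An uncontrolled run that
cannot reach `NX` within 50 lifespans raises an explicit failure rather
than looping. Sweeps stop at the first success; a full sweep without
success returns an explicit failure marker (serialized as ratio −1 in
CSV). Empty populations, empty male pools (females defer, consuming no
randomness) and zero-egg clutches are all well-defined no-ops.

## Known limitations

- Single release only; repeated-release strategies are out of scope.
- Biocide mortality is route- and sex-symmetric; donor/recipient dose
  asymmetries are not modelled.
- Lek transmission is a single pooled daily event independent of the
  number of contaminated males.
- The release-day heuristic depends on the generation-counting formula;
  for extreme fecundities the flagged fallback rule applies.
- Quantitative failure/rescue rates at high fecundity sit on thin margins
  (see above) and should be read as regime indicators, not point
  predictions.
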