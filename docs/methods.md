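# Methods

## Measurement model

A whole-blood sample is diluted 1:12 and hemolyzed, so intracellular and
plasma potassium mix. With hematocrit Ht (percent of blood volume occupied
by erythrocytes), the measured hemolysate potassium K_hem decomposes as

    K_all  = K_hem · dilution
    K_pl.d = K_pl · (100 − Ht) / 100
    K_er.d = K_all − K_pl.d
    K_er   = K_er.d · 100 / Ht        [mmol/L]

The chain assumes the hemolysate is a volume-weighted mixture of the two
compartments and applies no trapped-plasma correction to the hematocrit — a
known small bias source inherent to the dilution protocol. The decomposition
is algebraically exact: the generator's forward model
`k_hem = (k_er·ht/100 + k_pl·(100−ht)/100)/dilution` inverts it to 1e−9
relative error, which the round-trip tests exercise over 10⁴ random draws.

Interpretation hinges on three facts about the system: plasma potassium is
homeostatically defended and does not track the cellular store (so K_er is
an independent marker); a low K_er (< 90 mmol/L) marks cellular deficit from
loss, Na/K-pump inhibition, or osmotic sodium load; a high K_er
(> 110 mmol/L) marks uptake of KCl released by eryptosis, whose triggers
(inflammation, oxidative stress, sepsis) make it a severity signal.

## Derived panel and nomogram

By analogy with the plasma acid-base panel, referenced to plasma chloride:
K_er.st = Cl (standard-bicarbonate analog), K_er.exc = K_er − Cl
(base-excess analog; conservation K_er.st + K_er.exc = K_er holds by
construction), and pK_er = 7·Cl/K_er (pH analog; the ratio is ≈1 at normal
balance and is scaled by 7 so the neutral point reads as 7). pK_er > 7
denotes cellular alkalosis, < 7 cellular acidosis; exactly 7 (within a
configurable tolerance, default 1e−9) gets a distinct `neutral` label rather
than being forced onto a side. In the (pK_er, K_er.exc) plane the locus of
constant chloride, K_er.exc = 7·Cl/pK_er − Cl, is the buffer curve dividing
the nomogram; every curve passes through (7, 0) at K_er = Cl.

When a sample carries no measured chloride, K_er.st falls back to
100 mmol/L (the approximate normal) with an INFO-level log so assumed
values are auditable. Band boundaries 90 and 110 are inclusive to `normal`.

## Deficit formula

    deficit = mass_kg · 0.65 · (90 − K_er)    [mmol]

0.65 is the cellular fraction of body mass, 90 mmol/L the lower normal
limit used as the repletion target. The formula is linear in mass and in the
distance to target, signed (negative = surplus), and unclamped. The mass
factor is body mass in kilograms: back-solving the acute worked case
(deficit 1365 mmol at K_er 65) gives 84 kg, which then reproduces the
chronic case's printed 1200 mmol at K_er 68 to 0.1% — whereas reading the
factor as a body-mass *index* of 84 would be physiologically absurd.

## Cohort pipeline

Measurements outside the retention band [60, 210] mmol/L are spikes and are
excluded before statistics. Retention bounds are inclusive and configurable:
the band edges themselves are plausible values, and published practice is
ambiguous about whether exactly-210 readings survive a ">210" exclusion
rule. Descriptives are min/max, mean ± sd (sample, n−1 denominator — at
n ≈ 356 the distinction from the population sd is negligible but the choice
is fixed), and median with quartiles by linear interpolation between order
statistics (the common "type 7" definition; no standard is universal, so the
definition is stated rather than assumed).

Spearman correlation uses average ranks. In the tie-free case rho is
computed by the exact formula 1 − 6Σd²/(n(n²−1)), whose integer arithmetic
returns ±1 exactly for perfectly monotone pairs — the constant-chloride
invariant rho(K_er.exc, pK_er) = −1 depends on this; with ties it is Pearson
correlation on ranks. The p-value uses the t-approximation with n−2 degrees
of freedom by default; an exact permutation p-value is available for
n ≤ 10 (enumeration of all n! orderings). Missing values are deleted
pairwise per correlation pair with the effective n reported; a constant
series makes rho undefined and is flagged rather than silently zeroed.

## Synthetic cohort generator

The generator emulates the statistical structure of an ICU cohort so the
pipeline is testable without patient data. Defaults (all overridable in
`CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| n | 370 | study-scale cohort size |
| K_er marginal | shifted log-normal, shift 60 mmol/L, truncated at 210 | positive, right-tailed ("left-shifted" mode), supported on the retention band |
| K_er moments | mean 125.1, sd 26.8 mmol/L | calibration targets; (μ, σ) solved from closed-form truncated-lognormal moments at config time |
| K_pl | N(4.3, 0.4) mmol/L, drawn independently of K_er | plasma potassium does not track the cellular store |
| Cl | N(100, 3) mmol/L, mean −4 when K_er > 120 | chloride follows potassium into surviving erythrocytes; magnitude is a free parameter chosen for a detectable sign at n ≥ 200 |
| Ht | N(38, 5) %, slope −0.08 %·L/mmol above K_er 110, clipped to [12, 60] | eryptosis destroys cells while raising survivors' K_er; slope likewise sign-calibrated only |
| mass | N(84, 15) kg, truncated ≥ 35 | adult ICU range |
| dilution | 12 | measurement protocol |

The marginal family is a design choice: only the moments, range and skew
direction are externally constrained, so any positive right-tailed family
would do; the shifted log-normal is the simplest with an exact truncated-
moment calibration. Because draws are truncated into [60, 210] by inverse-CDF
sampling, no natural draw is ever a spike; outliers enter only through
`inject_spikes`, which replaces exactly k latent values with draws strictly
outside the band and re-derives the observed hemolysate reading, so
370 records + 14 injected spikes always filter to 356 — the bookkeeping the
tests assert. `spike_rate` offers a probabilistic alternative and defaults
to 0.

All draws come from one seeded generator in a fixed order (K_er, K_pl,
chloride noise, hematocrit noise, mass, spike decisions), so identical
config + seed gives a bit-identical table. Latent K_er is stored beside the
observed k_hem so recovery tests never conflate measurement inversion with
sampling noise.

**What passing tests do and do not show.** The generator reproduces the
marginal moments, the independence and coupling *signs*, and the spike
bookkeeping; it does not model repeated measurements per patient (each row
is an independent draw), instrument noise on the ion-selective electrode,
pre-analytical hemolysis artifacts, or any joint distribution beyond the
three stated couplings. Tests passing on synthetic cohorts therefore
validate the computational chain and its statistical machinery, not the
clinical claims about real ICU populations.

## Numerical choices and degenerate inputs

* Hematocrit is accepted only as a percent strictly inside (0, 100);
  fraction-looking values (0–1) are rejected rather than auto-scaled —
  silent unit guessing is a safety hazard.
* A negative erythrocyte share (hemolysate potassium below what plasma
  alone would contribute) raises `ImplausibleSampleError` per record, or
  flags the row `implausible` with NaN panels in the vectorized path; it is
  never clamped to zero.
* K_er = 0 leaves pK_er undefined (domain error in the scalar path, NaN in
  the vectorized path).
* Conservation K_er.st + K_er.exc = K_er is exact in real arithmetic and
  holds to one ulp of the chloride scale (~1e−14 mmol/L) in floats.
* Statistical sanity bands in tests are scaled to the sampling noise of the
  cohort size used: means are checked to 3 standard errors at n ≈ 356 and to
  ±2 mmol/L at n = 1000, where the standard error is ~0.85.
* CSV rows failing validation are quarantined with a stated reason, never
  dropped; quarantined + accepted always equals input.

## Problem sizes

Default test and script sizes — 370-sample cohorts (study scale) for
pipeline checks, n = 1000 for calibration recovery, 10⁴ draws for round
trips, 20 seeds for the independence average — keep the full suite around a
few seconds while leaving every statistical check well-powered.

## Known limitations

* The deficit formula is a linear single-compartment estimate; it ignores
  redistribution kinetics and treats the 0.65 cellular fraction as universal.
* Chloride standing in for the "normal ionic balance" makes the derived
  panel sensitive to chloride disturbances unrelated to potassium (e.g.
  hyperchloremic acidosis).
* No trapped-plasma correction; K_er is systematically measured on slightly
  "diluted" packed cells relative to NMR reference values (~148 mmol/L).
* The nomogram zones are an interpretive analogy, not a validated
  diagnostic classifier.
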