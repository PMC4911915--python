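# Methods

## Model structure and assumptions

The models are deterministic mass-action ODE systems over continuous
abundances (arbitrary units, hours).  They describe mean behaviour of a cell
population; no stochastic kernel is provided because only mean qPCR
abundances are fitted.  Each transcript carries at most one ribosome (the
state chain M → R0 → R1 → R2 → R3 is a single-occupancy abstraction), which
keeps every variant linear in the state given a fixed tRNA-Sec level.

The decisive structural choice is **where the NMD/drop-off competition
acts**: at the UGA-paused, tRNA-free state `R1`, in competition with
tRNA-Sec *binding* (release factor vs tRNA-Sec at the ribosomal A site).
Placing NMD downstream of tRNA binding instead would make steady-state mRNA
*decrease* with tRNA-Sec for every positive parameter set (more binding
would feed the decay branch), contradicting the defining property of the
competition model — that it can only produce a rise with selenium.  With the
competition at `R1` one can show `total = (v_txn − k_nmd·R1)/d_bg` with `R1`
strictly decreasing in the tRNA level, so monotonicity holds universally
(this is also verified as a property test on random parameter sets).

Other structural conventions:

* **Background decay** `d_bg` acts uniformly on every transcript-containing
  state.  This gives the clean invariant `total = v_txn/d_bg` whenever NMD
  (and critical-level loss) carries no flux — in particular at 100% UPF1
  knockdown for Model 1 — and avoids inventing state-specific decay rates.
* **Model 3 poly(A) semantics**: transcription enters at tail level 70;
  completed translation moves the mRNA down one level (70 → 60 → … → 10);
  completing translation at the critical level 10 destroys the transcript
  (no extra rate parameter); drop-off preserves the level.  The 35-species
  system is block-triangular in the levels and is solved as seven cascaded
  5-state chains (the generic linear solver is kept as a cross-check).
* **Model 1B**: gene-wise Model-1 copies share one finite tRNA-Sec pool via
  mass-action binding `R1 + tRNA → R2`.  The tRNA is returned on Sec
  insertion and on decay of the bound state, so free + bound tRNA is exactly
  conserved (NMD occurs before binding and involves no tRNA).  The steady
  state is found by bracketed root-finding on the free-pool level; each gene
  is then a linear chain.  For pool ≫ total mRNA the per-gene solutions
  converge to uncoupled Model 1.
* **Drop-off releases a translatable mRNA immediately** (no refractory
  state).
* **Selenium map**: `s(c) = s0 + smax·c/(c + k_half)` with defaults
  `s0 = 0.1`, `smax = 1.0` (a.u.), `k_half = 10 nM`, shared across genes.
  The basal term is required because cells express selenoproteins without
  added selenium; the saturating form matches the observed plateau above
  ~10–20 nM selenite.  The map is a modelling device, not a measured curve.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `v_txn` | transcription rate | a.u./h | 2 (generator: log-uniform 0.3–10 per gene) | absolute scale is not identifiable from normalized data; per-gene spread emulates the wide abundance range of real panels |
| `k_init` | initiation per free mRNA | 1/h | 8 | order of reported initiation rates; sets how strongly NMD can deplete the pool |
| `r_elong` | per-codon elongation | codons/h | 7200 (2 codons/s) | ribosome-profiling scale; both segment rates derive from it (`k_el1` scaling with the first segment can be switched off, falling back to a 100-codon reference) |
| `k_bind` | tRNA-Sec binding | 1/(a.u.·h) | fitted, bounds 0.1–1000 | the selenium-coupled rate; only the product `k_bind·s` matters |
| `k_nmd` | NMD commitment at `R1` | 1/h | fitted, bounds 1e-4–3 | NMD commitment on the minutes-to-hours scale; the upper bound encodes the physiological range (measured NMD target half-lives) |
| `k_sec` | Sec insertion from `R2` | 1/h | fitted, bounds 0.5–200 | slow relative to ordinary elongation (UGA recoding pauses) |
| `k_drop` | drop-off at `R1` | 1/h | 0 (M1/M1B); fitted for M2/M3, bounds 1e-4–200 | inverse-class genes need `k_drop ≫ k_nmd` |
| `d_bg` | background decay | 1/h | 0.1 | ~7 h mRNA half-life, global gene-expression scale |

All bounds and fixed values are config-exposed; none is hard-coded into the
algorithms.

## Synthetic-data generator

The generator emulates the *design* of the Caco-2 titration study: 11 genes,
selenite {0, 5, 10, 20, 40} nM, n = 8 replicates.  Hierarchy classes are
defined by the plateau fold change relative to NoSe — strong_up 2.5–3.5,
moderate_up 1.3–1.5, flat 0.95–1.05, inverse 0.60–0.75 (a ~30% decrease) —
and parameters are rejection-sampled per class until the *solved*
steady-state ratio of the generating model (M1 for the first three classes,
M3 with `k_drop/k_nmd` between 8 and 30 for the inverse class) lands in the
window, so class fidelity holds by construction, not by assumption.
Transcript features (codon counts, PTC-to-junction distance) are sampled so
that responsive classes are predicted NMD targets under the 50-nt positional
rule (threshold configurable across the 50–55 nt band) and flat genes are
not.

Noise is multiplicative lognormal with CV 0.15 (mean-preserving), i.i.d.
across replicates.  The CV is a calibration choice matched to the visual
error-bar scale of qPCR titration data; replicate correlation, plate/batch
effects, standard-curve/Ct structure and reference-gene (GAPDH) noise are
*not* modelled.  Passing tests therefore demonstrate correctness of the
pipeline under idealized qPCR noise, not robustness to real-world batch
structure.

## Calibration

Only normalized observables are fitted: per condition the model's
steady-state total divided by its own NoSe prediction is compared with the
observed condition mean of NoSe-normalized replicates, weighted by the
standard error (`sd_c/(mean_0·√n)`, delta method; the shared uncertainty of
the reference mean is neglected, which makes single-parameter profiles
slightly overconfident — with the binding rate free this scale error is
largely absorbed).  A condition with zero replicate spread is an error, with
a pooled-variance option.

The multistart scheme draws each start log-uniform within bounds and
alternates one global phase (differential evolution seeded with the
incumbent, small population) with one local phase (trust-region reflective
least squares) until the relative improvement falls below 1e-6 or five
rounds.  One hundred starts reproduce the study-scale protocol; tests and
the acceptance script use 4–8 starts, which suffice for these 3–4 parameter
problems (verified by the recovery tests).

Model ranking uses `BIC = χ² + k_free·ln(n_data)` (Gaussian likelihood with
known SEs, additive constants dropped).  Absolute BIC values are therefore
comparable only within one dataset slice and are not expected to reproduce
any externally reported absolute values; ΔBIC < 2 is flagged as a tie, in
which case the model with fewer parameters ranks first.

## Identifiability

Profiles fix one parameter on a log grid (21 points over ±2 decades around
the estimate by default, clipped to bounds) and re-optimize the remaining
parameters, warm-started sweeping outward.  The pointwise 95% threshold is
`χ²_best + 3.84` (1 dof).  Classification: *identifiable* if the profile
crosses the threshold on both sides; *practically unidentifiable* if it
stays below the threshold over the span on at least one side;
*structurally unidentifiable* if the profile is flat at the optimum to
numerical tolerance (range < 1e-6·max(1, χ²_best)).  Failed grid points are
flagged and skipped, never fatal.

A result derived during development and used as the structural test case:
under normalized steady-state fitting, `k_sec` enters Model 1 only through a
factor that multiplies `k_bind`, so it is *exactly* compensated — a gauge
freedom, classified structural.  Flat-response genes leave `k_nmd` and
`k_bind` practically unidentifiable (any sufficiently small NMD flux fits),
which is precisely why the non-responsive genes are excluded from downstream
mechanistic conclusions.

## Knockdown prediction

UPF1 knockdown is assumed to scale the NMD commitment linearly:
`k_nmd → k_nmd·(1 − kd)`, with `kd = 1` abolishing NMD.  Default levels
{0, 0.25, 0.52, 1.0} combine the measured siRNA efficiencies (48 h/72 h)
with the full-knockdown extrapolation.  Predictions recompute steady states
per scenario; fold changes are relative to `kd = 0` at the same condition.
A comparison report flags genes whose observed knockdown response lies
outside the prediction band (>2 SE in more than half the matched rows), the
SPS2-like discordance pattern.

Two model-level findings temper the predictions:

1. **Ridge dependence.**  Because `k_nmd` is practically unidentifiable
   upward from dose-response data alone, multistart fits often land at the
   top of the allowed range, and knockdown predictions differ along this
   ridge — at ridge-top calibrations the qualitative pattern can even
   invert.  Knockdown predictions are therefore made from calibrations in
   the physiological regime (in the synthetic study, the generating
   parameters); the identifiability stage is the guard that makes this
   caveat visible.  At such calibrations the pattern is robust: fold change
   is monotone in the knockdown fraction, strictly larger without added
   selenium than at 40 nM, and at full knockdown it fades monotonically
   across the titration.  At *partial* knockdown the fold-vs-selenium curve
   can have a tiny interior maximum (≤1% of the effect, for strong genes
   with `k_nmd` near the top of the class range); the deficient-vs-replete
   comparison is unaffected.
2. **Bounded inverse-class response.**  With uniform background decay, the
   full-knockdown fold of an inverse-window Model 3 gene is bounded (~2.5×
   at the default `d_bg`; ~7× even at `d_bg = 0.005/h`), always below the
   strong-class ~3–13×.  Extreme knockdown responses for inverse genes
   would require turnover dominated by deadenylation with negligible
   background decay, a different decay architecture than the uniform-decay
   design used here.

## Numerical choices

* Steady states: direct `numpy.linalg.solve` on the compiled linear system
  (singular systems — no transcript sink — raise an informative error);
  Model 1B by `brentq` on the free-pool balance (xtol 1e-15 relative).
* Time courses: `solve_ivp` (LSODA, rtol 1e-8/atol 1e-10 by default);
  integrator failure is flagged in the result, never silent.
* Chain closed forms guard against non-positive denominators and require
  `d_bg > 0`.
* Optimization in log10 space; penalty residuals (1e6) for degenerate
  parameter combinations instead of exceptions inside optimizers.
* Exact Spearman permutation p-values enumerate all n! orderings for
  n ≤ 10 (mid-ranks for ties, so the null conditions on the tie pattern);
  asymptotic p above that.  The study-size panel (n = 11) uses the
  asymptotic value.
* End-to-end determinism: one master seed is fanned out to every stage via
  `numpy.random.SeedSequence`; reruns with the same config are
  byte-identical.

## Problem sizes

The test suite and the acceptance script run the full study design
(5 conditions × 8 replicates) but scale the Monte-Carlo dimensions to what
the analyses need: 100 random parameter sets for the oracle and monotonicity
properties, 20 simulated datasets each for model selection, CI coverage and
unidentifiability detection, 4–8 multistart starts per fit and 13-point
profiles.  The study-scale protocol (100 starts, 21-point profiles) is the
library default.

## Known limitations

* Single-ribosome occupancy: no polysomes, no ribosome-density predictions.
* The selenium → tRNA-Sec map is assumed, shared across genes, and not
  separately identifiable from the binding constant.
* Protein output, SECIS/trans-factor mechanism, and the alternative
  regulation suspected for SPS2 are out of scope.
* Absolute abundance scales (and hence absolute BIC values) are
  intentionally not comparable across runs; only normalized responses are
  modelled.
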