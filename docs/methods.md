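# Methods

## The assay being modelled

EXPAR (isothermal exponential amplification reaction) amplifies a short
trigger oligonucleotide X — here the 22-nt microRNA let-7a — on a
single-stranded DNA template carrying two copies of the trigger's reverse
complement X', one at each terminus, separated by the complement of a
nicking-endonuclease recognition site plus a short post-cut spacer.  Trigger
annealed at the template's 3' X' copy primes polymerase extension into a
nickable double strand; the nicking enzyme (Nt.BstNBI, top-strand site
GAGTC, cut 4 nt downstream) then releases a fresh trigger copy, closing an
exponential feedback loop.  Annealing at the 5' X' copy is unproductive.
The fraction of annealed trigger that lands productively is called φ
(0 ≤ φ ≤ 1); a symmetric template sits near φ ≈ 0.5, and the asymmetric
designs modelled here (a biotin tag near the 5' terminus that destabilises
the unproductive duplex, plus a toehold-exchange hairpin at the 3' terminus
that filters near-matched interferents) push φ toward 1.

## Kinetic model (`exparkit.kinetics`)

Treating the loop as a consecutive reaction

    X/5'X'T ⇌(θ) X + T →(α) X/3'X'T →(ε) dsDNA →(γ) X

the trigger grows exponentially, c_X(t) = c_X0·e^{βt}, with

    β = ( γλ² / (ε(λ+1)) − (1−φ) / (φ(λ+1)) − α ) · c_T0.

λ is a dimensionless composite of the annealing-equilibrium treatment of
the 5' site.  Its internal definition is not pinned down here; the package
exposes it as a free input with default 1.0 rather than guessing a
composition.  β is strictly increasing in φ, the middle (5'-waste) term
vanishes at φ = 1, and 1/φ makes φ = 0 a domain error wherever it appears.

The per-cycle view is a branching process: each molecule spawns one new
copy per cycle with probability φ, so new copies are Binomial(N_k, φ) and
the mean outcome per starting molecule after n cycles is (1+φ)^n — 2^n for
the ideal reaction, 1.5^n at φ = 0.5.  The binomial per-molecule
independence is the simplest stochastic model with that mean; only the mean
law is externally constrained.

`simulate_mass_action` integrates a mass-action ODE of the full scheme
(free template, trigger, unproductive 5' duplex, extensible 3' duplex,
nickable double strand; nicking treated as catalytic, dsDNA → dsDNA + X)
with its own elementary rate set, because the reduced parameters
(θ, α, ε, γ, λ) and elementary constants are not uniquely
inter-convertible.  Agreement with the reduced model is asserted
qualitatively — early-phase log-linearity, faster annealing reaching a
trigger threshold sooner — never numerically against β.  The right-hand
side conserves total template exactly; LSODA with rtol 1e-10 / atol 1e-14
(both exposed as parameters) keeps the conservation error below 1e-9
relative at every output time, with observed errors near machine epsilon.
Tiny integrator-induced negative concentrations are clipped to zero.

Saturation (dNTP/enzyme exhaustion, dye plateau) is deliberately absent
from the kinetic model; the curve generator imposes it phenomenologically.

## Synthetic data (`exparkit.synthetic`)

Real-time traces are logistic in time,

    RFU(t) = baseline + drift·t + amplitude / (1 + e^{−k(t − POI)}) + N(0, σ²),

chosen because a logistic's midpoint is exactly its point of maximum slope,
so the ground-truth POI is a parameter, not a derived quantity.  Defaults
emulate a plate-reader channel: baseline 100 RFU, amplitude 1000 RFU,
k = 1.5 /min (a 2–3 minute rise), noise 20 RFU (2 % of amplitude), reads
every 60 s over 60 min.  Well POIs follow the log-linear truth
POI = a − b·lg(copies); the default truth (a = 28.3 min, b = 2.09 min per
decade over 0.602–6.02×10¹¹ copies) is the biotin-template calibration the
quantitation stage is designed around, and the standard-template truth is
two-segment ((35.1, 1.39) then (72.2, 5.51), crossing near lg ≈ 8.8–9.0).

Specificity plates scale each well's effective input by a per-species
cross-reaction fraction; defaults span 1.0 (target) down to 5×10⁻⁵,
mirroring the one-to-four-orders separation an asymmetric template
produces across the let-7 family.  Wells below a 0.1-copy floor stay flat;
between the floor and one molecule, Poisson occupancy decides whether the
well fires.  Melt curves are sums of two-state logistic transitions in
temperature (default width 1.5 °C) so −dF/dT peaks at each Tm; the
measured transition temperatures (64.3 °C for the symmetric duplex,
59.9/51.5 °C for the biotin-split pair, 66.61 °C for the hairpin stem)
enter only as generator parameters — nothing in the package predicts them.
Method-comparison tables apply mean-one lognormal multiplicative noise per
replicate (σ² = ln(1 + CV²)); defaults are CV 10 % for the reference
method and 5 % for the test method with 3 replicates per sample.

All generators are pure functions of (specification, seed); per-well seeds
are spawned from the plate seed so plates are reproducible element-wise.

What the generator does *not* emulate: plateau asymmetry and hook effects,
well-to-well amplitude variation, temperature ramping artefacts, and
nonspecific template-only amplification kinetics (available only as a
phenomenological late-POI flag, off by default).  Passing tests therefore
demonstrate correctness of the analysis pipeline under the stated
statistical structure, not robustness to every instrument pathology.

## Curve analysis (`exparkit.curves`)

POI is the time of maximum slope of the sigmoid.  The derivative is
estimated by Savitzky–Golay local least-squares smoothing (window 7,
order 2 by default — the smoothing is configurable because the convention
is not standardised) followed by differencing on the, possibly non-uniform,
grid; the argmax is refined by a parabola through its three neighbours,
with ties broken toward the earliest time.  A well is called amplifying
only when its maximum slope exceeds `min_slope`, which defaults to five
times a robust (MAD-based) noise level of the derivative over the whole
trace; the robust estimate keeps the threshold honest even when the rise
occurs within the first few reads, and because it scales with the signal
the call is invariant under positive affine transforms of the RFU axis.
A scale-relative 1e-12 floor keeps round-off on perfectly flat traces
below threshold.

Tm calling finds peaks of −dF/dT above a prominence threshold (default
10 % of the global maximum).  Here the smoothing window defaults to a span
of about 5 °C derived from the grid step, and peak positions are refined
by a parabola over about a third of that window: at realistic noise a
3-point refinement jitters by more than the 0.5 °C recovery band, while
the wide fit recovers transitions of width ≤ 2 °C to well within it.

Baseline correction subtracts a line fitted to the longest prefix whose
derivative stays below an amplification threshold; on a never-amplifying
trace the fit spans the whole curve, so pure drift is removed entirely.

## Quantitation (`exparkit.quant`)

Calibration is ordinary least squares of POI on lg(copies); on exact line
data coefficients are recovered to ≥ 10 digits and |r| = 1 (experimental
correlation coefficients are properties of the lab's raw points and are
not reproducible at the desk).  The two-segment fitter searches every
interior abscissa and midpoint (in lg space) as a candidate breakpoint,
keeps segments of at least 3 points, and minimises total residual sum of
squares; near-equal segment slopes flag a degenerate (single-line) fit.
Unknowns are quantified by inverse prediction, copies =
10^((POI − intercept)/slope), with a warning outside the fitted range.

φ is estimated from a two-fluorophore quench partition as
drop_3'/(drop_3' + drop_5'), the fraction of hybridised trigger at the
productive terminus under the assumption of matched quencher efficiencies
at the two ends.

Accuracy metrics: RE = (measured − reference)/reference × 100 (the signed
convention consistent with the published inter-method table, save one
ambiguous-sign cell which is excluded from exact checks) and RSD = sample
SD (n−1) / mean × 100.  Copy/mole conversion uses the Avogadro constant to
4 significant figures (6.022×10²³), matching printed conversions at their
precision.  Two LOD conventions are exposed: the lowest calibrated point,
and the copy number whose predicted POI sits 3 SD earlier than the mean
no-template-control POI.

## Template design and specificity (`exparkit.design`)

`build_template` assembles 5'-[X']-[rc(spacer)]-[rc(GAGTC)]-[X']-3', so
the extended top strand reads 5'-[X]-[GAGTC]-[spacer]-[X]-3' and the nick
(4 nt past the site) falls exactly at the junction before the terminal
trigger copy; a 4-nt spacer (default TCCA) is therefore required for
trigger-length release, and `validate_nease_site` checks site count,
release length, and that the template strand itself is not nickable.  The
biotin variant records a 1-based tag position (default 2, counted from the
5' terminus); the toehold variant appends a fold-back arm (default 10-nt
stem, 4-nt loop) leaving a 6-nt toehold, so the invading region exceeds
the incumbent by six bases.  Exact published template sequences are
treated as user input; the shipped let-7a construction is a synthetic
stand-in assembled from the documented architecture.

Nearest-neighbor duplex Tm uses the unified DNA/DNA parameter set with
mismatch tables and monovalent-salt correction (via Biopython's
`MeltingTemp.Tm_NN`).  Target/template hybrids are really RNA/DNA, so the
values are used for *ranking* designs (mismatch destabilises, extension
stabilises) and never asserted against measured transition temperatures.

Interference is defined through the calibration line: an interferent's
observed POI is inverted to apparent copies and reported as a percentage
of its input; non-amplifying wells report 0 % with a floor note.  This
apparent-copies definition is a reconstruction — the original raw
percentage bookkeeping is not available — but it round-trips generator
cross-reaction fractions on noiseless plates to within a few percent
relative.

## Pipeline and IO (`exparkit.pipeline`, `exparkit.io`, `exparkit.cli`)

CSV dialects are fixed-header UTF-8 (`well,time_min,rfu` /
`well,temp_c,rfu`); ingest rejects duplicate (well, time) pairs and
non-numeric cells with row numbers.  Minutes are the canonical time unit
throughout.  Run configuration is a plain `key = value` text file mapping
onto `RunConfig`.  `run_pipeline` chains simulation → POI extraction →
calibration → inverse quantitation → specificity → melt calls → method
comparison, derives every stage's seed from the run seed, names the
failing stage on error, and emits a JSON report whose SHA-256 makes
determinism checkable.  The `exparkit` console script exposes the stages
(`simulate`, `analyze`, `calibrate`, `quantify`, `design`, `specificity`,
`report`) as thin wrappers over the library.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen once: 9–12-decade
dilution plates at 1-min (0.25-min where sub-read-interval precision is
being measured) resolution, 100-seed POI recovery studies, 2000-replicate
branching means, 50-seed piecewise-fit recovery, and 0.25 °C melt grids.
The published wet-lab absolutes (POIs, Tms, quench drops, interference
percentages, LOD) are treated as generator parameters, formula inputs, or
qualitative orderings — for the template speed ordering the toehold POI
truth is taken as 10.24 min, the printed toehold calibration reread with
the decreasing-trend convention at 6.02×10⁹ copies, between the printed
biotin (7.19 min) and standard (15.5 min) values.  The printed toehold
equation itself carries a positive slope that contradicts the displayed
decreasing trend; the coefficients are implemented verbatim for recovery
tests and the inconsistency is flagged here rather than silently
corrected.

## Known limitations

- λ's composition, the exact per-cycle outcome table, the published
  template sequences, and the original interference bookkeeping are not
  reproducible from the available description; each is exposed as an input
  or reconstructed and documented above.
- The kinetic model has no saturation; it describes the exponential phase
  only.
- Nearest-neighbor Tm uses DNA/DNA parameters for RNA/DNA hybrids
  (ranking use only).
- The generator's noise model is Gaussian-additive per read (curves) and
  lognormal-multiplicative per replicate (tables); real instruments also
  show structured drift and outliers the analysis is not tested against.
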