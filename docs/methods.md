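# Methods

## Scope and model

`tricchan` analyzes single-channel recordings of trimeric intracellular
cation (TRIC) channels — homotrimers in which each protomer carries its own
ion-conducting pore — and provides the synthetic recordings needed to test
every analysis stage without raw patch data.

The gating model treats the trimer as N identical two-state monomers that
open and close independently. The number of open pores m ∈ {0..N} then
follows an aggregated birth–death Markov chain with rates

    up(m) = (N − m)·k_open,      down(m) = m·k_close,

whose stationary occupancy is Binomial(N, p), p = k_open/(k_open + k_close).
Aggregated-level sojourns are exponential with rate up(m) + down(m); the
fully open level, for instance, has mean lifetime 1/(N·k_close). Conductance
levels are free parameters rather than forced multiples of the single-pore
conductance, because measured multi-pore levels are sub-additive (the
wild-type levels 42.2/100.6/163.7 pS used throughout the fixtures are not
1:2:3).

Paths are simulated exactly (Gillespie): exponential waiting times by
inverse CDF from a seeded generator, so one integer seed reproduces both the
jump chain and, in rendering, the noise. The initial level is drawn from the
stationary distribution unless a start level is given; the final dwell is
truncated so dwell times sum exactly to the requested duration.

## Trace rendering

`render_trace` emulates the acquisition chain of an inside-out excised-patch
recording: 50 kHz sampling, additive white Gaussian baseline noise, and a
low-pass filter realized as a Gaussian kernel with its −3 dB point at the
cutoff (σ_t = √(ln 2)/(2π·f_c) ≈ 0.1325/f_c; default cutoff 0.5 kHz). A
mains notch filter is not emulated — synthetic data carry no mains
interference. Per-sample current at level m is γ_m·(V − E_rev)/1000 (pA from
pS·mV), with E_rev computed from the ionic conditions (below). The baseline
noise amplitude is a free parameter; fixtures use σ = 0.35 pA, which puts
adjacent levels ≳5σ apart at +60 mV — comparable to the separation a
well-resolved amplitude histogram shows.

## GHK electrodiffusion

Currents and reversal potentials follow the Goldman–Hodgkin–Katz
constant-field flux equation, summed over species with relative
permeabilities (K⁺ ≡ 1). Sign convention: membrane potential is bath
(cytoplasmic) minus pipette (extracellular), so positive current is cation
flow from bath to pipette; this makes a K⁺-preferring channel reverse at
positive potential under K⁺(pipette)/Na⁺(bath) bi-ionic conditions. The
removable singularity at zFV/RT = 0 is evaluated by its series limit.
Constants: F = 96485.332 C/mol, R = 8.31446 J/(mol·K). The default
temperature is 295.65 K (22.5 °C, the midpoint of a 21–24 °C room-temperature
session), giving RT/F = 25.48 mV; at this temperature a 4.84 mV bi-ionic
reversal at 210/210 mM converts to P_K/P_Na = 1.21 to printed precision.

Divalent cations are modeled as impermeant (permeability 0) — the regime the
impermeability controls probe; an extended GHK treatment of divalent flux is
out of scope. The absolute current scale (`p_scale`) maps the dimensionless
flux sum (mM concentrations) to pA. Its default, 0.04 pA/mM, gives a
~330 pS slope conductance in symmetric 210 mM K⁺ near 0 mV — a patch
holding two fully open trimers, the configuration multi-level patches
actually show. The scale cancels in all reversal-potential and permeability
analyses.

`ghk_reversal` locates the zero-current voltage by Brent root bracketing of
the flux sum over ±500 mV; for a pure monovalent bi-ionic condition it
agrees with the closed form (RT/F)·ln(P_K/P_Na) to 1e−9 mV.

## Amplitude histograms and mixture fits

All-points histograms use uniform right-open bins of 0.03 pA by default,
anchored so an edge falls exactly at 0 pA. Mixture decomposition fits a sum
of k Gaussians to raw counts by unweighted nonlinear least squares (lmfit);
Poisson weighting (1/√count) and a shared-σ constraint are options recorded
on the fit object, never silent defaults. k is user-supplied (4 for one
trimer, 7 for two) — no automatic model selection. Initial means come from
the k strongest local maxima of a 5-bin moving-average smoothing, which
stabilizes peak detection at 0.03 pA bins without displacing peaks;
components are reported sorted by mean with ties broken by ascending σ, and
components whose area falls below 0.1% of the total are flagged degenerate.
Conductances follow as γ_m = 1000·(μ_m − μ_0)/(V − E_rev) with μ_0 the
component nearest 0 pA.

## Idealization

Samples are assigned to the nearest level mean (equivalently, half-amplitude
thresholds at midpoints between adjacent means); a sample exactly on a
threshold goes to the lower level. Runs shorter than the dead time are
absorbed into the temporally preceding event (the leading event, having no
predecessor, absorbs forward), then same-level neighbours are coalesced, in
a single left-to-right pass. The default dead time is 0.3/f_c (0.6 ms at
500 Hz), twice the nominal filter rise time: shorter events cannot reach
half amplitude after filtering. With zero noise, no filter, and every dwell
spanning at least one sample, idealization inverts rendering exactly; dwells
shorter than one sampling interval are unobservable by construction, which
is why exactness tests simulate slow gating or sample fast.

## Gating statistics

NPo = t_o/T: total time at any open level over total record time,
deliberately unweighted by the number of open pores. A level-weighted
variant (`weighted_npo`, mean open fraction per monomer) exists under its
own name so the two conventions cannot be silently confused. Dwell summaries
report mean, sd and the maximum-likelihood exponential rate 1/mean;
boundary-truncated first/last events are censored observations and are
excluded from summary statistics (but not from time fractions). Group
comparisons use a two-sided t test, Welch by default with a pooled-variance
option; two identical zero-variance groups return (t = 0, p = 1) by
contract.

The binomial occupancy diagnostic checks the independence interpretation of
the multi-level openings: p̂ = (Σ m·f_m)/N from the time fractions, then a
chi-square of observed versus Binomial(N, p̂) fractions. Time fractions are
autocorrelated, so the statistic is scaled by a conservative effective
sample size of one independent observation per ten events (about threefold
fewer than the true effective count at fixture rates); p-values therefore
err toward non-rejection, which is the safe direction for a diagnostic
whose null is the model being checked.

## I/V fitting and selectivity

`fit_iv` is ordinary least squares, I = aV + b: slope conductance 1000·a,
E_rev = −b/a, standard errors from the usual regression formulas with
first-order propagation (including cov(a,b) = −V̄·var(a)) for E_rev. Because
the GHK bi-ionic I/V is curved, the default fit window is |V| ≤ 40 mV, and
E_rev extraction from strongly curved data should use a narrower window:
measured on the 1.21 bi-ionic condition, the straight-line zero-crossing
bias is ≈0.5 mV at ±40 mV, ≈0.1 mV at ±20 mV, and <0.02 mV at ±10 mV. If
the window would leave fewer than two distinct voltages, the fit falls back
to the full range. A slope within two standard errors of zero leaves E_rev
undefined (raised, not NaN).

`bi_ionic_permeability` implements P_K/P_Na = ([Na]_bath/[K]_pipette)·
exp(E_rev·F/RT) and is the exact inverse of `ghk_reversal` for the bi-ionic
layout.

## Structure geometry

Helix axes are the dominant principal direction (SVD) of the span's Cα
cloud, sign-normalized along the reference axis; kinked helices are handled
by fitting sub-segments (M2a/M2b style) independently, with spans supplied
as a config table — automatic secondary-structure assignment is out of
scope. The trimer C3 axis is the rotation axis of the least-squares (Kabsch)
superposition of chain A onto chain B; the A→C superposition is a
consistency check that warns above 2° disagreement, as does a rotation angle
far from 120°. Tilt angles fold into [0, 90]° via arccos|a·b|. Pore-radius
profiles are labeled by strict thresholds — constricted below 1.15 Å
(narrower than a dehydrated K⁺), wide above 2.30 Å (passes a partially
hydrated ion), intermediate between, boundary values inclusive — and
constriction sites (gates) are maximal constricted runs reported with axial
extent and minimum radius. Coordination contacts use a closed ball (atoms at
exactly the cutoff are included) and exclude hydrogens.

Published tilt tables for deposited structures are only approximately
reproducible because the helix residue ranges behind them are unpublished;
geometry is therefore validated on constructed fixtures (ideal helices with
1.5 Å rise and 100° twist, exact C3 trimers, jittered and rigidly moved
variants) with 1° recovery tolerances, not against deposited coordinates.

## What the synthetic data do and do not show

The generator reproduces the features the analyses rely on: multimeric
conductance levels, exponential aggregated dwells, binomial occupancy,
Gaussian baseline noise, finite filter bandwidth. It omits flicker/1-f
noise, correlated baseline drift, capacitive transients, leak, mains
interference, and any cooperative gating. Passing tests therefore establish
that the pipeline recovers known generating parameters under idealized
recording physics — not that real patches satisfy the independence model
(the occupancy diagnostic exists to ask that question of real data).

## Problem sizes and numerical choices

Default test and acceptance problem sizes: 10⁶-sample traces (20 s at
50 kHz) for histogram-based level recovery, ~10⁶ transitions for occupancy
statistics, 5 replicate I/V datasets at −40..40 mV in 20 mV steps with
0.5 pA measurement noise for reversal-potential recovery (0.1 pA for the
divalent control, whose true reversal is exactly 0). These sizes give
Monte-Carlo errors comfortably inside the published SEMs while keeping the
whole suite in the tens of seconds. All randomness flows from integer seeds
through `numpy.random.default_rng`; no global state.

Known limitations: no hidden-Markov idealization or missed-event likelihood
corrections (dead-time merging only); no multi-exponential dwell fitting or
burst analysis; no activity-coefficient or surface-charge corrections in
GHK; divalent permeation unmodeled; no pore-radius computation (profiles
come from an external profiler).
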