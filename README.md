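# tricchan

Single-channel electrophysiology analysis and structural geometry for
trimeric intracellular cation (TRIC) channels — homotrimers in which each
protomer carries its own pore, so one channel shows a ladder of conductance
levels (closed, one, two, three open pores; six with two trimers in the
patch).

The package is for channel biophysicists who need a reproducible, scripted
version of the classic single-channel workflow:

* **Simulation** — the trimer as an aggregated birth–death Markov chain of
  independent monomeric pores (rates `up(m) = (N−m)·k_open`,
  `down(m) = m·k_close`; stationary occupancy Binomial(N, p)), rendered
  into 50 kHz traces with Gaussian baseline noise and a 0.5 kHz low-pass
  filter.
* **Amplitude analysis** — all-points histograms (0.03 pA bins) decomposed
  into sums of Gaussians; level means → conductances via
  γ = 1000·(μ − μ₀)/(V − E_rev).
* **Idealization and gating statistics** — half-amplitude multi-level
  idealization with dead-time merging; NPo = t_o/T, dwell-time summaries,
  t tests, and a binomial occupancy diagnostic for monomer independence.
* **Selectivity** — linear I/V fits (slope conductance, reversal
  potential) and Goldman–Hodgkin–Katz analysis: P_K/P_Na =
  ([Na]_bath/[K]_pipette)·exp(E_rev·F/RT) under bi-ionic conditions.
* **Structure geometry** — transmembrane helix tilt angles η versus the
  trimer C3 axis from PDB/mmCIF coordinates, and three-class pore-radius
  labeling (constricted < 1.15 Å < intermediate < 2.30 Å < wide) with
  constriction-site (gate) detection.

## Worked example

Simulate a 20 s wild-type-like recording at +60 mV (conductance levels
0/42.2/100.6/163.7 pS, symmetric rates 50 s⁻¹, noise σ = 0.35 pA), resolve
its levels, and measure gating:

```python
import numpy as np
from tricchan import *
from tricchan.ghk import bi_ionic_k_na, symmetric_k

model = GatingModel(k_open=50, k_close=50,
                    level_conductances=(0, 42.2, 100.6, 163.7))
path = simulate_state_path(model, 20.0, seed=1)
config = RecordingConfig(duration=20.0, holding_potential=60.0,
                         noise_sd=0.35, seed=1)
trace = render_trace(path, config, symmetric_k(), model)

fit = fit_mixture(build_histogram(trace, bin_width=0.03), 4)
for m, s, a in fit.components:
    print(f"level mean {m:6.3f} pA   sd {s:.3f} pA")
print("conductances (pS):",
      np.round(levels_to_conductances(fit, 60.0, 0.0), 1))

rec = idealize(trace, [0.0, 2.532, 6.036, 9.822])
print("NPo =", round(npo(rec), 3), " events =", rec.n_events)
p_hat, chi2, p = binomial_occupancy_check(rec, 3)
print(f"binomial occupancy: p_hat={p_hat:.3f} chi2={chi2:.2f} p={p:.2f}")
print("P_K/P_Na(4.84 mV) =",
      round(bi_ionic_permeability(4.84, bi_ionic_k_na()), 2))
```

prints

```
level mean  0.001 pA   sd 0.053 pA
level mean  2.534 pA   sd 0.054 pA
level mean  6.035 pA   sd 0.054 pA
level mean  9.819 pA   sd 0.055 pA
conductances (pS): [ 42.2 100.6 163.6]
NPo = 0.879  events = 2537
binomial occupancy: p_hat=0.498 chi2=0.39 p=0.82
P_K/P_Na(4.84 mV) = 1.21
```

Four Gaussian peaks sit at the closed level and the one/two/three-pore
currents; the recovered conductances match the simulation inputs to 0.1 pS.
NPo is the fraction of time at any open level (here close to the binomial
prediction 1 − (1−½)³ = 0.875), and the occupancy diagnostic does not
reject monomer independence (p = 0.82). A reversal potential of 4.84 mV
under 210/210 mM K⁺/Na⁺ bi-ionic conditions converts to a K⁺:Na⁺
permeability ratio of 1.21 at 22.5 °C.

The same pipeline is scriptable from the shell:

```sh
tricchan simulate --k-open 50 --k-close 50 --duration 20 --seed 1 --out trace.tsv
tricchan hist --out hist.tsv trace.tsv
tricchan fitmix --k 4 --voltage 60 hist.tsv
tricchan idealize --levels 0,2.532,6.036,9.822 --out events.tsv trace.tsv
tricchan npo events.tsv
tricchan selectivity --erev 4.84
tricchan tilt --structure trimer.pdb --spans spans.tsv
tricchan poreclass profile.tsv
```

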