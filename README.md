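# circtrack

Bayesian tracking of time-varying von Mises concentration in circular time
series, with an ERP instantaneous-phase front end.

## The problem

Many neurophysiological questions reduce to: *how tightly are phases locked
across repetitions, and when does that lock change?*  A canonical example is
habituation to a repeated auditory stimulus: the instantaneous phase of the
N100 component of successive event-related potentials (ERPs) at a fixed
post-stimulus latency is tightly clustered while the stimulus holds
attention, and disperses as attention drifts away.  Treating the per-trial
phases θ₁…θ_N as draws from a von Mises distribution

&nbsp;&nbsp;&nbsp;&nbsp;f(θ; μ, κ) = exp(κ cos(θ − μ)) / (2π I₀(κ)),

the quantity of interest is the trajectory of the concentration κ_t over
trials.  The classical estimate — maximum-likelihood fits in sliding windows
of G trials — forces a bad trade-off: small G is noisy, large G smears the
very change points one wants to time.

`circtrack` implements a state-space alternative.  The hidden state
S_t = (μ_t, κ_t) lives on a discrete grid (m mean directions × m
concentrations) and performs a slow random walk: a von Mises step with
concentration K for μ, a Gaussian step with variance σ² for κ, each kernel
evaluated at the grid nodes and row-normalized (plus a tiny uniform mixing
floor that keeps every state reachable in finite precision).  The posterior
over S_t given *all* trials,

&nbsp;&nbsp;&nbsp;&nbsp;p(μ_t, κ_t | θ₁:N) ∝ p(θ_{t+1:N} | μ_t, κ_t) · p(μ_t, κ_t | θ₁:t),

is computed by forward and backward recursions with a three-sweep
initialization that removes any influence of the direction of time, and
summarized per trial as E(κ_t) and as the tail-normalized E′(κ_t), which
isolates relative change.  Transition hyperparameters (K, σ²) are selected
on a candidate grid by maximizing ρ, the ratio of between-group to average
within-group variance of E′ summaries across experimental conditions.

The package also provides the sliding-window ML baseline, a synthetic
piecewise-stationary generator with noise injection and MSE scoring, and the
ERP front end (zero-phase FIR bandpass, epoching, 50 µV artifact rejection,
non-local-means denoising, complex-Gaussian-wavelet phase extraction at a
fixed scale).

## Worked example

`examples/01_track_concentration.py` simulates 3000 trials whose
concentration steps 8 → 2 → 1 at trials 1000 and 2000, then smooths:

```
segment-wise mean of E(kappa_t) vs generating kappa:
  trials    0-1000: E(kappa) =  7.98   (true 8)
  trials 1000-2000: E(kappa) =  2.01   (true 2)
  trials 2000-3000: E(kappa) =  1.01   (true 1)
MSE of the whole track: 0.0102
E'(kappa) early/late: 7.98 / 1.00 (values > 1 early mean concentration decayed over the run)
```

The smoother recovers each plateau to within a few hundredths and localizes
both change points; the whole-track mean squared error of 0.0102 is
dominated by the few trials of genuine timing ambiguity at each step.  The
other examples compare against windowed ML under additive phase noise
(`02`, where the smoother beats the best window several-fold), select
(K, σ²) by the ρ criterion on a two-group design (`03`), and run the full
ERP pipeline on synthetic epochs (`04`).

A thin CLI wraps the same functionality:

```bash
circtrack simulate --preset fig7a --seed 0 --out series.txt
circtrack track --input series.txt --out track.csv
circtrack benchmark --preset fig7 --replicates 50 --seed 0 --out bench.csv
```

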