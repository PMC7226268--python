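# Methods

`hmnet` implements a complete in-silico study of how hierarchical modularity
and synaptic strength jointly shape activity fluctuations and information
flow in spiking networks: network construction with analytic connectivity
predictions, leaky integrate-and-fire (LIF) simulation, spectral and
count-based spike statistics, and microscopic (spike-train) and macroscopic
(module-rate) information measures.

## Network model

Networks are directed graphs of N neurons, 80% excitatory and 20%
inhibitory (the 4:1 cortical ratio; the count of excitatory neurons is
`round(0.8 N)`, since 0.8 N is never an integer for the power-of-two sizes
used).  Construction starts from a directed Erdos-Renyi graph G(N, eps) —
each ordered pair is connected independently with probability eps — and
applies H *split-and-rewire* elevations: every module is randomly divided
into two equal halves, and each edge that becomes intermodular is, with
probability Rex (excitatory presynaptic neuron) or Rin (inhibitory),
redirected to a uniformly chosen target inside the presynaptic neuron's own
module.  With the defaults Rex = 0.9, Rin = 1 all inhibition ends up
intramodular while excitation retains long-range edges.  Module indices
follow the binary-split genealogy (children of module m are 2m and 2m+1),
which doubles as the ring ordering used by the adjacent-module statistics.

The expected intramodular in-degree satisfies

    n_in(0)   = N eps
    n_in(h+1) = n_in(h) (1 - R)/2 + N eps R,      lim n_in = 2 N R eps / (R+1)

and n_out(h) = N eps − n_in(h); the intramodular density is
eps_in = 2^h n_in / N.  For the full-scale parameters (N = 2^17,
eps = 0.01, R = 0.9) the limit is 1241.7 inputs per neuron.

**Simple graphs versus multigraphs.**  Because n_in saturates while modules
shrink, eps_in exceeds 1 beyond a critical level (at full scale, from module
size 1024 downward) — the analytic in-degree is then only realisable if
parallel edges are allowed.  The builder therefore has two modes:

* default (simple): rewired edges redraw distinct free targets; when a
  presynaptic neuron's module row fills up, the leftover edges keep their
  original intermodular targets and are counted in `n_unrewired`.  The
  graph stays simple, at the price of capping eps_in at 1 (and, under
  saturation, leaving some inhibitory edges intermodular even at Rin = 1).
* `allow_multi_edges=True`: targets are drawn with replacement (only
  self-edges excluded), so the analytic recursion holds at every level.
  The dynamics sweeps use this mode — it is the only way the high-H regime
  of the model (strong intramodular recurrence in small modules, sharply
  rising population rates) exists at all, and it is implicitly what the
  connectivity analytics describe.

Free-slot sampling without replacement has exactly the same distribution as
redrawing uniformly until the edge is unoccupied, so the simple mode is
unbiased; measured intramodular in-degrees match the recursion to within
sampling error at every unsaturated level.

## Neuron and synapse model

Membrane potentials follow tau_m dv/dt = −v + RI_loc + RI_ext with
tau_m = 20 ms, threshold 20 mV, reset 10 mV, refractory period 0.5 ms and
constant external drive RI_ext = 30 mV applied to every neuron for T = 2 s.
Each presynaptic spike increments every target's potential by +J
(excitatory) or −gJ (inhibitory, g = 5) after a synaptic delay
tau_D = 0.55 ms.  An uncoupled neuron is a deterministic oscillator with
ISI = tau_ref + tau_m ln((RI_ext − v_r)/(RI_ext − v_th)) = 0.5 + 20 ln 2
≈ 14.36 ms (≈ 69.6 Hz), which anchors the simulator's decoupled limit.

Numerics: fixed grid dt = 0.1 ms; exact exponential subthreshold update;
synaptic events are instantaneous voltage jumps delivered through a
circular buffer; the delay is rounded to the nearest grid multiple
(0.55 ms → 6 steps; a `strict_delay` flag turns non-divisible delays into
errors instead).  The refractory clamp holds v at the reset value and
discards inputs arriving during the clamp.  Initial potentials are drawn
uniformly from [v_r, v_th) (seeded) to desynchronise the common
deterministic drive; with the grid quantisation the decoupled network rate
is 69.44 Hz versus the closed form 69.62 Hz (−0.26%).

**Reduced scale.**  The reference system has N = 2^17 neurons and
eps = 0.01 (expected in-degree K ≈ 1310.7).  Desk-scale runs keep either
eps (topology-faithful, `fixed_eps`) or K (dynamics-faithful,
`fixed_indegree`, the default: eps is raised to K/N so single-neuron input
statistics match the full-scale network).  At N = 2^14 the fixed-K
convention reproduces the full-scale homogeneous/heterogeneous rates at
H = 0 quantitatively; the modular (high-H) regime additionally depends on
absolute module counts and N, so only its qualitative trends transfer
downward, and absolute high-H rates do not.

## Spike statistics

The population (or module) rate r(t) is a spike histogram over 1 ms bins
divided by N and the bin width.  Spike-train spectra are single full-record
periodograms of mean-subtracted 0.1 ms binned trains, averaged over K
sampled neurons; for this estimator the high-frequency plateau equals the
mean rate nu and the f → 0 limit equals nu·FF.  Numerically the Fano
factor is the mean spectral power over (0, 5] Hz divided by nu (T = 2 s
gives ten usable bins); nu itself always comes from spike counts.  A
count-based FF (variance/mean of per-neuron counts, across neurons for a
full-record window or across tiled windows otherwise) cross-checks the
spectral estimate.  The correlation time

    tau_c = ∫ df (S(f) − nu)^2 / nu^4

is integrated over the estimated band excluding DC.  For Poisson input the
flat spectrum makes the integrand pure estimator noise, leaving a floor of
roughly 2 f_Nyq / (K nu^2) — about 1 ms at K = 1000 trains of 100 Hz —
so "tau_c ≈ 0" statements are always relative to that floor.
Correlograms use 1 ms bins, ±100 ms lags, FFT-based, mean-subtracted; the
autocorrelation is normalised by its zero-lag value, cross-correlograms by
the geometric mean of the two zero-lag autocorrelations.

## Microscopic transfer entropy

Spike trains are binarised at 0.1 ms.  The delayed transfer entropy from
source y to target x is the plug-in estimate of

    TE_{y→x}(d) = I(y_t ; x_{t+d} | x_{t+d−1}),

computed from the 8-cell joint histogram of (x_{t+d}, x_{t+d−1}, y_t) with
0·log 0 := 0.  With this indexing the profile of a synaptically coupled
pair peaks exactly at the connection delay, which is verified on the
deterministic two-neuron loop (mutual excitation with delays 3 and 2 bins:
argmaxes 3 and 2, with TE_{y→x}(3) ≈ 0.649 bits against TE_{x→y}(3) = 0).
All delays of one profile share a common sample window so that exact
symmetries of periodic inputs produce exact ties (resolved toward the
smaller delay).  The network measure ⟨TE⟩ averages the delay-maximised TE
over K random ordered neuron pairs, scanning d ∈ [155, 300] bins by
default (tau_D up to tau_D + tau_m in 0.1 ms steps).  Estimator bias is
assessed with source-shuffled controls, which scale as 1/n_samples.

The published ratio inside the TE logarithm is typographically corrupted
in its source; the literal rendering is preserved behind
`formula="printed"` for comparison only.

## Macroscopic information measures

Module rate series (1 ms bins, so 2000 samples at T = 2 s) are continuous
and bursty.  The macroscopic TE between modules predicts the target
module's next rate bin from its own current bin plus the source module's
current bin — the same conditional-information form as above at the
one-step horizon — and the mutual information between ring-adjacent
modules is averaged over the 2^H adjacent pairs.  Both use a product
Gaussian KDE with bandwidth 0.3 and entropies estimated by leave-one-out
resubstitution at the sample points.

Two numerical choices matter here and were validated against closed forms:

* **Normal-scores transform.**  MI and TE are invariant under monotone
  per-series maps, so each series is mapped through its empirical CDF onto
  exact N(0,1) margins before KDE (ties broken at random with a key stream
  seeded from the series content, so different series get independent
  tie-breaks while identical series transform identically).  A plain
  z-score is inadequate for bursty rate series — with 40% silent bins and
  tails beyond 10 SD, the bulk of the z-scored sample spans a range far
  narrower than any fixed bandwidth.
* **Leave-one-out.**  Plain resubstitution includes the self-kernel, whose
  density inflation grows like 1/(n h^dim) and does not cancel across the
  entropy combination; at n = 1500–2000 it biases TE by +0.15 bits on
  independent controls.  Leave-one-out reduces the residual to about
  ±0.03–0.05 bits, which is the effective noise floor quoted alongside
  macroscopic estimates.

Validation: bivariate Gaussian with rho = 0.5 gives MI within 0.05 bits of
−(1/2) log2(1 − rho²) ≈ 0.2075; a white-noise-driven AR(1) target
x_{t+1} = a x_t + c y_t + s eta_t gives TE within 20% of
(1/2) log2(1 + c²/s²); independent and identical series both return values
inside the noise floor.

## Synthetic fixtures

Every estimator is testable without network simulation: homogeneous
Poisson rasters (flat spectrum at nu, FF 1, tau_c at the floor), the
deterministic two-neuron loop (transient-trimmed so the returned trains
are exactly periodic; the canonical construction is a single seed spike,
for which the TE argmax provably equals the connection delay — seed
patterns spawning several phase families of the orbit can tie neighbouring
delays), delayed Bernoulli copies (TE at the true delay equals the binary
entropy of the spike probability), periodic and two-state bursting trains
bracketing FF = 1, and Gaussian/AR pairs with the closed forms above.

## Protocol sweeps

`run_sweep` executes build → simulate → statistics → information per
(J, H, seed) grid point, persists per-point JSON (restart-safe: completed
points are loaded, not recomputed) and tidy CSV summaries, and `aggregate`
produces per-(J, H) means/SDs (SD left NA for a single seed) and per-H
quartile summaries of the macroscopic TE.  Defaults are sized for one CPU:
N = 2^13 with fixed in-degree, K_spectrum = 1000, microscopic ⟨TE⟩ off
unless requested (it is the single most expensive measure), up to 100
macroscopic pairs.  `full_scale_config()` switches to the reference system
(N = 2^17, eps = 0.01, K = 10,000 sampled neurons/pairs, 500 module
pairs); that preset reproduces the printed full-scale rate bands but needs
hours per grid point on one CPU and is not exercised by the test suite.

## What the reduced scale does and does not reproduce

Verified at N = 2^13–2^14 (fixed in-degree, multigraph rewiring, T = 2 s):

* H = 0 population rates fall inside the full-scale mean ± SD bands at
  both J = 0.2 and J = 0.8 (N = 2^14).
* nu(J) keeps its interior minimum at H = 0 (the homogeneous →
  heterogeneous transition near J ≈ 0.3) and becomes monotonically
  increasing at high H.
* The Fano factor increases with J at low and intermediate H.  In the
  runaway high-H regime (modules far below ~256 neurons at fixed K) the
  reduced networks fire regularly at very high rates and FF collapses
  instead — a finite-size artefact of concentrating K = 1310 inputs into
  tiny modules.
* ⟨MI(H)⟩ decreases with H: modules become progressively more independent.
* ⟨TE(H)⟩ at reduced scale decays monotonically from H = 1 and sits at the
  KDE noise floor for H ≥ 2; the interior maximum over H seen at full
  scale (where the ascending branch is driven by modules of 10^4–10^5
  neurons whose rates are too noise-dominated to carry information at low
  H) has no counterpart in the desk-scale H range.  The package asserts
  the monotone-decay+floor behaviour it can actually produce and leaves
  the full-scale optimum to the full-scale preset.

Spike rasters, topologies, rate series and summaries round-trip through
plain-text TSV/CSV/JSON formats; a thin `hmn` CLI wraps build, simulate,
stats, TE and sweep for shell use.
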