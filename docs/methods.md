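# Methods

## Model

Each of N cortical regions is a Jansen–Rit neural mass: three coupled
populations (pyramidal cells, excitatory interneurons, inhibitory
interneurons). Synaptic filtering is the critically damped second-order
operator

    v'' + (2/τ) v' + v/τ² = (H/τ) m(t)

whose impulse response is the alpha kernel `(H/τ) t e^(−t/τ)` (peak `H/e`
at `t = τ`). Population output is the sigmoid `S(v) = e0 / (1 + exp(r(v0 −
v)))`. Writing the three second-order equations as six first-order ones,
region j evolves as

    v̇1 = x1      ẋ1 = (H_e/τ_e)(p + conn_j + C1·S(C2·v3)) − (2/τ_e)x1 − v1/τ_e²
    v̇2 = x2      ẋ2 = (H_i/τ_i)·C4·S(C3·v3)               − (2/τ_i)x2 − v2/τ_i²
    v̇3 = x3      ẋ3 = (H_e/τ_e)·S(v1 − v2)                − (2/τ_e)x3 − v3/τ_e²

The TMS pulse is a rectangular perturbation `p` applied to the excitatory
interneurons of the stimulated regions, weighted by a thresholded
E-field-like map (entries below 83% of the map maximum are zeroed). The
network input is

    conn_j(t) = S( g · Σ_{k≠j} a_jk · x1_k(t − m_jk) )

where `a` is the structural coupling matrix and `m_jk = length_jk /
velocity` the conduction delays. EEG channels are `Y = G·(v1 − v2) + ε`
with leadfield `G` and i.i.d. Gaussian sensor noise.

A documented variant (`printed_eq6=True`) moves the pyramidal feedback
term `C1·S(C2·v3)` outside the synaptic gain; the default keeps it inside,
which is the dimensionally consistent standard form. The delayed network
state defaults to the derivative x1; `drive_state="v1"` is available for
sensitivity analysis.

## Units and default constants

Time is in ms, potentials in mV, and firing rates (including the drive
terms `p` and `conn`) in ms⁻¹ throughout. In the sigmoid form used here
`e0` is the ceiling, i.e. the maximum population rate: the classic
parameter set has a 5 s⁻¹ maximum (half-maximum 2.5 s⁻¹), so the default
is `e0 = 0.005` ms⁻¹. With this convention the resting magnitudes land on
the familiar literature values. Remaining defaults are the canonical
Jansen–Rit constants: `H_e = 3.25` mV, `H_i = 22` mV, `τ_e = 10` ms,
`τ_i = 20` ms, `C1..C4 = 135·(1, 0.8, 0.25, 0.25)`, `r = 0.56` /mV,
`v0 = 6` mV. The tonic drive `p_baseline` defaults to 0 so the
unstimulated system is quiescent.

## Connectome preparation

The coupling matrix is the rescaled Laplacian `L/‖L‖` with `L = W −
diag(rowsum W)`: every row sums to zero (each node's weighted in-degree is
removed) and the spectrum has one zero eigenvalue with all other real
parts negative — the linearisation is stable. The norm is Frobenius by
default (deterministic, basis-independent; spectral available). Asymmetric
weight matrices are accepted as given; self-connections are zeroed with a
warning. Delays are `lengths/velocity`, which with mm and m/s gives ms
directly (100 mm at 5 m/s → 20 ms).

## Integration

Fixed-step forward Euler, default dt = 0.1 ms, with delays rounded to the
nearest step (at least one step for positive delays, with a warning when
dt exceeds the smallest delay). Delayed states are served from a ring
buffer initialised by holding the initial drive state constant for t < 0.
Halving dt changes the default channel trajectory by under 1% RMS; the
closed-form synaptic response is reproduced within 1e-3 relative error at
dt = 0.01 ms (with half-step midpoint alignment of the piecewise-constant
input, the standard first-order phase convention for forward Euler).
Divergence (|state| > 1e6) raises an integration error carrying the time
stamp and region.

Initial conditions: `simulate` defaults to seeded random starts (v ~
U[0, 0.2] mV, derivatives 0) followed by a discarded 20 ms burn-in.
Because the linearised resting state of the literature-standard parameter
set has a slow mode (time constant of order 100 ms), that burn-in leaves a
visible baseline drift; the package therefore also provides an exact
equilibrium start (`initial_state="equilibrium"`). This is computed by
root-finding the scalar fixed-point equation for v3 — valid for the whole
network because all derivative states vanish at any equilibrium, making
every delayed input equal to S(0). The ground-truth generator, the fitter
and the lesion experiments use the equilibrium start by default, which
makes them fully deterministic and keeps baselines flat; random starts
remain available everywhere.

## Synthetic study conditions

The generator produces every input the pipeline consumes:

- **Connectome** (default 200 regions): 7 planted modules mirroring the
  canonical functional networks; within-module connection probability 0.5
  vs 0.1 between; log-normal weight magnitudes (σ = 0.7); symmetric
  fiber lengths uniform in [25, 250] mm so delays at the default 5 m/s
  span 5–50 ms.
- **Leadfield** (default 64 channels): per-channel mixture of a
  module-level pattern (volume-conduction-like smoothness, weight 0.5) and
  i.i.d. Gaussian gains, scaled ×10 so projected evoked responses land at
  single-digit-microvolt-like numbers as in recorded TEPs. Full row rank
  whenever channels ≤ regions.
- **Stimulus**: a synthetic E-field map with 3 near-maximal focal regions
  in one module plus weak background that the 83% threshold removes;
  rectangular pulse, duration 1 ms, amplitude 1.0 ms⁻¹ (rate units),
  onset at t = 0 of the [−100, 300] ms epoch.
- **Global gain**: `g` was tuned once by grid search so the network is
  stable pre-stimulus and shows damped re-entrant activity post-stimulus:
  2×10⁵ at the default 200-region scale. The Frobenius rescaling shrinks
  coupling entries as N grows, so the same dynamical regime needs a
  smaller gain on small networks; the shipped value for ~30-region test
  networks is 5×10⁴.

Ground-truth datasets carry a manifest (all seeds and parameters) from
which they regenerate bit-identically. Observation noise in the
parameter-recovery experiments is 5% of the evoked (per-channel
mean-removed) signal RMS.

What the generator does **not** emulate: volume-conduction geometry and
electrode physics beyond smooth random mixing, trial-to-trial variability
(only trial-averaged epochs with additive Gaussian noise), sensory
co-activation artifacts, subject-specific anatomy, and any particular
empirical TEP morphology. Passing tests therefore demonstrate internal
consistency and recoverability under the model's own assumptions, not
fidelity to any recorded dataset.

## Fitting

The objective is the channel MSE plus a Gaussian-prior complexity term per
fitted parameter, `ln σ + (θ−μ)²/σ²`. The default fitted set is {τ_e,
τ_i, H_e, H_i, g}; priors default to the literature values with relative
sd 0.5, and positive parameters are optimised on the log scale with box
bounds [μ/5, 5μ]. Connection-weight fitting (prior variance 1/50 per
connection, prior means the rescaled coupling entries) is declared in the
interface but not served by the finite-difference gradient path, which
cannot scale to ~N² coordinates.

Three update schemes share this objective:

- **batch** (default): the reference rolling protocol — the epoch is cut
  into 20 ms windows, the simulator state (including the delay history) is
  carried across windows, and one Adam step is taken per window from
  central finite-difference gradients; on wrap-around the burn-in is
  re-simulated. Plateaus anneal the learning rate (halving after 4
  non-improving passes) rather than stopping; convergence is judged on the
  MSE component because the penalty's constant `ln σ` offset would mask
  progress in a relative-change test. Estimates are means over the final
  100 batches.
- **epoch**: one Adam step per full pass using the exact whole-epoch
  finite-difference gradient. Within-window gradients under state
  carry-over ignore the sensitivity path through earlier windows and can
  even be sign-biased; this scheme removes that truncation at the same
  cost per pass.
- **lsq**: the identical objective is, up to the constant `ln σ` terms, a
  sum of squares (scaled data residuals plus `(θ−μ)/σ`), so a trust-region
  Gauss–Newton solve applies directly. It is deterministic, the fastest of
  the three, and by far the most reliable in the narrow curved valleys
  this problem produces; the parameter-recovery experiments use it.

Two further optimisation aids, both optional and on by default: the gain
coordinates are internally reparametrised as `log(H·τ)` when a gain is
fitted jointly with its time constant (the baseline offset pins the
product tightly while the waveform constrains τ gently — decoupling aligns
the valley with the axes), and a coarse start grid (the starting point
plus ±1 prior sd along each axis, scored by the exact whole-epoch
objective) guards against the compensated local basins that arise because
different (τ, H) combinations reproduce the baseline offset almost equally
well.

Parameter recovery at the shipped reduced scale (30 regions, 16 channels,
dt 0.25 ms, 5 seeds, +30% one-at-a-time perturbations, 5% noise) returns
every parameter within 20% relative error; τ_i and H_i carry a persistent
~12% bias because the data constrain their product much more strongly than
the factors, and the prior splits the residual misfit between them.

## Virtual lesions

Node selection scores each region by the summed absolute pyramidal
potential over a window, screens at mean + 2 sd across regions, and keeps
the top ⌈1%·N⌉ of the passers (fewer if fewer qualify, logged). Lesions
zero the selected rows/columns of the coupling matrix from their onset to,
by default, the end of the epoch (permanent disconnection; a finite
offset is configurable, as is in/out/both mode). All conditions share the
control's seed and initial conditions, so pre-onset trajectories are
bit-identical and any post-onset difference is attributable to the
severed connections. LMFP is the RMS over a chosen electrode subset,
optionally baseline-corrected by the mean pre-stimulus value.

## Evoked-response metrics

- **LZ76**: exhaustive-history parsing; a word is extended while it can be
  reproduced from the prior text and closed by the first non-reproducible
  symbol (the final word may remain reproducible). Constant sequences of
  length ≥ 2 parse into exactly 2 words.
- **PCI-style index**: rows are baseline-mean-centred; the binarisation
  threshold is the (1−α) quantile of the bootstrap distribution (default
  500 resamples, α = 0.05) of the max |value| over rows of resampled
  baseline samples; rows with any suprathreshold response sample are
  binarised and concatenated row-major; the index is `c·log2(L)/(L·H)`
  with `c` the LZ76 count, `L` the length and `H` the empirical binary
  source entropy. No suprathreshold sample, or a zero-entropy sequence,
  gives 0. These choices (threshold construction, concatenation order,
  normalisation) are this package's own; the index is PCI-style, not a
  certified reimplementation of any published pipeline, and is invariant
  to channel order only approximately (<10% on the shipped fixtures).
- **SVD eigenmodes**: thin SVD after removing each channel's temporal
  mean (which makes variance-explained well defined); mode k explains
  `s_k²/Σs²`; peak latency is the argmax of |temporal mode|. Group modes
  are located within individual epochs at the sample of maximal cosine
  similarity; matches below 0.5 similarity are flagged low-confidence.
- **Permutation goodness of fit**: per-channel Pearson r against a null
  of time-shuffled surrogates (default 1000), one-sided
  (r ≥ observed), `p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm)`;
  zero-variance channels are reported as missing. Bonferroni correction
  divides α by the number of tests (0.05/7 ≈ 0.00714 for the 7-network
  comparisons).
- **Network averaging**: unweighted mean over member regions per
  canonical network and time point; empty networks are reported as
  missing.

## Problem sizes

The default test suite and the acceptance script run the full pipeline at
the sizes stated above: 200 regions / 64 channels for simulation, lesion
and fixture-shape checks (a single epoch takes about a second), and 30
regions / 16 channels / dt 0.25 ms for the 25 recovery fits. These are
the package's reference desk-scale conditions; all sizes are plain
function arguments.

## Known limitations

- Forward Euler is first-order; dt must stay well below τ_e and the
  smallest delay. No adaptive stepping.
- The network input is bounded by `e0` (the sigmoid ceiling), so with
  strong stimuli the re-entrant contribution is structurally small
  relative to the local response; the shipped conditions keep the evoked
  response in the regime where both are measurable.
- The batch scheme's truncated gradients make it a poor estimator at desk
  scale; it is retained as the reference protocol, with `epoch` and `lsq`
  as the recommended practical schemes.
- Per-connection weight estimation is interface-declared but not
  implemented for finite-difference gradients.
- Dynamical (process) noise is not modelled; randomness enters only
  through initial conditions and observation noise.
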