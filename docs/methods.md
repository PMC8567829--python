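# Methods

## Model

Each brain region is a reduced excitatory–inhibitory neural mass. The
excitatory population receives external current `WE*I0`, recurrent
excitation `wplus*JNMDA*SE`, long-range excitation
`G*JNMDA*sum_j C_ij SE_j` from the excitatory pools of connected regions,
and feedback inhibition `J*SI`; the inhibitory population receives
`WI*I0 + JNMDA*SE - SI`. Currents map to population rates through
`r(I) = (aI - b)/(1 - exp(-d(aI - b)))`, a soft-rectifying curve that is
linear for strong drive and decays to zero for hyperpolarizing input; its
removable singularity at `aI = b` is evaluated as the limit `1/d`.

The multiscale element is the gating kinetics: the average synaptic
gating of a population follows the receptor-binding rate equation
`dS/dt = -beta*S + alpha*(1-S)*T*r`, so the forward term scales with the
neurotransmitter concentration `T` (glutamate for NMDA-mediated
excitatory gating, GABA for inhibitory gating). At a constant rate the
fixed point is `S_ss = alpha*T*r~/(beta + alpha*T*r~)`. Concentrations
are spatially uniform — a stated model assumption, not a limitation of
the implementation of the sweep grids.

An inhibitory plasticity rule `dJ/dt = gamma*rI*(rE - rho)` adjusts the
feedback-inhibition weight until the excitatory rate sits at the target
`rho = 3 Hz`; its only fixed points are `rE = rho` or a silent
inhibitory pool.

### Unit conventions

Kinetic constants are in ms^-1 (forward rates ms^-1 mM^-1); transfer
rates are in Hz. Inside the gating and plasticity ODEs every rate symbol
is divided by 1000 so that all terms share units with beta. This is the
only convention under which the single-synapse kinetics (below) and the
mean-field steady state agree, which the oracle-equivalence test
verifies. Two further conventions the equations do not fix by
themselves:

- `sigma = 0.001` is treated as a gating-units noise amplitude added to
  both gating equations (no nA-to-gating conversion exists in the model);
- `gamma = 1` is dimensionless; with both rates converted to ms^-1 the
  effective learning timescale is seconds-to-tens-of-seconds, and J
  converges well within a 60 s burn-in from `J0 = 1`.

## Integration

Euler–Maruyama with `dt = 0.1 ms`: gating advances by `drift*dt +
sigma*sqrt(dt)*N(0,1)` with independent noise per region and per
population, then is clamped to [0, 1] (gating is a channel-open
probability; clamping events are counted and occur in well under 0.1% of
updates at default parameters — the trajectory records the fraction).
The plasticity ODE is deterministic and can run throughout (default),
freeze after burn-in, or stay off; the default reflects that the rule is
part of the coupled system. Initial conditions are near rest
(`S = 0.001`, `J = 1`): with S ~ 0 the external current alone puts the
excitatory rate close to rho, so the plasticity transient is mild.
Identical (seed, config) pairs give bitwise-identical trajectories; noise
is drawn in fixed-size blocks from a seeded PCG64 generator, so recorded
output does not depend on recording stride.

Default epochs are 60 s burn-in and ~60–514 s recording; the upper figure
mirrors a typical resting-state session (261 samples at TR = 1.97 s).
Tests and the acceptance script use 60 s recordings — long enough for
rate averages at these noise levels — to keep desk-scale runtimes in
minutes.

## Single-synapse oracle

The mean-field gating kinetics are validated against an independent
event-driven simulation of one synapse driven by a Poisson spike train:
`s` decays exponentially at rate beta between spikes and jumps by
`alpha*Tmax*(1-s)` at each spike (each spike delivers unit time-integral,
the only reading under which the averaged equation's fixed point matches
the single-synapse statistics). Integration between spikes is exact
(closed-form exponential segments), so the only error is Monte-Carlo.
The long-time mean is taken after a burn-in of `max(10/beta, 10%)` of the
simulated duration; results are flagged unconverged when
`duration*beta < 50` or fewer than ~20 spikes fall in the averaging
window. Across a 1–300 Hz rate grid the oracle matches the analytic
steady state to RMS <= 0.02 for both NMDA (slow, beta = 0.0066 ms^-1)
and GABA (fast, beta = 0.18 ms^-1) constants.

## Hemodynamics

The Balloon–Windkessel stage uses the standard four-state formulation
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin) with
literature constants: kappa = 0.65 s^-1, gamma_f = 0.41 s^-1,
tau = 0.98 s, Grubb exponent alpha = 0.32, E0 = 0.34, V0 = 0.02, and the
1.5 T readout weights k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2. The neural
input is the excitatory gating SE by default — the convention of the
antecedent mean-field literature — with `rE` and `SE + SI` available as
a config switch, since which variable drives the vasodilatory signal is
a genuine modeling choice. The ODEs are integrated deterministically at
1 ms substeps from the recorded trajectory (linear interpolation when the
recording is coarser), the first 20 s of BOLD are discarded as the
hemodynamic transient, and the signal is sampled at the TR.

## Observables

FC is the Pearson correlation of z-scored regional BOLD, by default
band-passed at 0.01–0.10 Hz for comparability with empirical
preprocessing (a raw option exists). Filtering is a zero-phase
second-order Butterworth band-pass (forward–backward `sosfiltfilt`);
narrowband zero-phase IIR filters ring at series edges, which is why
phase-derived summaries exclude 10 samples at each end by default.
Metastability is the temporal standard deviation of the Kuramoto order
parameter `R(t) = |sum_k exp(i phi_k)|/n` computed from Hilbert phases
of the 0.03–0.06 Hz band of z-scored BOLD (z-scored by default; raw
input is accepted). The FC distance is the Frobenius norm of the matrix
difference divided by N, summed over all N^2 entries exactly as defined
(unit diagonals cancel); FC correlation uses the strict upper triangle.
A label-subset mode computes both on e.g. the nine default-mode-network
regions.

## Graph metrics

Functional networks keep only positive correlations; the strongest
`K = round(PSW * N(N-1)/2)` edges are retained and binarized
(PSW = 0.25 default). K counts *possible* edges so that the edge count is
identical across equal-sized matrices; counting only positive entries is
available as an option since either reading is defensible. Ties break
deterministically by ascending (row, column). Global efficiency,
characteristic path length (finite distances only, with a warning on
disconnection), clustering coefficient, and local efficiency follow the
standard binary-graph definitions; modularity Q is always evaluated
exactly by the Newman formula on the returned partition, with partitions
proposed by seeded Louvain agglomeration (10 restarts, best Q kept, the
trivial single-community partition always among the candidates so
Q >= 0). All five metrics are verified against exhaustive brute-force
implementations on random graphs with n <= 8.

## Synthetic connectomes

The generator emulates the statistical shape of a max-normalized
probabilistic-tractography connectome: random planar region positions,
exponential distance kernel (length scale 0.15 in unit-square units),
lognormal weight jitter (sigma = 1.0), a 3x gain inside each of two
contiguous modules (hemisphere analogue), pruning to 35% density,
symmetrization and max-normalization. These defaults give right-skewed
weights (median nonzero weight ~0.03) and row sums ~1–2.6, matching
normalized tractography output; stronger or denser matrices push the
network into a plasticity overshoot that real SC statistics do not
produce. The generator is a fixture with realistic statistics, not an
anatomical claim: it has no geometric cortical folding, no
distance-dependent delays and no subject variability, so passing tests
demonstrate correct model mechanics, not empirical fit to human data.

## Operating point

At G = 0.69 with glutamate 7.46 mM and GABA 1.82 mM (healthy-brain
precuneus values), plasticity holds each region's excitatory rate at
~3 Hz; the current-balance equations then pin the inhibitory rate near
6 Hz (the inhibitory population's input depends only on SE and SI, and
SE is fixed by the homeostatic rate). Substantially higher inhibitory
rates would require excitatory rates well above the target and therefore
only occur transiently or when J is far from convergence.

## Known limitations

No conduction delays, no regional heterogeneity of concentrations or
hemodynamics, no neuromodulation, no dynamic (sliding-window) FC, and
weighted-graph metric variants are out of scope. Empirical SC/FC data are
not bundled; the package reads any delimited SC/FC matrix with the
documented conventions.
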