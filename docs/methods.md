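# Methods

`braincat` simulates how learning verbal labels shapes conceptual category
formation in a brain-constrained neural network. Twelve model areas —
six perisylvian "language" areas (auditory stream A1–AB–PB, articulatory
stream PF_i–PM_i–M1_i) and six extrasylvian "sensorimotor" areas (ventral
visual stream V1–TO–AT, hand-motor stream PF_L–PM_L–M1_L) — are linked by 22
reciprocal between-area connections in three neuroanatomically motivated
classes (next-neighbour, second-neighbour "jumping", long-distance), with
the four central areas (AT, PF_L, PB, PF_i) acting as connector hubs. Each
area holds a 25×25 sheet of excitatory cells paired with one inhibitory
interneuron cluster per column.

## Stimuli

Object/action *instances* are coded as "grounding patterns": 12 active cells
in each of V1 and M1_L, drawn independently per area. Six cells are shared
by all six instances of a category (category-critical features) and six are
unique to the instance, so within-category instance pairs overlap 50% and
between-category pairs 0%. All cells of one category are pairwise
non-adjacent under the Moore 8-neighbourhood, preventing co-activation by
mere spatial proximity; generation is round-robin rejection sampling over
the ten categories with a bounded retry/restart policy. Word forms are
12-cell patterns in A1 and M1_i under the same rules: *category terms* (CT)
map one-to-one onto categories, *proper names* (PN) onto trained instances.
Each category contributes three trained and three novel instances (60
total); novel instances never receive labels.

Interpretation choices: "non-adjacent" is read as 8-neighbourhood exclusion
(a proximity kernel is omnidirectional), enforced within a category's full
cell set; CT and PN symbols are drawn mutually disjoint per area, which is
the maximally controlled choice (they never co-occur in one condition).

## Dynamics

Cells are leaky integrators with binary (spiking) output, updated
synchronously in discrete time:

    V_e(t+1) = V_e + (1/τ_e)·(−V_e + k1·exc − k1·(w_ie·O_i + kG·g·ω_G + w_ff·S̄)
                              + ξ + stim)
    φ = 1  iff  V_e > thresh + α·ω_A

with τ_e = 2.5, τ_i = 5 steps, input rescaling k1 = 0.01, spiking threshold
0.18, and adaptation α = 8 on a low-passed spike count ω_A (τ_ADAPT = 10).
Rate estimates ω_E low-pass φ with τ_Favg = 30 during training and 5 during
testing; ω_E is both the analysis readout and the presynaptic "output
activity" entering the learning rule. Inhibition has three components:

1. **Local**: each column's i-cell integrates the spike count of its 5×5
   neighbourhood (gain w_ei = 0.15, τ_i = 5) and emits a graded output
   clipped to [0, 1] that inhibits its column with weight w_ie = 600 (in
   k1-rescaled units, a ceiling of 6 on the membrane scale). Sparse
   assemblies are only mildly self-inhibited; dense firing saturates it.
2. **Slow global**: per area, ω_G low-passes the spike count (τ_FGLOB = 12)
   scaled by a gain g = 2.5 and enters with strength kG = 0.8. This is the
   quantity behind the interstimulus reset criterion: the area's activity
   measure k1·kG·ω_G must fall below thresh = 0.18 everywhere before the
   state is zeroed.
3. **Fast feed-forward**: a per-area term proportional (w_ff = 3) to a
   rapidly-tracked spike count (instant rise, decay τ = 3). This is the
   stabilising element of this implementation: after every hard reset both
   other pathways need several steps to engage, and without a one-step
   population brake the reset-transient window accumulates runaway
   potentiation over trials.

Membrane noise is uniform, amplitude ±noise_amp/2 per step with
noise_amp = 0.3 — deliberately subthreshold, so spontaneous spiking is
essentially absent and the firing-rate readout at test has a clean floor.
During training, every area *not* receiving a pattern gets this noise
multiplied by 2.0, standing in for activity unrelated to instances or
symbols. This stronger noise is also the learning bootstrap: it
stochastically depolarises dendrites past the LTP threshold in proportion to
their anatomical convergence onto the stimulated pattern.

## Plasticity

Every existing excitatory synapse is plastic during training trials (never
during intervals or testing). With presynaptic output activity
ω_E ≥ ϑ_pre = 0.05, the weight moves by Δw = 0.0008: up if the postsynaptic
potential is at or above ϑ+ = 0.15, down if it lies in [ϑ− = 0.14, ϑ+) — the
"out-of-sync delink" band — and is clamped to [0, w_max = 8].

The gating potential is the **dendritic** potential D: the same leaky
integral as V but of excitatory input, stimulation and noise only, without
the perisomatic inhibition terms. This choice decouples stability from
selectivity — inhibition regulates firing and prevents seizure-like states
while synaptic selection follows the excitatory correlation structure. (The
somatic alternative is available via `plasticity_gate="somatic"`; in our
exploration it ties the learning equilibrium to the inhibition level, which
either freezes learning or locks the network into one global attractor.)

Two features bound what learning can build. First, ϑ_pre restricts
potentiation to synapses whose presynaptic cell fires persistently —
stimulated pattern cells and, later, strongly-driven "elite" cells — so
weight growth cannot percolate through the network. Second, with the
connectivity below, a cell reached by only one or two pattern cells sits at
a ceiling drive of ≤ 0.16, below both the firing threshold and reliable LTP
territory: such cells end up with strengthened afferents yet remain
functionally inert, while cells with high anatomical convergence from a
pattern (≈ 4+ links) become that instance's assembly.

## Connectivity and scaling constants

Within-area excitatory links are drawn in a radius-4 square neighbourhood
with Gaussian distance falloff (σ = 2.5), expected in-degree 50; between
linked areas, a topographic Gaussian kernel (σ = 3) gives expected in-degree
100 per afferent area. No autapses; masks are fixed at initialization;
initial weights are U(0, 2). "Initially weak" is read relative to the
learned ceiling (mean = w_max/8); reading it on the ϑ+ scale is dimensionally
inconsistent with k1 = 0.01 — no input could ever reach threshold.

Stimulation uses a strong-drive convention: driven cells receive a large
input (4·10⁶) for the stimulation steps, guaranteeing firing. Because the
membrane leak is exponential (τ_e = 2.5), this drive decays over ~25 steps
after stimulation ends — the "deactivation toward baseline" of the test
protocol — keeping pattern cells active deep into the 30-step recording so
that learned circuits are exercised inside the τ_Favg = 5 readout window.

All constants in this section are implementation calibrations: the model
family's defining equations are published only by reference, so the package
fixes them in the standard form above and calibrates the free scalings once
for a functional regime (stable training, selective ignition, readable
responses). They live in `ModelParams` and a YAML config mirrors them.

## Protocol

Training presents each trained instance's grounding pattern to V1/M1_L for
16 steps with plasticity on — alone (NoS), with its category's word form
(CT), or with its own proper name (PN) in A1/M1_i — 2,000 times per instance
in the main design (1,000/3,000 in the word-form-balanced control design),
in randomised order per epoch. Consecutive trials are separated by a
noise-only interval that ends when the slow activity measure is below
baseline in all 12 areas (cap 1,000 steps), after which the state is zeroed.
Each model instantiation is initialised once and cloned into every condition
(a within-subject design over instantiations). Testing is symbol-free: 2
steps of pure grounding stimulation, 28 free-running steps, response =
per-cell ω_E (τ = 5) at step 30, full reset between trials.

**Schedule compression.** Reduced-scale presets multiply the trial counts by
`trial_scale` and divide the learning rate by it, conserving the cumulative
plasticity budget (2,000·16·Δw per synapse-condition) so the end-of-training
weight landscape is comparable across scales. The reduced preset used by the
acceptance script runs 3 instantiations × 3 categories × 250 trials per
instance; the test suite's study fixture uses 3 instantiations × 3
categories × 150 trials.

## Analyses

RSA: per area and condition, pairwise Euclidean distances between the
625-long rate vectors of all test instances form a symmetric RDM; unordered
pairs fall into six classes (within/between category × trained/novel
combinations); class means are taken over the upper triangle within each
area and then averaged unweighted over the six extrasylvian areas (an
all-12-area variant is also produced). DissimDiff = |mean(W-TN) −
mean(W-TT)| indexes generalization. Cell assemblies: cells above 75% of the
area's maximal rate (strict), empty if that maximum is below 0.01; the three
trained assemblies of a category classify cells as unique/pair/triple-shared;
"shared" means pair-or-triple. Counts are averaged per instance first, then
across instances, areas, instantiations. Gain = (n_central −
n_primary)/n_primary × 100 with central = {AT, PF_L} and primary = {V1,
M1_L}. Statistics: two-factor repeated-measures ANOVAs over instantiations
(condition × measure), Mauchly's test with Greenhouse–Geisser correction,
and Bonferroni-adjusted paired t-tests at the conservative 0.005 threshold
(family of 10 in the main analysis).

## What the reduced-scale model does and does not reproduce

Robustly reproduced: exact stimulus-design constraints; stable training
(no runaway, bounded weights, naturally terminating intervals); primary-area
assemblies that recover the stimulated 6 shared + 6 unique cells; emergent
higher-area assemblies selective for instances; clear category structure at
test (between-category dissimilarity exceeds within-category in every
instantiation and condition); trained–novel within-category dissimilarity
below trained–trained (novel members inherit the category circuit without
idiosyncratic traces); and a generalization advantage for category terms
(lower DissimDiff under CT than NoS).

Weak at desk scale: the cross-condition (NoS/CT/PN) contrasts. Conditions
differ only via perisylvian word stimulation, and their extrasylvian impact
runs through the central-to-central binding links (AT–PB, PF_L–PF_i,
AT–PF_i, PB–PF_L), which mature too little within the plasticity budget for
word assemblies to re-ignite at test. The condition effects on extrasylvian
measures are therefore small relative to between-instantiation variability:
in the shipped reduced configuration the orderings for between-category
dissimilarity (highest under CT), shared-neuron counts (highest under CT),
unique-neuron counts (lowest under CT) and generalization (best under CT)
hold in the majority of instantiations, while the within-category
dissimilarity ordering (CT < PN < NoS) is not reliably reproduced. Not
reproduced: the positive central-versus-primary gain in shared neurons —
hub-area assemblies in this calibration are an order of magnitude smaller
than primary-area ones, so both neuron types are lost toward the hubs.
These limitations are properties of this calibration, not of the analysis
pipeline, which applies unchanged to full-scale runs.

Because all inputs are generated by the package's own pattern generator, a
passing suite demonstrates internal consistency of the learning dynamics
and analyses under the idealized stimulus statistics (exact overlaps, no
phonological similarity, no cross-category feature sharing); it does not
certify behaviour on any richer stimulus ensemble.
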