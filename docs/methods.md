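# Methods

`avwm` simulates a large-scale neural network model of auditory-visual
short-term memory and intersensory attention. This note documents the
model, its parameters, the synthetic stimuli, the numerical choices, and
the known limitations.

## The network model

### Units and dynamics

Every cortical unit is a Wilson-Cowan microcircuit: a pair of rate
variables (E, I) standing for the pyramidal and interneuron populations of
a cortical column. Both follow the shunting rate equation

    E <- E + h * [ S(in_E) * (1 - E) - delta * E ],      S(x) = 1 / (1 + e^(-K (x - phi)))

integrated by forward Euler with step `dt = 5 ms` on a 10 ms time unit
(dimensionless step h = 0.5), with activities clamped to [0, 1]. The input
`in_E` sums topographic and diffuse afferents, local inhibition
`-w_ie * I`, the diffuse attention bias (D2 units), and i.i.d. Gaussian
noise (std `noise_amplitude = 0.05` per unit per step) standing in for
background input from the rest of the brain. There are no transmission
delays between modules. The coarse Euler step is part of the model
definition, in the tradition of this model family; the integrator
nevertheless converges under step refinement (tested), and the coarse-step
trajectory differs from the continuum limit by a few percent of the
activity scale, which the calibration absorbs.

Gains `K`, thresholds `phi` and decay rates `delta` are per module type
(see `config.py`). The design logic: early sensory stages (A1/V1, gain 4)
are graded so stimulus saliency survives up the hierarchy; A2/V4 have slow
decay (`delta = 0.12`, an ~80 ms integration window) so they accumulate
sweep trajectories; the working-memory units (D1/D2) are steep (gain 10)
and bistable; readout units (R) are high-threshold coincidence detectors.

### Architecture

Two mirrored object-processing hierarchies:

* auditory: A1 (up-/down-sweep selective, 1 x 81 tonotopic) -> A2
  (up/down/contour-selective) -> ST -> MTL (gating) -> prefrontal
  FS / D1-D2 (x3 slots) / R
* visual: V1/V2 -> V4 -> IT -> EC (gating) -> prefrontal counterparts
  (all 9 x 9 arrays)

joined by a pair of mutually inhibitory anterior-insula (aINS) units that
compute exogenous attention from the mean outputs of IT and ST. All
modules are flattened to 81 units, so topographic projections are
unit-to-unit. Talairach coordinates are carried on outputs as metadata
labels only.

### Working memory

Each modality has three D1-D2 slot replicas. A slot sustains its pattern
through mutual D1<->D2 excitation; the D2 units additionally receive the
diffuse attention bias, which controls bistability: the memory attractor
exists for attention above ~0.2 and collapses within a few hundred
milliseconds below ~0.15. Encoding at the standard high attention (0.3)
completes within ~150 ms of stimulus onset. The D2 replicas compete
through weak diffuse mutual inhibition (`D2_slot_compete`), the capacity
pressure that makes three-item lists harder than one-item trials while
still allowing all three items to be stored.

### Gating

The gating modules (MTL auditory, EC visual) hold three winner-take-all
groups, one per memory slot (fixed wiring; lowest-index group wins exact
ties via a static bias). The gate is driven by a *novelty* signal: the
rectified difference between a fast-smoothed copy of the sensory trace and
a slower per-channel adaptation trace, summarized as the mean over the 15
most novel channels. This is the minimal mechanism that makes each group
usable exactly once per stimulus: a sustained stimulus adapts away and
cannot re-trigger gating, while each new list item produces a fresh onset.
The open group routes the sensory pattern into its D1 slot
(multiplicatively, gate activity x pattern); once the slot's activity
confirms storage, prefrontal feedback suppresses the group and it is
marked used for the remainder of the trial (released at trial boundaries
in continuous runs). Used groups receive no gating drive.

### Attention

Endogenous attention is a per-epoch task parameter (high 0.3, low 0.05,
bimodal 0.1). Exogenous attention is an affine readout of the
aINS units (50 ms moving average; `exo = 1.2 * (E_aINS - 0.3)`, clipped at
zero), which compete through both output mutual inhibition and feedforward
cross-stream inhibition (each stream drives the opposite unit's
interneuron) — the latter makes the competition graded enough for working
memory load to modulate the loser's attention. The total per modality,
`clip(endo + exo, 0, 0.35)`, is written to a task-specification relay unit
that projects diffusely onto every D2 unit of its modality. The cap of
0.35 reflects a saturating attentional resource; it also makes high-
attention task behavior insensitive to the small feedback-driven
attention echo, which keeps the feedback-ablated network's single-item
performance close to the intact network's.

In the DMS-with-distractors schedule the endogenous drop to 0.05 follows
the distractor's appearance with a 100 ms reaction lag (attention cannot
anticipate an unpredicted stimulus); by then the salient distractor has
begun to capture exogenous attention, which is what protects the stored
target through the low-endogenous window.

### Prefrontal feedback (the load-effect pathway)

D2 units feed back topographically to their sensory integrator (D2->ST,
D2->IT) and, more weakly, to the mid-level stage (D2->A2, D2->V4). Held
visual items therefore elevate IT activity, which raises the visual aINS
drive and — through the cross-inhibition — lowers the exogenous auditory
attention captured by an auditory distractor. Removing these projections
(`Network.ablate_feedback`) abolishes the load effect.

## Stimuli

Auditory objects are tonal contours: three channel-continuous frequency
sweeps of alternating direction (total duration 200-300 ms, the duration
of a single-syllable word), rendered as a Gaussian spectral bump
(sigma = 1.5 channels) following the sweep path, split between the up- and
down-selective A1 inputs. All contours are loudness-equalized (fixed total
drive energy) and scaled by the saliency scalar. Visual objects are 9 x 9
three-stroke line patterns with a 75 ms luminance onset ramp (which also
aligns the visual response rise with the auditory sweep buildup).

Nonmatch probes are *transposition lures*: the target contour shifted by a
random 5-9 channels (7-11 in the distractor task), preserving the sweep
structure while overlapping the target's footprint by roughly 0.4-0.6.
The lure shift range sets the discrimination difficulty and was calibrated,
together with the noise amplitude and response threshold, against the
published task accuracies.

Controls: auditory noise is a band-limited random walk of the spectral
peak, energy-matched exactly to a reference object; degraded shapes
scramble half of a shape's pixels at constant energy.

## Behavioral readout

The model "responds" when the mean R-unit activity over the first 150 ms
of the probe epoch exceeds `response_threshold = 0.052`. R units are
coincidence detectors of the cue-selective units (FS, reflecting the
probe) and the stored D2 patterns, so a match ignites them within
~100 ms. The readout window ends before probe-encoding-related R activity
develops (the probe itself is gated into a free slot late in the probe
epoch — a real process, but not a match signal). A response is correct iff
the probe matched a stored item.

## Simulated subjects

A cohort is created by multiplying every inter-module projection weight by
`1 + N(0, sigma)` with `sigma = 0.02`; microcircuit-internal constants are
untouched. Seeds derive hierarchically (master -> subject -> trial), so
any single trial can be reproduced in isolation.

## fMRI forward model

The integrated synaptic activity of a region is the sum of absolute
synaptic inputs (afferent, local, and bias currents; the background noise
is excluded) over the region's units, accumulated in 50 ms bins. Each
region's series is normalized by its run mean, scaled by a gain (0.6), and
passed through the balloon model (kappa = 0.65 s^-1, gamma = 0.41 s^-1,
tau = 0.98 s, alpha = 0.32, E0 = 0.34, V0 = 0.02; k1 = 7 E0, k2 = 2,
k3 = 2 E0 - 0.2), integrated by forward Euler at 10 ms and sampled at
TR = 1 s. The block design alternates blocks of three DMS trials (1 s
delay) with three passive-perception control trials of matched noise;
the event-related design extends delays to 20 s with 25 s between trial
onsets. Because the 6 s blocks are short relative to the hemodynamic
response, the task-vs-control contrast is estimated by projecting each
region's series onto the block indicator convolved with the model's own
hemodynamic impulse response.

## What the synthetic data do and do not show

The generator's defaults are the study conditions: 10 subjects, 20 trials
per experiment, balanced match/nonmatch, distractor saliency 1.0, bimodal
auditory saliency 0.55-0.6. Passing tests show the model reproduces the
published behavioral means, the load-vs-distraction effect, its
feedback-ablation signature, and the saliency switch point *under these
synthetic conditions*; they do not show that the stimulus statistics,
noise model, or subject variability resemble any empirical data set
beyond the summary statistics they were calibrated to.

## Known limitations

* The distractor-epoch ST-activity load contrasts are directionally
  present but an order of magnitude smaller than the published values.
  With attention entering only the D2 units and D2 being bistable, a
  salient distractor's prefrontal response saturates at the attractor
  level for any attention in the operating range, so the D2->ST feedback
  component of the ST response is nearly load-independent; the parameter
  regimes that amplify this pathway destroy low-attention memory decay,
  the saliency switch point, or the match/nonmatch readout margins.
* In the block-design fMRI experiment the control noise, being equally
  loud, captures exogenous attention and is transiently stored, so the
  prefrontal task-vs-control contrast is much smaller than the early
  sensory equality would suggest. Exogenous capture of salient stimuli at
  low endogenous attention is a required behavior of the attention model
  (it produces the event-related capture experiment), and we chose not to
  suppress it for the control condition.
* Behavioral error rates live on calibrated readout margins; the reported
  accuracies are stochastic with a between-seed spread of 1-2 points, and
  the DMS >= distractors >= Sternberg ordering holds in expectation with
  margins of only a few points.
* No transmission delays, spiking dynamics, scanner noise, or long-term
  memory; crossmodal (integrated-stream) tasks are out of scope.
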