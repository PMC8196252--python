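# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, what the scaled-down
study conditions do and do not show, and known limitations.

## Regulatory cascade

The cascade is a linear chain of cell states. S1 divides symmetrically;
an intracellular substance (initial quantity 100, decaying 1% per step)
acts as a clock, and the symmetric phase ends when it first drops below
`T_SYM = 65` — after exactly 43 steps. The number of symmetric
divisions is a separate parameter, `symmetric_rounds` (default 6): the
printed growth arithmetic (0.2 um diameter growth per step, division at
10 um) cannot fit six divisions into a 43-step window, so the division
count under-determines. We schedule `symmetric_rounds` synchronous
divisions uniformly inside the clock window; diameter growth between
them is cosmetic. The default is calibrated so that the four presets
reproduce the observed system totals (about 7000 / 11 000 / 16 000 /
24 000 cells for human, rat, mouse and macaque): 175 founders x 2^6
gives `N_P` = 11 200 progenitors. The clock substance is copied, not
split, at division, keeping the phase end synchronous.

At each asymmetric stage the fate draw is sequential — commit first
(probability `C`), then A1 apoptosis among the non-committers
(probability `P`) — so the outcome probabilities are
`(C, (1-C)P, (1-C)(1-P))` and per-stage survival is `(1-C)(1-P)`, the
only order consistent with the closed-form layer expectations. The
layer-6 expectation uses the survival factor `(1-P_M)` of the preceding
stage (the same pattern as all later layers). S7 is terminal: with
`P_2 = 1 - C_2` a cell there commits to the layer-2 fate or dies, and
nothing advances. Advancing cells divide once; both daughters enter the
next stage (one round of proliferation per stage).

The fast lineage Monte Carlo samples one multinomial per stage over the
cell population — distributionally identical to per-cell draws because
cells within a stage are exchangeable — which makes hundreds of
replicates at `N_P` = 11 200 take milliseconds. The spatial simulator
draws per cell, in creation order, from a single seeded generator.

## Physics

Cells are spheres with Cx3D-style conventions: overdamped motion
`dx = (F/mass) dt`, displacement capped at 3 um/step to prevent
tunnelling. The pair force is piecewise linear in the surface gap `g`:
repulsion `k_rep * (-g)` for `g < 0` (`k_rep` = 2), constant adhesion
`k_adh * min(adherence)` for `0 <= g <= 1 um` (`k_adh` = 1), zero
beyond; the interobject-force coefficient of the pair minimum scales
the interaction, keeping it antisymmetric. These constants are not
published for the original framework; they were chosen so a settled
monolayer is mechanically stable at the model's masses, and are
exposed in the configuration. Lateral walls reflect; the ventricular
floor (z = 0) and pial top clamp. Division conserves volume (daughter
diameter `d / 2^(1/3)`) along a uniformly random axis. The neighbor
index is a k-d tree with the exact contract "centers within r"; a
brute-force oracle pins it down in the tests.

Settled marginal-zone cells take mass and adherence 1e-4 and bond to
their nearest settled MZ neighbor (spring constant 1, no damping,
breaking at 500% strain); a cell whose partner dies re-bonds, so layer
1 remains a connected sheet. Other settled neurons take mass 10.
Migrating neurons carry an interobject-force coefficient of 1e-4: they
barely receive forces, while the cells they push (the feather-light
marginal zone) move freely — heavy cells push the light MZ pia-ward.

## Migration and stop rules

Committed neurons ascend the static linear pial gradient at 2 um/step
(the speed is not published; any value that delivers the MZ wave first
works, and the waiting clock below enforces the rest of the order).
Layer-6 neurons first wait on a decaying clock (threshold 95, about six
steps). Stop conditions: MZ cells stop where the cue reaches the
threshold concentration (default height 1100 um — this sets only the
distance between proliferative zone and cortex); layer 6 stops on
contact with one settled MZ cell; layers 2–5 stop on contact with two
settled MZ cells provided no earlier-born neuron is within the
exclusion radius (14.5 um). Three behaviours make this robust rather
than a race:

- a migrating cortical-plate cell arrests when it first touches the
  settled marginal zone (the MZ/pial boundary arrests radial
  migration) and trails its underside instead of passing through;
- the earlier-layer exclusion counts migrating as well as settled
  earlier-born neurons, which serialises the waves mechanically;
- arrested cells disperse tangentially (Gaussian, sd 1 um/step),
  exploring for a free settling pocket; uninterrupted arrest for 1000
  steps terminates migration in place (the A2 stage later judges such
  cells).

Settled neurons grow from 10 to 15 um (0.2 um/step) and never move by
their own action again.

## A2-type apoptosis

When the first layer-2 neurons settle they begin secreting a diffusible
substance (10 units/cell/step) into a 20-um voxel grid with explicit
zero-flux diffusion (D = 60 um^2/step; the stability bound
`D dt / h^2 <= 1/6` is checked at construction). A settled cell is
triggered when its voxel reaches the detection threshold (2 units);
the low threshold guarantees the already-injected mass covers the
cortical region even if the secreting cells later die. Each triggered
cell then evaluates the neighborhood rule exactly once, after a
3000-step signalling latency: within 20 um, at least three neighbors
belonging to one adjacent layer, or one neighbor of a more distant
layer, mean the cell has mislocalised and it dies. Layer distance is
the anatomical index difference (MZ/L1 = 1, L2 = 2, ..., L6 = 6), so
spatial neighbors are index neighbors. The adjacent count is taken per
single layer: a correctly placed cell at a flat interface faces about
two contacts from each side, and only cells pushed into a foreign band
exceed three from one layer. Marginal-zone cells additionally draw a
single Bernoulli death (p = 0.9) 2500 steps after their trigger onset.
The latencies let the architecture finish settling before judgment:
evaluating at onset punishes transient mislocation, and continuous
re-evaluation erodes packed interfaces without bound.

## Disease variants

Each variant changes exactly one mechanism: `polymicrogyria_a1` scales
every A1 probability by 1.5 (capped at 1); `polymicrogyria_short`
removes two symmetric-division rounds; `autism_no_a2` disables the A2
module; `heterotopia` gives every newly committed neuron a 20% chance
of never migrating (it stays in the proliferative zone). Thickness
contrasts use the mouse preset: it is the only preset whose scaled A1
probabilities all stay below 1 (the human `P_M` = 0.7 caps at 1.0 and
empties layers 6–2 entirely).

## Scaled-down study conditions and measurement protocol

Full-scale runs (175 founders, 6 rounds, 50 000 steps, 300 x 300 um)
exceed an interactive budget, so the tested configuration is 44
founders, 4 rounds and 8000 steps in a 70 x 70 um column. The narrow
footprint keeps each layer several cell monolayers thick at the
reduced numbers; at wider cross-sections the bands thin below the
20-um A2 sensing radius and segregation cannot be expressed. Laminar
statistics (median depths, thickness, overlap coefficients) are
computed on cells pooled from three independent replicate runs (six
for the sparse polymicrogyria variants), mirroring the replicate
averaging used for the original comparisons. Segregation is reported
over the reporting layers — L2/3 pooled, as in the experimental
reference counts — with the overlap coefficient `sum(min(p_a, p_b))`
on a fixed 15-um grid. Cortical thickness runs from the 5th percentile
of layer-6 depths to the 95th percentile of MZ depths; tighter
percentiles would let the handful of mislocated stragglers every run
produces define the boundary.

What the scaled runs demonstrate: the settlement sequence (MZ first,
then layers 6, 5, 4, 3, 2), inside-out final ordering with the MZ on
top, adjacent-layer segregation, the dominance of layer-1 death in the
A2 stage, and the variant phenotypes. What they do not demonstrate:
absolute cell numbers (those are checked at full lineage scale, where
physics is irrelevant) or absolute cortical thickness in millimetres.

## Numerical choices and degenerate inputs

Clock step counts use the closed form with an explicit boundary
correction against floating-point error. Coincident sphere centers get
a deterministic, pair-indexed separation axis (logged). Zero-variance
inputs to the agreement t-test return p = 1 for equal means and raise
otherwise. Diffusion refuses unstable configurations at construction.
The whole simulation is reproducible bit-for-bit from (configuration,
seed).

## Known limitations

- The fate waves are synchronous (deterministic growth), so commitment
  happens in discrete pulses rather than the staggered trickle of real
  neurogenesis; the arrest-and-explore migration makes lamination
  robust to this.
- No radial glial fibers, subplate, preplate splitting, neurites,
  electrical activity, or excitatory/inhibitory distinction; one
  progenitor chain models all lineages.
- Post-A2 architectures keep their skeleton: dead cells leave voids
  that nothing compacts (there is no gravity or global adhesion), so
  thickness after heavy apoptosis is an upper bound.
- The human layer-6 expectation (about 1129 column neurons) sits 17%
  above the measured value converted to column units (966); this is a
  property of the published cascade probabilities, not of the
  implementation, and one tolerance test encodes it as a known
  failure.
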