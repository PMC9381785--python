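# Methods

## Model

The package generates a connectome for a layered, curved cortical-like
volume (a CA1-style region) at single-cell resolution using geometric
probability clouds instead of reconstructed morphologies. The pipeline is
place → morph → connect → analyze (→ simulate), and every stage is a pure
function of its configuration and a seed.

### Region and placement

The synthetic region is a circular-arc slab: transversal arc length
(default 2000 µm), longitudinal extrusion (4000 µm) and four radially
stacked layers SO/SP/SR/SLM (150/100/300/150 µm). Curvature defaults to
1/1000 µm⁻¹ (a 2-radian bend); 0 gives a flat slab. Two planar
triangulated patches close the transversal ends at a 100 µm gap: CA3 at
the near end, subiculum at the far end. The curvature is not cosmetic —
the orientation frames need the soma→subiculum and soma→CA3
minimum-distance vectors to be non-collinear, which the bend guarantees
for every interior soma. These dimensions are plausible CA1-scale
placeholders and are fully config-overridable; the generator does not
attempt atlas fidelity (no density gradients within layers, no realistic
mesh anatomy).

Default class counts follow the published CA1 census: 45,408 deep and
216,435 superficial pyramidal cells, and 26,184 interneurons in four layer
groups (SO 1,979; SP 1,661; SR 10,147; SLM 12,397), a 10.0%
inhibitory/excitatory ratio. Within the SR group the IVY count is fixed at
5,074 (the value used in the published pruning example) and the remainder
is split evenly among BS/SCA/PPA; the SO and SP groups are split
near-evenly among their three classes, since only group totals are
published. A global scale factor (round-half-up, floor 1) shrinks every
class uniformly. Placement is uniform per layer shell via rejection
sampling on the radial Jacobian of the bent slab.

### Morphologies

Each class is a list of shape templates (ellipsoids and cones) in
`src/pma/data/morphology_catalogue.yaml` — two pyramidal archetypes and
seven interneuron archetypes (perisomatic, SLM-projecting, concentric,
multilaminar, Schaffer-associated, perforant-associated, neurogliaform).
Dimensions are normal draws with σ = 0.1 × mean, resampled while below 5%
of the mean ("half-width of 10%" is read as σ = 10% of the peak; the
source does not define it more precisely). Only the pyramidal apical cone
(height 400 µm, radius 80 µm) is anchored to published values; all other
dimensions are documented placeholders chosen for anatomical plausibility
(layer spans, soma-centered plexuses) and should be refit when class-wise
reconstructions are available.

Ellipsoid axes are tied to the anatomical triad: u₁ transversal (toward
the subiculum), u₂ longitudinal, u₃ vertical, with u₂/u₃ flipped together
when needed so u₃ points from SO toward SLM while keeping the frame
right-handed. The ellipsoid surface grid uses the canonical spherical
parameterisation x = λ₁cosθ sinφ, y = λ₂sinθ sinφ, z = λ₃cosφ (the
published equation prints x and y with identical factors, which cannot
span a surface; we treat it as a typo). Pyramidal axons implement the
anatomical rule: major semi-axis λ₁ = (min(sampled length, d_sub) +
100 µm)/2 along u₁ with the center offset λ₁ − 100 µm, i.e. a fixed
100 µm back-projection toward CA3 and truncation at the subiculum.
Superficial-PC axons are a thin soma→SO connector plus the main SO
ellipsoid (two hull components); membership in the axon is membership in
any component.

Axonal shapes are realised as convex hulls of 48 surface points (the hull
is inscribed in the analytic shape, which the narrow phase exploits as a
conservative prefilter). Dendritic shapes are filled with exactly
max(1, ⌊V/8000 µm³⌋) points — one per 20 µm voxel — on a jittered regular
grid cropped to the interior, trimmed or rejection-padded to the exact
count; the floor of one point keeps sub-voxel dendrites visible to the
intersection test. Gridding (rather than uniform random placement) was
chosen for even coverage at these low point densities; the jitter removes
grid-alignment artifacts between cells.

### Connectivity

Candidates are pairs whose axonal/dendritic AABBs overlap (closed
intervals: touching boxes count) and that share at least one dendritic
point inside an axonal hull (inclusive tolerance 1e-9 µm). Duplicate hits
collapse to one pair; self-pairs are excluded. Internally
`build_connectome` gathers dendritic points through a 75 µm uniform-grid
spatial index per presynaptic cell rather than looping over pairs; the
result is provably identical to narrow∘broad (a point inside a hull lies
inside both boxes) and is verified against brute force in the tests.

Pruning draws a uniform sample without replacement of size
min(round(n_pre·n_post·p), candidates) per ordered class pair, with a
per-pair RNG stream derived from (seed, class names) so results are
independent of table order. When candidates fall short of the target a
calibration warning is logged and all candidates are kept. The bundled
probability table carries the published superficial-PC→IVY value
(0.000933) and 40 plausibility placeholders of similar magnitude
(PC→PC 1.5e-3, PC→interneuron 9.33e-4, interneuron→PC 2e-3–5e-3).
PC→SCA and PC→NG are omitted: those dendrites are confined near the SLM,
out of reach of SO-resident pyramidal axons, matching their
entorhinal-driven physiology. Class pairs absent from the table produce
no edges, so partial tables are safe.

### Diagnostics

Degree distributions are exact per-cell tallies including zero-degree
cells, normalised over the observed degree range; the excitatory filter
restricts both the population and the edge set. The shape diagnostic fits
the degree density with a discrete convolution of a power law k^(−α)
(k ≥ 1) and an exponential kernel e^(−j/β) (grid search plus Nelder–Mead;
fewer than five occupied degree values returns a failure flag instead of
raising). It is a descriptive diagnostic, not a calibration target. Hubs
are cells at or above a total-degree percentile computed with the "lower"
quantile rule so ties and the 0⁺ limit behave as expected.

### Simulation

The simulator exists to validate wiring, not to predict physiology.
Neurons are current-based leaky integrate-and-fire units (τ_m 20 ms, rest
−65 mV, threshold −50 mV, 3 ms refractory) with an adaptive threshold
(+5 mV per spike, τ 50 ms) and exponential synaptic drive (τ_syn 3 ms).
Synapses carry Tsodyks–Markram short-term dynamics (x recovers to 1 with
τ_rec, u decays to 0 with τ_fac, facilitation u ← u + U(1−u) at each
spike, release u·x; both variables provably stay in [0, 1]) and
distance-dependent delays (1 ms + distance/500 µm ms⁻¹). The default
excitatory weight (200 drive units ≈ 21 mV peak EPSP against the 15 mV
threshold gap, given the measured 0.105 peak-transfer factor of this
membrane) makes single inputs suprathreshold; all defaults live in
`pma.simulate.DEFAULT_PARAMS` and none claims physiological calibration.
Dynamics are deterministic given the circuit; the seed only feeds optional
initial-potential jitter. Ties are resolved in cell-id order on a fixed
0.1 ms grid.

### Directional-propagation experiment

`pma.validation.directional_propagation` builds an excitatory-only
circuit, extracts a 500 µm transversal slice (both edge endpoints must lie
inside; the full circuit is built first and then sliced, because pruning
targets scale with the population passed in — building a connectome for
the slice population alone would under-connect it), and stimulates a sphere of cells
at 10% or 90% of the transversal arc. At 2% density the stimulus radius
is 300 µm, the scaled-density equivalent of ~200 cells in a 100 µm sphere
at full scale. The propagation index is the fraction of non-stimulated
excitatory cells that fire within the 40 ms window. The window matters:
forward recruitment jumps a full axon length (~1.5 mm) per synaptic hop
while reverse recruitment creeps by only the back-projection plus the
dendritic radius (~180 µm) per hop, so the asymmetry is measured before
the slow reverse wave saturates the small slice (in full-size tissue the
equivalent observation window is a few milliseconds).

## Problem sizes used

Scaled circuits keep the full geometry and all probability parameters and
shrink only the census: 2% scale (5,760 cells, ~51 k edges) for degree
diagnostics and the ten-seed propagation experiment, 1% for byte-level
determinism checks. These sizes were chosen so the complete validation
battery runs on a single CPU in minutes while every per-pair quantity
(targets, candidate counts) still follows the same calculus as the
full-scale circuit.

## Known limitations

- All shape dimensions except the apical cone, and all probabilities
  except PC→IVY, are placeholders; absolute candidate/edge counts at full
  scale are therefore not comparable to published full-scale totals.
- Interneurons are placed strictly in their census layer; real classes
  scatter into neighbouring layers.
- Pruning is uniform; distance-dependent pruning weights are not
  implemented.
- The synthetic region has uniform density, ideal layer shells and planar
  landmark patches; passing tests demonstrates algorithmic correctness and
  qualitative anatomy-driven behaviour, not atlas-level realism.
- The point-neuron model omits NMDA voltage dependence, long-term
  plasticity and oscillatory phenomena; the propagation benchmark is
  qualitative.
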