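# Default morphology catalogue: per-class probability-cloud templates.
#
# Every cell class is a combination of ellipsoids (axonal plexuses,
# modelled as convex hulls of surface points) and cones (dendritic
# territories, modelled as volume-filling point clouds).  Dimensions are
# nominal means in µm; at instantiation each is sampled from a normal
# distribution with sigma = 10% of the mean.  The pyramidal-cell apical
# cone (height 400, radius 80) is anchored to published CA1 estimates;
# the remaining dimensions are editable placeholders calibrated only for
# plausibility and should be refit when class-specific reconstructions
# are available.
#
# Template fields
#   primitive      ellipsoid | cone
#   role           axon | apical-dendrite | basal-dendrite
#   semiaxes       ellipsoid semi-axes {t, l, v} along the transversal
#                  (toward subiculum), longitudinal and vertical (toward
#                  SLM) anatomical directions
#   offset         shape reference-point offset from the soma {t, l, v}
#   anchor_layer   center the shape vertically on this layer's mid-depth
#                  ("ALL" = mid-depth of the whole slab)
#   span_to_layer  connector: stretch the vertical semi-axis from the
#                  soma to this layer's mid-depth (plus span_pad)
#   special        pc_axon = subiculum-truncated pyramidal axon with a
#                  fixed 100 µm back-projection toward CA3
#   axis           cone axis direction (+v toward SLM, -v toward SO)

classes:
  deep-PC:
    archetype: pyramidal-deep
    templates:
      - {primitive: ellipsoid, role: axon, special: pc_axon,
         length: 1500, semiaxes: {l: 200, v: 60}}
      - {primitive: cone, role: apical-dendrite, height: 400, radius: 80, axis: "+v"}
      - {primitive: cone, role: basal-dendrite, height: 100, radius: 80, axis: "-v"}

  superficial-PC:
    archetype: pyramidal-superficial
    templates:
      - {primitive: ellipsoid, role: axon, span_to_layer: SO, span_pad: 20,
         semiaxes: {t: 30, l: 30}}
      - {primitive: ellipsoid, role: axon, special: pc_axon, anchor_layer: SO,
         length: 1500, semiaxes: {l: 200, v: 60}}
      - {primitive: cone, role: apical-dendrite, height: 400, radius: 80, axis: "+v"}
      - {primitive: cone, role: basal-dendrite, height: 120, radius: 100, axis: "-v"}

  OLM:
    archetype: slm-projecting
    templates:
      - {primitive: ellipsoid, role: axon, span_to_layer: SLM, span_pad: 20,
         semiaxes: {t: 25, l: 25}}
      - {primitive: ellipsoid, role: axon, anchor_layer: SLM,
         semiaxes: {t: 250, l: 250, v: 70}}
      - {primitive: ellipsoid, role: basal-dendrite, semiaxes: {t: 200, l: 200, v: 60}}

  BP:
    archetype: slm-projecting
    templates:
      - {primitive: ellipsoid, role: axon, span_to_layer: SLM, span_pad: 20,
         semiaxes: {t: 25, l: 25}}
      - {primitive: ellipsoid, role: axon, anchor_layer: SLM,
         semiaxes: {t: 250, l: 250, v: 70}}
      - {primitive: ellipsoid, role: basal-dendrite, semiaxes: {t: 200, l: 200, v: 60}}

  Trilaminar:
    archetype: multilaminar
    templates:
      - {primitive: ellipsoid, role: axon, anchor_layer: ALL,
         semiaxes: {t: 200, l: 200, v: 330}}
      - {primitive: ellipsoid, role: basal-dendrite, semiaxes: {t: 150, l: 150, v: 70}}

  CCKBC:
    archetype: perisomatic
    templates:
      - {primitive: ellipsoid, role: axon, semiaxes: {t: 250, l: 250, v: 60}}
      - {primitive: cone, role: apical-dendrite, height: 450, radius: 80, axis: "+v"}
      - {primitive: cone, role: basal-dendrite, height: 180, radius: 80, axis: "-v"}

  PVBC:
    archetype: perisomatic
    templates:
      - {primitive: ellipsoid, role: axon, semiaxes: {t: 250, l: 250, v: 60}}
      - {primitive: cone, role: apical-dendrite, height: 450, radius: 80, axis: "+v"}
      - {primitive: cone, role: basal-dendrite, height: 180, radius: 80, axis: "-v"}

  AA:
    archetype: perisomatic
    templates:
      - {primitive: ellipsoid, role: axon, semiaxes: {t: 250, l: 250, v: 60}}
      - {primitive: cone, role: apical-dendrite, height: 450, radius: 80, axis: "+v"}
      - {primitive: cone, role: basal-dendrite, height: 180, radius: 80, axis: "-v"}

  IVY:
    archetype: concentric
    templates:
      - {primitive: ellipsoid, role: axon, semiaxes: {t: 250, l: 250, v: 300}}
      - {primitive: ellipsoid, role: apical-dendrite, semiaxes: {t: 150, l: 150, v: 300}}

  BS:
    archetype: concentric
    templates:
      - {primitive: ellipsoid, role: axon, semiaxes: {t: 250, l: 250, v: 300}}
      - {primitive: ellipsoid, role: apical-dendrite, semiaxes: {t: 150, l: 150, v: 300}}

  SCA:
    archetype: schaffer
    templates:
      - {primitive: ellipsoid, role: axon, anchor_layer: SO,
         semiaxes: {t: 200, l: 200, v: 90}}
      - {primitive: ellipsoid, role: apical-dendrite, span_to_layer: SLM,
         span_pad: 40, semiaxes: {t: 150, l: 150}}

  PPA:
    archetype: perforant
    templates:
      - {primitive: ellipsoid, role: axon, offset: {v: 100},
         semiaxes: {t: 250, l: 250, v: 150}}
      - {primitive: cone, role: apical-dendrite, height: 180, radius: 80, axis: "+v"}
      - {primitive: cone, role: basal-dendrite, height: 180, radius: 80, axis: "-v"}

  NG:
    archetype: neurogliaform
    templates:
      - {primitive: ellipsoid, role: axon, anchor_layer: SR,
         semiaxes: {t: 220, l: 220, v: 180}}
      - {primitive: ellipsoid, role: basal-dendrite, semiaxes: {t: 100, l: 100, v: 60}}
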