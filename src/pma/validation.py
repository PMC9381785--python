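"""Reference validation experiments on scaled-down circuits.

These functions bundle the two benchmark protocols used to judge a
generated connectome:

* degree diagnostics on a reduced circuit (degree conservation and the
  shift of the in-degree peak when inhibitory partners are included);
* the directional-propagation experiment: a transversal slice is cut from
  an excitatory-only circuit, a spherical group of pyramidal cells is
  stimulated near either the CA3 or the subiculum end, and the recruited
  fraction of the remaining excitatory population is compared.  CA1
  axonal anatomy (subiculum-directed axons with only a ~100 µm
  back-projection) predicts much stronger CA3->subiculum spread.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .connectivity import build_connectome, default_class_pair_table
from .morphology import default_catalogue, instantiate_all
from .placement import (DEFAULT_COUNTS, EXCITATORY_CLASSES, PopulationSpec,
                        generate_region, place_cells)
from .simulate import StimulusSpec, extract_slice, propagation_index, run


def build_circuit(scale: float, seed: int, excitatory_only: bool = False,
                  region_config: Optional[dict] = None) -> Dict:
    """Place, instantiate and connect a scaled circuit in one call.

    The single seed fans out to fixed per-stage child seeds so circuits
    built at different seeds are fully independent.
    """
    ss = np.random.SeedSequence(int(seed))
    s_place, s_morph, s_conn = (int(s.generate_state(1, dtype=np.uint32)[0]
                                    % (2 ** 31)) for s in ss.spawn(3))
    region = generate_region(region_config, seed=s_place)
    counts = dict(DEFAULT_COUNTS)
    if excitatory_only:
        counts = {k: (v if k in EXCITATORY_CLASSES else 0)
                  for k, v in counts.items()}
    cells = place_cells(region, PopulationSpec(counts=counts, scale=scale),
                        seed=s_place)
    morphs = instantiate_all(cells, default_catalogue(), region, seed=s_morph)
    edges = build_connectome(cells, morphs, default_class_pair_table(),
                             seed=s_conn)
    return {"region": region, "cells": cells, "morphologies": morphs,
            "edges": edges}


def directional_propagation(scale: float = 0.02, seed: int = 0,
                            slice_thickness_um: float = 500.0,
                            stim_radius_um: float = 300.0,
                            duration_ms: float = 40.0,
                            sim_params: Optional[dict] = None
                            ) -> Tuple[float, float]:
    """Recruited excitatory fractions for CA3-side vs subiculum-side stimulation.

    Builds an excitatory-only circuit at the given scale, extracts a
    transversal slice, stimulates a sphere of cells near either end of the
    transversal axis (10% / 90% of the arc) and returns the two
    propagation indices ``(ca3_side, subiculum_side)``.
    """
    circuit = build_circuit(scale, seed, excitatory_only=True)
    region, cells, edges = circuit["region"], circuit["cells"], circuit["edges"]
    slice_cells, slice_edges = extract_slice(
        cells, edges, axis=1, thickness=slice_thickness_um,
        excitatory_only=True)
    somata = np.array([c.soma for c in slice_cells])
    s, _, _ = region.from_world(somata)
    centers = {
        "ca3": somata[np.argmin(np.abs(s - 0.1 * region.arc_length))],
        "sub": somata[np.argmin(np.abs(s - 0.9 * region.arc_length))],
    }
    out = {}
    for side, center in centers.items():
        stim = StimulusSpec(center=center, radius=stim_radius_um)
        result = run(slice_cells, slice_edges, stim, params=sim_params,
                     duration_ms=duration_ms, seed=seed)
        out[side] = propagation_index(result, slice_cells)
    return out["ca3"], out["sub"]
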