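"""End-to-end orchestration: place -> morph -> connect -> analyze (-> simulate).

Every output file is derivable from (config, seed) alone; re-running with
the same configuration reproduces the node and edge tables byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .analysis import (degree_distributions, export_distribution,
                       length_distribution, plot_distributions)
from .config import RunConfig
from .connectivity import (build_connectome, default_class_pair_table,
                           export_hdf5, load_class_pair_table, save_edges)
from .errors import ConfigError
from .morphology import (default_catalogue, instantiate_all, load_catalogue,
                         sampled_dims_frame)
from .placement import (PopulationSpec, generate_region, place_cells,
                        save_positions)
from .simulate import StimulusSpec, extract_slice, propagation_index, run, save_raster

logger = logging.getLogger(__name__)

STAGES = ("place", "morph", "connect", "analyze", "simulate")


def run_pipeline(config: RunConfig, stop_after: str = "analyze") -> dict:
    """Execute the pipeline and return the artifact manifest.

    ``stop_after`` truncates the run after the named stage; the simulate
    stage additionally requires ``config.simulate`` or
    ``stop_after='simulate'``.
    """
    if stop_after not in STAGES:
        raise ConfigError(f"unknown stage {stop_after!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {"version": __version__, "numpy": np.__version__,
                "seed": int(config.seed), "scale": float(config.scale),
                "stages": {}, "files": {}}

    def record(stage, **counts):
        manifest["stages"][stage] = {"wall_s": round(time.time() - t0, 3), **counts}

    # -- place ---------------------------------------------------------------
    region = generate_region(config.region, seed=config.stage_seed("place"))
    if config.population_counts:
        base = PopulationSpec().counts
        base.update(config.population_counts)
        pop = PopulationSpec(counts=base, scale=config.scale)
    else:
        pop = PopulationSpec(scale=config.scale)
    cells = place_cells(region, pop, seed=config.stage_seed("place"))
    save_positions(cells, out / "nodes.csv")
    region.ca3_mesh.save(out / "ca3.ply")
    region.sub_mesh.save(out / "subiculum.ply")
    manifest["files"]["nodes"] = "nodes.csv"
    per_class = pd.Series([c.class_label for c in cells]).value_counts().to_dict()
    record("place", cells=len(cells), per_class=per_class)
    if stop_after == "place":
        return _write_manifest(manifest, out)

    # -- morph ---------------------------------------------------------------
    catalogue = (load_catalogue(config.catalogue_path)
                 if config.catalogue_path else default_catalogue())
    morphologies = instantiate_all(cells, catalogue, region,
                                   seed=config.stage_seed("morph"),
                                   sigma_frac=config.sigma_frac)
    sampled_dims_frame(morphologies).to_csv(out / "sampled_dims.csv",
                                            index=False, float_format="%.6f")
    manifest["files"]["sampled_dims"] = "sampled_dims.csv"
    record("morph", morphologies=len(morphologies))
    if stop_after == "morph":
        return _write_manifest(manifest, out)

    # -- connect ---------------------------------------------------------------
    table = (load_class_pair_table(config.probability_table_path)
             if config.probability_table_path else default_class_pair_table())
    edges = build_connectome(cells, morphologies, table,
                             seed=config.stage_seed("connect"))
    save_edges(edges, out / "edges.csv")
    manifest["files"]["edges"] = "edges.csv"
    if config.export_hdf5:
        export_hdf5(cells, edges, out / "circuit.h5")
        manifest["files"]["hdf5"] = "circuit.h5"
    record("connect", edges=len(edges))
    if stop_after == "connect":
        return _write_manifest(manifest, out)

    # -- analyze ---------------------------------------------------------------
    dists = {}
    for population in ("all", "excitatory"):
        d_in, d_out = degree_distributions(edges, cells, population)
        dists[population] = (d_in, d_out)
        export_distribution(d_in, out / f"degree_in_{population}.csv")
        export_distribution(d_out, out / f"degree_out_{population}.csv")
    counts, bin_edges = length_distribution(edges, cells)
    pd.DataFrame({"bin_lo_um": bin_edges[:-1], "bin_hi_um": bin_edges[1:],
                  "count": counts}).to_csv(out / "length_distribution.csv",
                                           index=False, float_format="%.6f")
    plot_distributions([("all, in", dists["all"][0]),
                        ("excitatory, in", dists["excitatory"][0])],
                       out / "degree_in.png", title="in-degree")
    plot_distributions([("all, out", dists["all"][1]),
                        ("excitatory, out", dists["excitatory"][1])],
                       out / "degree_out.png", title="out-degree")
    record("analyze",
           in_peak_all=dists["all"][0].peak,
           in_peak_exc=dists["excitatory"][0].peak)
    if stop_after == "analyze" and not config.simulate:
        return _write_manifest(manifest, out)

    # -- simulate ----------------------------------------------------------
    slice_cells, slice_edges = extract_slice(
        cells, edges, axis=1, thickness=config.slice_thickness_um,
        excitatory_only=True)
    if slice_cells:
        somata = np.array([c.soma for c in slice_cells])
        ca3_end = somata[np.argmin(somata[:, 0])]
        stim = StimulusSpec(center=ca3_end, radius=config.stim_radius_um)
        result = run(slice_cells, slice_edges, stim, params=config.sim_params,
                     duration_ms=config.sim_duration_ms,
                     seed=config.stage_seed("simulate"))
        save_raster(result, out / "raster.csv")
        manifest["files"]["raster"] = "raster.csv"
        record("simulate", spikes=len(result.raster),
               stimulated=len(result.stimulated_ids),
               propagation_index=round(propagation_index(result, slice_cells), 6))
    else:
        record("simulate", spikes=0, stimulated=0)
    return _write_manifest(manifest, out)


def _write_manifest(manifest: dict, out: Path) -> dict:
    manifest["wall_s"] = manifest["stages"][list(manifest["stages"])[-1]]["wall_s"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
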