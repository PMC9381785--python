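"""Per-class shape archetypes and landmark-driven cell instantiation.

Every cell class is described by a :class:`ClassMorphologySpec`: a list of
shape templates (ellipsoids and cones) whose nominal dimensions are sampled
per cell from normal distributions (sigma = 10% of the mean) and which are
anchored and oriented by the cell's anatomical frame.  Axonal shapes become
convex hulls of surface points; dendritic shapes become volume-filling
point clouds at one point per 8000 µm³.

Pyramidal-cell axons follow the anatomical rule observed in CA1: the major
axis points toward the subiculum, the soma sits 100 µm from the rear pole
(the residual back-projection toward CA3) and the overall extent is capped
by the distance to the subiculum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .geometry import (
    AABB,
    Cone,
    Ellipsoid,
    HullVolume,
    OrientationFrame,
    PointCloud,
    Shape,
    aabb,
    convex_hull,
    cone_surface_points,
    ellipsoid_surface_points,
    fill_points,
    frame_with_fallback,
    min_distances_to_mesh,
)
from .placement import CellRecord, RegionGeometry

#: residual pyramidal-axon extent behind the soma, toward CA3 (µm)
BACK_PROJECTION_UM = 100.0

#: surface points per axonal shape before hull construction
AXON_SURFACE_POINTS = 48

#: relative width of the dimension-sampling distributions
DEFAULT_SIGMA_FRAC = 0.10

_DIM_KEYS = ("height", "radius", "length", "a_t", "a_l", "a_v")


@dataclass
class ShapeTemplate:
    """One geometric component of a class morphology."""

    primitive: str                       # "ellipsoid" | "cone"
    role: str                            # axon | apical-dendrite | basal-dendrite
    semiaxes: Dict[str, float] = field(default_factory=dict)   # t, l, v (µm)
    offset: Dict[str, float] = field(default_factory=dict)     # t, l, v (µm)
    anchor_layer: Optional[str] = None
    span_to_layer: Optional[str] = None
    span_pad: float = 20.0
    special: Optional[str] = None        # "pc_axon"
    height: Optional[float] = None       # cone
    radius: Optional[float] = None       # cone
    axis: str = "+v"                     # cone axis direction
    length: Optional[float] = None       # pc_axon nominal extent

    def __post_init__(self):
        if self.primitive not in ("ellipsoid", "cone"):
            raise ConfigError(f"unknown primitive {self.primitive!r}")
        if self.role not in ("axon", "apical-dendrite", "basal-dendrite"):
            raise ConfigError(f"unknown role {self.role!r}")
        if self.primitive == "cone":
            if not self.height or not self.radius:
                raise ConfigError("cone template needs height and radius")
            if self.axis not in ("+v", "-v", "+t", "-t"):
                raise ConfigError(f"unknown cone axis {self.axis!r}")
        for value in self.nominal_dims().values():
            if value <= 0:
                raise ConfigError("template dimensions must be positive")

    def nominal_dims(self) -> Dict[str, float]:
        """Nominal (mean) values of every sampled dimension."""
        dims = {}
        if self.primitive == "cone":
            dims["height"] = float(self.height)
            dims["radius"] = float(self.radius)
        else:
            for key, name in (("t", "a_t"), ("l", "a_l"), ("v", "a_v")):
                if key in self.semiaxes:
                    dims[name] = float(self.semiaxes[key])
            if self.special == "pc_axon":
                dims["length"] = float(self.length)
        return dims

    def to_dict(self) -> dict:
        out = {"primitive": self.primitive, "role": self.role}
        if self.semiaxes:
            out["semiaxes"] = dict(self.semiaxes)
        if self.offset:
            out["offset"] = dict(self.offset)
        if self.anchor_layer:
            out["anchor_layer"] = self.anchor_layer
        if self.span_to_layer:
            out["span_to_layer"] = self.span_to_layer
            out["span_pad"] = self.span_pad
        if self.special:
            out["special"] = self.special
        if self.primitive == "cone":
            out.update(height=self.height, radius=self.radius, axis=self.axis)
        if self.length is not None:
            out["length"] = self.length
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeTemplate":
        return cls(**d)


@dataclass
class ClassMorphologySpec:
    """All shape templates of one cell class."""

    class_label: str
    templates: List[ShapeTemplate]
    archetype: str = ""

    def __post_init__(self):
        roles = {t.role for t in self.templates}
        if "axon" not in roles:
            raise ConfigError(f"{self.class_label}: no axon template")
        if not roles & {"apical-dendrite", "basal-dendrite"}:
            raise ConfigError(f"{self.class_label}: no dendrite template")


def load_catalogue(path) -> Dict[str, ClassMorphologySpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _catalogue_from_mapping(raw)


def _catalogue_from_mapping(raw: dict) -> Dict[str, ClassMorphologySpec]:
    out = {}
    for label, entry in raw["classes"].items():
        templates = [ShapeTemplate.from_dict(t) for t in entry["templates"]]
        out[label] = ClassMorphologySpec(label, templates,
                                         archetype=entry.get("archetype", ""))
    return out


def save_catalogue(catalogue: Dict[str, ClassMorphologySpec], path) -> None:
    raw = {"classes": {
        label: {"archetype": spec.archetype,
                "templates": [t.to_dict() for t in spec.templates]}
        for label, spec in catalogue.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_catalogue() -> Dict[str, ClassMorphologySpec]:
    """Bundled catalogue covering all 13 cell classes (9 archetypes)."""
    text = resources.files("pma").joinpath("data/morphology_catalogue.yaml").read_text()
    return _catalogue_from_mapping(yaml.safe_load(text))


def sample_dimensions(template: ShapeTemplate,
                      rng: np.random.Generator,
                      sigma_frac: float = DEFAULT_SIGMA_FRAC) -> Dict[str, float]:
    """Sample each nominal dimension from N(mean, sigma_frac * mean).

    Draws are repeated until the value exceeds 5% of the nominal, so
    dimensions are always positive.  ``sigma_frac=0`` returns the nominal
    values exactly.
    """
    out = {}
    for key, nominal in template.nominal_dims().items():
        if sigma_frac == 0:
            out[key] = nominal
            continue
        value = -math.inf
        while value <= 0.05 * nominal:
            value = rng.normal(nominal, sigma_frac * nominal)
        out[key] = value
    return out


@dataclass
class SampledMorphology:
    """Instantiated probability clouds of a single cell."""

    cell_id: int
    class_label: str
    soma: np.ndarray
    frame: OrientationFrame
    shapes: List[tuple]                  # (template index, role, Shape)
    axon_hulls: List[HullVolume]
    axon_shapes: List[Shape]             # generating shapes (hull superset)
    axon_aabbs: List[AABB]
    dendrite_clouds: List[PointCloud]
    dendrite_points: np.ndarray          # all dendritic points, stacked
    sampled_dims: List[Dict[str, float]]

    @property
    def axon_aabb(self) -> AABB:
        los = np.array([b.lo for b in self.axon_aabbs])
        his = np.array([b.hi for b in self.axon_aabbs])
        return AABB(los.min(axis=0), his.max(axis=0))

    @property
    def dendrite_aabb(self) -> AABB:
        return aabb(self.dendrite_points)


def _anatomical_frame(frame: OrientationFrame, w_region: np.ndarray) -> OrientationFrame:
    """Flip u2/u3 together so u3 points toward the SLM, keeping det = +1."""
    if float(frame.u3 @ w_region) >= 0:
        return frame
    return OrientationFrame(frame.u1, -frame.u2, -frame.u3)


def instantiate(cell: CellRecord,
                spec: ClassMorphologySpec,
                region: RegionGeometry,
                rng: np.random.Generator,
                landmark: Optional[tuple] = None,
                sigma_frac: float = DEFAULT_SIGMA_FRAC,
                n_surface: int = AXON_SURFACE_POINTS) -> SampledMorphology:
    """Build the oriented axonal hulls and dendritic clouds of one cell.

    ``landmark`` optionally carries precomputed ``(v_sub, v_ca3, d_sub)``
    minimum-distance vectors/distance; otherwise they are measured against
    the region's landmark meshes.
    """
    soma = cell.soma
    if landmark is None:
        from .geometry import min_distance_to_mesh
        d_sub, _, v_sub = min_distance_to_mesh(soma, region.sub_mesh)
        _, _, v_ca3 = min_distance_to_mesh(soma, region.ca3_mesh)
    else:
        v_sub, v_ca3, d_sub = landmark
        d_sub = float(d_sub)
    base_frame = frame_with_fallback(v_sub, v_ca3)
    w_region = region.vertical_direction(soma)[0]
    frame = _anatomical_frame(base_frame, w_region)
    t_hat, l_hat, v_hat = frame.u1, frame.u2, frame.u3
    _, _, d_arr = region.from_world(soma)
    d_soma = float(d_arr[0])

    shapes, dims_list = [], []
    for i, tpl in enumerate(spec.templates):
        dims = sample_dimensions(tpl, rng, sigma_frac)
        off = tpl.offset
        anchor = soma + (off.get("t", 0.0) * t_hat
                         + off.get("l", 0.0) * l_hat
                         + off.get("v", 0.0) * v_hat)
        if tpl.primitive == "cone":
            direction = {"+v": v_hat, "-v": -v_hat,
                         "+t": t_hat, "-t": -t_hat}[tpl.axis]
            shape: Shape = Cone(anchor, anchor + dims["height"] * direction,
                                dims["radius"])
        else:
            center = anchor.copy()
            a_t = dims.get("a_t", 0.0)
            a_l = dims.get("a_l", 0.0)
            a_v = dims.get("a_v", 0.0)
            if tpl.anchor_layer:
                d_mid = (region.total_depth / 2.0 if tpl.anchor_layer == "ALL"
                         else region.layer_mid_depth(tpl.anchor_layer))
                center = center + (d_mid - d_soma) * v_hat
            if tpl.span_to_layer:
                delta = region.layer_mid_depth(tpl.span_to_layer) - d_soma
                center = center + (delta / 2.0) * v_hat
                a_v = abs(delta) / 2.0 + tpl.span_pad
            if tpl.special == "pc_axon":
                effective = min(dims["length"], d_sub)
                a_t = (effective + BACK_PROJECTION_UM) / 2.0
                center = center + (a_t - BACK_PROJECTION_UM) * t_hat
            shape = Ellipsoid(center, frame, (a_t, a_l, a_v))
        shapes.append((i, tpl.role, shape))
        dims_list.append(dims)

    axon_hulls, axon_shapes, axon_aabbs, dendrite_clouds = [], [], [], []
    for _, role, shape in shapes:
        if role == "axon":
            surface = (ellipsoid_surface_points(shape, n_surface)
                       if isinstance(shape, Ellipsoid)
                       else cone_surface_points(shape, n_surface))
            hull = convex_hull(surface)
            axon_hulls.append(hull)
            axon_shapes.append(shape)
            axon_aabbs.append(aabb(surface))
        else:
            cloud = fill_points(shape, rng=rng)
            cloud.role = role
            dendrite_clouds.append(cloud)
    dendrite_points = np.vstack([c.points for c in dendrite_clouds])
    return SampledMorphology(cell.id, cell.class_label, soma, frame, shapes,
                             axon_hulls, axon_shapes, axon_aabbs,
                             dendrite_clouds, dendrite_points, dims_list)


def instantiate_all(cells: List[CellRecord],
                    catalogue: Dict[str, ClassMorphologySpec],
                    region: RegionGeometry,
                    seed: int = 0,
                    sigma_frac: float = DEFAULT_SIGMA_FRAC,
                    n_surface: int = AXON_SURFACE_POINTS
                    ) -> Dict[int, SampledMorphology]:
    """Instantiate every cell, batching the landmark distance queries."""
    missing = sorted({c.class_label for c in cells} - set(catalogue))
    if missing:
        raise ConfigError(f"classes missing from morphology catalogue: {missing}")
    rng = np.random.default_rng(seed)
    somata = np.array([c.soma for c in cells])
    d_sub, _, v_sub = min_distances_to_mesh(somata, region.sub_mesh)
    _, _, v_ca3 = min_distances_to_mesh(somata, region.ca3_mesh)
    out = {}
    for k, cell in enumerate(cells):
        out[cell.id] = instantiate(cell, catalogue[cell.class_label], region, rng,
                                   landmark=(v_sub[k], v_ca3[k], d_sub[k]),
                                   sigma_frac=sigma_frac, n_surface=n_surface)
    return out


def sampled_dims_frame(morphologies: Dict[int, SampledMorphology]) -> pd.DataFrame:
    """Audit table of per-cell sampled dimensions (one row per template)."""
    rows = []
    for m in morphologies.values():
        for i, dims in enumerate(m.sampled_dims):
            row = {"cell_id": m.cell_id, "class": m.class_label,
                   "template": i, "role": m.shapes[i][1]}
            row.update(dims)
            rows.append(row)
    return pd.DataFrame(rows)
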