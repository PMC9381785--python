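"""Synthetic CA1-like region and neuronal placement.

The synthetic region is a curved slab: a circular-arc cross-section in the
x-z plane (emulating the transversal curvature of CA1) extruded along the
longitudinal y axis.  Four layer shells are stacked radially in the order
SO, SP, SR, SLM (SO innermost), and two triangulated landmark patches --
CA3 at the near transversal end, subiculum at the far end -- provide the
anatomical references the orientation frames are built from.

Cell classes and default counts follow the standard CA1 census: two
excitatory pyramidal-cell classes and eleven interneuron classes assigned
to their home layers, with an inhibitory/excitatory ratio of 10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .geometry import TriMesh

LAYERS = ("SO", "SP", "SR", "SLM")

#: default layer thicknesses (µm), stacked SO -> SLM
DEFAULT_THICKNESSES = {"SO": 150.0, "SP": 100.0, "SR": 300.0, "SLM": 150.0}

#: (class label, home layer, default full-scale count)
CLASS_TABLE = [
    ("deep-PC", "SO", 45408),
    ("superficial-PC", "SP", 216435),
    ("OLM", "SO", 660),
    ("Trilaminar", "SO", 660),
    ("BP", "SO", 659),
    ("CCKBC", "SP", 554),
    ("PVBC", "SP", 554),
    ("AA", "SP", 553),
    ("IVY", "SR", 5074),
    ("BS", "SR", 1691),
    ("SCA", "SR", 1691),
    ("PPA", "SR", 1691),
    ("NG", "SLM", 12397),
]

CLASS_LABELS = tuple(c[0] for c in CLASS_TABLE)
CLASS_LAYER = {c[0]: c[1] for c in CLASS_TABLE}
DEFAULT_COUNTS = {c[0]: c[2] for c in CLASS_TABLE}
EXCITATORY_CLASSES = ("deep-PC", "superficial-PC")
INHIBITORY_CLASSES = tuple(c for c in CLASS_LABELS if c not in EXCITATORY_CLASSES)


@dataclass(frozen=True)
class CellRecord:
    """A placed neuron: id, class, home layer and soma position (µm)."""

    id: int
    class_label: str
    layer: str
    soma: np.ndarray

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ConfigError(f"unknown cell class {self.class_label!r}")
        if self.layer not in LAYERS:
            raise ConfigError(f"unknown layer {self.layer!r}")
        object.__setattr__(self, "soma", np.asarray(self.soma, dtype=float).reshape(3))


@dataclass
class RegionGeometry:
    """Curved layered slab with terminal landmark meshes.

    ``arc_length`` is the transversal extent measured along the arc at the
    inner (SO) surface; ``curvature`` is the reciprocal bend radius in 1/µm
    (0 gives a flat slab); ``long_extent`` is the longitudinal (y) extent.
    """

    arc_length: float = 2000.0
    long_extent: float = 4000.0
    curvature: float = 1.0 / 1000.0
    layer_thicknesses: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THICKNESSES))
    landmark_gap: float = 100.0
    ca3_mesh: Optional[TriMesh] = None
    sub_mesh: Optional[TriMesh] = None

    def __post_init__(self):
        if self.arc_length <= 0 or self.long_extent <= 0:
            raise ConfigError("region extents must be positive")
        if self.curvature < 0:
            raise ConfigError("curvature must be >= 0")
        for layer in LAYERS:
            if self.layer_thicknesses.get(layer, 0) <= 0:
                raise ConfigError(f"layer {layer} needs a positive thickness")

    # -- layer bookkeeping -------------------------------------------------

    @property
    def total_depth(self) -> float:
        return sum(self.layer_thicknesses[l] for l in LAYERS)

    @property
    def layer_bounds(self) -> Dict[str, tuple]:
        """Depth interval (from the SO top) occupied by each layer."""
        bounds, d = {}, 0.0
        for layer in LAYERS:
            t = self.layer_thicknesses[layer]
            bounds[layer] = (d, d + t)
            d += t
        return bounds

    def layer_mid_depth(self, layer: str) -> float:
        lo, hi = self.layer_bounds[layer]
        return 0.5 * (lo + hi)

    # -- coordinate maps ---------------------------------------------------

    @property
    def bend_radius(self) -> float:
        return math.inf if self.curvature == 0 else 1.0 / self.curvature

    def to_world(self, s, y, d) -> np.ndarray:
        """Map region coordinates (arc s, longitudinal y, depth d) to x,y,z."""
        s = np.asarray(s, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.asarray(d, dtype=float)
        if self.curvature == 0:
            return np.stack(np.broadcast_arrays(s - self.arc_length / 2.0, y, -d),
                            axis=-1)
        R0 = self.bend_radius
        half = self.arc_length / (2.0 * R0)
        alpha = s / R0 - half
        r = R0 + d
        return np.stack(np.broadcast_arrays(r * np.sin(alpha), y, -r * np.cos(alpha)),
                        axis=-1)

    def from_world(self, points) -> tuple:
        """Inverse of :meth:`to_world`; returns (s, y, d) arrays."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.curvature == 0:
            return pts[:, 0] + self.arc_length / 2.0, pts[:, 1], -pts[:, 2]
        R0 = self.bend_radius
        half = self.arc_length / (2.0 * R0)
        r = np.hypot(pts[:, 0], pts[:, 2])
        alpha = np.arctan2(pts[:, 0], -pts[:, 2])
        return (alpha + half) * R0, pts[:, 1], r - R0

    def vertical_direction(self, points) -> np.ndarray:
        """Unit vector(s) of increasing depth (SO toward SLM)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.curvature == 0:
            out = np.tile([0.0, 0.0, -1.0], (len(pts), 1))
        else:
            radial = pts.copy()
            radial[:, 1] = 0.0
            norm = np.linalg.norm(radial, axis=1, keepdims=True)
            out = radial / norm
        return out

    def transversal_direction(self, points) -> np.ndarray:
        """Unit tangent(s) of increasing arc coordinate (toward subiculum)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.curvature == 0:
            return np.tile([1.0, 0.0, 0.0], (len(pts), 1))
        s, _, _ = self.from_world(pts)
        half = self.arc_length / (2.0 * self.bend_radius)
        alpha = s / self.bend_radius - half
        return np.stack([np.cos(alpha), np.zeros_like(alpha), np.sin(alpha)], axis=-1)

    def point_in_layer(self, points, layer: str, tol: float = 1e-9) -> np.ndarray:
        s, y, d = self.from_world(points)
        lo, hi = self.layer_bounds[layer]
        return ((s >= -tol) & (s <= self.arc_length + tol)
                & (y >= -tol) & (y <= self.long_extent + tol)
                & (d >= lo - tol) & (d <= hi + tol))

    def subiculum_distance(self, points) -> np.ndarray:
        """Arc distance from each point to the subiculum-end cross-section."""
        s, _, _ = self.from_world(points)
        return np.maximum(0.0, self.arc_length - s) + self.landmark_gap


def _end_patch(region: RegionGeometry, end: str, n_grid: int = 5) -> TriMesh:
    """Flat triangulated rectangle closing one transversal end of the slab."""
    pad = 150.0
    d_lo, d_hi = -pad, region.total_depth + pad
    y_lo, y_hi = -pad, region.long_extent + pad
    ys = np.linspace(y_lo, y_hi, n_grid)
    ds = np.linspace(d_lo, d_hi, n_grid)
    if region.curvature == 0:
        x = (-region.arc_length / 2.0 - region.landmark_gap if end == "ca3"
             else region.arc_length / 2.0 + region.landmark_gap)
        verts = np.array([[x, y, -d] for d in ds for y in ys])
    else:
        R0 = region.bend_radius
        half = region.arc_length / (2.0 * R0)
        beta = (-half - region.landmark_gap / R0 if end == "ca3"
                else half + region.landmark_gap / R0)
        radial = np.array([math.sin(beta), 0.0, -math.cos(beta)])
        verts = np.array([(R0 + d) * radial + np.array([0.0, y, 0.0])
                          for d in ds for y in ys])
    faces = []
    for i in range(n_grid - 1):
        for j in range(n_grid - 1):
            a = i * n_grid + j
            b = a + 1
            c = a + n_grid
            e = c + 1
            faces += [[a, b, c], [b, e, c]]
    return TriMesh(verts, np.array(faces))


def generate_region(config: Optional[dict] = None, seed: int = 0) -> RegionGeometry:
    """Build the synthetic layered region with its two landmark meshes.

    Fully deterministic for a given configuration (the seed is accepted for
    interface symmetry with the other stages but the geometry is analytic).
    """
    config = dict(config or {})
    region = RegionGeometry(
        arc_length=float(config.get("arc_length", 2000.0)),
        long_extent=float(config.get("long_extent", 4000.0)),
        curvature=float(config.get("curvature", 1.0 / 1000.0)),
        layer_thicknesses=dict(config.get("layer_thicknesses", DEFAULT_THICKNESSES)),
        landmark_gap=float(config.get("landmark_gap", 100.0)),
    )
    region.ca3_mesh = _end_patch(region, "ca3")
    region.sub_mesh = _end_patch(region, "sub")
    return region


@dataclass
class PopulationSpec:
    """Per-class cell counts plus a global scale factor in (0, 1]."""

    counts: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    scale: float = 1.0

    def __post_init__(self):
        if not 0 < self.scale <= 1:
            raise ConfigError("scale must be in (0, 1]")
        unknown = set(self.counts) - set(CLASS_LABELS)
        if unknown:
            raise ConfigError(f"unknown classes in population spec: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ConfigError("class counts must be >= 0")

    def scaled_counts(self) -> Dict[str, int]:
        """Round-half-up scaling with a floor of 1 for non-empty classes."""
        out = {}
        for label in CLASS_LABELS:
            n = self.counts.get(label, 0)
            if n == 0:
                out[label] = 0
            else:
                out[label] = max(1, int(math.floor(self.scale * n + 0.5)))
        return out


def place_cells(region: RegionGeometry, pop: PopulationSpec,
                seed: int = 0) -> List[CellRecord]:
    """Place every class uniformly inside its home-layer shell.

    Uniformity in world volume is obtained by rejection on the radial
    Jacobian of the bent slab; counts per class are exact.
    """
    rng = np.random.default_rng(seed)
    counts = pop.scaled_counts()
    bounds = region.layer_bounds
    R0 = region.bend_radius
    cells: List[CellRecord] = []
    next_id = 0
    for label in CLASS_LABELS:
        n = counts[label]
        if n == 0:
            continue
        layer = CLASS_LAYER[label]
        d_lo, d_hi = bounds[layer]
        accepted = np.empty((0, 3))
        while len(accepted) < n:
            m = max(2 * (n - len(accepted)), 16)
            s = rng.uniform(0.0, region.arc_length, m)
            y = rng.uniform(0.0, region.long_extent, m)
            d = rng.uniform(d_lo, d_hi, m)
            if math.isfinite(R0):
                keep = rng.uniform(0.0, 1.0, m) <= (R0 + d) / (R0 + d_hi)
            else:
                keep = np.ones(m, dtype=bool)
            batch = np.stack([s[keep], y[keep], d[keep]], axis=-1)
            accepted = np.vstack([accepted, batch])
        accepted = accepted[:n]
        world = region.to_world(accepted[:, 0], accepted[:, 1], accepted[:, 2])
        for soma in world:
            cells.append(CellRecord(next_id, label, layer, soma))
            next_id += 1
    return cells


# ---------------------------------------------------------------------------
# node-table I/O
# ---------------------------------------------------------------------------

NODE_COLUMNS = ["id", "class", "layer", "x", "y", "z"]


def cells_to_frame(cells: List[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [c.id for c in cells],
        "class": [c.class_label for c in cells],
        "layer": [c.layer for c in cells],
        "x": [c.soma[0] for c in cells],
        "y": [c.soma[1] for c in cells],
        "z": [c.soma[2] for c in cells],
    })


def save_positions(cells: List[CellRecord], path) -> None:
    cells_to_frame(cells).to_csv(path, index=False, float_format="%.6f")


def load_positions(path) -> List[CellRecord]:
    """Read a node table CSV (id, class, layer, x, y, z) with validation."""
    df = pd.read_csv(path)
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"node table {path} missing columns {missing}")
    cells = []
    for idx, row in df.iterrows():
        label = str(row["class"])
        if label not in CLASS_LABELS:
            raise FormatError(f"row {idx}: unknown class {label!r}")
        layer = str(row["layer"])
        if layer not in LAYERS:
            raise FormatError(f"row {idx}: unknown layer {layer!r}")
        coords = [row["x"], row["y"], row["z"]]
        if any(pd.isna(v) or not np.isfinite(float(v)) for v in coords):
            raise FormatError(f"row {idx}: non-finite coordinates")
        cells.append(CellRecord(int(row["id"]), label, layer, np.asarray(coords, float)))
    return cells
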