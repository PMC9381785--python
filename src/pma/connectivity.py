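"""Broad-phase / narrow-phase intersection and calibrated pruning.

Connectivity is decided geometrically, in the spirit of Peters' rule: a
presynaptic cell is a candidate partner of a postsynaptic cell when at
least one of the post cell's dendritic cloud points falls inside one of
the pre cell's axonal convex hulls.  A cheap axis-aligned bounding-box
(AABB) overlap test filters the pairs first; candidate pairs are then
pruned by uniform sampling down to the count implied by the empirical
class-pair connection probability: ``round(n_pre * n_post * p)``.
"""

from __future__ import annotations

import logging
import math
import zlib
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .geometry import AABB
from .morphology import SampledMorphology
from .placement import CLASS_LABELS, CellRecord

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["pre_id", "post_id", "pre_class", "post_class", "distance_um"]


# ---------------------------------------------------------------------------
# probability tables
# ---------------------------------------------------------------------------

def default_class_pair_table() -> pd.DataFrame:
    """Bundled class-pair connection probabilities.

    The superficial-PC -> IVY probability (0.000933) is the published
    hippocampome-derived value; the remaining entries are editable
    plausibility placeholders in the same units (per ordered cell pair).
    """
    with resources.files("pma").joinpath("data/connection_probabilities.csv").open() as fh:
        return load_class_pair_table(fh)


def load_class_pair_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    missing = [c for c in ("pre_class", "post_class", "p") if c not in df.columns]
    if missing:
        raise FormatError(f"class-pair table missing columns {missing}")
    unknown = (set(df["pre_class"]) | set(df["post_class"])) - set(CLASS_LABELS)
    if unknown:
        raise FormatError(f"class-pair table has unknown classes: {sorted(unknown)}")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise FormatError("connection probabilities must lie in [0, 1]")
    if df.duplicated(["pre_class", "post_class"]).any():
        raise FormatError("duplicate class pairs in probability table")
    return df


# ---------------------------------------------------------------------------
# broad phase
# ---------------------------------------------------------------------------

def _boxes(morphs: Sequence[SampledMorphology], which: str):
    if which == "axon":
        boxes = [m.axon_aabb for m in morphs]
    else:
        boxes = [m.dendrite_aabb for m in morphs]
    lo = np.array([b.lo for b in boxes])
    hi = np.array([b.hi for b in boxes])
    return lo, hi


def broad_phase(pre_morphs: Sequence[SampledMorphology],
                post_morphs: Sequence[SampledMorphology],
                block: int = 512) -> np.ndarray:
    """All (pre, post) id pairs whose axonal/dendritic AABBs overlap.

    Equivalent to the all-pairs closed-interval scan; self pairs are
    excluded.  Returns an (n, 2) integer array of cell ids.
    """
    pre_morphs = list(pre_morphs)
    post_morphs = list(post_morphs)
    if not pre_morphs or not post_morphs:
        return np.empty((0, 2), dtype=int)
    pre_ids = np.array([m.cell_id for m in pre_morphs])
    post_ids = np.array([m.cell_id for m in post_morphs])
    a_lo, a_hi = _boxes(pre_morphs, "axon")
    d_lo, d_hi = _boxes(post_morphs, "dendrite")
    pairs = []
    for s in range(0, len(pre_morphs), block):
        e = min(s + block, len(pre_morphs))
        ok = (np.all(a_hi[s:e, None, :] >= d_lo[None, :, :], axis=2)
              & np.all(d_hi[None, :, :] >= a_lo[s:e, None, :], axis=2))
        ok &= pre_ids[s:e, None] != post_ids[None, :]
        idx = np.argwhere(ok)
        if len(idx):
            pairs.append(np.column_stack([pre_ids[s:e][idx[:, 0]],
                                          post_ids[idx[:, 1]]]))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.vstack(pairs)


# ---------------------------------------------------------------------------
# narrow phase
# ---------------------------------------------------------------------------

def narrow_phase(pre: SampledMorphology, post: SampledMorphology,
                 tol: float = 1e-9) -> bool:
    """True iff any dendritic point of ``post`` lies in any axonal hull of ``pre``."""
    return bool(_narrow_batch(pre, [post.dendrite_points], tol)[0])


def _in_box(points: np.ndarray, box: AABB, tol: float) -> np.ndarray:
    return (np.all(points >= box.lo - tol, axis=1)
            & np.all(points <= box.hi + tol, axis=1))


def _narrow_batch(pre: SampledMorphology,
                  point_sets: List[np.ndarray],
                  tol: float = 1e-9) -> np.ndarray:
    """Vectorised narrow phase of one pre cell against many post clouds."""
    lengths = np.array([len(p) for p in point_sets])
    pts = np.vstack(point_sets)
    inside = np.zeros(len(pts), dtype=bool)
    for hull, shape, box in zip(pre.axon_hulls, pre.axon_shapes, pre.axon_aabbs):
        cand = np.flatnonzero(~inside & _in_box(pts, box, tol))
        if len(cand):
            # the hull is inscribed in its generating shape, so the cheap
            # analytic containment test is a conservative prefilter
            near = shape.contains(pts[cand], tol=1e-6)
            cand = cand[near]
        if len(cand):
            inside[cand] = hull.contains(pts[cand], tol=tol)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    hits = np.add.reduceat(inside, offsets)
    return hits > 0


class _BinnedPoints:
    """Uniform-grid spatial index over the stacked dendritic points of a
    post-class, for fast per-presynaptic-cell point gathering.

    Using it inside :func:`build_connectome` yields exactly the candidate
    pairs of ``narrow_phase`` composed with ``broad_phase``: a dendritic
    point inside an axonal hull lies inside both cells' bounding boxes, so
    no pair the AABB filter would admit is ever missed.
    """

    def __init__(self, point_sets: List[np.ndarray], bin_size: float = 75.0):
        self.bin = float(bin_size)
        self.labels = np.repeat(np.arange(len(point_sets)),
                                [len(p) for p in point_sets])
        pts = np.vstack(point_sets)
        self.origin = pts.min(axis=0)
        cell_idx = np.floor((pts - self.origin) / self.bin).astype(np.int64)
        self.dims = cell_idx.max(axis=0) + 1
        keys = (cell_idx[:, 0] * self.dims[1] + cell_idx[:, 1]) * self.dims[2] \
            + cell_idx[:, 2]
        order = np.argsort(keys, kind="stable")
        self.points = pts[order]
        self.labels = self.labels[order]
        keys = keys[order]
        self.ukeys, starts = np.unique(keys, return_index=True)
        self.starts = np.append(starts, len(keys))

    def query_box(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Indices (into the reordered points) of all points whose grid
        cell intersects the box [lo, hi]."""
        lo_c = np.maximum(np.floor((lo - self.origin) / self.bin).astype(np.int64), 0)
        hi_c = np.minimum(np.floor((hi - self.origin) / self.bin).astype(np.int64),
                          self.dims - 1)
        if np.any(hi_c < lo_c):
            return np.empty(0, dtype=np.int64)
        gx, gy, gz = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo_c, hi_c)),
                                 indexing="ij")
        qkeys = ((gx.ravel() * self.dims[1] + gy.ravel()) * self.dims[2]
                 + gz.ravel())
        pos = np.searchsorted(self.ukeys, qkeys)
        ok = pos < len(self.ukeys)
        ok[ok] = self.ukeys[pos[ok]] == qkeys[ok]
        pos = pos[ok]
        if not len(pos):
            return np.empty(0, dtype=np.int64)
        starts = self.starts[pos]
        lengths = self.starts[pos + 1] - starts
        offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        return np.repeat(starts - offsets, lengths) + np.arange(lengths.sum())


def _candidates_for_pre(pre: SampledMorphology, index: _BinnedPoints,
                        tol: float = 1e-9) -> np.ndarray:
    """Post-set labels with at least one dendritic point in a pre hull."""
    box = pre.axon_aabb
    idx = index.query_box(box.lo - tol, box.hi + tol)
    if not len(idx):
        return np.empty(0, dtype=np.int64)
    pts = index.points[idx]
    inside = np.zeros(len(pts), dtype=bool)
    for hull, shape, cbox in zip(pre.axon_hulls, pre.axon_shapes, pre.axon_aabbs):
        cand = np.flatnonzero(~inside & _in_box(pts, cbox, tol))
        if len(cand):
            cand = cand[shape.contains(pts[cand], tol=1e-6)]
        if len(cand):
            inside[cand] = hull.contains(pts[cand], tol=tol)
    return np.unique(index.labels[idx[inside]])


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def target_count(n_pre: int, n_post: int, p: float) -> int:
    """Expected connection count: nearest integer of ``n_pre * n_post * p``."""
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"connection probability {p} outside [0, 1]")
    return int(math.floor(n_pre * n_post * p + 0.5))


def prune(pairs, target: int, seed=0) -> np.ndarray:
    """Uniform sample without replacement of ``min(target, n)`` pairs."""
    if target < 0:
        raise ConfigError("pruning target must be >= 0")
    pairs = np.asarray(pairs).reshape(-1, 2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pairs)
    if target >= n:
        if target > n:
            logger.warning(
                "pruning target %d exceeds %d geometric candidates; "
                "keeping all candidates (probability calibration short)", target, n)
        return pairs
    keep = np.sort(rng.choice(n, size=target, replace=False))
    return pairs[keep]


# ---------------------------------------------------------------------------
# full connectome
# ---------------------------------------------------------------------------

def _pair_rng(seed: int, pre_class: str, post_class: str) -> np.random.Generator:
    # stable per-(seed, class pair) stream, independent of table order
    ss = np.random.SeedSequence([int(seed),
                                 zlib.crc32(pre_class.encode()),
                                 zlib.crc32(post_class.encode())])
    return np.random.default_rng(ss)


def build_connectome(cells: List[CellRecord],
                     morphologies: Dict[int, SampledMorphology],
                     class_pair_table: Optional[pd.DataFrame] = None,
                     seed: int = 0) -> pd.DataFrame:
    """Geometric candidates, narrow-phase check and calibrated pruning.

    For every ordered class pair in the probability table the candidate
    pairs are the narrow-phase-true subset of the AABB-overlapping pairs;
    the retained edges are a uniform subsample of size
    ``min(round(n_pre * n_post * p), candidates)``.  Soma-to-soma
    Euclidean distances are attached to each edge.
    """
    if class_pair_table is None:
        class_pair_table = default_class_pair_table()
    absent = [c.id for c in cells if c.id not in morphologies]
    if absent:
        raise ConfigError(f"{len(absent)} cells lack instantiated morphologies")
    by_class: Dict[str, List[CellRecord]] = {}
    for c in cells:
        by_class.setdefault(c.class_label, []).append(c)
    for v in by_class.values():
        v.sort(key=lambda c: c.id)
    soma = {c.id: c.soma for c in cells}

    table = class_pair_table.sort_values(["pre_class", "post_class"])
    active = [(str(r["pre_class"]), str(r["post_class"]), float(r["p"]))
              for _, r in table.iterrows()
              if r["pre_class"] in by_class and r["post_class"] in by_class
              and float(r["p"]) > 0.0]
    # one shared point index over every post class that occurs in the table;
    # each pre cell is intersected once and its hits split by post class
    post_classes = sorted({pc for _, pc, _ in active})
    post_cells = [c for pc in post_classes for c in by_class[pc]]
    if not post_cells:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    index = _BinnedPoints([morphologies[c.id].dendrite_points for c in post_cells])
    post_ids = np.array([c.id for c in post_cells])
    post_cls = np.array([c.class_label for c in post_cells])
    hit_cache: Dict[int, np.ndarray] = {}

    def hits_for(pre_id: int) -> np.ndarray:
        if pre_id not in hit_cache:
            labels = _candidates_for_pre(morphologies[pre_id], index)
            hit_cache[pre_id] = labels[post_ids[labels] != pre_id]
        return hit_cache[pre_id]

    rows = []
    for pre_class, post_class, p in active:
        pres = by_class[pre_class]
        posts = by_class[post_class]
        confirmed = []
        for c in pres:
            labels = hits_for(c.id)
            hit_ids = post_ids[labels[post_cls[labels] == post_class]]
            if len(hit_ids):
                confirmed.append(np.column_stack(
                    [np.full(len(hit_ids), c.id), hit_ids]))
        cand = (np.vstack(confirmed) if confirmed else np.empty((0, 2), int))
        target = target_count(len(pres), len(posts), p)
        kept = prune(cand, target, seed=_pair_rng(seed, pre_class, post_class))
        for pre_id, post_id in kept:
            rows.append((int(pre_id), int(post_id), pre_class, post_class,
                         float(np.linalg.norm(soma[pre_id] - soma[post_id]))))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(["pre_class", "post_class", "pre_id", "post_id"],
                             ignore_index=True)


def save_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, index=False, float_format="%.6f")


def load_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"edge table missing columns {missing}")
    return df


def export_hdf5(cells: List[CellRecord], edges: pd.DataFrame, path) -> None:
    """Minimal circuit container with /nodes and /edges groups."""
    import h5py

    from .placement import cells_to_frame
    nodes = cells_to_frame(cells)
    with h5py.File(path, "w") as fh:
        g = fh.create_group("nodes")
        g.create_dataset("id", data=nodes["id"].to_numpy())
        g.create_dataset("class", data=nodes["class"].astype("S"))
        g.create_dataset("layer", data=nodes["layer"].astype("S"))
        g.create_dataset("position_um", data=nodes[["x", "y", "z"]].to_numpy())
        e = fh.create_group("edges")
        e.create_dataset("pre_id", data=edges["pre_id"].to_numpy())
        e.create_dataset("post_id", data=edges["post_id"].to_numpy())
        e.create_dataset("pre_class", data=edges["pre_class"].astype("S"))
        e.create_dataset("post_class", data=edges["post_class"].astype("S"))
        e.create_dataset("distance_um", data=edges["distance_um"].to_numpy())
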