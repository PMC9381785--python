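"""Minimal point-neuron dynamics for construction validation.

The goal of this module is not physiological prediction but a qualitative
check of the generated wiring: a transversal slice is extracted, a small
spherical group of pyramidal cells is stimulated, and the resulting
activity should invade the network in the CA3 -> subiculum direction much
more readily than in the reverse direction.

Neurons are current-based leaky integrate-and-fire units with an adaptive
threshold; synapses carry Tsodyks-Markram short-term plasticity (resource
fraction x, utilization u) with distance-dependent conduction delays.
All dynamics are deterministic for a given circuit; the seed only feeds
the optional initial membrane-potential jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .placement import EXCITATORY_CLASSES, CellRecord

DEFAULT_PARAMS = {
    # membrane
    "tau_m_ms": 20.0,          # membrane time constant
    "v_rest_mv": -65.0,
    "v_reset_mv": -65.0,
    "v_thresh_mv": -50.0,
    "t_ref_ms": 3.0,
    # adaptive threshold
    "theta_plus_mv": 5.0,      # increment per spike
    "tau_theta_ms": 50.0,
    # synapses
    # synaptic drive amplitude: with tau_m 20 ms / tau_syn 3 ms the peak
    # depolarization is ~0.105x the amplitude, so 200 -> ~21 mV EPSP,
    # suprathreshold by default (threshold gap is 15 mV): one input can
    # fire a resting cell.
    "tau_syn_ms": 3.0,
    "weight_exc_mv": 200.0,
    "weight_inh_mv": -200.0,
    "delay_base_ms": 1.0,
    "conduction_velocity_um_per_ms": 500.0,
    # short-term plasticity (depressing defaults)
    "stp_U": 0.5,
    "tau_rec_ms": 800.0,
    "tau_fac_ms": 0.0,
    # stimulation / init
    "stim_amplitude_mv": 500.0,
    "v_init_jitter_mv": 0.0,
}


@dataclass(frozen=True)
class StimulusSpec:
    """Spherical current stimulus (center µm, radius µm, onset ms)."""

    center: np.ndarray
    radius: float = 100.0
    onset_ms: float = 1.0
    amplitude: Optional[float] = None   # None -> params["stim_amplitude_mv"]

    def __post_init__(self):
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        if self.radius <= 0:
            raise ConfigError("stimulus radius must be > 0")


@dataclass
class SimResult:
    """Spike raster plus bookkeeping of the stimulated population."""

    raster: pd.DataFrame          # columns cell_id, t_ms, sorted by time
    stimulated_ids: np.ndarray
    duration_ms: float


def extract_slice(cells: List[CellRecord], edges: pd.DataFrame,
                  axis: int = 1, thickness: float = 500.0,
                  center: Optional[float] = None,
                  excitatory_only: bool = False
                  ) -> Tuple[List[CellRecord], pd.DataFrame]:
    """Slab cut: keep cells inside the slab and edges with both ends inside.

    ``axis`` is the world coordinate the slab is cut along (1 = y, the
    longitudinal axis, gives a transversal slice).  Cells exactly on the
    slab boundary are retained (closed interval).
    """
    import warnings

    if thickness <= 0:
        raise ConfigError("slice thickness must be > 0")
    coords = np.array([c.soma[axis] for c in cells])
    if center is None:
        center = 0.5 * (coords.min() + coords.max()) if len(coords) else 0.0
    lo, hi = center - thickness / 2.0, center + thickness / 2.0
    kept = [c for c, x in zip(cells, coords) if lo <= x <= hi]
    if excitatory_only:
        kept = [c for c in kept if c.class_label in EXCITATORY_CLASSES]
    ids = {c.id for c in kept}
    if not ids:
        warnings.warn("slice is empty", stacklevel=2)
        return [], edges.iloc[0:0]
    kept_edges = edges[edges["pre_id"].isin(ids) & edges["post_id"].isin(ids)]
    return kept, kept_edges.reset_index(drop=True)


def _tm_update(x, u, dt_since, U, tau_rec, tau_fac):
    """Tsodyks-Markram state update at a presynaptic spike.

    Between spikes x recovers toward 1 and u decays toward 0; at the spike
    u is facilitated by U(1-u) and the released fraction u*x is subtracted
    from x.  Returns (new_x, new_u, release).
    """
    x = 1.0 - (1.0 - x) * np.exp(-dt_since / tau_rec)
    if tau_fac > 0:
        u = u * np.exp(-dt_since / tau_fac)
    else:
        u = np.zeros_like(u)
    u = u + U * (1.0 - u)
    release = u * x
    x = x - release
    return x, u, release


def run(cells: List[CellRecord], edges: pd.DataFrame, stim: StimulusSpec,
        params: Optional[dict] = None, duration_ms: float = 40.0,
        dt_ms: float = 0.1, seed: int = 0) -> SimResult:
    """Simulate the circuit and return the spike raster.

    The stimulated set is every cell within the stimulus sphere; at onset
    each receives a current step that drives it over threshold.  Events
    are processed on a fixed time grid; simultaneous spikes are handled in
    ascending cell-id order.
    """
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    for key, val in p.items():
        if isinstance(val, (int, float)) and not math.isfinite(float(val)):
            raise ConfigError(f"non-finite parameter {key}")
    if dt_ms <= 0:
        raise ConfigError("dt must be > 0")

    n = len(cells)
    ids = np.array([c.id for c in cells])
    id_to_idx = {cid: k for k, cid in enumerate(ids)}
    pos = np.array([c.soma for c in cells]) if n else np.empty((0, 3))
    exc = np.array([c.class_label in EXCITATORY_CLASSES for c in cells])

    # --- synapse arrays ----------------------------------------------------
    pre = np.array([id_to_idx[i] for i in edges["pre_id"]], dtype=int)
    post = np.array([id_to_idx[i] for i in edges["post_id"]], dtype=int)
    dist = np.linalg.norm(pos[pre] - pos[post], axis=1) if len(pre) else np.empty(0)
    delay_ms = p["delay_base_ms"] + dist / p["conduction_velocity_um_per_ms"]
    delay_steps = np.maximum(1, np.round(delay_ms / dt_ms).astype(int))
    if len(delay_steps) and delay_ms.min() < dt_ms:
        raise ConfigError("synaptic delays must be >= dt")
    weight = np.where(exc[pre], p["weight_exc_mv"], p["weight_inh_mv"])
    x_syn = np.ones(len(pre))
    u_syn = np.zeros(len(pre))
    last_pre_spike = np.full(len(pre), -1e9)
    # CSR-style grouping of synapses by presynaptic cell
    order = np.argsort(pre, kind="stable")
    syn_sorted = order
    syn_starts = np.searchsorted(pre[order], np.arange(n + 1))

    # --- neuron state ------------------------------------------------------
    rng = np.random.default_rng(seed)
    v = np.full(n, p["v_rest_mv"])
    if p["v_init_jitter_mv"] > 0:
        v += rng.uniform(-p["v_init_jitter_mv"], p["v_init_jitter_mv"], n)
    theta = np.zeros(n)
    refrac = np.zeros(n, dtype=int)
    i_syn = np.zeros(n)

    n_steps = int(round(duration_ms / dt_ms))
    max_delay = int(delay_steps.max()) if len(delay_steps) else 1
    ring = np.zeros((max_delay + 1, n))
    decay_m = math.exp(-dt_ms / p["tau_m_ms"])
    decay_syn = math.exp(-dt_ms / p["tau_syn_ms"])
    decay_theta = math.exp(-dt_ms / p["tau_theta_ms"])
    ref_steps = max(1, int(round(p["t_ref_ms"] / dt_ms)))

    stim_mask = np.linalg.norm(pos - stim.center, axis=1) <= stim.radius if n else np.zeros(0, bool)
    stim_idx = np.flatnonzero(stim_mask)
    stim_step = int(round(stim.onset_ms / dt_ms))
    stim_amp = p["stim_amplitude_mv"] if stim.amplitude is None else stim.amplitude

    spikes_t: List[float] = []
    spikes_id: List[int] = []
    U, tau_rec, tau_fac = p["stp_U"], p["tau_rec_ms"], p["tau_fac_ms"]

    for step in range(n_steps):
        t = step * dt_ms
        slot = step % (max_delay + 1)
        i_syn = i_syn * decay_syn + ring[slot]
        ring[slot] = 0.0
        if step == stim_step:
            i_syn[stim_idx] += stim_amp
        v = p["v_rest_mv"] + (v - p["v_rest_mv"]) * decay_m + (1 - decay_m) * i_syn
        theta *= decay_theta
        refrac = np.maximum(refrac - 1, 0)
        fired = np.flatnonzero((v >= p["v_thresh_mv"] + theta) & (refrac == 0))
        if len(fired):
            fired = np.sort(fired)   # ties in cell-id order
            for k in fired:
                spikes_t.append(t)
                spikes_id.append(int(ids[k]))
            v[fired] = p["v_reset_mv"]
            theta[fired] += p["theta_plus_mv"]
            refrac[fired] = ref_steps
            for k in fired:
                s0, s1 = syn_starts[k], syn_starts[k + 1]
                if s0 == s1:
                    continue
                syn = syn_sorted[s0:s1]
                dt_since = t - last_pre_spike[syn]
                x_syn[syn], u_syn[syn], rel = _tm_update(
                    x_syn[syn], u_syn[syn], dt_since, U, tau_rec, tau_fac)
                last_pre_spike[syn] = t
                amp = weight[syn] * rel / U
                tgt_slot = (step + delay_steps[syn]) % (max_delay + 1)
                np.add.at(ring, (tgt_slot, post[syn]), amp)

    raster = pd.DataFrame({"cell_id": spikes_id, "t_ms": spikes_t})
    raster = raster.sort_values(["t_ms", "cell_id"], ignore_index=True)
    return SimResult(raster, ids[stim_idx], duration_ms)


def propagation_index(result: SimResult, cells: List[CellRecord],
                      excitatory_only: bool = True) -> float:
    """Fraction of non-stimulated (excitatory) cells that fired at least once."""
    stim = set(result.stimulated_ids.tolist())
    pool = [c.id for c in cells
            if c.id not in stim
            and (not excitatory_only or c.class_label in EXCITATORY_CLASSES)]
    if not pool:
        return 0.0
    fired = set(result.raster["cell_id"].tolist())
    return sum(1 for i in pool if i in fired) / len(pool)


def save_raster(result: SimResult, path) -> None:
    result.raster.to_csv(path, index=False, float_format="%.3f")
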