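"""Construction-validity diagnostics.

In/out-degree distributions (as probability densities over all cells,
including the unconnected ones), soma-to-soma connection-length
histograms, hub identification, and a diagnostic fit of the degree
density by a discrete convolution of a power law with an exponential
kernel — the shape family reported for cortical and hippocampal
connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import IntegrityError
from .placement import EXCITATORY_CLASSES, CellRecord


@dataclass
class DegreeDistribution:
    """Per-cell degrees plus the derived probability density."""

    cell_ids: np.ndarray
    degrees: np.ndarray
    population: str = "all"   # "all" | "excitatory"

    @property
    def values(self) -> np.ndarray:
        """Distinct degree values, ascending."""
        return np.unique(self.degrees)

    @property
    def counts(self) -> np.ndarray:
        values, counts = np.unique(self.degrees, return_counts=True)
        return counts

    @property
    def density(self) -> np.ndarray:
        c = self.counts
        return c / c.sum()

    @property
    def peak(self) -> int:
        """Degree value of maximal density (smallest on ties)."""
        return int(self.values[np.argmax(self.density)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.values, "count": self.counts,
                             "density": self.density})


def _filter_population(edges: pd.DataFrame, cells: List[CellRecord],
                       population: str):
    ids = np.array([c.id for c in cells])
    if population == "excitatory":
        keep = np.array([c.class_label in EXCITATORY_CLASSES for c in cells])
        ids = ids[keep]
        idset = set(ids.tolist())
        edges = edges[edges["pre_id"].isin(idset) & edges["post_id"].isin(idset)]
    elif population != "all":
        raise ValueError(f"unknown population filter {population!r}")
    return edges, ids


def degree_distributions(edges: pd.DataFrame, cells: List[CellRecord],
                         population: str = "all"
                         ) -> Tuple[DegreeDistribution, DegreeDistribution]:
    """Exact per-cell in-/out-degree tallies (zero-degree cells included)."""
    all_ids = {c.id for c in cells}
    bad = set(edges["pre_id"]).union(edges["post_id"]) - all_ids
    if bad:
        raise IntegrityError(f"edges reference unknown cell ids: {sorted(bad)[:5]}")
    edges, ids = _filter_population(edges, cells, population)
    index = pd.Index(ids)
    in_deg = edges["post_id"].value_counts().reindex(index, fill_value=0).to_numpy()
    out_deg = edges["pre_id"].value_counts().reindex(index, fill_value=0).to_numpy()
    return (DegreeDistribution(ids, in_deg, population),
            DegreeDistribution(ids, out_deg, population))


def length_distribution(edges: pd.DataFrame, cells: List[CellRecord],
                        bin_width: float = 50.0):
    """Histogram of Euclidean soma-to-soma connection lengths.

    Returns ``(counts, bin_edges)``; the counts sum to the edge count.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    soma = {c.id: c.soma for c in cells}
    if len(edges) == 0:
        return np.array([0]), np.array([0.0, bin_width])
    pre = np.array([soma[i] for i in edges["pre_id"]])
    post = np.array([soma[i] for i in edges["post_id"]])
    d = np.linalg.norm(pre - post, axis=1)
    top = max(bin_width, float(d.max()))
    n_bins = int(np.ceil(top / bin_width)) or 1
    edges_ = np.arange(n_bins + 1) * bin_width
    if edges_[-1] < top:
        edges_ = np.append(edges_, edges_[-1] + bin_width)
    counts, bin_edges = np.histogram(d, bins=edges_)
    return counts, bin_edges


# ---------------------------------------------------------------------------
# power-law x exponential shape diagnostic
# ---------------------------------------------------------------------------

@dataclass
class DegreeShapeFit:
    alpha: float
    beta: float
    rss: float
    success: bool


def _model_pmf(alpha: float, beta: float, kmax: int) -> np.ndarray:
    """Discrete convolution of k^-alpha (k >= 1) with exp(-j / beta), j >= 0."""
    k = np.arange(1, kmax + 1, dtype=float)
    power = k ** (-alpha)
    j = np.arange(0, kmax + 1, dtype=float)
    kernel = np.exp(-j / max(beta, 1e-9))
    full = np.convolve(power, kernel)[:kmax]   # support k = 1 .. kmax
    pmf = np.zeros(kmax + 1)
    pmf[1:] = full
    total = pmf.sum()
    return pmf / total if total > 0 else pmf


def fit_degree_shape(dist: DegreeDistribution) -> DegreeShapeFit:
    """Least-squares fit of the degree density by the convolution model.

    Grid search over (alpha, beta) followed by Nelder-Mead refinement.
    Returns a failure signal (``success=False``) instead of raising when
    the distribution has fewer than 5 occupied degree values.
    """
    values = dist.values
    if np.count_nonzero(dist.counts) < 5 or values.max() < 2:
        return DegreeShapeFit(np.nan, np.nan, np.nan, success=False)
    kmax = int(values.max())
    emp = np.zeros(kmax + 1)
    emp[values] = dist.density

    def rss(params):
        a, log_b = params
        if not (0.0 < a < 10.0):
            return np.inf
        model = _model_pmf(a, float(np.exp(log_b)), kmax)
        return float(((model - emp) ** 2).sum())

    best, best_val = None, np.inf
    for a in np.linspace(0.3, 3.5, 12):
        for b in np.geomspace(0.5, max(2.0, kmax), 12):
            v = rss((a, np.log(b)))
            if v < best_val:
                best, best_val = (a, np.log(b)), v
    res = optimize.minimize(rss, best, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000})
    a, log_b = res.x
    return DegreeShapeFit(float(a), float(np.exp(log_b)), float(res.fun), success=True)


def hubs(dist_in: DegreeDistribution, dist_out: DegreeDistribution,
         percentile: float = 95.0) -> set:
    """Cells whose total degree reaches the given percentile (ties included)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if not np.array_equal(dist_in.cell_ids, dist_out.cell_ids):
        raise IntegrityError("in/out distributions cover different cells")
    total = dist_in.degrees + dist_out.degrees
    # "lower" keeps the threshold at an attained degree value, so a
    # percentile just above zero selects every cell
    threshold = np.percentile(total, percentile, method="lower")
    return set(dist_in.cell_ids[total >= threshold].tolist())


def export_distribution(dist: DegreeDistribution, path) -> None:
    dist.to_frame().to_csv(path, index=False, float_format="%.9f")


def plot_distributions(dists: Iterable[Tuple[str, DegreeDistribution]], path,
                       title: str = "degree distribution") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, dist in dists:
        ax.plot(dist.values, dist.density, marker="o", ms=3, lw=1, label=label)
    ax.set_xlabel("degree")
    ax.set_ylabel("probability density")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
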