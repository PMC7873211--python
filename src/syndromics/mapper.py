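"""Mapper topological data analysis over subjects, with bootstrap consensus.

Canonical Mapper: project standardized outcomes through a low-dimensional
lens, cover the lens range with overlapping bins, single-linkage cluster
each bin's preimage (first-gap histogram heuristic for the cut), and link
clusters that share subjects.  Stability is assessed by resampling
subjects with replacement and recording how often pairs of subjects land
in a common node; consensus edges are those supported by the resampling
co-occurrence.

Node overlays color the graph by any outcome (node mean) or by group
membership (percent of node members in the group, 0-100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import OutcomeMatrix

logger = logging.getLogger(__name__)


@dataclass
class MapperConfig:
    metric: str = "euclidean"  # or "correlation"
    lens_spec: str | tuple = "pca2"  # "pca1", "pca2", or tuple of column names
    resolution: int = 10
    gain: float = 0.4
    cluster_histogram_bins: int = 10
    n_bootstrap: int = 50
    consensus_threshold: float = 0.5
    resample: bool = True  # False: replicates reuse the full cohort
    seed: int = 0

    def validate(self):
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if not (0.0 <= self.gain < 1.0):
            raise ValueError("gain must be in [0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.metric not in ("euclidean", "correlation"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class MapperGraph:
    """Nerve graph of the Mapper cover.

    nodes: list of dicts with keys ``id``, ``members`` (subject ids),
    ``bin`` (lens-bin index tuple).  edges: list of dicts with keys
    ``source``, ``target``, ``shared`` (shared-member count).
    overlays: variable name -> {node id: value}.
    """

    nodes: list
    edges: list
    overlays: dict = field(default_factory=dict)

    @property
    def node_ids(self):
        return [n["id"] for n in self.nodes]

    def members(self, node_id):
        for n in self.nodes:
            if n["id"] == node_id:
                return n["members"]
        raise KeyError(node_id)

    def n_components(self) -> int:
        import networkx as nx

        return nx.number_connected_components(self.to_networkx())

    def cycle_rank(self) -> int:
        """Edges - nodes + components (first Betti number of the graph)."""
        return len(self.edges) - len(self.nodes) + self.n_components()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n["id"], size=len(n["members"]))
        for e in self.edges:
            g.add_edge(e["source"], e["target"], shared=e["shared"])
        return g


def standardize_outcomes(outcomes: OutcomeMatrix) -> pd.DataFrame:
    """Column-standardize the outcome block, mean-imputing missing cells.

    Each retained column is centered and scaled to unit sample (n-1)
    standard deviation over its non-missing entries; missing entries are
    then imputed with the column mean, i.e. 0 after standardization.
    Constant (or all-missing) columns carry no metric information and
    are dropped with a warning.
    """
    df = outcomes.outcomes
    if df.shape[0] < 2:
        raise ValueError("need >= 2 subjects to standardize")
    kept = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size < 2 or np.nanstd(obs, ddof=1) == 0.0:
            logger.warning("dropping constant or empty outcome column %r", col)
            continue
        z = (x - obs.mean()) / obs.std(ddof=1)
        z[np.isnan(z)] = 0.0
        kept[col] = z
    if not kept:
        raise ValueError("all outcome columns constant or empty")
    return pd.DataFrame(kept, index=df.index)


def compute_lens(z: pd.DataFrame, lens_spec="pca2") -> np.ndarray:
    """Project standardized outcomes to 1-2 lens coordinates.

    ``"pca1"``/``"pca2"`` project onto the leading eigenvectors of the
    covariance of the standardized matrix (its correlation matrix up to
    the imputation); a tuple of column names passes those columns
    through unchanged.
    """
    if isinstance(lens_spec, str) and lens_spec in ("pca1", "pca2"):
        d = 1 if lens_spec == "pca1" else 2
        X = z.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        cov = (Xc.T @ Xc) / max(1, X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        vecs = evecs[:, order[:d]]
        # deterministic orientation: largest-|loading| entry positive
        for j in range(vecs.shape[1]):
            k = np.argmax(np.abs(vecs[:, j]))
            if vecs[k, j] < 0:
                vecs[:, j] = -vecs[:, j]
        return Xc @ vecs
    cols = (lens_spec,) if isinstance(lens_spec, str) else tuple(lens_spec)
    if len(cols) not in (1, 2):
        raise ValueError("lens must be 1- or 2-dimensional")
    missing = [c for c in cols if c not in z.columns]
    if missing:
        raise KeyError(f"lens columns not found: {missing}")
    return z[list(cols)].to_numpy(dtype=float)


def build_cover(lens: np.ndarray, resolution: int, gain: float) -> list:
    """Overlapping axis-aligned bins over the lens range.

    Per axis the observed range is split into ``resolution`` equal base
    intervals of width w, each expanded symmetrically to width
    w * (1 + gain); d-dimensional bins are the Cartesian products.
    Returns a list of (bin index tuple, list of (lo, hi) per axis).
    """
    lens = np.atleast_2d(np.asarray(lens, dtype=float))
    if lens.ndim == 2 and lens.shape[0] == 1 and lens.shape[1] > 2:
        lens = lens.T
    if not np.isfinite(lens).all():
        raise ValueError("non-finite lens values")
    d = lens.shape[1]
    axis_intervals = []
    for ax in range(d):
        lo, hi = lens[:, ax].min(), lens[:, ax].max()
        if hi == lo:
            if resolution > 1:
                raise ValueError(f"zero range on lens axis {ax} with resolution > 1")
            axis_intervals.append([(lo - 0.5, hi + 0.5)])
            continue
        w = (hi - lo) / resolution
        pad = gain * w / 2.0
        axis_intervals.append(
            [(lo + i * w - pad, lo + (i + 1) * w + pad) for i in range(resolution)]
        )
    bins = [((), ())]
    for ax_iv in axis_intervals:
        bins = [
            (idx + (i,), iv + (interval,))
            for idx, iv in bins
            for i, interval in enumerate(ax_iv)
        ]
    return [(idx, list(iv)) for idx, iv in bins]


def _bin_members(lens: np.ndarray, bin_intervals) -> np.ndarray:
    """Indices of lens points falling in the (closed) bin box."""
    lens = np.asarray(lens, dtype=float)
    mask = np.ones(lens.shape[0], dtype=bool)
    for ax, (lo, hi) in enumerate(bin_intervals):
        mask &= (lens[:, ax] >= lo) & (lens[:, ax] <= hi)
    return np.where(mask)[0]


def first_gap_threshold(distances: np.ndarray, n_bins: int) -> float | None:
    """Lower edge of the first empty bin of the distance histogram.

    Standard Mapper heuristic for choosing the single-linkage cut: the
    first gap in the pairwise-distance distribution separates within-
    cluster from between-cluster distances. Returns None when the
    histogram has no empty bin (one cluster).
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        return None
    counts, edges = np.histogram(distances, bins=n_bins)
    empty = np.where(counts == 0)[0]
    if empty.size == 0:
        return None
    return float(edges[empty[0]])


def cluster_bin(submatrix: np.ndarray, metric: str = "euclidean",
                cluster_histogram_bins: int = 10) -> np.ndarray:
    """Partition one bin's members by single linkage with a first-gap cut.

    Returns integer cluster labels (0-based, ordered by first member).
    """
    X = np.atleast_2d(np.asarray(submatrix, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty bin")
    if n <= 2:
        # a single pairwise distance carries no gap evidence
        return np.zeros(n, dtype=int)
    dvec = pdist(X, metric=metric)
    thr = first_gap_threshold(dvec, cluster_histogram_bins)
    if thr is None:
        return np.zeros(n, dtype=int)
    Z = linkage(dvec, method="single")
    # merge strictly below the gap's lower edge
    labels = fcluster(Z, t=np.nextafter(thr, -np.inf), criterion="distance")
    relabel, out = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = relabel.setdefault(lab, len(relabel))
    return out


def build_mapper_graph(outcomes: OutcomeMatrix, config: MapperConfig) -> MapperGraph:
    """Cover -> within-bin clustering -> nerve graph."""
    config.validate()
    z = standardize_outcomes(outcomes)
    return _mapper_from_standardized(z, config)


def _mapper_from_standardized(z: pd.DataFrame, config: MapperConfig) -> MapperGraph:
    lens = compute_lens(z, config.lens_spec)
    cover = build_cover(lens, config.resolution, config.gain)
    X = z.to_numpy(dtype=float)
    ids = np.asarray(z.index, dtype=object)
    nodes, node_sets = [], []
    for bin_idx, intervals in cover:
        members = _bin_members(lens, intervals)
        if members.size == 0:
            continue
        labels = cluster_bin(X[members], config.metric, config.cluster_histogram_bins)
        for c in range(labels.max() + 1):
            sel = members[labels == c]
            nodes.append(
                {
                    "id": f"b{'_'.join(map(str, bin_idx))}.c{c}",
                    "members": [str(s) for s in ids[sel]],
                    "bin": bin_idx,
                }
            )
            node_sets.append(set(sel))
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            shared = node_sets[i] & node_sets[j]
            if shared:
                edges.append(
                    {
                        "source": nodes[i]["id"],
                        "target": nodes[j]["id"],
                        "shared": len(shared),
                    }
                )
    return MapperGraph(nodes=nodes, edges=edges)


def overlay(graph: MapperGraph, outcomes: OutcomeMatrix, variable: str,
            group_column: str | None = None) -> dict:
    """Per-node overlay values; stored on the graph and returned.

    Numeric outcome or metadata variable -> node mean over members
    (missing excluded).  When ``group_column`` is given, ``variable``
    names a level of that metadata column and the overlay is the percent
    of node members in that group (0-100).
    """
    values = {}
    if group_column is not None:
        col = outcomes.metadata[group_column]
        for n in graph.nodes:
            memb = col.loc[n["members"]]
            values[n["id"]] = 100.0 * float((memb == variable).mean())
        graph.overlays[f"{group_column}={variable}"] = values
        return values
    if variable in outcomes.outcomes.columns:
        col = outcomes.outcomes[variable]
    elif variable in outcomes.metadata.columns:
        col = pd.to_numeric(outcomes.metadata[variable])
    else:
        raise KeyError(f"unknown overlay variable {variable!r}")
    for n in graph.nodes:
        memb = col.loc[n["members"]].astype(float)
        values[n["id"]] = float(memb.mean(skipna=True))
    graph.overlays[variable] = values
    return values


def bootstrap_consensus(outcomes: OutcomeMatrix, config: MapperConfig):
    """Resampling-consensus Mapper.

    Subjects are resampled with replacement ``n_bootstrap`` times; each
    replicate's Mapper graph contributes to a subject co-occurrence
    matrix: the fraction of replicates, among those drawing both
    subjects, in which the pair shared at least one node.  The consensus
    graph is the full-data Mapper graph with each edge kept only if the
    mean co-occurrence over its cross-node member pairs reaches
    ``consensus_threshold``.  Pairs never jointly resampled have NaN
    co-occurrence.

    Returns (co-occurrence DataFrame, consensus MapperGraph, full
    MapperGraph).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    z = standardize_outcomes(outcomes)
    ids = list(z.index)
    n = len(ids)
    pos = {s: i for i, s in enumerate(ids)}
    together = np.zeros((n, n))
    joint = np.zeros((n, n))
    for _ in range(config.n_bootstrap):
        if config.resample:
            draw = rng.integers(0, n, size=n)
            uniq = np.unique(draw)
        else:
            uniq = np.arange(n)
        zb = z.iloc[uniq]
        try:
            g = _mapper_from_standardized(zb, config)
        except ValueError:
            continue  # degenerate resample (e.g. zero lens range)
        present = np.zeros(n, dtype=bool)
        present[uniq] = True
        joint += np.outer(present, present)
        pair_hit = np.zeros((n, n), dtype=bool)
        for node in g.nodes:
            m = np.array([pos[s] for s in node["members"]])
            pair_hit[np.ix_(m, m)] = True
        together += pair_hit
    with np.errstate(invalid="ignore"):
        cooc = np.where(joint > 0, together / np.maximum(joint, 1), np.nan)
    np.fill_diagonal(cooc, 1.0)
    cooc_df = pd.DataFrame(cooc, index=ids, columns=ids)

    full = _mapper_from_standardized(z, config)
    kept = []
    for e in full.edges:
        a = full.members(e["source"])
        b = full.members(e["target"])
        vals = [cooc_df.at[x, y] for x in a for y in b if np.isfinite(cooc_df.at[x, y])]
        score = float(np.mean(vals)) if vals else 0.0
        if score >= config.consensus_threshold:
            kept.append({**e, "consensus": score})
    consensus = MapperGraph(nodes=[dict(nd) for nd in full.nodes], edges=kept)
    return cooc_df, consensus, full
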