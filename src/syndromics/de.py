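"""Differential expression, treatment-reversal classification, and
gene-set over-representation.

Counts are normalized to log2 counts-per-million; per-gene group
comparisons use Welch's two-sample t on log-expression with
Benjamini-Hochberg adjustment.  Genes significantly altered by injury
(vehicle vs reference) are classified by whether treatment moved their
expression back toward the uninjured reference: "full" when the treated
group is no longer distinguishable from the reference, "partial" when
it moved back but remains distinguishable, "none" otherwise.
Over-representation of significant genes in user-supplied gene sets
uses the one-sided hypergeometric upper tail with BH adjustment across
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SIG_LEVEL = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a testable universe."""

    sets: dict
    universe: set

    def __post_init__(self):
        self.universe = set(self.universe)
        filtered = {}
        for name, genes in self.sets.items():
            kept = set(genes) & self.universe
            if not kept:
                logger.warning("gene set %r empty after universe filter; dropped", name)
                continue
            filtered[name] = kept
        self.sets = filtered


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount) per sample."""
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative counts")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.columns[lib == 0])
        raise ValueError(f"zero library size in samples: {bad}")
    cpm = X / lib[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + pseudocount), index=counts.index,
                        columns=counts.columns)


def differential_expression(expr: pd.DataFrame, groups: pd.Series,
                            group_a: str, group_b: str) -> pd.DataFrame:
    """Per-gene Welch t test of group B vs group A on log-expression.

    Returns a DataFrame indexed by gene with columns ``mean_a``,
    ``mean_b``, ``log2fc`` (mean B - mean A), ``t``, ``p``, ``p_adj``
    (BH across all genes) and ``significant`` (p_adj < 0.05).  Genes
    with zero variance in both groups and equal means get p = 1.
    """
    groups = groups.reindex(expr.columns)
    a_cols = expr.columns[groups == group_a]
    b_cols = expr.columns[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    A = expr[a_cols].to_numpy(dtype=float)
    B = expr[b_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(B, A, axis=1, equal_var=False)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.where(~np.isfinite(p), 1.0, p)  # remaining pathologies: conservative
    t = np.where(np.isfinite(t), t, 0.0)
    p_adj = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_b - mean_a,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < SIG_LEVEL,
        },
        index=expr.index,
    )


def classify_reversal(veh_vs_ref: pd.DataFrame,
                      trt_vs_ref: pd.DataFrame) -> pd.Series:
    """Classify treatment reversal of injury-altered genes.

    Inputs are the per-gene tables of the vehicle-vs-reference and
    treated-vs-reference comparisons (both with the reference as group
    A).  For genes significant in vehicle-vs-reference: "full" if the
    treated shift away from vehicle opposes the injury shift and the
    treated group is not significantly different from the reference;
    "partial" if the direction opposes but the treated-vs-reference
    difference remains significant; "none" otherwise.  Genes not
    injury-altered get NaN (class undefined).
    """
    if not veh_vs_ref.index.equals(trt_vs_ref.index):
        raise ValueError("comparison tables must cover the same genes")
    m_ref = veh_vs_ref["mean_a"]
    if not np.allclose(m_ref, trt_vs_ref["mean_a"]):
        raise ValueError("reference means disagree between comparisons")
    m_veh = veh_vs_ref["mean_b"]
    m_trt = trt_vs_ref["mean_b"]
    injury_sign = np.sign(m_veh - m_ref)
    move = np.sign(m_trt - m_veh)
    opposes = (move != 0) & (move == -injury_sign)
    out = pd.Series(pd.NA, index=veh_vs_ref.index, dtype=object)
    sig_injury = veh_vs_ref["significant"].to_numpy(dtype=bool)
    still_sig = trt_vs_ref["significant"].to_numpy(dtype=bool)
    out[sig_injury & opposes.to_numpy() & ~still_sig] = "full"
    out[sig_injury & opposes.to_numpy() & still_sig] = "partial"
    out[sig_injury & ~opposes.to_numpy()] = "none"
    return out.rename("reversal_class")


def geneset_enrichment(significant: set, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    p = P(overlap >= observed) drawing len(significant) genes from a
    universe containing the set; BH adjustment across sets.
    """
    significant = set(significant)
    if not significant <= collection.universe:
        raise ValueError("significant genes must be a subset of the universe")
    M = len(collection.universe)
    N = len(significant)
    rows = []
    for name, genes in collection.sets.items():
        n = len(genes)
        if n > M:
            raise ValueError(f"set {name!r} larger than the universe")
        k = len(genes & significant)
        p = float(sps.hypergeom.sf(k - 1, M, n, N))
        rows.append({"set": name, "set_size": n, "overlap": k, "p": min(1.0, p)})
    if not rows:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "p", "p_adj"]).set_index("set")
    tab = pd.DataFrame(rows).set_index("set")
    tab["p_adj"] = benjamini_hochberg(tab["p"].to_numpy())
    return tab.sort_values("p")
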