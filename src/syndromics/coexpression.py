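"""Unsupervised gene co-expression module detection and merging.

Four-step procedure: (1) pairwise biweight midcorrelations (bicor)
between all gene profiles; (2) complete-linkage hierarchical clustering
with 1 - bicor as the distance; (3) a static cut at the height below
which the strongest 10% of pairwise correlations fall, keeping clusters
with at least 12 members as modules; (4) module summarization by
eigengenes (first principal component of the standardized module
submatrix via SVD) with iterative merging of module pairs whose
eigengene correlation exceeds 0.85 — highest pair first, eigengenes and
correlations recomputed after each merge.  Membership strength of every
gene for every module (kME) is the Pearson correlation of the gene's
profile with the module eigengene.

Sample quality screening follows a standardized-connectivity rule:
samples whose mean inter-sample correlation falls more than 2 SD below
the cohort mean are excluded, iteratively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix
from .stats import one_way_anova, tukey_hsd

logger = logging.getLogger(__name__)

BICOR_TUNING = 9.0  # standard Tukey biweight constant


@dataclass
class NetworkParams:
    min_module_size: int = 12
    cut_quantile: float = 0.10   # strongest fraction of pairwise correlations
    merge_threshold: float = 0.85
    linkage_method: str = "complete"
    outlier_z: float = -2.0

    def validate(self):
        if not (0.0 < self.cut_quantile < 1.0):
            raise ValueError("cut_quantile must be in (0, 1)")
        if not (0.0 < self.merge_threshold < 1.0):
            raise ValueError("merge_threshold must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleSet:
    """Module assignment with eigengene summaries.

    labels maps gene id -> module id ("M1", ...) or "unassigned";
    eigengenes is modules x samples (unit variance); kme is genes x
    modules; merge_log records each merge as (kept, absorbed,
    eigengene correlation) in execution order.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: dict
    kme: pd.DataFrame | None = None
    merge_log: list = field(default_factory=list)

    @property
    def module_ids(self) -> list:
        return list(self.eigengenes.index)

    def members(self, module_id) -> list:
        return list(self.labels.index[self.labels == module_id])


def _bicor_weights(x: np.ndarray):
    """Weighted median-centered deviations for one profile, or None if
    MAD is zero (Pearson fallback required)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return None
    u = (x - med) / (BICOR_TUNING * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors.

    Deviations from the median are downweighted by the Tukey biweight
    (tuning constant 9, unscaled MAD); points beyond 9 MADs get zero
    weight, making the estimate robust to gross outliers while staying
    close to Pearson on clean Gaussian data.  If either vector has zero
    MAD, falls back to Pearson with a warning; constant vectors under
    the fallback are undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("bicor needs two equal-length vectors of length >= 3")
    ax, ay = _bicor_weights(x), _bicor_weights(y)
    if ax is None or ay is None:
        logger.warning("zero MAD; falling back to Pearson")
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            logger.warning("constant vector; correlation undefined")
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])
    nx, ny = np.linalg.norm(ax), np.linalg.norm(ay)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.clip(ax @ ay / (nx * ny), -1.0, 1.0))


def bicor_matrix(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """All pairwise biweight midcorrelations between gene profiles.

    Vectorized: each gene's weighted deviation vector is normalized once
    and correlations are a single matrix product.  Genes with zero MAD
    use standardized (Pearson-equivalent) deviations instead.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    X = df.to_numpy(dtype=float)
    n_genes = X.shape[0]
    A = np.empty_like(X)
    fallback = 0
    for i in range(n_genes):
        a = _bicor_weights(X[i])
        if a is None:
            fallback += 1
            sd = X[i].std()
            a = (X[i] - X[i].mean()) if sd > 0 else np.zeros_like(X[i])
        norm = np.linalg.norm(a)
        A[i] = a / norm if norm > 0 else a
    if fallback:
        logger.warning("%d gene(s) with zero MAD used Pearson fallback", fallback)
    R = np.clip(A @ A.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return pd.DataFrame(R, index=df.index, columns=df.index)


def flag_outlier_samples(expr: ExpressionMatrix | pd.DataFrame,
                         z_cutoff: float = -2.0) -> list:
    """Iterative standardized-connectivity sample screening.

    Connectivity K_i is sample i's mean Pearson correlation with all
    other samples over genes; Z.K standardizes K over samples.  The
    lowest sample with Z.K below ``z_cutoff`` is removed and the screen
    repeats on the remainder.  Aborts rather than remove more than half
    the samples.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if df.shape[1] < 4:
        raise ValueError("need >= 4 samples to screen for outliers")
    excluded = []
    current = list(df.columns)
    limit = df.shape[1] // 2
    while True:
        sub = df[current].to_numpy(dtype=float)
        C = np.corrcoef(sub.T)
        K = (C.sum(axis=1) - 1.0) / (len(current) - 1)
        sd = K.std(ddof=1)
        if sd == 0.0:
            break
        zk = (K - K.mean()) / sd
        worst = int(np.argmin(zk))
        if zk[worst] >= z_cutoff:
            break
        excluded.append(current[worst])
        if len(excluded) > limit:
            raise ValueError(
                "outlier screen would remove more than half the samples"
            )
        current.pop(worst)
        if len(current) < 3:
            break
    return excluded


def median_center_batches(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's per-batch median (convenience only).

    The pipeline accepts matrices as already batch-corrected; this flag
    offers a crude per-batch location adjustment when no corrected
    matrix is available.  Requires batch labels on the matrix.
    """
    if expr.batch is None:
        raise ValueError("expression matrix carries no batch labels")
    values = expr.values.copy()
    for b in expr.batch.unique():
        cols = expr.batch.index[expr.batch == b]
        sub = values[cols]
        values[cols] = sub.sub(sub.median(axis=1), axis=0)
    return ExpressionMatrix(values=values, groups=expr.groups.copy(),
                            batch=expr.batch.copy())


def detect_modules(expr: ExpressionMatrix, params: NetworkParams | None = None,
                   corr: pd.DataFrame | None = None) -> ModuleSet:
    """Complete-linkage clustering of 1 - bicor with a top-correlation cut.

    The dendrogram is cut at the ``cut_quantile`` quantile of the
    off-diagonal distances, so only gene pairs among the strongest 10%
    of pairwise correlations (by default) can share a cluster; clusters
    of at least ``min_module_size`` genes become modules M1, M2, ...
    (ordered by size, descending), all other genes are "unassigned".
    """
    params = params or NetworkParams()
    params.validate()
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if df.shape[0] < params.min_module_size:
        raise ValueError("fewer genes than min_module_size")
    R = corr if corr is not None else bicor_matrix(df)
    D = 1.0 - R.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    offdiag = squareform(D, checks=False)
    h = float(np.quantile(offdiag, params.cut_quantile))
    if not np.isfinite(h):
        raise ValueError("non-finite cut height")
    Z = linkage(offdiag, method=params.linkage_method)
    flat = fcluster(Z, t=h, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    big = [c for c in sizes.index if sizes[c] >= params.min_module_size]
    big.sort(key=lambda c: (-sizes[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(big)}
    labels = pd.Series(
        [rename.get(c, "unassigned") for c in flat], index=df.index, name="module"
    )
    eigengenes, var_exp = {}, {}
    for mod in rename.values():
        eg, ve = module_eigengene(df.loc[labels == mod])
        eigengenes[mod] = eg
        var_exp[mod] = ve
    eg_df = (
        pd.DataFrame(eigengenes).T
        if eigengenes
        else pd.DataFrame(columns=df.columns)
    )
    eg_df.attrs["cut_height"] = h
    return ModuleSet(labels=labels, eigengenes=eg_df, variance_explained=var_exp)


def module_eigengene(module_df: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of the standardized module submatrix.

    Gene rows are z-scored (constant rows dropped), the first right
    singular vector is scaled to unit variance and oriented so its mean
    correlation with member genes is positive.  Returns (eigengene,
    fraction of variance explained).
    """
    X = module_df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("module needs >= 2 genes")
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all module genes constant")
    if (~keep).any():
        logger.warning("dropping %d constant gene(s) before SVD", (~keep).sum())
    Xz = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    U, s, Vt = np.linalg.svd(Xz, full_matrices=False)
    eg = Vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    eg = eg / eg.std(ddof=1)
    cors = np.array([np.corrcoef(row, eg)[0, 1] for row in Xz])
    if np.nanmean(cors) < 0:
        eg = -eg
    return pd.Series(eg, index=module_df.columns), var_explained


def merge_modules(modules: ModuleSet, expr: ExpressionMatrix | pd.DataFrame,
                  merge_threshold: float = 0.85) -> ModuleSet:
    """Iteratively merge module pairs with eigengene correlation above
    the threshold.

    At each step the pair with the highest Pearson eigengene correlation
    is merged (if above threshold), the combined eigengene is recomputed,
    and all pairwise correlations are re-evaluated; the loop ends when no
    pair exceeds the threshold.  The absorbed module keeps the smaller
    ordinal id of the pair.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    labels = modules.labels.copy()
    eigengenes = {m: modules.eigengenes.loc[m].copy() for m in modules.module_ids}
    var_exp = dict(modules.variance_explained)
    log = []
    while len(eigengenes) > 1:
        mods = sorted(eigengenes, key=lambda m: int(m[1:]) if m[1:].isdigit() else 0)
        best, best_r = None, -np.inf
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = float(np.corrcoef(eigengenes[mods[i]], eigengenes[mods[j]])[0, 1])
                if r > best_r:
                    best_r, best = r, (mods[i], mods[j])
        if best_r <= merge_threshold:
            break
        keep, absorb = best
        labels[labels == absorb] = keep
        eg, ve = module_eigengene(df.loc[labels == keep])
        eigengenes[keep] = eg
        var_exp[keep] = ve
        del eigengenes[absorb], var_exp[absorb]
        log.append((keep, absorb, best_r))
    order = sorted(eigengenes, key=lambda m: int(m[1:]) if m[1:].isdigit() else 0)
    eg_df = (
        pd.DataFrame({m: eigengenes[m] for m in order}).T
        if order
        else modules.eigengenes.iloc[:0]
    )
    return ModuleSet(
        labels=labels,
        eigengenes=eg_df,
        variance_explained={m: var_exp[m] for m in order},
        merge_log=modules.merge_log + log,
    )


def compute_kme(expr: ExpressionMatrix | pd.DataFrame,
                eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene profile with every eigengene."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=1)  # population scale; pairs with the /n below
    const = sd == 0
    if const.any():
        logger.warning("kME undefined for %d constant gene(s)", const.sum())
    Xz = np.where(
        const[:, None], np.nan, (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None]
    )
    out = {}
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        ez = (e - e.mean()) / e.std()
        out[m] = np.clip(Xz @ ez / X.shape[1], -1.0, 1.0)
    kme = pd.DataFrame(out, index=df.index)
    return kme


def module_trait_test(eigengene: pd.Series, groups: pd.Series,
                      ordered_groups: tuple, alpha: float = 0.05) -> dict:
    """Per-module ANOVA across (reference, vehicle, treated) with a
    treatment-reversion flag.

    The flag is True when the omnibus ANOVA is significant, the vehicle
    group differs from the reference (Tukey-adjusted p < alpha), and
    the treated-group mean lies strictly between the vehicle and
    reference means — i.e. treatment moved the module's transcriptional
    phenotype back toward the uninjured state.
    """
    ref, veh, trt = ordered_groups
    groups = groups.reindex(eigengene.index)
    for g in ordered_groups:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} missing or has < 2 samples")
    an = one_way_anova(eigengene.to_numpy(dtype=float), groups.to_numpy())
    tk = tukey_hsd(an)
    m_ref, m_veh, m_trt = (an.group_means[g] for g in ordered_groups)
    p_veh_ref = tk[frozenset((ref, veh))]["p_adj"]
    between = min(m_ref, m_veh) < m_trt < max(m_ref, m_veh)
    reversion = bool(an.p < alpha and p_veh_ref < alpha and between)
    return {
        "F": an.F,
        "p": an.p,
        "group_means": an.group_means,
        "tukey": tk,
        "reversion": reversion,
    }
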