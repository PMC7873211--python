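"""Shared univariate statistical kernel.

One-way ANOVA, Tukey HSD post-hocs, orthogonal polynomial contrasts for
dose-response trend testing, delta-delta-Ct relative quantification of
qPCR data, and thresholded immunoreactive-area quantification.

These primitives back the higher-level pipeline stages (syndromic PCA
dose-response tests, module-trait ANOVAs) and are usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "AreaQuant",
    "one_way_anova",
    "tukey_hsd",
    "orthogonal_polynomial_contrasts",
    "delta_delta_ct",
    "area_quantification",
]


@dataclass
class AnovaResult:
    """One-way ANOVA decomposition.

    Attributes
    ----------
    F : float
        Between/within mean-square ratio.
    df_between, df_within : int
        Degrees of freedom of the numerator and denominator.
    p : float
        Upper-tail probability from the F distribution.
    group_means : dict
        Per-group sample means, keyed by group label.
    group_n : dict
        Per-group sample sizes.
    mse : float
        Within-group (residual) mean square.
    ss_between, ss_within, ss_total : float
        Sums of squares of the decomposition.
    """

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    group_n: dict
    mse: float
    ss_between: float
    ss_within: float
    ss_total: float
    # raw data retained so post-hocs can be run from the result alone
    groups_: dict = field(default_factory=dict, repr=False)


@dataclass
class AreaQuant:
    """Thresholded immunoreactive-area quantification.

    positive_fraction is the fraction of pixels above threshold;
    laterality_percent is 100 x (ipsilateral positive pixels) /
    (contralateral positive pixels), or None when no contralateral
    image was supplied or it has no positive pixels.
    """

    threshold: float
    positive_fraction: float
    laterality_percent: float | None
    laterality_defined: bool


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    out = {}
    for g in pd_unique(labels):
        out[g] = values[labels == g]
    return out


def pd_unique(arr):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for a in arr:
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def one_way_anova(values, labels) -> AnovaResult:
    """Fixed-effects one-way ANOVA.

    Parameters
    ----------
    values : array-like of float
        Observations (NaN entries are dropped).
    labels : array-like
        Group label per observation; >= 2 groups each with >= 1
        observation, and >= 2 residual degrees of freedom overall.
    """
    groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("one_way_anova requires >= 2 groups")
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
    n_total = sum(v.size for v in groups.values())
    k = len(groups)
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(list(groups.values())).mean()
    ss_b = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = ss_w / df_w
    if mse == 0.0:
        F = 0.0 if ss_b == 0 else np.inf
    else:
        F = (ss_b / df_b) / mse
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_n={g: int(v.size) for g, v in groups.items()},
        mse=float(mse),
        ss_between=float(ss_b),
        ss_within=float(ss_w),
        ss_total=float(ss_b + ss_w),
        groups_={g: v.copy() for g, v in groups.items()},
    )


def tukey_hsd(anova: AnovaResult) -> dict:
    """Tukey HSD all-pairs comparisons after a one-way ANOVA.

    Uses the Tukey-Kramer statistic q = |m_i - m_j| /
    sqrt(MSE/2 * (1/n_i + 1/n_j)) with p values from the studentized
    range distribution on (k groups, df_within). Valid for unequal n.

    Returns a dict mapping frozenset({group_i, group_j}) to a dict with
    keys ``diff``, ``q`` and ``p_adj``.
    """
    labels = list(anova.group_means)
    k = len(labels)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = anova.group_means[b] - anova.group_means[a]
            na, nb = anova.group_n[a], anova.group_n[b]
            se = np.sqrt(anova.mse / 2.0 * (1.0 / na + 1.0 / nb))
            if se == 0.0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            if np.isinf(q):
                p = 0.0
            else:
                p = float(sps.studentized_range.sf(q, k, anova.df_within))
            out[frozenset((a, b))] = {"diff": float(diff), "q": float(q), "p_adj": min(1.0, p)}
    return out


def orthogonal_polynomial_contrasts(k: int, doses=None) -> np.ndarray:
    """Orthogonal polynomial contrast coefficients for k ordered groups.

    Columns are the linear, quadratic, ... order-(k-1) trend contrasts,
    built by Gram-Schmidt orthogonalization of powers of the centered
    dose codes and scaled to unit length. With equally spaced doses the
    columns are proportional to the classical tables, e.g. for k = 3
    linear (-1, 0, 1) and quadratic (1, -2, 1).

    Parameters
    ----------
    k : int
        Number of ordered groups (>= 2).
    doses : array-like of float, optional
        Numeric dose value per group; defaults to 0..k-1. Duplicate
        values are rejected because they make the polynomial basis
        collinear.
    """
    if k < 2:
        raise ValueError("need >= 2 groups for polynomial contrasts")
    if doses is None:
        x = np.arange(k, dtype=float)
    else:
        x = np.asarray(doses, dtype=float)
        if x.shape != (k,):
            raise ValueError("doses must have one value per group")
        if len(np.unique(x)) != k:
            raise ValueError("duplicate dose values")
    x = x - x.mean()
    # powers 1..k-1 orthogonalized against the intercept and each other
    basis = np.column_stack([x ** d for d in range(k)])
    Q, _ = np.linalg.qr(basis)
    C = Q[:, 1:]
    # fix sign so the highest-dose coefficient of each contrast is positive
    for c in range(C.shape[1]):
        lead = C[np.argmax(x), c]
        if lead < 0:
            C[:, c] = -C[:, c]
    C /= np.linalg.norm(C, axis=0, keepdims=True)
    return C


def delta_delta_ct(ct_target, ct_housekeeping, conditions, reference) -> dict:
    """Relative qPCR quantification by the delta-delta-Ct method.

    dCt = Ct_target - Ct_housekeeping averaged within each condition;
    ddCt = dCt_condition - dCt_reference; fold change = 2**(-ddCt),
    so the reference condition has fold change 1 by construction.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_h = np.asarray(ct_housekeeping, dtype=float)
    cond = np.asarray(conditions)
    if ct_t.shape != ct_h.shape or ct_t.shape != cond.shape:
        raise ValueError("Ct vectors and condition labels must align")
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_h).all()):
        raise ValueError("non-finite Ct value")
    if reference not in cond:
        raise ValueError(f"reference condition {reference!r} absent")
    dct = {g: float((ct_t[cond == g] - ct_h[cond == g]).mean()) for g in pd_unique(cond)}
    ref = dct[reference]
    return {g: float(2.0 ** -(d - ref)) for g, d in dct.items()}


def area_quantification(image, threshold: float, contralateral=None) -> AreaQuant:
    """Fraction of supra-threshold pixels, and ipsi/contra laterality.

    positive_fraction = (# pixels > threshold) / (total pixels).  When a
    contralateral image is supplied, laterality_percent = 100 x
    (ipsilateral positive count) / (contralateral positive count); it is
    undefined (None, flagged) if the contralateral side has no positive
    pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    pos = int((img > threshold).sum())
    frac = pos / img.size
    lat, defined = None, False
    if contralateral is not None:
        contra = np.asarray(contralateral, dtype=float)
        cpos = int((contra > threshold).sum())
        if cpos > 0:
            lat = 100.0 * pos / cpos
            defined = True
    return AreaQuant(
        threshold=float(threshold),
        positive_fraction=float(frac),
        laterality_percent=lat,
        laterality_defined=defined,
    )
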