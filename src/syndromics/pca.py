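"""Syndromic principal component analysis of multivariate outcomes.

Components are extracted by eigenvalue decomposition of the Pearson
correlation matrix of all outcomes, so that heterogeneous scales
(behavioral scores, histological measures) contribute equally and the
leading components represent whole-syndrome severity/recovery axes.

Retention applies three concurrent rules: the Kaiser rule (eigenvalue >
1.0), a scree elbow operationalized as the maximum acceleration (second
difference) of the log-eigenvalue sequence, and over-determination (at
least 3 loadings above |0.4|).  Subject scores on retained components
are unit-variance z-scores; treatment dose-response on a score is
tested by one-way ANOVA with orthogonal polynomial contrasts, where a
significant negative quadratic contrast flags an inverted-U dose
response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import OutcomeMatrix
from .stats import one_way_anova, orthogonal_polynomial_contrasts

logger = logging.getLogger(__name__)

KAISER_CUTOFF = 1.0
LOADING_CUTOFF = 0.4
MIN_SALIENT_LOADINGS = 3


@dataclass
class PCAModel:
    """Eigenstructure of the outcome correlation matrix.

    loadings are on the correlation scale (eigenvector x sqrt(eigenvalue),
    i.e. the correlation between variable and component); eigenvalues are
    sorted descending and sum to the number of variables.
    """

    loadings: pd.DataFrame          # variables x components
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # fraction per component
    eigenvectors: np.ndarray        # variables x components, unit norm
    variables: list
    retained: list = field(default_factory=list)
    retention_audit: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None


@dataclass
class DoseResponseResult:
    F: float
    p_omnibus: float
    df_between: int
    df_within: int
    group_means: dict
    group_n: dict
    contrasts: pd.DataFrame  # order, estimate, t, p
    inverted_u: bool


def _pairwise_correlation(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations; complete-case fallback
    when the pairwise matrix is not positive semidefinite."""
    corr = df.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        raise ValueError("correlation not estimable for some variable pair")
    evals = np.linalg.eigvalsh(corr.to_numpy())
    if evals.min() < -1e-10:
        logger.warning(
            "pairwise-complete correlation matrix not PSD (min eigenvalue %.3g); "
            "falling back to complete cases",
            evals.min(),
        )
        corr = df.dropna().corr(method="pearson")
    return corr


def correlation_pca(outcomes: OutcomeMatrix | pd.DataFrame,
                    correlation: pd.DataFrame | None = None) -> PCAModel:
    """Eigen-decompose the outcome correlation matrix.

    ``correlation`` may be supplied directly (e.g. for constructed
    fixtures); otherwise it is estimated pairwise-complete from the
    outcome table.  Components are oriented so each one's largest-
    magnitude loading is positive.
    """
    df = outcomes.outcomes if isinstance(outcomes, OutcomeMatrix) else outcomes
    df = df.loc[:, df.std(ddof=1, skipna=True) > 0]
    if correlation is None:
        if df.shape[1] < 2:
            raise ValueError("need >= 2 non-constant variables")
        correlation = _pairwise_correlation(df)
    variables = list(correlation.columns)
    R = correlation.to_numpy(dtype=float)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = evecs * np.sqrt(evals)[None, :]
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{j + 1}" for j in range(len(variables))]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        eigenvalues=evals,
        variance_explained=evals / len(variables),
        eigenvectors=evecs,
        variables=variables,
    )


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Scree elbow as the maximum-acceleration component (1-based).

    The elbow is the component index j (2..p-1) maximizing the second
    difference of the log-eigenvalue sequence — the point where the
    proportional decline flattens most sharply.  Components strictly
    before the elbow sit above the scree.
    """
    e = np.log(np.clip(np.asarray(eigenvalues, dtype=float), 1e-12, None))
    p = e.size
    if p < 3:
        return p  # no interior point; admit everything
    accel = e[:-2] - 2.0 * e[1:-1] + e[2:]  # at components 2..p-1
    return int(np.argmax(accel)) + 2


def retain_components(model: PCAModel) -> PCAModel:
    """Apply the three retention rules and record a per-component audit.

    A component is retained when it passes all of: (1) Kaiser —
    eigenvalue > 1.0; (2) scree — index strictly before the
    acceleration elbow; (3) over-determination — at least 3 loadings
    with |loading| > 0.4.
    """
    if len(model.variables) < MIN_SALIENT_LOADINGS:
        raise ValueError(
            "over-determination rule requires >= 3 variables"
        )
    elbow = scree_elbow(model.eigenvalues)
    rows = []
    retained = []
    for j, comp in enumerate(model.loadings.columns):
        kaiser = model.eigenvalues[j] > KAISER_CUTOFF
        scree = (j + 1) < elbow
        n_salient = int((model.loadings[comp].abs() > LOADING_CUTOFF).sum())
        overdet = n_salient >= MIN_SALIENT_LOADINGS
        keep = kaiser and scree and overdet
        if keep:
            retained.append(comp)
        rows.append(
            {
                "component": comp,
                "eigenvalue": model.eigenvalues[j],
                "kaiser": kaiser,
                "scree": scree,
                "n_salient_loadings": n_salient,
                "overdetermined": overdet,
                "retained": keep,
            }
        )
    model.retained = retained
    model.retention_audit = pd.DataFrame(rows).set_index("component")
    model.retention_audit.attrs["scree_elbow"] = elbow
    return model


def score_subjects(model: PCAModel, outcomes: OutcomeMatrix | pd.DataFrame,
                   components: list | None = None) -> pd.DataFrame:
    """Unit-variance subject scores on retained components.

    Outcomes are column-standardized with mean imputation of missing
    cells (a subject at every variable mean scores 0); scores are the
    standardized rows projected on the eigenvectors, rescaled to unit
    variance via sqrt(eigenvalue).  Subjects with all outcomes missing
    get NaN scores and are flagged in ``scores.attrs['undefined']``.
    """
    comps = components if components is not None else model.retained
    if not comps:
        raise ValueError("no retained components; run retain_components first")
    df = outcomes.outcomes if isinstance(outcomes, OutcomeMatrix) else outcomes
    df = df[model.variables]
    X = df.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    Z = (X - mu) / sd
    all_missing = np.isnan(Z).all(axis=1)
    Z = np.where(np.isnan(Z), 0.0, Z)
    cols = {}
    for comp in comps:
        j = list(model.loadings.columns).index(comp)
        lam = model.eigenvalues[j]
        if lam <= 0:
            raise ValueError(f"{comp} has zero eigenvalue; scores undefined")
        cols[comp] = Z @ model.eigenvectors[:, j] / np.sqrt(lam)
    scores = pd.DataFrame(cols, index=df.index)
    scores[all_missing] = np.nan
    scores.attrs["undefined"] = list(df.index[all_missing])
    model.scores = scores
    return scores


def test_dose_response(scores, groups, doses=None, alpha: float = 0.05) -> DoseResponseResult:
    """One-way ANOVA plus orthogonal polynomial trend contrasts.

    ``groups`` are ordered dose-group labels per subject; ``doses``
    optionally gives a numeric dose per group (equally spaced integer
    codes otherwise).  Each contrast t uses the pooled ANOVA mean
    square error: t = sum(c_k m_k) / sqrt(MSE * sum(c_k^2 / n_k)) on
    the residual degrees of freedom.  ``inverted_u`` is True when the
    quadratic estimate is negative with p < alpha.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(scores)
    scores, groups = scores[keep], groups[keep]
    an = one_way_anova(scores, groups)
    labels = list(an.group_means)  # order of first appearance
    try:  # numeric labels (e.g. raw doses) define their own order
        labels.sort(key=float)
    except (TypeError, ValueError):
        pass
    k = len(labels)
    if k < 3:
        raise ValueError("polynomial dose-response requires >= 3 ordered groups")
    for g, ng in an.group_n.items():
        if ng < 2:
            raise ValueError(f"group {g!r} has < 2 subjects")
    dose_values = None if doses is None else [doses[g] if isinstance(doses, dict) else doses[i] for i, g in enumerate(labels)]
    if dose_values is not None:
        order = np.argsort(dose_values)
        labels = [labels[i] for i in order]
        dose_values = [dose_values[i] for i in order]
    C = orthogonal_polynomial_contrasts(k, dose_values)
    m = np.array([an.group_means[g] for g in labels])
    nvec = np.array([an.group_n[g] for g in labels], dtype=float)
    names = ["linear", "quadratic", "cubic"] + [f"order{d}" for d in range(4, k)]
    rows = []
    for j in range(C.shape[1]):
        c = C[:, j]
        est = float(c @ m)
        se = np.sqrt(an.mse * np.sum(c ** 2 / nvec))
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p = float(2.0 * sps.t.sf(abs(t), an.df_within)) if np.isfinite(t) else 0.0
        rows.append({"order": names[j], "coefficients": c.copy(),
                     "estimate": est, "t": float(t), "p": p})
    contrasts = pd.DataFrame(rows).set_index("order")
    quad = contrasts.loc["quadratic"] if "quadratic" in contrasts.index else None
    inverted_u = bool(
        quad is not None and quad["estimate"] < 0 and quad["p"] < alpha
    )
    return DoseResponseResult(
        F=an.F,
        p_omnibus=an.p,
        df_between=an.df_between,
        df_within=an.df_within,
        group_means={g: an.group_means[g] for g in labels},
        group_n={g: an.group_n[g] for g in labels},
        contrasts=contrasts,
        inverted_u=inverted_u,
    )
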