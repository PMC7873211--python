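"""Seeded synthetic-data generators with known ground truth.

Two generators emulate the structure of a pooled preclinical study:

* :func:`simulate_trial` — a multi-arm trial of ~159 subjects with
  graded injury severity, correlated behavioral and histological
  outcomes driven by latent recovery/lesion factors, and one treated
  arm carrying an inverted-U dose effect on the behavioral (recovery)
  outcomes only.
* :func:`simulate_expression` — an RNA-seq-like count matrix over three
  groups (uninjured reference, lesioned + vehicle, lesioned + treated)
  with planted co-expression modules, injury-shifted genes, and a
  subset of injury genes whose treated-group expression moves back
  toward the reference (treatment-reversed genes).

Every downstream stage of the pipeline is testable against the ground
truth these generators return, with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OutcomeMatrix


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


# ---------------------------------------------------------------------------
# multi-arm trial


@dataclass
class TrialSimConfig:
    """Configuration of the multi-arm preclinical trial generator.

    ``arms`` maps each arm name to its ordered dose levels; subjects
    are allocated round-robin over all (arm, dose) cells.  The
    ``treated_arm`` receives ``dose_effect_shape`` — one additive shift
    of the latent recovery factor per dose level (inverted-U by
    default, peaking at intermediate dose).  ``latent_loading_*`` are
    the loadings of each outcome on its latent factor; residual noise
    has standard deviation ``noise_sd``.
    """

    n_subjects: int = 159
    arms: tuple = (
        ("minocycline", (1.0,)),
        ("ibuprofen", (1.0,)),
        ("etanercept", (1.0,)),
        ("licofelone", (1.0,)),
        ("sTNFR1", (0.0, 0.5, 1.0, 2.0, 4.0)),
    )
    treated_arm: str = "sTNFR1"
    severity_range: tuple = (600.0, 1800.0)
    n_behavioral: int = 6
    n_histological: int = 4
    latent_loading_behavioral: float = 0.8
    latent_loading_histological: float = 0.8
    # latent-recovery shift per dose level of the treated arm
    dose_effect_shape: tuple = (0.0, 1.0, 1.6, 1.0, 0.0)
    noise_sd: float = 0.6
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self):
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        arm_names = [a for a, _ in self.arms]
        if len(set(arm_names)) != len(arm_names):
            raise ConfigurationError("duplicate arm names")
        if self.treated_arm not in arm_names:
            raise ConfigurationError(f"treated arm {self.treated_arm!r} not among arms")
        doses = dict(self.arms)[self.treated_arm]
        if len(self.dose_effect_shape) != len(doses):
            raise ConfigurationError(
                "dose_effect_shape must have one entry per dose level of the treated arm"
            )
        if self.severity_range[0] >= self.severity_range[1]:
            raise ConfigurationError("severity_range must be a non-empty interval")


def simulate_trial(config: TrialSimConfig) -> tuple[OutcomeMatrix, dict]:
    """Generate a multi-arm trial outcome table plus ground truth.

    A latent recovery factor drives the behavioral outcomes and a
    latent lesion factor, tied to injury severity, drives the
    histological outcomes; the two factors are negatively coupled
    through severity so a single syndromic axis spans both domains.
    Treatment shifts the recovery factor of treated-arm subjects by
    the dose-specific entry of ``dose_effect_shape``.

    Returns
    -------
    (OutcomeMatrix, dict)
        The outcome table and a ground-truth record with the latent
        factor values, the per-(arm, dose) true behavioral shifts, and
        the generator configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = [(arm, dose) for arm, doses in config.arms for dose in doses]
    n = config.n_subjects
    assign = [cells[i % len(cells)] for i in range(n)]
    rng.shuffle(assign)
    arm = np.array([a for a, _ in assign], dtype=object)
    dose = np.array([d for _, d in assign], dtype=float)

    severity = rng.uniform(*config.severity_range, size=n)
    z_sev = (severity - severity.mean()) / severity.std(ddof=1)
    lesion = z_sev + 0.3 * rng.standard_normal(n)
    # worse injuries recover less; residual variance keeps Var(recovery) ~ 1
    recovery = -0.6 * z_sev + 0.8 * rng.standard_normal(n)

    treated_doses = list(dict(config.arms)[config.treated_arm])
    shape = dict(zip(treated_doses, config.dose_effect_shape))
    shift = np.array(
        [shape[d] if a == config.treated_arm else 0.0 for a, d in zip(arm, dose)]
    )
    recovery_shifted = recovery + shift

    lam_b = config.latent_loading_behavioral
    lam_h = config.latent_loading_histological
    beh = (
        lam_b * recovery_shifted[:, None]
        + config.noise_sd * rng.standard_normal((n, config.n_behavioral))
    )
    hist = (
        lam_h * lesion[:, None]
        + config.noise_sd * rng.standard_normal((n, config.n_histological))
    )
    cols = [f"beh_{i + 1}" for i in range(config.n_behavioral)] + [
        f"hist_{i + 1}" for i in range(config.n_histological)
    ]
    values = np.hstack([beh, hist])
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan

    ids = [f"S{i + 1:03d}" for i in range(n)]
    outcomes = pd.DataFrame(values, index=ids, columns=cols)
    metadata = pd.DataFrame(
        {"arm": arm, "dose": dose, "severity": severity}, index=ids
    )
    truth = {
        "recovery_latent": dict(zip(ids, recovery_shifted.tolist())),
        "lesion_latent": dict(zip(ids, lesion.tolist())),
        "treated_arm": config.treated_arm,
        "dose_levels": treated_doses,
        "dose_effect_shape": list(config.dose_effect_shape),
        "true_behavioral_shift": {
            str(d): lam_b * s for d, s in zip(treated_doses, config.dose_effect_shape)
        },
        "behavioral_columns": cols[: config.n_behavioral],
        "histological_columns": cols[config.n_behavioral:],
    }
    return OutcomeMatrix(outcomes=outcomes, metadata=metadata), truth


# ---------------------------------------------------------------------------
# planted-module expression matrix


@dataclass
class ExprSimConfig:
    """Configuration of the planted-module RNA-seq-like generator.

    Module member genes share a per-sample latent factor so their
    log-scale intra-module correlation is approximately
    ``within_module_cor``.  ``n_injury_genes`` background genes are
    shifted by ``injury_shift`` log2 units (alternating sign) in both
    lesioned groups; the first ``n_reversal_genes`` of them are instead
    moved back toward the reference in the treated group by
    ``reversal_fraction`` of the shift.  Counts are Poisson draws from
    log-normal latent intensities with sample-specific library sizes
    around ``library_size``.
    """

    n_genes: int = 350
    n_samples_per_group: int = 5
    groups: tuple = ("sham", "vehicle", "treated")
    n_modules: int = 3
    module_size: int = 50
    within_module_cor: float = 0.7
    n_injury_genes: int = 100
    n_reversal_genes: int = 80
    injury_shift: float = 2.0
    reversal_fraction: float = 1.0
    gene_noise_sd: float = 0.5
    n_housekeeping: int = 11  # kept below min module size downstream
    library_size: float = 2e6
    seed: int = 0

    def validate(self):
        if len(self.groups) != 3:
            raise ConfigurationError("exactly three ordered groups are required")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("module budget exceeds n_genes")
        if self.n_reversal_genes > self.n_injury_genes:
            raise ConfigurationError("n_reversal_genes must be <= n_injury_genes")
        n_background = self.n_genes - self.n_modules * self.module_size
        if self.n_injury_genes + self.n_housekeeping > n_background:
            raise ConfigurationError(
                "injury + housekeeping genes must fit among background "
                "(non-module) genes"
            )
        if not (0.0 < self.within_module_cor < 1.0) and self.n_modules > 0:
            raise ConfigurationError("within_module_cor must be in (0, 1)")
        if not (0.0 < self.reversal_fraction <= 1.0):
            raise ConfigurationError("reversal_fraction must be in (0, 1]")


def simulate_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate a count matrix, sample-group labels, and ground truth.

    Returns
    -------
    (counts, groups, truth)
        ``counts`` — genes x samples non-negative integer DataFrame;
        ``groups`` — sample id -> group label Series (reference group
        first); ``truth`` — module label and gene class per gene, plus
        the per-group true log2 shifts of injury/reversal genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref, veh, trt = config.groups
    nspg = config.n_samples_per_group
    samples = [f"{g}_{i + 1}" for g in config.groups for i in range(nspg)]
    n_samples = len(samples)
    group_of = pd.Series(
        [g for g in config.groups for _ in range(nspg)], index=samples, name="group"
    )

    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    base = rng.uniform(6.0, 10.0, size=config.n_genes)  # log2 baseline intensity
    # a handful of high-expression, low-variance housekeeping genes at
    # the end of the background block dominate the library mass, as in
    # real RNA-seq; this keeps per-sample totals stable so library
    # normalization does not induce spurious compositional correlation
    n_stable = min(config.n_housekeeping, config.n_genes)
    if n_stable:
        base[-n_stable:] = 15.0
    log2x = base[:, None] + np.zeros((config.n_genes, n_samples))

    module_label = np.array(["background"] * config.n_genes, dtype=object)
    rho = config.within_module_cor
    idx = 0
    group_idx = np.repeat(np.arange(len(config.groups)), nspg)
    for m in range(config.n_modules):
        members = slice(idx, idx + config.module_size)
        module_label[members] = f"M{m + 1}"
        # eigengene-like factor: per-group means plus within-group
        # variation, mirroring modules that respond to injury/treatment;
        # uniform draws keep the factor free of single extreme samples
        # that the biweight midcorrelation would otherwise downweight
        group_means = rng.uniform(-1.0, 1.0, size=len(config.groups))
        factor = group_means[group_idx] + 0.7 * rng.uniform(-1.0, 1.0, size=n_samples)
        factor = (factor - factor.mean()) / factor.std()
        eps = rng.standard_normal((config.module_size, n_samples))
        # exact realized loadings: noise centered, orthogonal to the
        # factor, unit variance — so mean intra-module correlation of
        # the generated signal sits at within_module_cor, not below it
        eps -= eps.mean(axis=1, keepdims=True)
        eps -= np.outer(eps @ factor / (factor @ factor), factor)
        eps /= eps.std(axis=1, keepdims=True)
        log2x[members] += np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
        idx += config.module_size

    n_bg = config.n_genes - idx
    gene_class = np.array(["background"] * config.n_genes, dtype=object)
    bg_start = idx
    injury_idx = np.arange(bg_start, bg_start + config.n_injury_genes)
    reversal_idx = injury_idx[: config.n_reversal_genes]
    gene_class[injury_idx] = "injury"
    gene_class[reversal_idx] = "reversal"

    # independent biological noise for all non-module genes;
    # housekeeping genes are near-constant
    noise_sd = np.full(n_bg, config.gene_noise_sd)
    if n_stable:
        noise_sd[-n_stable:] = 0.1
    log2x[bg_start:] += noise_sd[:, None] * rng.standard_normal((n_bg, n_samples))

    signs = np.where(np.arange(config.n_injury_genes) % 2 == 0, 1.0, -1.0)
    in_veh = group_of.to_numpy() == veh
    in_trt = group_of.to_numpy() == trt
    shift_veh = signs * config.injury_shift
    is_rev = np.isin(injury_idx, reversal_idx)
    shift_trt = np.where(
        is_rev, shift_veh * (1.0 - config.reversal_fraction), shift_veh
    )
    log2x[injury_idx[:, None], np.where(in_veh)[0][None, :]] += shift_veh[:, None]
    log2x[injury_idx[:, None], np.where(in_trt)[0][None, :]] += shift_trt[:, None]

    intensity = 2.0 ** log2x
    lib = config.library_size * np.exp(rng.normal(0.0, 0.1, size=n_samples))
    expected = intensity / intensity.sum(axis=0, keepdims=True) * lib[None, :]
    counts = rng.poisson(expected)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64)
    truth = {
        "module_label": dict(zip(genes, module_label.tolist())),
        "gene_class": dict(zip(genes, gene_class.tolist())),
        "injury_genes": [genes[i] for i in injury_idx],
        "reversal_genes": [genes[i] for i in reversal_idx],
        "true_shift_vehicle": {
            genes[i]: float(s) for i, s in zip(injury_idx, shift_veh)
        },
        "true_shift_treated": {
            genes[i]: float(s) for i, s in zip(injury_idx, shift_trt)
        },
        "n_modules": config.n_modules,
        "groups": list(config.groups),
    }
    return counts_df, group_of, truth
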