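"""End-to-end pipeline orchestration.

Runs the analysis stages in sequence — synthetic data generation (when
no input files are supplied), Mapper topology with bootstrap consensus,
syndromic PCA with dose-response testing, co-expression module
detection/merging, and differential expression with reversal
classification and optional gene-set enrichment — writing each stage's
tables under the output directory together with a deterministic JSON
manifest (parameters, seeds, SHA-256 of every output).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .containers import ExpressionMatrix, OutcomeMatrix
from .coexpression import (
    NetworkParams,
    compute_kme,
    detect_modules,
    flag_outlier_samples,
    merge_modules,
    module_trait_test,
)
from .de import (
    GeneSetCollection,
    classify_reversal,
    differential_expression,
    geneset_enrichment,
    normalize_counts,
)
from .mapper import MapperConfig, bootstrap_consensus, overlay
from .pca import correlation_pca, retain_components, score_subjects, test_dose_response
from .simulate import ExprSimConfig, TrialSimConfig, simulate_expression, simulate_trial

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "tda", "pca", "modules", "de", "enrich")


@dataclass
class PipelineConfig:
    outdir: str = "syndromics_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # input files; when None the simulate stage provides them
    outcomes_path: str | None = None
    counts_path: str | None = None
    groups_path: str | None = None
    gmt_path: str | None = None
    group_order: tuple = ("sham", "vehicle", "treated")
    treated_arm: str = "sTNFR1"
    trial: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    mapper: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self):
        for st in self.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage {st!r}")
        for p in (self.outcomes_path, self.counts_path, self.groups_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages in order; returns the manifest dict.

    The manifest records the global seed, each stage's parameters and
    the SHA-256 of every file it wrote; identical config + seed yields
    a byte-identical manifest.  A stage failure aborts with the stage
    name while earlier outputs remain on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}

    outcomes: OutcomeMatrix | None = None
    counts = groups = None
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            tcfg = TrialSimConfig(**{"seed": config.seed, **config.trial})
            outcomes, trial_truth = simulate_trial(tcfg)
            sio.write_outcome_table(outcomes, out / "outcomes.csv")
            (out / "trial_truth.json").write_text(
                json.dumps(trial_truth, indent=1, sort_keys=True)
            )
            ecfg = ExprSimConfig(**{"seed": config.seed + 1, **config.expression})
            counts, groups, expr_truth = simulate_expression(ecfg)
            sio.write_counts(counts, out / "counts.tsv")
            sio.write_groups(groups, out / "groups.tsv")
            (out / "expr_truth.json").write_text(
                json.dumps(expr_truth, indent=1, sort_keys=True)
            )
            _record(manifest, "simulate",
                    {"trial": asdict(tcfg), "expression": asdict(ecfg)},
                    [out / "outcomes.csv", out / "trial_truth.json",
                     out / "counts.tsv", out / "groups.tsv",
                     out / "expr_truth.json"])

        if outcomes is None and config.outcomes_path:
            outcomes = sio.read_outcome_table(config.outcomes_path)
        if counts is None and config.counts_path:
            counts = sio.read_counts(config.counts_path)
            groups = sio.read_groups(config.groups_path, counts)

        if "tda" in config.stages:
            stage = "tda"
            if outcomes is None:
                raise ValueError("tda stage needs an outcome table")
            mcfg = MapperConfig(**{"seed": config.seed, **config.mapper})
            cooc, consensus, full = bootstrap_consensus(outcomes, mcfg)
            for var in outcomes.outcomes.columns:
                overlay(consensus, outcomes, var)
            if "arm" in outcomes.metadata.columns:
                for arm in sorted(outcomes.metadata["arm"].unique()):
                    overlay(consensus, outcomes, arm, group_column="arm")
            files = list(sio.write_graph(consensus, out / "mapper_consensus"))
            sio.write_table(cooc.round(6), out / "cooccurrence.tsv", "subject_id")
            files.append(out / "cooccurrence.tsv")
            _record(manifest, "tda", asdict(mcfg), files)

        if "pca" in config.stages:
            stage = "pca"
            if outcomes is None:
                raise ValueError("pca stage needs an outcome table")
            model = retain_components(correlation_pca(outcomes))
            comps = model.retained or [model.loadings.columns[0]]
            scores = score_subjects(model, outcomes, comps)
            sio.write_table(model.loadings, out / "pca_loadings.tsv", "variable")
            eig = pd.DataFrame(
                {"eigenvalue": model.eigenvalues,
                 "variance_explained": model.variance_explained},
                index=model.loadings.columns,
            )
            sio.write_table(eig, out / "pca_eigenvalues.tsv", "component")
            sio.write_table(model.retention_audit, out / "pca_retention_audit.tsv",
                            "component")
            sio.write_table(scores, out / "pca_scores.tsv", "subject_id")
            files = [out / "pca_loadings.tsv", out / "pca_eigenvalues.tsv",
                     out / "pca_retention_audit.tsv", out / "pca_scores.tsv"]
            meta = outcomes.metadata
            dr_info = {}
            if "arm" in meta.columns and (meta["arm"] == config.treated_arm).any():
                sub = meta["arm"] == config.treated_arm
                pc = comps[0]
                dr = test_dose_response(
                    scores.loc[sub, pc].to_numpy(),
                    meta.loc[sub, "dose"].astype(float).to_numpy(),
                )
                tab = dr.contrasts.drop(columns=["coefficients"]).copy()
                tab.insert(0, "F_omnibus", dr.F)
                tab.insert(1, "p_omnibus", dr.p_omnibus)
                sio.write_table(tab, out / "dose_response.tsv", "contrast")
                files.append(out / "dose_response.tsv")
                dr_info = {"component": pc, "inverted_u": dr.inverted_u,
                           "p_omnibus": dr.p_omnibus}
            _record(manifest, "pca",
                    {"retained": comps, **dr_info}, files)

        expr = None
        if counts is not None and any(s in config.stages for s in ("modules", "de", "enrich")):
            logx = normalize_counts(counts)
            expr = ExpressionMatrix(values=logx, groups=groups)

        de_tables = {}
        if "modules" in config.stages:
            stage = "modules"
            if expr is None:
                raise ValueError("modules stage needs counts + groups")
            params = NetworkParams(**config.network)
            outliers = flag_outlier_samples(expr, params.outlier_z)
            kept = [s for s in expr.sample_ids if s not in outliers]
            expr_kept = ExpressionMatrix(expr.values[kept], expr.groups[kept])
            pre = detect_modules(expr_kept, params)
            mods = merge_modules(pre, expr_kept, params.merge_threshold)
            kme = compute_kme(expr_kept, mods.eigengenes)
            assign = pd.DataFrame({"module": mods.labels})
            assign["kme_own"] = [
                kme.at[g, m] if (m := mods.labels[g]) != "unassigned" else np.nan
                for g in assign.index
            ]
            sio.write_table(assign, out / "module_assignment.tsv", "gene")
            sio.write_table(mods.eigengenes, out / "module_eigengenes.tsv", "module")
            sio.write_table(kme, out / "kme.tsv", "gene")
            mlog = pd.DataFrame(mods.merge_log,
                                columns=["kept", "absorbed", "eigengene_cor"])
            sio.write_table(mlog, out / "merge_log.tsv")
            trait_rows = []
            for m in mods.module_ids:
                res = module_trait_test(mods.eigengenes.loc[m], expr_kept.groups,
                                        tuple(config.group_order))
                trait_rows.append({"module": m, "F": res["F"], "p": res["p"],
                                   "reversion": res["reversion"]})
            trait = pd.DataFrame(trait_rows).set_index("module")
            sio.write_table(trait, out / "module_trait.tsv", "module")
            _record(manifest, "modules",
                    {**asdict(params), "outliers": outliers,
                     "n_modules": len(mods.module_ids)},
                    [out / "module_assignment.tsv", out / "module_eigengenes.tsv",
                     out / "kme.tsv", out / "merge_log.tsv",
                     out / "module_trait.tsv"])

        if "de" in config.stages:
            stage = "de"
            if expr is None:
                raise ValueError("de stage needs counts + groups")
            ref, veh, trt = config.group_order
            veh_ref = differential_expression(expr.values, expr.groups, ref, veh)
            trt_ref = differential_expression(expr.values, expr.groups, ref, trt)
            trt_veh = differential_expression(expr.values, expr.groups, veh, trt)
            rev = classify_reversal(veh_ref, trt_ref)
            deg = trt_veh.copy()
            deg.columns = [f"trt_vs_veh_{c}" for c in deg.columns]
            deg["veh_vs_ref_log2fc"] = veh_ref["log2fc"]
            deg["veh_vs_ref_p_adj"] = veh_ref["p_adj"]
            deg["trt_vs_ref_p_adj"] = trt_ref["p_adj"]
            deg["reversal_class"] = rev
            sio.write_table(deg, out / "deg_table.tsv", "gene")
            de_tables["trt_vs_veh"] = trt_veh
            counts_summary = {
                "n_deg_trt_vs_veh": int(trt_veh["significant"].sum()),
                "n_injury_genes": int(veh_ref["significant"].sum()),
                "n_reversed": int(rev.isin(["partial", "full"]).sum()),
            }
            _record(manifest, "de", counts_summary, [out / "deg_table.tsv"])

        if "enrich" in config.stages and config.gmt_path:
            stage = "enrich"
            if expr is None or "trt_vs_veh" not in de_tables:
                raise ValueError("enrich stage needs the de stage")
            universe = set(expr.gene_ids)
            sets = sio.read_gmt(config.gmt_path, universe)
            coll = GeneSetCollection(sets=sets, universe=universe)
            sig = set(
                de_tables["trt_vs_veh"].index[de_tables["trt_vs_veh"]["significant"]]
            )
            enr = geneset_enrichment(sig, coll)
            sio.write_table(enr, out / "enrichment.tsv", "set")
            _record(manifest, "enrich", {"n_sets": len(coll.sets)},
                    [out / "enrichment.tsv"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _record(manifest: dict, stage: str, params: dict, files) -> None:
    manifest["stages"][stage] = {
        "params": json.loads(json.dumps(params, default=str, sort_keys=True)),
        "outputs": {Path(f).name: _sha256(Path(f)) for f in files},
    }
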