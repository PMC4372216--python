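"""End-to-end pipeline driver: prepare -> build -> weight -> prioritize ->
diff -> modules -> survival, with a machine-readable provenance manifest."""

from __future__ import annotations

import json
import logging
import os
import platform
from datetime import datetime, timezone

import numpy as np

from . import __version__
from .config import RunConfig
from .module_scoring import (
    connected_component_detector,
    compare_module_weights,
    read_modules_tsv,
    score_modules,
    GeneModule,
)
from .network_build import LAYER_TAGS, build_ican, build_single_level
from .network_io import read_edge_tsv
from .omics import OmicsProfiles, discretize
from .prioritize import candidate_significance, cv_auc, rwr
from .survival import ClinicalTable, screen_survival_features

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

STAGES = ("prepare", "build", "weight", "prioritize", "diff", "modules", "survival")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def run_pipeline(config: RunConfig) -> str:
    """Execute every stage in order, writing artifacts under config.outdir.

    Any stage error aborts with the stage name; artifacts written so far are
    kept and listed as partial in the manifest. All randomness flows from
    ``config.rng_seed``, split per stage, so a re-run with the same config is
    byte-identical.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "started": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "stages": {},
    }
    root_seed = np.random.SeedSequence(config.rng_seed)
    stage_seeds = {
        stage: np.random.default_rng(child)
        for stage, child in zip(STAGES, root_seed.spawn(len(STAGES)))
    }

    def finish(stage: str, info: dict) -> None:
        manifest["stages"][stage] = info
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "prepare"
    try:
        profiles = OmicsProfiles.from_dir(config.profiles_dir)
        hbn = read_edge_tsv(config.hbn_path)
        with open(config.seeds_path) as fh:
            seeds = {line.strip() for line in fh if line.strip()}
        finish(stage, {
            "genes": profiles.n_genes,
            "samples": profiles.n_samples,
            "hbn_nodes": hbn.n_nodes,
            "hbn_edges": hbn.n_edges,
            "seeds": len(seeds),
        })

        stage = "build"
        networks = {"ICan": build_ican(
            hbn, profiles, alpha=config.alpha,
            weight_basis=config.weight_basis, bartlett_form=config.bartlett_form,
        )}
        for layer, tag in LAYER_TAGS.items():
            networks[tag] = build_single_level(hbn, profiles, layer)
        finish(stage, {
            name: {"nodes": net.n_nodes, "edges": net.n_edges}
            for name, net in networks.items()
        })

        stage = "weight"
        for name, net in networks.items():
            net.to_tsv(os.path.join(outdir, f"network_{name.lower()}.tsv"))
        finish(stage, {"written": sorted(networks)})

        stage = "prioritize"
        ican = networks["ICan"]
        ranking = rwr(ican, seeds, r=config.restart, tol=config.tol).to_frame()
        table = candidate_significance(
            ican, seeds, n_perm=config.n_perm, rng=stage_seeds[stage],
            r=config.restart, tol=config.tol,
        )
        merged = ranking.merge(
            table[["gene", "empirical_p", "adjusted_p", "candidate"]],
            on="gene", how="left",
        )
        merged.to_csv(os.path.join(outdir, "ranking.tsv"), sep="\t", index=False)
        info = {"candidates": int(table["candidate"].sum())}
        known_in_net = set(seeds) & set(ican.graph.nodes)
        if len(known_in_net) >= config.folds:
            auc = cv_auc(ican, known_in_net, folds=config.folds, rng=stage_seeds[stage],
                         r=config.restart, tol=config.tol)
            info["cv_mean_auc"] = auc["mean_auc"]
            info["cv_max_auc"] = auc["max_auc"]
        finish(stage, info)

        stage = "diff"
        if config.normal_dir:
            import pandas as pd

            from .single_level import differential_expression, differential_methylation

            normal = OmicsProfiles.from_dir(config.normal_dir)
            tumor_expr = pd.DataFrame(
                profiles.expression, index=profiles.genes, columns=profiles.samples
            )
            normal_expr = pd.DataFrame(
                normal.expression, index=normal.genes, columns=normal.samples
            ).reindex(profiles.genes)
            de = differential_expression(
                tumor_expr, normal_expr, fc_min=config.fc_min,
                fdr_max=config.expr_fdr, rng=stage_seeds[stage],
            )
            de.to_csv(os.path.join(outdir, "diff_expression.tsv"), sep="\t")
            tumor_meth = pd.DataFrame(
                profiles.methylation, index=profiles.genes, columns=profiles.samples
            )
            normal_meth = pd.DataFrame(
                normal.methylation, index=normal.genes, columns=normal.samples
            ).reindex(profiles.genes)
            dm = differential_methylation(tumor_meth, normal_meth, fdr_max=config.meth_fdr)
            dm.to_csv(os.path.join(outdir, "diff_methylation.tsv"), sep="\t")
            finish(stage, {
                "de_significant": int(de["significant"].sum()),
                "dm_significant": int(dm["significant"].sum()),
            })
        else:
            finish(stage, {"status": "skipped (no normal cohort in inputs)"})

        stage = "modules"
        if config.modules_path:
            modules = read_modules_tsv(config.modules_path)
        else:
            comps = connected_component_detector(ican.graph, config.module_cutoff)
            modules = [GeneModule(id=i, members=c) for i, c in enumerate(comps)]
        scores = score_modules(modules, ican)
        scores.to_csv(os.path.join(outdir, "module_scores.tsv"), sep="\t", index=False)
        comparison = compare_module_weights(modules, networks)
        comparison["per_module"].to_csv(
            os.path.join(outdir, "module_weights_by_network.tsv"), sep="\t", index=False
        )
        finish(stage, {"modules": len(modules), "pvalues": comparison["pvalues"]})

        stage = "survival"
        if config.clinical_path:
            clinical = ClinicalTable.from_tsv(config.clinical_path)
            calls = discretize(profiles, beta_low=config.beta_low, beta_high=config.beta_high)
            candidates = table.loc[table["candidate"], "gene"].tolist() or list(
                table["gene"].head(20)
            )
            screen = screen_survival_features(
                calls, clinical, candidates,
                p_max=config.surv_p, fdr_max=config.surv_fdr, min_group=config.min_group,
            )
            screen.to_csv(os.path.join(outdir, "survival_screen.tsv"), sep="\t", index=False)
            finish(stage, {
                "tested": int(len(screen)),
                "significant": int(screen["significant"].sum()) if len(screen) else 0,
            })
        else:
            finish(stage, {"status": "skipped (no clinical table)"})
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
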