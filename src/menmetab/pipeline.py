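"""End-to-end orchestration: normalize -> cluster -> wcna -> enrichment -> survival.

Every stage writes its artifacts under the output directory and appends
to a run manifest holding parameters, per-stage seeds, and artifact
checksums, so a run can be re-executed bit-identically from the manifest.
The single configured seed is forked deterministically per stage by
hashing the stage name, so re-running one stage does not perturb the
others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinstats, cluster, enrichment, normalize, wcna
from .containers import ClinicalTable, MetaboliteMatrix
from .io import (read_clinical_table, read_metabolite_table,
                 write_metabolite_table)

log = logging.getLogger("menmetab")


@dataclass
class PipelineConfig:
    matrix_path: str
    clinical_path: str | None = None
    out_dir: str = "menmetab_out"
    top_n: int = 100
    k_min: int = 2
    k_max: int = 12
    pseudocount: float = 1.0
    beta_min: int = 1
    beta_max: int = 20
    cut_height: float = 0.75
    min_module_size: int = 5
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage fork of the run seed (stable across runs)."""
    h = zlib.crc32(f"{seed}:{stage}".encode())
    return int(h % (2**31 - 1))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the report bundle (also on disk).

    Raises on the first failing stage (named in the error); artifacts of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": {}}
    report: dict = {}

    matrix = read_metabolite_table(config.matrix_path)
    clinical = (read_clinical_table(config.clinical_path)
                if config.clinical_path else None)
    if clinical is not None:
        clinical = clinical.aligned_to(matrix.sample_ids)

    def record(stage: str, **params) -> None:
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage),
                                     **params}
        log.info("stage %s done (%s)", stage, params)

    def save(name: str, path: Path) -> None:
        manifest["artifacts"][name] = _checksum(path)

    try:
        stage = "normalize"
        normed = normalize.pq_normalize(matrix, pseudocount=config.pseudocount)
        centered = normalize.log2_median_center(normed)
        top = normalize.top_variable(centered,
                                     n=min(config.top_n, centered.n_metabolites))
        p = out / "matrix_top_variable.tsv"
        write_metabolite_table(top, p)
        save("matrix_top_variable", p)
        record(stage, top_n=top.n_metabolites)

        stage = "cluster"
        cres = cluster.select_k(top, k_range=range(config.k_min, config.k_max + 1),
                                seed=stage_seed(config.seed, stage))
        labels = cres.labels
        core_ids = cres.core_sample_ids()
        core = centered.with_values(centered.values.loc[core_ids], centered.state)
        sig = cluster.shrunken_centroid_signature(
            core, labels.loc[core_ids], seed=stage_seed(config.seed, stage))
        glm = cluster.glm_signature(core, labels.loc[core_ids], alpha=config.alpha)
        report["cluster"] = {
            "k_selected": cres.k_selected,
            "cluster_sizes": {str(k): v for k, v in cres.cluster_sizes.items()},
            "mean_silhouette_by_k": cres.mean_silhouette_by_k,
            "n_core": len(core_ids),
            "nsc_signature": sig.signature,
            "nsc_delta": sig.delta,
            "glm_significant": glm.loc[glm["significant"],
                                       "metabolite"].unique().tolist(),
        }
        p = out / "cluster_labels.tsv"
        pd.DataFrame({"cluster": labels, "silhouette": cres.silhouette,
                      "core": cres.core_mask}).to_csv(p, sep="\t")
        save("cluster_labels", p)
        # heatmap-ready matrix: samples ordered by cluster then silhouette
        order = (pd.DataFrame({"c": labels, "s": -cres.silhouette})
                 .sort_values(["c", "s"]).index)
        hp = out / "matrix_heatmap_order.tsv"
        write_metabolite_table(
            top.with_values(top.values.loc[order], top.state), hp)
        save("matrix_heatmap_order", hp)
        record(stage, k_selected=cres.k_selected)

        stage = "subcluster"
        report["subcluster"] = {}
        if cres.k_selected >= 2:
            big = max(cres.cluster_sizes, key=cres.cluster_sizes.get)
            try:
                sub = cluster.subcluster(top, cres, big,
                                         k_range=range(config.k_min,
                                                       config.k_max + 1),
                                         seed=stage_seed(config.seed, stage))
                report["subcluster"] = {
                    "parent_cluster": int(big),
                    "k_selected": sub.k_selected,
                    "sizes": {str(k): v for k, v in sub.cluster_sizes.items()},
                }
            except (ValueError, cluster.DegenerateDataError) as exc:
                report["subcluster"] = {"skipped": str(exc)}
        record(stage)

        stage = "wcna"
        wres = wcna.run_wcna(centered, clinical,
                             beta_grid=range(config.beta_min, config.beta_max + 1),
                             cut_height=config.cut_height,
                             min_size=config.min_module_size)
        module_sizes = wres.module_of.value_counts().to_dict()
        report["wcna"] = {
            "beta": wres.beta,
            "modules": {str(k): int(v) for k, v in module_sizes.items()},
            "hubs": wres.hubs,
        }
        if wres.trait_stats is not None and len(wres.trait_stats):
            p = out / "module_trait_stats.tsv"
            wres.trait_stats.to_csv(p, sep="\t", index=False)
            save("module_trait_stats", p)
            top_assoc = wres.trait_stats.nsmallest(5, "p_adj")
            report["wcna"]["top_trait_associations"] = top_assoc.to_dict("records")
        if len(wres.kme):
            adj = wcna.adjacency_matrix(centered, wres.beta)
            p = out / "network_edges.csv"
            wcna.export_network(adj, wres.module_of, threshold=0.2,
                                graphml_path=out / "network.graphml",
                                edgelist_path=p, kme=wres.kme)
            save("network_edges", p)
        record(stage, beta=wres.beta)

        stage = "enrichment"
        library = enrichment.MetaboliteSetLibrary.builtin().restricted_to(
            centered.metabolite_names)
        sel = report["cluster"]["nsc_signature"] or report["cluster"]["glm_significant"]
        report["enrichment"] = {}
        if sel and len(library.sets):
            ora_res = enrichment.ora(sel, library, centered.metabolite_names)
            report["enrichment"]["ora"] = ora_res.to_dict("records")
            p = out / "enrichment_ora.tsv"
            ora_res.to_csv(p, sep="\t", index=False)
            save("enrichment_ora", p)
        if cres.k_selected == 2 and len(library.sets):
            qea_res = enrichment.qea(centered, labels, library,
                                     n_perm=config.n_perm,
                                     seed=stage_seed(config.seed, stage))
            report["enrichment"]["qea"] = qea_res.to_dict("records")
        record(stage)

        stage = "clinstats"
        if clinical is not None and cres.k_selected == 2:
            table = clinstats.cohort_table(clinical, labels)
            p = out / "cohort_table.tsv"
            table.to_csv(p, sep="\t", index=False)
            save("cohort_table", p)
            report["cohort_table"] = table.to_dict("records")
        record(stage)

        stage = "survival"
        if clinical is not None and cres.k_selected == 2 and \
                {"pfs_time", "pfs_event"} <= set(clinical.data.columns):
            d = clinical.data
            sr = clinstats.log_rank(d["pfs_time"], d["pfs_event"],
                                    labels.loc[d.index])
            report["survival"] = {
                "chi2": sr.chi2, "p": sr.p,
                "observed": {str(k): v for k, v in sr.observed.items()},
                "expected": {str(k): v for k, v in sr.expected.items()},
            }
            for grp, curve in sr.curves.items():
                p = out / f"km_cluster_{grp}.csv"
                curve.to_csv(p, index=False)
                save(f"km_cluster_{grp}", p)
        record(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return report
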