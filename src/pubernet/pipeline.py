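"""End-to-end study orchestration.

``run_study`` executes the whole analysis from one config:

    filter (0.2 RPKM) -> mixed-model normalization -> DE test ->
    network input list (DEx ∪ expressed TFs) -> PCIT co-expression
    network -> hub genes (co-expression ∩ PPI, mean + 2 SD degree) ->
    RIF key regulators (|z| > 1.96) -> gene-set enrichment

Each stage's outputs are written under the output directory,
checksummed into ``manifest.json`` and summarized in ``summary.json``
(number expressed, number DEx and up/down split, network size, hubs,
key TFs, TF-family breakdown).  Stage outputs are pure functions of
(inputs, config, seed); two runs with the same seed produce identical
artifacts.  A stage failure aborts the run with the stage name while
earlier artifacts persist.

``demo_dataset`` writes a complete seeded synthetic study (expression,
metadata, TF list, TF families, PPI, gene sets, truth) so the pipeline
runs offline end-to-end in seconds.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .enrich import hypergeometric_enrichment
from .expression import ExpressionMatrix, filter_expressed, log2_transform, pca_outliers
from .normalize import fit_normalization, test_de
from .pcit import build_input_list, correlation_matrix, pcit_filter, write_edge_list, write_sif
from .regulators import classify_tf_family, find_hubs, key_regulators, rif
from .simulate import (
    SimulationConfig,
    config_to_dict,
    generate_expression,
    generate_gene_sets,
    generate_ppi,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and thresholds for one study run."""

    expression: str  # log2 expression TSV
    metadata: str
    tf_list: str
    ppi: str | None = None
    gene_sets: str | None = None
    tf_families: str | None = None
    out_dir: str = "pubernet_out"
    rpkm_threshold: float = 0.2
    log_offset: float = 0.0  # for re-log2 after the RPKM filter round trip
    de_alpha: float = 0.05
    de_method: str = "welch"
    pooled_correlations: bool = True
    hub_sd_multiplier: float = 2.0
    rif_threshold: float = 1.96
    pca_sd_multiplier: float = 3.0
    drop_pca_outliers: bool = False
    ppi_min_score: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("rpkm_threshold", "de_alpha", "hub_sd_multiplier", "rif_threshold"):
            v = getattr(self, name)
            if not v > 0 and not np.isinf(v):
                raise ValueError(f"{name} must be positive")
        for name in ("expression", "metadata", "tf_list"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {k: v for k, v in vars(config).items()}, "stages": {}}
    summary: dict = {}

    def record(stage: str, files: list[Path], counts: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: {"sha256": _sha256(f)} for f in files},
            "counts": counts,
        }
        logger.info("stage %s done: %s", stage, counts)

    stage = "load"
    try:
        expr = pio.read_expression_tsv(config.expression, scale="log2")
        meta = pio.read_metadata_tsv(config.metadata)
        tf_ids = pio.read_id_list(config.tf_list)
        record(stage, [], {"n_genes": expr.n_genes, "n_samples": expr.n_samples})

        stage = "qc"
        qc = pca_outliers(expr, sd_multiplier=config.pca_sd_multiplier)
        if config.drop_pca_outliers and qc.outliers:
            keep = [s for s in expr.sample_ids if s not in set(qc.outliers)]
            expr = ExpressionMatrix(expr.data[keep], scale="log2")
            meta = meta.loc[keep]
        pio.write_json(
            {"outliers": qc.outliers,
             "variance_explained": list(map(float, qc.variance_explained))},
            out / "qc.json",
        )
        record(stage, [out / "qc.json"], {"n_outliers": len(qc.outliers)})

        stage = "filter"
        rpkm = ExpressionMatrix(2.0**expr.data, scale="rpkm")
        groupings = meta["group"].to_dict()
        kept = filter_expressed(rpkm, groupings, threshold=config.rpkm_threshold)
        expressed = log2_transform(kept, offset=config.log_offset) if kept.n_genes else None
        summary["n_expressed"] = kept.n_genes
        if expressed is not None:
            pio.write_expression_tsv(expressed, out / "expressed_log2.tsv")
            record(stage, [out / "expressed_log2.tsv"], {"n_expressed": kept.n_genes})
        else:
            record(stage, [], {"n_expressed": 0})
            summary.update(
                {"status": "stopped_at_filter",
                 "note": "no gene passed the expression filter"}
            )
            pio.write_json(summary, out / "summary.json")
            pio.write_json(manifest, out / "manifest.json")
            return manifest

        stage = "normalize"
        adjusted, mm = fit_normalization(expressed, meta)
        pio.write_expression_tsv(adjusted, out / "adjusted_log2.tsv")
        record(
            stage,
            [out / "adjusted_log2.tsv"],
            {
                "sigma2_gene": mm.sigma2_gene,
                "sigma2_residual": mm.sigma2_residual,
                "library_dropped": mm.library_dropped,
                "n_iter": mm.n_iter,
            },
        )

        stage = "de"
        groups = meta["group"]
        de = test_de(
            adjusted, groups, alpha=config.de_alpha, method=config.de_method,
            residual_var=mm.sigma2_residual,
        )
        de.to_csv(out / "de.tsv", sep="\t")
        n_dex = int(de["dex_flag"].sum())
        n_up = int((de["dex_flag"] & (de["direction"] == "up")).sum())
        n_down = int((de["dex_flag"] & (de["direction"] == "down")).sum())
        assert n_up + n_down == n_dex
        summary.update({"n_dex": n_dex, "n_up": n_up, "n_down": n_down})
        record(stage, [out / "de.tsv"], {"n_dex": n_dex, "n_up": n_up, "n_down": n_down})

        stage = "pcit"
        expressed_tfs = [t for t in tf_ids if t in set(adjusted.gene_ids)]
        nodes = build_input_list(de, expressed_tfs, adjusted.gene_ids)
        pio.write_id_list(nodes, out / "input_list.txt")
        if config.pooled_correlations:
            corr = correlation_matrix(adjusted, nodes)
        else:  # within-group mean correlation variant
            pre_cols = groups.index[groups == "PRE"]
            post_cols = groups.index[groups == "POST"]
            c1 = correlation_matrix(
                ExpressionMatrix(adjusted.data[list(pre_cols)], scale="log2"), nodes
            )
            c2 = correlation_matrix(
                ExpressionMatrix(adjusted.data[list(post_cols)], scale="log2"), nodes
            )
            avg = (c1.to_numpy() + c2.to_numpy()) / 2.0
            np.fill_diagonal(avg, 1.0)
            corr = pd.DataFrame(avg, index=nodes, columns=nodes)
        res = pcit_filter(corr, with_diagnostics=True)
        coexp = res.network
        write_sif(coexp, str(out / "coexpression.sif"))
        write_edge_list(coexp, str(out / "coexpression_edges.tsv"))
        summary["network_nodes"] = coexp.number_of_nodes()
        summary["network_edges"] = coexp.number_of_edges()
        record(
            stage,
            [out / "coexpression.sif", out / "coexpression_edges.tsv", out / "input_list.txt"],
            {
                "n_nodes": coexp.number_of_nodes(),
                "n_edges": coexp.number_of_edges(),
                "n_degenerate_trios": res.n_degenerate_trios,
            },
        )

        stage = "hubs"
        hubs: set[str] = set()
        if config.ppi:
            ppi = pio.read_ppi_tsv(config.ppi, min_score=config.ppi_min_score)
            hubs = find_hubs(coexp, ppi, sd_multiplier=config.hub_sd_multiplier)
            pio.write_id_list(sorted(hubs), out / "hubs.txt")
            record(stage, [out / "hubs.txt"], {"n_hubs": len(hubs)})
        summary["n_hubs"] = len(hubs)
        summary["hubs"] = sorted(hubs)

        stage = "rif"
        de_ids = de.index[de["dex_flag"]].tolist()
        if de_ids and expressed_tfs:
            scores = rif(adjusted, groups, expressed_tfs, de_ids,
                         threshold=config.rif_threshold)
            scores.to_csv(out / "rif.tsv", sep="\t")
            keys = key_regulators(scores, threshold=config.rif_threshold)
            summary["n_key_tfs"] = len(keys)
            summary["key_tfs"] = sorted(keys)
            record(stage, [out / "rif.tsv"], {"n_key_tfs": len(keys)})
            if config.tf_families:
                fam_df = pd.read_csv(config.tf_families, sep="\t", index_col=0, comment="#")
                fams = classify_tf_family(sorted(keys), fam_df.iloc[:, 0].to_dict())
                fams.to_csv(out / "tf_families.tsv", sep="\t")
                summary["tf_family_counts"] = fams["count"].to_dict()
        else:
            summary["n_key_tfs"] = 0
            summary["key_tfs"] = []

        stage = "enrichment"
        if config.gene_sets and de_ids:
            sets = pio.read_gmt(config.gene_sets)
            enr = hypergeometric_enrichment(
                set(de_ids), set(adjusted.gene_ids), sets
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t")
            summary["n_enriched_sets_05"] = int((enr["adjusted_p"] < 0.05).sum())
            record(stage, [out / "enrichment.tsv"],
                   {"n_sets": len(enr),
                    "n_enriched_sets_05": summary["n_enriched_sets_05"]})

    except StageError:
        raise
    except Exception as exc:  # persist what completed, then abort with stage name
        pio.write_json(manifest, out / "manifest.json")
        raise StageError(stage, exc) from exc

    summary["status"] = "ok"
    pio.write_json(summary, out / "summary.json")
    pio.write_json(manifest, out / "manifest.json")
    return manifest


def demo_dataset(out_dir: str | Path, seed: int = 0,
                 config: SimulationConfig | None = None) -> PipelineConfig:
    """Write a seeded synthetic study to disk; returns a ready
    :class:`PipelineConfig` pointing at the files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # demo star is modest and drawn from the TF block: the pipeline's
    # network covers DEx genes and TFs only, and a dominant star would
    # leak into the per-library means the normalization removes
    sim = config or SimulationConfig(
        seed=seed, hub_degree=20, hub_rho=0.8, hubs_from_tfs=True
    )
    expr, meta, truth = generate_expression(sim)
    ppi = generate_ppi(truth, background_edge_prob=0.01, seed=sim.seed + 1)
    sets = generate_gene_sets(truth, n_sets=10, set_size=15,
                              enriched_overlap=min(10, len(truth.de_gene_ids)),
                              seed=sim.seed + 2)
    pio.write_expression_tsv(expr, out / "expression_log2.tsv")
    pio.write_metadata_tsv(meta, out / "metadata.tsv")
    pio.write_id_list(truth.tf_ids, out / "tf_list.txt")
    pio.write_ppi_tsv(ppi, out / "ppi.tsv")
    pio.write_gmt(sets, out / "gene_sets.gmt")
    fam = pd.DataFrame(
        {"family": ["zf-C2H2" if i % 2 == 0 else "bHLH"
                    for i in range(len(truth.tf_ids))]},
        index=pd.Index(truth.tf_ids, name="tf_id"),
    )
    fam.to_csv(out / "tf_families.tsv", sep="\t")
    pio.write_json(
        {
            "config": config_to_dict(sim),
            "de_gene_ids": truth.de_gene_ids,
            "regulator_ids": truth.regulator_ids,
            "hub_ids": truth.hub_ids,
            "hub_partners": truth.hub_partners,
            "silent_ids": truth.silent_ids,
        },
        out / "truth.json",
    )
    return PipelineConfig(
        expression=str(out / "expression_log2.tsv"),
        metadata=str(out / "metadata.tsv"),
        tf_list=str(out / "tf_list.txt"),
        ppi=str(out / "ppi.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        tf_families=str(out / "tf_families.tsv"),
        out_dir=str(out / "results"),
        seed=sim.seed,
    )
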