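"""End-to-end orchestration: simulate -> DE filter -> DPhospho -> concordance
-> metagene -> ORA / TF clustering -> network, with a run manifest.

A run is driven by a single flat key:value config (YAML). Every threshold and
simulation parameter is addressable; re-running with the same config and seed
reproduces identical stage outputs (the manifest's timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import concordance as conc
from . import diffexpr, enrichment, metagene, network, phospho
from . import io as pio
from . import simulate as sim
from .model import Thresholds, ValidationError

log = logging.getLogger(__name__)

STAGES = ("simulate", "de_filter", "dphospho", "concordance", "metagene",
          "ora", "tf_cluster", "network")


class ConfigError(ValueError):
    """Pipeline configuration violates its schema."""


_SIM_FIELDS = {f.name for f in fields(sim.SimulationConfig)}
_TH_FIELDS = {f.name for f in fields(Thresholds)}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    overwrite: bool = False
    data_dir: str | None = None  # read a written dataset instead of simulating
    reference_mutant_contrast: str = "WT"
    near_zero_band: float = 0.2
    k_gene_clusters: int = 2
    jaccard_collapse: float = 0.75
    top_hubs: int = 10
    sim: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_flat(cls, raw: dict) -> "PipelineConfig":
        own = {f.name for f in fields(cls)} - {"sim", "thresholds"}
        kwargs: dict = {"sim": {}, "thresholds": {}}
        for key, value in raw.items():
            if key in own:
                kwargs[key] = value
            elif key in _SIM_FIELDS:
                kwargs["sim"][key] = value
            elif key in _TH_FIELDS:
                kwargs["thresholds"][key] = value
            else:
                raise ConfigError(f"unknown config field: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key:value mapping")
        return cls.from_flat(raw)

    def build_thresholds(self) -> Thresholds:
        return Thresholds(**self.thresholds)

    def build_sim_config(self) -> sim.SimulationConfig:
        kw = dict(self.sim)
        kw.setdefault("seed", self.seed)
        if "conditions" in kw:
            kw["conditions"] = tuple(kw["conditions"])
        return sim.SimulationConfig(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=pio.FLOAT_FMT)
    return len(df)


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    th = config.build_thresholds()  # pre-flight: validates threshold values

    # pre-flight checks touch no outputs
    if config.data_dir is not None:
        missing = [f for f in sim.DATASET_FILES.values()
                   if not (Path(config.data_dir) / f).exists()]
        if missing:
            raise ConfigError(f"data_dir is missing file(s): {', '.join(missing)}")
        sim_cfg = None
    else:
        sim_cfg = config.build_sim_config()

    out = pio.ensure_outdir(config.out_dir, overwrite=config.overwrite)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "config": {**dataclasses.asdict(config)},
        "stages": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        # ---- simulate / load -------------------------------------------------
        info = stage("simulate")
        if sim_cfg is not None:
            bundle = sim.simulate(sim_cfg)
            data_dir = sim.write_dataset(bundle, out / "data", overwrite=True)
        else:
            data_dir = Path(config.data_dir)
            bundle = sim.read_dataset(data_dir)
        info["input_digests"] = {f: _sha256(data_dir / f)
                                 for f in sorted(sim.DATASET_FILES.values())}
        info["n_proteins"] = len(bundle.proteins.feature_ids)
        info["n_transcripts"] = len(bundle.transcripts.feature_ids)
        info["n_phosphopeptides"] = len(bundle.phosphopeptides.feature_ids)

        design_p, design_r = bundle.design_protein, bundle.design_rna
        mutants = [c for c in design_r.conditions if c not in ("LP", "WT")]

        # ---- differential expression ----------------------------------------
        info = stage("de_filter")
        prot_allmut = diffexpr.standin_test(
            bundle.proteins, design_p,
            diffexpr.contrast_samples(design_p, mutants, "WT"), th)
        prot_wt_lp = diffexpr.standin_test(
            bundle.proteins, design_p,
            diffexpr.contrast_samples(design_p, "WT", "LP"), th)
        rna_allmut = diffexpr.standin_test(
            bundle.transcripts, design_r,
            diffexpr.contrast_samples(design_r, mutants, "WT"), th)
        rna_lp_vs_wt = diffexpr.standin_test(
            bundle.transcripts, design_r,
            diffexpr.contrast_samples(design_r, "LP", "WT"), th)
        rna_per_mut = {m: diffexpr.standin_test(
            bundle.transcripts, design_r,
            diffexpr.contrast_samples(design_r, m, "WT"), th) for m in mutants}

        pio.write_contrast(prot_allmut, out / "protein_allmut_vs_wt.tsv")
        pio.write_contrast(prot_wt_lp, out / "protein_wt_vs_lp.tsv")
        pio.write_contrast(rna_allmut, out / "rna_allmut_vs_wt.tsv")
        pio.write_contrast(rna_lp_vs_wt, out / "rna_lp_vs_wt.tsv")
        for m, res in rna_per_mut.items():
            pio.write_contrast(res, out / f"rna_{m}_vs_wt.tsv")

        dep_report = diffexpr.apply_thresholds(prot_allmut, th)
        deg_report = diffexpr.apply_thresholds(rna_allmut, th)
        per_mut_reports = {m: diffexpr.apply_thresholds(r, th)
                           for m, r in rna_per_mut.items()}
        info["dep_allmut"] = dep_report.to_dict()
        info["deg_allmut"] = deg_report.to_dict()
        info["deg_per_mutant"] = {m: r.to_dict() for m, r in per_mut_reports.items()}

        # ---- differential phosphorylation -----------------------------------
        info = stage("dphospho")
        dph = phospho.run_dphospho(bundle.phosphopeptides, bundle.proteins,
                                   bundle.phospho_records, design_p, th,
                                   mutants=mutants)
        s1_all = pd.concat(dph["strategy1"].values(), ignore_index=True)
        info["strategy1_rows"] = _write_tsv(s1_all, out / "dphospho_strategy1.tsv")
        info["strategy2_rows"] = _write_tsv(dph["strategy2"], out / "dphospho_strategy2.tsv")
        info["consensus_rows"] = _write_tsv(dph["consensus"], out / "dphospho_consensus.tsv")
        if not dph["strategy2"].empty:
            volcano = dph["strategy2"][["peptide_id", "condition", "effect", "p_adj"]].copy()
            volcano["neg_log10_p_adj"] = -np.log10(np.maximum(volcano["p_adj"], 1e-300))
            _write_tsv(volcano, out / "dphospho_volcano.tsv")
        info["n_high_confidence"] = int((dph["consensus"]["confidence"] == "high").sum()) \
            if not dph["consensus"].empty else 0

        # ---- concordance -----------------------------------------------------
        info = stage("concordance")
        deps_passing = [r for r in prot_allmut if r.feature_id in set(dep_report.passing)]
        match = conc.match_features(deps_passing, rna_allmut, bundle.protein_gene_map)
        cres = conc.remove_outliers_and_correlate(match.pairs, th)
        _write_tsv(cres.pairs, out / "concordance_pairs.tsv")
        info.update(cres.summary())
        info["n_unmapped"] = match.n_unmapped

        # ---- metagene --------------------------------------------------------
        info = stage("metagene")
        per_mut_sets = {m: set(r.passing) for m, r in per_mut_reports.items()}
        common, overlap = diffexpr.intersect_degs(per_mut_sets)
        overlap.to_csv(out / "deg_overlap_matrix.tsv", sep="\t")
        info["n_common_degs"] = len(common)
        if common:
            per_gene, subset_tests = metagene.metagene_classify(
                common, rna_per_mut, rna_lp_vs_wt, th, config.near_zero_band)
            _write_tsv(per_gene, out / "metagene_genes.tsv")
            _write_tsv(metagene.violin_table(common, rna_per_mut),
                       out / "metagene_violin.tsv")
            info["subset_tests"] = [dataclasses.asdict(t) for t in subset_tests]
            info["class_counts"] = per_gene["class"].value_counts().to_dict()

        # ---- ORA -------------------------------------------------------------
        info = stage("ora")
        collection = enrichment.GeneSetCollection.from_gmt(bundle.gene_sets)
        universe = set(bundle.transcripts.feature_ids)
        query = set(deg_report.passing)
        ora_df = enrichment.ora(query, collection, universe)
        info["ora_rows"] = _write_tsv(ora_df, out / "ora_results.tsv")
        bubble = enrichment.select_bubble_terms(ora_df, config.jaccard_collapse)
        info["bubble_rows"] = _write_tsv(
            bubble[["set_name", "source_db", "p_adj", "k", "K"]],
            out / "ora_bubble.tsv")

        # ---- TF matrix + clustering -----------------------------------------
        info = stage("tf_cluster")
        expressed = set(bundle.proteins.feature_ids) | set(bundle.transcripts.feature_ids)
        matrix = enrichment.build_tf_matrix(sorted(query), bundle.tf_edges, expressed)
        matrix.cells.to_csv(out / "tf_matrix.tsv", sep="\t")
        cluster = enrichment.two_way_cluster(matrix, config.k_gene_clusters)
        members = cluster.gene_clusters.rename_axis("gene_id").reset_index()
        info["matrix_shape"] = list(matrix.cells.shape)
        info["cluster_rows"] = _write_tsv(members, out / "tf_gene_clusters.tsv")

        # ---- network ---------------------------------------------------------
        info = stage("network")
        dph_parents = set()
        if not dph["consensus"].empty:
            parent_of = dph["normalized"].parent
            dph_parents = {parent_of[p] for p in dph["consensus"]["peptide_id"]
                           if p in parent_of}
        node_sets = {
            "DEP": set(dep_report.passing),
            "DPhospho": dph_parents,
            "TF": set(matrix.cells.columns),
        }
        net = network.build_network(bundle.ppi_edges, node_sets)
        _write_tsv(net.node_table(), out / "network_nodes.tsv")
        _write_tsv(net.edge_table(), out / "network_edges.tsv")
        hubs = network.rank_hubs(net, config.top_hubs)
        _write_tsv(hubs, out / "network_hubs.tsv")
        info["n_nodes"] = net.graph.number_of_nodes()
        info["n_edges"] = net.graph.number_of_edges()
        info["top_hub"] = hubs.iloc[0]["node"] if not hubs.empty else None
    except Exception as exc:
        failed = next((n for n in reversed(list(manifest["stages"])) if True), "?")
        manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise ValidationError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
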