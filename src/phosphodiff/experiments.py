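"""Multi-seed recovery and calibration experiments on synthetic data.

These drive every stage of the pipeline against the generator's planted
ground truth: sensitivity of the differential-phosphorylation strategies,
family-wise error of strategy 2 under a null simulation, concordance
correlation when every DEP has a matching transcript, metagene
gain/loss-of-function recovery, TF-module clustering agreement, and hub
identification. The experiment problem sizes are scaled-down versions of the
default study (same fractions, effect sizes, noise and replicate structure;
fewer features) so that multi-seed loops stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import concordance as conc
from . import diffexpr, enrichment, metagene, network, phospho
from . import simulate as sim
from .model import Thresholds

_TH = Thresholds()


def study_config(seed: int, **overrides) -> sim.SimulationConfig:
    """Scaled-down default study conditions (fractions/effects/noise unchanged)."""
    kw = dict(n_proteins=300, n_transcripts=900, n_phosphopeptides=40,
              n_gof_genes=25, n_lof_genes=25, n_tfs=10, seed=seed)
    kw.update(overrides)
    return sim.SimulationConfig(**kw)


def null_study_config(seed: int, **overrides) -> sim.SimulationConfig:
    kw = dict(n_proteins=120, n_transcripts=300, n_phosphopeptides=25,
              frac_dep=0.0, frac_deg=0.0, frac_dphospho=0.0, frac_concordant=0.0,
              n_gof_genes=0, n_lof_genes=0, n_tfs=6, seed=seed)
    kw.update(overrides)
    return sim.SimulationConfig(**kw)


def _dphospho(bundle: sim.SimulatedBundle, th: Thresholds = _TH) -> dict:
    return phospho.run_dphospho(bundle.phosphopeptides, bundle.proteins,
                                bundle.phospho_records, bundle.design_protein,
                                th, mutants=list(bundle.config.mutants))


@dataclass
class DPhosphoRecovery:
    strategy1_sensitivity: float
    union_sensitivity: float
    consensus_sensitivity: float
    consensus_fdr: float


def dphospho_recovery(seeds: range, th: Thresholds = _TH, **config_overrides
                      ) -> DPhosphoRecovery:
    """Recovery of planted differentially phosphorylated peptides."""
    s1_sens, union_sens, cons_sens, cons_fdr = [], [], [], []
    for seed in seeds:
        b = sim.simulate(study_config(seed, **config_overrides))
        res = _dphospho(b, th)
        planted = set(b.truth.dphospho_ids)
        f1: set[str] = set()
        for df in res["strategy1"].values():
            f1 |= set(df.loc[df["is_outlier"], "peptide_id"])
        s2 = res["strategy2"]
        f2 = set(s2.loc[s2["is_significant"], "peptide_id"])
        cons = res["consensus"]
        both = set(cons.loc[cons["by_strategy1"] & cons["by_strategy2"], "peptide_id"]) \
            if not cons.empty else set()
        s1_sens.append(len(f1 & planted) / len(planted))
        union_sens.append(len((f1 | f2) & planted) / len(planted))
        cons_sens.append(len(both & planted) / len(planted))
        cons_fdr.append(len(both - planted) / max(len(both), 1))
    return DPhosphoRecovery(float(np.mean(s1_sens)), float(np.mean(union_sens)),
                            float(np.mean(cons_sens)), float(np.mean(cons_fdr)))


def strategy2_null_fwe(n_seeds: int, seed0: int = 0, th: Thresholds = _TH) -> float:
    """Fraction of null simulations where Bonferroni-corrected strategy 2
    flags at least one peptide (the family-wise error rate)."""
    hits = 0
    for k in range(n_seeds):
        b = sim.simulate(null_study_config(seed0 + k))
        s2 = _dphospho(b, th)["strategy2"]
        hits += int((not s2.empty) and bool(s2["is_significant"].any()))
    return hits / n_seeds


def strategy1_worked_example() -> dict:
    """Closed-form identities of the normalized-difference statistic."""
    d = lambda a, b: (max(a, b) - min(a, b)) / (a + b)
    return {"d_equal": d(1.7, 1.7), "d_one_three": d(1.0, 3.0)}


def concordant_correlation(seeds: range, th: Thresholds = _TH) -> float:
    """Mean Pearson r when every planted DEP has a same-direction DEG."""
    rs = []
    for seed in seeds:
        b = sim.simulate(study_config(seed, frac_concordant=1.0,
                                      n_gof_genes=10, n_lof_genes=10))
        mutants = list(b.config.mutants)
        prot = diffexpr.standin_test(
            b.proteins, b.design_protein,
            diffexpr.contrast_samples(b.design_protein, mutants, "WT"), th)
        rna = diffexpr.standin_test(
            b.transcripts, b.design_rna,
            diffexpr.contrast_samples(b.design_rna, mutants, "WT"), th)
        rep = diffexpr.apply_thresholds(prot, th)
        deps = [r for r in prot if r.feature_id in set(rep.passing)]
        pairs = conc.match_features(deps, rna, b.protein_gene_map).pairs
        rs.append(conc.remove_outliers_and_correlate(pairs, th).r)
    return float(np.mean(rs))


@dataclass
class MetageneRecovery:
    gof_sensitivity: float
    lof_sensitivity: float
    cross_contamination: int
    worst_down_p: float
    worst_up_p: float


def metagene_recovery(seeds: range, th: Thresholds = _TH) -> MetageneRecovery:
    gof_s, lof_s, cross = [], [], 0
    down_p, up_p = [], []
    for seed in seeds:
        b = sim.simulate(study_config(seed))
        mutants = list(b.config.mutants)
        contrasts, deg_sets = {}, {}
        for m in mutants:
            res = diffexpr.standin_test(
                b.transcripts, b.design_rna,
                diffexpr.contrast_samples(b.design_rna, m, "WT"), th)
            contrasts[m] = res
            deg_sets[m] = set(diffexpr.apply_thresholds(res, th).passing)
        common, _ = diffexpr.intersect_degs(deg_sets)
        lp = diffexpr.standin_test(
            b.transcripts, b.design_rna,
            diffexpr.contrast_samples(b.design_rna, "LP", "WT"), th)
        per_gene, tests = metagene.metagene_classify(common, contrasts, lp, th)
        gof, lof = set(b.truth.gof_gene_ids), set(b.truth.lof_gene_ids)
        called_gof = set(per_gene.loc[per_gene["class"] == "GoF", "gene_id"])
        called_lof = set(per_gene.loc[per_gene["class"] == "LoF", "gene_id"])
        gof_s.append(len(called_gof & gof) / len(gof))
        lof_s.append(len(called_lof & lof) / len(lof))
        cross += len(called_gof & lof) + len(called_lof & gof)
        by_name = {t.subset: t for t in tests if t.computable}
        if "down" in by_name:
            down_p.append(by_name["down"].p_mut_vs_wt)
        if "up" in by_name:
            up_p.append(by_name["up"].p_mut_vs_wt)
    return MetageneRecovery(float(np.mean(gof_s)), float(np.mean(lof_s)), cross,
                            float(np.max(down_p)), float(np.max(up_p)))


def tf_cluster_ari(seeds: range, th: Thresholds = _TH) -> float:
    """Adjusted Rand index between the 2-cut gene clustering and the two
    planted TF-module gene groups."""
    aris = []
    for seed in seeds:
        b = sim.simulate(study_config(seed))
        mutants = list(b.config.mutants)
        rna = diffexpr.standin_test(
            b.transcripts, b.design_rna,
            diffexpr.contrast_samples(b.design_rna, mutants, "WT"), th)
        degs = diffexpr.apply_thresholds(rna, th).passing
        expressed = set(b.proteins.feature_ids) | set(b.transcripts.feature_ids)
        matrix = enrichment.build_tf_matrix(degs, b.tf_edges, expressed)
        labels = enrichment.two_way_cluster(matrix, 2).gene_clusters
        truth = b.truth.gene_modules
        keep = [g for g in labels.index if g in truth]
        aris.append(adjusted_rand_score([truth[g] for g in keep],
                                        labels.loc[keep].tolist()))
    return float(np.mean(aris))


def hub_top1_rate(seeds: range) -> float:
    hits = 0
    for seed in seeds:
        b = sim.simulate(study_config(seed))
        node_sets = {
            "DEP": set(b.truth.dep_directions),
            "DPhospho": {r.parent_protein_id for r in b.phospho_records},
            "TF": set(b.truth.tf_module_assignments),
        }
        net = network.build_network(b.ppi_edges, node_sets)
        hits += int(network.rank_hubs(net, 1).iloc[0]["node"] == b.truth.hub_id)
    return hits / len(list(seeds))
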