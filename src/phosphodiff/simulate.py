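"""Synthetic paired proteome / phosphoproteome / transcriptome generator.

Emulates the structure of a label-free MS + RNA-Seq experiment over a control
line (LP), a WT-transgene line and five activating-variant lines, with a
planted ground truth for every effect the downstream analysis is designed to
detect:

* differentially expressed proteins (DEPs) shifted in the mutant conditions;
* differentially expressed genes (DEGs), a configurable fraction of which are
  concordant (same direction) with a planted DEP of the matching gene;
* gain-of-function genes (up in mutants only) and loss-of-function genes
  (up in WT relative to both LP and the mutants);
* phosphopeptides whose phosphorylation changes independently of their parent
  protein (the signal both differential-phosphorylation strategies target),
  while every other phosphopeptide tracks its parent exactly up to noise;
* a TF->target bipartite graph with two planted co-regulated modules; and
* a PPI network with one designated hub of maximal degree.

Abundances are log-normal (log2 mean 20, sd 2 for proteins) with
multiplicative replicate noise of a stated coefficient of variation; all
randomness flows from a single seed, so identical configs give bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .model import (
    AbundanceTable,
    PhosphopeptideRecord,
    SampleDesign,
    ValidationError,
)

MUTANT_CONDITIONS = ("T1", "T5", "T12", "T15", "Q79KW80R")
DEFAULT_CONDITIONS = ("LP", "WT") + MUTANT_CONDITIONS


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 2000
    n_transcripts: int = 5000
    n_phosphopeptides: int = 60
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates: int = 3
    wt_protein_replicates: int = 4
    frac_dep: float = 0.1
    frac_deg: float = 0.1
    frac_dphospho: float = 0.25
    effect_log2: float = 2.0
    cv_noise: float = 0.2
    frac_concordant: float = 0.2
    n_gof_genes: int = 40
    n_lof_genes: int = 40
    n_tfs: int = 29
    missing_rate: float = 0.0
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dep", "frac_deg", "frac_dphospho", "frac_concordant", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.replicates < 2 or self.wt_protein_replicates < 2:
            raise ConfigError("every tested condition needs >= 2 replicates")
        if len(self.conditions) < 3 or self.conditions[0] != "LP" or self.conditions[1] != "WT":
            raise ConfigError("conditions must start with LP, WT and include >= 1 mutant")
        if self.n_transcripts < self.n_proteins:
            raise ConfigError("n_transcripts must be >= n_proteins (1:1 protein->gene mapping)")
        if self.cv_noise <= 0:
            raise ConfigError("cv_noise must be > 0")

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(self.conditions[2:])

    @property
    def noise_sd_log2(self) -> float:
        # CV of a log-normal: cv^2 = exp(sigma_ln^2) - 1
        return math.sqrt(math.log1p(self.cv_noise**2)) / math.log(2)


@dataclass
class GroundTruth:
    """Ledger of every planted effect, keyed by feature identifier."""

    dep_directions: dict[str, int] = field(default_factory=dict)
    deg_directions: dict[str, int] = field(default_factory=dict)
    dphospho_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    gof_gene_ids: list[str] = field(default_factory=list)
    lof_gene_ids: list[str] = field(default_factory=list)
    tf_module_assignments: dict[str, int] = field(default_factory=dict)
    gene_modules: dict[str, int] = field(default_factory=dict)
    hub_id: str = ""

    def __post_init__(self) -> None:
        if set(self.gof_gene_ids) & set(self.lof_gene_ids):
            raise ValidationError("gain- and loss-of-function gene sets must be disjoint")

    @property
    def dphospho_ids(self) -> list[str]:
        return sorted(self.dphospho_effects)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    design_protein: SampleDesign
    design_rna: SampleDesign
    proteins: AbundanceTable
    phosphopeptides: AbundanceTable
    transcripts: AbundanceTable
    phospho_records: list[PhosphopeptideRecord]
    protein_gene_map: dict[str, str]
    tf_edges: list[tuple[str, str]]
    ppi_edges: list[tuple[str, str]]
    gene_sets: dict[str, dict]
    truth: GroundTruth


def _make_design(conditions, replicates, wt_reps, prefix) -> SampleDesign:
    rows = []
    for cond in conditions:
        n = wt_reps if (cond == "WT" and wt_reps is not None) else replicates
        for r in range(1, n + 1):
            rows.append((f"{prefix}_{cond}_{r}", cond, r))
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]),
                        reference="LP")


def _abundance_matrix(rng, base_log2, offsets, design, sd) -> pd.DataFrame:
    """base_log2: (n_feat,), offsets: dict cond -> (n_feat,) additive log2 shift."""
    cols = {}
    for sid, cond in zip(design.table["sample_id"], design.table["condition"]):
        shift = offsets.get(cond)
        mu = base_log2 if shift is None else base_log2 + shift
        cols[sid] = np.exp2(mu + rng.normal(0.0, sd, size=base_log2.size))
    return pd.DataFrame(cols, index=None)


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Generate one complete paired dataset with its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd_log2
    eff = config.effect_log2
    mutants = list(config.mutants)

    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    genes = [f"G{i:05d}" for i in range(config.n_transcripts)]
    mapping = dict(zip(proteins, genes[: config.n_proteins]))

    truth = GroundTruth()

    # ---- planted DEPs -----------------------------------------------------
    # directions are balanced exactly and magnitudes jittered around
    # effect_log2: real fold-change distributions are continuous, and a
    # point-mass at +/-effect would make robust (median/MAD) screens treat
    # whole effect groups as a single outlying mode
    n_dep = round(config.frac_dep * config.n_proteins)
    dep_ids = list(rng.choice(proteins, size=n_dep, replace=False))
    dep_dirs = np.ones(n_dep, dtype=int)
    dep_dirs[: n_dep // 2] = -1
    dep_dirs = dep_dirs[rng.permutation(n_dep)]
    dep_mags = eff * rng.uniform(0.75, 1.25, size=n_dep)
    truth.dep_directions = {p: int(d) for p, d in zip(dep_ids, dep_dirs)}
    dep_shift_of = {p: float(d * u) for p, d, u in zip(dep_ids, dep_dirs, dep_mags)}

    # ---- planted DEGs: concordant, GoF, LoF, generic ----------------------
    n_conc = round(config.frac_concordant * n_dep)
    conc_deps = dep_ids[:n_conc]  # dep_ids already in random order
    conc_genes = {mapping[p]: truth.dep_directions[p] for p in conc_deps}
    # a concordant DEG shares its DEP's signed shift (same underlying regulation)
    conc_gene_shift = {mapping[p]: dep_shift_of[p] for p in conc_deps}

    n_deg = round(config.frac_deg * config.n_transcripts)
    n_special = n_conc + config.n_gof_genes + config.n_lof_genes
    if n_deg < n_special:
        raise ConfigError(
            f"DEG budget {n_deg} smaller than concordant+GoF+LoF genes ({n_special}); "
            "raise frac_deg or n_transcripts"
        )
    dep_genes = {mapping[p] for p in dep_ids}
    free_genes = [g for g in genes if g not in dep_genes]
    picked = rng.choice(free_genes, size=n_deg - n_conc, replace=False)
    gof = list(picked[: config.n_gof_genes])
    lof = list(picked[config.n_gof_genes: config.n_gof_genes + config.n_lof_genes])
    generic = list(picked[config.n_gof_genes + config.n_lof_genes:])
    half = len(generic) // 2
    generic_up, generic_down = generic[:half], generic[half:]

    truth.gof_gene_ids = sorted(gof)
    truth.lof_gene_ids = sorted(lof)
    # direction = sign of the mutant-vs-WT log2FC
    truth.deg_directions = {
        **conc_genes,
        **{g: 1 for g in gof},
        **{g: -1 for g in lof},
        **{g: 1 for g in generic_up},
        **{g: -1 for g in generic_down},
    }
    up_group = sorted(set(gof) | set(generic_up) | {g for g, d in conc_genes.items() if d > 0})
    down_group = sorted(set(lof) | set(generic_down) | {g for g, d in conc_genes.items() if d < 0})
    truth.gene_modules = {**{g: 1 for g in down_group}, **{g: 2 for g in up_group}}

    # ---- designs ----------------------------------------------------------
    design_protein = _make_design(config.conditions, config.replicates,
                                  config.wt_protein_replicates, "MS")
    design_rna = _make_design(config.conditions, config.replicates, None, "RNA")

    # ---- protein table ----------------------------------------------------
    prot_base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                           size=config.n_proteins)
    prot_idx = {p: i for i, p in enumerate(proteins)}
    prot_shift = np.zeros(config.n_proteins)
    for p, s in dep_shift_of.items():
        prot_shift[prot_idx[p]] = s
    prot_offsets = {m: prot_shift for m in mutants}
    prot_values = _abundance_matrix(rng, prot_base, prot_offsets, design_protein, sd)
    prot_values.index = proteins
    prot_values.index.name = "feature_id"

    # ---- transcript table -------------------------------------------------
    rna_base = rng.normal(10.0, 2.0, size=config.n_transcripts)
    gene_idx = {g: i for i, g in enumerate(genes)}
    mut_shift = np.zeros(config.n_transcripts)
    deg_mag = {g: float(eff * rng.uniform(0.75, 1.25))
               for g in sorted(truth.deg_directions)}
    for g, d in truth.deg_directions.items():
        if g in truth.lof_gene_ids:
            continue  # handled via the WT offset below
        mut_shift[gene_idx[g]] = conc_gene_shift.get(g, d * deg_mag[g])
    wt_shift = np.zeros(config.n_transcripts)
    for g in truth.lof_gene_ids:
        # LoF: activated by WT only -> WT sits above the LP/mutant baseline,
        # giving mutant-vs-WT = LP-vs-WT = -shift
        wt_shift[gene_idx[g]] = deg_mag[g]
    # offsets are expressed on the common LP baseline
    rna_offsets = {"WT": wt_shift}
    for m in mutants:
        rna_offsets[m] = mut_shift
    rna_values = _abundance_matrix(rng, rna_base, rna_offsets, design_rna, sd)
    rna_values.index = genes
    rna_values.index.name = "feature_id"

    # ---- phosphopeptides --------------------------------------------------
    n_pp = config.n_phosphopeptides
    n_dph = round(config.frac_dphospho * n_pp)
    peptide_ids = [f"pep{i:04d}" for i in range(n_pp)]
    non_dep = [p for p in proteins if p not in truth.dep_directions]
    planted_parents = list(rng.choice(non_dep, size=n_dph, replace=False))
    # the remaining peptides track their parents; draw half the parents from
    # DEPs so protein-level normalization is genuinely exercised
    n_rest = n_pp - n_dph
    n_on_dep = min(len(dep_ids), n_rest // 2)
    rest_parents = list(rng.choice(dep_ids, size=n_on_dep, replace=False)) + list(
        rng.choice(non_dep, size=n_rest - n_on_dep, replace=False)
    )
    parents = planted_parents + rest_parents
    order = rng.permutation(n_pp)
    parents = [parents[i] for i in order]
    planted_flags = np.array([True] * n_dph + [False] * n_rest)[order]

    stoich = rng.uniform(-3.0, -1.0, size=n_pp)  # log2 site stoichiometry
    residues = rng.choice(["S", "T", "Y"], size=n_pp)
    positions = rng.integers(5, 400, size=n_pp)
    records = []
    for k, pid in enumerate(peptide_ids):
        score = float(rng.uniform(60, 100)) if planted_flags[k] else float(rng.uniform(35, 100))
        records.append(PhosphopeptideRecord(
            peptide_id=pid,
            parent_protein_id=parents[k],
            site_descriptor=f"{residues[k]}{positions[k]}",
            ptmrs_score=round(score, 2),
        ))

    dph_shift = {}  # peptide -> {condition: log2 shift}
    for k, pid in enumerate(peptide_ids):
        if not planted_flags[k]:
            continue
        n_cond = int(rng.integers(2, len(mutants) + 1))
        chosen = sorted(rng.choice(mutants, size=n_cond, replace=False))
        dph_shift[pid] = {c: eff for c in chosen}
    truth.dphospho_effects = dph_shift

    pep_cols = {}
    cond_of = dict(zip(design_protein.table["sample_id"], design_protein.table["condition"]))
    for sid in design_protein.sample_ids:
        cond = cond_of[sid]
        parent_vals = prot_values.loc[parents, sid].to_numpy()
        shift = np.array([dph_shift.get(pid, {}).get(cond, 0.0) for pid in peptide_ids])
        noise = rng.normal(0.0, sd, size=n_pp)
        pep_cols[sid] = parent_vals * np.exp2(stoich + shift + noise)
    pep_values = pd.DataFrame(pep_cols, index=peptide_ids)
    pep_values.index.name = "feature_id"

    # ---- optional MCAR missingness ---------------------------------------
    if config.missing_rate > 0:
        for frame in (prot_values, pep_values):
            mask = rng.random(frame.shape) < config.missing_rate
            frame.mask(pd.DataFrame(mask, index=frame.index, columns=frame.columns),
                       inplace=True)

    # ---- TF -> target edges with two planted modules ----------------------
    tf_pool = [p for p in non_dep if p not in set(parents)]
    tf_ids = sorted(rng.choice(tf_pool, size=config.n_tfs, replace=False))
    half_tf = config.n_tfs // 2
    module_of_tf = {tf: (1 if i < half_tf else 2) for i, tf in enumerate(tf_ids)}
    truth.tf_module_assignments = module_of_tf
    tf_edges: list[tuple[str, str]] = []
    for tf in tf_ids:
        own = down_group if module_of_tf[tf] == 1 else up_group
        other = up_group if module_of_tf[tf] == 1 else down_group
        for g in own:
            if rng.random() < 0.8:
                tf_edges.append((tf, g))
        for g in other:
            if rng.random() < 0.05:
                tf_edges.append((tf, g))
    # one unexpressed TF exercises the expression filter downstream
    ghost = "TF_unexpressed"
    for g in list(down_group[:3]) + list(up_group[:3]):
        tf_edges.append((ghost, g))

    # ---- PPI network with a designated hub --------------------------------
    ppi_nodes = sorted(set(dep_ids) | set(parents) | set(tf_ids))
    hub = ppi_nodes[int(rng.integers(0, len(ppi_nodes)))]
    truth.hub_id = hub
    ppi_edges: set[tuple[str, str]] = set()
    n_nodes = len(ppi_nodes)
    p_edge = min(0.03, 8.0 / max(n_nodes, 1))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                ppi_edges.add((ppi_nodes[i], ppi_nodes[j]))
    targets = rng.choice([n for n in ppi_nodes if n != hub],
                         size=max(1, int(0.5 * n_nodes)), replace=False)
    for t in targets:
        a, b = sorted((hub, t))
        ppi_edges.add((a, b))
    ppi_edge_list = sorted(ppi_edges)

    # ---- gene sets (GMT) ---------------------------------------------------
    gene_sets: dict[str, dict] = {}
    if down_group:
        gene_sets["planted_down_response"] = {
            "description": "go_bp", "members": set(down_group)}
    if up_group:
        gene_sets["planted_up_response"] = {
            "description": "bioplanet", "members": set(up_group)}
    for s in range(6):
        size = int(rng.integers(20, 60))
        members = set(rng.choice(genes, size=size, replace=False))
        gene_sets[f"random_set_{s:02d}"] = {
            "description": "go_bp" if s % 2 == 0 else "bioplanet", "members": members}

    return SimulatedBundle(
        config=config,
        design_protein=design_protein,
        design_rna=design_rna,
        proteins=AbundanceTable(prot_values, "protein"),
        phosphopeptides=AbundanceTable(pep_values, "phosphopeptide"),
        transcripts=AbundanceTable(rna_values, "transcript"),
        phospho_records=records,
        protein_gene_map=mapping,
        tf_edges=tf_edges,
        ppi_edges=ppi_edge_list,
        gene_sets=gene_sets,
        truth=truth,
    )


DATASET_FILES = {
    "design_protein": "design_protein.tsv",
    "design_rna": "design_rna.tsv",
    "proteins": "proteins.tsv",
    "phosphopeptides": "phosphopeptides.tsv",
    "transcripts": "transcripts.tsv",
    "phospho_records": "phospho_records.tsv",
    "mapping": "protein_gene_map.tsv",
    "tf_edges": "tf_edges.tsv",
    "ppi_edges": "ppi_edges.tsv",
    "gene_sets": "gene_sets.gmt",
    "truth": "ground_truth.json",
    "config": "sim_config.json",
}


def write_dataset(bundle: SimulatedBundle, directory: str | Path, overwrite: bool = False) -> Path:
    """Write every table of a simulated bundle in the pipeline's file formats."""
    d = pio.ensure_outdir(directory, overwrite=overwrite)
    f = DATASET_FILES
    pio.write_design(bundle.design_protein, d / f["design_protein"])
    pio.write_design(bundle.design_rna, d / f["design_rna"])
    pio.write_abundance(bundle.proteins, d / f["proteins"])
    pio.write_abundance(bundle.phosphopeptides, d / f["phosphopeptides"])
    pio.write_abundance(bundle.transcripts, d / f["transcripts"])
    pio.write_phospho_records(bundle.phospho_records, d / f["phospho_records"])
    pio.write_mapping(bundle.protein_gene_map, d / f["mapping"])
    pio.write_edge_list(bundle.tf_edges, d / f["tf_edges"], cols=("tf_id", "target_gene_id"))
    pio.write_edge_list(bundle.ppi_edges, d / f["ppi_edges"])
    pio.write_gmt(bundle.gene_sets, d / f["gene_sets"])
    (d / f["truth"]).write_text(bundle.truth.to_json())
    (d / f["config"]).write_text(json.dumps(dataclasses.asdict(bundle.config), indent=1))
    return d


def read_dataset(directory: str | Path) -> SimulatedBundle:
    d = Path(directory)
    f = DATASET_FILES
    cfg = json.loads((d / f["config"]).read_text())
    cfg["conditions"] = tuple(cfg["conditions"])
    return SimulatedBundle(
        config=SimulationConfig(**cfg),
        design_protein=pio.read_design(d / f["design_protein"], reference="LP"),
        design_rna=pio.read_design(d / f["design_rna"], reference="LP"),
        proteins=pio.read_abundance(d / f["proteins"], "protein"),
        phosphopeptides=pio.read_abundance(d / f["phosphopeptides"], "phosphopeptide"),
        transcripts=pio.read_abundance(d / f["transcripts"], "transcript"),
        phospho_records=pio.read_phospho_records(d / f["phospho_records"]),
        protein_gene_map=pio.read_mapping(d / f["mapping"]),
        tf_edges=pio.read_edge_list(d / f["tf_edges"]),
        ppi_edges=pio.read_edge_list(d / f["ppi_edges"]),
        gene_sets=pio.read_gmt(d / f["gene_sets"]),
        truth=GroundTruth.from_json((d / f["truth"]).read_text()),
    )
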