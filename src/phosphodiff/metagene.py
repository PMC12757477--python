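"""Metagene gain/loss-of-function classification of common DEGs.

For the genes differentially expressed in *every* mutant-vs-WT contrast, the
per-gene mutant log2 fold changes are averaged and compared with the gene's
LP-vs-WT fold change:

* **loss of function (LoF)** — the gene is down in the mutants relative to WT
  and also down in LP relative to WT: WT activates it and the mutants have
  lost that activation;
* **gain of function (GoF)** — the gene is up in the mutants while WT leaves
  it at the control (LP) level: activation is specific to the mutant forms.

Each subset (down- and up-regulated) is additionally tested as an aggregate:
one-sample t-tests of its mutant-vs-WT means and of its LP-vs-WT fold changes
against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ContrastResult, Thresholds, ValidationError

log = logging.getLogger(__name__)


@dataclass
class SubsetTest:
    subset: str  # "down" or "up"
    n_genes: int
    mean_mut_vs_wt: float
    p_mut_vs_wt: float
    mean_lp_vs_wt: float
    p_lp_vs_wt: float
    computable: bool


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t against 0; zero-variance input gives p = 1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.allclose(values, values[0]):
        return 1.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def metagene_classify(
    common_degs: set[str],
    mutant_contrasts: dict[str, list[ContrastResult]],
    lp_contrast: list[ContrastResult],
    th: Thresholds = Thresholds(),
    near_zero_band: float = 0.2,
) -> tuple[pd.DataFrame, list[SubsetTest]]:
    """Classify common DEGs as LoF / GoF / unclassified and test both subsets.

    The per-gene mean over mutant contrasts is unweighted. A gene's LP-vs-WT
    effect counts as real only when it is both statistically significant
    (adjusted p < alpha) and at least ``near_zero_band`` in magnitude; a pure
    magnitude band would misread ordinary estimation noise on truly
    unaffected genes as an LP effect. Genes fitting neither pattern are
    unclassified. Classification is invariant to the order of the mutant
    contrasts (only the mean enters).
    """
    if not common_degs:
        raise ValidationError("empty common DEG set")
    if not mutant_contrasts:
        raise ValidationError("no mutant contrasts supplied")
    lp = {r.feature_id: r for r in lp_contrast}
    per_mut = {m: {r.feature_id: r.log2fc for r in res}
               for m, res in mutant_contrasts.items()}
    for m, table in per_mut.items():
        absent = [g for g in common_degs if g not in table]
        if absent:
            raise ValidationError(
                f"gene(s) missing from contrast {m!r}: {', '.join(sorted(absent)[:5])}")
    absent_lp = [g for g in common_degs if g not in lp]
    if absent_lp:
        raise ValidationError(
            f"gene(s) missing from LP contrast: {', '.join(sorted(absent_lp)[:5])}")

    rows = []
    for gene in sorted(common_degs):
        mut_fcs = [per_mut[m][gene] for m in mutant_contrasts]
        mean_mut = float(np.mean(mut_fcs))
        lp_res = lp[gene]
        lp_fc = lp_res.log2fc
        lp_changed = lp_res.p_adj < th.alpha_adj and abs(lp_fc) >= near_zero_band
        if mean_mut < 0 and lp_changed and lp_fc < 0:
            cls = "LoF"
        elif mean_mut > 0 and not lp_changed:
            cls = "GoF"
        else:
            cls = "unclassified"
        rows.append({
            "gene_id": gene,
            "mean_log2fc_mut_vs_wt": mean_mut,
            "log2fc_lp_vs_wt": lp_fc,
            "class": cls,
        })
    per_gene = pd.DataFrame(rows)

    subset_tests = []
    for name, mask in (("down", per_gene["mean_log2fc_mut_vs_wt"] < 0),
                       ("up", per_gene["mean_log2fc_mut_vs_wt"] > 0)):
        sub = per_gene.loc[mask]
        if len(sub) < 3:
            log.warning("metagene: %s-subset has %d gene(s); test not computable",
                        name, len(sub))
            subset_tests.append(SubsetTest(name, len(sub), float("nan"), float("nan"),
                                           float("nan"), float("nan"), computable=False))
            continue
        mut_vals = sub["mean_log2fc_mut_vs_wt"].to_numpy()
        lp_vals = sub["log2fc_lp_vs_wt"].to_numpy()
        subset_tests.append(SubsetTest(
            subset=name,
            n_genes=int(len(sub)),
            mean_mut_vs_wt=float(mut_vals.mean()),
            p_mut_vs_wt=_one_sample_p(mut_vals),
            mean_lp_vs_wt=float(lp_vals.mean()),
            p_lp_vs_wt=_one_sample_p(lp_vals),
            computable=True,
        ))
    return per_gene, subset_tests


def violin_table(common_degs: set[str],
                 mutant_contrasts: dict[str, list[ContrastResult]]) -> pd.DataFrame:
    """One row per gene x mutant contrast, for violin-style plotting."""
    rows = []
    for m, res in mutant_contrasts.items():
        fc = {r.feature_id: r.log2fc for r in res}
        for g in sorted(common_degs):
            if g in fc:
                rows.append({"gene_id": g, "contrast": m, "log2fc": fc[g]})
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc"])
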