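"""Proteome–transcriptome fold-change concordance.

Matches differentially expressed proteins to their transcripts through an
explicit protein->gene mapping, removes robust outliers on either axis with
the Iglewicz–Hoaglin modified Z-score (threshold 3.5 by default), and reports
the Pearson correlation of the surviving fold-change pairs together with the
count of same-direction changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ContrastResult, Thresholds, ValidationError
from .phospho import modified_zscore

log = logging.getLogger(__name__)


@dataclass
class MatchReport:
    pairs: pd.DataFrame  # protein_id, gene_id, log2fc_protein, log2fc_rna, same_direction
    n_unmapped: int
    n_unmeasured: int


def match_features(
    deps: list[ContrastResult],
    degs: list[ContrastResult],
    mapping: dict[str, str],
) -> MatchReport:
    """Pair each DEP with its measured transcript via the explicit mapping.

    DEPs without a mapping entry, and DEPs whose mapped gene is absent from
    the transcript results, are counted but excluded. ``same_direction`` is
    False whenever either fold change is exactly zero (zero has no sign).
    """
    if not mapping:
        raise ValidationError("empty protein->gene mapping")
    rna_fc = {r.feature_id: r.log2fc for r in degs}
    rows, n_unmapped, n_unmeasured = [], 0, 0
    for dep in deps:
        gene = mapping.get(dep.feature_id)
        if gene is None:
            n_unmapped += 1
            continue
        if gene not in rna_fc:
            n_unmeasured += 1
            continue
        fc_p, fc_r = dep.log2fc, rna_fc[gene]
        rows.append({
            "protein_id": dep.feature_id,
            "gene_id": gene,
            "log2fc_protein": fc_p,
            "log2fc_rna": fc_r,
            "same_direction": bool(np.sign(fc_p) == np.sign(fc_r) != 0),
        })
    if n_unmapped or n_unmeasured:
        log.info("match_features: %d unmapped, %d without measured transcript",
                 n_unmapped, n_unmeasured)
    pairs = pd.DataFrame(rows, columns=["protein_id", "gene_id", "log2fc_protein",
                                        "log2fc_rna", "same_direction"])
    return MatchReport(pairs=pairs, n_unmapped=n_unmapped, n_unmeasured=n_unmeasured)


@dataclass
class ConcordanceResult:
    r: float
    p_value: float
    n_kept: int
    n_removed: int
    n_same_direction: int
    pairs: pd.DataFrame  # annotated with z_protein, z_rna, is_outlier

    def summary(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "n_kept": self.n_kept,
                "n_removed": self.n_removed, "n_same_direction": self.n_same_direction}


def remove_outliers_and_correlate(
    pairs: pd.DataFrame,
    th: Thresholds = Thresholds(),
) -> ConcordanceResult:
    """Single-pass robust outlier removal, then Pearson r on the survivors.

    The modified Z-score is computed separately on the protein and RNA
    fold-change vectors; a pair is an outlier when |z| >= the concordance
    threshold on either axis (the two axes are screened independently, not
    jointly).
    """
    if len(pairs) < 4:
        raise ValidationError(f"need >= 4 pairs, got {len(pairs)}")
    fc_p = pairs["log2fc_protein"].to_numpy(dtype=float)
    fc_r = pairs["log2fc_rna"].to_numpy(dtype=float)
    z_p = modified_zscore(fc_p)
    z_r = modified_zscore(fc_r)
    is_outlier = (np.abs(z_p) >= th.z_concordance) | (np.abs(z_r) >= th.z_concordance)

    annotated = pairs.copy()
    annotated["z_protein"] = z_p
    annotated["z_rna"] = z_r
    annotated["is_outlier"] = is_outlier

    kept = annotated.loc[~is_outlier]
    if len(kept) < 3:
        raise ValidationError("insufficient pairs after outlier removal")
    r, p = stats.pearsonr(kept["log2fc_protein"], kept["log2fc_rna"])
    return ConcordanceResult(
        r=float(r),
        p_value=float(p),
        n_kept=int(len(kept)),
        n_removed=int(is_outlier.sum()),
        n_same_direction=int(kept["same_direction"].sum()),
        pairs=annotated,
    )
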