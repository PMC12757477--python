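"""Differential-expression filtering and a stand-in per-feature test.

Real experiments supply DE tables from dedicated tools (DESeq2 for RNA-Seq,
Progenesis ANOVA for label-free MS); those tables are inputs here. The
stand-in test (Welch's t on log2 abundances with BH adjustment) exists so
synthetic end-to-end runs need no external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    AbundanceTable,
    ContrastResult,
    SampleDesign,
    Thresholds,
    ValidationError,
    direction_of,
)

log = logging.getLogger(__name__)


def _epsilon(table: AbundanceTable, th: Thresholds) -> float:
    """Pseudocount for log of means: half the smallest positive observed value."""
    if th.pseudocount_abund is not None:
        return th.pseudocount_abund
    vals = table.values.to_numpy(dtype=float)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        return 1.0
    return float(pos.min()) / 2.0


def standin_test(
    table: AbundanceTable,
    design: SampleDesign,
    contrast: tuple[list[str], list[str]],
    th: Thresholds = Thresholds(),
    var_mode: str = "pooled",
) -> list[ContrastResult]:
    """Two-group differential test on log2 abundances for every complete feature.

    ``contrast`` is (test sample ids, reference sample ids). log2FC is
    log2((mean_test + eps) / (mean_ref + eps)) on the raw scale; p-values are
    BH-adjusted across features. Features with any missing value on either
    side are dropped (count logged).

    ``var_mode`` selects the variance model:

    * ``"pooled"`` (default) — a common log-scale variance is estimated by
      averaging the per-feature pooled variances across all features, and a
      normal test is applied. Replicate noise in label-free and RNA-Seq-like
      data is well approximated as a shared multiplicative CV, and dedicated
      DE tools (DESeq2, limma) gain their power at n = 3 precisely by
      sharing variance information across features; a per-feature t at n = 3
      has so few degrees of freedom that real effects cannot survive
      multiple-testing correction.
    * ``"student"`` — classical equal-variance two-sample t per feature.
    * ``"welch"`` — unequal-variance t per feature.
    """
    test_ids, ref_ids = contrast
    if len(test_ids) < 2 or len(ref_ids) < 2:
        raise ValidationError("both sides of a contrast need >= 2 replicates")
    known = set(design.sample_ids)
    unknown = [s for s in list(test_ids) + list(ref_ids) if s not in known]
    if unknown:
        raise ValidationError(f"samples not in design: {', '.join(unknown)}")

    eps = _epsilon(table, th)
    sub = table.values[list(test_ids) + list(ref_ids)]
    complete = ~sub.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("standin_test: dropped %d feature(s) with missing values", n_dropped)
    sub = sub.loc[complete]
    if sub.empty:
        raise ValidationError("no features with complete data on both sides")

    a = sub[list(test_ids)].to_numpy(dtype=float)
    b = sub[list(ref_ids)].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + eps) - np.log2(b.mean(axis=1) + eps)

    la, lb = np.log2(a + eps), np.log2(b + eps)
    if var_mode == "pooled":
        na, nb = la.shape[1], lb.shape[1]
        ss = ((la - la.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
             ((lb - lb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2_common = float(np.mean(ss / (na + nb - 2)))
        diff = la.mean(axis=1) - lb.mean(axis=1)
        if s2_common == 0.0:
            p_raw = np.where(np.isclose(diff, 0.0), 1.0, 0.0)
        else:
            z = diff / np.sqrt(s2_common * (1.0 / na + 1.0 / nb))
            p_raw = 2.0 * stats.norm.sf(np.abs(z))
    elif var_mode in ("student", "welch"):
        with np.errstate(invalid="ignore", divide="ignore"):
            t_res = stats.ttest_ind(la, lb, axis=1, equal_var=(var_mode == "student"))
        p_raw = np.asarray(t_res.pvalue, dtype=float)
        # zero variance on both sides: p = 1 for equal means, 0 otherwise
        degenerate = np.isnan(p_raw)
        if degenerate.any():
            equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
            p_raw[degenerate & equal] = 1.0
            p_raw[degenerate & ~equal] = 0.0
    else:
        raise ValidationError(f"unknown var_mode {var_mode!r}")
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    return [
        ContrastResult(
            feature_id=str(fid),
            log2fc=float(fc),
            p_raw=float(pr),
            p_adj=float(pa),
            direction=direction_of(float(fc), float(pa), th),
        )
        for fid, fc, pr, pa in zip(sub.index, log2fc, p_raw, p_adj)
    ]


def contrast_samples(design: SampleDesign, test: str | list[str], reference: str
                     ) -> tuple[list[str], list[str]]:
    """Resolve condition labels into sample-id lists (test may pool conditions)."""
    tests = [test] if isinstance(test, str) else list(test)
    design.require_replicates(tests + [reference], minimum=2)
    test_ids = [s for c in tests for s in design.samples_for(c)]
    return test_ids, design.samples_for(reference)


@dataclass
class DEFilterReport:
    """Counts and feature lists after applying significance + fold-change filters."""

    n_tested: int
    n_significant: int
    n_pass_fc: int
    n_up: int
    n_down: int
    significant: list[str] = field(default_factory=list)
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_pass_fc > self.n_significant:
            raise ValidationError("n_pass_fc cannot exceed n_significant")
        if self.n_up + self.n_down != self.n_pass_fc:
            raise ValidationError("n_up + n_down must equal n_pass_fc")

    @property
    def passing(self) -> list[str]:
        return sorted(set(self.up) | set(self.down))

    def to_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "n_pass_fc": self.n_pass_fc,
            "n_up": self.n_up,
            "n_down": self.n_down,
        }


def apply_thresholds(results: list[ContrastResult], th: Thresholds = Thresholds()
                     ) -> DEFilterReport:
    """Classify contrast results by adjusted p and |log2FC| thresholds.

    Features significant by p but failing the fold-change filter stay in the
    report: both counts are meaningful (e.g. 174 significant vs 171 passing).
    """
    significant, up, down = [], [], []
    for r in results:
        if r.p_adj < th.alpha_adj:
            significant.append(r.feature_id)
            if abs(r.log2fc) >= th.log2fc_min:
                (up if r.log2fc > 0 else down).append(r.feature_id)
    return DEFilterReport(
        n_tested=len(results),
        n_significant=len(significant),
        n_pass_fc=len(up) + len(down),
        n_up=len(up),
        n_down=len(down),
        significant=sorted(significant),
        up=sorted(up),
        down=sorted(down),
    )


def intersect_degs(per_mutant: dict[str, set[str]]
                   ) -> tuple[set[str], pd.DataFrame]:
    """Common DEGs across all mutant contrasts plus the pairwise overlap matrix."""
    if not per_mutant:
        raise ValidationError("empty per-mutant DEG map")
    if len(per_mutant) < 2:
        raise ValidationError("need >= 2 mutants to intersect")
    names = sorted(per_mutant)
    common = set.intersection(*(set(per_mutant[m]) for m in names))
    overlap = pd.DataFrame(
        [[len(set(per_mutant[a]) & set(per_mutant[b])) for b in names] for a in names],
        index=names, columns=names, dtype=int,
    )
    return common, overlap
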