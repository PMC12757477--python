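"""Differential-phosphorylation calling.

Two complementary strategies identify phosphopeptides whose phosphorylation
changes independently of their parent protein's abundance:

* **Strategy 1** plots the parent protein's log2 fold change (A) against the
  phosphopeptide's log2 fold change (B), corrects the trend-line intercept to
  zero, forms the normalized difference D = (max(A,B) − min(A,B)) / (A + B),
  and flags outliers of D by the Iglewicz–Hoaglin modified Z-score.
* **Strategy 2** computes, per peptide and mutant condition, all pairwise
  mutant/control ratios of the protein-normalized phosphopeptide abundance
  and of the parent protein abundance, maps each ratio through
  log2(ratio + 1), compares the two transformed ratio sets with a Student
  t-test, and applies a Bonferroni correction over every peptide x condition
  test in the run.

Peptides flagged by both strategies in at least two mutant conditions are
reported as high-confidence calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import _epsilon
from .model import (
    AbundanceTable,
    PhosphopeptideRecord,
    SampleDesign,
    Thresholds,
    ValidationError,
)

log = logging.getLogger(__name__)


def filter_ptmrs(records: list[PhosphopeptideRecord], th: Thresholds = Thresholds()
                 ) -> list[PhosphopeptideRecord]:
    """Keep records with ptmRS score strictly greater than the threshold."""
    kept = [r for r in records if r.ptmrs_score > th.ptmrs_min]
    removed = len(records) - len(kept)
    if removed:
        log.info("ptmRS filter: excluded %d of %d phosphopeptide record(s) (score <= %g)",
                 removed, len(records), th.ptmrs_min)
    return kept


@dataclass
class NormalizedPhosphoTable:
    """Per-sample phosphopeptide abundance divided by parent protein abundance."""

    values: pd.DataFrame  # index peptide_id, columns sample_id
    parent: dict[str, str]
    dropped: list[tuple[str, str]] = field(default_factory=list)


def normalize_phospho(
    phospho: AbundanceTable,
    protein: AbundanceTable,
    records: list[PhosphopeptideRecord],
) -> NormalizedPhosphoTable:
    """Normalize each phosphopeptide to its parent protein, sample by sample.

    Scale-free: multiplying both tables' column s by any constant leaves the
    normalized values for s unchanged. Entries whose parent protein value is
    missing become missing; peptides whose parent is absent from the protein
    table are dropped with a per-peptide log entry.
    """
    parent_of = {r.peptide_id: r.parent_protein_id for r in records}
    shared = [s for s in phospho.sample_ids if s in set(protein.sample_ids)]
    if not shared:
        raise ValidationError("phospho and protein tables share no samples")
    rows, kept, dropped = [], [], []
    prot_index = set(protein.feature_ids)
    for pid in phospho.feature_ids:
        parent = parent_of.get(pid)
        if parent is None:
            dropped.append((pid, "no phosphopeptide record"))
            continue
        if parent not in prot_index:
            dropped.append((pid, f"parent protein {parent!r} absent from protein table"))
            continue
        num = phospho.values.loc[pid, shared].to_numpy(dtype=float)
        den = protein.values.loc[parent, shared].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = num / den
        ratio[~np.isfinite(ratio)] = np.nan
        rows.append(ratio)
        kept.append(pid)
    for pid, reason in dropped:
        log.warning("normalize_phospho: dropped %s (%s)", pid, reason)
    if not kept:
        raise ValidationError("no phosphopeptide could be normalized")
    values = pd.DataFrame(rows, index=kept, columns=shared)
    values.index.name = "feature_id"
    return NormalizedPhosphoTable(values=values,
                                  parent={p: parent_of[p] for p in kept},
                                  dropped=dropped)


def modified_zscore(x: np.ndarray | list[float]) -> np.ndarray:
    """Iglewicz–Hoaglin modified Z-score: 0.6745 (x − median) / MAD.

    When the MAD is zero the recommended fallback (x − median) /
    (1.253314 * mean absolute deviation) is used; an all-equal vector maps
    to all zeros. Affine-invariant; requires length >= 3.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError(f"modified Z-score needs >= 3 values, got {x.size}")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return 0.6745 * dev / mad
    mean_ad = np.mean(np.abs(dev))
    if mean_ad > 0:
        return dev / (1.253314 * mean_ad)
    return np.zeros_like(x)


def _log2fc(table: pd.DataFrame, features: list[str], test_ids: list[str],
            ref_ids: list[str], eps: float) -> pd.Series:
    sub = table.loc[features]
    mean_t = sub[test_ids].mean(axis=1, skipna=True)
    mean_r = sub[ref_ids].mean(axis=1, skipna=True)
    return np.log2(mean_t + eps) - np.log2(mean_r + eps)


def strategy1(
    A: pd.Series,
    B_raw: pd.Series,
    th: Thresholds = Thresholds(),
    delta: float = 1e-6,
    robust: bool = False,
) -> pd.DataFrame:
    """Normalized-difference outlier analysis of expression vs phosphorylation.

    ``A`` and ``B_raw`` are aligned per-peptide log2 fold changes (parent
    protein expression and phosphorylation). The trend line of B_raw on A is
    fitted (OLS by default, Theil–Sen with ``robust=True``) and its intercept
    subtracted from B_raw so that the corrected trend passes through the
    origin. D = (max(A,B) − min(A,B)) / (A + B); peptides with |A + B| below
    ``delta`` are excluded from the outlier scan (flagged in the output, not
    clamped). Outliers are peptides whose modified Z-score of D is >= the
    configured threshold.
    """
    A = A.astype(float)
    B_raw = B_raw.reindex(A.index).astype(float)
    ok = A.notna() & B_raw.notna()
    if int(ok.sum()) < 3:
        raise ValidationError("strategy 1 needs >= 3 peptides with both fold changes")
    a, b_raw = A[ok], B_raw[ok]

    if robust:
        slope, intercept, *_ = stats.theilslopes(b_raw.to_numpy(), a.to_numpy())
    else:
        slope, intercept = np.polyfit(a.to_numpy(), b_raw.to_numpy(), 1)
    b = b_raw - intercept

    denom = a + b
    usable = denom.abs() >= delta
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("strategy1: excluded %d peptide(s) with |A+B| < %g", n_excluded, delta)
    if int(usable.sum()) < 3:
        raise ValidationError("strategy 1: fewer than 3 peptides usable for D")

    d = (np.maximum(a, b) - np.minimum(a, b)) / denom
    z = pd.Series(np.nan, index=a.index)
    z[usable] = modified_zscore(d[usable].to_numpy())
    out = pd.DataFrame({
        "peptide_id": a.index,
        "A": a,
        "B_raw": b_raw,
        "B": b,
        "D": d.where(usable),
        "z": z,
        "is_outlier": (z >= th.z_dphospho).fillna(False),
        "excluded": ~usable,
    }).reset_index(drop=True)
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    return out


def strategy1_fold_changes(
    phospho: AbundanceTable,
    protein: AbundanceTable,
    norm: NormalizedPhosphoTable,
    design: SampleDesign,
    condition: str,
    reference: str = "WT",
    th: Thresholds = Thresholds(),
    use_normalized: bool = False,
    use_median: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Per-peptide (A, B_raw) inputs for strategy 1 in one mutant condition.

    A is the parent protein's log2FC (condition vs reference). B_raw is the
    phosphopeptide abundance log2FC; under the null of no differential
    phosphorylation it tracks A, which is what the D statistic exploits.
    ``use_normalized=True`` instead takes B from the protein-normalized
    phosphopeptide values (whose null is B ≈ 0).
    """
    test_ids = [s for s in design.samples_for(condition)]
    ref_ids = [s for s in design.samples_for(reference)]
    peptides = norm.values.index.tolist()
    eps_p = _epsilon(protein, th)
    parents = [norm.parent[p] for p in peptides]
    a_by_parent = _log2fc(protein.values, parents, test_ids, ref_ids, eps_p)
    if use_median:
        sub = protein.values.loc[parents]
        a_by_parent = np.log2(sub[test_ids].median(axis=1) + eps_p) - np.log2(
            sub[ref_ids].median(axis=1) + eps_p)
    A = pd.Series(a_by_parent.to_numpy(), index=peptides)

    source = norm.values if use_normalized else phospho.values.loc[peptides]
    eps_b = float(np.nanmin(source.to_numpy()[source.to_numpy() > 0]) / 2.0) \
        if np.any(source.to_numpy() > 0) else 1.0
    if use_median:
        B = np.log2(source[test_ids].median(axis=1) + eps_b) - np.log2(
            source[ref_ids].median(axis=1) + eps_b)
    else:
        B = np.log2(source[test_ids].mean(axis=1) + eps_b) - np.log2(
            source[ref_ids].mean(axis=1) + eps_b)
    return A, pd.Series(B.to_numpy(), index=peptides)


def _ratio_set(test_vals: np.ndarray, ref_vals: np.ndarray) -> np.ndarray:
    test_vals = test_vals[np.isfinite(test_vals)]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if test_vals.size == 0 or ref_vals.size == 0:
        return np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.outer(test_vals, 1.0 / ref_vals).ravel()
    return r[np.isfinite(r)]


def strategy2(
    norm: NormalizedPhosphoTable,
    protein: AbundanceTable,
    design: SampleDesign,
    condition: str,
    reference: str = "WT",
    th: Thresholds = Thresholds(),
    welch: bool = False,
) -> pd.DataFrame:
    """All-pairs ratio t-test for one mutant condition (raw p-values only).

    For each peptide, every mutant/control ratio of the phosphopeptide
    abundance and of the parent protein abundance is formed (n_mut x n_ctrl
    ratios per side), shifted by the ratio pseudocount, log2-transformed and
    averaged; the two transformed ratio sets are compared with a two-sample
    t-test (equal-variance Student by default) and the effect is
    log2FC_phospho − log2FC_tot — the subtraction is what corrects the
    phosphorylation change for the parent protein's change, so a peptide
    that merely tracks its protein has effect ≈ 0. Bonferroni adjustment
    across the whole run is applied afterwards by :func:`bonferroni_finalize`.

    ``norm`` carries the per-sample peptide values and the peptide->parent
    map; the caller decides whether those values are raw or protein-
    normalized abundances (raw in the default pipeline: normalizing first
    *and* subtracting the protein fold change would remove the protein
    contribution twice and mis-flag peptides of regulated proteins).
    """
    design.require_replicates([condition, reference], minimum=2)
    test_ids = design.samples_for(condition)
    ref_ids = design.samples_for(reference)
    pc = th.pseudocount_ratio
    rows = []
    for pid in norm.values.index:
        parent = norm.parent[pid]
        r_phos = _ratio_set(norm.values.loc[pid, test_ids].to_numpy(dtype=float),
                            norm.values.loc[pid, ref_ids].to_numpy(dtype=float))
        r_tot = _ratio_set(protein.values.loc[parent, test_ids].to_numpy(dtype=float),
                           protein.values.loc[parent, ref_ids].to_numpy(dtype=float))
        if r_phos.size < 2 or r_tot.size < 2:
            log.info("strategy2: skipped %s in %s (<2 usable ratios on a side)",
                     pid, condition)
            continue
        l_phos = np.log2(r_phos + pc)
        l_tot = np.log2(r_tot + pc)
        m_phos, m_tot = float(l_phos.mean()), float(l_tot.mean())
        if l_phos.var(ddof=1) == 0.0 and l_tot.var(ddof=1) == 0.0:
            p_raw = 1.0 if np.isclose(m_phos, m_tot) else 0.0
        else:
            p_raw = float(stats.ttest_ind(l_phos, l_tot, equal_var=not welch).pvalue)
        rows.append({
            "peptide_id": pid,
            "condition": condition,
            "log2fc_phospho": m_phos,
            "log2fc_tot": m_tot,
            "effect": m_phos - m_tot,
            "p_raw": p_raw,
            "n_ratios": int(r_phos.size),
        })
    return pd.DataFrame(rows, columns=["peptide_id", "condition", "log2fc_phospho",
                                       "log2fc_tot", "effect", "p_raw", "n_ratios"])


def bonferroni_finalize(per_condition: dict[str, pd.DataFrame],
                        th: Thresholds = Thresholds()) -> pd.DataFrame:
    """Concatenate per-condition strategy-2 results and Bonferroni-adjust.

    The correction family is every peptide x condition test performed in the
    run (the most conservative reading of an unspecified family).
    """
    frames = [df for df in per_condition.values() if not df.empty]
    if not frames:
        return pd.DataFrame(columns=["peptide_id", "condition", "log2fc_phospho",
                                     "log2fc_tot", "effect", "p_raw", "p_adj",
                                     "is_significant", "n_ratios"])
    all_df = pd.concat(frames, ignore_index=True)
    m = len(all_df)
    all_df["p_adj"] = np.minimum(1.0, all_df["p_raw"] * m)
    all_df["is_significant"] = all_df["p_adj"] < th.alpha_adj
    return all_df


def consensus(calls1: dict[str, pd.DataFrame], calls2: pd.DataFrame) -> pd.DataFrame:
    """Combine the two strategies into tiered differential-phosphorylation calls.

    A peptide is *high* confidence when both strategies flag it and it is
    detected in at least two mutant conditions (union over strategies);
    otherwise it is a *candidate*. Only peptides flagged at least once appear.
    """
    universe1 = set()
    flags1: dict[str, set[str]] = {}
    for cond, df in calls1.items():
        universe1.update(df["peptide_id"])
        for pid in df.loc[df["is_outlier"], "peptide_id"]:
            flags1.setdefault(pid, set()).add(cond)
    universe2 = set(calls2["peptide_id"]) if not calls2.empty else set()
    if universe1 and universe2 and not (universe1 & universe2):
        raise ValidationError("strategy 1 and 2 peptide universes are disjoint "
                              "(upstream misjoin?)")
    flags2: dict[str, set[str]] = {}
    if not calls2.empty:
        sig = calls2.loc[calls2["is_significant"]]
        for pid, cond in zip(sig["peptide_id"], sig["condition"]):
            flags2.setdefault(pid, set()).add(cond)

    rows = []
    for pid in sorted(set(flags1) | set(flags2)):
        conds = sorted(flags1.get(pid, set()) | flags2.get(pid, set()))
        by1, by2 = pid in flags1, pid in flags2
        high = by1 and by2 and len(conds) >= 2
        rows.append({
            "peptide_id": pid,
            "conditions_detected": ",".join(conds),
            "n_conditions": len(conds),
            "by_strategy1": by1,
            "by_strategy2": by2,
            "confidence": "high" if high else "candidate",
        })
    df = pd.DataFrame(rows, columns=["peptide_id", "conditions_detected", "n_conditions",
                                     "by_strategy1", "by_strategy2", "confidence"])
    if not df.empty:
        # "high" sorts before "candidate"
        df = df.sort_values(["confidence", "peptide_id"],
                            ascending=[False, True], ignore_index=True)
    return df


def run_dphospho(
    phospho: AbundanceTable,
    protein: AbundanceTable,
    records: list[PhosphopeptideRecord],
    design: SampleDesign,
    th: Thresholds = Thresholds(),
    mutants: list[str] | None = None,
    reference: str = "WT",
    use_normalized_for_s1: bool = False,
    use_normalized_for_s2: bool = False,
    robust: bool = False,
    welch: bool = False,
) -> dict:
    """End-to-end differential-phosphorylation analysis over mutant conditions."""
    kept = filter_ptmrs(records, th)
    if not kept:
        raise ValidationError("no phosphopeptide passes the ptmRS filter")
    pep_ids = [r.peptide_id for r in kept if r.peptide_id in set(phospho.feature_ids)]
    phospho = AbundanceTable(phospho.values.loc[pep_ids].copy(), "phosphopeptide")
    norm = normalize_phospho(phospho, protein, kept)
    if mutants is None:
        mutants = [c for c in design.conditions if c not in ("LP", reference)]

    raw_with_parents = NormalizedPhosphoTable(
        values=phospho.values.loc[norm.values.index], parent=dict(norm.parent))
    s2_input = norm if use_normalized_for_s2 else raw_with_parents

    s1: dict[str, pd.DataFrame] = {}
    s2_raw: dict[str, pd.DataFrame] = {}
    for cond in mutants:
        A, B = strategy1_fold_changes(phospho, protein, norm, design, cond,
                                      reference, th, use_normalized_for_s1)
        df1 = strategy1(A, B, th, robust=robust)
        df1.insert(1, "condition", cond)
        s1[cond] = df1
        s2_raw[cond] = strategy2(s2_input, protein, design, cond, reference, th,
                                 welch=welch)
    s2 = bonferroni_finalize(s2_raw, th)
    calls = consensus(s1, s2)
    return {"normalized": norm, "strategy1": s1, "strategy2": s2, "consensus": calls,
            "n_filtered_records": len(records) - len(kept)}
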