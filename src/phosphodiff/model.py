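"""Shared domain types for the pipeline.

All tabular data move through two containers: :class:`SampleDesign` (which
samples belong to which condition) and :class:`AbundanceTable` (a non-negative
feature x sample matrix with an explicit missingness mask, NaN = missing).
Per-contrast statistics travel as lists of :class:`ContrastResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


FEATURE_KINDS = ("protein", "phosphopeptide", "transcript")


@dataclass(frozen=True)
class Thresholds:
    """Statistical cut-offs used throughout the pipeline.

    Defaults reproduce the published analysis settings: BH-adjusted p < 0.05,
    |log2FC| >= 0.585 (fold change 1.5), modified Z >= 1 for differential
    phosphorylation, modified Z >= 3.5 for concordance outliers, ptmRS
    localization score > 50, and a pseudocount of 1 on abundance ratios.
    """

    alpha_adj: float = 0.05
    log2fc_min: float = 0.585
    z_dphospho: float = 1.0
    z_concordance: float = 3.5
    ptmrs_min: float = 50.0
    pseudocount_ratio: float = 1.0
    #: epsilon for log of means; None = half the smallest positive value observed
    pseudocount_abund: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not v > 0:
                raise ValidationError(f"threshold {f.name} must be strictly positive, got {v}")


@dataclass
class SampleDesign:
    """Maps sample identifiers to condition labels and replicate indices."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate
    reference: str | None = None

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing column(s): {', '.join(missing)}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate sample_id(s): {', '.join(map(str, sorted(set(dup))))}")
        if len(self.table) == 0:
            raise FormatError("design table is empty")
        reps = pd.to_numeric(self.table["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any():
            raise ValidationError("replicate indices must be positive integers")
        self.table = self.table.assign(replicate=reps.astype(int)).reset_index(drop=True)
        if self.reference is not None and self.reference not in set(self.table["condition"]):
            raise ValidationError(f"reference condition {self.reference!r} not present in design")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.table.loc[self.table["condition"] == condition, "sample_id"]
        if sel.empty:
            raise ValidationError(f"no samples for condition {condition!r}")
        return sel.tolist()

    def condition_sizes(self) -> dict[str, int]:
        return self.table["condition"].value_counts().to_dict()

    def require_replicates(self, conditions: Iterable[str], minimum: int = 2) -> None:
        sizes = self.condition_sizes()
        for c in conditions:
            if sizes.get(c, 0) < minimum:
                raise ValidationError(
                    f"condition {c!r} has {sizes.get(c, 0)} samples; >= {minimum} required"
                )


@dataclass
class AbundanceTable:
    """Non-negative feature x sample matrix; NaN entries are missing (not zero)."""

    values: pd.DataFrame  # index = feature_id, columns = sample_id, dtype float
    feature_kind: str = "protein"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id(s): {', '.join(map(str, dups))}")
        vals = self.values.to_numpy(dtype=float)
        neg = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        return AbundanceTable(self.values[sample_ids].copy(), self.feature_kind)

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass(frozen=True)
class PhosphopeptideRecord:
    """One quantified phosphopeptide with its localization confidence score."""

    peptide_id: str
    parent_protein_id: str
    site_descriptor: str
    ptmrs_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ptmrs_score <= 100.0):
            raise ValidationError(
                f"ptmRS score for {self.peptide_id!r} out of [0, 100]: {self.ptmrs_score}"
            )


def direction_of(log2fc: float, p_adj: float, th: Thresholds) -> str:
    """Categorise a feature as up/down/unchanged under the active thresholds."""
    if p_adj < th.alpha_adj and abs(log2fc) >= th.log2fc_min:
        return "up" if log2fc > 0 else "down"
    return "unchanged"


@dataclass(frozen=True)
class ContrastResult:
    """Per-feature statistics for one contrast (test condition over reference)."""

    feature_id: str
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str = "unchanged"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0) or not (0.0 <= self.p_adj <= 1.0):
            raise ValidationError(f"p-values out of [0,1] for {self.feature_id!r}")
        # tiny tolerance: BH guarantees p_adj >= p_raw analytically, but values
        # round-tripped through text at 12 significant digits may tie imperfectly
        if self.p_adj < self.p_raw - 1e-9:
            raise ValidationError(
                f"p_adj < p_raw for {self.feature_id!r} ({self.p_adj} < {self.p_raw})"
            )


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "direction": [r.direction for r in results],
        }
    )


def frame_to_contrasts(df: pd.DataFrame) -> list[ContrastResult]:
    return [
        ContrastResult(
            feature_id=str(row.feature_id),
            log2fc=float(row.log2fc),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            direction=str(row.direction),
        )
        for row in df.itertuples(index=False)
    ]
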