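"""Overrepresentation analysis and TF-target matrix clustering.

ORA is the classical hypergeometric upper-tail test of a query gene set
against annotated collections, BH-adjusted across tested sets. Bubble-plot
term selection reproduces the published rules: sort by adjusted p, keep the
best-scoring duplicate of same-named terms across databases, collapse terms
whose member sets nearly coincide (Jaccard) keeping the most general one,
and optionally drop terms on a user-supplied exclusion list.

The TF-target analysis encodes "TF j regulates DEG i" as a binary incidence
matrix and clusters both axes hierarchically with average linkage on
1 − Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .model import ValidationError

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with a per-set source database tag."""

    sets: dict[str, set[str]]
    source_db: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValidationError(f"empty gene set(s): {', '.join(empty)}")

    @classmethod
    def from_gmt(cls, gmt: dict[str, dict]) -> "GeneSetCollection":
        return cls(sets={n: set(e["members"]) for n, e in gmt.items()},
                   source_db={n: e.get("description", "") for n, e in gmt.items()})


def ora(query: set[str], collection: GeneSetCollection, universe: set[str]) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each collection set.

    p_raw = P[X >= k] with X ~ Hypergeometric(N, K, n) where N is the
    universe size, K the set size within the universe, n the query size and
    k the overlap. Query genes outside the universe are dropped with a log
    message; sets with k = 0 are omitted; BH adjustment runs across the
    tested sets. Output is sorted by adjusted then raw p.
    """
    outside = query - universe
    if outside:
        log.info("ora: dropped %d query gene(s) outside the universe", len(outside))
    query = query & universe
    if not query:
        raise ValidationError("query is empty after restricting to the universe")
    n, N = len(query), len(universe)
    rows = []
    for name, members in collection.sets.items():
        members_u = members & universe
        k = len(query & members_u)
        K = len(members_u)
        if k == 0 or K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "source_db": collection.source_db.get(name, ""),
                     "k": k, "K": K, "n": n, "N": N, "p_raw": p,
                     "overlap_genes": ",".join(sorted(query & members_u))})
    df = pd.DataFrame(rows, columns=["set_name", "source_db", "k", "K", "n", "N",
                                     "p_raw", "overlap_genes"])
    if df.empty:
        return df.assign(p_adj=pd.Series(dtype=float))
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p_adj", "p_raw", "set_name"], ignore_index=True)


def select_bubble_terms(
    rows: pd.DataFrame,
    jaccard_collapse: float = 0.75,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Reduce multi-database ORA output to the terms worth plotting.

    Rules, in order: (i) sort by adjusted p; (ii) when the same term name
    occurs in several source databases keep the occurrence with the smallest
    adjusted p; (iii) collapse term pairs whose overlap-gene Jaccard index is
    >= ``jaccard_collapse``, keeping the larger (more general, higher-K) set;
    finally drop any term on the explicit exclusion list (domain relevance is
    a user judgment, never inferred here).
    """
    if rows.empty:
        return rows.copy()
    df = rows.sort_values(["p_adj", "p_raw", "set_name"], ignore_index=True)
    df = df.loc[df.groupby("set_name")["p_adj"].idxmin()]
    df = df.sort_values(["p_adj", "p_raw", "set_name"], ignore_index=True)

    members = {r.set_name: set(str(r.overlap_genes).split(",")) if r.overlap_genes else set()
               for r in df.itertuples(index=False)}
    sizes = dict(zip(df["set_name"], df["K"]))
    dropped: set[str] = set()
    names = df["set_name"].tolist()
    for i, a in enumerate(names):
        if a in dropped:
            continue
        for b in names[i + 1:]:
            if b in dropped:
                continue
            ma, mb = members[a], members[b]
            union = ma | mb
            if not union:
                continue
            jac = len(ma & mb) / len(union)
            if jac >= jaccard_collapse:
                # keep the more general (larger-K) term; ties keep the better p
                loser = a if sizes[a] < sizes[b] else b
                if sizes[a] == sizes[b]:
                    loser = b
                dropped.add(loser)
                if loser == a:
                    break
    df = df.loc[~df["set_name"].isin(dropped)]
    if exclude:
        df = df.loc[~df["set_name"].isin(exclude)]
    return df.reset_index(drop=True)


@dataclass
class TFTargetMatrix:
    """Binary incidence of DE genes (rows) over TFs (columns)."""

    cells: pd.DataFrame  # index gene_id, columns tf_id, values 0/1
    dropped_tfs: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.cells.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("TF-target matrix must be binary")
        if self.cells.index.duplicated().any() or self.cells.columns.duplicated().any():
            raise ValidationError("TF-target matrix labels must be unique")


def build_tf_matrix(
    degs: list[str],
    tf_edges: list[tuple[str, str]],
    expressed_filter: set[str],
) -> TFTargetMatrix:
    """Binary TF-target incidence restricted to expressed TFs and regulated DEGs.

    TFs absent from ``expressed_filter`` (not detected in the proteome or
    transcriptome) are dropped, as are TFs left with no DEG target and DEGs
    with no retained regulator. Duplicate edges are idempotent.
    """
    if not tf_edges:
        raise ValidationError("empty TF->target edge list")
    deg_set = set(degs)
    targets_of: dict[str, set[str]] = {}
    dropped_unexpressed = set()
    for tf, g in tf_edges:
        if tf not in expressed_filter:
            dropped_unexpressed.add(tf)
            continue
        if g in deg_set:
            targets_of.setdefault(tf, set()).add(g)
    if dropped_unexpressed:
        log.info("build_tf_matrix: dropped unexpressed TF(s): %s",
                 ", ".join(sorted(dropped_unexpressed)))
    tfs = sorted(tf for tf, t in targets_of.items() if t)
    if not tfs:
        raise ValidationError("no TF survives the expression/target filters")
    regulated = sorted(set.union(*(targets_of[tf] for tf in tfs)))
    dropped_genes = sorted(deg_set - set(regulated))
    cells = pd.DataFrame(0, index=regulated, columns=tfs, dtype=int)
    for tf in tfs:
        cells.loc[sorted(targets_of[tf]), tf] = 1
    cells.index.name = "gene_id"
    if dropped_genes:
        log.info("build_tf_matrix: %d DEG(s) have no retained regulator", len(dropped_genes))
    return TFTargetMatrix(cells=cells, dropped_tfs=sorted(dropped_unexpressed),
                          dropped_genes=dropped_genes)


def _correlation_distance(mat: np.ndarray, labels: list[str]) -> np.ndarray:
    """Condensed 1 − Pearson distance; constant vectors get maximal distance (2)."""
    n = mat.shape[0]
    const = mat.std(axis=1) == 0
    if const.any():
        log.info("two_way_cluster: %d constant vector(s) assigned maximal distance",
                 int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return squareform(np.clip(dist, 0.0, 2.0), checks=False)


@dataclass
class ClusterResult:
    gene_order: list[str]
    tf_order: list[str]
    gene_clusters: pd.Series  # index gene_id, values 1..k
    gene_linkage: np.ndarray
    tf_linkage: np.ndarray


def two_way_cluster(matrix: TFTargetMatrix, k_gene_clusters: int = 2) -> ClusterResult:
    """Average-linkage hierarchical clustering of genes and TFs.

    Distance is 1 − Pearson correlation on matrix rows (genes) and columns
    (TFs). Input rows/columns are sorted lexicographically first so that the
    result is deterministic and invariant to input ordering; the gene tree is
    cut into ``k_gene_clusters`` flat clusters.
    """
    cells = matrix.cells.sort_index(axis=0).sort_index(axis=1)
    genes, tfs = cells.index.tolist(), cells.columns.tolist()
    if len(genes) < 3 or len(tfs) < 2:
        raise ValidationError("need >= 3 genes and >= 2 TFs to cluster")
    arr = cells.to_numpy(dtype=float)
    if arr.all() or not arr.any():
        raise ValidationError("no structure: matrix is constant")

    gene_link = hierarchy.linkage(_correlation_distance(arr, genes), method="average")
    tf_link = hierarchy.linkage(_correlation_distance(arr.T, tfs), method="average")
    gene_order = [genes[i] for i in hierarchy.leaves_list(gene_link)]
    tf_order = [tfs[i] for i in hierarchy.leaves_list(tf_link)]
    labels = hierarchy.fcluster(gene_link, t=k_gene_clusters, criterion="maxclust")
    return ClusterResult(
        gene_order=gene_order,
        tf_order=tf_order,
        gene_clusters=pd.Series(labels, index=genes, name="cluster"),
        gene_linkage=gene_link,
        tf_linkage=tf_link,
    )
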