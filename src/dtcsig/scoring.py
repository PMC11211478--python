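"""Per-cell gene-set scoring, cluster profiling and reference-gene association.

The per-cell score of gene set GS_x for cell C_j is the UMI fraction

    score(C_j, GS_x) = sum(UMI of GS_x genes in C_j) / sum(UMI of C_j)

so scores live in [0, 1], the all-genes set scores exactly 1, and sets
partitioning the gene universe have scores summing to 1 per cell.

Cluster profiles give, per (gene, cluster): the mean CP10K/log1p-normalized
expression, its z-score across clusters (population SD; all-equal means map
to z = 0), and the fraction of cells with a nonzero raw count — the numbers
behind dot plots and z-score heat maps. Phenotype association correlates
each gene's per-cluster mean vector with a reference gene (e.g. AGER for
AT1, SERPINE1 for mesenchymal, BPIFB1 for mucous/serous); genes with
Pearson r above the threshold (default 0.9) are flagged as representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, ValidationError

__all__ = ["CellScoreVector", "ClusterProfile", "PhenotypeAssociation",
           "score_cells", "cluster_profile", "associate_with_reference"]


@dataclass
class CellScoreVector:
    set_name: str
    scores: pd.Series  # index cell_id, values in [0, 1]

    def __post_init__(self) -> None:
        v = self.scores.to_numpy()
        if ((v < 0) | (v > 1 + 1e-12)).any():
            raise ValidationError("cell scores outside [0, 1]")


@dataclass
class ClusterProfile:
    """Per-(gene, cluster) mean expression, z-score and expressing fraction."""

    mean_expr: pd.DataFrame  # genes x clusters, normalized means
    zscore: pd.DataFrame     # genes x clusters
    frac_expressing: pd.DataFrame  # genes x clusters, in [0, 1]

    @property
    def clusters(self) -> list[str]:
        return list(self.mean_expr.columns)


@dataclass
class PhenotypeAssociation:
    reference_gene: str
    r_threshold: float
    table: pd.DataFrame  # index gene; pearson_r, p_value, selected

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def score_cells(umi: CountMatrix, members: list[str],
                set_name: str = "") -> CellScoreVector:
    """UMI-fraction score of one gene set for every cell.

    Set members absent from the matrix contribute 0; an empty post-matching
    set scores 0 everywhere. Cells with zero total UMI are an error.
    """
    totals = umi.counts.sum(axis=0)
    if (totals == 0).any():
        bad = [umi.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"cells with zero total UMI: {bad}")
    member_set = {m.upper() for m in members}
    mask = np.fromiter((g in member_set for g in umi.gene_ids), bool,
                       len(umi.gene_ids))
    in_set = umi.counts[mask].sum(axis=0) if mask.any() else np.zeros(
        len(umi.sample_ids)
    )
    scores = pd.Series(in_set / totals, index=umi.sample_ids, name=set_name)
    return CellScoreVector(set_name=set_name, scores=scores)


def _normalize_cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0, keepdims=True).astype(float)
    return np.log1p(counts / totals * 1e4)


def cluster_profile(umi: CountMatrix, clusters: pd.Series | dict,
                    normalize: bool = True) -> ClusterProfile:
    """Mean normalized expression, cross-cluster z-score and expressing
    fraction per (gene, cluster).

    ``clusters`` maps cell_id -> cluster label and must cover every cell.
    z-scores standardize each gene's cluster means with the population SD;
    genes with identical means in all clusters get z = 0.
    """
    labels = pd.Series(clusters) if not isinstance(clusters, pd.Series) else clusters
    missing = set(umi.sample_ids) - set(labels.index)
    if missing:
        raise ValidationError(f"cells without cluster label: {sorted(missing)[:5]}")
    lab = labels.reindex(umi.sample_ids).to_numpy()
    uniq = sorted(set(lab))
    if len(uniq) < 2:
        raise ValidationError("need >=2 clusters for z-scores")
    norm = _normalize_cp10k_log1p(umi.counts) if normalize else umi.counts.astype(float)
    means, fracs = {}, {}
    for c in uniq:
        idx = np.flatnonzero(lab == c)
        if idx.size == 0:
            raise ValidationError(f"cluster {c!r} has no cells")
        means[c] = norm[:, idx].mean(axis=1)
        fracs[c] = (umi.counts[:, idx] > 0).mean(axis=1)
    mean_df = pd.DataFrame(means, index=umi.gene_ids)
    frac_df = pd.DataFrame(fracs, index=umi.gene_ids)
    mu = mean_df.mean(axis=1)
    sd = mean_df.std(axis=1, ddof=0)
    z = (mean_df.sub(mu, axis=0)).div(sd.where(sd > 0, np.inf), axis=0)
    return ClusterProfile(mean_expr=mean_df, zscore=z, frac_expressing=frac_df)


def associate_with_reference(profile: ClusterProfile, reference_gene: str,
                             r_threshold: float = 0.9) -> PhenotypeAssociation:
    """Pearson correlation of every gene's per-cluster mean vector with a
    reference gene's, plus the simple-linear-regression two-sided p-value.

    Genes with r > ``r_threshold`` are flagged ``selected``. Requires >=3
    clusters (a correlation p-value needs at least 3 points) and a reference
    with nonzero variance across clusters.
    """
    reference_gene = reference_gene.upper()
    if reference_gene not in profile.mean_expr.index:
        raise ValidationError(f"reference gene {reference_gene!r} not in profile")
    m = profile.mean_expr
    if m.shape[1] < 3:
        raise ValidationError("need >=3 clusters for correlation p-values")
    ref = m.loc[reference_gene].to_numpy(dtype=float)
    if np.ptp(ref) == 0:
        raise ValidationError("reference gene has zero variance across clusters")
    x = m.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * rc).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    n = m.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    table = pd.DataFrame(
        {"pearson_r": r, "p_value": p,
         "selected": np.nan_to_num(r, nan=-2.0) > r_threshold},
        index=m.index,
    )
    return PhenotypeAssociation(reference_gene=reference_gene,
                                r_threshold=r_threshold, table=table)
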