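"""m-of-n consensus differential-expression signature across models.

A gene enters the UP signature when it passes (p < alpha, log2FC > tau) in
at least ``min_support`` of the n per-model DE tables (DOWN symmetric with
log2FC < -tau). The study constants are alpha=0.01, tau=0.5, support 6 of 7;
the resulting lists are the DTC_UP / DTC_DOWN drug-tolerance signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk_de import DETable
from .io import GeneSetCollection, ValidationError

__all__ = ["ConsensusSignature", "OverlapReport", "build_consensus",
           "rank_by_mean_lfc", "overlap_with_cohort"]

DEFAULT_ALPHA = 0.01
DEFAULT_LFC = 0.5
DEFAULT_MIN_SUPPORT = 6


@dataclass
class ConsensusSignature:
    """DTC_UP / DTC_DOWN gene lists with per-gene support and mean effect.

    ``table`` is indexed by gene with columns: direction {up, down},
    support (models meeting the criterion), mean_log2fc (over all models),
    plus per-model ``log2fc_<model>`` and ``p_<model>`` columns.
    """

    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    lfc_threshold: float = DEFAULT_LFC
    min_support: int = DEFAULT_MIN_SUPPORT
    n_models: int = 0
    model_ids: list[str] = field(default_factory=list)

    @property
    def up_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "down"])

    def to_gmt(self) -> GeneSetCollection:
        sets = {}
        if self.up_genes:
            sets["DTC_UP"] = self.up_genes
        if self.down_genes:
            sets["DTC_DOWN"] = self.down_genes
        return GeneSetCollection(sets)


@dataclass
class OverlapReport:
    """Signature vs cohort-DE overlap at a shared significance criterion."""

    n_signature: int
    n_overlap: int
    direction: str
    alpha: float
    lfc_threshold: float
    missing_genes: list[str] = field(default_factory=list)

    @property
    def percent_overlap(self) -> float:
        return 100.0 * self.n_overlap / self.n_signature

    def __str__(self) -> str:  # e.g. "136/212 (64.2%)"
        return (f"{self.n_overlap}/{self.n_signature} "
                f"({self.percent_overlap:.1f}%) {self.direction}")


def _support_matrix(tables: list[DETable], genes: pd.Index, alpha: float,
                    tau: float, direction: str,
                    p_column: str = "p_value") -> np.ndarray:
    cols = []
    for t in tables:
        sub = t.table.reindex(genes)
        p = sub[p_column].to_numpy()
        lfc = sub["log2fc"].to_numpy()
        with np.errstate(invalid="ignore"):
            if direction == "up":
                ok = (p < alpha) & (lfc > tau)
            else:
                ok = (p < alpha) & (lfc < -tau)
        cols.append(np.nan_to_num(ok.astype(float), nan=0.0).astype(bool))
    return np.column_stack(cols)


def build_consensus(tables: list[DETable], alpha: float = DEFAULT_ALPHA,
                    lfc_threshold: float = DEFAULT_LFC,
                    min_support: int = DEFAULT_MIN_SUPPORT,
                    universe: str = "intersection",
                    use_adjusted_p: bool = False) -> ConsensusSignature:
    """Intersect per-model DE tables into an m-of-n consensus signature.

    Genes absent from a model's table (or NA there) count as non-supporting
    in that model. ``universe`` chooses whether candidate genes come from the
    intersection (default) or union of the models' tested genes.
    ``use_adjusted_p`` applies the significance cut to BH-adjusted rather
    than raw p-values (the default mirrors thresholding each model's raw
    test-level p before intersecting).
    """
    if len(tables) < 2:
        raise ValidationError("need at least 2 DE tables")
    if min_support > len(tables):
        raise ValidationError(
            f"min_support {min_support} exceeds number of models {len(tables)}"
        )
    if universe == "intersection":
        genes = tables[0].genes
        for t in tables[1:]:
            genes = genes.intersection(t.genes)
    elif universe == "union":
        genes = tables[0].genes
        for t in tables[1:]:
            genes = genes.union(t.genes)
    else:
        raise ValueError("universe must be 'intersection' or 'union'")
    genes = genes.sort_values()

    model_ids = [t.model_id or f"model{i + 1}" for i, t in enumerate(tables)]
    p_col = "p_adjusted" if use_adjusted_p else "p_value"
    sup_up = _support_matrix(tables, genes, alpha, lfc_threshold, "up", p_col)
    sup_dn = _support_matrix(tables, genes, alpha, lfc_threshold, "down", p_col)
    n_up = sup_up.sum(axis=1)
    n_dn = sup_dn.sum(axis=1)

    lfc_mat = np.column_stack(
        [t.table.reindex(genes)["log2fc"].to_numpy() for t in tables]
    )
    p_mat = np.column_stack(
        [t.table.reindex(genes)["p_value"].to_numpy() for t in tables]
    )
    mean_lfc = np.nanmean(lfc_mat, axis=1)

    is_up = n_up >= min_support
    is_dn = n_dn >= min_support
    # a gene cannot satisfy both unless thresholds degenerate; up wins ties
    is_dn &= ~is_up
    chosen = is_up | is_dn

    data = {
        "direction": np.where(is_up, "up", "down")[chosen],
        "support": np.where(is_up, n_up, n_dn)[chosen],
        "mean_log2fc": mean_lfc[chosen],
    }
    for j, mid in enumerate(model_ids):
        data[f"log2fc_{mid}"] = lfc_mat[chosen, j]
        data[f"p_{mid}"] = p_mat[chosen, j]
    table = pd.DataFrame(data, index=genes[chosen])
    table.index.name = "gene"
    return ConsensusSignature(table, alpha=alpha, lfc_threshold=lfc_threshold,
                              min_support=min_support, n_models=len(tables),
                              model_ids=model_ids)


def rank_by_mean_lfc(sig: ConsensusSignature) -> pd.DataFrame:
    """Signature genes ordered by mean log2FC (descending), ties by symbol."""
    if len(sig.table) == 0:
        raise ValidationError("empty signature")
    t = sig.table.copy()
    t["_gene"] = t.index
    t = t.sort_values(["mean_log2fc", "_gene"], ascending=[False, True],
                      kind="mergesort").drop(columns="_gene")
    return t


def overlap_with_cohort(sig: ConsensusSignature, cohort_de: DETable,
                        direction: str, alpha: float = DEFAULT_ALPHA,
                        lfc_threshold: float = DEFAULT_LFC) -> OverlapReport:
    """Count signature genes meeting the same criterion in an external cohort.

    Genes missing from the cohort table count as non-overlapping and are
    listed in the report.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sig_genes = sig.up_genes if direction == "up" else sig.down_genes
    if not sig_genes:
        raise ValidationError(f"signature has no {direction} genes")
    sub = cohort_de.table.reindex(sig_genes)
    missing = list(sub.index[sub["p_value"].isna()])
    p = sub["p_value"].to_numpy()
    lfc = sub["log2fc"].to_numpy()
    with np.errstate(invalid="ignore"):
        if direction == "up":
            ok = (p < alpha) & (lfc > lfc_threshold)
        else:
            ok = (p < alpha) & (lfc < -lfc_threshold)
    n_overlap = int(np.nansum(ok))
    return OverlapReport(n_signature=len(sig_genes), n_overlap=n_overlap,
                         direction=direction, alpha=alpha,
                         lfc_threshold=lfc_threshold, missing_genes=missing)
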