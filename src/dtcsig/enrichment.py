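"""Gene-set enrichment on ranked DE results and cross-model sharing counts.

The enrichment score is the classic weighted Kolmogorov-Smirnov running sum:
walking down the ranked gene list, set members ("hits") increment the sum by
|score|^weight_p normalized by the total hit weight, non-members decrement
by 1/(N - n_set); the ES is the signed extremum. Significance comes from
gene-label permutations of set membership (preranked mode), with the
normalized enrichment score NES = ES / mean(|null ES| of matching sign) and
the +1-corrected one-sided permutation p among same-sign nulls.

``sharing_count`` tabulates, per gene set, how many models show a
significant positive (NES > 1) or negative (NES < -1) enrichment — the
least-shared-to-most-shared ordering used to find programs common to all
drug-tolerance models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bulk_de import DETable
from .io import ValidationError

__all__ = ["EnrichmentResult", "rank_genes", "enrichment_score",
           "es_from_positions", "nes_and_p", "sharing_count"]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    n_hits: int
    model_id: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValidationError(f"ES {self.es} outside [-1, 1]")
        if not 0.0 <= self.nominal_p <= 1.0:
            raise ValidationError("nominal p outside [0, 1]")

    @property
    def direction(self) -> str:
        if self.nes > 1:
            return "up"
        if self.nes < -1:
            return "down"
        return "none"


def rank_genes(table: DETable, metric: str = "signed_log2fc") -> pd.Series:
    """Ranking metric per gene, descending; ties broken lexicographically.

    ``signed_log2fc`` ranks by the fold change itself; ``signed_logp`` by
    sign(log2fc) * -log10(p).
    """
    t = table.table.dropna(subset=["log2fc", "p_value"])
    if metric == "signed_log2fc":
        score = t["log2fc"]
    elif metric == "signed_logp":
        p = np.clip(t["p_value"].to_numpy(), 1e-300, 1.0)
        score = pd.Series(np.sign(t["log2fc"].to_numpy()) * (-np.log10(p)),
                          index=t.index)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    if not np.isfinite(score.to_numpy()).all():
        raise ValidationError("non-finite ranking metric")
    df = pd.DataFrame({"score": score.to_numpy(),
                       "symbol": score.index.to_numpy()})
    df = df.sort_values(["score", "symbol"], ascending=[False, True],
                        kind="mergesort")
    return pd.Series(df["score"].to_numpy(), index=df["symbol"].to_numpy())


def enrichment_score(ranked: pd.Series, members: list[str],
                     weight_p: float = 1.0) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one gene set.

    Degenerate case: if the set covers the whole universe there are no
    misses and the running sum climbs monotonically to +1.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    member_set = {m.upper() for m in members}
    hit = np.fromiter((g in member_set for g in genes), bool, len(genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError("no set member present in the ranked universe")
    n = len(genes)
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-zero scores: fall back to unweighted hits
        hit_w = hit.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    if n_hit < n:
        inc = inc - np.where(hit, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(inc)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int,
                      weight_p: float = 1.0) -> np.ndarray:
    """Vectorized ES for many sets given as (B, k) arrays of hit positions.

    ``pos`` holds 0-based rank positions, ``weights`` the |score| of the gene
    at each position. Equivalent to :func:`enrichment_score` but O(k log k)
    per row: between hits the running sum only moves down, so its extrema
    occur just before or at the hits.
    """
    order = np.argsort(pos, axis=1)
    pos = np.take_along_axis(pos, order, axis=1)
    w = np.take_along_axis(np.abs(weights) ** weight_p, order, axis=1)
    total = w.sum(axis=1, keepdims=True)
    uniform = total == 0
    if uniform.any():
        w = np.where(uniform, 1.0, w)
        total = np.where(uniform, w.shape[1], total)
    cum = np.cumsum(w, axis=1) / total
    k = pos.shape[1]
    if n == k:
        return np.ones(pos.shape[0])
    miss = 1.0 / (n - k)
    idx = np.arange(k)[None, :]
    misses_before = (pos - idx) * miss
    at_hit = cum - misses_before                  # value just after each hit
    before_hit = cum - w / total - misses_before  # value just before each hit
    cand = np.concatenate([at_hit, before_hit], axis=1)
    amax = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(cand.shape[0]), amax]


def nes_and_p(ranked: pd.Series, members: list[str], set_name: str = "",
              n_perm: int = 1000, seed: int = 0, weight_p: float = 1.0,
              model_id: str = "") -> EnrichmentResult:
    """Permutation-normalized enrichment with gene-label (preranked) nulls.

    NES = ES / mean(|null ES| with the same sign); the nominal p-value uses
    the +1 correction over same-sign nulls, so it is never exactly zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, _ = enrichment_score(ranked, members, weight_p=weight_p)
    genes = np.asarray(ranked.index)
    member_set = {m.upper() for m in members}
    k = int(sum(g in member_set for g in genes))
    n = len(genes)
    rng = np.random.default_rng(seed)
    scores = np.abs(ranked.to_numpy(dtype=float))
    # random k-subsets of rank positions per permutation
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    null = es_from_positions(pos, scores[pos], n, weight_p=weight_p)
    same = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    n_same = int(same.sum())
    mean_same = float(np.abs(null[same]).mean()) if n_same else float(
        np.abs(null).mean()
    )
    nes = es / mean_same if mean_same > 0 else 0.0
    extreme = int((np.abs(null[same]) >= abs(es)).sum())
    nominal_p = (1.0 + extreme) / (1.0 + n_same) if n_same else 1.0
    return EnrichmentResult(set_name=set_name, es=es, nes=float(nes),
                            nominal_p=float(nominal_p), n_hits=k,
                            model_id=model_id)


def sharing_count(results: list[EnrichmentResult],
                  p_threshold: float = 0.05) -> pd.DataFrame:
    """Per gene set, number of models significantly up / down enriched.

    Up requires nominal_p < threshold and NES > 1; down NES < -1. Output is
    ordered most-shared first (by n_models_up + n_models_down, then name).
    """
    if not results:
        raise ValidationError("no enrichment results")
    rows: dict[str, dict[str, set]] = {}
    for r in results:
        d = rows.setdefault(r.set_name, {"up": set(), "down": set()})
        if r.nominal_p < p_threshold:
            if r.nes > 1:
                d["up"].add(r.model_id)
            elif r.nes < -1:
                d["down"].add(r.model_id)
    out = pd.DataFrame(
        {
            "set_name": list(rows),
            "n_models_up": [len(v["up"]) for v in rows.values()],
            "n_models_down": [len(v["down"]) for v in rows.values()],
        }
    ).set_index("set_name")
    out["n_shared"] = out["n_models_up"] + out["n_models_down"]
    return out.sort_values(["n_shared", "set_name"],
                           ascending=[False, True]).drop(columns="n_shared")
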