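"""Synthetic data with planted ground truth for every pipeline input.

Three generators emulate the study designs the pipeline analyzes:

* ``simulate_bulk_models`` — several "models" (cell line / PDX datasets) of
  treated-vs-untreated bulk RNA-seq counts with a planted shared up/down
  program that may drop out of a subset of models, mimicking an m-of-n
  consensus band.
* ``simulate_sc`` — a clustered UMI matrix with per-cluster marker programs
  (mucous/serous, AT1-like alveolar, mesenchymal, cycling), multinomial
  sampling per cell.
* ``simulate_tracks`` — two-channel FUCCI reporter time series with planted
  per-cell fates (mitosis, endoreplication, death) after S/G2 entry.

All generators are deterministic given their seed, and return a
:class:`SimTruth` carrying the planted structure for downstream oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet, TrackTable

__all__ = [
    "BulkSimConfig",
    "ClusterSpec",
    "ScSimConfig",
    "TrackSimConfig",
    "SimTruth",
    "simulate_bulk_models",
    "simulate_sc",
    "simulate_tracks",
    "default_cluster_spec",
]


@dataclass
class SimTruth:
    """Planted ground truth: the acceptance oracle for downstream stages."""

    planted_up: list[str] = field(default_factory=list)
    planted_down: list[str] = field(default_factory=list)
    dropout_models: dict[str, list[str]] = field(default_factory=dict)
    cluster_labels: dict[str, str] = field(default_factory=dict)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    fates: dict[str, str] = field(default_factory=dict)
    conditions: dict[str, str] = field(default_factory=dict)
    phase_series: pd.DataFrame | None = None  # cell_id, time_h, phase

    def __post_init__(self) -> None:
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted up/down gene lists must be disjoint")


# ---------------------------------------------------------------------------
# bulk models


@dataclass
class BulkSimConfig:
    """Treated-vs-untreated bulk count simulation across several models.

    Defaults mirror the consensus-signature design: 7 models, 3 vs 3
    replicates, a planted program of 212 up and 495 down genes at
    |log2FC| = 1.5, NB dispersion 0.1 (Var = mu + alpha mu^2), and each
    planted gene silent (no effect) in ``dropout_models_per_gene`` randomly
    chosen models — the mechanism behind a 6-of-7 support band.
    """

    n_models: int = 7
    genes_total: int = 5000
    n_up_planted: int = 212
    n_down_planted: int = 495
    effect_log2fc: float = 1.5
    dropout_models_per_gene: int = 1
    samples_per_condition: int = 3
    nb_dispersion: float = 0.1
    library_size_mean: float = 2_000_000.0
    baseline_log_sd: float = 1.0
    library_size_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up_planted + self.n_down_planted >= self.genes_total:
            raise ValueError("planted genes must be fewer than genes_total")
        if not 0 <= self.dropout_models_per_gene < self.n_models:
            raise ValueError("dropout_models_per_gene must be in [0, n_models)")
        if self.nb_dispersion < 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion must be >=0 and library size positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: float) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, Var = mean + alpha*mean^2)."""
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_bulk_models(
    cfg: BulkSimConfig,
) -> tuple[list[CountMatrix], SampleSheet, SimTruth]:
    """Generate per-model count matrices, a joint sample sheet and the truth.

    Gene baselines are log-normal around ``library_size_mean/genes_total``;
    planted genes have their treated mean multiplied by ``2**(+/-effect)``
    except in their dropout models. Model ids are ``model1..modelN``;
    conditions ``control``/``DTC``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(1, cfg.genes_total + 1)]
    planted = rng.choice(cfg.genes_total, cfg.n_up_planted + cfg.n_down_planted,
                         replace=False)
    up_idx = planted[: cfg.n_up_planted]
    down_idx = planted[cfg.n_up_planted:]
    model_ids = [f"model{i + 1}" for i in range(cfg.n_models)]

    dropout: dict[str, list[str]] = {}
    drop_matrix = np.zeros((cfg.genes_total, cfg.n_models), dtype=bool)
    if cfg.dropout_models_per_gene > 0:
        for gi in planted:
            drop = rng.choice(cfg.n_models, cfg.dropout_models_per_gene,
                              replace=False)
            drop_matrix[gi, drop] = True
            dropout[genes[gi]] = [model_ids[d] for d in drop]

    base = rng.lognormal(mean=0.0, sigma=cfg.baseline_log_sd, size=cfg.genes_total)
    base = base / base.sum()  # relative expression, shared across models

    fold_up = 2.0 ** cfg.effect_log2fc
    fold_down = 2.0 ** (-cfg.effect_log2fc)

    matrices: list[CountMatrix] = []
    sheet_rows = []
    nsc = cfg.samples_per_condition
    for mi, model in enumerate(model_ids):
        # model-specific baseline jitter: datasets differ in absolute levels
        model_base = base * rng.lognormal(0.0, 0.2, size=cfg.genes_total)
        model_base = model_base / model_base.sum()
        effect = np.ones(cfg.genes_total)
        active = ~drop_matrix[:, mi]
        effect[up_idx[active[up_idx]]] = fold_up
        effect[down_idx[active[down_idx]]] = fold_down
        cols, names = [], []
        for cond, eff in (("control", np.ones(cfg.genes_total)), ("DTC", effect)):
            for r in range(nsc):
                lib = cfg.library_size_mean * rng.lognormal(
                    -0.5 * cfg.library_size_cv**2, cfg.library_size_cv
                )
                # treated mean is exactly baseline * 2^(+/-effect); the small
                # resulting library-size shift is left for size factors
                mu = model_base * lib * eff
                cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
                name = f"{model}_{cond}_{r + 1}"
                names.append(name)
                sheet_rows.append({"sample_id": name, "model_id": model,
                                   "condition": cond})
        matrices.append(CountMatrix(list(genes), names, np.column_stack(cols)))

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = SimTruth(
        planted_up=[genes[i] for i in up_idx],
        planted_down=[genes[i] for i in down_idx],
        dropout_models=dropout,
    )
    return matrices, sheet, truth


# ---------------------------------------------------------------------------
# single cell


@dataclass
class ClusterSpec:
    """One cluster: size, marker program and fold-boost of marker mass."""

    name: str
    n_cells: int
    marker_genes: list[str] = field(default_factory=list)
    marker_fold: float = 8.0
    condition: str | None = None  # defaults to the cluster name

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.condition is None:
            self.condition = self.name


@dataclass
class ScSimConfig:
    """Clustered UMI matrix simulation (multinomial per cell)."""

    cluster_spec: list[ClusterSpec] = field(default_factory=list)
    genes_total: int = 2000
    umi_per_cell_mean: float = 5000.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.cluster_spec]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")


# marker programs of the persister phenotypes profiled in the study
AT1_MARKERS = ["AGER", "PDPN", "HOPX", "CAV1", "CLIC5"]
MESENCHYMAL_MARKERS = ["SERPINE1", "VIM", "CDH2", "FN1", "TAGLN"]
MUCOUS_SEROUS_MARKERS = ["BPIFB1", "MUC5B", "SCGB1A1", "LTF", "LYZ"]
CYCLING_MARKERS = ["MKI67", "CCNB1", "TOP2A", "PCNA", "E2F1"]


def default_cluster_spec(n_cells: int = 200, marker_fold: float = 8.0) -> list[ClusterSpec]:
    """Cluster layout emulating the treated/untreated persister landscape:
    untreated cycling cells plus AT1-like, mesenchymal and mucous/serous
    drug-tolerant clusters."""
    return [
        ClusterSpec("CT_cycling", n_cells, CYCLING_MARKERS, marker_fold, "control"),
        ClusterSpec("osi_AT1", n_cells, AT1_MARKERS, marker_fold, "DTC"),
        ClusterSpec("osi_mesenchymal", n_cells, MESENCHYMAL_MARKERS, marker_fold, "DTC"),
        ClusterSpec("osi_mucous_serous", n_cells, MUCOUS_SEROUS_MARKERS, marker_fold, "DTC"),
    ]


def simulate_sc(
    cfg: ScSimConfig,
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Generate a UMI matrix over cells plus per-cell metadata.

    Per-cell totals are Poisson around ``umi_per_cell_mean``; gene
    probabilities are a shared log-normal baseline with each cluster's marker
    genes' mass multiplied by its ``marker_fold`` and renormalized.
    Returns (counts over cells, metadata with condition/cluster, truth).
    """
    if not cfg.cluster_spec:
        cfg = ScSimConfig(cluster_spec=default_cluster_spec(),
                          genes_total=cfg.genes_total,
                          umi_per_cell_mean=cfg.umi_per_cell_mean,
                          seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    background = [f"G{i:05d}" for i in range(1, cfg.genes_total + 1)]
    markers = list(dict.fromkeys(
        g.upper() for c in cfg.cluster_spec for g in c.marker_genes
    ))
    genes = background + [m for m in markers if m not in background]
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    base = rng.lognormal(0.0, cfg.baseline_log_sd, size=n_genes)
    base /= base.sum()

    cols, cell_ids, rows_meta = [], [], []
    labels: dict[str, str] = {}
    for spec in cfg.cluster_spec:
        probs = base.copy()
        for g in spec.marker_genes:
            probs[gene_index[g.upper()]] *= spec.marker_fold
        probs /= probs.sum()
        totals = rng.poisson(cfg.umi_per_cell_mean, size=spec.n_cells)
        totals = np.maximum(totals, 1)
        draws = rng.multinomial(totals, probs)  # n_cells x n_genes
        for ci in range(spec.n_cells):
            cid = f"{spec.name}_c{ci + 1:04d}"
            cell_ids.append(cid)
            rows_meta.append({"cell_id": cid, "condition": spec.condition,
                              "cluster": spec.name})
            labels[cid] = spec.name
        cols.append(draws.T)

    counts = CountMatrix(genes, cell_ids, np.hstack(cols))
    meta = pd.DataFrame(rows_meta).set_index("cell_id")
    truth = SimTruth(
        cluster_labels=labels,
        marker_genes={c.name: [g.upper() for g in c.marker_genes]
                      for c in cfg.cluster_spec},
        conditions={cid: meta.loc[cid, "condition"] for cid in cell_ids},
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# FUCCI tracks


@dataclass
class TrackSimConfig:
    """Two-channel reporter track simulation with planted fates.

    Cells start in G1 (red high), enter S/G2 (green high) after an
    exponential G1 duration, then realize their planted fate after an
    exponential S/G2 duration: mitosis (divided=1, track ends),
    endoreplication (return to G1, no division) or death (dead=1,
    absorbing). Channels live on [0, 1000] arbitrary units with logistic
    transitions of timescale ``transition_tau_h`` and Gaussian noise.
    """

    n_cells_per_condition: int = 20
    fate_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # mitosis, endo, death
    phase_duration_means_h: tuple[float, float] = (8.0, 14.0)  # G1, S/G2
    channel_noise_sd: float = 20.0
    sampling_interval_h: float = 1.0
    track_length_h: float = 72.0
    transition_tau_h: float = 1.0
    channel_low: float = 30.0
    channel_high: float = 800.0
    condition: str = "osimertinib"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fate_probs) - 1.0) > 1e-9:
            raise ValueError("fate probabilities must sum to 1")
        if min(self.phase_duration_means_h) <= 0:
            raise ValueError("phase durations must be positive")


FATES = ("mitosis", "endoreplication", "death")


def _logistic(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - t0) / tau))


def simulate_tracks(cfg: TrackSimConfig) -> tuple[TrackTable, SimTruth]:
    """Generate reporter tracks and the planted fate/phase truth.

    The truth phase at each timepoint is obtained by thresholding the
    *noiseless* channel trajectories at the channel midpoint (above-midpoint
    on both channels = transition), so phase-caller accuracy on noisy data
    measures noise robustness only.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells_per_condition
    fates = rng.choice(3, size=n, p=np.asarray(cfg.fate_probs, dtype=float))
    t = np.arange(0.0, cfg.track_length_h + 1e-9, cfg.sampling_interval_h)
    lo, hi, tau = cfg.channel_low, cfg.channel_high, cfg.transition_tau_h
    mid = (lo + hi) / 2.0
    mg1, msg2 = cfg.phase_duration_means_h

    rows = []
    truth_rows = []
    fate_of: dict[str, str] = {}
    cond_of: dict[str, str] = {}
    for ci in range(n):
        cid = f"{cfg.condition}_c{ci + 1:04d}"
        fate = FATES[fates[ci]]
        fate_of[cid] = fate
        cond_of[cid] = cfg.condition
        t1 = rng.exponential(mg1)  # G1 -> S/G2 entry
        t2 = t1 + rng.exponential(msg2)  # fate event
        # clean (noiseless) channel trajectories
        up1 = _logistic(t, t1, tau)
        red = lo + (hi - lo) * (1.0 - up1)
        green = lo + (hi - lo) * up1
        divided = np.zeros(t.size, dtype=int)
        dead = np.zeros(t.size, dtype=int)
        keep = np.ones(t.size, dtype=bool)
        if fate == "mitosis":
            after = t > t2
            keep = ~after
            if keep.sum() == 0:
                keep[0] = True
            last = np.flatnonzero(keep)[-1]
            divided[last] = 1
        elif fate == "endoreplication":
            back = _logistic(t, t2, tau)
            red = red + (hi - lo) * back * up1
            green = green - (hi - lo) * back * up1
        else:  # death
            dead[t >= t2] = 1
            decay = _logistic(t, t2, tau)
            red = red * (1.0 - decay)
            green = green * (1.0 - decay)
        red = np.clip(red, 0, 1000)
        green = np.clip(green, 0, 1000)

        phase = np.where(dead == 1, "dead",
                         np.where((red > mid) & (green <= mid), "G1",
                                  np.where((green > mid) & (red <= mid), "S/G2",
                                           "transition")))
        noisy_red = np.clip(red + rng.normal(0, cfg.channel_noise_sd, t.size), 0, None)
        noisy_green = np.clip(green + rng.normal(0, cfg.channel_noise_sd, t.size), 0, None)
        for k in np.flatnonzero(keep):
            rows.append({"cell_id": cid, "time_h": t[k], "red": noisy_red[k],
                         "green": noisy_green[k], "divided": int(divided[k]),
                         "dead": int(dead[k])})
            truth_rows.append({"cell_id": cid, "time_h": t[k], "phase": phase[k]})

    tracks = TrackTable(pd.DataFrame(rows))
    truth = SimTruth(fates=fate_of, conditions=cond_of,
                     phase_series=pd.DataFrame(truth_rows))
    return tracks, truth


def simulate_track_conditions(
    configs: Sequence[TrackSimConfig],
) -> tuple[TrackTable, SimTruth]:
    """Concatenate tracks from several per-condition configs."""
    tables, fates, conds, phases = [], {}, {}, []
    for cfg in configs:
        tr, truth = simulate_tracks(cfg)
        tables.append(tr.table)
        fates.update(truth.fates)
        conds.update(truth.conditions)
        phases.append(truth.phase_series)
    return (
        TrackTable(pd.concat(tables, ignore_index=True)),
        SimTruth(fates=fates, conditions=conds,
                 phase_series=pd.concat(phases, ignore_index=True)),
    )
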