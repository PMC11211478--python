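"""FUCCI reporter analytics: phase calling, population curves, fate tracking.

The FUCCI system marks G1 with a red reporter and S/G2/M with a green one.
``call_phases`` turns two-channel intensity tracks into per-timepoint phase
calls with hysteresis to suppress noise flicker; ``population_curve``
reproduces treatment-response curves (percentage of total / G1 / S/G2 cells
relative to baseline); ``classify_fate`` assigns each cell entering S/G2 one
of three outcomes — mitosis (a division event), endoreplication / mitotic
slippage (return to G1 without dividing) or death before division — and
``fate_summary`` aggregates per-condition percentages and phase durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrackTable, ValidationError

__all__ = ["PhaseSeries", "PopulationCurve", "FateRecord", "call_phases",
           "population_curve", "classify_fate", "fate_summary",
           "find_early_escapers"]

PHASES = ("G1", "S/G2", "transition", "dead")
DEFAULT_RED_ON = 300.0
DEFAULT_GREEN_ON = 300.0
DEFAULT_HYSTERESIS = 0.2


@dataclass
class PhaseSeries:
    """Per-(cell, timepoint) phase calls; dead is absorbing."""

    table: pd.DataFrame  # cell_id, time_h, phase

    def __post_init__(self) -> None:
        bad = set(self.table["phase"]) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown phases {sorted(bad)}")

    def for_cell(self, cell_id: str) -> pd.DataFrame:
        return self.table[self.table["cell_id"] == cell_id]


@dataclass
class PopulationCurve:
    """Counts and baseline-normalized percentages per timepoint."""

    table: pd.DataFrame  # time_h, n_total, n_G1, n_SG2, pct_total, pct_G1, pct_SG2


@dataclass
class FateRecord:
    cell_id: str
    t_sg2_entry: float
    fate: str | None  # mitosis / endoreplication / death; None = censored
    durations: dict[str, float] = field(default_factory=dict)

    @property
    def censored(self) -> bool:
        return self.fate is None


def _hysteresis_on(values: np.ndarray, threshold: float,
                   fraction: float) -> np.ndarray:
    """Stateful on/off calling: a channel toggles on above threshold*(1+f)
    and off below threshold*(1-f); between the two it keeps its state."""
    hi = threshold * (1.0 + fraction)
    lo = threshold * (1.0 - fraction)
    state = values[0] > threshold  # first point: plain threshold
    out = np.empty(values.size, dtype=bool)
    out[0] = state
    for i in range(1, values.size):
        if state and values[i] < lo:
            state = False
        elif not state and values[i] > hi:
            state = True
        out[i] = state
    return out


def call_phases(tracks: TrackTable,
                thresholds: tuple[float, float] = (DEFAULT_RED_ON, DEFAULT_GREEN_ON),
                hysteresis_fraction: float = DEFAULT_HYSTERESIS,
                noise_floor: tuple[float, float] | None = None) -> PhaseSeries:
    """Call G1/S-G2/transition/dead at every observed timepoint.

    Green on and red off → S/G2; red on and green off → G1; both on →
    transition; both off → the previous call is kept (initial both-off →
    transition). A dead flag overrides everything from its first occurrence.
    ``noise_floor`` (mean, sd of a zero-signal calibration window) triggers a
    warning when thresholds sit within 2 SD of the floor.
    """
    red_on, green_on = thresholds
    if red_on <= 0 or green_on <= 0:
        raise ValidationError("thresholds must be positive")
    if noise_floor is not None:
        floor_mean, floor_sd = noise_floor
        if min(red_on, green_on) < floor_mean + 2 * floor_sd:
            warnings.warn(
                "phase threshold within 2 SD of the zero-signal noise floor; "
                "calls will flicker", stacklevel=2,
            )
    rows = []
    for cid, grp in tracks.table.groupby("cell_id", sort=False):
        red = grp["red"].to_numpy(dtype=float)
        green = grp["green"].to_numpy(dtype=float)
        dead = grp["dead"].to_numpy() == 1
        r_on = _hysteresis_on(red, red_on, hysteresis_fraction)
        g_on = _hysteresis_on(green, green_on, hysteresis_fraction)
        phase = np.empty(red.size, dtype=object)
        prev = "transition"
        for i in range(red.size):
            if dead[i]:
                prev = "dead"
            elif r_on[i] and not g_on[i]:
                prev = "G1"
            elif g_on[i] and not r_on[i]:
                prev = "S/G2"
            elif r_on[i] and g_on[i]:
                prev = "transition"
            # both off: keep previous call
            phase[i] = prev
        rows.append(pd.DataFrame({"cell_id": cid,
                                  "time_h": grp["time_h"].to_numpy(),
                                  "phase": phase}))
    return PhaseSeries(pd.concat(rows, ignore_index=True))


def population_curve(phases: PhaseSeries, baseline_time: float = 0.0,
                     normalize: str = "baseline") -> PopulationCurve:
    """Alive-cell counts per phase per timepoint.

    Percentages are relative to the baseline total (default) or to the
    per-timepoint total (``normalize='timepoint'``). A cell whose track has
    ended (e.g. division) simply stops being counted.
    """
    t = phases.table
    alive = t[t["phase"] != "dead"]
    base_n = alive[alive["time_h"] == baseline_time]["cell_id"].nunique()
    if base_n == 0:
        raise ValidationError("no alive cell at baseline time")
    rows = []
    for time, grp in alive.groupby("time_h"):
        n_tot = grp["cell_id"].nunique()
        n_g1 = (grp["phase"] == "G1").sum()
        n_sg2 = (grp["phase"] == "S/G2").sum()
        denom = n_tot if normalize == "timepoint" else base_n
        rows.append({"time_h": time, "n_total": n_tot, "n_G1": n_g1,
                     "n_SG2": n_sg2,
                     "pct_total": 100.0 * n_tot / base_n,
                     "pct_G1": 100.0 * n_g1 / denom,
                     "pct_SG2": 100.0 * n_sg2 / denom})
    return PopulationCurve(pd.DataFrame(rows).sort_values("time_h")
                           .reset_index(drop=True))


def classify_fate(phases: PhaseSeries, tracks: TrackTable) -> list[FateRecord]:
    """One fate per cell that enters S/G2: mitosis, endoreplication or death.

    Mitosis: a divided=1 event after S/G2 entry. Death: dead=1 before any
    division. Endoreplication: the phase returns to G1 after S/G2 with
    neither division nor death. Cells still in S/G2 (or transition) at track
    end are censored (fate None) and excluded from percentage summaries.
    Cells that never enter S/G2 are not reported.
    """
    records: list[FateRecord] = []
    ptab = phases.table.set_index(["cell_id", "time_h"])["phase"]
    for cid, grp in tracks.table.groupby("cell_id", sort=False):
        times = grp["time_h"].to_numpy()
        ph = ptab.loc[cid].reindex(times).to_numpy()
        divided = grp["divided"].to_numpy()
        dead = grp["dead"].to_numpy()
        if ((divided == 1) & (dead == 1)).any():
            raise ValidationError(f"cell {cid!r} divided and dead at once")
        sg2 = np.flatnonzero(ph == "S/G2")
        if sg2.size == 0:
            continue
        entry = sg2[0]
        t_entry = float(times[entry])
        div_after = np.flatnonzero((divided == 1) & (np.arange(len(times)) >= entry))
        dead_idx = np.flatnonzero(dead == 1)
        g1_after = np.flatnonzero((ph == "G1") & (np.arange(len(times)) > entry))
        fate: str | None
        t_event: float | None
        if div_after.size and not (dead_idx.size and dead_idx[0] < div_after[0]):
            fate, t_event = "mitosis", float(times[div_after[0]])
        elif dead_idx.size:
            fate, t_event = "death", float(times[dead_idx[0]])
        elif g1_after.size:
            fate, t_event = "endoreplication", float(times[g1_after[0]])
        else:
            fate, t_event = None, None
        durations = {"G1_before_entry": t_entry - float(times[0])}
        if t_event is not None:
            durations["SG2_to_event"] = t_event - t_entry
        records.append(FateRecord(cell_id=cid, t_sg2_entry=t_entry, fate=fate,
                                  durations=durations))
    return records


def fate_summary(records: list[FateRecord],
                 conditions: dict[str, str] | None = None) -> pd.DataFrame:
    """Fate percentages (over uncensored cells) and mean durations with SEM.

    ``conditions`` maps cell_id -> condition; omitted, everything is pooled
    under 'all'. Percentages of the three fates sum to 100 per condition.
    """
    if not records:
        raise ValidationError("no fate records")
    cond_of = conditions or {}
    rows = []
    by_cond: dict[str, list[FateRecord]] = {}
    for r in records:
        by_cond.setdefault(cond_of.get(r.cell_id, "all"), []).append(r)
    for cond, recs in sorted(by_cond.items()):
        complete = [r for r in recs if not r.censored]
        if not complete:
            raise ValidationError(f"no uncensored cell in condition {cond!r}")
        n = len(complete)
        durs = [r.durations.get("SG2_to_event", np.nan) for r in complete]
        row = {"condition": cond, "n": n, "n_censored": len(recs) - n,
               "mean_sg2_to_event_h": float(np.nanmean(durs)),
               "sem_sg2_to_event_h": float(np.nanstd(durs, ddof=1) / np.sqrt(n))
               if n > 1 else np.nan}
        for fate in ("mitosis", "endoreplication", "death"):
            row[f"pct_{fate}"] = 100.0 * sum(r.fate == fate for r in complete) / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


def find_early_escapers(phases: PhaseSeries, after_h: float = 24.0) -> list[str]:
    """Cells with a G1 → S/G2 transition at or after ``after_h`` of treatment,
    the qualitative definition of early escapers amid a G1-arrested bulk."""
    out = []
    for cid, grp in phases.table.groupby("cell_id", sort=False):
        ph = grp["phase"].to_numpy()
        times = grp["time_h"].to_numpy()
        for i in range(1, len(ph)):
            if ph[i] == "S/G2" and ph[i - 1] != "S/G2" and "G1" in ph[:i]:
                if times[i] >= after_h:
                    out.append(cid)
                break
    return out
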