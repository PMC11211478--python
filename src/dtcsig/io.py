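"""Readers and writers for every external representation the pipeline touches.

Count matrices come in as TSV/CSV tables (first column = gene symbol, header =
sample ids) or as MatrixMarket triplets with ``barcodes.tsv``/``features.tsv``
sidecars, the interchange layout produced by droplet scRNA-seq pipelines.
Gene sets use the MSigDB GMT format; FUCCI reporter tracks are long-format CSV.

Gene identity is uppercase symbol, exact string match; duplicate symbol rows
are collapsed by summation so per-cell totals (the denominator of the
gene-set score) are preserved.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneSetCollection",
    "TrackTable",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_tracks",
    "write_tracks",
    "read_sample_sheet",
    "write_sample_sheet",
]

PROVENANCE_PREFIX = "#"

TRACK_COLUMNS = ["cell_id", "time_h", "red", "green", "divided", "dead"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class CountMatrix:
    """Genes × samples (or cells) matrix of non-negative integer counts.

    ``sample_ids`` doubles as cell barcodes for single-cell matrices.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids after harmonization")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        _check_counts(self.counts)
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return harmonize(list(df.index.astype(str)), list(df.columns.astype(str)),
                         df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class SampleSheet:
    """Sample → (model, condition) design table for the bulk comparisons."""

    table: pd.DataFrame  # columns: sample_id, model_id, condition

    def __post_init__(self) -> None:
        missing = {"sample_id", "model_id", "condition"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")

    def samples_for(self, condition: str, model_id: str | None = None) -> list[str]:
        t = self.table
        if model_id is not None:
            t = t[t["model_id"] == model_id]
        return list(t.loc[t["condition"] == condition, "sample_id"])

    def validate_against(self, counts: CountMatrix, min_per_condition: int = 2) -> None:
        absent = set(self.table["sample_id"]) - set(counts.sample_ids)
        if absent:
            raise ValidationError(f"sheet samples absent from counts: {sorted(absent)}")
        sizes = self.table.groupby(["model_id", "condition"]).size()
        if (sizes < min_per_condition).any():
            bad = sizes[sizes < min_per_condition]
            raise ValidationError(
                f"conditions with <{min_per_condition} samples: {bad.to_dict()}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB-style); members uppercase and de-duplicated."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(m.upper() for m in members))
            if not uniq:
                raise ValidationError(f"gene set {name!r} empty after de-duplication")
            clean[name] = uniq
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


@dataclass
class TrackTable:
    """Long-format FUCCI reporter tracks, sorted by (cell_id, time_h).

    Invariants: strictly increasing time within a cell, non-negative
    intensities, death absorbing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"track table missing columns: {sorted(missing)}")
        t = (
            self.table[TRACK_COLUMNS]
            .sort_values(["cell_id", "time_h"], kind="mergesort")
            .reset_index(drop=True)
        )
        if (t[["red", "green"]].to_numpy() < 0).any():
            raise ValidationError("negative reporter intensity")
        for col in ("divided", "dead"):
            if not t[col].isin([0, 1]).all():
                raise ValidationError(f"{col} must be 0/1")
        for cid, grp in t.groupby("cell_id", sort=False):
            times = grp["time_h"].to_numpy()
            if np.any(np.diff(times) <= 0):
                raise ValidationError(f"non-monotone time within cell {cid!r}")
            dead = grp["dead"].to_numpy()
            if np.any(np.diff(dead) < 0):
                raise ValidationError(f"dead→alive transition in cell {cid!r}")
        self.table = t

    @property
    def cell_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_id"]))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrackTable) and self.table.equals(other.table)


def _check_counts(arr: np.ndarray) -> None:
    if np.issubdtype(arr.dtype, np.floating):
        frac = arr != np.floor(arr)
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise ValidationError(f"non-integer count at row {i}, column {j}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(f"negative count at row {i}, column {j}")


def harmonize(gene_ids: Sequence[str], sample_ids: Sequence[str],
              counts: np.ndarray) -> CountMatrix:
    """Uppercase symbols and collapse duplicate gene rows by summation."""
    counts = np.asarray(counts)
    _check_counts(counts)
    upper = [g.upper() for g in gene_ids]
    if len(set(upper)) != len(upper):
        df = pd.DataFrame(counts, index=upper)
        df = df.groupby(level=0, sort=False).sum()
        upper, counts = list(df.index), df.to_numpy()
    return CountMatrix(upper, list(sample_ids), counts)


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV, CSV or a MatrixMarket triplet directory.

    For ``mtx-triplet``, *path* is a directory containing ``matrix.mtx``,
    ``barcodes.tsv`` and ``features.tsv`` (feature file order defines gene
    order). Gene symbols are uppercased; duplicate symbols collapsed by
    summation.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "mtx-triplet"
        elif path.suffix == ".csv":
            format = "csv"
        else:
            format = "tsv"
    if format == "mtx-triplet":
        return _read_mtx_triplet(path)
    if format not in ("tsv", "csv"):
        raise FormatError(f"unknown count format {format!r}")
    sep = "\t" if format == "tsv" else ","
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"malformed count table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"count table {path} has no sample columns")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric count in column {col!r}, row {bad.index[0]!r}"
            )
    return harmonize(list(df.index.astype(str)), list(df.columns.astype(str)),
                     df.to_numpy())


def _read_mtx_triplet(d: Path) -> CountMatrix:
    mtx = _first_existing(d, ["matrix.mtx", "counts.mtx"])
    barcodes = _first_existing(d, ["barcodes.tsv", "barcodes.txt"])
    features = _first_existing(d, ["features.tsv", "genes.tsv", "features.txt"])
    mat = scipy.io.mmread(mtx)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = [line.split("\t")[0] for line in _read_lines(features)]
    cells = [line.split("\t")[0] for line in _read_lines(barcodes)]
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix {dense.shape} inconsistent with {len(genes)} features "
            f"and {len(cells)} barcodes"
        )
    return harmonize(genes, cells, dense)


def _first_existing(d: Path, names: list[str]) -> Path:
    for n in names:
        if (d / n).exists():
            return d / n
    raise FileNotFoundError(f"none of {names} found in {d}")


def _read_lines(p: Path) -> list[str]:
    return [ln for ln in p.read_text().splitlines() if ln.strip()]


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv",
                 provenance: str | None = None) -> None:
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(cm.counts)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse, field="integer")
        (path / "features.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(cm.sample_ids) + "\n")
        return
    sep = "\t" if format == "tsv" else ","
    buf = _io.StringIO()
    if provenance:
        buf.write(f"{PROVENANCE_PREFIX} {provenance}\n")
    cm.to_frame().to_csv(buf, sep=sep, index_label="gene")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members…``.

    The description column is discarded; members are de-duplicated and
    uppercased. Duplicate set names and short lines are errors.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                              "expected name, description, members…")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = [m for m in fields[2:] if m]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Mapping[str, Sequence[str]],
              path: str | Path, description: str = "dtcsig") -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FUCCI tracks


def read_tracks(path: str | Path) -> TrackTable:
    """Read long-format reporter tracks; rows are canonicalized to
    (cell_id, time_h) order and the domain invariants enforced."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"malformed tracks CSV {path}: {exc}") from exc
    return TrackTable(df)


def write_tracks(tracks: TrackTable, path: str | Path,
                 provenance: str | None = None) -> None:
    buf = _io.StringIO()
    if provenance:
        buf.write(f"{PROVENANCE_PREFIX} {provenance}\n")
    tracks.table.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)
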