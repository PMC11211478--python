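"""Pseudo-bulk aggregation: random equal partition of cells, summed reads.

Cells of each condition are shuffled and dealt round-robin into k groups
(default 3), so group sizes within a condition differ by at most one; each
pseudo-sample is the gene-wise sum of its cells' UMIs. The resulting matrix
and sample sheet feed straight into :func:`dtcsig.bulk_de.nb_wald_test`,
treating the pseudo-replicates like a classic bulk RNA-seq design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet, ValidationError

__all__ = ["PseudobulkDesign", "partition_and_sum"]

DEFAULT_K = 3


@dataclass
class PseudobulkDesign:
    k_groups: int
    seed: int
    assignment: dict[str, str] = field(default_factory=dict)  # cell -> pseudo-sample

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.assignment.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes


def partition_and_sum(
    umi: CountMatrix, conditions: pd.Series | dict, k: int = DEFAULT_K,
    seed: int = 0, model_id: str = "pseudobulk",
) -> tuple[CountMatrix, SampleSheet, PseudobulkDesign]:
    """Partition cells within each condition into k pseudo-replicates.

    ``conditions`` maps cell_id -> condition label for every cell. Gene-wise
    totals are conserved exactly per condition; identical seeds give
    identical assignments.
    """
    labels = pd.Series(conditions) if not isinstance(conditions, pd.Series) else conditions
    missing = set(umi.sample_ids) - set(labels.index)
    if missing:
        raise ValidationError(f"cells without condition: {sorted(missing)[:5]}")
    lab = labels.reindex(umi.sample_ids)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    cols, names, sheet_rows = [], [], []
    for cond in sorted(lab.unique()):
        cells = np.flatnonzero((lab == cond).to_numpy())
        if cells.size < k:
            raise ValidationError(
                f"condition {cond!r} has {cells.size} cells, fewer than k={k}"
            )
        perm = rng.permutation(cells)
        for g in range(k):
            members = perm[g::k]  # round-robin after shuffling
            name = f"{cond}_rep{g + 1}"
            names.append(name)
            cols.append(umi.counts[:, members].sum(axis=1))
            sheet_rows.append({"sample_id": name, "model_id": model_id,
                               "condition": cond})
            for ci in members:
                assignment[umi.sample_ids[ci]] = name
    pseudo = CountMatrix(list(umi.gene_ids), names, np.column_stack(cols))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return pseudo, sheet, PseudobulkDesign(k_groups=k, seed=seed,
                                           assignment=assignment)
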