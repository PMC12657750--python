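"""Cross-stage migration of pattern-group membership.

When treatment starts at a later disease stage, genes that were fully
rescued at an early stage typically "migrate" to the partially-rescued or
not-treatable groups. This module cross-tabulates the pattern labels of a
shared gene universe between two stages and verifies that the counts are
conserved (every origin-group gene is accounted for among destinations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from dipaseq.dipa import PATTERN_LABELS


@dataclass
class MigrationMatrix:
    """Origin-label x destination-label gene counts on a shared universe."""

    table: pd.DataFrame  # rows: origin labels, columns: destination labels
    universe_size: int
    origin_stage: str = ""
    dest_stage: str = ""
    only_in_origin: list[str] = field(default_factory=list)
    only_in_dest: list[str] = field(default_factory=list)

    def origin_sizes(self) -> pd.Series:
        return self.table.sum(axis=1)

    def dest_sizes(self) -> pd.Series:
        return self.table.sum(axis=0)


def migration_matrix(
    dt_i: pd.DataFrame,
    dt_j: pd.DataFrame,
    origin_stage: str = "",
    dest_stage: str = "",
) -> MigrationMatrix:
    """Cross-tabulate pattern labels between two DiPa tables.

    The universe is the intersection of the two gene sets; genes present
    in only one table are listed separately rather than counted. Rows and
    columns cover the full pattern-label set in a fixed order, so
    ``migration_matrix(a, b).table`` is the transpose of
    ``migration_matrix(b, a).table``.
    """
    common = dt_i.index.intersection(dt_j.index)
    if len(common) == 0:
        raise ValueError("the two DiPa tables share no genes")
    origin = dt_i.loc[common, "label"]
    dest = dt_j.loc[common, "label"]
    table = (
        pd.crosstab(origin, dest)
        .reindex(index=PATTERN_LABELS, columns=PATTERN_LABELS, fill_value=0)
        .rename_axis(index="origin", columns="destination")
        .astype(int)
    )
    return MigrationMatrix(
        table=table,
        universe_size=len(common),
        origin_stage=origin_stage,
        dest_stage=dest_stage,
        only_in_origin=sorted(dt_i.index.difference(common)),
        only_in_dest=sorted(dt_j.index.difference(common)),
    )


def check_conservation(mm: MigrationMatrix, origin_sizes: dict[str, int] | pd.Series) -> dict:
    """Verify that migration counts account for every origin-group gene.

    Passes iff each row sum equals the stated origin group size and the
    grand total equals the universe size. Returns a report with per-label
    discrepancies (row sum minus stated size).
    """
    stated = pd.Series(origin_sizes, dtype=int).reindex(PATTERN_LABELS, fill_value=0)
    row_sums = mm.origin_sizes()
    diff = (row_sums - stated).astype(int)
    discrepancies = {label: int(d) for label, d in diff.items() if d != 0}
    grand_total = int(mm.table.to_numpy().sum())
    passed = not discrepancies and grand_total == mm.universe_size
    return {
        "pass": passed,
        "grand_total": grand_total,
        "universe_size": mm.universe_size,
        "discrepancies": discrepancies,
    }
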