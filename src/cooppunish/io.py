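"""Tabular and JSON I/O for counts, trial records and fit results.

Counts travel as a tidy delimited table with columns
``condition, partner_tree, participant_decision, punished, count``
(one row per category) or as JSON mapping each condition to its 8-vector in
the frozen category order.  Trial tables use the documented column header of
:mod:`cooppunish.simulate`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import CategoryCounts
from .model import CATEGORY_ORDER
from .simulate import TRIAL_COLUMNS

COUNTS_COLUMNS = ["condition", "partner_tree", "participant_decision", "punished", "count"]


def counts_to_table(counts: CategoryCounts) -> pd.DataFrame:
    rows = []
    for cond, vec in counts.counts.items():
        for (tree, decision, punished), n in zip(CATEGORY_ORDER, vec):
            rows.append((cond, tree, decision, punished, int(n)))
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def counts_from_table(table: pd.DataFrame) -> CategoryCounts:
    missing = set(COUNTS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"counts table is missing columns {sorted(missing)}")
    index = {key: i for i, key in enumerate(CATEGORY_ORDER)}
    counts: dict[str, np.ndarray] = {}
    for row in table.itertuples(index=False):
        key = (row.partner_tree, row.participant_decision, str(row.punished))
        if key not in index:
            raise ValueError(f"unrecognised category row: {tuple(row)}")
        vec = counts.setdefault(str(row.condition), np.zeros(8))
        vec[index[key]] += float(row.count)
    return CategoryCounts(counts)


def write_counts(counts: CategoryCounts, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "json":
        payload = {cond: [int(v) for v in vec] for cond, vec in counts.counts.items()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        counts_to_table(counts).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> CategoryCounts:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return CategoryCounts({cond: np.asarray(vec, float) for cond, vec in payload.items()})
    return counts_from_table(pd.read_csv(path, sep="\t", dtype={"punished": str}))


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_trials(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a trial table; ``column_mapping`` renames external columns
    (e.g. from a public data deposit) onto the documented header."""
    table = pd.read_csv(path, sep="\t")
    if column_mapping:
        table = table.rename(columns=column_mapping)
    missing = set(TRIAL_COLUMNS[:7]) - set(table.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    return table


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
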