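"""Candidate-interaction databases and DE-list constrained pairing.

A :class:`TargetDB` holds directed candidate edges of one type —
lncRNA->miRNA (sponge candidates) or miRNA->mRNA (target candidates) — each
tagged with the name of the database it came from.  Real analyses load these
from exports of resources such as miRcode/StarBase (lncRNA->miRNA) or
miRDB/TargetScan (miRNA->mRNA); the pairing operations then intersect the
edges with the differential-expression lists, so only DE features can enter
the ceRNA network.

ID matching is exact-string (whitespace-trimmed on load); no alias
resolution is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

EDGE_TYPES = ("lncRNA->miRNA", "miRNA->mRNA")

EDGE_COLUMNS = ("source_id", "target_id", "db_name")


@dataclass
class TargetDB:
    """Set of directed candidate edges of a single type.

    ``edges`` has columns source_id / target_id / db_name; duplicate
    (source, target, db_name) rows are collapsed on construction.
    """

    edges: pd.DataFrame
    edge_type: str

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValidationError(f"edge_type must be one of {EDGE_TYPES}")
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValidationError(f"target DB missing columns: {missing}")
        self.edges = (
            self.edges.loc[:, list(EDGE_COLUMNS)]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def db_names(self) -> set[str]:
        return set(self.edges["db_name"])


def load_target_db(
    path: str | Path, edge_type: str, db_name: str | None = None
) -> TargetDB:
    """Load a target DB from a headered TSV with >= 2 columns.

    Columns: source_id, target_id and optionally db_name.  When the third
    column is absent, ``db_name`` defaults to the file stem.  IDs are
    whitespace-trimmed, case preserved.  Malformed rows raise with their
    line number.
    """
    path = Path(path)
    default_db = db_name if db_name is not None else path.stem
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return TargetDB(
                pd.DataFrame(columns=list(EDGE_COLUMNS)), edge_type=edge_type
            )
        if len(header) < 2:
            raise ValidationError(f"{path}: header must have >= 2 columns")
        has_db_col = len(header) >= 3
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise ValidationError(f"{path}: malformed row at line {lineno}: {row!r}")
            db = row[2].strip() if has_db_col and len(row) >= 3 and row[2].strip() else default_db
            rows.append((row[0].strip(), row[1].strip(), db))
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    return TargetDB(edges=edges, edge_type=edge_type)


def _pool_edges(dbs: Sequence[TargetDB], edge_type: str) -> pd.DataFrame:
    if not dbs:
        raise ValidationError("at least one target DB is required")
    for db in dbs:
        if db.edge_type != edge_type:
            raise ValidationError(
                f"expected edge_type {edge_type!r}, got {db.edge_type!r}"
            )
    return pd.concat([db.edges for db in dbs], ignore_index=True).drop_duplicates()


def _constrained_pairs(
    de_source: Iterable[str],
    de_target: Iterable[str],
    dbs: Sequence[TargetDB],
    edge_type: str,
    combine: str,
) -> pd.DataFrame:
    if combine not in ("union", "intersection"):
        raise ValidationError("combine must be 'union' or 'intersection'")
    pooled = _pool_edges(dbs, edge_type)
    de_source, de_target = set(de_source), set(de_target)
    keep = pooled["source_id"].isin(de_source) & pooled["target_id"].isin(de_target)
    pooled = pooled.loc[keep]
    grouped = pooled.groupby(["source_id", "target_id"])["db_name"].agg(
        lambda s: sorted(set(s))
    )
    if combine == "intersection":
        all_names = set(pd.concat([db.edges for db in dbs])["db_name"])
        grouped = grouped[grouped.map(lambda names: set(names) >= all_names)]
    out = grouped.reset_index()
    out["db_name"] = out["db_name"].map(",".join)
    return out.rename(columns={"db_name": "dbs"}).sort_values(
        ["source_id", "target_id"]
    ).reset_index(drop=True)


def lncrna_mirna_pairs(
    de_lnc: Iterable[str],
    de_mirna: Iterable[str],
    dbs: Sequence[TargetDB],
    combine: str = "union",
) -> pd.DataFrame:
    """lncRNA-miRNA pairs: DB edges restricted to DE lncRNAs and DE miRNAs.

    ``combine='union'`` keeps a pair supported by any database;
    ``'intersection'`` requires support from every database label present in
    the pooled input.  Columns: source_id (lncRNA), target_id (miRNA), dbs.
    """
    return _constrained_pairs(de_lnc, de_mirna, dbs, EDGE_TYPES[0], combine)


def mirna_mrna_pairs(
    de_mirna: Iterable[str],
    de_genes: Iterable[str],
    dbs: Sequence[TargetDB],
    combine: str = "union",
) -> pd.DataFrame:
    """miRNA-mRNA pairs: DB edges restricted to DE miRNAs and DE genes."""
    return _constrained_pairs(de_mirna, de_genes, dbs, EDGE_TYPES[1], combine)
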