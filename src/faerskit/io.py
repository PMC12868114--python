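"""Reading and writing FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System publishes quarterly extracts as
``$``-delimited text files, one per table: DEMO (demographics), DRUG
(drug rows with role codes), REAC (MedDRA-coded reactions), OUTC
(outcome codes) and THER (therapy dates).  This module reads those
tables into a :class:`RawRecordSet` of string-typed DataFrames — dates
are kept as digit strings until preprocessing so that partial dates
(YYYYMM, YYYY) are never silently promoted to full days — and writes
them back bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column sets per table kind (lower-case)
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "occp_cod", "reporter_country",
    ],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
}

TABLE_KINDS = tuple(TABLE_COLUMNS)

DEFAULT_DELIMITER = "$"


class SchemaError(ValueError):
    """A mandatory column is missing from a quarterly table."""


@dataclass
class RawRecordSet:
    """Raw (pre-deduplication) multi-table record set.

    Each attribute is a string-typed DataFrame with the columns of
    :data:`TABLE_COLUMNS`.  ``rejects`` collects unparseable input rows
    (table kind, raw line) rather than dropping them silently;
    ``orphan_counts`` counts child-table rows whose (primaryid, caseid)
    has no DEMO row — such rows are kept but flagged.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    rejects: list[tuple[str, str]] = field(default_factory=list)
    orphan_counts: dict[str, int] = field(default_factory=dict)

    def table(self, kind: str) -> pd.DataFrame:
        if kind not in TABLE_KINDS:
            raise KeyError(f"unknown table kind {kind!r}")
        return getattr(self, kind)

    @classmethod
    def empty(cls) -> "RawRecordSet":
        return cls(**{k: _empty_table(k) for k in TABLE_KINDS})

    def row_counts(self) -> dict[str, int]:
        return {k: len(self.table(k)) for k in TABLE_KINDS}

    @property
    def n_orphans(self) -> int:
        return sum(self.orphan_counts.values())

    def flag_orphans(self) -> None:
        """Recompute orphan counts for child tables against DEMO keys."""
        keys = set(zip(self.demo["primaryid"], self.demo["caseid"]))
        self.orphan_counts = {}
        for kind in ("drug", "reac", "outc", "ther"):
            tab = self.table(kind)
            if len(tab) == 0:
                self.orphan_counts[kind] = 0
                continue
            present = [
                (p, c) in keys
                for p, c in zip(tab["primaryid"], tab["caseid"])
            ]
            self.orphan_counts[kind] = int(len(tab) - sum(present))

    def equals(self, other: "RawRecordSet") -> bool:
        """String-field equality of all five tables, ignoring row order."""
        for kind in TABLE_KINDS:
            a = self.table(kind).sort_values(list(TABLE_COLUMNS[kind]))
            b = other.table(kind).sort_values(list(TABLE_COLUMNS[kind]))
            if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        return True


def _empty_table(kind: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in TABLE_COLUMNS[kind]})


def _read_table(path: Path, kind: str, delimiter: str,
                rejects: list[tuple[str, str]]) -> pd.DataFrame:
    want = TABLE_COLUMNS[kind]
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = [h.strip().lower() for h in header_line.split(delimiter)]
        missing = [c for c in want if c not in header]
        if missing:
            raise SchemaError(
                f"table {kind!r} ({path}): missing column(s) {missing}"
            )
        idx = {c: header.index(c) for c in want}
        rows: list[list[str]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(delimiter)
            if len(parts) != len(header):
                rejects.append((kind, line))
                continue
            rows.append([parts[idx[c]] for c in want])
    df = pd.DataFrame(rows, columns=want, dtype=str) if rows else _empty_table(kind)
    logger.info("read %s: %d rows (%d rejected)", kind, len(df),
                sum(1 for k, _ in rejects if k == kind))
    return df


def read_quarter(paths: Mapping[str, str | Path],
                 delimiter: str = DEFAULT_DELIMITER) -> RawRecordSet:
    """Read one quarter's tables into a :class:`RawRecordSet`.

    Parameters
    ----------
    paths
        Mapping from table kind (``demo``, ``drug``, ``reac``, ``outc``,
        ``ther``) to a file path.  DEMO, DRUG and REAC are mandatory;
        OUTC and THER may be omitted (empty tables are substituted).
    delimiter
        Field separator, ``$`` in public FAERS releases.

    Raises
    ------
    SchemaError
        If a present file lacks a mandatory column.  Unparseable rows
        are collected in ``rejects``, never silently dropped.
    """
    for kind in ("demo", "drug", "reac"):
        if kind not in paths:
            raise SchemaError(f"mandatory table {kind!r} not given")
    rejects: list[tuple[str, str]] = []
    tables = {}
    for kind in TABLE_KINDS:
        if kind in paths:
            tables[kind] = _read_table(Path(paths[kind]), kind, delimiter, rejects)
        else:
            tables[kind] = _empty_table(kind)
    rs = RawRecordSet(**tables, rejects=rejects)
    rs.flag_orphans()
    return rs


def write_quarter(records: RawRecordSet, out_dir: str | Path,
                  delimiter: str = DEFAULT_DELIMITER) -> dict[str, Path]:
    """Write a record set as ``$``-delimited text files, one per table.

    Round-trips bit-identically for string fields.  A field containing
    the delimiter cannot be represented and raises ``ValueError``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for kind in TABLE_KINDS:
        df = records.table(kind)
        for col in TABLE_COLUMNS[kind]:
            bad = df[col].astype(str).str.contains(delimiter, regex=False)
            if bad.any():
                raise ValueError(
                    f"table {kind!r} column {col!r}: field contains the "
                    f"delimiter {delimiter!r} and cannot be written"
                )
        path = out / f"{kind}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(delimiter.join(TABLE_COLUMNS[kind]) + "\n")
            for row in df.itertuples(index=False):
                fh.write(delimiter.join(str(v) for v in row) + "\n")
        written[kind] = path
    return written


@dataclass
class MeddraMap:
    """Preferred Term → primary System Organ Class mapping.

    MedDRA itself cannot be redistributed, so the mapping is supplied as
    a two-column delimited text file (PT, SOC).  Unknown PTs map to the
    sentinel SOC ``"UNMAPPED"``.
    """

    pt_to_soc: dict[str, str]

    UNMAPPED = "UNMAPPED"

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(pt, self.UNMAPPED)

    @classmethod
    def read(cls, path: str | Path, delimiter: str = "\t") -> "MeddraMap":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pt, soc = line.split(delimiter, 1)
                mapping[pt] = soc
        return cls(mapping)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pt, soc in sorted(self.pt_to_soc.items()):
                fh.write(f"{pt}{delimiter}{soc}\n")
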