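"""Readers and writers for the tabular and sequence formats the pipeline touches.

Sequences (mature miRNAs, 3' UTR reporter inserts) travel as FASTA and are
normalized into RNA space (T→U, uppercase) on read.  Plate-level luminescence,
score matrices, prediction tables and known-interaction tables are long-format
TSV with header; missing values are encoded as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
#: residues accepted in input FASTA before normalization
_INPUT_ALPHABET = frozenset("ACGTUacgtu")

PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = range(1, 13)

#: treatment vocabulary for screen wells; miRNA treatments carry the mimic id
NTC = "NTC"
VEHICLE = "vehicle"

WELL_COLUMNS = [
    "gene",
    "replicate",
    "plate",
    "row",
    "column",
    "treatment",
    "luc2P",
    "Rluc",
]

SCORE_METRICS = ("NRA", "z", "interaction", "B", "knockdown")


class ScreenIOError(ValueError):
    """Malformed input table or sequence file."""


@dataclass(frozen=True)
class SequenceRecord:
    """One mature miRNA or 3' UTR insert, in normalized RNA space."""

    id: str
    residues: str
    moiety: Literal["miRNA", "UTR"]
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ScreenIOError(f"empty sequence for record {self.id!r}")
        bad = [(i, c) for i, c in enumerate(self.residues, start=1) if c not in RNA_ALPHABET]
        if bad:
            pos, c = bad[0]
            raise ScreenIOError(
                f"record {self.id!r}: invalid residue {c!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase and map T→U; reject residues outside the DNA/RNA alphabet."""
    for i, c in enumerate(raw, start=1):
        if c not in _INPUT_ALPHABET:
            raise ScreenIOError(
                f"record {record_id!r}: invalid residue {c!r} at position {i}"
            )
    return raw.upper().replace("T", "U")


def read_sequences(path: str | Path, moiety: Literal["miRNA", "UTR"]) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Ids must be unique; the accession is taken from the first ``|``- or
    whitespace-separated token of the description when it looks like a
    miRBase accession (``MIMAT...``).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ScreenIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        accession = None
        for token in rec.description.replace("|", " ").split():
            if token.startswith("MIMAT"):
                accession = token
                break
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=normalize_residues(str(rec.seq), rec.id),
                moiety=moiety,
                accession=accession,
            )
        )
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# plate tables


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format TSV of wells (one row per well) and validate it.

    Returns a DataFrame with :data:`WELL_COLUMNS` plus a boolean ``usable``
    column.  Wells with nonpositive luminescence are flagged unusable, never
    dropped, so downstream exclusion counts stay auditable.
    """
    wells = pd.read_csv(path, sep="\t", dtype={"gene": str, "plate": str, "row": str,
                                               "treatment": str})
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ScreenIOError(f"{path}: missing well columns {missing}")
    return validate_wells(wells)


def validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Check WellRecord invariants and attach the ``usable`` flag."""
    wells = wells.copy()
    dup = wells.duplicated(subset=["plate", "row", "column"])
    if dup.any():
        first = wells.loc[dup, ["plate", "row", "column"]].iloc[0]
        raise ScreenIOError(
            f"well listed twice: plate {first['plate']!r} {first['row']}{first['column']}"
        )
    genes_per_plate = wells.groupby("plate")["gene"].nunique()
    multi = genes_per_plate[genes_per_plate > 1]
    if len(multi):
        raise ScreenIOError(
            f"plate {multi.index[0]!r} spans {multi.iloc[0]} genes; one gene per plate"
        )
    bad_row = ~wells["row"].isin(set(PLATE_ROWS))
    if bad_row.any():
        raise ScreenIOError(f"invalid plate row {wells.loc[bad_row, 'row'].iloc[0]!r}")
    bad_col = ~wells["column"].isin(set(PLATE_COLUMNS))
    if bad_col.any():
        raise ScreenIOError(f"invalid plate column {wells.loc[bad_col, 'column'].iloc[0]!r}")
    if (wells["replicate"] < 1).any():
        raise ScreenIOError("replicate indices must be >= 1")
    wells["usable"] = (wells["luc2P"] > 0) & (wells["Rluc"] > 0)
    return wells


def write_plate_table(wells: pd.DataFrame, path: str | Path) -> None:
    wells.loc[:, WELL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# annotation tables (predictions, known interactions)


@dataclass(frozen=True)
class PredictionTable:
    """Deduplicated (miRNA, gene, model) prediction labels."""

    entries: frozenset[tuple[str, str, str]]

    @property
    def models(self) -> frozenset[str]:
        return frozenset(m for _, _, m in self.entries)

    def predicted_by_at_least(self, k: int) -> frozenset[tuple[str, str]]:
        counts: dict[tuple[str, str], int] = {}
        for m, g, _ in self.entries:
            counts[(m, g)] = counts.get((m, g), 0) + 1
        return frozenset(pair for pair, n in counts.items() if n >= k)

    def predicted_by(self, model: str) -> frozenset[tuple[str, str]]:
        return frozenset((m, g) for m, g, mod in self.entries if mod == model)


@dataclass(frozen=True)
class KnownInteractionSet:
    """Literature-validated (miRNA, gene) interactions, optional PMIDs."""

    entries: frozenset[tuple[str, str]]
    provenance: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_annotation_table(
    path: str | Path,
    kind: Literal["predictions", "known"],
    known_mirnas: Iterable[str] | None = None,
    known_genes: Iterable[str] | None = None,
) -> PredictionTable | KnownInteractionSet:
    """Read a predictions or known-interactions TSV into a deduplicated set.

    Unknown miRNA/gene ids (relative to the optional vocabularies) are
    permitted but reported on the returned object via ``unknown_ids``.
    """
    required = ["mirna", "gene"] + (["model"] if kind == "predictions" else [])
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ScreenIOError(f"{path}: missing columns {missing}")
    for lineno, row in table.iterrows():
        if any(pd.isna(row[c]) or str(row[c]).strip() == "" for c in required):
            raise ScreenIOError(f"{path}: malformed row at line {int(lineno) + 2}")

    unknown: set[str] = set()
    if known_mirnas is not None:
        unknown |= set(table["mirna"]) - set(known_mirnas)
    if known_genes is not None:
        unknown |= set(table["gene"]) - set(known_genes)

    if kind == "predictions":
        entries = frozenset(
            (r.mirna, r.gene, r.model) for r in table.itertuples(index=False)
        )
        result: PredictionTable | KnownInteractionSet = PredictionTable(entries)
    else:
        pairs = frozenset((r.mirna, r.gene) for r in table.itertuples(index=False))
        provenance: dict[tuple[str, str], tuple[str, ...]] = {}
        if "pmid" in table.columns:
            for r in table.itertuples(index=False):
                if pd.notna(r.pmid):
                    key = (r.mirna, r.gene)
                    provenance[key] = provenance.get(key, ()) + (str(r.pmid),)
        result = KnownInteractionSet(pairs, provenance)
    object.__setattr__(result, "unknown_ids", frozenset(unknown))
    return result


# ---------------------------------------------------------------------------
# score matrices


def write_score_table(scores: pd.DataFrame, metric: str, path: str | Path) -> None:
    """Write a score matrix TSV tagged with its metric.

    Values are encoded as decimal text with 17 significant digits so the
    read∘write round trip is bit-exact; missing cells are written as ``NA``.
    """
    if metric not in SCORE_METRICS:
        raise ScreenIOError(f"unknown score metric {metric!r}")
    out = scores.copy()
    out.insert(0, "metric", metric)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_score_table(path: str | Path, expect_metric: str | None = None) -> tuple[pd.DataFrame, str]:
    table = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"metric": str},
                        float_precision="round_trip")
    if "metric" not in table.columns or len(table) and table["metric"].nunique() != 1:
        raise ScreenIOError(f"{path}: missing or inconsistent metric tag")
    metric = str(table["metric"].iloc[0]) if len(table) else (expect_metric or "")
    if metric not in SCORE_METRICS:
        raise ScreenIOError(f"{path}: unknown metric tag {metric!r}")
    if expect_metric is not None and metric != expect_metric:
        raise ScreenIOError(
            f"{path}: metric tag {metric!r} does not match expected {expect_metric!r}"
        )
    return table.drop(columns=["metric"]), metric
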