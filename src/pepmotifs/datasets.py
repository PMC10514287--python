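"""Peptide dataset input, presequence extraction and filtering.

Inputs are a FASTA of peptide (or full-protein) sequences plus a TSV
metadata table keyed by sequence id with columns ``id``, ``seq_type``
(cTP | mTP | SP | AMP), ``lineage`` (semicolon-delimited, root→leaf) and
optionally ``cleavage_pos`` — the 1-based position of the last presequence
residue, used to cut the N-terminal presequence out of a full protein.

Filtering mirrors curated-dataset practice for targeting peptides: drop
sequences with non-standard or ambiguous residues (anything outside the 20
canonical letters, incl. B, J, O, U, X, Z), then sequences shorter than 10,
then — for AMP sets — longer than 100, then exact duplicate residue strings
(first occurrence kept).  Each step's removals are tallied in a
:class:`FilterReport`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .motifs import STANDARD_AA

logger = logging.getLogger(__name__)

SEQ_TYPES = ("cTP", "mTP", "SP", "AMP")
_STANDARD_SET = frozenset(STANDARD_AA)


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: identity, residues, sequence type and taxonomy lineage."""

    id: str
    sequence: str
    seq_type: str
    lineage: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"record {self.id!r} has an empty sequence")
        if self.seq_type not in SEQ_TYPES:
            raise DataError(
                f"record {self.id!r}: seq_type must be one of {SEQ_TYPES}, "
                f"got {self.seq_type!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Sequence tallies for each filtering step; counts sum exactly."""

    n_input: int = 0
    n_removed_nonstandard: int = 0
    n_removed_short: int = 0
    n_removed_long: int = 0
    n_removed_duplicate: int = 0
    n_output: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def extract_presequence(record: PeptideRecord, cleavage_pos: int) -> PeptideRecord:
    """Cut the N-terminal presequence: residues 1..cleavage_pos (1-based,
    inclusive).  Out-of-range positions reject the record."""
    if not 1 <= cleavage_pos <= len(record.sequence):
        raise DataError(
            f"record {record.id!r}: cleavage position {cleavage_pos} outside "
            f"1..{len(record.sequence)}"
        )
    return replace(record, sequence=record.sequence[:cleavage_pos])


def filter_dataset(
    records: Sequence[PeptideRecord],
    min_len: int = 10,
    max_len: int | None = None,
) -> tuple[list[PeptideRecord], FilterReport]:
    """Apply the standard filters in order (nonstandard → short → long →
    duplicate); a sequence failing several rules is counted once, under the
    first.  Survivors keep their input order."""
    report = FilterReport(n_input=len(records))
    kept: list[PeptideRecord] = []
    seen: set[str] = set()
    for rec in records:
        seq = rec.sequence
        if not _STANDARD_SET.issuperset(seq):
            report.n_removed_nonstandard += 1
        elif len(seq) < min_len:
            report.n_removed_short += 1
        elif max_len is not None and len(seq) > max_len:
            report.n_removed_long += 1
        elif seq in seen:
            report.n_removed_duplicate += 1
        else:
            seen.add(seq)
            kept.append(rec)
    report.n_output = len(kept)
    return kept, report


def _parse_lineage(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return ()
    return tuple(t.strip() for t in str(value).split(";") if t.strip())


def read_peptides(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[PeptideRecord]:
    """Join FASTA sequences with the TSV metadata table.

    Ids present in FASTA but absent from metadata are rejected with a logged
    reason, as are records whose cleavage position is out of range.  When a
    ``cleavage_pos`` value is present, the presequence is extracted before
    any filtering.
    """
    try:
        fasta = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise DataError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    if not fasta:
        raise DataError(f"no FASTA records parsed from {fasta_path}")
    seen_ids: set[str] = set()
    for rec in fasta:
        if rec.id in seen_ids:
            raise DataError(f"duplicate id {rec.id!r} within FASTA {fasta_path}")
        seen_ids.add(rec.id)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str})
    required = {"id", "seq_type", "lineage"}
    if not required.issubset(meta.columns):
        raise DataError(
            f"metadata {metadata_path} must have columns {sorted(required)}"
        )
    meta = meta.set_index("id", verify_integrity=True)

    records: list[PeptideRecord] = []
    for rec in fasta:
        if rec.id not in meta.index:
            logger.warning("rejecting %s: no metadata row", rec.id)
            continue
        row = meta.loc[rec.id]
        record = PeptideRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            seq_type=str(row["seq_type"]),
            lineage=_parse_lineage(row.get("lineage")),
        )
        cleavage = row.get("cleavage_pos")
        if cleavage is not None and not pd.isna(cleavage):
            try:
                record = extract_presequence(record, int(cleavage))
            except DataError as exc:
                logger.warning("rejecting %s: %s", rec.id, exc)
                continue
        records.append(record)
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_metadata(records: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = [
        {"id": r.id, "seq_type": r.seq_type, "lineage": ";".join(r.lineage)}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "seq_type", "lineage"]).to_csv(
        path, sep="\t", index=False
    )
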