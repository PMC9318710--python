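"""Protein sequence databases and annotation bookkeeping.

Reads curated allergen FASTA databases (or any FASTA) into validated
:class:`ProteinRecord` objects, attaches signal-peptide ranges supplied as a
side table, and tallies accessions by Pfam-style family/clan annotations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 proteinogenic residues plus X for an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry.

    ``signal_range`` is a 1-based inclusive interval marking an N-terminal
    signal peptide (removed in planta for seed storage proteins); positions
    elsewhere in the package are always reported on the full precursor.
    """

    accession: str
    sequence: str
    description: str = ""
    source_tag: str = ""
    signal_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in VALID_RESIDUES]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"non-amino-acid character {char!r} at position {pos} "
                f"in accession {self.accession!r}"
            )
        if self.signal_range is not None:
            s, e = self.signal_range
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(
                    f"signal range {self.signal_range} outside [1, {len(self.sequence)}] "
                    f"for accession {self.accession!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_accession(header_id: str) -> str:
    """First whitespace token, with UniProt ``db|ACC|name`` reduced to ACC."""
    token = header_id.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def load_fasta(path: str | Path, source_tag: str = "") -> list[ProteinRecord]:
    """Read a FASTA file into validated protein records, in file order.

    Sequences are uppercased and ``*`` stop characters stripped from the ends.
    Duplicate accessions, empty sequences and non-amino-acid characters are
    hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = _parse_accession(entry.id)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        sequence = str(entry.seq).upper().strip("*")
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=sequence,
                description=entry.description,
                source_tag=source_tag,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Serialise records back to FASTA (used by the round-trip tests)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def load_signal_ranges(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a ``accession  start  end`` TSV of 1-based inclusive signal ranges."""
    table = pd.read_csv(path, sep="\t", dtype={"accession": str})
    required = {"accession", "start", "end"}
    if not required <= set(table.columns):
        raise ValueError(f"signal-range table must have columns {sorted(required)}")
    return {
        str(row.accession): (int(row.start), int(row.end))
        for row in table.itertuples(index=False)
    }


def attach_signal_ranges(
    records: Sequence[ProteinRecord], ranges: dict[str, tuple[int, int]]
) -> list[ProteinRecord]:
    """Return records with signal ranges attached where the table provides one."""
    return [
        replace(r, signal_range=ranges[r.accession]) if r.accession in ranges else r
        for r in records
    ]


def load_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read an ``accession  family  clan`` TSV; the clan column may be empty."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"accession", "family"} <= set(table.columns):
        raise ValueError("annotation table must have columns accession and family")
    if "clan" not in table.columns:
        table["clan"] = ""
    return table[["accession", "family", "clan"]]


def tally_by_annotation(
    records: Sequence[ProteinRecord],
    annotation_table: pd.DataFrame,
    group_by: str = "family",
) -> pd.DataFrame:
    """Count distinct accessions per annotation group.

    Every accession is counted once per distinct group it maps to; accessions
    absent from the table (or mapping only to empty groups) are reported under
    ``unassigned``. Returns a DataFrame with columns ``group`` and ``n``.
    """
    if group_by not in ("family", "clan"):
        raise ValueError(f"group_by must be 'family' or 'clan', got {group_by!r}")
    if not records:
        return pd.DataFrame(columns=["group", "n"])
    mapping = annotation_table[annotation_table[group_by] != ""]
    acc_groups: dict[str, set[str]] = {}
    for row in mapping.itertuples(index=False):
        acc_groups.setdefault(row.accession, set()).add(getattr(row, group_by))
    tally: dict[str, int] = {}
    unassigned = 0
    for record in records:
        groups = acc_groups.get(record.accession, set())
        if not groups:
            unassigned += 1
        for group in groups:
            tally[group] = tally.get(group, 0) + 1
    if unassigned:
        tally["unassigned"] = unassigned
    return pd.DataFrame(sorted(tally.items()), columns=["group", "n"])


def fetch_uniprot_fasta(accession: str, dest: str | Path) -> Path:
    """Download one UniProt entry as FASTA and cache it at ``dest``.

    Purely a convenience for environments with network access (e.g. to place
    the real allergen sequence behind a validation fixture); nothing in the
    package or its tests requires the network — they fall back to the shipped
    synthetic stand-in.
    """
    import urllib.request

    dest = Path(dest)
    if not dest.exists():
        url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
        with urllib.request.urlopen(url, timeout=30) as response:
            dest.write_bytes(response.read())
    return dest


def packaged_path(name: str) -> Path:
    """Path to a data file shipped inside the package (rule tables, fixtures)."""
    return Path(str(importlib.resources.files("digestomics") / "data" / name))
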