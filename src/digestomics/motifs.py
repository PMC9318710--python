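"""IgE-epitope and coeliac-toxic-motif scanning of identified peptides.

Containment is exact substring matching against a curated motif library;
overlapping occurrences all count. Bioaccessibility tallies are per
identified-peptide row by default (the most literal "non-unique" counting),
with a per-distinct-peptide alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapping import PeptideObservation, strip_modifications
from .sequence_db import packaged_path

MOTIF_CLASSES = ("IgE_epitope", "coeliac_toxic")


@dataclass(frozen=True)
class MotifEntry:
    motif: str
    motif_class: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"motif {self.motif!r} shorter than 4 residues")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(
                f"motif class {self.motif_class!r} not in {MOTIF_CLASSES}"
            )


@dataclass(frozen=True)
class MotifInstance:
    """One motif occurrence within a peptide (1-based offset)."""

    peptide: str
    sample: str
    motif: str
    motif_class: str
    offset: int

    def __post_init__(self) -> None:
        window = strip_modifications(self.peptide)[
            self.offset - 1 : self.offset - 1 + len(self.motif)
        ]
        if window != self.motif:
            raise ValueError(
                f"slice check failed: {self.peptide!r}[{self.offset}..] != {self.motif!r}"
            )


class MotifLibrary:
    """Unique (motif, class) entries with optional deamidation-aware matching."""

    def __init__(self, entries: Iterable[MotifEntry]):
        seen: set[tuple[str, str]] = set()
        unique: list[MotifEntry] = []
        for entry in entries:
            key = (entry.motif, entry.motif_class)
            if key in seen:
                raise ValueError(f"duplicate library entry {key}")
            seen.add(key)
            unique.append(entry)
        self.entries: tuple[MotifEntry, ...] = tuple(unique)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifLibrary":
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"motif", "class"}
        if not required <= set(table.columns):
            raise ValueError("motif library TSV needs columns 'motif' and 'class'")
        return cls(
            MotifEntry(
                motif=str(row["motif"]),
                motif_class=str(row["class"]),
                source_id=str(row.get("source_id", "")),
            )
            for _, row in table.iterrows()
        )

    @classmethod
    def demo(cls) -> "MotifLibrary":
        """The small shipped demonstration library (motifs quoted in print)."""
        return cls.from_tsv(packaged_path("motifs_demo.tsv"))


def scan_peptide(
    peptide: str,
    library: MotifLibrary,
    sample: str = "",
    deamidation_aware: bool = False,
) -> list[MotifInstance]:
    """All motif occurrences within one peptide, overlaps included.

    With ``deamidation_aware`` a Glu in the peptide may stand in for a Gln in
    the motif (tissue-transglutaminase Q->E deamidation). Results are ordered
    by (motif, offset).
    """
    if len(library) == 0:
        raise ValueError("motif library is empty")
    backbone = strip_modifications(peptide)
    haystack = backbone.replace("E", "Q") if deamidation_aware else backbone
    instances: list[MotifInstance] = []
    for entry in sorted(library, key=lambda e: (e.motif, e.motif_class)):
        needle = entry.motif.replace("E", "Q") if deamidation_aware else entry.motif
        i = haystack.find(needle)
        while i != -1:
            instances.append(
                MotifInstance(
                    peptide=peptide,
                    sample=sample,
                    motif=backbone[i : i + len(entry.motif)]
                    if deamidation_aware
                    else entry.motif,
                    motif_class=entry.motif_class,
                    offset=i + 1,
                )
            )
            i = haystack.find(needle, i + 1)
    instances.sort(key=lambda m: (m.motif, m.offset))
    return instances


def scan_observations(
    observations: Sequence[PeptideObservation],
    library: MotifLibrary,
    deamidation_aware: bool = False,
    dedupe_peptides: bool = False,
) -> list[MotifInstance]:
    """Scan every observation row (or every distinct (peptide, sample))."""
    if dedupe_peptides:
        seen: set[tuple[str, str]] = set()
        rows = []
        for obs in observations:
            key = (strip_modifications(obs.peptide), obs.sample)
            if key not in seen:
                seen.add(key)
                rows.append(obs)
    else:
        rows = list(observations)
    instances: list[MotifInstance] = []
    for obs in rows:
        instances.extend(
            scan_peptide(
                obs.peptide, library, sample=obs.sample,
                deamidation_aware=deamidation_aware,
            )
        )
    return instances


def tally_by_sample(
    observations: Sequence[PeptideObservation],
    library: MotifLibrary,
    dedupe_peptides: bool = False,
    deamidation_aware: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample bioaccessibility tallies.

    Returns two tables: (1) per (sample, class): total motif-instance count,
    number of scanned peptide rows carrying >= 1 instance, number carrying
    >= 2 distinct IgE-epitope instances (IgE rows only), and the median length
    of motif-bearing peptides; (2) the long-form per-class peptide-length
    distribution underlying those medians.
    """
    rows = []
    length_rows = []
    if dedupe_peptides:
        seen: set[tuple[str, str]] = set()
        scanned = []
        for obs in observations:
            key = (strip_modifications(obs.peptide), obs.sample)
            if key not in seen:
                seen.add(key)
                scanned.append(obs)
    else:
        scanned = list(observations)
    per_key: dict[tuple[str, str], dict[str, list[int] | int]] = {}
    for obs in scanned:
        instances = scan_peptide(
            obs.peptide, library, sample=obs.sample, deamidation_aware=deamidation_aware
        )
        length = len(strip_modifications(obs.peptide))
        by_class: dict[str, int] = {}
        for inst in instances:
            by_class[inst.motif_class] = by_class.get(inst.motif_class, 0) + 1
        for motif_class in MOTIF_CLASSES:
            key = (obs.sample, motif_class)
            slot = per_key.setdefault(
                key, {"instances": 0, "peptides": 0, "multi": 0, "lengths": []}
            )
            n = by_class.get(motif_class, 0)
            slot["instances"] += n
            if n >= 1:
                slot["peptides"] += 1
                slot["lengths"].append(length)
                length_rows.append(
                    {"sample": obs.sample, "class": motif_class, "length": length}
                )
            if motif_class == "IgE_epitope" and n >= 2:
                slot["multi"] += 1
    for (sample, motif_class), slot in sorted(per_key.items()):
        lengths = slot["lengths"]
        rows.append(
            {
                "sample": sample,
                "class": motif_class,
                "instances": slot["instances"],
                "peptides_with_motif": slot["peptides"],
                "peptides_with_2plus_ige": slot["multi"]
                if motif_class == "IgE_epitope"
                else 0,
                "median_length": float(np.median(lengths)) if lengths else float("nan"),
            }
        )
    tally = pd.DataFrame(
        rows,
        columns=[
            "sample", "class", "instances", "peptides_with_motif",
            "peptides_with_2plus_ige", "median_length",
        ],
    )
    lengths = pd.DataFrame(length_rows, columns=["sample", "class", "length"])
    return tally, lengths


def instance_table(instances: Iterable[MotifInstance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": m.peptide,
                "sample": m.sample,
                "motif": m.motif,
                "class": m.motif_class,
                "offset": m.offset,
            }
            for m in instances
        ],
        columns=["peptide", "sample", "motif", "class", "offset"],
    )
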