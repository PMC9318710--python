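"""Peptide-to-protein mapping, spectral-count profiles and length summaries.

Identified peptides are located exactly on the parent sequence; peptides
occurring at more than one position within a protein (typical of prolamin
repetitive domains) are flagged ambiguous and excluded from per-residue
spectral counting, with their summed counts tallied separately so nothing is
silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_db import ProteinRecord

log = logging.getLogger(__name__)

_MOD_PATTERN = re.compile(r"\([^)]*\)|\[[^\]]*\]|[^A-Za-z]")


def strip_modifications(peptide: str) -> str:
    """Reduce a search-engine peptide string to its plain uppercase backbone.

    Removes parenthesised/bracketed modification annotations (e.g.
    ``Q(+.98)QPF``) and any non-letter characters.
    """
    return _MOD_PATTERN.sub("", peptide).upper()


@dataclass(frozen=True)
class PeptideObservation:
    """One identified-peptide row of a PEAKS-style export."""

    peptide: str
    sample: str
    spectral_count: int = 1
    modifications: str | None = None
    claimed_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")


@dataclass(frozen=True)
class PeptideLocation:
    """One exact occurrence of a peptide within a protein (1-based inclusive)."""

    accession: str
    start: int
    end: int
    ambiguous: bool


@dataclass
class ResidueProfile:
    """Per-residue summed spectral counts over one protein."""

    accession: str
    counts: np.ndarray
    denominator_mask: np.ndarray  # True where a residue counts toward coverage
    ambiguous_spectral_count: int = 0
    n_unmapped: int = 0

    @property
    def coverage_fraction(self) -> float:
        denom = int(self.denominator_mask.sum())
        if denom == 0:
            return 0.0
        covered = int(((self.counts > 0) & self.denominator_mask).sum())
        return covered / denom


def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read a ``peptide  sample  spectral_count  modifications  accession`` TSV.

    The last three columns are optional; without a count column each row
    counts one spectrum.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty and not {"peptide", "sample"} <= set(table.columns):
        return []
    if not {"peptide", "sample"} <= set(table.columns):
        raise ValueError("peptide table must have columns 'peptide' and 'sample'")
    observations = []
    for row in table.itertuples(index=False):
        count = getattr(row, "spectral_count", None)
        observations.append(
            PeptideObservation(
                peptide=str(row.peptide),
                sample=str(row.sample),
                spectral_count=int(count) if count is not None and not pd.isna(count) else 1,
                modifications=getattr(row, "modifications", None) or None,
                claimed_accession=getattr(row, "accession", None) or None,
            )
        )
    return observations


def write_peptide_table(observations: Iterable[PeptideObservation], path: str | Path) -> None:
    rows = [
        {
            "peptide": o.peptide,
            "sample": o.sample,
            "spectral_count": o.spectral_count,
            "modifications": o.modifications or "",
            "accession": o.claimed_accession or "",
        }
        for o in observations
    ]
    pd.DataFrame(
        rows, columns=["peptide", "sample", "spectral_count", "modifications", "accession"]
    ).to_csv(path, sep="\t", index=False)


def locate(
    peptide: str, protein: ProteinRecord | str, il_equivalent: bool = False
) -> list[PeptideLocation]:
    """All exact occurrences of ``peptide`` in the protein, overlaps included.

    Matching is on the modification-stripped sequence; with ``il_equivalent``
    Ile and Leu are folded together before matching. Every returned location
    is flagged ambiguous when there is more than one.
    """
    if isinstance(protein, ProteinRecord):
        accession, sequence = protein.accession, protein.sequence
    else:
        accession, sequence = "", protein
    query = strip_modifications(peptide)
    if not query:
        raise ValueError("peptide must be non-empty")
    haystack = sequence
    if il_equivalent:
        query = query.replace("I", "L")
        haystack = haystack.replace("I", "L")
    starts = []
    i = haystack.find(query)
    while i != -1:
        starts.append(i + 1)
        i = haystack.find(query, i + 1)
    ambiguous = len(starts) > 1
    return [
        PeptideLocation(accession, s, s + len(query) - 1, ambiguous) for s in starts
    ]


def build_profile(
    observations: Sequence[PeptideObservation],
    protein: ProteinRecord,
    denominator: str = "full",
    il_equivalent: bool = False,
) -> ResidueProfile:
    """Per-residue spectral-count accumulation over one protein.

    Unambiguous observations add their spectral count to every residue they
    span; ambiguous (multi-locus) observations contribute nothing to the
    counts but their summed spectral counts are tallied on the profile.
    Observations that do not locate in the protein are dropped with a warning.
    """
    if denominator not in ("full", "exclude_signal"):
        raise ValueError("denominator must be 'full' or 'exclude_signal'")
    L = len(protein.sequence)
    counts = np.zeros(L, dtype=np.int64)
    mask = np.ones(L, dtype=bool)
    if denominator == "exclude_signal" and protein.signal_range is not None:
        s, e = protein.signal_range
        mask[s - 1 : e] = False
    ambiguous_total = 0
    n_unmapped = 0
    for obs in observations:
        locations = locate(obs.peptide, protein, il_equivalent=il_equivalent)
        if not locations:
            n_unmapped += 1
            log.warning(
                "peptide %s (sample %s) does not locate in %s; dropped",
                obs.peptide, obs.sample, protein.accession,
            )
            continue
        if locations[0].ambiguous:
            ambiguous_total += obs.spectral_count
            continue
        loc = locations[0]
        counts[loc.start - 1 : loc.end] += obs.spectral_count
    return ResidueProfile(
        accession=protein.accession,
        counts=counts,
        denominator_mask=mask,
        ambiguous_spectral_count=ambiguous_total,
        n_unmapped=n_unmapped,
    )


def coverage(profile: ResidueProfile) -> float:
    """Fraction of denominator residues with a positive spectral count."""
    return profile.coverage_fraction


def profile_table(profile: ResidueProfile, protein: ProteinRecord) -> pd.DataFrame:
    """Long-form ``accession  position  residue  count`` table of a profile."""
    return pd.DataFrame(
        {
            "accession": profile.accession,
            "position": np.arange(1, len(protein.sequence) + 1),
            "residue": list(protein.sequence),
            "count": profile.counts,
        }
    )


def length_summary(
    observations: Sequence[PeptideObservation],
    compare: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample peptide-length profile and pairwise rank-sum tests.

    Lengths are weighted one per observation row (not by spectral count),
    measured on the modification-stripped backbone. Returns a per-sample
    summary (n, median, q1, q3) and a table of two-sided Wilcoxon rank-sum
    p-values for the requested sample pairs (default: all pairs, in sorted
    sample order).
    """
    lengths: dict[str, list[int]] = {}
    for obs in observations:
        lengths.setdefault(obs.sample, []).append(len(strip_modifications(obs.peptide)))
    summary = pd.DataFrame(
        [
            {
                "sample": sample,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            }
            for sample, vals in sorted(lengths.items())
        ],
        columns=["sample", "n", "median", "q1", "q3"],
    )
    samples = sorted(lengths)
    if compare is None:
        compare = [(a, b) for i, a in enumerate(samples) for b in samples[i + 1 :]]
    rows = []
    for a, b in compare:
        if a not in lengths or b not in lengths:
            raise ValueError(f"comparison with empty/unknown group: {a!r} vs {b!r}")
        result = stats.ranksums(lengths[a], lengths[b])
        rows.append({"sample_a": a, "sample_b": b, "statistic": float(result.statistic),
                     "p_value": float(result.pvalue)})
    tests = pd.DataFrame(rows, columns=["sample_a", "sample_b", "statistic", "p_value"])
    return summary, tests


def plot_profile(profile: ResidueProfile, ax=None, **kwargs):
    """Spectral counts as a function of residue position (Fig-7-style)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(np.arange(1, len(profile.counts) + 1), profile.counts, **kwargs)
    ax.set_xlabel("residue position")
    ax.set_ylabel("spectral count")
    ax.set_title(profile.accession)
    return ax
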