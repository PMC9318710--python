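"""Observed cleavage-site inference and classification.

Peptide termini of unambiguously mapped peptides are read as evidence of an
inter-residue cleavage; each observed site is then classified against the
predicted specificity of the enzymes active in the digestion phase. Sites
explained by no enzyme are "alternative" — in glutamine-rich seed storage
prolamins these cluster next to Gln, which the adjacency summary quantifies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digestion import CleavageSiteSet
from .mapping import PeptideObservation, locate
from .sequence_db import ProteinRecord

log = logging.getLogger(__name__)

#: Enzyme-class label attached to each specificity model name.
ENZYME_CLASSES = {
    "pepsin_ph1.3": "peptic",
    "pepsin_ph2": "peptic",
    "pepsin": "peptic",
    "chymotrypsin_high": "chymotryptic",
    "chymotrypsin_low": "chymotryptic",
    "chymotrypsin_low_paper": "chymotryptic",
    "chymo_low_full": "chymotryptic",
    "chymo_low_paper": "chymotryptic",
    "trypsin": "tryptic",
}

#: Enzyme classes active per digestion phase. Pepsin is retained in the
#: duodenal set because peptic termini from the gastric phase carry over.
PHASE_ENZYMES = {
    "gastric": frozenset({"peptic"}),
    "duodenal": frozenset({"peptic", "chymotryptic", "tryptic"}),
}


@dataclass(frozen=True)
class SiteClassification:
    """One observed inter-residue cleavage position with its enzyme labels."""

    accession: str
    site: int
    observed_count: int
    classes: frozenset[str]
    is_common: bool
    is_alternative: bool
    p1_residue: str
    p1prime_residue: str


def infer_observed_sites(
    observations: Sequence[PeptideObservation],
    protein: ProteinRecord,
    il_equivalent: bool = False,
) -> dict[int, int]:
    """Map observed cleavage site -> summed spectral counts of its evidence.

    A peptide located unambiguously at ``(s, e)`` evidences the bond ``s-1``
    (unless it starts at the N-terminus) and the bond ``e`` (unless it ends at
    the C-terminus). Ambiguous (multi-locus) peptides are excluded.
    """
    L = len(protein.sequence)
    sites: dict[int, int] = {}
    for obs in observations:
        locations = locate(obs.peptide, protein, il_equivalent=il_equivalent)
        if not locations or locations[0].ambiguous:
            continue
        loc = locations[0]
        if loc.start > 1:
            sites[loc.start - 1] = sites.get(loc.start - 1, 0) + obs.spectral_count
        if loc.end < L:
            sites[loc.end] = sites.get(loc.end, 0) + obs.spectral_count
    return sites


def classify_sites(
    observed: Mapping[int, int],
    predicted: Mapping[str, CleavageSiteSet],
    protein: ProteinRecord,
    phase: str,
    min_site_count: int = 1,
) -> tuple[list[SiteClassification], dict[str, int]]:
    """Label each observed site by the enzyme specificities that predict it.

    ``predicted`` maps specificity-model names (e.g. ``pepsin_ph2``) to site
    sets; models whose enzyme class is outside the phase are ignored with a
    warning. The summary reports single-enzyme counts *inclusively* (a common
    pepsin/chymotrypsin site counts under both and under ``common``) together
    with two totals: ``total_distinct`` (classified union + alternative — the
    arithmetic of the predicted-sites accounting) and ``inclusive_sum`` (sum
    of the per-class columns plus alternative, the other published
    convention), so both tallies stay auditable.
    """
    if phase not in PHASE_ENZYMES:
        raise ValueError(f"phase must be one of {sorted(PHASE_ENZYMES)}")
    active = PHASE_ENZYMES[phase]
    by_class: dict[str, frozenset[int]] = {}
    for name, site_set in predicted.items():
        enzyme_class = ENZYME_CLASSES.get(name)
        if enzyme_class is None:
            raise KeyError(f"no enzyme class for specificity model {name!r}")
        if enzyme_class not in active:
            warnings.warn(
                f"model {name!r} ({enzyme_class}) is outside the {phase} phase; ignored",
                stacklevel=2,
            )
            continue
        by_class[enzyme_class] = by_class.get(enzyme_class, frozenset()) | site_set.sites

    records: list[SiteClassification] = []
    for site in sorted(observed):
        count = observed[site]
        if count < min_site_count:
            continue
        classes = frozenset(c for c, sites in by_class.items() if site in sites)
        records.append(
            SiteClassification(
                accession=protein.accession,
                site=site,
                observed_count=count,
                classes=classes,
                is_common={"peptic", "chymotryptic"} <= classes,
                is_alternative=not classes,
                p1_residue=protein.sequence[site - 1],
                p1prime_residue=protein.sequence[site],
            )
        )

    classified_union = sum(1 for r in records if r.classes)
    summary = {
        "peptic": sum(1 for r in records if "peptic" in r.classes),
        "chymotryptic": sum(1 for r in records if "chymotryptic" in r.classes),
        "common": sum(1 for r in records if r.is_common),
        "tryptic": sum(1 for r in records if "tryptic" in r.classes),
        "alternative": sum(1 for r in records if r.is_alternative),
        "total_distinct": len(records),
    }
    summary["inclusive_sum"] = (
        summary["peptic"] + summary["chymotryptic"] + summary["tryptic"]
        + summary["alternative"]
    )
    assert summary["total_distinct"] == classified_union + summary["alternative"]
    return records, summary


def classification_table(records: Iterable[SiteClassification]) -> pd.DataFrame:
    """Long-form per-site TSV layout of a classification."""
    rows = [
        {
            "accession": r.accession,
            "site": r.site,
            "p1": r.p1_residue,
            "p1prime": r.p1prime_residue,
            "classes": ",".join(sorted(r.classes)) or "alternative",
            "common": r.is_common,
            "alternative": r.is_alternative,
            "observed_count": r.observed_count,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "site", "p1", "p1prime", "classes",
            "common", "alternative", "observed_count",
        ],
    )


def residue_adjacency_summary(
    classifications: Sequence[SiteClassification], focus_residue: str = "Q"
) -> pd.DataFrame:
    """Among alternative sites, how many have the focus residue at P1 / P1'.

    Returns rows for contexts ``P1``, ``P1'`` and ``either`` with the count of
    alternative sites and the fraction of all alternative sites.
    """
    alternative = [c for c in classifications if c.is_alternative]
    n_alt = len(alternative)
    n_p1 = sum(1 for c in alternative if c.p1_residue == focus_residue)
    n_p1p = sum(1 for c in alternative if c.p1prime_residue == focus_residue)
    n_either = sum(
        1
        for c in alternative
        if focus_residue in (c.p1_residue, c.p1prime_residue)
    )
    rows = [
        {"context": "P1", "n_alternative": n_p1},
        {"context": "P1'", "n_alternative": n_p1p},
        {"context": "either", "n_alternative": n_either},
    ]
    for row in rows:
        row["fraction"] = row["n_alternative"] / n_alt if n_alt else 0.0
    return pd.DataFrame(rows, columns=["context", "n_alternative", "fraction"])
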