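"""Data-driven protease specificity engine.

Predicts endoprotease cleavage sites from rule tables over the P4..P4'
positions flanking a scissile bond, in the style of the PeptideCutter/Keil
specificity documentation, and enumerates digestion fragments with missed
cleavages.

Conventions
-----------
A cleavage *site* is an integer ``k`` meaning the bond between residues ``k``
and ``k+1`` (1-based), so ``k`` ranges over ``[1, L-1]``; P1 is residue ``k``
and P1' residue ``k+1``. Window positions beyond the termini act as wildcards
when licensing a site; an exception pattern, by contrast, only fires when its
positive context is actually present. The unknown residue X never satisfies a
positive residue constraint and never triggers an exception.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import yaml

from .sequence_db import AMINO_ACIDS, packaged_path

# Residue index (1-based) of each named window position relative to bond k:
# Pn sits n-1 residues N-terminal of the bond, Pn' sits n residues C-terminal.
POSITION_OFFSETS: dict[str, int] = {
    "P4": -3, "P3": -2, "P2": -1, "P1": 0,
    "P1'": 1, "P2'": 2, "P3'": 3, "P4'": 4,
}


@dataclass(frozen=True)
class Constraint:
    """One position constraint: residue must be ``in`` / ``not`` in a set."""

    mode: str  # "in" or "not"
    residues: frozenset[str]

    def satisfied_by(self, residue: str | None, *, positive_context: bool) -> bool:
        if residue is None:  # beyond the terminus
            return not positive_context or self.mode == "not"
        if self.mode == "in":
            return residue in self.residues and residue != "X"
        return residue not in self.residues


@dataclass(frozen=True)
class Rule:
    """Constraint map over named window positions; all must hold to match."""

    constraints: tuple[tuple[str, Constraint], ...]

    def matches(self, sequence: str, k: int, *, positive_context: bool = False) -> bool:
        for position, constraint in self.constraints:
            idx = k + POSITION_OFFSETS[position]  # 1-based residue index
            residue = sequence[idx - 1] if 1 <= idx <= len(sequence) else None
            if not constraint.satisfied_by(residue, positive_context=positive_context):
                return False
        return True


@dataclass(frozen=True)
class CleavageRuleSet:
    """A protease specificity model: licensing rules plus veto exceptions."""

    enzyme_name: str
    rules: tuple[Rule, ...]
    exceptions: tuple[Rule, ...] = ()
    description: str = ""

    def cuts_at(self, sequence: str, k: int) -> bool:
        """True iff some rule licenses bond ``k`` and no exception vetoes it."""
        if not any(rule.matches(sequence, k) for rule in self.rules):
            return False
        return not any(
            exc.matches(sequence, k, positive_context=True) for exc in self.exceptions
        )


@dataclass(frozen=True)
class CleavageSiteSet:
    """Predicted (or otherwise derived) cleavage sites of one protein."""

    accession: str
    enzyme_name: str
    sites: frozenset[int]

    def __len__(self) -> int:
        return len(self.sites)


def _parse_constraint(spec: str) -> Constraint:
    mode, _, residues = spec.strip().partition(" ")
    if mode not in ("in", "not") or not residues:
        raise ValueError(f"bad constraint {spec!r}; expected 'in RES' or 'not RES'")
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"constraint {spec!r} uses non-standard residues {sorted(bad)}")
    return Constraint(mode, frozenset(residues))


def _parse_rule(block: dict[str, str]) -> Rule:
    constraints = []
    for position, spec in block.items():
        if position not in POSITION_OFFSETS:
            raise ValueError(f"unknown window position {position!r}")
        constraints.append((position, _parse_constraint(str(spec))))
    rule = Rule(tuple(constraints))
    if not any(p in ("P1", "P1'") for p, _ in rule.constraints):
        raise ValueError("every rule must constrain P1 or P1'")
    return rule


@functools.lru_cache(maxsize=1)
def _builtin_tables(path: str | None = None) -> dict[str, CleavageRuleSet]:
    source = Path(path) if path else packaged_path("enzymes.yaml")
    with open(source) as handle:
        raw = yaml.safe_load(handle)
    tables: dict[str, CleavageRuleSet] = {}
    for name, body in raw.items():
        ruleset = CleavageRuleSet(
            enzyme_name=name,
            rules=tuple(_parse_rule(b) for b in body["rules"]),
            exceptions=tuple(_parse_rule(b) for b in body.get("exceptions") or ()),
            description=body.get("description", "").strip(),
        )
        tables[name] = ruleset
        for alias in body.get("aliases") or ():
            tables[alias] = ruleset
    return tables


def list_rulesets() -> list[str]:
    """Names (including aliases) of the shipped specificity models."""
    return sorted(_builtin_tables())


def load_ruleset(name: str) -> CleavageRuleSet:
    """Load a shipped specificity model by name; unknown names are an error."""
    tables = _builtin_tables()
    if name not in tables:
        raise KeyError(
            f"unknown enzyme ruleset {name!r}; available: {', '.join(sorted(tables))}"
        )
    return tables[name]


def predict_sites(
    sequence: str, ruleset: CleavageRuleSet | str, accession: str = ""
) -> CleavageSiteSet:
    """All bonds of ``sequence`` cut by the model; termini are never reported."""
    if isinstance(ruleset, str):
        ruleset = load_ruleset(ruleset)
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2 to contain a bond")
    sites = frozenset(
        k for k in range(1, len(sequence)) if ruleset.cuts_at(sequence, k)
    )
    return CleavageSiteSet(accession=accession, enzyme_name=ruleset.enzyme_name, sites=sites)


def common_sites(a: CleavageSiteSet, b: CleavageSiteSet) -> CleavageSiteSet:
    """Set intersection of two site sets of the same protein."""
    if a.accession != b.accession:
        raise ValueError(
            f"accession mismatch: {a.accession!r} vs {b.accession!r}"
        )
    return CleavageSiteSet(
        accession=a.accession,
        enzyme_name=f"{a.enzyme_name}∩{b.enzyme_name}",
        sites=a.sites & b.sites,
    )


def union_sites(*site_sets: CleavageSiteSet) -> CleavageSiteSet:
    """Set union over site sets of the same protein."""
    accessions = {s.accession for s in site_sets}
    if len(accessions) != 1:
        raise ValueError(f"accession mismatch across site sets: {sorted(accessions)}")
    sites: frozenset[int] = frozenset().union(*(s.sites for s in site_sets))
    return CleavageSiteSet(
        accession=site_sets[0].accession,
        enzyme_name="∪".join(s.enzyme_name for s in site_sets),
        sites=sites,
    )


def digest(
    sequence: str,
    sites: frozenset[int] | set[int],
    max_missed: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[tuple[str, int, int]]:
    """Enumerate fragments delimited by <= ``max_missed`` skipped internal sites.

    Returns ``(peptide, start, end)`` triples with 1-based inclusive
    coordinates, ordered by (start, end), filtered to ``[min_len, max_len]``.
    """
    L = len(sequence)
    if any(not 1 <= k <= L - 1 for k in sites):
        raise ValueError("sites must lie in [1, L-1]")
    boundaries = [0] + sorted(sites) + [L]
    fragments: list[tuple[str, int, int]] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            length = end - start + 1
            if length < min_len or (max_len is not None and length > max_len):
                continue
            fragments.append((sequence[start - 1 : end], start, end))
    fragments.sort(key=lambda f: (f[1], f[2]))
    return fragments
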