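"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written directly from the published cleavage-rule shorthand as
an anchored regular expression over an explicit P4..P2' window, deliberately
bypassing the package's data-driven rule engine. Window positions beyond the
termini are padded with '-' which, mirroring the wildcard convention, is
added to every character class of a *licensing* rule but to none of an
*exception* pattern.
"""

import re

PAD = "-"

# Window layout handed to each pattern: P4 P3 P2 P1 P1' P2' (6 characters).
# "in" classes get the pad char appended (wildcard beyond termini); "not"
# classes [^...] accept the pad (and X) automatically.
_RULES = {
    "pepsin_ph1.3": [r".[^HKR][^P][^R][FL][^P]", r".[^HKR][^P][FL-].[^P]"],
    "pepsin_ph2": [r".[^HKR][^P][^R][FLWY][^P]", r".[^HKR][^P][FLWY-].[^P]"],
    "chymotrypsin_high": [r"...[FY-][^P].", r"...[W-][^MP]."],
    "chymotrypsin_low": [
        r"...[FLY-][^P].",
        r"...[W-][^MP].",
        r"...[M-][^PY].",
        r"...[H-][^DMPW].",
    ],
    "chymotrypsin_low_paper": [r"...[FYWML-][^P]."],
    "trypsin": [r"...[KR-][^P].", r"..[W-][K-]P.", r"..[M-][R-]P."],
}
# Exceptions demand positive evidence: no pad in any class.
_EXCEPTIONS = {
    "trypsin": [r"..[CD]KD.", r"..CK[HY].", r"..CRK.", r"..RRH.", r"..RRR."],
}

# The pad-extended "in" classes above would wrongly let the P1/P1' pad match,
# but P1 and P1' always exist for a bond k in [1, L-1], so only P4..P2 and
# P2' ever hold the pad.


def window(sequence: str, k: int) -> str:
    padded = PAD * 3 + sequence + PAD
    return padded[k - 1 : k + 5]  # P4..P2' of the bond after residue k


def oracle_sites(sequence: str, enzyme: str) -> set[int]:
    rules = [re.compile(p) for p in _RULES[enzyme]]
    vetoes = [re.compile(p) for p in _EXCEPTIONS.get(enzyme, [])]
    sites = set()
    for k in range(1, len(sequence)):
        w = window(sequence, k)
        if any(r.fullmatch(w) for r in rules) and not any(v.fullmatch(w) for v in vetoes):
            sites.add(k)
    return sites


def oracle_fragments(sequence, sites, max_missed, min_len, max_len):
    """Exhaustive enumeration over all (start-boundary, end-boundary) pairs."""
    bounds = [0] + sorted(sites) + [len(sequence)]
    out = []
    for i, a in enumerate(bounds):
        for j in range(i + 1, len(bounds)):
            if j - i - 1 > max_missed:
                continue
            b = bounds[j]
            n = b - a
            if n < min_len or (max_len is not None and n > max_len):
                continue
            out.append((sequence[a:b], a + 1, b))
    return sorted(out, key=lambda f: (f[1], f[2]))


def naive_locate_starts(peptide: str, sequence: str) -> list[int]:
    """O(L*m) sliding-window scan, overlaps included (1-based starts)."""
    m = len(peptide)
    return [
        i + 1
        for i in range(len(sequence) - m + 1)
        if sequence[i : i + m] == peptide
    ]


def naive_scan_offsets(peptide: str, motif: str) -> list[int]:
    return naive_locate_starts(motif, peptide)
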