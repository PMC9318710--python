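# Gastrointestinal endoprotease specificity tables, hand-transcribed from the
# public PeptideCutter / Keil cleavage-rule documentation.
#
# Semantics (see digestomics.digestion):
#   * A bond k (between residues k and k+1, 1-based) is cut iff at least one
#     rule of the enzyme matches the P4..P4' window around it and no exception
#     pattern fires.
#   * Position constraints are "in <set>" (residue must be in the set) or
#     "not <set>" (residue must not be in the set).
#   * In rules, window positions beyond the termini are wildcards and satisfy
#     any constraint; in exceptions they satisfy only "not" constraints, so an
#     exception needs positive evidence of its blocking context.
#   * The unknown residue X never satisfies an "in" constraint and never
#     triggers an exception.

pepsin_ph1.3:
  description: >
    Pepsin at pH 1.3. Cleaves on either side of Phe/Leu; blocked by Pro at
    P2 or P2', by His/Lys/Arg at P3 and by Arg at P1.
  rules:
    - {P3: not HKR, P2: not P, P1: not R, "P1'": in FL, "P2'": not P}
    - {P3: not HKR, P2: not P, P1: in FL, "P2'": not P}
  exceptions: []

pepsin_ph2:
  description: >
    Pepsin at pH > 2. As pH 1.3 but with the hydrophobic/aromatic preference
    widened to Phe/Leu/Trp/Tyr on either side of the scissile bond.
  aliases: [pepsin]
  rules:
    - {P3: not HKR, P2: not P, P1: not R, "P1'": in FLWY, "P2'": not P}
    - {P3: not HKR, P2: not P, P1: in FLWY, "P2'": not P}
  exceptions: []

chymotrypsin_high:
  description: >
    Chymotrypsin, high-specificity model: C-terminal to Phe/Tyr (not before
    Pro) and Trp (not before Met or Pro).
  rules:
    - {P1: in FY, "P1'": not P}
    - {P1: in W, "P1'": not MP}
  exceptions: []

chymotrypsin_low:
  description: >
    Chymotrypsin, low-specificity model (full documented table): C-terminal
    to Phe/Leu/Tyr (not before Pro), Trp (not before Met/Pro), Met (not
    before Pro/Tyr) and His (not before Asp/Met/Pro/Trp).
  aliases: [chymo_low_full]
  rules:
    - {P1: in FLY, "P1'": not P}
    - {P1: in W, "P1'": not MP}
    - {P1: in M, "P1'": not PY}
    - {P1: in H, "P1'": not DMPW}
  exceptions: []

chymotrypsin_low_paper:
  description: >
    Chymotrypsin, low-specificity model reduced to its one-line shorthand:
    C-terminal to [FYWML], not before Pro. Kept alongside chymotrypsin_low
    because the shorthand omits the His rule and the Trp/Met exceptions of
    the full table.
  aliases: [chymo_low_paper]
  rules:
    - {P1: in FYWML, "P1'": not P}
  exceptions: []

trypsin:
  description: >
    Trypsin, default model: C-terminal to Lys/Arg, not before Pro, with the
    documented Keil exceptions; Trp-Lys-Pro and Met-Arg-Pro are cut despite
    the Pro.
  rules:
    - {P1: in KR, "P1'": not P}
    - {P2: in W, P1: in K, "P1'": in P}
    - {P2: in M, P1: in R, "P1'": in P}
  exceptions:
    - {P2: in CD, P1: in K, "P1'": in D}
    - {P2: in C, P1: in K, "P1'": in HY}
    - {P2: in C, P1: in R, "P1'": in K}
    - {P2: in R, P1: in R, "P1'": in HR}
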