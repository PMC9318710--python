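# Methods

## The specificity engine

A protease model is a list of *rules* over the window P4 P3 P2 P1 | P1′ P2′
around a candidate bond `k` (P1 = residue `k`, P1′ = residue `k+1`,
1-based; `k ∈ [1, L−1]`, so the chain termini are never sites). Each rule
constrains some positions with an allowed (`in`) or forbidden (`not`)
residue set; a bond is licensed when any rule matches. *Exception* patterns
(used by the trypsin model: `[CD]KD`, `CK[HY]`, `CRK`, `RR[HR]`) veto a
licensed bond.

Numerical/edge conventions, chosen once and applied uniformly:

* **Termini.** Window positions beyond the sequence are wildcards for
  licensing rules (a site such as `A|F…` at bond 1 is reportable), but an
  exception only fires when its full positive context is present — absence
  of a residue is not evidence of a blocking context.
* **Unknown residues.** `X` never satisfies an `in` constraint and never
  triggers an exception; it passes `not` constraints. This is conservative
  for prediction: an unknown residue cannot create specificity evidence.
* **Duplicates.** A bond matched by several rules of one enzyme counts
  once; site sets are genuine sets.

The shipped tables are hand transcriptions of the public PeptideCutter/Keil
documentation: `pepsin_ph1.3`, `pepsin_ph2`, `chymotrypsin_high`,
`chymotrypsin_low` (full table, including the His rule and the Trp/Met
exclusions) and `trypsin`. Because the one-line shorthand "C-terminal to
[FYWML], not before P" differs from the full low-specificity chymotrypsin
table, both are shipped (`chymotrypsin_low_paper` vs `chymotrypsin_low`)
rather than silently picking one; which variant reproduces published
predicted-site counts can only be decided against the real allergen
sequence (see *Limitations*). The transcription is validated in tests by an
independent window-regex oracle over random sequences, and by hand-derived
examples; the published-count gate itself stays red until a real sequence
is supplied.

## Peptide mapping and spectral counting

Localisation is exact substring matching of the modification-stripped
peptide (PEAKS-style `Q(+.98)` annotations removed); variable modifications
are treated as decorations of the same backbone. No I/L equivalence by
default — exactness is auditable — with an `il_equivalent` option. A
peptide occurring at more than one position *within* one protein cannot be
placed and is excluded from per-residue counting; its summed spectral
counts are tallied separately so the exclusion is visible. Occurrence in
multiple proteins does not trigger exclusion; each protein is mapped
independently.

Per-residue profiles add each unambiguous observation's spectral count to
every residue it spans, so total profile mass equals
Σ count × length over unambiguous observations (a test invariant).
Coverage is the fraction of denominator residues with positive count; the
denominator defaults to the full precursor (signal peptide included)
because published coverage figures do not state their denominator, with
`exclude_signal` available.

Length statistics weight one length per observation row, not per spectrum:
a row is one identified peptide species, and spectral count is a
semi-quantitative abundance, not a sample size. Group comparisons use the
two-sided Wilcoxon rank-sum test (normal approximation), which returns
p = 1 for identical groups.

## Observed-site inference and classification

An unambiguous peptide at (s, e) evidences bonds s−1 (if s > 1) and e
(if e < L), each weighted by its spectral count. Classification labels a
site with every enzyme class whose predicted set contains it, restricted to
the phase's enzyme set — gastric {pepsin}; duodenal {pepsin, chymotrypsin,
trypsin}, pepsin retained because gastric termini carry over. A site with
no label is *alternative*. Labels depend only on the sequence window and
the predicted sets, never on counts, so classification is invariant to
observation order and to splitting counts across duplicate rows (tested).

Published predicted-vs-determined site tables use two different
accountings: the predicted row satisfies pepsin + chymotrypsin − common +
trypsin = union, while determined rows sum the inclusive columns without
subtracting the common ones. Rather than guessing which the reader wants,
the summary reports both: `total_distinct` (union + alternative) and
`inclusive_sum`. The Gln-adjacency summary reports, among alternative
sites, the count and fraction with Gln at P1, at P1′, and at either.

## The synthetic generator

The simulator emulates the *statistical shape* of a timepoint-resolved
digestion peptidome, not its chemistry. Per molecule (default 5000 per
protein) and per step, every predicted site of each active enzyme is cut
independently with probability `p_cleave` (pepsin 0.15/step × 8 gastric
steps; trypsin and chymotrypsin 0.2/step × 8 duodenal steps); bonds with
Gln at P1 or P1′ that no model predicts are cut with `p_alternative`
(0.01/step) — the atypical Gln-adjacent cleavage phenomenon seen in real
digests, injected at known positions. Cuts accumulate across phases; the oral phase contributes no
proteolysis and exists for pipeline-shape fidelity. Samples G0/G60/G120 and
D0/D60/D120 read the cut state at steps 1/4/8 of each phase (0.3, 60,
120 min on an 8-step grid); the duodenal phase continues from the *end* of
the gastric phase (simpler than branching from G60, documented deviation
from the wet protocol). At a sampled timepoint, each molecule's fragments
between consecutive realized cuts are emitted if their length lies in
[6, 40] — a hard stand-in for MS detectability (digestomics profiling is
typically limited to peptides longer than 5 residues, with the longest
identified peptides near 38), not a physical model. The spectral
count of a fragment is the number of molecules yielding it, optionally
Poisson-perturbed (zero draws drop the row, emulating detection dropout).

Defaults are the stated experimental world where one exists (timepoint
grid, enzyme phases, length floor) and one-time realism choices elsewhere
(5000 molecules gives per-site realization counts comparable to deep MS
profiling at desk-scale runtime; the cut probabilities put the gastric
endpoint near the published partial-digestion regime with median peptide
lengths in the low teens by D120). The default substrate is the packaged
synthetic LMW glutenin stand-in: Gln-rich, with a degenerate repetitive
domain whose two identical 16-mer blocks exercise the multi-locus
exclusion pathway, and a cysteine-poor C-terminal domain with few Lys/Arg,
like real low-molecular-weight glutenin subunits.

What a green simulator-recovery test establishes: the inference chain
(mapping → terminus inference → classification → adjacency) recovers the
generator's own ground truth under the generator's assumptions
(independent Bernoulli cutting, exact identifications, no chemistry). What
it does not establish: correctness on real spectra — no missed/false
identifications, no deamidation-induced mass shifts, no solubility or
matrix effects, no enzyme kinetics or secondary-structure protection.

## Degenerate inputs and tie-breaks

Empty peptide tables produce complete all-zero reports (exit 0 with a
warning). Peptides that do not locate are dropped with a logged warning and
counted on the profile. Within a simulation step, enzymes act in the
phase's declaration order, so a site cuttable by two enzymes in the same
step is attributed to the first; this only affects provenance labels on
common sites, never cut dynamics, since a cut site stays cut. Fragments are
emitted in (sample, start, end) order and all reports use fixed column
order and `\n` newlines, making reruns byte-identical (tested).

## Known limitations

* The packaged allergen fixture is synthetic. Its landmark coordinates
  (signal 1–20, repeat domain 34–197, 16-mer at 77/115, 20-mer at 142–161,
  Met344-Cys345, Thr354-Thr355) follow the published Tri a 36 peptide map,
  but its residue-level content is invented, so published absolute numbers
  (predicted-site counts 47/49/21/7/82, coverage percentages) are not
  reproduced by it, and the corresponding validation gate stays red until
  a real sequence is supplied at `tests/data/B2Y2Q7.fasta`.
* Specificity is rule-based and binary; no probabilistic cleavage scores,
  no proline-endopeptidase or brush-border enzymes, no pH interpolation.
* Motif matching is exact containment (optionally Q/E-folded); no partial
  epitopes, no HLA-DQ binding or transglutaminase site prediction.
* The simulator has no cooperativity, kinetics or matrix effects; counts
  are molecule tallies, not ion intensities.
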