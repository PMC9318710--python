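# digestomics

Analysis toolkit for *digestomics*: tracking what happens to food-allergen
proteins — and the immunologically active peptides they release — during
simulated gastrointestinal digestion, as measured by LC-MS/MS peptidomics.

It is written for food-allergy and coeliac-disease researchers who profile
in vitro oral–gastric–duodenal digests of protein-rich foods (wheat, soy,
novel proteins under allergenicity risk assessment) and need to go from a
peptide identification table to biological conclusions:

* **In silico digestion** — a data-driven protease specificity engine
  (pepsin at pH 1.3 and pH > 2, chymotrypsin high/low specificity, trypsin
  with its exception patterns, transcribed from the public
  PeptideCutter/Keil rule tables) predicting cleavage sites and theoretical
  digests with missed cleavages.
* **Peptide mapping** — exact localisation of identified peptides on parent
  proteins, exclusion of multi-locus peptides from repetitive prolamin
  domains, per-residue spectral-count profiles, sequence coverage and
  peptide-length statistics per digestion timepoint.
* **Cleavage-site classification** — observed peptide termini read as
  cleavage evidence and classified against predicted enzyme specificity;
  sites no enzyme explains are "alternative", and their adjacency to Gln
  (P1/P1′) is quantified — the signature of atypical cleavage in
  glutamine-rich cereal proteins.
* **Motif scanning** — exact-substring detection of IgE epitopes and
  coeliac toxic motifs in identified peptides, with per-timepoint
  bioaccessibility tallies and motif-bearing-peptide length distributions.
* **A synthetic digestion simulator** — progressive multi-phase Bernoulli
  cleavage with rare Gln-adjacent alternative cuts, a detectability length
  window and Poisson count noise, emitting PEAKS-style peptide tables
  *plus a full ground-truth record* for validating the analysis chain.

## Conventions

A cleavage site `k` is the bond between residues `k` and `k+1` (1-based);
P1 is residue `k`, P1′ residue `k+1`. A specificity model is an ordered set
of rules, each constraining window positions P4…P4′ with allowed/forbidden
residue sets, plus exception patterns that veto otherwise-licensed sites
(e.g. trypsin's `CK[HY]`). Rule tables live in an editable YAML data file,
not in code.

## Worked example

```python
import digestomics as dg
from digestomics.sequence_db import packaged_path
from digestomics.simulate import SimulationConfig, simulate

protein = dg.load_fasta(packaged_path("lmw_gs_synthetic.fasta"))[0]
pepsin = dg.predict_sites(protein.sequence, "pepsin_ph2", protein.accession)
chymo  = dg.predict_sites(protein.sequence, "chymotrypsin_low", protein.accession)
trypsin = dg.predict_sites(protein.sequence, "trypsin", protein.accession)
print(len(pepsin), len(chymo), len(dg.common_sites(pepsin, chymo)),
      len(trypsin), len(dg.union_sites(pepsin, chymo, trypsin)))
# 55 47 23 5 83   (predicted sites on the synthetic stand-in)

observations, truth = simulate(SimulationConfig.default(seed=1))
summary, tests = dg.length_summary(observations)
print(summary[summary["sample"].isin(["G0", "D120"])])
#   sample     n  median    q1    q3
#     D120  1573    11.0   8.0  15.0
#       G0  2291    22.0  13.0  31.0
```

The simulated digest reproduces the qualitative biology the analysis is
built for: median peptide length falls from 22 (G0) to 11 (D120) residues
(two-sided rank-sum p ≈ 5e-186), multi-epitope peptides peak in the late
gastric / early duodenal samples, and 100 % of "alternative" observed
cleavage sites sit N- or C-terminal to a Gln — exactly where the simulator
injects them, as recovered by `classify_sites` + `residue_adjacency_summary`.

The same workflow is scriptable from the shell:

```bash
digestomics simulate --seed 1 --out-prefix sim
digestomics run --config run.yaml        # full report bundle
digestomics digest-predict --fasta db.fasta \
    --enzyme pepsin_ph2+chymotrypsin_low+trypsin --out sites.tsv
```

`digestomics run` writes fixed-column TSVs (predicted sites, residue
profiles, coverage, per-sample observed/classified site summaries in the
predicted-vs-determined table layout, Gln-adjacency, motif tallies, length
summaries) plus a manifest with a config hash for reproducible reruns.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end workflow from scratch: it generates the
default synthetic digestion bundle with the given seed, runs the full
pipeline on it, and writes the results JSON to `--out`.
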