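import numpy as np
import pytest

from digestomics.cleavage import (
    SiteClassification,
    classification_table,
    classify_sites,
    infer_observed_sites,
    residue_adjacency_summary,
)
from digestomics.digestion import CleavageSiteSet
from digestomics.mapping import PeptideObservation
from digestomics.sequence_db import ProteinRecord

from oracles import naive_locate_starts


def _sets(accession, **sites):
    names = {"pepsin": "pepsin_ph2", "chymo": "chymotrypsin_low", "trypsin": "trypsin"}
    return {
        names[k]: CleavageSiteSet(accession, names[k], frozenset(v))
        for k, v in sites.items()
    }


class TestInferObservedSites:
    def test_full_length_peptide_contributes_no_sites(self, toy_protein):
        obs = [PeptideObservation(toy_protein.sequence, "D0")]
        assert infer_observed_sites(obs, toy_protein) == {}

    def test_internal_peptide_contributes_both_termini(self):
        protein = ProteinRecord("P", "A" * 4 + "MKVQQFSD" + "A" * 8)  # (5,12) of L=20
        obs = [PeptideObservation("MKVQQFSD", "D0", spectral_count=2)]
        assert infer_observed_sites(obs, protein) == {4: 2, 12: 2}

    def test_ambiguous_peptides_excluded(self, lmw_gs):
        obs = [PeptideObservation("QQQPPFSQQQPPFSQQ", "G60", spectral_count=9)]
        assert infer_observed_sites(obs, lmw_gs) == {}

    def test_matches_terminus_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))
        protein = ProteinRecord("P", seq)
        obs, expected = [], {}
        for _ in range(30):
            s = int(rng.integers(0, 140))
            n = int(rng.integers(6, 12))
            pep = seq[s : s + n]
            count = int(rng.integers(1, 5))
            obs.append(PeptideObservation(pep, "D0", spectral_count=count))
            starts = naive_locate_starts(pep, seq)
            if len(starts) != 1:
                continue
            start, end = starts[0], starts[0] + len(pep) - 1
            if start > 1:
                expected[start - 1] = expected.get(start - 1, 0) + count
            if end < len(seq):
                expected[end] = expected.get(end, 0) + count
        assert infer_observed_sites(obs, protein) == expected


class TestClassifySites:
    def test_gastric_single_enzyme(self, toy_protein):
        records, summary = classify_sites(
            {4: 1}, _sets("TOY1", pepsin={4}), toy_protein, phase="gastric"
        )
        assert summary == {
            "peptic": 1, "chymotryptic": 0, "common": 0, "tryptic": 0,
            "alternative": 0, "total_distinct": 1, "inclusive_sum": 1,
        }

    def test_duodenal_definitional_counts(self, toy_protein):
        records, summary = classify_sites(
            {4: 1, 9: 1},
            _sets("TOY1", pepsin={4}, chymo={4}, trypsin=set()),
            toy_protein,
            phase="duodenal",
        )
        assert summary["peptic"] == summary["chymotryptic"] == summary["common"] == 1
        assert summary["alternative"] == 1 and summary["total_distinct"] == 2
        assert summary["inclusive_sum"] == 3  # inclusive accounting double-counts common
        by_site = {r.site: r for r in records}
        assert by_site[4].is_common and not by_site[4].is_alternative
        assert by_site[9].is_alternative and by_site[9].classes == frozenset()

    def test_out_of_phase_model_ignored_with_warning(self, toy_protein):
        with pytest.warns(UserWarning, match="outside the gastric phase"):
            _, summary = classify_sites(
                {4: 1}, _sets("TOY1", pepsin={4}, trypsin={4}), toy_protein, phase="gastric"
            )
        assert summary["tryptic"] == 0 and summary["peptic"] == 1

    def test_min_site_count_threshold(self, toy_protein):
        _, summary = classify_sites(
            {4: 1, 9: 5}, _sets("TOY1", pepsin={4, 9}), toy_protein,
            phase="gastric", min_site_count=2,
        )
        assert summary["total_distinct"] == 1

    def test_invariant_to_count_splitting_and_order(self):
        """Class labels depend on sites only; splitting counts over duplicate
        rows or permuting observations changes nothing."""
        rng = np.random.default_rng(29)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        protein = ProteinRecord("P", seq)
        peps = [seq[s : s + 8] for s in (3, 17, 40, 60)]
        whole = [PeptideObservation(p, "D0", spectral_count=4) for p in peps]
        split = [PeptideObservation(p, "D0", spectral_count=2) for p in peps for _ in range(2)]
        rng.shuffle(split)
        predicted = _sets("P", pepsin={5, 11}, chymo={11}, trypsin={25})
        results = []
        for obs in (whole, split):
            records, summary = classify_sites(
                infer_observed_sites(obs, protein), predicted, protein, phase="duodenal"
            )
            results.append((classification_table(records).to_dict("records"), summary))
        assert results[0] == results[1]

    def test_summary_accounting_identity(self, toy_protein):
        """alternative + |classified union| = total; inclusive sum obeys
        inclusion-exclusion on the common column."""
        records, summary = classify_sites(
            {k: 1 for k in (2, 4, 6, 9, 11)},
            _sets("TOY1", pepsin={2, 4}, chymo={4, 6}, trypsin={11}),
            toy_protein,
            phase="duodenal",
        )
        classified = sum(1 for r in records if r.classes)
        assert summary["alternative"] + classified == summary["total_distinct"]
        distinct_classified = (
            summary["peptic"] + summary["chymotryptic"] - summary["common"]
            + sum(1 for r in records if r.classes == {"tryptic"})
        )
        assert distinct_classified == classified


class TestResidueAdjacency:
    def _alt(self, p1, p1p, site=5):
        return SiteClassification(
            accession="P", site=site, observed_count=1, classes=frozenset(),
            is_common=False, is_alternative=True, p1_residue=p1, p1prime_residue=p1p,
        )

    def test_no_alternative_sites_zero_table(self):
        table = residue_adjacency_summary([])
        assert table.n_alternative.tolist() == [0, 0, 0]
        assert table.fraction.tolist() == [0.0, 0.0, 0.0]

    def test_either_fraction(self):
        sites = [self._alt("Q", "A", 1), self._alt("A", "Q", 2), self._alt("F", "L", 3)]
        table = residue_adjacency_summary(sites).set_index("context")
        assert table.loc["P1", "n_alternative"] == 1
        assert table.loc["P1'", "n_alternative"] == 1
        assert table.loc["either", "fraction"] == pytest.approx(2 / 3)
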