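import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digestomics.mapping import (
    PeptideObservation,
    build_profile,
    coverage,
    length_summary,
    locate,
    profile_table,
    read_peptide_table,
    strip_modifications,
    write_peptide_table,
)
from digestomics.sequence_db import ProteinRecord

from oracles import naive_locate_starts


class TestLocate:
    def test_overlapping_occurrences_counted(self):
        starts = [l.start for l in locate("ARA", "ARARAR")]
        assert starts == [1, 3]
        assert all(l.ambiguous for l in locate("ARA", "ARARAR"))

    def test_full_length_match_unambiguous(self, toy_protein):
        locs = locate(toy_protein.sequence, toy_protein)
        assert [(l.start, l.end, l.ambiguous) for l in locs] == [
            (1, len(toy_protein), False)
        ]

    def test_no_match_empty(self, toy_protein):
        assert locate("WWWW", toy_protein) == []

    def test_multilocus_sixteen_mer(self, lmw_gs):
        locs = locate("QQQPPFSQQQPPFSQQ", lmw_gs)
        assert [(l.start, l.end) for l in locs] == [(77, 92), (115, 130)]
        assert all(l.ambiguous for l in locs)

    def test_modifications_stripped_before_matching(self, toy_protein):
        assert [l.start for l in locate("M(+15.99)KV", toy_protein)] == [1]

    def test_il_equivalence_flag(self):
        protein = ProteinRecord("P", "AAILAA")
        assert locate("AALL", protein) == []
        assert [l.start for l in locate("AALL", protein, il_equivalent=True)] == [1]

    @settings(deadline=None, max_examples=200)
    @given(
        seq=st.text(alphabet="ARNDQ", min_size=1, max_size=60),
        pep=st.text(alphabet="ARNDQ", min_size=1, max_size=6),
    )
    def test_agrees_with_naive_scan(self, seq, pep):
        assert [l.start for l in locate(pep, seq)] == naive_locate_starts(pep, seq)


class TestBuildProfile:
    def test_single_unambiguous_peptide_conservation(self):
        protein = ProteinRecord("P", "A" * 9 + "MKVQQF" + "A" * 5)
        obs = [PeptideObservation("MKVQQF", "G0", spectral_count=3)]
        profile = build_profile(obs, protein)
        assert profile.counts[9:15].tolist() == [3] * 6
        assert profile.counts.sum() == 3 * 6
        assert profile.ambiguous_spectral_count == 0

    def test_ambiguous_peptide_excluded_but_tallied(self, lmw_gs):
        obs = [PeptideObservation("QQQPPFSQQQPPFSQQ", "G60", spectral_count=5)]
        profile = build_profile(obs, lmw_gs)
        assert profile.counts.sum() == 0
        assert profile.ambiguous_spectral_count == 5

    def test_unmapped_peptide_dropped_with_tally(self, toy_protein):
        profile = build_profile([PeptideObservation("WWWW", "G0")], toy_protein)
        assert profile.counts.sum() == 0 and profile.n_unmapped == 1

    def test_random_observations_match_accumulation_oracle(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seq = "".join(rng.choice(alphabet, size=200))
        protein = ProteinRecord("P", seq)
        expected = np.zeros(200, dtype=int)
        obs = []
        for _ in range(20):
            s = int(rng.integers(0, 190))
            n = int(rng.integers(6, 11))
            count = int(rng.integers(1, 9))
            pep = seq[s : s + n]
            obs.append(PeptideObservation(pep, "G0", spectral_count=count))
            starts = naive_locate_starts(pep, seq)
            if len(starts) == 1:
                expected[s : s + n] += count
        profile = build_profile(obs, protein)
        assert profile.counts.tolist() == expected.tolist()

    def test_adding_observations_is_monotone(self, toy_protein):
        obs = [
            PeptideObservation("MKVIL", "G0", spectral_count=2),
            PeptideObservation("FSQQQ", "G0", spectral_count=1),
        ]
        before = build_profile(obs[:1], toy_protein)
        after = build_profile(obs, toy_protein)
        assert (after.counts >= before.counts).all()
        assert coverage(after) >= coverage(before)


class TestCoverage:
    def test_all_zero_profile(self, toy_protein):
        assert coverage(build_profile([], toy_protein)) == 0.0

    def test_full_length_peptide_gives_one(self, toy_protein):
        obs = [PeptideObservation(toy_protein.sequence, "G0")]
        assert coverage(build_profile(obs, toy_protein)) == 1.0

    def test_quarter_coverage(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        protein = ProteinRecord("P", seq)
        obs = [PeptideObservation(seq[:50], "G0")]  # covers residues 1-50 uniquely
        assert coverage(build_profile(obs, protein)) == pytest.approx(0.25)

    def test_exclude_signal_denominator(self):
        protein = ProteinRecord("P", "MKTFLVFALLAVAATSAIAQCDEGHINPRS", signal_range=(1, 10))
        obs = [PeptideObservation(protein.sequence[10:], "G0")]  # mature chain only
        assert coverage(build_profile(obs, protein, denominator="exclude_signal")) == 1.0
        assert coverage(build_profile(obs, protein)) == pytest.approx(20 / 30)


class TestLengthSummary:
    def test_identical_groups_p_one(self):
        obs = [PeptideObservation("A" * 10, s) for s in ["G0"] * 3 + ["D120"] * 3]
        summary, tests = length_summary(obs)
        assert set(summary["median"]) == {10.0}
        assert tests.loc[0, "p_value"] == pytest.approx(1.0)

    def test_median_of_three(self):
        obs = [PeptideObservation("A" * n, "G0") for n in (5, 7, 9)]
        summary, _ = length_summary(obs)
        assert summary.loc[0, "median"] == 7

    def test_lengths_weighted_per_row_not_by_count(self):
        obs = [
            PeptideObservation("A" * 10, "G0", spectral_count=100),
            PeptideObservation("A" * 20, "G0", spectral_count=1),
        ]
        summary, _ = length_summary(obs)
        assert summary.loc[0, "median"] == 15.0

    def test_empty_comparison_group_is_error(self):
        obs = [PeptideObservation("AAAAA", "G0")]
        with pytest.raises(ValueError):
            length_summary(obs, compare=[("G0", "D120")])

    def test_shifted_distributions_detected(self):
        """Two groups shifted by 3 residues (n=200 each) give rank-sum p < 0.01."""
        rng = np.random.default_rng(42)
        lengths_a = rng.integers(8, 20, size=200)
        lengths_b = lengths_a + 3
        obs = [PeptideObservation("A" * int(n), "G0") for n in lengths_a]
        obs += [PeptideObservation("A" * int(n), "D120") for n in lengths_b]
        _, tests = length_summary(obs)
        assert tests.loc[0, "p_value"] < 0.01


class TestPeptideTableIO:
    def test_round_trip_and_default_count(self, tmp_path):
        path = tmp_path / "peps.tsv"
        path.write_text("peptide\tsample\nQQPF\tG0\nQQPF\tG0\n")
        obs = read_peptide_table(path)
        assert [o.spectral_count for o in obs] == [1, 1]
        out = tmp_path / "out.tsv"
        write_peptide_table(obs, out)
        assert [o.peptide for o in read_peptide_table(out)] == ["QQPF", "QQPF"]

    def test_profile_table_layout(self, toy_protein):
        table = profile_table(build_profile([], toy_protein), toy_protein)
        assert list(table.columns) == ["accession", "position", "residue", "count"]
        assert len(table) == len(toy_protein)


@pytest.mark.parametrize(
    "raw,clean",
    [
        ("Q(+.98)QPF", "QQPF"),
        ("M[Oxidation]KV", "MKV"),
        ("QQ(+.98)P(+15.99)F", "QQPF"),
        ("qqpf", "QQPF"),
    ],
)
def test_strip_modifications(raw, clean):
    assert strip_modifications(raw) == clean
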