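"""Collagen chain handling, coverage statistic, distances and trees."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import zoomskit as z
from zoomskit.collagen_seq import DistanceMatrix, PhyloTree, read_bounds

from conftest import make_chain, make_profile, random_additive_tree


class TestChainModel:
    def test_invalid_chain_rejected(self):
        with pytest.raises(ValueError):
            z.CollagenChain("s", "COL1a1a", "", 1, 1)
        with pytest.raises(ValueError):
            z.CollagenChain("s", "COL1a1a", "GPZG", 1, 4)
        with pytest.raises(ValueError):
            z.CollagenChain("s", "COL1a1a", "GPAG", 2, 5)

    def test_mature_sequence_substring(self):
        chain = z.CollagenChain("s", "COL1a1a", "AAAGPGPAGR", 4, 10)
        assert z.mature_sequence(chain) == "GPGPAGR"
        whole = z.CollagenChain("s", "COL1a1a", "GPGPAGR", 1, 7)
        assert z.mature_sequence(whole) == "GPGPAGR"

    def test_propeptide_trimming_length(self):
        chain = make_chain("G" * 90, pre="A" * 50)
        assert chain.mature_length == len(chain.residues) - 50
        assert z.mature_sequence(chain) == "G" * 90

    def test_duplicate_chain_ids_rejected(self):
        c = make_chain("GPA", species="s")
        with pytest.raises(ValueError):
            z.SpeciesProfile("s", (c, c))


class TestCoverage:
    class Span:
        def __init__(self, a, b):
            self.span = (a, b)

    def test_no_peptides_zero(self):
        assert z.coverage_pct(make_chain("G" * 10), []) == 0.0

    def test_min_support_two_counts_overlap_only(self):
        chain = make_chain("G" * 10)
        peps = [self.Span(1, 6), self.Span(4, 10)]
        assert z.coverage_pct(chain, peps, min_support=2) == pytest.approx(30.0)
        assert z.coverage_pct(chain, peps, min_support=1) == pytest.approx(100.0)

    def test_out_of_bounds_peptide_rejected(self):
        with pytest.raises(ValueError):
            z.coverage_pct(make_chain("G" * 10), [self.Span(5, 11)])

    def test_monotone_in_support_and_peptides(self):
        rng = np.random.default_rng(5)
        chain = make_chain("G" * 50)
        peps = [
            self.Span(a, min(50, a + int(l)))
            for a, l in zip(
                rng.integers(1, 45, size=12), rng.integers(3, 15, size=12)
            )
        ]
        for k in range(1, 5):
            assert z.coverage_pct(chain, peps, k) >= z.coverage_pct(
                chain, peps, k + 1
            )
        for n in range(len(peps)):
            assert z.coverage_pct(chain, peps[: n + 1], 2) >= z.coverage_pct(
                chain, peps[:n], 2
            )


class TestPDistance:
    def test_examples(self):
        assert z.p_distance("GPAGPA", "GPAGPA") == 0.0
        assert z.p_distance("GPAGPA", "GPSGPA") == pytest.approx(1 / 6)
        # X positions are excluded from numerator and denominator
        assert z.p_distance("GXAG", "GPAG") == 0.0

    def test_all_masked_is_an_error(self):
        with pytest.raises(ValueError):
            z.p_distance("XX", "GG")
        with pytest.raises(ValueError):
            z.p_distance("GG", "GGG")

    @given(
        st.text(alphabet="GPAX", min_size=1, max_size=30),
        st.text(alphabet="GPAX", min_size=1, max_size=30),
    )
    def test_semimetric(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        comparable = [
            (x, y) for x, y in zip(a, b) if x != "X" and y != "X"
        ]
        if not comparable:
            return
        d_ab = z.p_distance(a, b)
        assert d_ab == z.p_distance(b, a)
        assert (d_ab == 0.0) == all(x == y for x, y in comparable)
        assert 0.0 <= d_ab <= 1.0


class TestProfilesIO:
    def _write_fasta(self, tmp_path, records):
        p = tmp_path / "chains.fasta"
        p.write_text("".join(f">{h}\n{s}\n" for h, s in records))
        return p

    def test_twelve_records_four_profiles(self, tmp_path):
        records = [
            (f"sp{i}|{cid}", "GPA" * 20)
            for i in range(4)
            for cid in ("COL1a1a", "COL1a2", "COL1a1b")
        ]
        profiles = z.read_profiles(self._write_fasta(tmp_path, records))
        assert len(profiles) == 4
        assert all(len(p.chains) == 3 for p in profiles)

    def test_header_without_chain_tag_is_an_error(self, tmp_path):
        path = self._write_fasta(tmp_path, [("justaspecies", "GPA")])
        with pytest.raises(ValueError, match="justaspecies"):
            z.read_profiles(path)

    def test_unknown_chain_id_is_an_error(self, tmp_path):
        path = self._write_fasta(tmp_path, [("sp1|COL9", "GPA")])
        with pytest.raises(ValueError, match="COL9"):
            z.read_profiles(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert z.read_profiles(p) == []

    def test_bounds_table_applied(self, tmp_path):
        path = self._write_fasta(tmp_path, [("sp1|COL1a2", "AAAGPGPAGR")])
        b = tmp_path / "bounds.tsv"
        b.write_text("species\tchain\tstart\tend\nsp1\tCOL1a2\t4\t10\n")
        (profile,) = z.read_profiles(path, str(b))
        assert z.mature_sequence(profile.chain("COL1a2")) == "GPGPAGR"
        assert read_bounds(b) == {("sp1", "COL1a2"): (4, 10)}


class TestTrees:
    def test_nj_on_additive_quartet(self):
        d = np.array(
            [
                [0, 0.2, 0.6, 0.6],
                [0.2, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.2],
                [0.6, 0.6, 0.2, 0],
            ]
        )
        tree = z.nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        assert tree.splits() == {frozenset({"C", "D"})}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            z.nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1.0], [1.0, 0]])))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0, 1.0], [2.0, 0]]))

    def test_random_additive_matrices_recover_topology(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            taxa, d, want = random_additive_tree(rng, n)
            tree = z.nj_tree(DistanceMatrix(tuple(taxa), d))
            assert tree.splits() == want

    def test_newick_round_trip(self):
        d = np.array(
            [
                [0, 0.2, 0.6, 0.62],
                [0.2, 0, 0.6, 0.62],
                [0.6, 0.6, 0, 0.21],
                [0.62, 0.62, 0.21, 0],
            ]
        )
        tree = z.nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        back = PhyloTree.from_newick(tree.to_newick())
        assert back.splits() == tree.splits()
        orig = sorted(n.length for n in tree.tree.traverse() if n.length)
        rt = sorted(n.length for n in back.tree.traverse() if n.length)
        assert rt == pytest.approx(orig, abs=1e-9)


class TestBootstrap:
    @staticmethod
    def _diverged_profiles():
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("GPASTLDE"), size=90))
        other = list(base)
        for i in rng.choice(len(base), size=9, replace=False):
            other[i] = "N" if base[i] != "N" else "Q"
        other = "".join(other)
        chains = {"COL1a1a": None, "COL1a2": None, "COL1a1b": None}
        return [
            make_profile(name, {cid: seq for cid in chains})
            for name, seq in [("A1", base), ("A2", base), ("B1", other), ("B2", other)]
        ]

    def test_duplicated_taxa_split_has_full_support(self):
        tree = z.bootstrap_support(self._diverged_profiles(), B=50, seed=1)
        support = tree.support()
        assert support[frozenset({"B1", "B2"})] == 100.0

    def test_deterministic_for_fixed_seed(self):
        profs = self._diverged_profiles()
        a = z.bootstrap_support(profs, B=30, seed=9).to_newick()
        b = z.bootstrap_support(profs, B=30, seed=9).to_newick()
        assert a == b
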