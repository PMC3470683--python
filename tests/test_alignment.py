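"""Pairwise identity and cross-talk network construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from permutome.alignment import (
    AlignmentParams,
    AlphabetError,
    CrossTalkParams,
    ProbeSequence,
    build_crosstalk_network,
    identity_matrix,
    percent_identity,
)

from .conftest import random_dna
from .oracles import brute_force_identity

DNA = st.text(alphabet="ACGT", min_size=1, max_size=10)


class TestProbeSequence:
    def test_uppercased_and_validated(self):
        p = ProbeSequence("x", "GBSS", "acgtn")
        assert p.bases == "ACGTN"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProbeSequence("x", "GBSS", "")

    def test_illegal_symbol_names_position(self):
        with pytest.raises(AlphabetError, match=r"'Q' at position 2"):
            ProbeSequence("x", "GBSS", "ACQT")


class TestPercentIdentity:
    @pytest.mark.parametrize("seq", ["ACGT", "A", "ACGTNRY" * 3])
    def test_self_identity_is_100(self, seq):
        assert percent_identity(seq, seq) == 100.0

    def test_single_terminal_mismatch(self):
        assert percent_identity("ACGT", "ACGA") == pytest.approx(75.0)

    def test_n_is_wildcard(self):
        assert percent_identity("ACNT", "ACGT") == 100.0

    def test_ambiguity_as_mismatch_when_disabled(self):
        p = AlignmentParams(ambiguity_is_match=False)
        assert percent_identity("ACNT", "ACGT", p) == pytest.approx(75.0)

    @pytest.mark.parametrize("n_sub", [1, 3, 5])
    def test_substituted_copy_identity(self, n_sub):
        # k mismatching substitutions into a length-n sequence -> 100(n-k)/n
        rng = np.random.default_rng(7 + n_sub)
        n = 40
        seq = random_dna(rng, n)
        pos = rng.choice(n, size=n_sub, replace=False)
        mutant = list(seq)
        for i in pos:
            mutant[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[i]]
        assert percent_identity(seq, "".join(mutant)) == pytest.approx(
            100.0 * (n - n_sub) / n
        )

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(a=DNA, b=DNA)
    def test_symmetry(self, a, b):
        assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    @pytest.mark.parametrize("seed,la,lb", [(0, 4, 4), (1, 6, 5), (2, 8, 8),
                                            (3, 9, 7), (4, 12, 6)])
    def test_matches_brute_force_enumeration(self, seed, la, lb):
        """The aligner equals exhaustive enumeration of all gapped alignments."""
        rng = np.random.default_rng(seed)
        a, b = random_dna(rng, la), random_dna(rng, lb)
        params = AlignmentParams()
        _, oracle_identity = brute_force_identity(a, b, params)
        observed = percent_identity(a, b, params, max_alignments=50000)
        assert observed == pytest.approx(oracle_identity)

    def test_end_gaps_not_free_changes_denominator(self):
        # with end gaps penalized and counted, a length offset costs identity
        free = percent_identity("AAACGT", "CGT")
        strict = percent_identity("AAACGT", "CGT", AlignmentParams(end_gaps_free=False))
        assert free == 100.0
        assert strict < free

    def test_reverse_complement_mode(self):
        a = "ACGTTACC"
        rc = str(ProbeSequence("a", "", a).reverse_complement().bases)
        assert percent_identity(a, rc, reverse_complement=True) == 100.0


class TestTable3Pair:
    def test_printed_pair_identity_near_77(self, table3_probes):
        arachin, fad = table3_probes
        pid = percent_identity(arachin, fad)
        assert pid == pytest.approx(77.0, abs=2.0)


def _probe_triple():
    """Three probes with pairwise identities ~80 / ~70 / ~50 percent."""
    rng = np.random.default_rng(11)
    n = 40
    a = random_dna(rng, n)

    def mutate(seq, positions):
        out = list(seq)
        for i in positions:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)

    b_pos = [0, 5, 10, 15, 20, 25, 30, 35]                    # a-b: 80 %
    c_pos = [2, 4, 7, 9, 12, 14, 17, 19, 22, 24, 27, 29]      # a-c: 70 %
    b = mutate(a, b_pos)
    c = mutate(a, c_pos)                                      # b-c: 50 %
    return (
        ProbeSequence("a", "Pi_translocator", a),
        ProbeSequence("b", "GBSS", b),
        ProbeSequence("c", "PGM", c),
    )


class TestCrossTalkNetwork:
    def test_thresholding_yields_expected_edges(self):
        pa, pb, pc = _probe_triple()
        net = build_crosstalk_network([pa, pb, pc])
        idm = net.identity
        assert 70.0 <= idm.loc["a", "b"] < 100.0
        assert 70.0 <= idm.loc["a", "c"] < 100.0
        assert idm.loc["b", "c"] < 70.0
        assert net.edges == {frozenset("ab"), frozenset("ac")}

    def test_same_pathway_pair_never_edges(self):
        pa, pb, _ = _probe_triple()
        pb_same = ProbeSequence("b", pa.pathway, pb.bases)
        net = build_crosstalk_network([pa, pb_same])
        assert net.edges == frozenset()

    def test_identity_100_excluded_from_window(self):
        pa = ProbeSequence("a", "GBSS", "ACGTACGTACGT")
        pb = ProbeSequence("b", "PGM", "ACGTACGTACGT")
        net = build_crosstalk_network([pa, pb])
        assert net.identity.loc["a", "b"] == 100.0
        assert net.edges == frozenset()

    def test_edge_set_invariant_under_input_order(self):
        probes = list(_probe_triple())
        forward = build_crosstalk_network(probes)
        backward = build_crosstalk_network(probes[::-1])
        assert forward.edges == backward.edges
        assert forward.identity.sort_index().sort_index(axis=1).equals(
            backward.identity.sort_index().sort_index(axis=1)
        )

    def test_duplicate_ids_rejected(self):
        pa, pb, _ = _probe_triple()
        with pytest.raises(ValueError, match="duplicate"):
            build_crosstalk_network([pa, ProbeSequence("a", pb.pathway, pb.bases)])

    def test_table3_pair_forms_protection_edge(self, table3_probes):
        net = build_crosstalk_network(
            table3_probes, window=CrossTalkParams(70.0, 100.0)
        )
        assert net.edges == {frozenset({"arachin_h1_probe", "fad_probe"})}
        assert net.protected_pathways() == {
            "arachin_biosynthesis",
            "fatty_acid_desaturase",
        }

    def test_matrix_symmetric_with_unit_diagonal(self, table3_probes):
        mat = identity_matrix(table3_probes)
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 100.0).all()
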