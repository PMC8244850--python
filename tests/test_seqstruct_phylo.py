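"""Alignment engines, distances, NJ, likelihood, bootstrap."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from its2kit.seqstruct_phylo import (
    Alignment,
    AlignParams,
    DistanceMatrix,
    RateModel,
    SeqStructAlignParams,
    Tree,
    TreeNode,
    bootstrap_supports,
    decode_seqstruct,
    distance_matrix,
    encode_seqstruct,
    k2p_distance,
    k2p_from_freq,
    logdet_distance,
    msa,
    nj_tree,
    seqstruct_align,
    tree_likelihood,
    optimize_branch_lengths,
)
from its2kit.seqstruct_phylo import _rate_matrix, _gamma_rates


class TestMsa:
    def test_identical_sequences_gapless(self):
        aln = msa([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert aln.rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_gap_alignment_and_score(self):
        """ACGT vs ACT needs exactly one gap; the affine score matches an
        exhaustive enumeration of all pairwise alignments."""
        params = AlignParams()
        aln = msa([("a", "ACGT"), ("b", "ACT")], params)
        assert sorted(aln.rows, key=len, reverse=True)[0] == "ACGT"
        assert "-" in aln.row("b") and aln.row("b").replace("-", "") == "ACT"

        def score(row_a, row_b):
            s, gap = 0.0, None
            for x, y in zip(row_a, row_b):
                if x == "-" or y == "-":
                    which = "a" if x == "-" else "b"
                    s -= params.gap_extend if gap == which else params.gap_open
                    gap = which
                else:
                    gap = None
                    if x == y:
                        s += params.match
                    else:
                        purine = {"A", "G"}
                        same_class = (x in purine) == (y in purine)
                        s += params.transition if same_class else params.transversion
            return s

        # brute-force best over all monotone gap placements of ACT into 4 cols
        best = max(
            score("ACGT", cand)
            for cand in ["-ACT", "A-CT", "AC-T", "ACT-"]
        )
        assert score(aln.row("a"), aln.row("b")) == pytest.approx(best)

    def test_degapping_returns_originals(self):
        seqs = [("a", "ACGTTGCA"), ("b", "ACGGCA"), ("c", "AGTTGCA")]
        aln = msa(seqs)
        assert aln.n_columns >= max(len(s) for _, s in seqs)
        assert aln.degapped() == [s for _, s in seqs]

    def test_single_record_passthrough_warns(self):
        with pytest.warns(UserWarning):
            aln = msa([("a", "ACGT")])
        assert aln.rows == ["ACGT"]


class TestEncoding:
    def test_definition(self):
        assert encode_seqstruct("ACGU", "(..)") == "aCGV"

    def test_all_unpaired_degenerates_to_sequence(self):
        assert encode_seqstruct("ACGU", "....") == "ACGU"

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGU"), size=50))
        db = "((((.....))))" + "." * 37
        enc = encode_seqstruct(seq, db)
        assert decode_seqstruct(enc) == (seq, db)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_seqstruct("ACGU", "(.)")


class TestSeqStructAlign:
    def test_identical_pairs_gapless(self):
        enc = encode_seqstruct("GGCAAAGCCAAA", "(((....)))..")
        aln = seqstruct_align([("a", enc), ("b", enc)])
        assert aln.rows == [enc, enc]

    def test_structure_agreement_scores_higher(self):
        """Same sequences with different structures score strictly below
        the identical-structure alignment (pairwise profile score)."""
        from its2kit.seqstruct_phylo import _align_profiles, _ss_subst

        params = SeqStructAlignParams()
        ab, S = _ss_subst(params)
        seq = "GGCAAAGCCAAA"
        e1 = encode_seqstruct(seq, "(((....)))..")
        e2 = encode_seqstruct(seq, "..(((....)))")
        _, _, same = _align_profiles([e1], [e1], ab, S,
                                     params.indel_open, params.indel_extend)
        _, _, diff = _align_profiles([e1], [e2], ab, S,
                                     params.indel_open, params.indel_extend)
        assert diff < same

    def test_mixed_plain_input_rejected(self):
        enc = encode_seqstruct("ACGU", "....")
        with pytest.raises(ValueError, match="12-letter"):
            seqstruct_align([("a", enc), ("b", "AC-GT")])

    def test_no_crossing_pairs_introduced(self):
        """Aligned columns preserve the relative order of base-pair
        partners (no crossings) for every row."""
        from its2kit.structure2d import fold_mfe, pair_map
        from its2kit.synthetic_data import its2_template

        enc = []
        for name in ("M1", "M2", "PUT_G1"):
            t = its2_template(name)
            ss = fold_mfe(t.seq)
            enc.append((name, encode_seqstruct(ss.seq, ss.structure)))
        aln = seqstruct_align(enc)
        for row in aln.rows:
            _, db = decode_seqstruct(row)
            pm = pair_map(db.replace("-", "."))
            opens = [(i, pm[i]) for i in range(len(pm)) if pm[i] > i]
            for (i1, j1), (i2, j2) in zip(opens, opens[1:]):
                assert not (i1 < i2 < j1 < j2)  # nesting or disjoint only


class TestDistances:
    def test_identical_rows_zero(self):
        row = "ACGTACGTACGTAAGG"
        assert k2p_distance(row, row) == 0.0
        assert logdet_distance(row, row) == 0.0

    def test_k2p_closed_form(self):
        """P=0.1, Q=0.05 -> d = -0.5 ln 0.75 - 0.25 ln 0.9 = 0.1702."""
        F = np.eye(4) * 0.2125
        F[0, 2] = F[2, 0] = F[1, 3] = F[3, 1] = 0.025
        F[0, 1] = F[1, 0] = F[2, 3] = F[3, 2] = 0.0125
        assert k2p_from_freq(F, None) == pytest.approx(0.1702, abs=5e-5)

    def test_k2p_saturation(self):
        F = np.full((4, 4), 1 / 16)  # P = 0.5, Q = 0.25
        assert math.isnan(k2p_from_freq(F, None))

    def test_gamma_reduces_to_plain_at_large_alpha(self):
        F = np.eye(4) * 0.23
        F[0, 2] = F[2, 0] = 0.04
        plain = k2p_from_freq(F, None)
        assert k2p_from_freq(F, 1e7) == pytest.approx(plain, rel=1e-4)

    def test_logdet_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = "".join(
            c if rng.random() > 0.1 else rng.choice(list("ACGT")) for c in a
        )
        perm = str.maketrans("ACGT", "GTAC")
        d1 = logdet_distance(a, b)
        d2 = logdet_distance(a.translate(perm), b.translate(perm))
        assert d1 == pytest.approx(d2, abs=1e-12)

    @pytest.mark.parametrize("method", ["k2p", "logdet"])
    def test_simulated_distance_recovery(self, method):
        """Sequences simulated under K2P at d=0.1 over 10 kb recover the
        true distance within 3 bootstrap SEs."""
        rng = np.random.default_rng(17)
        rate = RateModel(model="K2P", alpha=None, kappa=2.0)
        Q = _rate_matrix(rate, np.full(4, 0.25))
        P = expm(Q * 0.05)  # half the distance per branch
        L = 10_000
        anc = rng.integers(0, 4, size=L)
        def evolve(codes):
            out = np.empty_like(codes)
            for i, c in enumerate(codes):
                out[i] = rng.choice(4, p=P[c])
            return out
        a = evolve(anc)
        b = evolve(anc)
        bases = np.array(list("ACGT"))
        row_a, row_b = "".join(bases[a]), "".join(bases[b])
        fn = k2p_distance if method == "k2p" else logdet_distance
        d = fn(row_a, row_b)
        # column bootstrap SE
        reps = []
        for _ in range(200):
            cols = rng.integers(0, L, size=L)
            reps.append(fn("".join(bases[a[cols]]), "".join(bases[b[cols]])))
        se = float(np.std(reps, ddof=1))
        assert abs(d - 0.1) < 3 * se


class TestNJ:
    def test_additive_four_taxon_matrix(self):
        D = np.array(
            [[0, 5, 9, 10], [5, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(ids=list("ABCD"), matrix=D))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.root.walk() if n.is_leaf()}
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=list("abc"), matrix=D))
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_nonfinite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = math.nan
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=list("abc"), matrix=D))

    def test_random_additive_trees_reconstructed(self):
        """NJ recovers the generating topology exactly on 100 random
        additive matrices (4-12 taxa)."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            true = _random_tree(n, rng)
            D, ids = _path_length_matrix(true)
            est = nj_tree(DistanceMatrix(ids=ids, matrix=D))
            assert est.bipartitions() == true.bipartitions()


def _random_tree(n: int, rng: np.random.Generator) -> Tree:
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(children=[b, a], length=float(rng.uniform(0.1, 1.0)))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    return Tree(root=TreeNode(children=nodes))


def _path_length_matrix(tree: Tree):
    ids = sorted(tree.tips())
    idx = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    D = np.zeros((n, n))

    def pairwise(node):
        below = []
        if node.is_leaf():
            return [(node.name, node.length if node is not tree.root else 0.0)]
        groups = []
        for c in node.children:
            sub = pairwise(c)
            groups.append(sub)
            below.extend(sub)
        for g1, g2 in itertools.combinations(groups, 2):
            for (t1, d1) in g1:
                for (t2, d2) in g2:
                    D[idx[t1], idx[t2]] = D[idx[t2], idx[t1]] = d1 + d2
        return [(t, d + (node.length if node is not tree.root else 0.0))
                for t, d in below]

    pairwise(tree.root)
    return D, ids


class TestLikelihood:
    def _toy(self):
        root = TreeNode(children=[
            TreeNode(name="a", length=0.1),
            TreeNode(name="b", length=0.2),
            TreeNode(name="c", length=0.15),
        ])
        aln = Alignment(ids=["a", "b", "c"], rows=["ACGTA", "ACGTT", "AGGTA"])
        return Tree(root=root), aln

    def test_identical_bases_t0_limit(self):
        root = TreeNode(children=[TreeNode(name=t, length=1e-9) for t in "abc"])
        aln = Alignment(ids=["a", "b", "c"], rows=["G", "G", "G"])
        tr = Tree(root=root)
        ll = tree_likelihood(tr, aln, RateModel(model="K2P", alpha=None))
        assert ll == pytest.approx(math.log(0.25), abs=1e-6)

    @pytest.mark.parametrize("alpha", [None, 0.7])
    def test_pruning_equals_brute_force_enumeration(self, alpha):
        """Pruning log-likelihood equals explicit summation over all
        internal-state assignments for a 4-taxon tree."""
        inner = TreeNode(children=[
            TreeNode(name="c", length=0.3), TreeNode(name="d", length=0.25)
        ], length=0.12)
        root = TreeNode(children=[
            TreeNode(name="a", length=0.1), TreeNode(name="b", length=0.2), inner
        ])
        tree = Tree(root=root)
        aln = Alignment(ids=list("abcd"),
                        rows=["ACGTTA", "ACGTCA", "AGGTTC", "ATGTTA"])
        rate = RateModel(model="K2P", alpha=alpha, categories=4, kappa=2.0)
        ll = tree_likelihood(tree, aln, rate)

        Q = _rate_matrix(rate, np.full(4, 0.25))
        rates = _gamma_rates(alpha, 4)
        code = {b: i for i, b in enumerate("ACGT")}
        total = 0.0
        for site in range(6):
            obs = {t: code[aln.row(t)[site]] for t in "abcd"}
            site_like = 0.0
            for r in rates:
                P = {t: expm(Q * (bl * r)) for t, bl in
                     [("a", 0.1), ("b", 0.2), ("c", 0.3), ("d", 0.25), ("u", 0.12)]}
                s = 0.0
                for x in range(4):         # root state
                    for y in range(4):     # internal node state
                        s += (0.25 * P["a"][x, obs["a"]] * P["b"][x, obs["b"]]
                              * P["u"][x, y] * P["c"][y, obs["c"]]
                              * P["d"][y, obs["d"]])
                site_like += s / len(rates)
            total += math.log(site_like)
        assert ll == pytest.approx(total, abs=1e-9)

    def test_large_alpha_matches_homogeneous(self):
        tree, aln = self._toy()
        plain = tree_likelihood(tree, aln, RateModel(model="K2P", alpha=None))
        big = tree_likelihood(tree, aln, RateModel(model="K2P", alpha=1e6))
        assert big == pytest.approx(plain, abs=1e-4)

    def test_branch_optimum_is_local_maximum(self):
        tree, aln = self._toy()
        rate = RateModel(model="K2P", alpha=None)
        ll = optimize_branch_lengths(tree, aln, rate, sweeps=2)
        for node in tree.root.children:
            x0 = node.length
            for delta in (-0.01, 0.01):
                if x0 + delta <= 0:
                    continue
                node.length = x0 + delta
                assert tree_likelihood(tree, aln, rate) <= ll + 1e-6
                node.length = x0

    def test_zero_length_alignment_rejected(self):
        tree, _ = self._toy()
        with pytest.raises(ValueError):
            tree_likelihood(tree, Alignment(ids=["a", "b", "c"], rows=["", "", ""]),
                            RateModel())


class TestBootstrap:
    def _aln(self):
        rng = np.random.default_rng(31)
        base = "".join(rng.choice(list("ACGT"), size=400))
        groups = []
        for g in range(2):
            anc = list(base)
            for _ in range(60):
                p = int(rng.integers(400))
                anc[p] = rng.choice([c for c in "ACGT" if c != anc[p]])
            for i in range(3):
                s = list(anc)
                for _ in range(5):
                    p = int(rng.integers(400))
                    s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
                groups.append((f"g{g}_{i}", "".join(s)))
        return msa(groups)

    @staticmethod
    def _builder(aln):
        return nj_tree(distance_matrix(aln, "k2p", RateModel(alpha=None)))

    def test_congruent_signal_high_support(self):
        tree = bootstrap_supports(self._aln(), self._builder, reps=100, seed=5)
        group_split = frozenset({"g0_0", "g0_1", "g0_2"})
        node = [n for n in tree.internal_nodes()
                if frozenset(n.tip_names()) in (group_split,)]
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert max(supports) >= 99.0

    def test_single_rep_supports_binary(self):
        tree = bootstrap_supports(self._aln(), self._builder, reps=1, seed=2)
        for n in tree.internal_nodes():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_seeded_repeatability(self):
        t1 = bootstrap_supports(self._aln(), self._builder, reps=30, seed=9)
        t2 = bootstrap_supports(self._aln(), self._builder, reps=30, seed=9)
        assert t1.newick() == t2.newick()

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports(self._aln(), self._builder, reps=0, seed=1)
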