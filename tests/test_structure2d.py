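"""MFE folding, energy audit, helix decomposition, motifs, classification."""

import numpy as np
import pytest

import its2kit.energy_params as ep
from its2kit.structure2d import (
    SecondaryStructure,
    classify_model,
    consensus_structure,
    decompose_helices,
    detect_motifs,
    fold_mfe,
    pair_map,
    structure_energy,
)
from its2kit.synthetic_data import its2_template

RC = str.maketrans("ACGU", "UGCA")


def nussinov_max_pairs(seq: str, min_hairpin: int = 3) -> int:
    """Independent maximum-pairing DP (the classic Nussinov recursion)."""
    codes = ep.encode_rna(seq)
    n = len(codes)
    N = [[0] * n for _ in range(n)]
    for d in range(min_hairpin + 1, n):
        for i in range(n - d):
            j = i + d
            best = N[i][j - 1]
            for k in range(i, j - min_hairpin):
                if ep.PAIR_TYPE[codes[k], codes[j]]:
                    left = N[i][k - 1] if k > i else 0
                    best = max(best, left + 1 + N[k + 1][j - 1])
            N[i][j] = best
    return N[0][n - 1] if n else 0


class TestFolding:
    def test_designed_hairpin_energy_hand_summed(self):
        """A strong 10-bp hairpin folds to itself; its energy equals the
        nine stack terms plus the tetraloop penalty, summed here directly."""
        stem = "GGCGAGGCAC"
        seq = stem + "AAAC" + stem.translate(RC)[::-1]
        ss = fold_mfe(seq)
        assert ss.structure == "(" * 10 + "...." + ")" * 10
        codes = ep.encode_rna(seq)
        expected = ep.hairpin_dg(4)
        for k in range(9):
            p = ep.PAIR_TYPE[codes[k], codes[23 - k]]
            q = ep.PAIR_TYPE[codes[k + 1], codes[22 - k]]
            expected += ep.STACK_DG[p, q]
        assert ss.mfe == pytest.approx(expected)

    def test_poly_a_unpaired(self):
        ss = fold_mfe("A" * 60)
        assert ss.structure == "." * 60 and ss.mfe == 0.0

    def test_template_energies_in_folded_band(self):
        """Generator templates fold with strongly negative MFE (the real
        directly-folded spacers live in a deep-energy band)."""
        for name in ("M1", "M2", "PUT_G1"):
            ss = fold_mfe(its2_template(name).seq)
            assert ss.mfe < -36.8

    def test_determinism(self):
        seq = its2_template("M1").seq
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert a.structure == b.structure and a.mfe == b.mfe

    def test_non_rna_symbol_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGUNACGU" * 8)


class TestEnergyAudit:
    def test_audit_equals_mfe_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(40, 160))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            ss = fold_mfe(seq)
            assert structure_energy(ss.seq, ss.structure) == pytest.approx(
                ss.mfe, abs=1e-9
            )

    def test_mfe_pairs_bounded_by_nussinov(self):
        """On an exhaustive seeded set of short sequences the MFE structure
        never pairs more bases than the maximum-pairing oracle allows."""
        rng = np.random.default_rng(13)
        for _ in range(150):
            n = int(rng.integers(10, 31))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            ss = fold_mfe(seq)
            n_pairs = ss.structure.count("(")
            assert n_pairs <= nussinov_max_pairs(seq)


class TestDecomposition:
    def test_single_hairpin(self):
        ss = SecondaryStructure(seq="GGGGACCCCCCC", structure="((((....))))", mfe=0.0)
        hs = decompose_helices(ss)
        assert hs.n_top == 1
        assert hs.helices[0].n_pairs == 4
        assert len(hs.helices[0].terminal_loop) == 4

    def test_four_planted_stems_recovered(self):
        ss = fold_mfe(its2_template("M1").seq)
        hs = decompose_helices(ss)
        assert hs.is_four and not hs.not_four_fingered
        # helix III strictly longest in paired positions
        pairs = [h.n_pairs for h in hs.helices]
        assert pairs[2] == max(pairs) and pairs.count(max(pairs)) == 1

    def test_m1_helix_iii_loops(self):
        """Model-1 helix III: five 1x1 internal loops, 6-nt terminal loop."""
        hs = decompose_helices(fold_mfe(its2_template("M1").seq))
        h3 = hs.helix("III")
        assert h3.n_internal_loops == 5
        assert len(h3.terminal_loop) == 6

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError):
            pair_map("((..)")

    def test_deterministic(self):
        seq = its2_template("M4").seq
        a = decompose_helices(fold_mfe(seq))
        b = decompose_helices(fold_mfe(seq))
        assert [h.outer for h in a.helices] == [h.outer for h in b.helices]


class TestMotifs:
    def test_m1_signature(self):
        hs = decompose_helices(fold_mfe(its2_template("M1").seq))
        mr = detect_motifs(hs)
        assert mr.uu_mismatch_helixII
        assert mr.helixIII_motif == "UGG"
        assert "GTACCC" in mr.ring_I_IV

    def test_putative_signature(self):
        hs = decompose_helices(fold_mfe(its2_template("PUT_G1").seq))
        mr = detect_motifs(hs)
        assert "TCCATG" in mr.ring_I_IV
        assert mr.helixIII_motif is None
        assert mr.uu_mismatch_helixII

    def test_helix_ii_without_uu_loop(self):
        hs = decompose_helices(fold_mfe(its2_template("M1-2").seq))
        mr = detect_motifs(hs)
        assert not mr.uu_mismatch_helixII  # the U-U loop became a bulge


class TestClassification:
    @pytest.mark.parametrize(
        "template,expected",
        [
            ("M1", "M1"), ("M1-2", "M1-2"), ("M1-3", "M1-3"), ("M2", "M2"),
            ("M3", "M3"), ("M4", "M4"), ("M5", "M5"), ("M6", "M6"),
            ("M7", "M7"), ("PUT_G1", "PUTATIVE"), ("PUT_G2", "PUTATIVE"),
            ("PUT_OG", "PUTATIVE"),
        ],
    )
    def test_template_labels(self, template, expected):
        hs = decompose_helices(fold_mfe(its2_template(template).seq))
        label = classify_model(hs, detect_motifs(hs))
        assert label.label == expected
        assert label.evidence  # every classified model carries evidence

    def test_not_four_helices_unclassified(self):
        ss = fold_mfe("GGCAGCAGCAAACTGCTGCC")  # a single hairpin
        hs = decompose_helices(ss)
        label = classify_model(hs, None)
        assert label.label == "UNCLASSIFIED" and label.evidence == []

    def test_m2_ring_text_and_figure_variants_both_accepted(self):
        """The Model-2 ring is printed as GTCTCC in one place and GTGTCC in
        another; the classifier accepts both and reports which matched."""
        base = its2_template("M2")
        hs = decompose_helices(fold_mfe(base.seq))
        mr = detect_motifs(hs)
        assert classify_model(hs, mr).label == "M2"
        mr_fig = detect_motifs(hs)
        mr_fig.ring_I_IV = mr.ring_I_IV.replace("GTCTCC", "GTGTCC")
        lab = classify_model(hs, mr_fig)
        assert lab.label == "M2"
        assert any("GTGTCC" in e or "GTCTCC" in e for e in lab.evidence)


class TestConsensus:
    def test_identical_rows(self):
        rows = [("ACGU", "(..)"), ("ACGU", "(..)")]
        cons = consensus_structure(rows)
        assert cons.sequence == "ACGU" and cons.structure == "(..)"
        assert (cons.conservation == 1.0).all()

    def test_one_divergent_column(self):
        rows = [("ACGU", "...."), ("AGGU", "....")]
        cons = consensus_structure(rows)
        assert cons.conservation[1] == pytest.approx(0.5)
        assert all(cons.conservation[k] == 1.0 for k in (0, 2, 3))

    def test_gap_policies_differ_exactly_at_gap_columns(self):
        rows = [("AC-U", "((-)"), ("ACGU", "(())"), ("ACGU", "(())")]
        keep = consensus_structure(rows, gap_policy="keep")
        drop = consensus_structure(rows, gap_policy="drop")
        gap_cols = {2}
        assert set(keep.kept_columns) - set(drop.kept_columns) == gap_cols

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_structure([])
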