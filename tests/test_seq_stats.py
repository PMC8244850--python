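"""Content statistics, rank tests, indel events, group summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from its2kit.seq_stats import (
    count_indel_events,
    dunn_posthoc,
    group_summary,
    kruskal_wallis,
    normalized_length,
    nucleotide_content,
)


class TestContent:
    @pytest.mark.parametrize(
        "seq,at,gc,counted",
        [("ATAT", 100.0, 0.0, 4), ("ACGT", 50.0, 50.0, 4), ("ACGTN", 50.0, 50.0, 4)],
    )
    def test_examples(self, seq, at, gc, counted):
        cs = nucleotide_content(seq)
        assert cs.at_pct == pytest.approx(at)
        assert cs.gc_pct == pytest.approx(gc)
        assert cs.counted_bases == counted

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            nucleotide_content("NNNN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, seq):
        cs = nucleotide_content(seq)
        assert cs.at_pct + cs.gc_pct == pytest.approx(100.0)


class TestNormalizedLength:
    @pytest.mark.parametrize(
        "length,expected", [(139, 19.94), (157, 22.52), (697, 100.00)]
    )
    def test_reference_values(self, length, expected):
        assert normalized_length(length) == pytest.approx(expected, abs=0.01)

    def test_over_reference_warns_but_returns(self):
        with pytest.warns(UserWarning):
            v = normalized_length(700)
        assert v == pytest.approx(100.43, abs=0.005)


class TestKruskalWallis:
    def test_two_small_groups_hand_value(self):
        """Ranks 1..4 in groups {1,2},{3,4}: H = 12/20*(2*(1.5-2.5)^2 +
        2*(3.5-2.5)^2) = 2.4, verified by exact permutation enumeration."""
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.H == pytest.approx(2.4)
        # Exact permutation null for the p-value.
        from itertools import permutations

        vals = [1, 2, 3, 4]
        stats = []
        for perm in permutations(vals):
            stats.append(kruskal_wallis([list(perm[:2]), list(perm[2:])]).H)
        p_exact = sum(s >= res.H - 1e-12 for s in stats) / len(stats)
        assert res.p == pytest.approx(sps.chi2.sf(2.4, 1), rel=1e-6)
        assert p_exact == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        groups = [list(rng.normal(size=8)), list(rng.normal(1, 1, size=6)),
                  list(rng.normal(2, 1, size=7))]
        h1 = kruskal_wallis(groups).H
        h2 = kruskal_wallis([[math.exp(v) for v in g] for g in groups]).H
        assert h1 == pytest.approx(h2)

    def test_k2_matches_wilcoxon_relation(self):
        """For two groups H equals z^2 of the rank-sum test asymptotically."""
        rng = np.random.default_rng(1)
        a = list(rng.normal(0, 1, 300))
        b = list(rng.normal(0.3, 1, 300))
        H = kruskal_wallis([a, b]).H
        z = sps.norm.isf(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue / 2)
        assert H == pytest.approx(z**2, rel=0.02)


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        table = dunn_posthoc(res)
        assert table.z.iloc[0] == pytest.approx(0.0)
        assert table.p.iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        res = kruskal_wallis([list(range(1, 11)), list(range(101, 111))])
        table = dunn_posthoc(res)
        assert table.p.iloc[0] < 0.01

    def test_group_swap_negates_z(self):
        g1, g2 = [1, 5, 9, 2], [3, 7, 11, 20]
        t1 = dunn_posthoc(kruskal_wallis([g1, g2]))
        t2 = dunn_posthoc(kruskal_wallis([g2, g1]))
        assert t1.z.iloc[0] == pytest.approx(-t2.z.iloc[0])
        assert t1.p.iloc[0] == pytest.approx(t2.p.iloc[0])

    def test_requires_omnibus_first(self):
        from its2kit.seq_stats import TestResult

        bare = TestResult(H=1.0, df=1, p=0.5, group_sizes=(2, 2))
        with pytest.raises(ValueError, match="kruskal_wallis"):
            dunn_posthoc(bare)

    def test_matches_permutation_null(self):
        """Dunn two-sided p agrees with a 10k-permutation null of the
        rank-mean difference within Monte-Carlo error."""
        rng = np.random.default_rng(2)
        g1 = list(rng.normal(0, 1, 8))
        g2 = list(rng.normal(0.9, 1, 8))
        res = kruskal_wallis([g1, g2])
        p_dunn = dunn_posthoc(res).p.iloc[0]
        pooled = np.array(g1 + g2)
        n = len(g1)
        obs = abs(np.mean(sps.rankdata(pooled)[:n]) - np.mean(sps.rankdata(pooled)[n:]))
        count = 0
        reps = 10_000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            r = sps.rankdata(perm)
            if abs(r[:n].mean() - r[n:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / reps
        mc_se = math.sqrt(p_perm * (1 - p_perm) / reps)
        assert abs(p_dunn - p_perm) < max(4 * mc_se, 0.02)


class TestIndelEvents:
    def test_gapless(self):
        assert count_indel_events(["ACGT", "ACGT"]).I == 0

    def test_single_run(self):
        rep = count_indel_events(["ACGTACGT", "ACG---GT"])
        assert rep.I == 1
        assert rep.events[0][0] == (3, 6)

    def test_shared_vs_shifted_runs(self):
        """Two rows sharing an identical gap run count once; a shifted run
        is a second event (exhaustive signature enumeration)."""
        aln = ["ACGTACGT", "AC--ACGT", "AC--ACGT", "ACG--CGT"]
        rep = count_indel_events(aln)
        assert rep.I == 2
        signatures = {span for span, _ in rep.events}
        assert signatures == {(2, 4), (3, 5)}

    def test_all_gap_column_stripped_with_warning(self):
        with pytest.warns(UserWarning, match="all-gap"):
            rep = count_indel_events(["A-CG", "A-CG"])
        assert rep.I == 0

    def test_row_order_invariance(self):
        rows = ["AC--GT", "ACGTGT", "A---GT", "AC--GT"]
        base = count_indel_events(rows)
        perm = count_indel_events(rows[::-1])
        assert base.I == perm.I
        assert {s for s, _ in base.events} == {s for s, _ in perm.events}


class TestGroupSummary:
    def test_constant_5_8s_and_sem(self, small_study, truth_by_id):
        from its2kit.its_delimit import DelimitParams, delimit_its, find_flank_motifs

        params = DelimitParams()
        parts = {}
        for rec in small_study.records:
            parts[rec.id] = delimit_its(rec, find_flank_motifs(rec, params), params)
        table = group_summary(small_study.records, parts, small_study.manifest)
        row = table[(table.group == "OUTGROUP") & (table.region == "5.8S")].iloc[0]
        assert (row.len_min, row.len_max) == (157, 157)
        assert row.len_sem == pytest.approx(0.0)

    def test_single_member_group_sem_zero(self):
        import numpy as np

        from its2kit.its_delimit import ItsPartition
        from its2kit.sequence_io import GroupManifest, SeqRecord

        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=100))
        rec = SeqRecord(id="solo", seq=seq)
        part = ItsPartition(
            flank_18S=(0, 0), its1=(0, 40), s5_8=(40, 70), its2=(70, 100),
            flank_28S=(100, 100),
        )
        m = GroupManifest(groups={"solo": "OUTGROUP"})
        table = group_summary([rec], {"solo": part}, m)
        its_row = table[table.region == "ITS"].iloc[0]
        assert its_row.len_mean == 100 and its_row.len_sem == 0.0

    def test_mean_sem_match_direct_recomputation(self, small_study, truth_by_id):
        from its2kit.its_delimit import DelimitParams, delimit_its, find_flank_motifs

        params = DelimitParams()
        parts = {
            rec.id: delimit_its(rec, find_flank_motifs(rec, params), params)
            for rec in small_study.records
        }
        table = group_summary(small_study.records, parts, small_study.manifest)
        row = table[(table.group == "AMPELOMYCES") & (table.region == "ITS1")].iloc[0]
        lens = np.array([
            parts[r.id].its1[1] - parts[r.id].its1[0]
            for r in small_study.records if r.group == "AMPELOMYCES"
        ], dtype=float)
        assert row.len_mean == pytest.approx(lens.mean())
        assert row.len_sem == pytest.approx(lens.std(ddof=1) / math.sqrt(lens.size))
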