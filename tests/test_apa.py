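"""PAC construction, Fisher's exact test, shift testing, 3'UTR lengths."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from readerstab.annotation import GeneModel, GeneModelSet
from readerstab.apa import (
    FEATURE_CDS,
    FEATURE_INTERGENIC,
    FEATURE_UTR3,
    PAC,
    assign_features,
    attach_tpm,
    cluster_sites,
    compare_utr_lengths,
    filter_pacs,
    fisher_exact_2x2,
    gene_weighted_utr_length,
    pac_shift_test,
    weighted_utr_length,
)


def sites_frame(positions, counts=None, chrom="chrS", strand="+"):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "position": positions,
            "strand": [strand] * n,
            "S1": counts if counts is not None else [1] * n,
        }
    )


def brute_force_single_linkage(positions, gap=25):
    """O(n^2) transitive-closure clustering oracle."""
    pos = sorted(positions)
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if abs(pos[i] - pos[j]) <= gap:
            parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(pos[i])
    return sorted(tuple(sorted(c)) for c in clusters.values())


class TestClusterSites:
    def test_inclusive_25nt_boundary_merges(self):
        pacs = cluster_sites(sites_frame([100, 125]))
        assert len(pacs) == 1
        assert (pacs[0].start, pacs[0].end) == (100, 126)

    def test_26nt_distance_splits(self):
        pacs = cluster_sites(sites_frame([100, 126]))
        assert len(pacs) == 2

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(2, 200))
            positions = sorted(set(rng.integers(0, 3000, size=n).tolist()))
            got = sorted(tuple(sorted(p.member_positions)) for p in cluster_sites(sites_frame(positions)))
            assert got == brute_force_single_linkage(positions)

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        positions = rng.integers(0, 500, size=60).tolist()
        shuffled = positions.copy()
        rng.shuffle(shuffled)
        a = sorted((p.start, p.end) for p in cluster_sites(sites_frame(positions)))
        b = sorted((p.start, p.end) for p in cluster_sites(sites_frame(shuffled)))
        assert a == b

    def test_strands_and_chroms_do_not_merge(self):
        df = pd.concat(
            [sites_frame([100], strand="+"), sites_frame([110], strand="-")],
            ignore_index=True,
        )
        assert len(cluster_sites(df)) == 2

    def test_representative_is_max_pooled_tag_site(self):
        pacs = cluster_sites(sites_frame([100, 110, 120], counts=[5, 50, 7]))
        assert pacs[0].representative_position == 110

    def test_negative_positions_rejected(self):
        with pytest.raises(ValueError):
            cluster_sites(sites_frame([-5, 10]))


class TestFilterPACs:
    def _pacs(self, counts_by_sample):
        pacs = cluster_sites(
            pd.DataFrame(
                {
                    "chrom": ["chrS"] * len(counts_by_sample),
                    "position": [100 * (i + 1) for i in range(len(counts_by_sample))],
                    "strand": ["+"] * len(counts_by_sample),
                }
                | {
                    s: [row[s] for row in counts_by_sample]
                    for s in counts_by_sample[0]
                }
            )
        )
        return attach_tpm(pacs)

    def test_tpm_exactly_3_in_one_sample_retained(self):
        # sample A: 3 of 1e6 total scaled -> construct TPM == 3 exactly
        pacs = self._pacs([{"A": 3, "B": 0}, {"A": 999_997, "B": 100}])
        kept = filter_pacs(pacs, min_tpm=3)
        assert len(kept) == 2  # first PAC sits exactly at TPM 3 in A

    def test_below_threshold_everywhere_dropped(self):
        pacs = self._pacs([{"A": 2, "B": 2}, {"A": 999_998, "B": 999_998}])
        assert len(filter_pacs(pacs, min_tpm=3)) == 1

    def test_all_samples_mode_is_stricter(self):
        pacs = self._pacs([{"A": 5000, "B": 1}, {"A": 995_000, "B": 999_999}])
        assert len(filter_pacs(pacs, min_tpm=3, all_samples=False)) == 2
        assert len(filter_pacs(pacs, min_tpm=3, all_samples=True)) == 1

    def test_empty_input(self):
        assert filter_pacs([], min_tpm=3) == []


def _gene(gene_id="G1", strand="+", start=1000):
    # 100 nt 5'UTR, 300 nt CDS, 300 nt 3'UTR
    if strand == "+":
        return GeneModel(gene_id, "chrS", start, start + 700, "+",
                         start + 100, start + 400, start + 400, start + 700)
    return GeneModel(gene_id, "chrS", start, start + 700, "-",
                     start + 300, start + 600, start, start + 300)


def _pac_at(position, strand="+", counts=None, tpm=None):
    counts = counts if counts is not None else {"A": 10}
    p = PAC(
        chrom="chrS", strand=strand, start=position, end=position + 1,
        representative_position=position, counts=pd.Series(counts),
        member_positions=[position],
    )
    p.tpm = pd.Series(tpm) if tpm is not None else pd.Series(counts, dtype=float)
    return p


class TestAssignFeatures:
    def test_inside_utr3(self):
        gene = _gene()
        pacs = assign_features([_pac_at(1500)], GeneModelSet([gene]))
        assert pacs[0].gene_id == "G1"
        assert pacs[0].feature == FEATURE_UTR3

    def test_downstream_extension_assigned_as_utr3(self):
        gene = _gene()  # ends at 1700
        pacs = assign_features([_pac_at(1900)], GeneModelSet([gene]), extension=500)
        assert pacs[0].gene_id == "G1"
        assert pacs[0].feature == FEATURE_UTR3

    def test_beyond_extension_intergenic(self):
        pacs = assign_features([_pac_at(2300)], GeneModelSet([_gene()]), extension=500)
        assert pacs[0].gene_id is None
        assert pacs[0].feature == FEATURE_INTERGENIC

    def test_antisense_pac_unassigned(self):
        pacs = assign_features([_pac_at(1500, strand="-")], GeneModelSet([_gene()]))
        assert pacs[0].gene_id is None

    def test_cds_feature(self):
        pacs = assign_features([_pac_at(1200)], GeneModelSet([_gene()]))
        assert pacs[0].feature == FEATURE_CDS

    def test_two_gene_ambiguity_nearest_stop_wins(self):
        g1 = _gene("G1", start=1000)           # + strand, ends 1700, stop at 1399
        g2 = _gene("G2", strand="-", start=1800)  # - strand would not compete (strand)
        g3 = _gene("G3", start=1750)           # + strand, overlapping extension zone
        pacs = assign_features([_pac_at(1850)], GeneModelSet([g1, g2, g3]), extension=500)
        # G3's stop codon (2149) vs G1's (1399): G1 is 451 away, G3 is 299 away
        assert pacs[0].gene_id == "G3"


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration over all tables
    with the observed margins (math.comb arithmetic, no floats)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_enumeration_oracle_on_fixed_margins(self):
        _, p = fisher_exact_2x2([[3, 7], [9, 1]])
        assert p == pytest.approx(fisher_enumeration_oracle(3, 7, 9, 1), abs=1e-12)

    def test_zero_margin_degenerate(self):
        odds, p = fisher_exact_2x2([[0, 0], [5, 5]])
        assert p == 1.0
        assert math.isnan(odds)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = rng.integers(0, 50, size=(2, 2))
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(stats.fisher_exact(t)[1], abs=1e-10)

    def test_odds_ratio_sample_definition(self):
        odds, _ = fisher_exact_2x2([[10, 5], [2, 8]])
        assert odds == pytest.approx((10 * 8) / (5 * 2))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestPACShift:
    def _two_pac_gene(self, a_counts, b_counts, strand="+"):
        """Two PACs at 100 (proximal on +) and 300 with given per-condition
        counts; TPM mirrors counts."""
        pacs = []
        for i, pos in enumerate((100, 300)):
            counts = {"A1": a_counts[i], "B1": b_counts[i]}
            pacs.append(_pac_at(pos, strand=strand, counts=counts))
        return pacs

    def test_clear_swap_detected_distal(self):
        pacs = self._two_pac_gene(a_counts=(90, 10), b_counts=(10, 90))
        r = pac_shift_test("G1", pacs, ["A1"], ["B1"])
        assert r.p_value < 0.05 and r.shifted
        assert r.direction == "distal"
        assert r.p_value == pytest.approx(fisher_enumeration_oracle(90, 10, 10, 90), abs=1e-12)

    def test_identical_usage_not_shifted(self):
        pacs = self._two_pac_gene(a_counts=(50, 50), b_counts=(50, 50))
        r = pac_shift_test("G1", pacs, ["A1"], ["B1"])
        assert r.p_value == pytest.approx(1.0)
        assert not r.shifted

    def test_single_pac_gene_skipped(self):
        r = pac_shift_test("G1", [_pac_at(100)], ["A"], ["A"])
        assert r.skipped == "single-PAC"

    def test_zero_half_skipped(self):
        pacs = self._two_pac_gene(a_counts=(100, 0), b_counts=(80, 0))
        r = pac_shift_test("G1", pacs, ["A1"], ["B1"])
        assert r.skipped == "zero-half"

    def test_minus_strand_direction_flips(self):
        """On the minus strand the genomically-left PAC is distal, so the
        same count pattern reverses direction."""
        plus = pac_shift_test("G1", self._two_pac_gene((90, 10), (10, 90)), ["A1"], ["B1"])
        minus = pac_shift_test(
            "G1", self._two_pac_gene((90, 10), (10, 90), strand="-"), ["A1"], ["B1"]
        )
        assert plus.direction == "distal"
        assert minus.direction == "proximal"
        assert plus.p_value == pytest.approx(minus.p_value)


class TestWeightedUTRLength:
    def test_single_pac_is_its_distance(self):
        assert weighted_utr_length([200], [7.3]) == pytest.approx(200.0)

    def test_equal_weights_average(self):
        assert weighted_utr_length([100, 300], [5, 5]) == pytest.approx(200.0)

    def test_three_to_one_weights(self):
        assert weighted_utr_length([100, 300], [3, 1]) == pytest.approx(150.0)

    def test_zero_total_weight_nan(self):
        assert math.isnan(weighted_utr_length([100, 300], [0, 0]))

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_weight_rescaling(self, c):
        base = weighted_utr_length([50, 150, 400], [1, 2, 3])
        scaled = weighted_utr_length([50, 150, 400], [c, 2 * c, 3 * c])
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_gene_level_strand_aware_distance(self):
        gene = _gene(strand="-", start=1000)  # stop codon at 1300
        pacs = [_pac_at(1100, strand="-", counts={"A": 1}), _pac_at(1200, strand="-", counts={"A": 1})]
        # distances: 1300-1100=200 and 1300-1200=100, equal weights -> 150
        assert gene_weighted_utr_length(gene, pacs, ["A"]) == pytest.approx(150.0)


class TestCompareUTRLengths:
    def test_identical_lengths_t_zero_p_one(self):
        lengths = pd.Series({"g1": 100.0, "g2": 200.0, "g3": 150.0})
        out = compare_utr_lengths(lengths, lengths.copy(), {"all": list(lengths.index)})
        assert out.loc["all", "t"] == pytest.approx(0.0)
        assert out.loc["all", "p_value"] == pytest.approx(1.0)

    def test_constant_offset_matches_paired_t_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        a = pd.Series(rng.uniform(100, 400, size=30), index=genes)
        b = a + 100 + rng.normal(0, 5, size=30)
        out = compare_utr_lengths(a, b, {"grp": genes})
        t_oracle, p_oracle = stats.ttest_rel(b, a)
        assert out.loc["grp", "t"] == pytest.approx(float(t_oracle))
        assert out.loc["grp", "p_value"] == pytest.approx(float(p_oracle))
        assert out.loc["grp", "p_value"] < 1e-6
        assert out.loc["grp", "mean_diff"] > 0

    def test_single_gene_group_skipped(self):
        a = pd.Series({"g1": 100.0})
        out = compare_utr_lengths(a, a + 50, {"solo": ["g1"]})
        assert bool(out.loc["solo", "skipped"])
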