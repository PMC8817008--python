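import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyqevo.seqio import CodonAlignment
from polyqevo.tracts import (
    PolyQOutlierModel,
    Tract,
    TractRecord,
    extract_ortholog_tract,
    filter_conserved_tracts,
    find_polyq_tracts,
    map_tract_window,
    rank_outliers,
    tract_metrics,
    tract_zscores,
    tracts_from_alignment,
)

# synthetic stand-in for a murine HTT exon1 start: 7 Q codons after the
# 17-residue N-terminal segment (the murine tract length)
SYNTHETIC_MOUSE_EXON1 = (
    "ATGGCGACCCTGGAAAAGCTGATGAAGGCCTTCGAGTCCCTCAAGTCCTTC"
    + "CAG" * 5 + "CAA" + "CAG"
    + "CCGCCACCG"
)


def QT(*codons, gene="g", taxon="t", start=0):
    return Tract(gene, taxon, start, start + len(codons), tuple(codons))


class TestFindTracts:
    def test_direct_scan(self):
        tracts = find_polyq_tracts("ATGCAGCAGCAACAGTAA")
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.start_codon, t.end_codon) == (1, 5)
        assert t.codons == ("CAG", "CAG", "CAA", "CAG")

    def test_below_threshold_yields_nothing(self):
        assert find_polyq_tracts("ATGCAGCAGCAGTAA") == []

    def test_min_len_configurable(self):
        assert len(find_polyq_tracts("ATGCAGCAGCAGTAA", min_len=3)) == 1

    def test_ambiguous_codon_breaks_run(self):
        # CAR is Q-compatible but uncertain: must split the run
        assert find_polyq_tracts("CAGCAGCARCAGCAGCAGCAG", min_len=4) == [
            QT("CAG", "CAG", "CAG", "CAG", taxon="", gene="", start=3)
        ]

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            find_polyq_tracts("ATGTAACAGCAGCAGCAG")

    def test_murine_length_tract_detected(self):
        tracts = find_polyq_tracts(SYNTHETIC_MOUSE_EXON1)
        assert len(tracts) == 1
        assert len(tracts[0]) == 7


class TestTractMetrics:
    @pytest.mark.parametrize(
        "codons, lq, lni, pq",
        [
            (("CAG", "CAG", "CAA", "CAG"), 4, 2, 0.75),
            (("CAA",) * 4, 4, 0, 0.0),
            (("CAG",) * 7, 7, 7, 1.0),
            (("CAA", "CAG", "CAG", "CAG", "CAA"), 5, 3, 0.6),
        ],
    )
    def test_examples(self, codons, lq, lni, pq):
        rec = tract_metrics(QT(*codons))
        assert (rec.LQ, rec.LNI, rec.PQ) == (lq, lni, pq)

    @given(st.lists(st.sampled_from(["CAA", "CAG"]), min_size=1, max_size=40))
    @settings(deadline=None)
    def test_invariants(self, codons):
        rec = tract_metrics(QT(*codons))
        assert rec.LNI <= rec.LQ
        assert 0 <= rec.PQ <= 1
        # PQ * LQ is the integer CAG count
        assert math.isclose(rec.PQ * rec.LQ, round(rec.PQ * rec.LQ))


class TestWindowMapping:
    def make_aln(self, focal_codons, other_codons):
        return CodonAlignment(
            ["h", "o"], {"h": focal_codons, "o": other_codons}, coding=False
        )

    def test_window_without_gaps(self):
        focal = ["ATG", "CAG", "CAG", "CAG", "CAG", "GTT"]
        aln = self.make_aln(focal, ["ATG", "CAA", "CAA", "CAA", "CAA", "GTT"])
        tract = find_polyq_tracts("".join(focal))[0]
        assert map_tract_window(aln, "h", tract) == (1, 5)

    def test_conjoined_gaps_extend_window(self):
        focal = ["ATG", "CAG", "CAG", "CAG", "CAG", "---", "---", "GTT"]
        other = ["ATG", "CAA", "CAA", "CAA", "CAA", "CAA", "CAA", "GTT"]
        aln = self.make_aln(focal, other)
        tract = find_polyq_tracts("".join(c for c in focal if c != "---"))[0]
        assert map_tract_window(aln, "h", tract) == (1, 7)

    def test_nonadjacent_gaps_do_not_extend(self):
        focal = ["ATG", "CAG", "CAG", "CAG", "CAG", "GTT", "---", "GTT"]
        other = ["ATG", "CAA", "CAA", "CAA", "CAA", "GTT", "AAA", "GTT"]
        aln = self.make_aln(focal, other)
        tract = find_polyq_tracts("ATGCAGCAGCAGCAGGTTGTT")[0]
        assert map_tract_window(aln, "h", tract) == (1, 5)

    def test_window_clipped_at_alignment_edge(self):
        focal = ["CAG", "CAG", "CAG", "CAG", "---"]
        other = ["CAA", "CAA", "CAA", "CAA", "ATG"]
        aln = self.make_aln(focal, other)
        tract = find_polyq_tracts("CAGCAGCAGCAG")[0]
        assert map_tract_window(aln, "h", tract) == (0, 5)

    def test_tract_not_in_row_is_error(self):
        aln = self.make_aln(["ATG", "GTT"], ["ATG", "GTT"])
        with pytest.raises(ValueError, match="not found"):
            map_tract_window(aln, "h", QT("CAG", "CAG", "CAG", "CAG", start=1))


class TestExtractOrtholog:
    def test_longest_overlapping_run_wins(self):
        row = (["ATG"] * 10 + ["CAG"] * 7 + ["ATG"] * 10 + ["CAA"] * 5 + ["ATG"])
        t = extract_ortholog_tract(row, (10, 30))
        assert len(t) == 7
        assert t.codons == ("CAG",) * 7

    def test_no_overlap_returns_none(self):
        row = ["ATG"] * 10 + ["CAG"] * 5
        assert extract_ortholog_tract(row, (0, 5)) is None

    def test_equal_length_tie_breaks_5prime(self):
        row = ["CAG"] * 3 + ["ATG"] + ["CAA"] * 3 + ["ATG"]
        t = extract_ortholog_tract(row, (0, 8))
        assert t.start_codon == 0 and t.codons == ("CAG",) * 3

    def test_gap_columns_do_not_interrupt_a_run(self):
        row = ["CAG", "---", "CAG", "CAG", "ATG"]
        t = extract_ortholog_tract(row, (0, 4))
        assert len(t) == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_never_exceeds_longest_run_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        row = [str(rng.choice(["CAG", "CAA", "ATG", "---"])) for _ in range(50)]
        lo = int(rng.integers(0, 40))
        hi = int(rng.integers(lo + 1, 51))
        t = extract_ortholog_tract(row, (lo, hi))
        # oracle: longest Q run over the ungapped row by direct scan
        best = cur = 0
        for c in row:
            if c == "---":
                continue
            cur = cur + 1 if c in ("CAG", "CAA") else 0
            best = max(best, cur)
        if t is not None:
            assert len(t) <= best


class TestZScores:
    def test_focal_equal_to_mean_gives_zero(self):
        orth = [TractRecord(4, 4, 1.0), TractRecord(8, 8, 1.0)]
        z = tract_zscores(TractRecord(6, 6, 1.0), orth)
        assert z.z_LQ == pytest.approx(0.0)

    def test_frozen_textbook_value(self):
        # oracle: mean([4,4,7,9]) = 6, sample sd = sqrt(18/3) = sqrt(6)
        orth = [TractRecord(v, v, 1.0) for v in (4, 4, 7, 9)]
        z = tract_zscores(TractRecord(21, 21, 1.0), orth)
        assert z.z_LQ == pytest.approx(15.0 / math.sqrt(6.0))

    def test_zero_spread_flagged_undefined(self):
        orth = [TractRecord(4, 4, 0.5), TractRecord(4, 4, 0.5)]
        z = tract_zscores(TractRecord(9, 9, 1.0), orth)
        assert z.z_LQ is None and z.z_PQ is None

    def test_fewer_than_two_orthologs_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            tract_zscores(TractRecord(4, 4, 1.0), [TractRecord(4, 4, 1.0)])

    @given(
        st.lists(st.integers(4, 30), min_size=3, max_size=12),
        st.integers(4, 40),
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    @settings(deadline=None, max_examples=60)
    def test_affine_invariance(self, orth_vals, focal_val, shift, scale):
        """z is unchanged by any common shift + positive rescale."""
        orth = [TractRecord(v, v, 1.0) for v in orth_vals]
        z0 = tract_zscores(TractRecord(focal_val, focal_val, 1.0), orth)
        orth_t = [TractRecord(shift + scale * v, shift + scale * v, 1.0)
                  for v in orth_vals]
        z1 = tract_zscores(
            TractRecord(shift + scale * focal_val, shift + scale * focal_val, 1.0),
            orth_t,
        )
        if z0.z_LQ is None:
            assert z1.z_LQ is None
        else:
            assert z1.z_LQ == pytest.approx(z0.z_LQ, abs=1e-6)


def make_set(n_pri, n_non, lengths):
    """Ortholog tract set with cycled lengths across taxa."""
    out = {}
    taxa = [f"p{i}" for i in range(n_pri)] + [f"n{i}" for i in range(n_non)]
    for i, t in enumerate(taxa):
        lq = lengths[i % len(lengths)]
        out[t] = QT(*(("CAG",) * lq), taxon=t)
    taxonomy = {t: ("primate" if t.startswith("p") else "non-primate") for t in taxa}
    return out, taxonomy


class TestConservationFilter:
    def test_six_and_six_with_two_lengths_kept(self):
        s, tax = make_set(6, 6, [4, 7])
        assert filter_conserved_tracts({"g": s}, tax) == {"g": s}

    def test_five_primates_dropped_strict_boundary(self):
        s, tax = make_set(5, 20, [4, 7])
        assert filter_conserved_tracts({"g": s}, tax) == {}

    def test_no_length_variation_dropped(self):
        s, tax = make_set(10, 10, [4])
        assert filter_conserved_tracts({"g": s}, tax) == {}

    def test_codon_string_variation_mode(self):
        # same LQ everywhere but two distinct codon strings
        s = {f"p{i}": QT("CAG", "CAG", "CAG", "CAG") for i in range(6)}
        s.update({f"n{i}": QT("CAG", "CAA", "CAG", "CAG") for i in range(6)})
        tax = {t: ("primate" if t.startswith("p") else "non-primate") for t in s}
        assert filter_conserved_tracts({"g": s}, tax) == {}  # lq mode drops
        kept = filter_conserved_tracts({"g": s}, tax, variation="codons")
        assert "g" in kept

    def test_unlabeled_taxon_error(self):
        s, tax = make_set(6, 6, [4, 7])
        del tax["p0"]
        with pytest.raises(ValueError, match="p0"):
            filter_conserved_tracts({"g": s}, tax)

    def test_monotone_adding_orthologs_never_removes(self):
        s, tax = make_set(6, 6, [4, 7])
        kept_before = filter_conserved_tracts({"g": s}, tax)
        assert "g" in kept_before
        s2 = dict(s)
        for i in range(3):
            t = f"extra{i}"
            s2[t] = QT(*(("CAA",) * 5), taxon=t)
            tax[t] = "non-primate"
        assert "g" in filter_conserved_tracts({"g": s2}, tax)


class TestRanking:
    def test_planted_outlier_ranks_first(self):
        from polyqevo.tracts import TractZScores

        scores = {
            "plain1": TractZScores(0.5, 0.2, 0.1, 10),
            "outlier": TractZScores(9.0, 8.0, 2.0, 10),
            "plain2": TractZScores(-1.0, 0.0, 0.3, 10),
        }
        ranked, undefined = rank_outliers(scores)
        top = ranked[(ranked.metric == "z_LQ") & (ranked["rank"] == 1)]
        assert top["key"].iloc[0] == "outlier"
        assert undefined.empty

    def test_all_equal_scores_share_input_order(self):
        from polyqevo.tracts import TractZScores

        scores = {k: TractZScores(1.0, 1.0, 1.0, 5) for k in ("a", "b", "c")}
        ranked, _ = rank_outliers(scores)
        lq = ranked[ranked.metric == "z_LQ"]
        assert list(lq["key"]) == ["a", "b", "c"]
        assert set(lq["percentile"]) == {1 / 3, 2 / 3, 1.0}

    def test_undefined_scores_partitioned_out(self):
        from polyqevo.tracts import TractZScores

        scores = {
            "ok": TractZScores(1.0, 1.0, 1.0, 5),
            "flat": TractZScores(None, None, None, 5),
        }
        ranked, undefined = rank_outliers(scores)
        assert "flat" not in set(ranked["key"])
        assert set(undefined["key"]) == {"flat"}


class TestAlignmentPipeline:
    def test_focal_tract_mapped_across_orthologs(self):
        rows = {
            "human": ["ATG"] + ["CAG"] * 6 + ["GTT"],
            "chimp": ["ATG"] + ["CAG"] * 5 + ["---", "GTT"],
            "mouse": ["ATG"] + ["CAA"] * 4 + ["---", "---", "GTT"],
        }
        aln = CodonAlignment(list(rows), rows, coding=False)
        sets = tracts_from_alignment(aln, "human", gene="HTT")
        assert len(sets) == 1
        by_taxon = next(iter(sets.values()))
        assert len(by_taxon["human"]) == 6
        assert len(by_taxon["chimp"]) == 5
        assert len(by_taxon["mouse"]) == 4

    def test_model_recovers_planted_outlier(self):
        from polyqevo import simulate

        table, taxonomy, truth = simulate.make_tract_dataset(
            simulate.TractSimParams(seed=11, n_genes=12),
            simulate.OutlierSpec("human", boost_lq=15, genes=("gene3",)),
        )
        res = PolyQOutlierModel(table, taxonomy, "human").fit()
        assert res.rank_of("gene3", "z_LQ") == 1
        assert res.rank_of("gene3", "z_LNI") == 1
        assert "gene3" in res.summary()
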