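"""Promoter windows, peak overlap, Fisher enrichment and GO tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from newrna.enrichment import (
    expression_matched_background,
    factor_enrichment,
    fisher_exact_two_sided,
    gene_windows,
    go_overrepresentation,
    peak_in_promoter,
    promoter_window,
    region_enrichment,
)


def _fisher_fraction_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p (sum of tables no more probable)."""
    n1, n2, K = a + b, c + d, a + c
    N = n1 + n2
    tot = comb(N, n1)
    p_obs = Fraction(comb(K, a) * comb(N - K, n1 - a), tot)
    p = Fraction(0)
    for x in range(max(0, K - n2), min(K, n1) + 1):
        px = Fraction(comb(K, x) * comb(N - K, n1 - x), tot)
        if px <= p_obs:
            p += px
    return float(p)


class TestPromoterWindow:
    def test_plus_strand_convention(self):
        w = promoter_window("g", 10_000, "+", "chr1")
        assert (w.start, w.end) == (9000, 10100)
        assert w.end - w.start == 1100

    def test_minus_strand_mirrored(self):
        w = promoter_window("g", 10_000, "-", "chr1")
        assert (w.start, w.end) == (9900, 11000)
        assert w.end - w.start == 1100

    def test_truncated_at_chromosome_start(self):
        w = promoter_window("g", 500, "+", "chr1")
        assert w.start == 0 and w.end == 600

    def test_invalid_tss_rejected(self):
        with pytest.raises(ValueError):
            promoter_window("g", 0, "+", "chr1")


class TestPeakOverlap:
    def _windows(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    def test_half_open_boundary_semantics(self):
        windows = self._windows([("g1", "chr1", 999, 1100, "+")])
        # peak abutting the window end: no overlap under half-open intervals
        peaks = pd.DataFrame(
            [("chr1", 1100, 1200, "f")], columns=["chrom", "start", "end", "name"]
        )
        assert not peak_in_promoter(windows, peaks).iloc[0, 0]
        # one-bp encroachment overlaps
        peaks2 = pd.DataFrame(
            [("chr1", 1099, 1200, "f")], columns=["chrom", "start", "end", "name"]
        )
        assert peak_in_promoter(windows, peaks2).iloc[0, 0]

    def test_spanning_peak_overlaps(self):
        windows = self._windows([("g1", "chr1", 1000, 2100, "+")])
        peaks = pd.DataFrame(
            [("chr1", 500, 5000, "f")], columns=["chrom", "start", "end", "name"]
        )
        assert peak_in_promoter(windows, peaks).iloc[0, 0]

    def test_agrees_with_bruteforce_all_pairs(self, rng):
        chroms = ["chr1", "chr2"]
        windows = self._windows(
            [
                (f"g{i}", chroms[i % 2], s := int(rng.integers(0, 50_000)), s + 1100, "+")
                for i in range(300)
            ]
        )
        starts = rng.integers(0, 51_000, size=300)
        peaks = pd.DataFrame(
            {
                "chrom": rng.choice(chroms, 300),
                "start": starts,
                "end": starts + rng.integers(50, 800, size=300),
                "name": rng.choice(["f1", "f2", "f3"], 300),
            }
        )
        table = peak_in_promoter(windows, peaks)
        for w in windows.sample(60, random_state=1).itertuples(index=False):
            for factor in ["f1", "f2", "f3"]:
                sub = peaks[(peaks["name"] == factor) & (peaks["chrom"] == w.chrom)]
                brute = bool(
                    ((sub["start"] < w.end) & (sub["end"] > w.start)).any()
                )
                assert table.at[w.gene_id, factor] == brute


class TestFisher:
    def test_printed_table_matches_enumeration(self):
        p = fisher_exact_two_sided([[30, 70], [10, 90]])
        assert p == pytest.approx(_fisher_fraction_oracle(30, 70, 10, 90), abs=1e-10)

    def test_identical_proportions_maximal_p(self):
        assert fisher_exact_two_sided([[30, 70], [30, 70]]) == pytest.approx(1.0)

    def test_random_tables_within_1e10_of_oracle(self, rng):
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 100, 4))
            assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
                _fisher_fraction_oracle(a, b, c, d), abs=1e-10
            )


class TestFactorEnrichment:
    def _table(self, up_hits, up_total, down_hits, down_total):
        genes = [f"u{i}" for i in range(up_total)] + [f"d{i}" for i in range(down_total)]
        vals = [i < up_hits for i in range(up_total)] + [
            i < down_hits for i in range(down_total)
        ]
        return (
            [f"u{i}" for i in range(up_total)],
            [f"d{i}" for i in range(down_total)],
            pd.DataFrame({"F": vals}, index=pd.Index(genes, name="gene_id")),
        )

    def test_fold_change_is_fraction_ratio(self):
        up, down, table = self._table(30, 100, 10, 100)
        res = factor_enrichment(up, down, table)
        assert res.iloc[0]["fold_change"] == pytest.approx(3.0)
        assert res.iloc[0]["p_value"] == pytest.approx(
            _fisher_fraction_oracle(30, 70, 10, 90), abs=1e-10
        )

    def test_label_symmetry_inverts_fold_change(self):
        up, down, table = self._table(30, 100, 10, 100)
        fwd = factor_enrichment(up, down, table)
        rev = factor_enrichment(down, up, table)
        assert rev.iloc[0]["fold_change"] == pytest.approx(
            1 / fwd.iloc[0]["fold_change"]
        )
        assert rev.iloc[0]["p_value"] == pytest.approx(fwd.iloc[0]["p_value"], abs=1e-12)

    def test_degenerate_margin_skipped(self):
        up, down, table = self._table(0, 20, 0, 20)
        res = factor_enrichment(up, down, table)
        assert res.empty
        assert res.attrs["skipped"][0][0] == "F"

    def test_region_scheme_produces_all_regions(self):
        ann = pd.DataFrame(
            {"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"],
             "tss": [10_000, 40_000], "tes": [20_000, 30_000],
             "strand": ["+", "-"]}
        )
        peaks = pd.DataFrame(
            [("chr1", 9_500, 9_600, "F"), ("chr1", 15_000, 15_200, "F"),
             ("chr1", 29_000, 29_500, "F")],
            columns=["chrom", "start", "end", "name"],
        )
        res = region_enrichment(["gA"], ["gB"], peaks, ann)
        assert set(res["region"]) == {"promoter", "gene_body", "downstream"}


class TestGeneWindows:
    def test_gene_body_and_downstream_orientation(self):
        ann = pd.DataFrame(
            {"gene_id": ["gp", "gm"], "chrom": ["chr1", "chr1"],
             "tss": [10_000, 50_000], "tes": [20_000, 40_000],
             "strand": ["+", "-"]}
        )
        body = gene_windows(ann, region="gene_body").set_index("gene_id")
        assert body.loc["gp", ["start", "end"]].tolist() == [10_100, 20_000]
        assert body.loc["gm", ["start", "end"]].tolist() == [40_000, 49_900]
        down = gene_windows(ann, region="downstream").set_index("gene_id")
        assert down.loc["gp", ["start", "end"]].tolist() == [20_000, 21_000]
        assert down.loc["gm", ["start", "end"]].tolist() == [39_000, 40_000]


class TestExpressionMatching:
    def test_alternating_input_matches_nearest_neighbors(self):
        expr = pd.Series(np.arange(100, 0, -1, dtype=float), index=[f"g{i}" for i in range(100)])
        input_genes = [f"g{i}" for i in range(0, 100, 2)]
        bg, match_map = expression_matched_background(input_genes, expr)
        assert len(bg) == len(input_genes)
        ranked = list(expr.sort_values(ascending=False).index)
        rank_of = {g: i for i, g in enumerate(ranked)}
        for g, m in match_map.items():
            assert abs(rank_of[g] - rank_of[m]) == 1

    def test_isolated_gene_stays_unmatched(self):
        # every neighbour within 100 ranks of g0 belongs to the input set
        expr = pd.Series(
            np.arange(300, 0, -1, dtype=float), index=[f"g{i}" for i in range(300)]
        )
        input_genes = [f"g{i}" for i in range(0, 102)]
        bg, match_map = expression_matched_background(input_genes, expr)
        assert "g0" not in match_map  # fenced in by other input genes

    def test_matched_background_mean_close_to_input(self, rng):
        expr = pd.Series(
            np.sort(rng.lognormal(2, 1, 2000))[::-1], index=[f"g{i}" for i in range(2000)]
        )
        input_genes = [f"g{i}" for i in rng.choice(2000, 200, replace=False)]
        bg, _ = expression_matched_background(input_genes, expr)
        assert abs(expr[bg].mean() - expr[input_genes].mean()) / expr[input_genes].mean() < 0.05

    def test_small_universe_rejected(self):
        expr = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            expression_matched_background(["a", "b"], expr)


class TestGoOverrepresentation:
    def _annotation(self, members):
        return pd.DataFrame(
            [(g, t) for t, genes in members.items() for g in genes],
            columns=["gene_id", "go_id"],
        )

    def test_identical_sets_are_null(self):
        genes = [f"g{i}" for i in range(40)]
        g2g = self._annotation({"GO:1": genes[:15]})
        res = go_overrepresentation(genes, genes, g2g)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_large_expected_counts_use_chisquare(self):
        study = [f"s{i}" for i in range(60)]
        bg = [f"b{i}" for i in range(90)]
        members = {"GO:1": study[:24] + bg[:26]}  # expected counts all > 10
        res = go_overrepresentation(study, bg, self._annotation(members))
        assert res.iloc[0]["test"] == "chi2"

    def test_small_expected_counts_use_fisher_with_oracle(self):
        study = [f"s{i}" for i in range(30)]
        bg = [f"b{i}" for i in range(30)]
        members = {"GO:1": study[:5] + bg[:1]}
        res = go_overrepresentation(study, bg, self._annotation(members))
        assert res.iloc[0]["test"] == "fisher"
        assert res.iloc[0]["p_value"] == pytest.approx(
            _fisher_fraction_oracle(5, 25, 1, 29), abs=1e-10
        )

    def test_obsolete_terms_excluded(self):
        study = [f"s{i}" for i in range(10)]
        bg = [f"b{i}" for i in range(10)]
        members = {"GO:ok": study[:3], "GO:dead": study[:3]}
        ontology = pd.DataFrame(
            {"term_id": ["GO:ok", "GO:dead"], "name": ["x", "y"],
             "is_obsolete": [False, True]}
        )
        res = go_overrepresentation(study, bg, self._annotation(members), ontology)
        assert set(res["term_id"]) == {"GO:ok"}
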