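import numpy as np
import pandas as pd
import pytest

from dcescan.binning import BinGrid
from dcescan.detection import DCE, DCESet
from dcescan.enrichment import (
    Territory, _random_placement, ep_disruption, entropy_group_test,
    geneset_enrichment, shannon_entropy, track_enrichment,
)


def dce(start, end, chrom="chr1"):
    return DCE(chrom=chrom, start_bin=0, end_bin=0, start=start, end=end,
               mean_signal=0.5, left_p=0.01, right_p=0.01)


@pytest.fixture
def territory():
    grid = BinGrid(chrom="chr1", bin_size=100, anchor=0, n_bins=50)
    return Territory(grids={"chr1": grid}, bins={"chr1": np.arange(50)})


def genes_at(positions, width=80):
    return pd.DataFrame({
        "gene_name": [f"g{i}" for i in range(len(positions))],
        "chrom": ["chr1"] * len(positions),
        "start": [p for p in positions],
        "end": [p + width for p in positions],
        "strand": ["+"] * len(positions),
        "gene_type": ["protein_coding"] * len(positions),
    })


class TestEntropy:
    @pytest.mark.parametrize("n", [2, 4, 8, 16])
    def test_uniform_is_log2_n(self, n):
        assert shannon_entropy(np.full(n, 1 / n)) == pytest.approx(np.log2(n))

    def test_degenerate_is_zero_and_permutation_invariant(self):
        assert shannon_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0)
        p = [0.5, 0.25, 0.25]
        assert shannon_entropy(p) == pytest.approx(1.5)
        assert shannon_entropy(p[::-1]) == pytest.approx(shannon_entropy(p))

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            shannon_entropy([-0.1, 1.1])
        with pytest.raises(ValueError, match="sum"):
            shannon_entropy([0.4, 0.4])

    def test_group_test_separated_and_identical(self):
        assert entropy_group_test([3.0, 3.1, 3.2], [1.0, 1.1, 1.2]) == pytest.approx(0.1)
        assert entropy_group_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


class TestPlacement:
    def test_placements_valid_and_cover_all_slots(self, rng):
        for _ in range(50):
            spans = _random_placement(rng, 30, [4, 7, 2])
            occupied = []
            for s, l in spans:
                assert 0 <= s and s + l <= 30
                occupied.extend(range(s, s + l))
            assert len(occupied) == len(set(occupied)) == 13
        assert sorted(l for _, l in spans) == [2, 4, 7]

    def test_uniform_over_exhaustive_toy_placements(self, rng):
        # one 3-bin interval on a 10-bin axis: 8 possible starts
        counts = np.zeros(10)
        n = 4000
        for _ in range(n):
            (s, _), = _random_placement(rng, 10, [3])
            counts[s] += 1
        assert counts[8:].sum() == 0
        np.testing.assert_allclose(counts[:8] / n, 1 / 8, atol=0.03)


class TestGenesetEnrichment:
    def test_planted_signal_detected(self, territory, rng):
        dces = DCESet(group="g", dces=[dce(1000, 1500)])  # bins 10..14
        genes = genes_at([1010, 1120, 1230, 1340, 4000, 4400])
        res = geneset_enrichment(
            dces, ["g0", "g1", "g2", "g3"], genes, territory, n_perm=400, seed=1
        )
        assert res.observed == 4
        assert res.z > 1.5
        # exhaustively, only 2 of 46 placements cover all four gene bins
        assert res.p_enrich == pytest.approx(2 / 46, abs=0.03)

    def test_p_matches_exhaustive_enumeration_on_toy(self, territory):
        # one 5-bin domain on a 50-bin axis: 46 equally likely placements;
        # a single gene in one bin is covered by exactly 5 of them
        dces = DCESet(group="g", dces=[dce(1000, 1500)])
        genes = genes_at([2510])
        res = geneset_enrichment(dces, ["g0"], genes, territory, n_perm=4000, seed=2)
        exact = 5 / 46
        assert res.observed == 0
        # (k+1)/(n+1) estimator of P(null >= 0) = 1, P(null <= 0) ~ 1 - 5/46
        assert res.p_enrich == pytest.approx(1.0, abs=0.01)
        assert res.p_deplete == pytest.approx(1 - exact, abs=0.02)

    def test_empty_domain_set_counts_zero(self, territory):
        res = geneset_enrichment(
            DCESet(group="g", dces=[]), ["g0"], genes_at([100]), territory,
            n_perm=50, seed=3,
        )
        assert res.observed == 0

    def test_no_covered_gene_is_an_error(self, territory):
        genes = genes_at([100])
        genes["chrom"] = "chrX"
        with pytest.raises(ValueError, match="covered chromosome"):
            geneset_enrichment(DCESet(group="g", dces=[dce(0, 500)]),
                               ["g0"], genes, territory, n_perm=10, seed=0)


class TestTrackEnrichment:
    def test_genome_wide_track_shows_no_enrichment(self, territory):
        dces = DCESet(group="g", dces=[dce(1000, 2000)])
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5000],
                              "label": ["everything"]})
        out = track_enrichment(dces, track, territory, n_perm=200, seed=4)
        row = out.iloc[0]
        assert row["observed_bp"] == row["null_mean"]
        assert row["p_two_sided"] > 0.9

    def test_focal_label_enriched_and_bh_monotone(self, territory):
        dces = DCESet(group="g", dces=[dce(1000, 2000)])
        track = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chrX"],
            "start": [1000, 3000, 0],
            "end": [2000, 3500, 100],
            "label": ["hit", "elsewhere", "absent"],
        })
        out = track_enrichment(dces, track, territory, n_perm=300, seed=5)
        out = out.set_index("label")
        assert out.loc["hit", "z"] > 0
        assert not out.loc["absent", "testable"]
        assert np.isnan(out.loc["absent", "p_adjusted"])
        testable = out[out["testable"]].sort_values("p_two_sided")
        assert testable["p_adjusted"].is_monotonic_increasing


class TestEPDisruption:
    def test_split_disrupts_spanning_links_only(self):
        ref = DCESet(group="r", dces=[dce(0, 1000)])
        query = DCESet(group="q", dces=[dce(0, 400), dce(600, 1000)])
        links = pd.DataFrame({
            "gene_name": ["spanning", "inside", "outside"],
            "chrom": ["chr1"] * 3,
            "promoter_pos": [100, 100, 5000],
            "enh_start": [700, 300, 5400],
            "enh_end": [760, 360, 5460],
        })
        df, summary = ep_disruption(links, ref, query)
        status = dict(zip(df["gene_name"], df["status"]))
        assert status == {"spanning": "disrupted", "inside": "preserved",
                          "outside": "not_evaluable"}
        assert summary["n_evaluable"] == 2
        assert summary["fraction_disrupted"] == pytest.approx(0.5)
        assert summary["disrupted_genes"] == ["spanning"]

    def test_intact_query_preserves_links(self):
        ref = DCESet(group="r", dces=[dce(0, 1000)])
        query = DCESet(group="q", dces=[dce(0, 1000)])
        links = pd.DataFrame({
            "gene_name": ["a"], "chrom": ["chr1"], "promoter_pos": [100],
            "enh_start": [700], "enh_end": [760],
        })
        _, summary = ep_disruption(links, ref, query)
        assert summary["n_disrupted"] == 0

    def test_malformed_links_skipped_with_warning(self):
        ref = DCESet(group="r", dces=[dce(0, 1000)])
        links = pd.DataFrame({
            "gene_name": ["bad", "good"], "chrom": ["chr1", "chr1"],
            "promoter_pos": [100, 100], "enh_start": [900, 200],
            "enh_end": [800, 300],  # first has start >= end
        })
        with pytest.warns(UserWarning, match="malformed"):
            df, summary = ep_disruption(links, ref, ref)
        assert summary["n_skipped"] == 1
        assert len(df) == 1
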