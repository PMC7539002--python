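import numpy as np
import pandas as pd
import pytest

from dcescan.detection import DCE, DCESet
from dcescan.dynamics import (
    bp_distance, classify_dces, coverage_stats, disruptor_report,
    find_disruptors, genome_bp_distance, jaccard,
)


def dce(start, end, chrom="chr1"):
    return DCE(chrom=chrom, start_bin=0, end_bin=0, start=start, end=end,
               mean_signal=0.5, left_p=0.01, right_p=0.01)


def dset(intervals, group="g"):
    return DCESet(group=group, dces=[dce(s, e) for s, e in intervals])


class TestJaccard:
    def test_identical_disjoint_partial(self):
        assert jaccard((0, 100), (0, 100)) == pytest.approx(1.0)
        assert jaccard((0, 100), (200, 300)) == 0.0
        assert jaccard((0, 100), (50, 150)) == pytest.approx(1 / 3)

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError, match="zero-length"):
            jaccard((5, 5), (0, 10))


def brute_force_bp(seg_a, seg_b, length):
    """Oracle: per-base-pair segment labels, then the size-weighted formula."""
    def labels(segs):
        lab = np.full(length, -1)
        for k, (s, e) in enumerate(sorted(segs)):
            lab[s:e] = k
        # background gaps become their own segments
        out = np.zeros(length, dtype=int)
        current = 0
        for i in range(1, length):
            if lab[i] != lab[i - 1]:
                current += 1
            out[i] = current
        return out

    la, lb = labels(seg_a), labels(seg_b)
    total = 0.0
    for a in np.unique(la):
        for b in np.unique(lb):
            o = int(((la == a) & (lb == b)).sum())
            if o:
                total += o * o / max((la == a).sum(), (lb == b).sum())
    return 1.0 - total / length


class TestBPDistance:
    def test_identity_and_symmetry(self):
        a = [(10, 40), (60, 90)]
        b = [(5, 35), (50, 95)]
        assert bp_distance(a, a, 100) == pytest.approx(0.0)
        assert bp_distance(a, b, 100) == pytest.approx(bp_distance(b, a, 100))

    def test_matches_per_bp_oracle_on_random_partitions(self, rng):
        for _ in range(20):
            length = int(rng.integers(50, 400))

            def rand_segs():
                cuts = np.sort(rng.choice(length, size=int(rng.integers(1, 6)),
                                          replace=False))
                segs, prev = [], 0
                for c in cuts:
                    if c > prev and rng.random() < 0.7:
                        segs.append((int(prev), int(c)))
                    prev = c
                return segs

            a, b = rand_segs(), rand_segs()
            got = bp_distance(a, b, length)
            assert got == pytest.approx(brute_force_bp(a, b, length), abs=1e-10)
            assert 0.0 <= got <= 1.0

    def test_three_segment_example(self):
        a = [(0, 30), (30, 60)]   # plus background [60,100)
        b = [(0, 50), (50, 100)]
        assert bp_distance(a, b, 100) == pytest.approx(brute_force_bp(a, b, 100), abs=1e-12)

    def test_genome_weighted_average(self):
        ref = DCESet(group="r", dces=[dce(0, 50, "chr1"), dce(0, 80, "chr2")])
        query = DCESet(group="q", dces=[dce(0, 50, "chr1")])
        per_chrom, weighted = genome_bp_distance(ref, query, {"chr1": 100, "chr2": 100})
        assert per_chrom["chr1"] == pytest.approx(0.0)
        assert per_chrom["chr2"] > 0
        assert weighted == pytest.approx(np.mean([per_chrom["chr1"], per_chrom["chr2"]]))


class TestClassify:
    def test_split_depleted_intact(self):
        ref = dset([(0, 100), (200, 300), (400, 500)])
        query = dset([(0, 40), (60, 100), (400, 500)])
        rep = classify_dces(ref, query)
        assert rep.ref_labels == {0: "split", 1: "depleted", 2: "intact"}
        assert rep.query_labels == {0: "split", 1: "split", 2: "intact"}

    def test_merge_emerged_expanded_contracted(self):
        ref = dset([(0, 40), (60, 100), (200, 260), (400, 440)])
        query = dset([(0, 100), (190, 270), (410, 430), (600, 700)])
        rep = classify_dces(ref, query)
        assert rep.ref_labels[0] == "merged" and rep.ref_labels[1] == "merged"
        assert rep.ref_labels[2] == "expanded"
        assert rep.ref_labels[3] == "contracted"
        assert rep.query_labels[3] == "emerged"

    def test_swap_maps_labels_symmetrically(self):
        ref = dset([(0, 100), (200, 300), (400, 460), (600, 700)])
        query = dset([(0, 40), (60, 100), (190, 310), (800, 900)])
        fwd = classify_dces(ref, query)
        rev = classify_dces(query, ref)
        swap = {"depleted": "emerged", "emerged": "depleted",
                "split": "merged", "merged": "split",
                "expanded": "contracted", "contracted": "expanded",
                "intact": "intact"}
        assert rev.ref_labels == {i: swap[l] for i, l in fwd.query_labels.items()}
        assert rev.query_labels == {i: swap[l] for i, l in fwd.ref_labels.items()}

    def test_every_dce_gets_exactly_one_label_and_ratios_sum_to_one(self):
        ref = dset([(0, 100), (150, 250), (300, 400)])
        query = dset([(0, 30), (50, 100), (140, 260)])
        rep = classify_dces(ref, query)
        assert set(rep.ref_labels) == {0, 1, 2}
        assert sum(rep.ratios("ref").values()) == pytest.approx(1.0)
        assert sum(rep.ratios("query").values()) == pytest.approx(1.0)

    def test_overlapping_input_rejected(self):
        ref = DCESet(group="r", dces=[dce(0, 100)])
        query = DCESet(group="q", dces=[dce(0, 100)])
        query.dces.append(dce(50, 150))  # bypass constructor check
        with pytest.raises(ValueError, match="within one set"):
            classify_dces(ref, query)


class TestDisruptors:
    @pytest.fixture
    def split_setup(self):
        ref_dce = dce(0, 100)
        partners = [dce(0, 40), dce(60, 100)]
        genes = pd.DataFrame({
            "gene_name": ["in_gap", "in_fragment", "straddler", "outside"],
            "chrom": ["chr1"] * 4,
            "start": [45, 10, 35, 300],
            "end": [55, 20, 45, 320],
            "strand": ["+"] * 4,
            "gene_type": ["protein_coding"] * 4,
        })
        return ref_dce, partners, genes

    def test_three_conditions(self, split_setup):
        ref_dce, partners, genes = split_setup
        out = find_disruptors(ref_dce, partners, genes)
        assert out == ["in_gap"]  # fragment gene and straddler excluded

    def test_no_genes_in_gap(self, split_setup):
        ref_dce, partners, genes = split_setup
        empty = find_disruptors(ref_dce, partners, genes[genes.gene_name == "outside"])
        assert empty == []

    def test_non_split_is_an_error(self, split_setup):
        ref_dce, partners, genes = split_setup
        with pytest.raises(ValueError, match="split"):
            find_disruptors(ref_dce, partners[:1], genes)

    def test_report_covers_split_events(self, split_setup):
        ref_dce, partners, genes = split_setup
        ref = DCESet(group="r", dces=[ref_dce])
        query = DCESet(group="q", dces=partners)
        rep = classify_dces(ref, query)
        df = disruptor_report(rep, ref, query, genes)
        assert df["gene_name"].tolist() == ["in_gap"]


class TestCoverage:
    def test_fraction_arithmetic(self):
        from dcescan.binning import BinGrid

        grid = BinGrid(chrom="chr1", bin_size=10, anchor=0, n_bins=200)
        eligible = {"chr1": np.arange(200)}
        one = DCESet(group="g", dces=[dce(0, 100)])       # 10 bins of 200
        stats = coverage_stats(one, eligible, {"chr1": grid})
        assert stats["genome_fraction"] == pytest.approx(0.05)
        two = DCESet(group="g", dces=[dce(0, 50), dce(100, 250)])  # 5 + 15 bins
        assert coverage_stats(two, eligible, {"chr1": grid})["genome_fraction"] == \
               pytest.approx(0.10)
        empty = DCESet(group="g", dces=[])
        assert coverage_stats(empty, eligible, {"chr1": grid})["genome_fraction"] == 0.0
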