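"""Marker filters, LD blocks, kinship, CNV markers and gene events."""

import numpy as np
import pandas as pd
import pytest

from stressgwas import synthio
from stressgwas.genotypes import (CoreMask, GenotypeMatrix, classify_cnv,
                                  cnv_markers, filter_core_maf,
                                  gene_cnv_events, kinship, ld_blocks,
                                  read_vcf, write_vcf)


def matrix(dosages, strains=None, chrom="chrI", spacing=100):
    dos = np.asarray(dosages, dtype=float)
    strains = strains or [f"S{i}" for i in range(dos.shape[1])]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(dos.shape[0]) * spacing + 10,
         "ref": "A", "alt": "T", "kind": "snp"}
    )
    return GenotypeMatrix(markers=markers, dosages=dos, strains=strains)


class TestVCF:
    def test_round_trip(self, tmp_path):
        gm, _, _ = synthio.gen_genotypes(8, n_markers=30, seed=1)
        gm.dosages[3, 2] = np.nan  # a missing call survives the trip
        path = tmp_path / "g.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.strains == gm.strains
        np.testing.assert_array_equal(
            back.markers[["chrom", "pos", "ref", "alt"]].to_numpy(),
            gm.markers[["chrom", "pos", "ref", "alt"]].to_numpy(),
        )
        np.testing.assert_array_equal(back.dosages, gm.dosages)

    def test_het_call_is_dosage_one(self, tmp_path):
        gm = matrix([[0, 1, 2]])
        path = tmp_path / "h.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.dosages[0, 1] == 1.0

    def test_homozygous_strain_zero_heterozygosity(self):
        gm = matrix([[0, 1], [2, 1], [0, 1]])
        het = gm.heterozygosity()
        assert het["S0"] == 0.0
        assert het["S1"] == 1.0


class TestFilter:
    def test_full_mask_zero_maf_is_identity(self):
        gm = matrix([[0, 1, 2, 1], [2, 2, 0, 0]])
        mask = CoreMask(pd.DataFrame(
            [{"chrom": "chrI", "start": 0, "end": 10_000}]))
        out = filter_core_maf(gm, mask, maf_min=0.0)
        assert out.n_markers == 2

    def test_maf_exactly_at_threshold_removed(self):
        # 20 strains, one heterozygote: allele frequency exactly 0.05 -> the
        # strict > rule drops it; 0.05 + epsilon survives
        dos_at = np.zeros((1, 20))
        dos_at[0, 0] = 2.0  # p = 2/40 = 0.05
        assert filter_core_maf(matrix(dos_at), maf_min=0.05).n_markers == 0
        dos_above = np.zeros((1, 20))
        dos_above[0, 0] = 2.0
        dos_above[0, 1] = 1.0  # p = 3/40 = 0.075
        assert filter_core_maf(matrix(dos_above), maf_min=0.05).n_markers == 1

    def test_half_open_mask_boundary(self):
        gm = matrix([[0, 1, 1, 2]], spacing=0)  # marker at pos 10
        inside = CoreMask(pd.DataFrame([{"chrom": "chrI", "start": 10, "end": 11}]))
        outside = CoreMask(pd.DataFrame([{"chrom": "chrI", "start": 11, "end": 20}]))
        assert filter_core_maf(gm, inside, maf_min=0.0).n_markers == 1
        assert filter_core_maf(gm, outside, maf_min=0.0).n_markers == 0

    def test_idempotent(self):
        gm, _, _ = synthio.gen_genotypes(12, n_markers=60, seed=2)
        once = filter_core_maf(gm, maf_min=0.05)
        twice = filter_core_maf(once, maf_min=0.05)
        assert once.n_markers == twice.n_markers
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_empty_result_warns(self):
        gm = matrix([[0, 0, 0, 1]])
        with pytest.warns(UserWarning, match="no markers"):
            filter_core_maf(gm, maf_min=0.4)


class TestLDBlocks:
    def test_identical_adjacent_markers_one_block(self):
        gm = matrix([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]])
        blocks, reps = ld_blocks(gm)
        assert len(blocks) == 1
        assert blocks[0].members == [0, 1]
        assert reps.n_markers == 1

    def test_independent_markers_singletons(self, rng):
        dos = rng.binomial(2, 0.5, size=(6, 40)).astype(float)
        blocks, _ = ld_blocks(matrix(dos), r2_min=0.8)
        assert len(blocks) == 6

    def test_gap_breaks_block(self):
        gm = matrix([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]], spacing=30_000)
        blocks, _ = ld_blocks(gm, max_gap_bp=20_000)
        assert len(blocks) == 2

    def test_chaining_definition_holds(self, rng):
        """Each block satisfies the greedy chaining contract and is maximal."""
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 30)[:, None],
                           size=(30, 25)).astype(float)
        # duplicate some rows to create LD
        for j in (3, 9, 15):
            dos[j + 1] = dos[j]
        gm = matrix(dos)
        blocks, _ = ld_blocks(gm, r2_min=0.8, max_gap_bp=500)
        covered = sorted(m for b in blocks for m in b.members)
        assert covered == list(range(30))  # partition
        maf = gm.maf()
        for b in blocks:
            rep_maf = maf[b.representative]
            assert rep_maf == max(maf[m] for m in b.members)
            # members were admitted against the representative at join time;
            # verify contiguity and gap bound
            pos = gm.markers.loc[b.members, "pos"].to_numpy()
            assert np.all(np.diff(pos) <= 500)

    def test_representative_highest_maf(self):
        dos = np.array([[0, 0, 1, 1, 1, 1], [0, 1, 1, 1, 1, 1]], dtype=float)
        # rows correlated (r2 >= 0.8 required) -> craft perfectly equal rows
        dos[1] = dos[0]
        gm = matrix(dos)
        blocks, _ = ld_blocks(gm)
        assert blocks[0].representative == 0  # equal MAF: leftmost wins


class TestKinship:
    def test_duplicate_strains_share_diagonal_value(self):
        base = np.random.default_rng(1).binomial(2, 0.4, size=(200, 5)).astype(float)
        dos = np.column_stack([base, base[:, 0]])  # strain 5 duplicates 0
        K = kinship(matrix(dos)).values
        assert K[0, 5] == pytest.approx(K[0, 0], rel=1e-9)

    def test_independent_markers_approach_identity(self, rng):
        # sample-frequency centering biases off-diagonals by -1/(n-1), so
        # the identity limit needs both many markers and enough strains
        n = 100
        dos = rng.binomial(2, 0.5, size=(20_000, n)).astype(float)
        K = kinship(matrix(dos)).values
        assert np.max(np.abs(K - np.eye(n))) < 0.05

    def test_population_structure_visible(self):
        gm, _, truth = synthio.gen_genotypes(30, n_markers=800,
                                             n_populations=2, fst_like=0.25,
                                             seed=5)
        K = kinship(gm).values
        pops = np.arange(30) % 2
        same = K[np.ix_(pops == 0, pops == 0)]
        cross = K[np.ix_(pops == 0, pops == 1)]
        iu = np.triu_indices(same.shape[0], k=1)
        assert same[iu].mean() > cross.mean()

    def test_invariant_to_marker_permutation(self, rng):
        gm, _, _ = synthio.gen_genotypes(10, n_markers=100, seed=7)
        K1 = kinship(gm).values
        perm = rng.permutation(100)
        K2 = kinship(gm.subset_markers(perm)).values
        np.testing.assert_allclose(K1, K2, atol=1e-10)

    def test_psd_and_symmetric(self):
        gm, _, _ = synthio.gen_genotypes(15, n_markers=50, seed=9)
        K = kinship(gm).values
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10


def seg(chrom, start, end, copy, strain):
    return {"chrom": chrom, "start": start, "end": end,
            "copy_number": copy, "strain": strain}


def brute_force_markers(segments, event, strains, genome_len=10_000):
    """Per-base presence oracle for CNV marker construction."""
    seg_df = classify_cnv(segments)
    if event == "gain":
        seg_df = seg_df[seg_df["event"] == "gain"]
    else:
        seg_df = seg_df[seg_df["event"].isin(["loss", "deletion"])]
    out = []
    n = len(strains)
    for chrom in seg_df["chrom"].unique():
        grid = np.zeros((genome_len, n), dtype=int)
        for _, r in seg_df[seg_df["chrom"] == chrom].iterrows():
            grid[r["start"]:r["end"], strains.index(r["strain"])] = 1
        start = 0
        while start < genome_len:
            end = start
            while end < genome_len and np.array_equal(grid[end], grid[start]):
                end += 1
            vec = grid[start]
            k = vec.sum()
            if 0 < k < n and min(k, n - k) / n >= 0.05:
                out.append((chrom, start, end, tuple(vec)))
            start = end
    return sorted(out)


class TestCNVMarkers:
    STRAINS = ["A", "B", "C"]

    def test_identical_interval_single_marker(self):
        segments = pd.DataFrame([seg("chrI", 100, 200, 4, "A"),
                                 seg("chrI", 100, 200, 4, "B")])
        mk = cnv_markers(segments, "gain", self.STRAINS)
        assert len(mk) == 1
        assert (mk[0].start, mk[0].end) == (100, 200)
        assert mk[0].presence.to_dict() == {"A": 1, "B": 1, "C": 0}

    def test_staircase_overlap(self):
        segments = pd.DataFrame([seg("chrI", 0, 100, 4, "A"),
                                 seg("chrI", 50, 150, 4, "B")])
        mk = cnv_markers(segments, "gain", self.STRAINS)
        spans = {(m.start, m.end): tuple(m.presence) for m in mk}
        assert spans == {(0, 50): (1, 0, 0), (50, 100): (1, 1, 0),
                         (100, 150): (0, 1, 0)}

    def test_staircase_two_strain_universe_drops_constant(self):
        segments = pd.DataFrame([seg("chrI", 0, 100, 4, "A"),
                                 seg("chrI", 50, 150, 4, "B")])
        mk = cnv_markers(segments, "gain", ["A", "B"])
        spans = sorted((m.start, m.end) for m in mk)
        assert spans == [(0, 50), (100, 150)]  # middle is present in all

    def test_gain_and_loss_kept_separate(self):
        segments = pd.DataFrame([seg("chrI", 0, 100, 4, "A"),
                                 seg("chrI", 0, 100, 1, "B")])
        gains = cnv_markers(segments, "gain", self.STRAINS)
        losses = cnv_markers(segments, "loss", self.STRAINS)
        assert len(gains) == 1 and tuple(gains[0].presence) == (1, 0, 0)
        assert len(losses) == 1 and tuple(losses[0].presence) == (0, 1, 0)

    def test_no_events_no_markers(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end",
                                      "copy_number", "strain"])
        assert cnv_markers(empty, "gain", self.STRAINS) == []

    @pytest.mark.parametrize("event", ["gain", "loss"])
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_per_base_brute_force(self, event, trial):
        rng = np.random.default_rng(1000 * (event == "loss") + trial)
        strains = [f"S{i}" for i in range(int(rng.integers(3, 8)))]
        rows = []
        for s in strains:
            for _ in range(rng.integers(0, 5)):
                start = int(rng.integers(0, 9_000))
                end = start + int(rng.integers(50, 1_000))
                copy = int(rng.choice([0, 1, 3, 4]))
                rows.append(seg("chrI", start, min(end, 10_000), copy, s))
        segments = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "copy_number", "strain"])
        mk = cnv_markers(segments, event, strains, min_class_frac=0.05)
        got = sorted((m.chrom, m.start, m.end, tuple(m.presence)) for m in mk)
        expected = brute_force_markers(segments, event, strains)
        assert got == expected


class TestGeneCNVEvents:
    GENES = pd.DataFrame(
        [{"gene_id": "G1", "chrom": "chrI", "start": 1000, "end": 2000,
          "strand": "+", "orf_class": "verified", "tf_superfamily": ""}]
    )

    def test_full_cover_gain_assigned(self):
        segments = pd.DataFrame([seg("chrI", 500, 2500, 4, "A")])
        labels = gene_cnv_events(self.GENES, segments)
        assert labels.loc["G1", "A"] == "gain"

    def test_partial_gain_not_assigned(self):
        segments = pd.DataFrame([seg("chrI", 1500, 2500, 4, "A")])
        labels = gene_cnv_events(self.GENES, segments)
        assert labels.loc["G1", "A"] == "none"

    def test_partial_loss_assigned(self):
        segments = pd.DataFrame([seg("chrI", 1500, 2500, 1, "A")])
        labels = gene_cnv_events(self.GENES, segments)
        assert labels.loc["G1", "A"] == "loss"

    def test_partial_deletion_assigned(self):
        segments = pd.DataFrame([seg("chrI", 1500, 2500, 0, "A")])
        labels = gene_cnv_events(self.GENES, segments)
        assert labels.loc["G1", "A"] == "deletion"

    def test_adjacent_gain_pieces_merge_to_full_cover(self):
        segments = pd.DataFrame([seg("chrI", 500, 1500, 4, "A"),
                                 seg("chrI", 1500, 2500, 4, "A")])
        labels = gene_cnv_events(self.GENES, segments)
        assert labels.loc["G1", "A"] == "gain"

    def test_whole_chromosome_gain_labels_every_gene(self):
        genes = synthio.gen_genes(chrom_lengths={"chrI": 50_000},
                                  genes_per_chrom=8, seed=1)
        segments = pd.DataFrame([seg("chrI", 0, 50_000, 3, "A")])
        labels = gene_cnv_events(genes, segments)
        assert (labels["A"] == "gain").all()

    def test_deletion_dominates_gain(self):
        segments = pd.DataFrame([seg("chrI", 500, 2500, 4, "A"),
                                 seg("chrI", 1500, 1600, 0, "A")])
        labels = gene_cnv_events(self.GENES, segments)
        assert labels.loc["G1", "A"] == "deletion"
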