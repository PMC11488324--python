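import numpy as np
import pandas as pd
import pytest

from mitoscatac import GenotypingConfig
from mitoscatac.genotyping import (
    _CODE,
    aggregate_pseudobulk,
    apply_bulk_filters,
    compute_cell_vaf,
    identify_candidate_variants,
    pileup_allele_counts,
    qpcr_copy_number,
)
from mitoscatac.io import MITO_READ_COLUMNS

from conftest import make_tensor


def naive_pileup(reads, config, genome, barcodes):
    """Independent per-read/per-base oracle for the pileup."""
    idx = {b: i for i, b in enumerate(barcodes)}
    counts = np.zeros((len(barcodes), genome.mito_length + 1, 4, 2), dtype=np.int64)
    for _, r in reads.iterrows():
        if r["mapq"] < config.min_mapq or r["nm"] > config.max_mismatches:
            continue
        if r["barcode"] not in idx:
            continue
        s = 0 if r["strand"] == "+" else 1
        for j, (base, qc) in enumerate(zip(r["seq"], r["qual"])):
            pos = r["pos"] + j
            if pos > genome.mito_length:
                continue
            if ord(qc) - 33 < config.min_base_quality:
                continue
            if base not in "ACGT":
                continue
            counts[idx[r["barcode"]], pos, _CODE[base], s] += 1
    return counts


def random_reads(rng, genome, n, barcodes, read_len=40):
    rows = []
    for _ in range(n):
        pos = int(rng.integers(1, genome.mito_length - read_len + 1))
        seq = "".join(rng.choice(list("ACGT"), size=read_len))
        qual = "".join(chr(33 + int(q)) for q in rng.integers(5, 45, size=read_len))
        rows.append(
            [rng.choice(barcodes), genome.mito_chrom, pos,
             rng.choice(["+", "-"]), int(rng.integers(0, 61)),
             int(rng.integers(0, 5)), seq, qual]
        )
    return pd.DataFrame(rows, columns=MITO_READ_COLUMNS)


class TestPileup:
    def test_packed_path_equals_mrf_path(self, small_dataset, mouse_genome, geno_config):
        """The packed-array fast path and the MRF DataFrame path produce
        byte-identical tensors for the same simulated reads."""
        from mitoscatac import simulate_mito_read_arrays

        packed = simulate_mito_read_arrays(
            small_dataset["truth"], small_dataset["config"], mouse_genome
        )
        t1 = pileup_allele_counts(packed, geno_config, mouse_genome)
        t2 = pileup_allele_counts(small_dataset["reads"], geno_config, mouse_genome,
                                  barcodes=t1.barcodes)
        assert (t1.counts == t2.counts).all()

    def test_matches_naive_oracle_on_random_reads(self, mouse_genome, geno_config):
        rng = np.random.default_rng(11)
        barcodes = np.array(["c1", "c2", "c3"])
        reads = random_reads(rng, mouse_genome, 1_000, barcodes)
        tensor = pileup_allele_counts(reads, geno_config, mouse_genome, barcodes=barcodes)
        oracle = naive_pileup(reads, geno_config, mouse_genome, barcodes)
        assert (tensor.counts == oracle).all()

    def test_low_mapq_read_contributes_nothing(self, mouse_genome, geno_config):
        reads = pd.DataFrame(
            [["c1", mouse_genome.mito_chrom, 100, "+", 29, 0, "ACGT", "IIII"]],
            columns=MITO_READ_COLUMNS,
        )
        tensor = pileup_allele_counts(reads, geno_config, mouse_genome)
        assert tensor.counts.sum() == 0

    def test_excess_mismatches_excluded(self, mouse_genome, geno_config):
        reads = pd.DataFrame(
            [["c1", mouse_genome.mito_chrom, 100, "+", 60, 3, "ACGT", "IIII"]],
            columns=MITO_READ_COLUMNS,
        )
        tensor = pileup_allele_counts(reads, geno_config, mouse_genome)
        assert tensor.counts.sum() == 0

    def test_low_base_quality_masks_single_base(self, mouse_genome, geno_config):
        qual = "I" + chr(33 + 5) + "II"  # second base Q5 < 20
        reads = pd.DataFrame(
            [["c1", mouse_genome.mito_chrom, 100, "+", 60, 0, "ACGT", qual]],
            columns=MITO_READ_COLUMNS,
        )
        tensor = pileup_allele_counts(reads, geno_config, mouse_genome)
        assert tensor.counts.sum() == 3
        assert tensor.counts[0, 101].sum() == 0

    def test_overhanging_read_clipped_with_warning(self, mouse_genome, geno_config):
        L = mouse_genome.mito_length
        reads = pd.DataFrame(
            [["c1", mouse_genome.mito_chrom, L - 1, "+", 60, 0, "ACGT", "IIII"]],
            columns=MITO_READ_COLUMNS,
        )
        with pytest.warns(UserWarning, match="clip"):
            tensor = pileup_allele_counts(reads, geno_config, mouse_genome)
        assert tensor.counts.sum() == 2  # only positions L-1 and L


class TestPseudobulk:
    def test_single_cell_equals_bulk(self, mouse_genome):
        t = make_tensor({(100, "A", "+"): [7]}, ["c1"], mouse_genome)
        bulk = aggregate_pseudobulk(t)
        assert (bulk == t.counts[0]).all()

    def test_two_cells_sum_elementwise(self, mouse_genome):
        t = make_tensor({(100, "A", "+"): [3, 4], (200, "C", "-"): [1, 2]},
                        ["c1", "c2"], mouse_genome)
        bulk = aggregate_pseudobulk(t)
        assert bulk[100, 0, 0] == 7
        assert bulk[200, 1, 1] == 3

    def test_total_count_conserved(self, mouse_genome):
        rng = np.random.default_rng(3)
        t = make_tensor(
            {(int(p), a, s): rng.integers(0, 5, size=4)
             for p in rng.integers(1, 16_000, 20) for a in "ACGT" for s in "+-"},
            ["a", "b", "c", "d"], mouse_genome,
        )
        assert aggregate_pseudobulk(t).sum() == t.counts.sum()


class TestCellVaf:
    def test_basic_ratio(self, mouse_genome):
        t = make_tensor({(50, "T", "+"): [3], (50, "A", "+"): [7]}, ["c1"], mouse_genome)
        ref = mouse_genome.mito_base(50)
        # force a clean ref/alt layout regardless of reference base
        t2 = make_tensor({(50, ref, "+"): [7], (50, "T" if ref != "T" else "G", "+"): [3]},
                         ["c1"], mouse_genome)
        alt = "T" if ref != "T" else "G"
        assert compute_cell_vaf(t2, 50, ref, alt)["c1"] == pytest.approx(0.30)

    def test_low_coverage_is_missing_not_zero(self, mouse_genome):
        ref = mouse_genome.mito_base(60)
        alt = "A" if ref != "A" else "C"
        t = make_tensor({(60, ref, "+"): [6], (60, alt, "+"): [3]}, ["c1"], mouse_genome)
        assert np.isnan(compute_cell_vaf(t, 60, ref, alt)["c1"])  # coverage 9 < 10

    def test_zero_alt_is_zero(self, mouse_genome):
        ref = mouse_genome.mito_base(70)
        alt = "A" if ref != "A" else "C"
        t = make_tensor({(70, ref, "+"): [15]}, ["c1"], mouse_genome)
        assert compute_cell_vaf(t, 70, ref, alt)["c1"] == 0.0

    def test_pseudobulk_vaf_is_depth_weighted_cell_mean(self, mouse_genome):
        # with no low-coverage masking, bulk VAF == depth-weighted mean VAF
        rng = np.random.default_rng(5)
        cfg = GenotypingConfig(low_coverage_threshold=0)
        ref = mouse_genome.mito_base(90)
        alt = "A" if ref != "A" else "C"
        alt_n = rng.integers(0, 20, size=6)
        ref_n = rng.integers(1, 30, size=6)
        t = make_tensor({(90, ref, "+"): ref_n, (90, alt, "+"): alt_n},
                        [f"c{i}" for i in range(6)], mouse_genome, cfg)
        vaf = compute_cell_vaf(t, 90, ref, alt)
        depth = alt_n + ref_n
        weighted = (vaf * depth).sum() / depth.sum()
        bulk_vaf = alt_n.sum() / depth.sum()
        assert weighted == pytest.approx(bulk_vaf)


class TestCandidateScreen:
    def test_homoplasmic_constant_vaf_not_informative(self, mouse_genome):
        cfg = GenotypingConfig()
        ref = mouse_genome.mito_base(500)
        alt = "A" if ref != "A" else "C"
        # VAF exactly 1 in every cell -> VMR 0 -> excluded
        t = make_tensor({(500, alt, "+"): [20] * 30, (500, alt, "-"): [20] * 30},
                        [f"c{i}" for i in range(30)], mouse_genome, cfg)
        cand = identify_candidate_variants(t, cfg, mouse_genome)
        row = cand[(cand["pos"] == 500) & (cand["alt"] == alt)]
        assert len(row) == 1
        assert row.iloc[0]["vmr"] == pytest.approx(0.0, abs=1e-12)
        assert not row.iloc[0]["candidate"]

    def test_heteroplasmic_subpopulation_detected(self, mouse_genome):
        rng = np.random.default_rng(8)
        cfg = GenotypingConfig()
        ref = mouse_genome.mito_base(700)
        alt = "A" if ref != "A" else "C"
        n = 100
        carrier = np.zeros(n); carrier[:20] = 0.5  # 20% of cells at VAF 0.5
        alt_plus = rng.binomial(20, carrier)
        alt_minus = rng.binomial(20, carrier)
        ref_plus = 20 - alt_plus + rng.integers(5, 10, n)
        ref_minus = 20 - alt_minus + rng.integers(5, 10, n)
        t = make_tensor(
            {(700, alt, "+"): alt_plus, (700, alt, "-"): alt_minus,
             (700, ref, "+"): ref_plus, (700, ref, "-"): ref_minus},
            [f"c{i}" for i in range(n)], mouse_genome, cfg,
        )
        cand = identify_candidate_variants(t, cfg, mouse_genome)
        row = cand[(cand["pos"] == 700) & (cand["alt"] == alt)].iloc[0]
        assert row["candidate"]
        assert row["n_cells"] >= 18

    def test_ref_only_position_yields_no_candidate(self, mouse_genome):
        cfg = GenotypingConfig()
        ref = mouse_genome.mito_base(900)
        t = make_tensor({(900, ref, "+"): [30] * 10}, [f"c{i}" for i in range(10)],
                        mouse_genome, cfg)
        cand = identify_candidate_variants(t, cfg, mouse_genome)
        assert (cand["pos"] != 900).all()


def brute_force_flags(row, bulk, config, species_blacklist):
    """Independent plain-python re-derivation of the cascade flags."""
    pos, ref, alt = int(row["pos"]), row["ref"], row["alt"]
    bulk_alt = int(bulk[pos, _CODE[alt], :].sum())
    bulk_ref = int(bulk[pos, _CODE[ref], :].sum())
    if min(bulk_alt, bulk_ref) == 0:
        ratio_ok = True
    else:
        ratio_ok = (max(bulk_alt, bulk_ref) / min(bulk_alt, bulk_ref)) >= config.allele_depth_ratio
    if not config.allele_ratio_enabled:
        ratio_ok = True
    pf = row["plus_strand_fraction"]
    strand_ok = max(pf, 1 - pf) <= config.strand_support_max
    depth_ok = int(bulk[pos].sum()) >= config.min_bulk_depth
    cells_ok = row["n_cells"] >= config.min_cells
    black_ok = pos not in species_blacklist
    return {
        "pass_allele_ratio": ratio_ok, "pass_strand_bias": strand_ok,
        "pass_bulk_depth": depth_ok, "pass_min_cells": cells_ok,
        "pass_blacklist": black_ok,
        "pass_all": ratio_ok and strand_ok and depth_ok and cells_ok and black_ok,
    }


class TestFilterCascade:
    def _random_candidates(self, genome, n=1_000, seed=17):
        rng = np.random.default_rng(seed)
        pos = rng.integers(1, genome.mito_length, size=n)
        refs = [genome.mito_base(int(p)) for p in pos]
        alts = [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
        counts = {}
        cand = pd.DataFrame({
            "pos": pos, "ref": refs, "alt": alts,
            "n_cells": rng.integers(0, 200, size=n),
            "plus_strand_fraction": rng.random(n),
        })
        barcodes = ["b1", "b2"]
        tensor_counts = np.zeros((2, genome.mito_length + 1, 4, 2), dtype=np.int64)
        for i, (p, r, a) in enumerate(zip(pos, refs, alts)):
            tensor_counts[:, p, _CODE[r], 0] += rng.integers(0, 400, size=2)
            tensor_counts[:, p, _CODE[a], 0] += rng.integers(0, 120, size=2)
            tensor_counts[:, p, _CODE[a], 1] += rng.integers(0, 120, size=2)
        from mitoscatac.genotyping import AlleleCountTensor

        t = AlleleCountTensor(np.array(barcodes), tensor_counts,
                              genome.mito_length, GenotypingConfig())
        return cand, t

    def test_matches_brute_force_oracle(self, mouse_genome):
        cfg = GenotypingConfig()
        cand, tensor = self._random_candidates(mouse_genome)
        out = apply_bulk_filters(cand, tensor, cfg, mouse_genome)
        bulk = aggregate_pseudobulk(tensor)
        black = set(cfg.blacklist.get(mouse_genome.species, ()))
        for i, row in out.iterrows():
            expect = brute_force_flags(row, bulk, cfg, black)
            for key, val in expect.items():
                assert row[key] == val, f"{key} mismatch at row {i} (pos {row['pos']})"

    def test_monotone_under_threshold_tightening(self, mouse_genome):
        cand, tensor = self._random_candidates(mouse_genome, seed=23)
        base = apply_bulk_filters(cand, tensor, GenotypingConfig(), mouse_genome)
        tight = apply_bulk_filters(
            cand, tensor,
            GenotypingConfig(min_bulk_depth=400, min_cells=80,
                             strand_support_max=0.8, allele_depth_ratio=8),
            mouse_genome,
        )
        assert not (tight["pass_all"] & ~base["pass_all"]).any()

    def test_bulk_depth_boundary(self, mouse_genome):
        ref = mouse_genome.mito_base(1000)
        alt = "A" if ref != "A" else "C"
        t = make_tensor({(1000, ref, "+"): [200], (1000, alt, "+"): [25], (1000, alt, "-"): [24]},
                        ["c1"], mouse_genome)
        cand = pd.DataFrame({"pos": [1000], "ref": [ref], "alt": [alt],
                             "n_cells": [60], "plus_strand_fraction": [0.51]})
        out = apply_bulk_filters(cand, t, GenotypingConfig(), mouse_genome)
        assert not out.iloc[0]["pass_bulk_depth"]  # depth 249 < 250
        assert not out.iloc[0]["pass_all"]

    def test_min_cells_boundary(self, mouse_genome):
        ref = mouse_genome.mito_base(1100)
        alt = "A" if ref != "A" else "C"
        t = make_tensor({(1100, ref, "+"): [300], (1100, alt, "+"): [30], (1100, alt, "-"): [30]},
                        ["c1"], mouse_genome)
        cand = pd.DataFrame({"pos": [1100], "ref": [ref], "alt": [alt],
                             "n_cells": [49], "plus_strand_fraction": [0.5]})
        out = apply_bulk_filters(cand, t, GenotypingConfig(), mouse_genome)
        assert not out.iloc[0]["pass_min_cells"]

    def test_human_polyc_blacklist(self, human_genome):
        t = make_tensor({(310, "T", "+"): [300], (310, "C", "+"): [30], (310, "C", "-"): [30]},
                        ["c1"], human_genome)
        cand = pd.DataFrame({"pos": [310], "ref": ["T"], "alt": ["C"],
                             "n_cells": [200], "plus_strand_fraction": [0.5]})
        out = apply_bulk_filters(cand, t, GenotypingConfig(), human_genome)
        assert not out.iloc[0]["pass_blacklist"]
        # the same site passes for mouse, where no blacklist applies
        from mitoscatac import mouse_mito_genome

        mg = mouse_mito_genome()
        ref = mg.mito_base(310)
        alt = "C" if ref != "C" else "T"
        t2 = make_tensor({(310, ref, "+"): [300], (310, alt, "+"): [30], (310, alt, "-"): [30]},
                         ["c1"], mg)
        cand2 = cand.assign(ref=ref, alt=alt)
        out2 = apply_bulk_filters(cand2, t2, GenotypingConfig(), mg)
        assert out2.iloc[0]["pass_blacklist"]


class TestQpcr:
    @pytest.mark.parametrize("ct_nu,ct_mt,copies", [(20, 20, 2.0), (30, 20, 2048.0), (18, 20, 0.5)])
    def test_formula(self, ct_nu, ct_mt, copies):
        assert qpcr_copy_number(ct_nu, ct_mt) == copies

    def test_delta_antisymmetric(self):
        assert qpcr_copy_number(25, 20) * qpcr_copy_number(20, 25) == pytest.approx(4.0)
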