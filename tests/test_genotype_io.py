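import numpy as np
import pytest

from popgenpipe.genotypes import MISSING, GenotypeError, GenotypeMatrix
from popgenpipe.genotype_io import (
    PlinkFormatError,
    QCConfig,
    apply_qc,
    compute_uar,
    intersect_panels,
    prune_related,
    read_plink,
    write_plink,
)
from conftest import make_panel


# ---------------------------------------------------------------------------
# read/write
# ---------------------------------------------------------------------------


class TestPlinkIO:
    def test_ped_fixture_round_trip(self, tiny_panel, tmp_path):
        # hand-written 2-sample, 3-SNP fixture
        (tmp_path / "t.map").write_text(
            "1\ts0\t0\t100\n1\ts1\t0\t200\n2\ts2\t0\t150\n"
        )
        (tmp_path / "t.ped").write_text(
            "FAM1 ind0 0 0 0 -9 A A A G G G\n"
            "FAM2 ind1 0 0 0 -9 G G G A A A\n"
        )
        g = read_plink(tmp_path / "t", "ped")
        assert g.n_samples == 2 and g.n_snps == 3
        assert list(g.populations) == ["FAM1", "FAM2"]
        assert g.equals(tiny_panel, harmonize_alleles=True)

    @pytest.mark.parametrize("fmt", ["ped", "bed"])
    def test_round_trip_random_panel(self, fmt, tmp_path, sim_two_pop):
        g, _ = sim_two_pop
        write_plink(g, tmp_path / "rt", format=fmt)
        g2 = read_plink(tmp_path / "rt", fmt)
        assert g2.equals(g, harmonize_alleles=True)

    def test_bed_exact_round_trip_preserves_codes(self, tmp_path, sim_two_pop):
        # BIM carries both alleles, so BED round-trips dosage codes exactly
        g, _ = sim_two_pop
        write_plink(g, tmp_path / "x", format="bed")
        g2 = read_plink(tmp_path / "x", "bed")
        assert np.array_equal(g.dosage, g2.dosage)
        assert g.equals(g2)

    def test_bed_magic_checked(self, tmp_path, tiny_panel):
        write_plink(tiny_panel, tmp_path / "m", format="bed")
        raw = (tmp_path / "m.bed").read_bytes()
        (tmp_path / "m.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink(tmp_path / "m", "bed")

    def test_bed_dimension_mismatch(self, tmp_path):
        g = make_panel([[0, 1], [1, 1], [2, 0], [0, 0]])  # 4 samples: 1 byte/SNP
        write_plink(g, tmp_path / "d", format="bed")
        with open(tmp_path / "d.fam", "a") as fh:
            fh.write("X extra 0 0 0 -9\n")
        with pytest.raises(PlinkFormatError, match="does not match"):
            read_plink(tmp_path / "d", "bed")

    def test_ped_bad_allele_count_names_locus(self, tmp_path):
        (tmp_path / "b.map").write_text("1\tsnpX\t0\t100\n")
        (tmp_path / "b.ped").write_text("F i0 0 0 0 -9 A C\nF i1 0 0 0 -9 G G\nF i2 0 0 0 -9 T T\n")
        with pytest.raises(PlinkFormatError, match="snpX"):
            read_plink(tmp_path / "b", "ped")

    def test_missing_genotypes_round_trip(self, tmp_path):
        g = make_panel([[MISSING, 1], [2, MISSING]])
        write_plink(g, tmp_path / "mi", format="ped")
        g2 = read_plink(tmp_path / "mi", "ped")
        assert np.array_equal(g2.dosage == MISSING, g.dosage == MISSING)


# ---------------------------------------------------------------------------
# intersect_panels
# ---------------------------------------------------------------------------


class TestIntersect:
    def _two_panels(self):
        a = make_panel(
            [[0, 1, 2], [1, 1, 0]],
            ids=["s1", "s2", "s3"],
            pos=[10, 20, 30],
        )
        b = make_panel(
            [[2, 0, 1], [0, 1, 2]],
            ids=["s2", "s3", "s4"],
            pos=[20, 30, 40],
        )
        b.sample_ids = np.array(["x0", "x1"], dtype=object)
        return a, b

    def test_snp_set_intersection(self):
        a, b = self._two_panels()
        out = intersect_panels(a, b)
        assert sorted(out.snps["id"]) == ["s2", "s3"]
        assert out.n_samples == 4

    def test_allele_swap_flips_dosage(self):
        a = make_panel([[0]], alleles=[("A", "G")])
        b = make_panel([[2]], alleles=[("G", "A")])
        b.sample_ids = np.array(["other"], dtype=object)
        out = intersect_panels(a, b)
        # dosage 2 of swapped-coding panel counts the other allele -> 0
        assert out.dosage[1, 0] == 0

    def test_self_intersection_identity(self, sim_two_pop):
        g, _ = sim_two_pop
        renamed = GenotypeMatrix(
            np.array([f"copy_{s}" for s in g.sample_ids], dtype=object),
            g.populations.copy(),
            g.snps.copy(),
            g.dosage.copy(),
        )
        out = intersect_panels(g, renamed)
        assert out.n_snps == g.n_snps
        assert out.n_samples == 2 * g.n_samples

    def test_symmetry_of_snp_content(self):
        a, b = self._two_panels()
        ab = intersect_panels(a, b)
        ba = intersect_panels(b, a)
        assert set(ab.snps["id"]) == set(ba.snps["id"])

    def test_duplicate_sample_ids_error(self):
        a, _ = self._two_panels()
        with pytest.raises(GenotypeError, match="duplicate"):
            intersect_panels(a, a)

    def test_zero_overlap_error(self):
        a = make_panel([[0]], ids=["only_a"])
        b = make_panel([[0]], ids=["only_b"])
        b.sample_ids = np.array(["z"], dtype=object)
        with pytest.raises(GenotypeError, match="overlap"):
            intersect_panels(a, b)

    def test_irreconcilable_alleles_dropped(self):
        a = make_panel([[0, 0]], ids=["s1", "s2"], alleles=[("A", "G"), ("A", "G")])
        b = make_panel([[0, 0]], ids=["s1", "s2"], alleles=[("A", "G"), ("C", "T")])
        b.sample_ids = np.array(["z"], dtype=object)
        out = intersect_panels(a, b)
        assert list(out.snps["id"]) == ["s1"]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


class TestQC:
    def test_low_call_rate_snp_removed(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(10, 100)).astype(np.int8)
        dosage[:, 5] = np.where(np.arange(10) < 2, MISSING, 1)  # 20% missing
        # keep other columns polymorphic and fully called
        g = make_panel(dosage, pos=list(range(1, 101)), ids=[f"s{j}" for j in range(100)])
        g2, rep = apply_qc(g, QCConfig(snp_call_rate_min=0.90, maf_min=0.0, sample_missing_max=0.5))
        assert "s5" not in set(g2.snps["id"])
        assert rep.snps_removed_call_rate == 1

    def test_monomorphic_snp_removed(self):
        dosage = np.array([[0, 1], [0, 1], [0, 2]], dtype=np.int8)
        g = make_panel(dosage)
        g2, rep = apply_qc(g, QCConfig(maf_min=0.05))
        assert list(g2.snps["id"]) == ["s1"]
        assert rep.snps_removed_maf == 1

    def test_filter_order_and_counts(self):
        # sample 0 heavily missing; chrom 27 SNP; one rare SNP
        dosage = np.full((5, 4), 1, dtype=np.int8)
        dosage[0, :] = MISSING
        dosage[:, 3] = [0, 0, 0, 0, 1]  # MAF 0.1 after sample 0 dropped? -> 1/8
        g = make_panel(dosage, chrom=[1, 1, 27, 1], pos=[1, 2, 3, 4])
        g2, rep = apply_qc(
            g, QCConfig(sample_missing_max=0.5, maf_min=0.2, snp_call_rate_min=0.9)
        )
        assert rep.samples_removed_missing == 1
        assert rep.snps_removed_nonautosomal == 1
        assert rep.snps_removed_maf == 1
        assert rep.n_samples_out == 4 and rep.n_snps_out == 2

    def test_brute_force_refilter_oracle(self, sim_two_pop):
        g, _ = sim_two_pop
        cfg = QCConfig(snp_call_rate_min=0.95, maf_min=0.1, sample_missing_max=0.05)
        g2, _ = apply_qc(g, cfg)
        # independent recount: which SNPs should survive, scalar loop
        keep_samples = [
            i
            for i in range(g.n_samples)
            if np.mean(g.dosage[i] == MISSING) <= cfg.sample_missing_max
        ]
        survivors = []
        for j in range(g.n_snps):
            col = g.dosage[keep_samples, j]
            calls = col[col != MISSING]
            if len(calls) / len(keep_samples) < cfg.snp_call_rate_min:
                continue
            p = calls.sum() / (2 * len(calls))
            if min(p, 1 - p) < cfg.maf_min:
                continue
            survivors.append(g.snps["id"].iloc[j])
        assert list(g2.snps["id"]) == survivors

    def test_qc_idempotent(self, sim_two_pop):
        g, _ = sim_two_pop
        cfg = QCConfig()
        g1, _ = apply_qc(g, cfg)
        g2, rep2 = apply_qc(g1, cfg)
        assert g1.equals(g2)
        assert rep2.snps_removed_call_rate == 0 and rep2.snps_removed_maf == 0

    def test_empty_after_qc_error(self):
        g = make_panel([[0, 0], [0, 0]])
        with pytest.raises(GenotypeError, match="empty after QC"):
            apply_qc(g, QCConfig(maf_min=0.05))


# ---------------------------------------------------------------------------
# UAR + pruning
# ---------------------------------------------------------------------------


class TestUAR:
    def test_hand_evaluated_entry(self):
        # p = 0.5 overall; pair of dosage-2 individuals: (2-1)(2-1)/(2*.5*.5) = 2
        g = make_panel([[2], [2], [0], [0]])
        a = compute_uar(g)
        assert a.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_duplicated_individual_matches_diagonal(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        dosage[5] = dosage[0]  # duplicate
        g = make_panel(dosage, pos=list(range(1, 51)), ids=[f"s{j}" for j in range(50)])
        a = compute_uar(g)
        # same-genotype pair: off-diagonal equals cross form, diagonal uses
        # the same-individual form; they agree in expectation, not exactly,
        # so check the duplicate pair is the largest off-diagonal
        off = a.values.copy()
        np.fill_diagonal(off, -np.inf)
        assert np.unravel_index(np.argmax(off), off.shape) in [(0, 5), (5, 0)]

    def test_unrelated_panel_moments(self):
        # HWE genotypes, all individuals unrelated: E[offdiag]=0, E[diag]=1
        rng = np.random.default_rng(2)
        n, m = 40, 4000
        p = rng.uniform(0.1, 0.9, size=m)
        dosage = (rng.random((n, m)) < p).astype(np.int8) + (
            rng.random((n, m)) < p
        ).astype(np.int8)
        g = make_panel(dosage, pos=list(range(1, m + 1)), ids=[f"s{j}" for j in range(m)])
        a = compute_uar(g)
        off = a.values[np.triu_indices(n, 1)]
        # with sample-estimated frequencies rows sum to ~0, so the exact
        # expectation of the off-diagonal mean is -1/(n-1), which -> 0 in n
        assert off.mean() == pytest.approx(-1.0 / (n - 1), abs=3e-3)
        assert abs(off.mean()) < 0.05
        d = np.diag(a.values)
        se_d = d.std() / np.sqrt(n)
        assert abs(d.mean() - 1.0) < 3 * se_d + 1e-2

    def test_monomorphic_rejected(self):
        g = make_panel([[2, 0], [2, 1]])
        with pytest.raises(GenotypeError, match="QC"):
            compute_uar(g)

    def test_invariant_to_snp_and_sample_order(self, sim_panel_qcd):
        g = sim_panel_qcd.take_samples(range(10)).take_snps(range(200))
        g, _ = apply_qc(g, QCConfig(maf_min=0.01))  # drop subset-monomorphic loci
        a = compute_uar(g)
        rng = np.random.default_rng(3)
        sperm = rng.permutation(g.n_samples)
        jperm = rng.permutation(g.n_snps)
        g2 = g.take_samples(sperm).take_snps(jperm)
        a2 = compute_uar(g2)
        assert np.allclose(a2.values, a.values[np.ix_(sperm, sperm)], atol=1e-10)


class TestPruneRelated:
    def test_no_pairs_above_threshold_identity(self, sim_panel_qcd):
        g = sim_panel_qcd.take_samples(range(8))
        g, _ = apply_qc(g, QCConfig(maf_min=0.01))
        a = compute_uar(g)
        a.values[np.triu_indices(8, 1)] = 0.1  # force below threshold
        a.values.T[np.triu_indices(8, 1)] = 0.1
        out = prune_related(g, a)
        assert list(out.sample_ids) == list(g.sample_ids)

    def test_duplicate_pair_one_removed(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(8, 300)).astype(np.int8)
        dosage[1] = dosage[0]
        g = make_panel(dosage, pos=list(range(1, 301)), ids=[f"s{j}" for j in range(300)])
        a = compute_uar(g)
        out = prune_related(g, a, 0.35)
        kept = set(out.sample_ids)
        assert len({"ind0", "ind1"} & kept) == 1
        assert out.n_samples == 7

    def test_exhaustive_post_check(self):
        # half-sib family embedded in an unrelated panel
        from popgenpipe import synthetic_data as sd

        cfg = sd.SimConfig(
            n_chromosomes=10,
            snps_per_chromosome=300,
            chromosome_length_bp=60_000_000,
            populations=[sd.PopulationSpec("P", 20, [(0, 200)])],
            pedigree_loops=[sd.PedigreeLoop("full-sib", 3, "P", include_parents=True)],
            seed=11,
        )
        g, _ = sd.simulate_panel(cfg)
        from popgenpipe.genotype_io import apply_qc

        g, _ = apply_qc(g, QCConfig())
        a = compute_uar(g)
        out = prune_related(g, a, 0.35)
        assert out.n_samples < g.n_samples  # the sib loops must trigger pruning
        # exhaustive pair scan over the retained rows of the original matrix
        kept = [list(g.sample_ids).index(s) for s in out.sample_ids]
        sub = a.values[np.ix_(kept, kept)]
        iu = np.triu_indices(len(kept), 1)
        assert (sub[iu] <= 0.35).all()
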