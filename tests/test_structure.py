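import numpy as np
import pytest

from popgenpipe.genotypes import GenotypeError, MISSING
from popgenpipe.structure import (
    FstMatrix,
    classical_mds,
    export_external,
    fst_matrix,
    ibs_distance_matrix,
    pairwise_fst,
    pca,
    read_nexus,
    read_phylip,
)
from popgenpipe import synthetic_data as sd
from conftest import make_panel
from helpers_oracles import ibs_distance_brute, wc_theta_brute


class TestPairwiseFst:
    def test_fixed_difference_is_one(self):
        g = make_panel([[0, 0], [0, 0], [2, 2], [2, 2]], pops=["P1", "P1", "P2", "P2"])
        assert pairwise_fst(g, "P1", "P2") == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_components(self):
        rng = np.random.default_rng(0)
        da = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
        db = rng.integers(0, 3, size=(9, 10)).astype(np.int8)
        db[2, 4] = MISSING
        g = make_panel(np.vstack([da, db]), pops=["P1"] * 6 + ["P2"] * 9,
                       pos=list(range(1, 11)), ids=[f"s{j}" for j in range(10)])
        theta = pairwise_fst(g, "P1", "P2")
        assert theta == pytest.approx(wc_theta_brute(da, db), abs=1e-12)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(1)
        thetas = []
        for rep in range(20):
            p = rng.uniform(0.1, 0.9, size=400)
            dosage = (rng.random((40, 400)) < p).astype(int) + (
                rng.random((40, 400)) < p
            ).astype(int)
            g = make_panel(dosage, pops=["P1"] * 20 + ["P2"] * 20,
                           pos=list(range(1, 401)), ids=[f"s{j}" for j in range(400)])
            thetas.append(pairwise_fst(g, "P1", "P2"))
        se = np.std(thetas) / np.sqrt(len(thetas))
        assert abs(np.mean(thetas)) <= 3 * se

    def test_allele_swap_and_pop_order_invariance(self, sim_two_pop):
        g, _ = sim_two_pop
        t1 = pairwise_fst(g, "A", "B")
        t2 = pairwise_fst(g, "B", "A")
        assert t1 == pytest.approx(t2, abs=1e-12)
        flipped = g.take_snps(range(g.n_snps))
        for j in range(0, g.n_snps, 2):
            col = flipped.dosage[:, j]
            called = col != MISSING
            flipped.dosage[called, j] = 2 - col[called]
        assert pairwise_fst(flipped, "A", "B") == pytest.approx(t1, abs=1e-12)

    def test_monomorphic_only_error(self):
        g = make_panel([[0], [0], [0], [0]], pops=["P1", "P1", "P2", "P2"])
        with pytest.raises(GenotypeError):
            pairwise_fst(g, "P1", "P2")


class TestFstMatrix:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(2)
        block = rng.integers(0, 3, size=(10, 100)).astype(np.int8)
        g = make_panel(np.vstack([block] * 3), pops=["P1"] * 10 + ["P2"] * 10 + ["P3"] * 10,
                       pos=list(range(1, 101)), ids=[f"s{j}" for j in range(100)])
        m = fst_matrix(g)
        off = m.values[np.triu_indices(3, 1)]
        # copied samples have zero between-group variance while the estimator
        # subtracts its sampling expectation, so theta ~ 0 with O(1/n) bias
        assert (np.abs(off) < 2.0 / 10).all()
        assert np.allclose(off, off[0], atol=1e-12)  # all pairs identical
        assert np.allclose(np.diag(m.values), 0.0)

    def test_drift_oracle_star_divergence(self):
        # per-branch fixation F = 1 - (1 - 1/(2N))^t; theta_hat ~ mean branch F
        reps = 4
        thetas, expects = [], []
        for rep in range(reps):
            cfg = sd.SimConfig(
                n_chromosomes=10,
                snps_per_chromosome=200,
                chromosome_length_bp=50_000_000,
                populations=[
                    sd.PopulationSpec("A", 40, [(10, 100)]),
                    sd.PopulationSpec("B", 40, [(10, 100)]),
                ],
                seed=100 + rep,
            )
            g, truth = sd.simulate_panel(cfg)
            thetas.append(pairwise_fst(g, "A", "B"))
            expects.append(truth.expected_pairwise_fst["A|B"])
        err = np.array(thetas) - np.array(expects)
        se = err.std(ddof=1) / np.sqrt(reps)
        assert abs(err.mean()) < max(3 * se, 0.01)

    def test_monotone_in_divergence_time(self):
        thetas = []
        for t in (2, 8, 24):
            cfg = sd.SimConfig(
                n_chromosomes=8,
                snps_per_chromosome=150,
                chromosome_length_bp=50_000_000,
                populations=[
                    sd.PopulationSpec("A", 30, [(t, 100)]),
                    sd.PopulationSpec("B", 30, [(t, 100)]),
                ],
                seed=7,
            )
            g, _ = sd.simulate_panel(cfg)
            thetas.append(pairwise_fst(g, "A", "B"))
        assert thetas == sorted(thetas)

    def test_phylip_round_trip(self, tmp_path):
        m = FstMatrix(["P1", "P2", "P3"], np.array([[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]]))
        export_external(m, "phylip", tmp_path / "f")
        m2 = read_phylip(tmp_path / "f.phy")
        assert m2.populations == ["P1", "P2", "P3"]
        assert np.allclose(m2.values, m.values, atol=1e-6)

    def test_nexus_round_trip(self, tmp_path):
        m = FstMatrix(["north pop", "south"], np.array([[0, 0.05], [0.05, 0]]))
        export_external(m, "nexus", tmp_path / "f")
        m2 = read_nexus(tmp_path / "f.nex")
        assert np.allclose(m2.values, m.values, atol=1e-6)
        assert m2.populations == ["north_pop", "south"]  # whitespace sanitized


class TestIbs:
    def test_identical_zero(self):
        g = make_panel([[0, 1, 2], [0, 1, 2]])
        d = ibs_distance_matrix(g)
        assert d.iloc[0, 1] == 0.0

    def test_opposite_one(self):
        g = make_panel([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance_matrix(g).iloc[0, 1] == 1.0

    def test_brute_force_recount(self):
        rng = np.random.default_rng(3)
        dosage = rng.choice([0, 1, 2, MISSING], size=(6, 80), p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        # ensure every pair has comparable loci
        dosage[:, 0] = 1
        g = make_panel(dosage, pos=list(range(1, 81)), ids=[f"s{j}" for j in range(80)])
        d = ibs_distance_matrix(g)
        for i in range(6):
            for j in range(i + 1, 6):
                assert d.iloc[i, j] == pytest.approx(
                    ibs_distance_brute(dosage[i], dosage[j]), abs=1e-12
                )

    def test_no_comparable_loci_error(self):
        dosage = np.array([[0, MISSING], [MISSING, 0]], dtype=np.int8)
        g = make_panel(dosage)
        with pytest.raises(GenotypeError, match="ind"):
            ibs_distance_matrix(g)


class TestMds:
    def test_collinear_points_recovered(self):
        # three collinear points spaced 1 and 2 apart
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        ord_ = classical_mds(d, k=1)
        x = ord_.coordinates[:, 0]
        got = np.abs(np.subtract.outer(x, x))
        assert np.allclose(got, d, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        g = make_panel([[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2]])
        d = ibs_distance_matrix(g)
        ord_ = classical_mds(d, k=2)
        assert np.allclose(ord_.coordinates[0], ord_.coordinates[1], atol=1e-9)

    def test_full_rank_euclidean_exact(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ord_ = classical_mds(d, k=5)  # reduced to positive-eigenvalue count
        emb = ord_.coordinates
        d2 = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d2, d, atol=1e-9)

    def test_explained_fractions_sorted(self, sim_panel_qcd):
        d = ibs_distance_matrix(sim_panel_qcd)
        ord_ = classical_mds(d, k=3)
        ef = ord_.explained_fraction
        assert (np.diff(ef) <= 1e-12).all()
        assert ((ef >= 0) & (ef <= 1)).all()

    def test_separates_diverged_populations(self, sim_panel_qcd):
        g = sim_panel_qcd
        d = ibs_distance_matrix(g)
        ord_ = classical_mds(d, k=2)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(ord_.coordinates[:, :1], g.populations) > 0.5


class TestPca:
    def test_separates_populations_axis1(self, sim_panel_qcd):
        g = sim_panel_qcd
        ord_ = pca(g, k=2)
        x = ord_.coordinates[:, 0]
        a = x[g.populations == "A"]
        b = x[g.populations == "B"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_duplicated_loci_scale_invariance(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        g1 = make_panel(dosage, pos=list(range(1, 41)), ids=[f"s{j}" for j in range(40)])
        g2 = make_panel(
            np.hstack([dosage, dosage]),
            pos=list(range(1, 81)),
            ids=[f"s{j}" for j in range(80)],
        )
        o1, o2 = pca(g1, k=3), pca(g2, k=3)
        assert np.allclose(o1.explained_fraction, o2.explained_fraction, atol=1e-9)
        assert np.allclose(np.abs(o1.coordinates) * np.sqrt(2), np.abs(o2.coordinates), atol=1e-6)

    def test_explained_sums_below_one(self, sim_panel_qcd):
        ord_ = pca(sim_panel_qcd, k=5)
        assert ord_.explained_fraction.sum() <= 1.0 + 1e-12


class TestExports:
    def test_phylip_five_populations(self, tmp_path):
        rng = np.random.default_rng(6)
        v = rng.uniform(0.01, 0.2, size=(5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = FstMatrix([f"POP{i}" for i in range(5)], v)
        (out,) = export_external(m, "phylip", tmp_path / "five")
        m2 = read_phylip(out)
        assert len(m2.populations) == 5
        assert np.allclose(m2.values, v, atol=1e-6)

    def test_treemix_counts_hand_tally(self, tmp_path):
        import gzip

        g = make_panel(
            [[0, 1], [1, 2], [2, 2], [0, MISSING]],
            pops=["P1", "P1", "P2", "P2"],
        )
        (out,) = export_external(g, "treemix_freq", tmp_path / "tm")
        lines = gzip.open(out, "rt").read().strip().splitlines()
        assert lines[0].split() == ["P1", "P2"]
        # locus 1: P1 dosages (0,1): b=1 of 4; P2 (2,0): b=2 of 4
        assert lines[1].split() == ["3,1", "2,2"]
        # locus 2: P1 (1,2): b=3 of 4 -> 1,3; P2 (2,missing): 0,2
        assert lines[2].split() == ["1,3", "0,2"]

    def test_admixture_ped_readable(self, tmp_path, tiny_panel):
        from popgenpipe.genotype_io import read_plink

        files = export_external(tiny_panel, "admixture_ped", tmp_path / "adm")
        g2 = read_plink(tmp_path / "adm", "ped")
        assert g2.equals(tiny_panel, harmonize_alleles=True)
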