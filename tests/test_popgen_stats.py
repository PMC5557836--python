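import numpy as np
import pytest

import oracles
from applepop import popgen_stats as ps
from applepop.io_formats import MISSING, GenotypeDataset, PopulationGrouping
from conftest import make_dataset


def _grouping(dataset, split=None):
    """Split accessions into two groups (first `split` vs rest)."""
    n = dataset.n_accessions
    split = split if split is not None else n // 2
    return PopulationGrouping.from_dict(
        {"A": dataset.accession_ids[:split], "B": dataset.accession_ids[split:]}
    )


class TestPiWindows:
    def test_single_het_site_value(self):
        """One SNP, 2 diploids both het: pi_site = 4/6 by pair enumeration,
        window value 6.667e-5 over 10 kb."""
        dataset = make_dataset([[1], [1]], positions=[5000])
        grouping = PopulationGrouping.from_dict({"G": dataset.accession_ids})
        track = ps.pi_windows(dataset, grouping, "G")
        assert track.table["value"][0] == pytest.approx(
            oracles.site_pi_pair_enumeration([1, 1]) / 10000, abs=1e-15
        )
        assert track.table["value"][0] == pytest.approx(6.667e-5, rel=1e-3)

    def test_monomorphic_window_is_zero(self):
        dataset = make_dataset([[0], [0], [0]])
        grouping = PopulationGrouping.from_dict({"G": dataset.accession_ids})
        assert ps.pi_windows(dataset, grouping, "G").table["value"][0] == 0.0

    def test_matches_pairwise_difference_oracle(self, two_pop_sim):
        """Genome-wide window sums equal brute-force per-site pair counts."""
        sim = two_pop_sim
        idx = sim.grouping.indices(sim.dataset, "P1")
        track = ps.pi_windows(sim.dataset, sim.grouping, "P1")
        total_from_windows = (track.table["value"] * track.width).sum()
        total_brute = sum(
            oracles.site_pi_pair_enumeration(sim.dataset.dosages[idx, j])
            for j in range(sim.dataset.n_sites)
        )
        assert total_from_windows == pytest.approx(total_brute, abs=1e-12 * max(total_brute, 1))

    def test_conservation_of_site_sum(self, two_pop_sim):
        sim = two_pop_sim
        pi_site, n = ps.per_site_pi(sim.dataset.dosages[sim.grouping.indices(sim.dataset, "P2")])
        track = ps.pi_windows(sim.dataset, sim.grouping, "P2")
        assert (track.table["value"] * track.width).sum() == pytest.approx(
            pi_site[n >= 2].sum(), rel=1e-12
        )

    def test_bad_width_rejected(self, two_pop_sim):
        with pytest.raises(ValueError):
            ps.pi_windows(two_pop_sim.dataset, two_pop_sim.grouping, "P1", width=0)


class TestFst:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(4)
        dosages = rng.binomial(2, np.tile(rng.uniform(0.1, 0.9, 2000), (40, 1)))
        dataset = make_dataset(dosages, positions=range(1, 2001))
        fst = ps.multilocus_fst(dataset, _grouping(dataset), ["A", "B"])
        assert abs(fst) < 0.02

    def test_fixed_difference_is_one(self):
        dataset = make_dataset([[0] * 5] * 4 + [[2] * 5] * 4)
        fst = ps.multilocus_fst(dataset, _grouping(dataset), ["A", "B"])
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_wc_oracle(self):
        """2 groups x 10 diploids x 50 sites with missing data, against the
        loop-coded variance-component oracle."""
        rng = np.random.default_rng(8)
        dosages = rng.binomial(2, 0.4, size=(20, 50)).astype(np.int8)
        dosages[rng.random(dosages.shape) < 0.1] = MISSING
        dataset = make_dataset(dosages, positions=range(10, 510, 10))
        grouping = _grouping(dataset, split=10)
        fst = ps.multilocus_fst(dataset, grouping, ["A", "B"])
        oracle = oracles.wc_fst_multilocus(
            [dataset.dosages[:10].tolist(), dataset.dosages[10:].tolist()]
        )
        assert fst == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_accession_order_and_allele_relabel(self, two_pop_sim):
        sim = two_pop_sim
        base = ps.pairwise_fst(sim.dataset, sim.grouping).matrix
        # accession order: reverse rows within the dataset
        order = list(range(sim.dataset.n_accessions))[::-1]
        shuffled = GenotypeDataset(
            [sim.dataset.accession_ids[i] for i in order],
            sim.dataset.sites.copy(),
            sim.dataset.dosages[order],
        )
        assert np.allclose(ps.pairwise_fst(shuffled, sim.grouping).matrix, base, atol=1e-12)
        # allele relabel: dosage d -> 2 - d at every site
        flipped_dos = np.where(sim.dataset.dosages == MISSING, MISSING, 2 - sim.dataset.dosages)
        flipped = GenotypeDataset(
            list(sim.dataset.accession_ids), sim.dataset.sites.copy(), flipped_dos
        )
        assert np.allclose(ps.pairwise_fst(flipped, sim.grouping).matrix, base, atol=1e-12)

    def test_matrix_structure(self, two_pop_sim):
        fst = ps.pairwise_fst(two_pop_sim.dataset, two_pop_sim.grouping)
        assert np.all(np.diag(fst.matrix) == 0)
        assert np.allclose(fst.matrix, fst.matrix.T)


class TestPerSnpTop:
    def test_ceil_rule_on_200_snps(self):
        rng = np.random.default_rng(13)
        dosages = rng.binomial(2, 0.5, size=(20, 200)).astype(np.int8)
        dataset = make_dataset(dosages, positions=range(1, 201))
        top = ps.per_snp_fst_top(dataset, _grouping(dataset), "A", "B", top_frac=0.01)
        assert len(top) >= 2  # ceil(0.01 * 200) = 2 plus any cutoff ties

    def test_all_ties_retained(self):
        dataset = make_dataset([[0] * 10] * 5 + [[2] * 10] * 5)
        top = ps.per_snp_fst_top(dataset, _grouping(dataset), "A", "B", top_frac=0.01)
        assert len(top) == 10  # every site has F_ST 1

    def test_implanted_divergent_site_ranks_first(self):
        rng = np.random.default_rng(21)
        dosages = rng.binomial(2, 0.5, size=(30, 100)).astype(np.int8)
        dosages[:15, 42] = 0
        dosages[15:, 42] = 2
        dataset = make_dataset(dosages, positions=range(1, 101))
        top = ps.per_snp_fst_top(dataset, _grouping(dataset, 15), "A", "B")
        assert top.iloc[0]["pos"] == 43  # positions are 1-based of column 42

    def test_empty_dataset(self):
        import pandas as pd

        dataset = GenotypeDataset(
            ["a", "b", "c", "d"],
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
            np.zeros((4, 0), dtype=np.int8),
        )
        top = ps.per_snp_fst_top(dataset, _grouping(dataset), "A", "B")
        assert len(top) == 0


class TestMds:
    def test_exact_planar_configuration_recovered(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, rho = ps.mds_embed(ps.FstMatrix(["a", "b", "c"], D))
        assert rho == pytest.approx(1.0)
        embedded = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(embedded, D, atol=1e-10)

    def test_two_groups_embed_at_their_distance(self):
        D = np.array([[0.0, 0.37], [0.37, 0.0]])
        with pytest.warns(UserWarning, match="rank"):
            coords, _ = ps.mds_embed(ps.FstMatrix(["a", "b"], D))
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.37, abs=1e-12)
        assert coords.shape == (2, 2)  # zero-padded second axis

    def test_matches_spectral_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 5))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, _ = ps.mds_embed(ps.FstMatrix(list("abcdefgh"), D), dims=2)
        oracle = oracles.cmdscale_oracle(D, 2)
        d_impl = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        d_orac = np.sqrt(((oracle[:, None] - oracle[None]) ** 2).sum(-1))
        assert np.allclose(d_impl, d_orac, atol=1e-8)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (5, 0, 5), (10, 0, 0), (0, 0, 0), (3, 7, 2), (1, 1, 28)],
    )
    def test_matches_fraction_oracle(self, counts):
        expected = float(oracles.hwe_exact_fraction(*counts))
        assert ps.hwe_exact(counts) == pytest.approx(expected, abs=1e-12)

    def test_modal_configuration_near_one(self):
        assert ps.hwe_exact((25, 50, 25)) == pytest.approx(1.0, abs=1e-9)

    def test_het_deficit_significant(self):
        assert ps.hwe_exact((5, 0, 5)) < 0.01

    def test_monomorphic_is_one(self):
        assert ps.hwe_exact((17, 0, 0)) == 1.0

    def test_exhaustive_all_tables_up_to_n30(self):
        """Implementation equals the exact integer-arithmetic enumeration for
        every genotype table with n <= 30."""
        for n in range(1, 31):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    counts = (n_aa, n_ab, n - n_aa - n_ab)
                    expected = float(oracles.hwe_exact_fraction(*counts))
                    got = ps.hwe_exact(counts)
                    assert got == pytest.approx(expected, abs=1e-10), counts


class TestLdDecay:
    def _dataset_with_duplicate(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.5, size=(50, 1)).astype(np.int8)
        rest = rng.binomial(2, 0.5, size=(50, 8)).astype(np.int8)
        dosages = np.concatenate([base, base, rest], axis=1)
        positions = [1000, 1100] + list(range(100000, 100000 + 8 * 20000, 20000))
        return make_dataset(dosages, positions=positions)

    def test_duplicated_column_r2_one(self):
        dataset = self._dataset_with_duplicate()
        grouping = PopulationGrouping.from_dict({"G": dataset.accession_ids})
        curve = ps.ld_decay(dataset, grouping, "G", bins=[0, 200, 500000])
        first = curve[curve["bin_lo"] == 0]
        assert first["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_sites_low_r2(self):
        rng = np.random.default_rng(6)
        dosages = rng.binomial(2, 0.5, size=(50, 60)).astype(np.int8)
        dataset = make_dataset(dosages, positions=range(1000, 61000, 1000))
        grouping = PopulationGrouping.from_dict({"G": dataset.accession_ids})
        curve = ps.ld_decay(dataset, grouping, "G", bins=np.linspace(0, 60000, 7))
        assert (curve["mean_r2"] < 0.06).all()  # E[r^2] ~ 1/n = 0.02

    def test_low_maf_site_contributes_no_pair(self):
        rng = np.random.default_rng(9)
        common = rng.binomial(2, 0.5, size=(50, 2)).astype(np.int8)
        rare = np.zeros((50, 1), dtype=np.int8)
        rare[:8] = 1  # MAF 0.08 < 0.10
        dosages = np.concatenate([common[:, :1], rare, common[:, 1:]], axis=1)
        dataset = make_dataset(dosages, positions=[100, 200, 300])
        grouping = PopulationGrouping.from_dict({"G": dataset.accession_ids})
        curve = ps.ld_decay(dataset, grouping, "G", bins=[0, 1000])
        assert curve["n_pairs"].sum() == 1  # only the two common sites pair up
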