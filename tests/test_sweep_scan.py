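import numpy as np
import pandas as pd
import pytest

import oracles
from applepop import sweep_scan as sw
from applepop.io_formats import MISSING, GeneModel, GeneModelSet, GeneticMap, PopulationGrouping
from applepop.popgen_stats import WindowTrack
from conftest import make_dataset


def _uniform_map(chrom="chr1", length=1_000_000, cm_per_mb=1.0):
    return GeneticMap({chrom: (np.array([0, length]), np.array([0.0, length / 1e6 * cm_per_mb]))})


class TestInterpolateCm:
    def test_linear_midpoint(self):
        gmap = _uniform_map()
        assert sw.interpolate_cM(gmap, "chr1", [500_000])[0] == pytest.approx(0.5)

    def test_anchor_point_exact(self):
        gmap = GeneticMap({"c": (np.array([100, 1000, 5000]), np.array([0.0, 0.3, 0.5]))})
        assert sw.interpolate_cM(gmap, "c", [1000])[0] == pytest.approx(0.3)

    def test_three_anchor_hand_trace(self):
        gmap = GeneticMap({"c": (np.array([0, 1000, 3000]), np.array([0.0, 0.2, 0.8]))})
        # segment 1: 0.2 cM over 1000 bp; segment 2: 0.6 cM over 2000 bp
        assert sw.interpolate_cM(gmap, "c", [500])[0] == pytest.approx(0.1)
        assert sw.interpolate_cM(gmap, "c", [2000])[0] == pytest.approx(0.2 + 0.3)
        # beyond the last anchor: mean rate = 0.8/3000 cM/bp
        assert sw.interpolate_cM(gmap, "c", [6000])[0] == pytest.approx(0.8 + 3000 * 0.8 / 3000)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            sw.interpolate_cM(_uniform_map(), "chrX", [1])


def _window_inputs(ref_rows, obj_rows, cm):
    ref = np.asarray(ref_rows, dtype=np.int8)
    obj = np.asarray(obj_rows, dtype=np.int8)
    return ref, obj, np.asarray(cm, dtype=float)


class TestCompositeScore:
    def test_zero_without_object_fixed_sites(self):
        """Polymorphic object windows force a zero score: the sweep model
        can only remove likelihood there."""
        rng = np.random.default_rng(0)
        params = sw.ScanParams()
        for _ in range(200):
            n_snps = int(rng.integers(1, 8))
            ref = rng.integers(0, 3, size=(6, n_snps)).astype(np.int8)
            # object genotypes guaranteed polymorphic: at least one het
            obj = rng.integers(0, 3, size=(6, n_snps)).astype(np.int8)
            obj[0] = 1
            cm = np.sort(rng.uniform(0, 0.05, size=n_snps))
            score = sw.composite_score(ref, obj, cm, 0.025, params, omega=0.1)
            if score is not None:
                assert score == 0.0

    def test_single_snp_agrees_with_quadrature_oracle(self):
        """One object-fixed SNP at p_ref = 0.5: the score reduces to
        2 log[(c L0 + (1-c) * 0.5) / L0] with L0 from the drift marginal."""
        omega = 0.05
        ref = [[1], [1]]  # p_ref = 0.5, n_ref = 4
        obj = [[2]] * 5  # k = n = 10
        d_m = 0.0005  # Morgans
        s = d_m / np.log(2.0)  # c = 1 - exp(-d/s) = 0.5
        params = sw.ScanParams(sel_grid=np.array([s]), n_quad=4000)
        cm = [0.0]
        grid_cm = d_m * 100  # back to cM
        ref_a, obj_a, cm_a = _window_inputs(ref, obj, cm)
        score = sw.composite_score(ref_a, obj_a, cm_a, grid_cm, params, omega=omega)
        L0 = oracles.neutral_likelihood_quad(0.5, 10, 10, omega)
        expected = 2 * np.log((0.5 * L0 + 0.5 * 0.5) / L0)
        assert score == pytest.approx(expected, rel=1e-5)

    def test_invariant_to_joint_allele_relabel(self):
        rng = np.random.default_rng(44)
        params = sw.ScanParams()
        for _ in range(20):
            n_snps = int(rng.integers(1, 6))
            ref = rng.integers(0, 3, size=(8, n_snps)).astype(np.int8)
            obj = rng.integers(0, 3, size=(8, n_snps)).astype(np.int8)
            cm = np.sort(rng.uniform(0, 0.05, size=n_snps))
            s1 = sw.composite_score(ref, obj, cm, 0.02, params, omega=0.2)
            s2 = sw.composite_score(
                (2 - ref).astype(np.int8), (2 - obj).astype(np.int8), cm, 0.02, params, omega=0.2
            )
            if s1 is None:
                assert s2 is None
            else:
                assert s2 == pytest.approx(s1, rel=1e-9, abs=1e-12)

    def test_no_usable_snp_returns_none(self):
        # reference fixed at every site -> nothing usable
        ref = [[0, 0], [0, 0]]
        obj = [[2, 1], [2, 0]]
        ref_a, obj_a, cm_a = _window_inputs(ref, obj, [0.0, 0.01])
        assert sw.composite_score(ref_a, obj_a, cm_a, 0.0, sw.ScanParams(), omega=0.1) is None

    def test_bad_omega_rejected(self):
        ref_a, obj_a, cm_a = _window_inputs([[1], [1]], [[2], [2]], [0.0])
        with pytest.raises(ValueError):
            sw.composite_score(ref_a, obj_a, cm_a, 0.0, sw.ScanParams(), omega=0.0)


class TestScanChromosome:
    def _tiny_scan(self, dosages, positions, length=100_000):
        dataset = make_dataset(dosages, positions=positions)
        half = len(dosages) // 2
        grouping = PopulationGrouping.from_dict(
            {"R": dataset.accession_ids[:half], "O": dataset.accession_ids[half:]}
        )
        gmap = _uniform_map(length=length)
        return dataset, grouping, gmap

    def test_empty_chromosome_all_missing(self):
        dataset, grouping, gmap = self._tiny_scan(
            [[1] * 3] * 8, [1000, 2000, 3000], length=100_000
        )
        out = sw.scan_chromosome(
            dataset, grouping, "R", "O", gmap, "chr2", omega=0.1, chrom_length=50_000
        )
        # chr2 has no SNPs at all
        assert out["score"].isna().all() or len(out) == 0

    def test_grid_spacing_halves_point_count(self):
        dataset, grouping, gmap = self._tiny_scan([[1] * 3] * 8, [1000, 2000, 3000])
        out1 = sw.scan_chromosome(
            dataset, grouping, "R", "O", gmap, "chr1", omega=0.1,
            params=sw.ScanParams(grid_spacing=100), chrom_length=10_000,
        )
        out2 = sw.scan_chromosome(
            dataset, grouping, "R", "O", gmap, "chr1", omega=0.1,
            params=sw.ScanParams(grid_spacing=200), chrom_length=10_000,
        )
        assert len(out1) == 2 * len(out2)

    def test_far_grid_points_are_missing(self):
        """Grid points more than the half-window away from every SNP score
        as missing."""
        dosages = [[1, 1]] * 10
        dataset, grouping, gmap = self._tiny_scan(dosages, [1000, 1200], length=200_000)
        out = sw.scan_chromosome(
            dataset, grouping, "R", "O", gmap, "chr1", omega=0.1, chrom_length=200_000
        )
        # half window 0.025 cM = 25 kb on this map; beyond ~26.2 kb nothing
        far = out[out["pos"] > 1200 + 25_000]
        assert far["score"].isna().all()
        near = out[(out["pos"] >= 1000) & (out["pos"] <= 1200)]
        assert near["score"].notna().all()

    def test_matches_single_point_scorer(self):
        """The vectorized scan equals composite_score point by point."""
        rng = np.random.default_rng(12)
        n_snps = 40
        positions = np.sort(rng.choice(np.arange(1000, 99_000), n_snps, replace=False))
        ref = rng.binomial(2, 0.4, size=(10, n_snps)).astype(np.int8)
        obj = rng.binomial(2, rng.uniform(0, 1, n_snps), size=(10, n_snps)).astype(np.int8)
        dosages = np.concatenate([ref, obj])
        dataset = make_dataset(dosages, positions=[int(p) for p in positions])
        grouping = PopulationGrouping.from_dict(
            {"R": dataset.accession_ids[:10], "O": dataset.accession_ids[10:]}
        )
        gmap = _uniform_map(length=100_000)
        params = sw.ScanParams(grid_spacing=5000)
        out = sw.scan_chromosome(
            dataset, grouping, "R", "O", gmap, "chr1", params=params,
            omega=0.15, chrom_length=100_000,
        )
        cm = sw.interpolate_cM(gmap, "chr1", positions)
        for row in out.itertuples(index=False):
            grid_cm = sw.interpolate_cM(gmap, "chr1", [row.pos])[0]
            in_win = np.abs(cm - grid_cm) <= params.window_half_cm
            expected = sw.composite_score(
                ref[:, in_win], obj[:, in_win], cm[in_win], grid_cm, params, omega=0.15
            ) if in_win.any() else None
            if expected is None:
                assert np.isnan(row.score)
            else:
                assert row.score == pytest.approx(expected, rel=1e-8, abs=1e-10)


class TestWindowAverage:
    def test_constant_scores(self):
        grid = pd.DataFrame(
            {"chrom": "chr1", "pos": range(100, 20100, 100), "score": 5.0}
        )
        track = sw.window_average(grid)
        assert (track.table["value"] == 5.0).all()

    def test_mean_of_mixed_window(self):
        grid = pd.DataFrame({"chrom": "chr1", "pos": [100, 200], "score": [0.0, 10.0]})
        track = sw.window_average(grid)
        assert track.table["value"][0] == 5.0

    def test_missing_aware_mean_matches_recomputation(self):
        rng = np.random.default_rng(31)
        pos = np.arange(100, 50100, 100)
        scores = rng.uniform(0, 10, len(pos))
        scores[rng.random(len(pos)) < 0.3] = np.nan
        grid = pd.DataFrame({"chrom": "chr1", "pos": pos, "score": scores})
        track = sw.window_average(grid, width=10000)
        for row in track.table.itertuples(index=False):
            in_w = (pos >= row.start) & (pos < row.start + 10000)
            vals = scores[in_w]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                assert np.isnan(row.value)
            else:
                assert row.value == pytest.approx(vals.mean(), rel=1e-12)


def _track(values, chrom="chr1", width=10000):
    rows = [
        (chrom, i * width + 1, width, v, 0 if v is None or np.isnan(v) else 1)
        for i, v in enumerate(values)
    ]
    return WindowTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "width", "value", "n_sites"]), width
    )


class TestMergeRegions:
    def test_hand_trace_with_single_gap_merge(self):
        """[1,1,10,1,10,1,1]: mean 25/7, threshold ~2.857; windows 3 and 5
        qualify and merge across the single low window between them."""
        regions = sw.merge_regions(_track([1, 1, 10, 1, 10, 1, 1]))
        assert len(regions) == 1
        region = regions[0]
        assert (region.start, region.end) == (20001, 50000)
        assert region.score == 10.0
        assert region.n_windows == 3

    def test_all_equal_windows_single_region_kept_by_ties(self):
        regions = sw.merge_regions(_track([4.0] * 6))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 60000)

    def test_no_window_reaches_threshold(self):
        # a NaN-heavy track where the only scored window sits below 80% of
        # the mean is impossible on one window; use two chromosomes instead
        t1 = _track([10.0, np.nan, np.nan])
        t2 = _track([1.0], chrom="chr2")
        track = WindowTrack(pd.concat([t1.table, t2.table], ignore_index=True), 10000)
        regions = sw.merge_regions(track)
        assert all(r.chrom == "chr1" for r in regions)

    def test_scaling_scores_leaves_membership_unchanged(self):
        rng = np.random.default_rng(50)
        values = list(rng.uniform(0, 5, 40))
        base = sw.merge_regions(_track(values))
        scaled = sw.merge_regions(_track([v * 7.3 for v in values]))
        assert [(r.start, r.end) for r in base] == [(r.start, r.end) for r in scaled]

    def test_chromosome_order_invariance_and_no_overlap(self):
        rng = np.random.default_rng(51)
        v1, v2 = list(rng.uniform(0, 5, 30)), list(rng.uniform(0, 5, 30))
        t_ab = WindowTrack(
            pd.concat([_track(v1).table, _track(v2, "chr2").table], ignore_index=True), 10000
        )
        t_ba = WindowTrack(
            pd.concat([_track(v2, "chr2").table, _track(v1).table], ignore_index=True), 10000
        )
        r_ab = {(r.chrom, r.start, r.end) for r in sw.merge_regions(t_ab)}
        r_ba = {(r.chrom, r.start, r.end) for r in sw.merge_regions(t_ba)}
        assert r_ab == r_ba
        by_chrom = {}
        for chrom, start, end in sorted(r_ab):
            assert start > by_chrom.get(chrom, 0)
            by_chrom[chrom] = end

    def test_empty_track(self):
        assert sw.merge_regions(_track([np.nan, np.nan])) == []


class TestPiRatioFilter:
    def _regions(self, n):
        return [
            sw.SweepRegion("chr1", i * 10000 + 1, (i + 1) * 10000, 5.0, 1)
            for i in range(n)
        ]

    def _dataset_with_pi_gradient(self):
        # 4 regions; object diversity rises with position so pi-ratio falls
        rng = np.random.default_rng(60)
        ref = rng.binomial(2, 0.5, size=(10, 40)).astype(np.int8)
        obj = np.zeros((10, 40), dtype=np.int8)
        for region in range(4):
            p = [0.0, 0.1, 0.3, 0.5][region]
            obj[:, region * 10 : (region + 1) * 10] = rng.binomial(2, p, size=(10, 10))
        dosages = np.concatenate([ref, obj])
        positions = [region * 10000 + 500 + j * 300 for region in range(4) for j in range(10)]
        dataset = make_dataset(dosages, positions=positions)
        grouping = PopulationGrouping.from_dict(
            {"R": dataset.accession_ids[:10], "O": dataset.accession_ids[10:]}
        )
        return dataset, grouping

    def test_keeps_top_half_by_ratio(self):
        dataset, grouping = self._dataset_with_pi_gradient()
        kept = sw.pi_ratio_filter(self._regions(4), dataset, grouping, "R", "O")
        assert len(kept) == 2
        assert {r.start for r in kept} == {1, 10001}  # lowest object diversity

    def test_single_region_kept(self):
        dataset, grouping = self._dataset_with_pi_gradient()
        kept = sw.pi_ratio_filter(self._regions(1), dataset, grouping, "R", "O")
        assert len(kept) == 1

    def test_zero_object_diversity_ranks_first(self):
        dataset, grouping = self._dataset_with_pi_gradient()
        kept = sw.pi_ratio_filter(self._regions(4), dataset, grouping, "R", "O")
        assert kept[0].pi_ratio == np.inf


class TestAnnotateGenes:
    def _genes(self):
        return GeneModelSet(
            [
                GeneModel("inside", "chr1", "+", [(1200, 1400, 0)]),
                GeneModel("outside", "chr1", "+", [(9000, 9200, 0)]),
                GeneModel("abutting", "chr1", "+", [(2001, 2300, 0)]),
                GeneModel("one_bp", "chr1", "+", [(2000, 2299, 0)]),
            ]
        )

    def test_overlap_rules(self):
        region = sw.SweepRegion("chr1", 1000, 2000, 1.0, 1)
        sw.annotate_genes([region], self._genes())
        assert region.genes == ["inside", "one_bp"]


class TestThresholdOverride:
    def test_explicit_threshold_replaces_mean_rule(self):
        track = _track([1, 1, 10, 1, 10, 1, 1])
        # with an override above 10 nothing qualifies
        assert sw.merge_regions(track, threshold=11.0) == []
        # a permissive override makes one full-span region
        regions = sw.merge_regions(track, threshold=0.5)
        assert [(r.start, r.end) for r in regions] == [(1, 70000)]
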