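"""Microarray analysis: empirical null, effects, aneuploidy, clustering."""

import numpy as np
import pandas as pd
import pytest

import sumostress as ss
from sumostress import arrays as arr
from sumostress import synthetic as syn


def exact_sd_sample(target_sd, n=200, seed=0):
    """A vector whose sample SD (ddof=1) equals target_sd to float precision."""
    x = np.random.default_rng(seed).normal(size=n)
    return (x - x.mean()) / np.std(x, ddof=1) * target_sd


class TestDeriveThreshold:
    def test_all_zero_ratios(self):
        thr = arr.derive_threshold(np.zeros(200))
        assert thr.null_sd == 0.0
        assert thr.fold_threshold == 1.0

    def test_printed_threshold_arithmetic(self):
        """Sample SD of 0.65/3 gives the 0.65 log2 / 1.57-fold threshold."""
        thr = arr.derive_threshold(exact_sd_sample(0.65 / 3), k=3)
        assert thr.log2_threshold == pytest.approx(0.65, abs=1e-12)
        assert round(thr.fold_threshold, 2) == 1.57

    def test_gaussian_null_converges(self):
        thr = arr.derive_threshold(ss.gen_self_self(15000, sd=0.22, seed=4), k=3)
        assert thr.fold_threshold == pytest.approx(2 ** 0.66, rel=0.02)

    def test_large_sample_invariant(self):
        """Threshold on Gaussian(0, sigma) converges to 2**(k*sigma)."""
        thr = arr.derive_threshold(ss.gen_self_self(100_000, sd=0.3, seed=5), k=2)
        assert thr.fold_threshold == pytest.approx(2 ** 0.6, rel=0.01)

    def test_small_or_nonfinite_input(self):
        with pytest.raises(ValueError, match="100"):
            arr.derive_threshold(np.zeros(50))
        with_nan = np.concatenate([exact_sd_sample(0.2), [np.nan, np.inf]])
        thr = arr.derive_threshold(with_nan)
        assert thr.n_excluded == 2
        assert thr.null_sd == pytest.approx(0.2, abs=1e-12)


class TestAveragingAndEffects:
    def test_replicate_mean_arithmetic(self):
        truth = syn.ArrayTruth(n_genes=30, seed=1)
        expr, _ = ss.gen_array_experiment(truth)
        avg = arr.average_replicates(expr)
        # brute-force per-cell mean
        for strain in ("wt", "tup1KR"):
            for tp in (0, 30):
                cols = expr.arrays_for(strain=strain, timepoint=tp)
                expected = expr.values[cols].mean(axis=1)
                np.testing.assert_allclose(
                    avg.values[(strain, tp)], expected, atol=1e-12
                )
        assert (avg.n == 2).all().all()

    def test_single_replicate_passthrough(self):
        truth = syn.ArrayTruth(n_genes=20, seed=2)
        expr, _ = ss.gen_array_experiment(truth)
        one = expr.values.iloc[:, :1]
        sub = arr.ExpressionSet(
            values=one,
            arrays=expr.arrays.iloc[:1],
            genes=expr.genes,
            chrom_lengths=expr.chrom_lengths,
        )
        avg = arr.average_replicates(sub)
        np.testing.assert_allclose(avg.values.iloc[:, 0], one.iloc[:, 0])

    def test_wt_minus_wt_is_zero(self):
        expr, _ = ss.gen_array_experiment(syn.ArrayTruth(n_genes=25, seed=3))
        avg = arr.average_replicates(expr)
        values = pd.concat({"wt": avg.values["wt"], "mut": avg.values["wt"]}, axis=1)
        values.columns.names = ["strain", "timepoint"]
        n = pd.concat({"wt": avg.n["wt"], "mut": avg.n["wt"]}, axis=1)
        n.columns.names = ["strain", "timepoint"]
        doubled = arr.AveragedMatrix(values=values, n=n)
        effects = arr.mutant_effect(doubled, wild_type="wt")
        assert (effects.abs() < 1e-15).all().all()

    def test_effect_arithmetic_and_planted_recovery(self):
        planted = {"G0005": {("tup1KR", 30): 1.0}}
        truth = syn.ArrayTruth(n_genes=60, planted_effects=planted, seed=6)
        expr, _ = ss.gen_array_experiment(truth, n_replicates=4)
        avg = arr.average_replicates(expr)
        effects = arr.mutant_effect(avg, wild_type="wt")
        # SE of (mean of 4) - (mean of 4) at SD 0.22
        se = 0.22 * np.sqrt(2 / 4)
        assert effects.loc["G0005", ("tup1KR", 30)] == pytest.approx(1.0, abs=3 * se)
        assert effects.loc["G0005", ("tup1KR", 30)] == pytest.approx(
            avg.values.loc["G0005", ("tup1KR", 30)]
            - avg.values.loc["G0005", ("wt", 30)],
            abs=1e-12,
        )


class TestCallSignificant:
    def test_boundary_inclusive(self):
        vals = pd.DataFrame({"c": [0.65, 0.64, -0.65, -0.64]}, index=list("abcd"))
        sig = arr.call_significant(vals, 0.65, direction="both")
        assert sig["c"] == {"a", "c"}
        assert arr.call_significant(vals, 0.65, direction="up")["c"] == {"a"}
        assert arr.call_significant(vals, 0.65, direction="down")["c"] == {"c"}

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            rng.normal(size=(50, 3)),
            index=[f"g{i}" for i in range(50)],
            columns=list("xyz"),
        )
        sig = arr.call_significant(vals, 0.5, direction="both")
        for col in vals.columns:
            expected = {
                g for g in vals.index if abs(vals.loc[g, col]) >= 0.5
            }
            assert sig[col] == expected

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        sizes = [
            len(arr.call_significant(vals, t, "both")["a"])
            for t in np.linspace(0, 2, 9)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestTelomereProximity:
    def test_trivial_positions(self):
        genes = pd.DataFrame(
            {
                "chrom": ["c1", "c1"],
                "start": [1, 500_000 - 250],
                "end": [500, 500_000 + 250],
            },
            index=["near", "center"],
        )
        flags = arr.telomere_proximity(genes, {"c1": 1_000_000}, 25_000)
        assert bool(flags["near"]) and not bool(flags["center"])

    def test_matches_bruteforce_over_annotation(self):
        genes, lengths = syn.synthetic_annotation(120)
        for cutoff in (500, 25_000, 60_000):
            flags = arr.telomere_proximity(genes, lengths, cutoff)
            for g, row in genes.iterrows():
                d = min(row["start"] - 1, lengths[row["chrom"]] - row["end"])
                assert flags[g] == (d <= cutoff)

    def test_unknown_chromosome_rejected(self):
        genes = pd.DataFrame(
            {"chrom": ["cX"], "start": [1], "end": [10]}, index=["g"]
        )
        with pytest.raises(ValueError, match="unknown"):
            arr.telomere_proximity(genes, {"c1": 100}, 10)


class TestAneuploidyScan:
    def test_null_data_yields_no_regions(self):
        expr, _ = ss.gen_array_experiment(syn.ArrayTruth(n_genes=200, seed=10))
        regions, masked = arr.detect_aneuploid_region(
            expr, "tup1KR", elevation_cutoff=0.66, min_run=5
        )
        assert regions == []
        assert len(masked.genes) == 200

    def test_planted_segment_recovered_exactly(self):
        seg = syn.AneuploidSegment("chrII", 60, 79, 0.8, "tup1KR")
        truth = syn.ArrayTruth(n_genes=200, aneuploid_segment=seg, seed=11)
        expr, _ = ss.gen_array_experiment(truth)
        regions, masked = arr.detect_aneuploid_region(
            expr, "tup1KR", elevation_cutoff=0.4, min_run=5
        )
        assert len(regions) == 1
        (r,) = regions
        assert r.gene_ids == tuple(expr.genes.index[60:80])
        assert len(masked.genes) == 180
        assert r.span_bp == r.end_bp - r.start_bp + 1

    def test_two_segments_do_not_cross_chromosomes(self):
        genes, lengths = syn.synthetic_annotation(200)
        # plant manually on two chromosomes, adjacent across the boundary
        truth = syn.ArrayTruth(n_genes=200, seed=12)
        expr, _ = ss.gen_array_experiment(truth, strains=("wt", "mut"))
        vals = expr.values.copy()
        flagged = expr.arrays_for(strain="mut")
        chrI_end = (genes["chrom"] == "chrI").sum()
        vals.iloc[chrI_end - 6 : chrI_end + 6, [expr.values.columns.get_loc(c) for c in flagged]] += 2.0
        expr2 = arr.ExpressionSet(
            values=vals, arrays=expr.arrays, genes=expr.genes,
            chrom_lengths=expr.chrom_lengths,
        )
        regions, _ = arr.detect_aneuploid_region(expr2, "mut", 0.5, min_run=5)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"chrI", "chrII"}
        for r in regions:
            assert len(set(expr.genes.loc[list(r.gene_ids), "chrom"])) == 1

    def test_parameter_validation(self):
        expr, _ = ss.gen_array_experiment(syn.ArrayTruth(n_genes=50, seed=1))
        with pytest.raises(ValueError, match="min_run"):
            arr.detect_aneuploid_region(expr, "wt", 0.5, min_run=2)
        with pytest.raises(ValueError, match="no arrays"):
            arr.detect_aneuploid_region(expr, "nope", 0.5)

    def test_zero_false_positives_over_null_sims(self):
        """No spurious regions on 20 null simulations at 3x null SD."""
        for seed in range(20):
            expr, _ = ss.gen_array_experiment(
                syn.ArrayTruth(n_genes=150, seed=100 + seed), strains=("wt", "mut")
            )
            regions, _ = arr.detect_aneuploid_region(expr, "mut", 0.66, min_run=5)
            assert regions == []


class TestUncenteredCorrelation:
    def test_trivial_values(self):
        x = np.array([1.0, 2.0, -1.0])
        assert arr.uncentered_correlation(x, x) == pytest.approx(1.0)
        assert arr.uncentered_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 1.0, 0.0]
        expected = (2 + 2 + 0) / np.sqrt((1 + 4 + 9) * (4 + 1 + 0))
        assert arr.uncentered_correlation(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            arr.uncentered_correlation([0.0, 0.0], [1.0, 2.0])

    def test_pairwise_finite_exclusion(self):
        got = arr.uncentered_correlation([1.0, np.nan, 3.0], [2.0, 5.0, 0.0])
        assert got == pytest.approx(2 / np.sqrt(10 * 4), rel=1e-12)


def bruteforce_agglomerate(X, similarity):
    """O(n^3) oracle: recompute all-pairs average similarity each step."""
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ii, a in enumerate(ids):
            for b in ids[ii + 1 :]:
                s = np.mean(
                    [similarity(X[i], X[j]) for i in clusters[a] for j in clusters[b]]
                )
                if best is None or s > best[0]:
                    best = (s, a, b)
        s, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, 1.0 - s, len(clusters[next_id])))
        next_id += 1
    return merges


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(5, 4))
        X[3] = X[1]
        res = arr.hcluster_average(X)
        a, b, h, size = res.merges[0]
        assert {a, b} == {1, 3}
        assert h == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    def test_duplicated_matrix_pairs_merge_at_zero(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(4, 5))
        X = np.vstack([base, base])
        res = arr.hcluster_average(X)
        zero_merges = [m for m in res.merges if abs(m[2]) < 1e-12]
        assert len(zero_merges) >= 4

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(4, 8), rng.integers(3, 6)))
            res = arr.hcluster_average(X)
            oracle = bruteforce_agglomerate(X, arr.uncentered_correlation)
            assert [(a, b) for a, b, _, _ in res.merges] == [
                (a, b) for a, b, _, _ in oracle
            ]
            np.testing.assert_allclose(
                [h for _, _, h, _ in res.merges],
                [h for _, _, h, _ in oracle],
                atol=1e-10,
            )

    def test_row_permutation_preserves_height_multiset(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        h1 = sorted(m[2] for m in arr.hcluster_average(X).merges)
        h2 = sorted(m[2] for m in arr.hcluster_average(X[perm]).merges)
        np.testing.assert_allclose(h1, h2, atol=1e-10)

    def test_undefined_similarity_reported(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="row pairs"):
            arr.hcluster_average(X)


class TestSetOverlaps:
    def test_disjoint_and_identical(self):
        out = arr.set_overlaps({"a": {1, 2}, "b": {3, 4}})
        assert out["pairwise"][("a", "b")] == 0
        out = arr.set_overlaps({"a": {1, 2}, "b": {1, 2}})
        assert out["pairwise"][("a", "b")] == 2

    def test_three_way_matches_enumeration(self):
        rng = np.random.default_rng(17)
        universe = list(range(40))
        sets = {
            k: set(rng.choice(universe, size=rng.integers(5, 25), replace=False))
            for k in ("a", "b", "c")
        }
        out = arr.set_overlaps(sets)
        assert out["triple"] == len(sets["a"] & sets["b"] & sets["c"])
        region_total = sum(out["regions"].values())
        assert region_total == len(sets["a"] | sets["b"] | sets["c"])

    def test_more_than_three_sets_pairwise_only(self):
        out = arr.set_overlaps({k: {1} for k in "abcd"})
        assert "regions" not in out
        assert len(out["pairwise"]) == 6

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            arr.set_overlaps({"a": {1}})


class TestFileFormats:
    def test_expression_tsv_round_trip(self, tmp_path):
        expr, _ = ss.gen_array_experiment(syn.ArrayTruth(n_genes=30, seed=18))
        path = tmp_path / "expr.tsv"
        arr.write_expression_tsv(expr, path)
        back = arr.read_expression_tsv(path)
        np.testing.assert_allclose(back.values, expr.values, atol=1e-9)
        assert back.chrom_lengths == expr.chrom_lengths
        pd.testing.assert_frame_equal(back.genes, expr.genes)

    def test_bed_is_zero_based_half_open(self, tmp_path):
        r = arr.GenomicRegion(
            chrom="chrII", first_gene="G1", last_gene="G2",
            gene_ids=("G1", "G2"), start_bp=501, end_bp=4000, mean_elevation=0.8,
        )
        path = tmp_path / "regions.bed"
        arr.write_bed([r], path)
        chrom, start, end, name, score = path.read_text().split()
        assert (chrom, start, end) == ("chrII", "500", "4000")

    def test_cdt_gtr_output(self, tmp_path):
        rng = np.random.default_rng(19)
        mat = pd.DataFrame(
            rng.normal(size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"a{i}" for i in range(4)],
        )
        res = arr.hcluster_average(mat.to_numpy())
        arr.write_cdt_gtr(mat, res, tmp_path / "out.cdt", tmp_path / "out.gtr")
        gtr_lines = (tmp_path / "out.gtr").read_text().strip().splitlines()
        assert len(gtr_lines) == 5  # n-1 merges
        cdt_lines = (tmp_path / "out.cdt").read_text().strip().splitlines()
        assert cdt_lines[0].startswith("GID\tUNIQID\tNAME\tGWEIGHT")
        assert len(cdt_lines) == 2 + 6  # header + EWEIGHT + genes
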