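"""Rotation permutation test: identities, calibration, power, linkage control."""

import numpy as np
import pytest
from scipy.stats import kstest

from sweepscape.clr import ScanResult
from sweepscape.enrichment import (
    bh_qvalues, candidate_geneset_test, genes_hit, outlier_sites,
    rotation_test, shuffle_test, _gene_site_ranges, _hits_for_offsets,
)
from sweepscape.simulate import make_gene_annotation
from sweepscape.types import GeneModel, GeneSetCatalog


def make_scan(scores, spacing=1000, chrom="1"):
    scores = np.asarray(scores, dtype=float)
    return ScanResult(
        chrom=np.full(len(scores), chrom, dtype=object),
        positions=np.arange(1, len(scores) + 1) * spacing,
        clr=scores,
        lambda_hat=np.full(len(scores), np.nan),
    )


class TestOutliers:
    def test_distinct_scores_exact_count(self):
        scan = make_scan(np.arange(1000))
        assert len(outlier_sites(scan, 0.99)) == 10

    def test_all_equal_all_outliers(self):
        scan = make_scan(np.ones(500))
        assert len(outlier_sites(scan, 0.99)) == 500

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(1000)
        a = outlier_sites(make_scan(scores), 0.99)
        b = outlier_sites(make_scan(np.exp(5 * scores)), 0.99)
        np.testing.assert_array_equal(a, b)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            outlier_sites(make_scan([]), 0.99)


class TestGenesHit:
    def test_flank_boundaries(self):
        scan = make_scan(np.zeros(10), spacing=100)  # positions 100..1000
        genes = [GeneModel("g", "1", 1500, 1600)]
        # site at exactly start - 1000 = 500 is a hit
        hit = genes_hit(genes, scan, np.array([4]), flank=1000)  # pos 500
        assert hit == {"g"}
        hit = genes_hit(genes, scan, np.array([3]), flank=1000)  # pos 400
        assert hit == set()

    def test_one_site_hits_overlapping_genes(self):
        scan = make_scan(np.zeros(5), spacing=100)
        genes = [GeneModel("a", "1", 250, 450), GeneModel("b", "1", 280, 320)]
        hit = genes_hit(genes, scan, np.array([2]), flank=0)  # pos 300
        assert hit == {"a", "b"}


class TestRotationIdentities:
    def _setup(self, seed=0, n=2000, n_genes=40):
        rng = np.random.default_rng(seed)
        scores = rng.exponential(size=n)
        scan = make_scan(scores, spacing=1000)
        genes, catalog = make_gene_annotation(n * 1000, n_genes, seed=seed)
        return scan, genes, catalog

    def test_offset_zero_reproduces_observed(self):
        scan, genes, catalog = self._setup()
        term = catalog.terms()[0]
        members = [g for g in genes if g.gene_id in catalog.sets[term]]
        out = outlier_sites(scan, 0.99)
        out_bool = np.zeros(len(scan.clr), dtype=bool)
        out_bool[out] = True
        ranges = _gene_site_ranges(members, scan, 1000)
        observed = _hits_for_offsets(out_bool, ranges, np.array([0]))[0]
        direct = len(genes_hit(members, scan, out, flank=1000))
        assert observed == direct

    def test_rotation_preserves_outlier_count_exhaustive(self):
        # every offset of a <=5000-site grid keeps the outlier set size
        rng = np.random.default_rng(1)
        n = 1500
        out_bool = np.zeros(n, dtype=bool)
        out_bool[rng.choice(n, size=15, replace=False)] = True
        for offset in range(n):
            assert np.roll(out_bool, offset).sum() == 15

    def test_p_floor(self):
        # observed beats every rotation -> p = 1/(N+1)
        n = 500
        scores = np.zeros(n)
        scores[250] = 100.0
        scan = make_scan(scores)
        genes = [GeneModel("g", "1", 250_500, 250_900)]
        res = candidate_geneset_test(scan, ["g"], genes, quantile=0.998,
                                     flank=1000, n_perm=200, seed=3)
        assert res.observed == 1
        # rotations hit the single tiny gene rarely; p stays small
        assert res.p_value <= 0.05

    def test_monotone_score_transform_invariance(self):
        scan, genes, catalog = self._setup(seed=5)
        r1 = rotation_test(scan, catalog, genes, n_perm=100, seed=7)
        scan2 = make_scan(np.log1p(scan.clr))
        r2 = rotation_test(scan2, catalog, genes, n_perm=100, seed=7)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]

    def test_bad_inputs(self):
        scan, genes, catalog = self._setup()
        with pytest.raises(ValueError):
            rotation_test(scan, catalog, genes, n_perm=0)
        with pytest.raises(ValueError):
            candidate_geneset_test(scan, [], genes)


class TestCalibration:
    def test_null_p_values_uniform(self):
        """Scores independent of gene placement: p ~ Uniform(0, 1).

        The gene set is large (250 genes of 12 kb) so the hit-count
        statistic has wide support; with a low-variance statistic the
        add-one estimator is visibly conservative through ties, which is a
        property of discreteness, not mis-calibration.
        """
        rng = np.random.default_rng(11)
        n = 12_000
        genes = [GeneModel(f"g{i}", "1", 1 + 24_000 * i, 12_000 + 24_000 * i)
                 for i in range(500)]
        gene_ids = [g.gene_id for g in genes]
        ps = []
        for run in range(200):
            scores = rng.exponential(size=n)
            scan = make_scan(scores)
            res = candidate_geneset_test(scan, gene_ids, genes,
                                         quantile=0.99, flank=1000,
                                         n_perm=200, seed=1000 + run)
            ps.append(res.p_value)
        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_power_on_planted_enrichment(self):
        """Scores elevated over half the candidate genes: p <= 0.01."""
        rng = np.random.default_rng(12)
        n = 4000
        genes, catalog = make_gene_annotation(n * 1000, 60, seed=2,
                                              n_random_terms=1,
                                              genes_per_term=30)
        gene_ids = sorted(catalog.sets[catalog.terms()[0]])
        hits = 0
        runs = 20
        for run in range(runs):
            scores = rng.exponential(size=n)
            # elevate scores over half the candidate genes
            for g in [x for x in genes if x.gene_id in gene_ids[:15]]:
                lo = g.start // 1000
                hi = g.end // 1000 + 1
                scores[lo:hi] += 50.0
            scan = make_scan(scores)
            res = candidate_geneset_test(scan, gene_ids, genes,
                                         quantile=0.99, flank=1000,
                                         n_perm=1000, seed=2000 + run)
            if res.p_value <= 0.01:
                hits += 1
        assert hits >= int(0.9 * runs)

    def test_disjoint_candidate_set_p_near_one(self):
        rng = np.random.default_rng(13)
        n = 3000
        scores = np.zeros(n)
        scores[:40] = 100.0  # one contiguous outlier block at the start
        genes = [GeneModel(f"g{i}", "1", 1_000_000 + 40_000 * i,
                           1_002_000 + 40_000 * i) for i in range(20)]
        res = candidate_geneset_test(make_scan(scores),
                                     [g.gene_id for g in genes], genes,
                                     quantile=0.99, flank=1000,
                                     n_perm=500, seed=4)
        assert res.observed == 0
        assert res.p_value > 0.5

    def test_clustered_confound_rotation_vs_shuffle(self):
        """One sweep over a physical gene cluster: the naive i.i.d. shuffle
        reports smaller p than the linkage-aware rotation."""
        rng = np.random.default_rng(14)
        n = 4000
        rot_larger = 0
        runs = 11
        for run in range(runs):
            genes, catalog = make_gene_annotation(
                n * 1000, 40,
                cluster_spec={"term": "clu", "n_genes": 10, "span": 40_000,
                              "start": 2_000_000},
                seed=100 + run)
            gene_ids = sorted(catalog.sets["clu"])
            scores = rng.exponential(size=n)
            scores[1995:2050] += 50.0  # a single sweep over the cluster
            scan = make_scan(scores)
            p_rot = candidate_geneset_test(scan, gene_ids, genes,
                                           quantile=0.99, flank=1000,
                                           n_perm=300,
                                           seed=300 + run).p_value
            p_shuf = shuffle_test(scan, gene_ids, genes, quantile=0.99,
                                  flank=1000, n_perm=300,
                                  seed=300 + run).p_value
            if p_shuf < p_rot:
                rot_larger += 1
        assert rot_larger > runs / 2


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_qvalues(np.array([0.03])), [0.03])

    def test_step_up_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_order_preserving(self):
        rng = np.random.default_rng(15)
        p = rng.random(50)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_qvalues(np.array([]))
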