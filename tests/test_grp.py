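"""The Gene Removal Procedure: pools, sampling, correction, full runs."""

import numpy as np
import pytest

from grpsig.catalog import Signature
from grpsig.errors import DegenerateInputError
from grpsig.grp import (
    ALL,
    GenePool,
    GrpConfig,
    TermLevelSet,
    bm_term_levels,
    bonferroni,
    build_pool,
    run_grp,
    sample_random_sets,
    summarize,
)
from grpsig.ontology import Annotation, Ontology, meaning, meaning_overlap
from grpsig.synthetic import SyntheticConfig, make_annotation, make_cohort, make_ontology


def _sig(name, genes):
    return Signature(name=name, genes=frozenset(genes))


class TestBmTermLevels:
    def test_direct_lookup_with_levels(self, toy_ontology):
        ann = Annotation({1: frozenset({"GO3", "GO4"})}, toy_ontology)
        tls = bm_term_levels(_sig("s", {1}), ann, toy_ontology)
        assert tls.levels == {"GO3": 2, "GO4": 2}
        assert tls.l_min == 2

    def test_shared_term_listed_once(self, toy_ontology):
        ann = Annotation(
            {1: frozenset({"GO1"}), 2: frozenset({"GO1"})}, toy_ontology
        )
        tls = bm_term_levels(_sig("s", {1, 2}), ann, toy_ontology)
        assert len(tls) == 1

    def test_terms_can_outnumber_genes(self, toy_ontology):
        # 3 genes, 5 distinct terms: m <= t
        ann = Annotation(
            {
                1: frozenset({"GO1", "GO2"}),
                2: frozenset({"GO2", "GO3"}),
                3: frozenset({"GO4", "BP_ROOT"}),
            },
            toy_ontology,
        )
        tls = bm_term_levels(_sig("s", {1, 2, 3}), ann, toy_ontology)
        assert len(tls) == 5 >= 3

    def test_unannotated_signature_gives_empty_set(self, toy_ontology, caplog):
        ann = Annotation({1: frozenset({"GO1"})}, toy_ontology)
        with caplog.at_level("WARNING"):
            tls = bm_term_levels(_sig("s", {99}), ann, toy_ontology)
        assert len(tls) == 0


class TestBuildPool:
    @pytest.fixture
    def setup(self, toy_ontology):
        universe = frozenset(range(1, 11))
        ann = Annotation(
            {1: frozenset({"GO1"}), 5: frozenset({"GO1"}), 9: frozenset({"GO1"})},
            toy_ontology,
        )
        sig = _sig("bm", {1})
        tls = bm_term_levels(sig, ann, toy_ontology)
        return universe, sig, ann, tls

    def test_manual_set_subtraction(self, setup):
        universe, sig, ann, tls = setup
        pool = build_pool(universe, sig, GrpConfig(), tls, ann, ALL)
        assert pool.genes == {2, 3, 4, 6, 7, 8, 10}

    def test_unannotated_signature_removes_only_itself(self, toy_ontology):
        ann = Annotation({5: frozenset({"GO1"})}, toy_ontology)
        sig = _sig("bm", {1})
        tls = bm_term_levels(sig, ann, toy_ontology)
        pool = build_pool(frozenset(range(1, 11)), sig, GrpConfig(), tls, ann, ALL)
        assert pool.genes == frozenset(range(2, 11))

    def test_proliferation_removal(self, setup):
        universe, sig, ann, tls = setup
        cfg = GrpConfig(remove_proliferation=True, proliferation_genes=frozenset({2}))
        pool = build_pool(universe, sig, cfg, tls, ann, ALL)
        assert 2 not in pool.genes
        assert pool.removed_proliferation == {2}

    def test_stage_level_is_cumulative_deepest_first(self, toy_ontology):
        # GO3 at level 2, GO1 at level 1: stage 2 removes only GO3 genes,
        # stage 1 removes both
        ann = Annotation(
            {
                1: frozenset({"GO1", "GO3"}),
                4: frozenset({"GO3"}),
                5: frozenset({"GO1"}),
            },
            toy_ontology,
        )
        sig = _sig("bm", {1})
        tls = bm_term_levels(sig, ann, toy_ontology)
        universe = frozenset(range(1, 8))
        deep = build_pool(universe, sig, GrpConfig(), tls, ann, 2)
        shallow = build_pool(universe, sig, GrpConfig(), tls, ann, 1)
        assert deep.genes == universe - {1, 4}
        assert shallow.genes == universe - {1, 4, 5}
        assert shallow.genes <= deep.genes


class TestSampleRandomSets:
    def _pool(self, genes):
        return GenePool(frozenset(genes), frozenset(), frozenset(), frozenset(), ALL)

    def test_full_size_draw_is_forced(self):
        pool = self._pool(range(1, 6))
        sets = sample_random_sets(pool, 5, 3, rng=0)
        assert all(s == pool.genes for s in sets)

    def test_seed_reproducibility(self):
        pool = self._pool(range(100))
        assert sample_random_sets(pool, 10, 5, rng=42) == sample_random_sets(
            pool, 10, 5, rng=42
        )

    def test_oversized_request_is_an_error(self):
        with pytest.raises(DegenerateInputError):
            sample_random_sets(self._pool({1, 2}), 3, 1, rng=0)

    def test_single_gene_draws_are_uniform(self):
        pool = self._pool(range(10))
        draws = sample_random_sets(pool, 1, 10_000, rng=7)
        counts = np.bincount([next(iter(s)) for s in draws], minlength=10)
        # Binomial(10000, 0.1): 3 sigma ~ 90
        assert np.all(np.abs(counts - 1000) < 3 * np.sqrt(10_000 * 0.1 * 0.9))


class TestBonferroni:
    def test_multiplication(self):
        assert bonferroni([0.0001], 1000)[0] == pytest.approx(0.1)

    def test_cap_at_one(self):
        assert bonferroni([0.01], 1000)[0] == 1.0

    def test_m_one_is_identity(self):
        p = [0.3, 0.7, 0.001]
        assert np.allclose(bonferroni(p, 1), p)

    def test_order_preserving_and_never_decreasing(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(50))
        corrected = bonferroni(p, 17)
        assert np.all(corrected >= p)
        assert np.all(np.diff(corrected) >= 0)
        assert np.all(corrected <= 1)


class TestSummarize:
    def test_degenerate_all_ones(self):
        s = summarize(np.ones(100), alpha=0.05)
        assert (s.median_p, s.q03_p, s.frac_significant) == (1.0, 1.0, 0.0)

    def test_fraction_counts_strictly_below_alpha(self):
        p = np.array([0.01] * 5 + [0.5] * 95)
        assert summarize(p, 0.05).frac_significant == pytest.approx(0.05)

    def test_lower_third_percentile_on_uniform_grid(self):
        grid = np.arange(1, 1001) / 1000.0
        # type-7 linear interpolation oracle: h = 0.03 * 999 = 29.97
        h = 0.03 * 999
        expected = grid[29] + (h - 29) * (grid[30] - grid[29])
        assert summarize(grid).q03_p == pytest.approx(expected, abs=1e-15)


@pytest.fixture(scope="module")
def grp_world():
    """Small synthetic world for full GRP runs (fast: 300 genes)."""
    cfg = SyntheticConfig(n_genes=300, n_samples=100, module_size=6, seed=5)
    cohort, _ = make_cohort(cfg, 5)
    ontology = make_ontology(depth=3, branching=2, categories=("BP",), seed=5)
    annotation = make_annotation(
        sorted(cohort.genes), ontology, density=1.5, seed=5
    )
    signature = _sig("PLANTED", set(range(1, 7)))
    return cohort, ontology, annotation, signature


class TestRunGrp:
    def test_single_level_signature_runs_one_stage(self, toy_ontology, small_cohort):
        # all signature terms at one level: L_max == L_min, one stage == ALL pool
        ann_map = {g: frozenset({"GO1"}) for g in range(1, 9)}
        ann_map.update({g: frozenset({"GO2"}) for g in range(9, 30)})
        ann = Annotation(ann_map, toy_ontology)
        sig = _sig("s", set(range(1, 9)))
        cfg = GrpConfig(n_random_sets=20, seed=1)
        result = run_grp(small_cohort, sig, toy_ontology, ann, cfg)
        assert len(result.stages) == 1
        all_pool = build_pool(
            frozenset(small_cohort.expr.index), sig, cfg,
            TermLevelSet({"GO1": 1}), ann, ALL,
        )
        assert result.stages[0].pool_size == len(all_pool.genes)

    def test_final_stage_sets_are_meaning_disjoint(self, grp_world):
        cohort, ontology, annotation, signature = grp_world
        cfg = GrpConfig(n_random_sets=50, seed=3)
        result = run_grp(cohort, signature, ontology, annotation, cfg)
        bm_meaning = meaning(signature.genes, annotation, "BP")
        final = result.stages[-1]
        for rgs in final.sets:
            assert not meaning_overlap(meaning(rgs, annotation, "BP"), bm_meaning)

    def test_pool_monotone_across_stages(self, grp_world):
        cohort, ontology, annotation, signature = grp_world
        result = run_grp(
            cohort, signature, ontology, annotation, GrpConfig(n_random_sets=5, seed=2)
        )
        sizes = [s.pool_size for s in result.stages]
        assert sizes == sorted(sizes, reverse=True)

    def test_pool_exhaustion_stops_immediately(self, toy_ontology):
        # universe barely larger than the signature: stop before sampling
        cfg = SyntheticConfig(n_genes=12, n_samples=50, module_size=6, seed=9)
        cohort, _ = make_cohort(cfg, 9)
        ann = Annotation(
            {g: frozenset({"GO1"}) for g in range(1, 10)}, toy_ontology
        )
        sig = _sig("s", set(range(1, 7)))
        result = run_grp(cohort, sig, toy_ontology, ann, GrpConfig(n_random_sets=5))
        assert result.stop_reason == "pool-exhausted"
        assert result.stages == []

    def test_signature_absent_from_cohort_is_an_error(self, grp_world):
        cohort, ontology, annotation, _ = grp_world
        with pytest.raises(DegenerateInputError):
            run_grp(cohort, _sig("gone", {99999}), ontology, annotation, GrpConfig())

    def test_bitwise_determinism(self, grp_world):
        cohort, ontology, annotation, signature = grp_world
        cfg = GrpConfig(n_random_sets=25, seed=123)
        a = run_grp(cohort, signature, ontology, annotation, cfg)
        b = run_grp(cohort, signature, ontology, annotation, cfg)
        assert len(a.stages) == len(b.stages)
        for sa, sb in zip(a.stages, b.stages):
            assert (sa.p_raw == sb.p_raw).all()
            assert sa.sets == sb.sets

    def test_corrected_dominate_raw_and_cap(self, grp_world):
        cohort, ontology, annotation, signature = grp_world
        result = run_grp(
            cohort, signature, ontology, annotation, GrpConfig(n_random_sets=30, seed=4)
        )
        for stage in result.stages:
            assert np.all(stage.p_bonferroni >= stage.p_raw)
            assert np.all(stage.p_bonferroni <= 1.0)

    def test_frames_export(self, grp_world):
        cohort, ontology, annotation, signature = grp_world
        result = run_grp(
            cohort, signature, ontology, annotation, GrpConfig(n_random_sets=10, seed=6)
        )
        detail = result.detail_frame()
        summary = result.summary_frame()
        assert len(detail) == 10 * len(result.stages)
        assert set(summary.columns) >= {
            "level", "pool_size", "median_p", "lower_third_percentile_p",
            "frac_significant", "signature_p", "stop_reason",
        }
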