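"""Block construction, nearest-neighbor distances, null sampling, rank tests."""

import itertools

import numpy as np
import pytest

from cnc4c import (
    CIRSet,
    GenomicInterval,
    NullConfig,
    RestrictionFragment,
    build_nonexonic_blocks,
    distance_sample,
    nearest_block,
    nearest_block_scores,
    pool_samples,
    qq_points,
    sample_null_fragments,
    wilcoxon_rank_sum,
)


def iv(chrom, start, end, score=600.0, name=None):
    return GenomicInterval(chrom, start, end, name=name, score=score)


def brute_force_subtract(blocks, exons):
    """Oracle: per-bp membership arithmetic."""
    out = []
    for b in blocks:
        covered = set(range(b.start, b.end))
        for e in exons:
            if e.chrom == b.chrom:
                covered -= set(range(e.start, e.end))
        for _, grp in itertools.groupby(
            enumerate(sorted(covered)), key=lambda t: t[1] - t[0]
        ):
            pos = [g[1] for g in grp]
            out.append((b.chrom, pos[0], pos[-1] + 1, b.score))
    return sorted(out)


class TestBuildNonexonicBlocks:
    def test_exon_splits_block_and_pieces_inherit_score(self):
        blocks = build_nonexonic_blocks([iv("c1", 0, 100, 600)], [iv("c1", 40, 60)])
        assert [(b.start, b.end, b.score) for b in blocks.blocks] == [
            (0, 40, 600), (60, 100, 600)
        ]

    def test_block_inside_exon_removed(self):
        blocks = build_nonexonic_blocks([iv("c1", 50, 80)], [iv("c1", 0, 100)])
        assert blocks.blocks == []

    def test_no_exons_is_identity(self):
        src = [iv("c1", 0, 100), iv("c1", 200, 300), iv("c2", 5, 50)]
        blocks = build_nonexonic_blocks(src, [])
        assert blocks.blocks == src

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            blocks = []
            pos = 0
            for _ in range(rng.integers(1, 8)):
                pos += int(rng.integers(1, 50))
                end = pos + int(rng.integers(1, 60))
                blocks.append(iv("c1", pos, end, float(rng.integers(500, 700))))
                pos = end
            exons = [
                iv("c1", s, s + int(rng.integers(1, 80)))
                for s in rng.integers(0, 400, size=rng.integers(0, 5))
            ]
            got = build_nonexonic_blocks(blocks, exons)
            assert [
                (b.chrom, b.start, b.end, b.score) for b in got.blocks
            ] == brute_force_subtract(blocks, exons)

    def test_length_conservation(self):
        blocks = [iv("c1", 0, 100), iv("c1", 150, 250)]
        exons = [iv("c1", 90, 160), iv("c1", 200, 210)]
        got = build_nonexonic_blocks(blocks, exons)
        overlap = (100 - 90) + (160 - 150) + (210 - 200)
        assert got.total_length == 200 - overlap


class TestNearestBlock:
    BLOCKS = build_nonexonic_blocks(
        [iv("c1", 300, 400), iv("c1", 950, 1050)], []
    )  # centers 350, 1000

    def test_nearest_of_two(self):
        block, dist = nearest_block(RestrictionFragment("c1", 100, 200), self.BLOCKS)
        assert (block.center, dist) == (350, 200)

    def test_coincident_center(self):
        _, dist = nearest_block(RestrictionFragment("c1", 300, 400), self.BLOCKS)
        assert dist == 0

    def test_tie_resolves_to_smaller_start(self):
        blocks = build_nonexonic_blocks([iv("c1", 0, 100), iv("c1", 600, 700)], [])
        # centers 50 and 650; query center 350 is equidistant (300)
        block, dist = nearest_block(RestrictionFragment("c1", 300, 400), blocks)
        assert dist == 300 and block.start == 0

    def test_no_block_on_chromosome_raises(self):
        with pytest.raises(KeyError):
            nearest_block(RestrictionFragment("cX", 0, 10), self.BLOCKS)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            starts = np.sort(rng.choice(10_000, size=n, replace=False))
            blocks = [iv("c1", int(s), int(s) + int(rng.integers(1, 30))) for s in starts]
            bset = build_nonexonic_blocks(blocks, [])
            for _ in range(20):
                c = int(rng.integers(0, 10_000))
                q = RestrictionFragment("c1", c, c + 2)  # center == c+1
                got_block, got_dist = nearest_block(q, bset)
                want = min(
                    bset.blocks, key=lambda b: (abs(b.center - q.center), b.start)
                )
                assert got_dist == abs(want.center - q.center)
                assert got_block.start == want.start


class TestDistanceSample:
    BLOCKS = build_nonexonic_blocks([iv("c1", 0, 100)], [])

    def make_cirs(self, frags):
        from cnc4c import Bait

        return CIRSet(
            bait=Bait("B1", RestrictionFragment("c1", 0, 10)),
            threshold=50,
            members=[(f, 60) for f in frags],
        )

    def test_one_distance_per_member(self):
        frags = [RestrictionFragment("c1", s, s + 10) for s in (0, 100, 300)]
        s = distance_sample(self.make_cirs(frags), self.BLOCKS)
        assert s.n == 3

    def test_blockless_chromosome_excluded_and_counted(self):
        frags = [
            RestrictionFragment("c1", 0, 10),
            RestrictionFragment("c1", 100, 110),
            RestrictionFragment("cX", 0, 10),
        ]
        s = distance_sample(self.make_cirs(frags), self.BLOCKS)
        assert s.n == 2 and s.n_excluded == 1

    def test_pooling_concatenates(self):
        a = distance_sample(self.make_cirs([RestrictionFragment("c1", 0, 10)]), self.BLOCKS)
        b = distance_sample(self.make_cirs([RestrictionFragment("c1", 200, 220)]), self.BLOCKS)
        pooled = pool_samples([a, b], label="experiment")
        assert pooled.n == 2 and pooled.source_bait_ids == ["B1", "B1"]


class TestNullSampling:
    def test_deterministic_given_seed(self, study_world):
        idx = study_world["index"]
        a = sample_null_fragments(idx, NullConfig(n_samples=100, seed=7))
        b = sample_null_fragments(idx, NullConfig(n_samples=100, seed=7))
        assert a == b

    def test_exhaustive_sample_is_full_set(self, toy_index):
        got = sample_null_fragments(toy_index, NullConfig(n_samples=3, seed=0))
        assert sorted(got, key=lambda f: f.start) == toy_index.all_fragments()

    def test_oversampling_without_replacement_rejected(self, toy_index):
        with pytest.raises(ValueError):
            sample_null_fragments(toy_index, NullConfig(n_samples=4, seed=0))


def exact_rank_sum_p(x, y):
    """Independent oracle: exact null distribution of the rank sum by
    dynamic programming over subsets of {1..n} (counts of size-k subsets
    with each possible sum), tie-free data only."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = sorted(x + y)
    ranks_x = [pooled.index(v) + 1 for v in x]
    u_obs = sum(ranks_x) - n1 * (n1 + 1) / 2
    u_hi = max(u_obs, n1 * n2 - u_obs)
    max_sum = n * (n + 1) // 2
    ways = [[0] * (max_sum + 1) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            row_k, row_km1 = ways[k], ways[k - 1]
            for s in range(max_sum, r - 1, -1):
                row_k[s] += row_km1[s - r]
    total = sum(ways[n1])
    hits = 0
    for s, count in enumerate(ways[n1]):
        u = s - n1 * (n1 + 1) / 2
        if u >= u_hi or u <= n1 * n2 - u_hi:
            hits += count
    return hits / total


class TestWilcoxonRankSum:
    def test_exact_shift_example(self):
        r = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert r.method == "exact" and r.p_value == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        x = np.array([3.0, 1, 4, 1, 5])
        r = wilcoxon_rank_sum(x, x.copy())
        assert r.p_value == pytest.approx(1.0)
        assert r.method == "normal-approximation"  # ties force the approximation

    def test_exact_method_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            vals = rng.choice(10_000, size=16, replace=False).astype(float)
            x, y = list(vals[:8]), list(vals[8:])
            r = wilcoxon_rank_sum(np.array(x), np.array(y))
            assert r.method == "exact"
            assert r.p_value == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        # above the exact-method cutoff (n1 + n2 > 20) the package uses the
        # continuity-corrected normal approximation; it must track the true
        # enumeration p closely
        for _ in range(10):
            vals = rng.choice(10_000, size=22, replace=False).astype(float)
            x, y = list(vals[:11]), list(vals[11:])
            r = wilcoxon_rank_sum(np.array(x), np.array(y))
            assert r.method == "normal-approximation"
            assert abs(r.p_value - exact_rank_sum_p(x, y)) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestQQPoints:
    def test_identical_samples_on_diagonal(self, rng):
        x = rng.uniform(0, 100, size=50)
        pts = qq_points(x, x.copy(), n_quantiles=11)
        assert all(qx == pytest.approx(qy) for qx, qy in pts)

    def test_scale_equivariance(self, rng):
        x = rng.uniform(0, 100, size=50)
        pts = qq_points(x, 2 * x, n_quantiles=11)
        assert all(qy == pytest.approx(2 * qx) for qx, qy in pts)

    def test_two_quantiles_are_extremes(self):
        pts = qq_points(np.array([1.0, 2, 3]), np.array([10.0, 20, 30]), n_quantiles=2)
        assert pts == [(1.0, 10.0), (3.0, 30.0)]


class TestNearestBlockScores:
    BLOCKS = build_nonexonic_blocks([iv("c1", 0, 100, score=710.0)], [])

    def test_score_of_nearest_block(self):
        frags = [RestrictionFragment("c1", s, s + 10) for s in (0, 500, 900)]
        sample, _ = nearest_block_scores(frags, self.BLOCKS)
        assert list(sample.values) == [710.0, 710.0, 710.0]

    def test_self_comparison_not_significant(self):
        frags = [RestrictionFragment("c1", s, s + 10) for s in range(0, 300, 20)]
        sample, result = nearest_block_scores(
            frags, self.BLOCKS, comparison=np.full(15, 710.0)
        )
        assert result is not None and result.p_value == pytest.approx(1.0)
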