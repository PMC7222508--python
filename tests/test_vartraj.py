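from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from clonaltraj.io import GenotypeMatrix, SampleSheet
from clonaltraj.simgen import (
    CANONICAL_SWEEP_COUNTS,
    SimConfig,
    simulate_genotypes,
    sweep_genotypes,
)
from clonaltraj.vartraj import (
    DistanceMatrix,
    MafTrajectory,
    classical_mds,
    hamming_distance,
    per_generation_maf,
    separation_score,
    trajectory_filter,
)


def _matrix(dosages, sheet=None):
    dosages = np.asarray(dosages, dtype=float)
    if sheet is None:
        sheet = SampleSheet.default()
    loci = pd.DataFrame(
        {
            "locus_id": [f"chr1:{100 + i}:A:G" for i in range(len(dosages))],
            "chrom": "chr1",
            "pos": [100 + i for i in range(len(dosages))],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(loci, dosages, sheet)


class TestPerGenerationMaf:
    def test_canonical_sweep_frequencies(self):
        """Allele counts 0,1,2,2,4 over six chromosomes give the
        trajectory 0, 0.166667, 0.333333, 0.333333, 0.666667."""
        (traj,) = per_generation_maf(sweep_genotypes(CANONICAL_SWEEP_COUNTS))
        assert traj.fractions == (
            Fraction(0), Fraction(1, 6), Fraction(1, 3), Fraction(1, 3), Fraction(2, 3),
        )
        assert [round(f, 6) for f in traj.freqs] == [
            0.0, 0.166667, 0.333333, 0.333333, 0.666667,
        ]

    def test_all_reference_gives_zero(self):
        (traj,) = per_generation_maf(_matrix([[0.0] * 15]))
        assert traj.freqs == (0.0,) * 5

    def test_missing_sample_shrinks_denominator(self):
        # g1: one missing, the other two heterozygous -> 2/4
        row = [np.nan, 1, 1] + [0] * 12
        (traj,) = per_generation_maf(_matrix([row]))
        assert traj.fractions[0] == Fraction(1, 2)
        assert traj.callable_chromosomes == (4, 6, 6, 6, 6)

    def test_fully_missing_generation_is_undefined(self):
        row = [np.nan] * 3 + [1] * 12
        (traj,) = per_generation_maf(_matrix([row]))
        assert not traj.defined
        with pytest.raises(ValueError, match="undefined"):
            traj.fractions

    def test_invariant_to_sample_and_locus_order(self):
        rng = np.random.default_rng(42)
        dosages = rng.integers(0, 3, size=(20, 15)).astype(float)
        sheet = SampleSheet.default()
        base = per_generation_maf(_matrix(dosages, sheet))
        perm = rng.permutation(15)
        shuffled_sheet = sheet.reordered([sheet.sample_ids[i] for i in perm])
        shuffled = per_generation_maf(_matrix(dosages[:, perm], shuffled_sheet))
        assert [t.alt_counts for t in base] == [t.alt_counts for t in shuffled]
        locus_perm = rng.permutation(20)
        by_locus = {
            t.locus_id: t.alt_counts
            for t in per_generation_maf(_matrix(dosages[locus_perm], sheet))
        }
        # locus ids are positional in _matrix, so compare the multiset
        assert sorted(by_locus.values()) == sorted(t.alt_counts for t in base)


def _oracle_verdict(freqs, low=Fraction(1, 3), high=Fraction(2, 3)):
    """Direct, independent evaluation of the two filter rules."""
    up = all(a <= b for a, b in zip(freqs, freqs[1:])) and freqs[0] <= low and freqs[-1] >= high
    down = all(a >= b for a, b in zip(freqs, freqs[1:])) and freqs[0] >= high and freqs[-1] <= low
    if up:
        return True, "increasing"
    if down:
        return True, "decreasing"
    return False, "none"


class TestTrajectoryFilter:
    def _traj(self, sixths):
        return MafTrajectory("L", tuple(sixths), (6,) * len(sixths))

    def test_canonical_sweep_passes_increasing(self):
        # the internal tie 2/6, 2/6 forces the non-strict monotone reading
        v = trajectory_filter(self._traj(CANONICAL_SWEEP_COUNTS))
        assert v.passes and v.direction == "increasing"

    def test_flat_intermediate_trajectory_fails(self):
        v = trajectory_filter(self._traj((3, 3, 3, 3, 3)))
        assert not v.passes and v.direction == "none"

    def test_decreasing_sweep_passes(self):
        t = MafTrajectory("L", (8, 7, 5, 4, 2), (10,) * 5)  # 0.8 .. 0.2
        v = trajectory_filter(t)
        assert v.passes and v.direction == "decreasing"

    def test_boundaries_are_inclusive(self):
        v = trajectory_filter(self._traj((2, 2, 3, 4, 4)))  # 1/3 .. 2/3 exactly
        assert v.passes and v.direction == "increasing"

    def test_monotone_but_shallow_fails(self):
        v = trajectory_filter(self._traj((0, 1, 1, 2, 3)))  # ends at 1/2 < 2/3
        assert not v.passes

    def test_undefined_trajectory_rejected(self):
        t = MafTrajectory("L", (0, 0, 0, 0, 0), (0, 6, 6, 6, 6))
        with pytest.raises(ValueError):
            trajectory_filter(t)

    def test_matches_brute_force_oracle_on_full_grid(self):
        """All 7^5 trajectories on the {0, 1/6, ..., 1} grid."""
        for counts in product(range(7), repeat=5):
            t = self._traj(counts)
            v = trajectory_filter(t)
            passes, direction = _oracle_verdict(t.fractions)
            assert (v.passes, v.direction) == (passes, direction), counts

    def test_neutral_cohort_pass_rate_small_and_symmetric(self):
        """Binomially resampled constant-frequency loci rarely pass, with
        no direction bias (two-sided binomial test at alpha 0.01)."""
        rng = np.random.default_rng(2024)
        n = 100_000
        p0 = rng.uniform(0, 1, size=n)
        counts = rng.binomial(6, p0[:, None], size=(n, 5))
        n_up = n_down = 0
        for row in counts:
            v = trajectory_filter(MafTrajectory("L", tuple(row), (6,) * 5))
            n_up += v.direction == "increasing"
            n_down += v.direction == "decreasing"
        assert 0 < (n_up + n_down) / n < 0.05
        assert stats.binomtest(n_up, n_up + n_down, 0.5).pvalue > 0.01

    def test_planted_recovery_noise_free(self):
        """With deterministic allele-count paths, planted monotone loci
        are recovered with recall 1 and constant loci never pass."""
        cfg = SimConfig(
            seed=9, noise_sd=0.0, n_loci=500,
            frac_selected_up=0.04, frac_selected_down=0.04,
            n_genes=100, n_planted_degs=5, n_eqtl_links=5,
            n_mirnas=10, n_target_pairs=5, n_concordant_pairs=3,
            n_immune_genes=10, n_immune_candidates=2,
        )
        g, truth = simulate_genotypes(cfg)
        verdicts = {
            t.locus_id: trajectory_filter(t) for t in per_generation_maf(g)
        }
        expected_dir = {"selected_up": "increasing", "selected_down": "decreasing"}
        for locus_id, cls in zip(truth["locus_id"], truth["class"]):
            v = verdicts[locus_id]
            if cls == "neutral":
                assert not v.passes
            else:
                assert v.passes and v.direction == expected_dir[cls]


class TestHammingDistance:
    def test_identical_columns_are_zero(self):
        d = hamming_distance(_matrix(np.ones((10, 15))))
        assert np.all(d.d == 0)

    def test_hand_counted_proportion(self):
        sheet = SampleSheet(("a", "b"), (1, 1), (1, 2))
        dosages = np.zeros((10, 2))
        dosages[:3, 1] = 2  # differ at 3 of 10 loci
        d = hamming_distance(_matrix(dosages, sheet))
        assert d.d[0, 1] == pytest.approx(0.3)

    def test_pairwise_missing_loci_skipped(self):
        sheet = SampleSheet(("a", "b"), (1, 1), (1, 2))
        dosages = np.array([[0, 2], [np.nan, 2], [1, np.nan], [0, 0]], dtype=float)
        d = hamming_distance(_matrix(dosages, sheet))
        assert d.d[0, 1] == pytest.approx(1 / 2)  # 1 mismatch over 2 usable loci

    def test_no_mutually_callable_loci_raises(self):
        sheet = SampleSheet(("a", "b"), (1, 1), (1, 2))
        dosages = np.array([[np.nan, 2], [1, np.nan]], dtype=float)
        with pytest.raises(ValueError, match="a.*b"):
            hamming_distance(_matrix(dosages, sheet))

    def test_invariant_to_locus_order(self):
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(30, 15)).astype(float)
        d1 = hamming_distance(_matrix(dosages))
        d2 = hamming_distance(_matrix(dosages[rng.permutation(30)]))
        np.testing.assert_allclose(d1.d, d2.d)


class TestClassicalMds:
    def _dm(self, d):
        n = len(d)
        return DistanceMatrix(tuple(f"s{i}" for i in range(n)), np.asarray(d, float))

    def test_two_points_embed_at_half_distance(self):
        emb = classical_mds(self._dm([[0, 4], [4, 0]]), k=1)
        assert sorted(emb.coords[:, 0]) == pytest.approx([-2.0, 2.0])

    def test_equilateral_triangle_preserved(self):
        emb = classical_mds(self._dm(1 - np.eye(3)), k=2)
        d = squareform(pdist(emb.coords))
        np.testing.assert_allclose(d, 1 - np.eye(3), atol=1e-9)

    def test_euclidean_configuration_reconstructed(self):
        """Full-rank embedding of a Euclidean distance matrix reproduces
        every pairwise distance to 1e-9."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 4))
        D = squareform(pdist(pts))
        emb = classical_mds(self._dm(D), k=11)
        np.testing.assert_allclose(squareform(pdist(emb.coords)), D, atol=1e-9)

    def test_all_zero_distances_give_zero_coordinates(self):
        emb = classical_mds(self._dm(np.zeros((4, 4))), k=2)
        assert np.all(emb.coords == 0)

    def test_deterministic_sign_convention(self):
        D = squareform(pdist(np.random.default_rng(1).normal(size=(6, 2))))
        a = classical_mds(self._dm(D), k=2)
        b = classical_mds(self._dm(D), k=2)
        np.testing.assert_array_equal(a.coords, b.coords)
        for col in a.coords.T:
            assert col[np.argmax(np.abs(col))] >= 0

    def test_k_limited_by_sample_count(self):
        with pytest.raises(ValueError):
            classical_mds(self._dm(np.zeros((3, 3))), k=3)


class TestSeparationScore:
    def test_well_separated_generations_score_high(self, sheet):
        coords = np.zeros((15, 2))
        coords[12:, 0] = 10.0  # g5 samples far away
        from clonaltraj.vartraj import MdsEmbedding

        e = MdsEmbedding(tuple(sheet.sample_ids), coords, np.zeros(15))
        assert separation_score(e, sheet, {5}) > 0.5

    def test_coincident_samples_score_zero(self, sheet):
        from clonaltraj.vartraj import MdsEmbedding

        e = MdsEmbedding(tuple(sheet.sample_ids), np.ones((15, 2)), np.zeros(15))
        assert separation_score(e, sheet, {5}) == 0.0

    def test_filtering_sharpens_generation5_separation(self):
        """Planted-selection cohort: the P5 silhouette is higher on
        filter-passing loci than on all loci."""
        cfg = SimConfig(seed=21, frac_selected_up=0.025, frac_selected_down=0.025)
        g, _ = simulate_genotypes(cfg)
        trajs = per_generation_maf(g)
        passing = [
            t.locus_id for t in trajs if t.defined and trajectory_filter(t).passes
        ]
        s_all = separation_score(
            classical_mds(hamming_distance(g)), g.sample_sheet, {5}
        )
        s_filt = separation_score(
            classical_mds(hamming_distance(g, passing)), g.sample_sheet, {5}
        )
        assert s_filt > s_all
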