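"""Manhattan-distance ranking, evaluation, and global assignment."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cityblock

from osteomatch import (
    Assemblage,
    BoneType,
    ComputationError,
    LandmarkConfiguration,
    Side,
    SimulationParams,
    evaluate_rankings,
    generate_assemblage,
    global_assignment,
    manhattan_distance,
    minimum_cost_assignment,
    rank_all,
    rank_candidates,
    template_pair,
)
from osteomatch.matching import MatchRanking
from conftest import make_config, random_rotation


class TestManhattanDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([0, 0, 0, 1, 0, 0], [0, 1, 0, 1, 1, 0], 2.0),
            ([1.5], [-2.5], 4.0),
        ],
    )
    def test_hand_examples(self, x, y, expected):
        assert manhattan_distance(x, y) == expected

    def test_matches_scipy_cityblock(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=33), rng.normal(size=33)
            assert manhattan_distance(x, y) == pytest.approx(cityblock(x, y), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ComputationError, match="length mismatch"):
            manhattan_distance([1, 2], [1, 2, 3])


def _naive_gpa_unit_shapes(arrays, n_iter=200):
    """Independent plain-loop GPA used as an oracle (no shared code path).

    Manhattan distances depend on the orientation of the shared coordinate
    frame, so the oracle also pins the frame the same way: consensus on its
    principal axes, first two axis signs by largest-magnitude loading,
    third axis the cross product.
    """
    shapes = []
    for a in arrays:
        c = a - a.mean(axis=0)
        shapes.append(c / np.sqrt((c**2).sum()))
    consensus = shapes[0]
    for _ in range(n_iter):
        rotated = []
        for s in shapes:
            u, _, vt = np.linalg.svd(s.T @ consensus)
            r = u @ vt
            if np.linalg.det(r) < 0:
                u[:, -1] *= -1
                r = u @ vt
            rotated.append(s @ r)
        shapes = rotated
        consensus = np.mean(shapes, axis=0)
    evals, evecs = np.linalg.eigh(consensus.T @ consensus)
    axes = evecs[:, np.argsort(evals)[::-1]]
    for j in range(2):
        if axes[np.argmax(np.abs(axes[:, j])), j] < 0:
            axes[:, j] = -axes[:, j]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return [s @ axes for s in shapes]


class TestRankCandidates:
    def test_zero_noise_true_pair_ranks_first_among_decoys(self, rng):
        params = SimulationParams(
            n_individuals=10, digitization_sd=0.0, shape_sd=0.05, seed=42
        )
        asm, gt = generate_assemblage(params)
        truth = gt.acetabulum_to_femur()
        query = asm.acetabula[0]
        ranking = rank_candidates(query, asm.femora)
        assert ranking.candidates[0][0] == truth[query.specimen_id]
        assert ranking.candidates[0][1] < 1e-8

    def test_candidate_order_invariance(self, rng):
        asm, _ = generate_assemblage(SimulationParams(n_individuals=6, seed=5))
        query = asm.acetabula[0]
        fwd = rank_candidates(query, asm.femora)
        rev = rank_candidates(query, asm.femora[::-1])
        assert fwd.candidate_ids == rev.candidate_ids
        for (_, da), (_, db) in zip(fwd.candidates, rev.candidates):
            assert db == pytest.approx(da, abs=1e-10)

    def test_similarity_transform_of_an_input_leaves_ranking_distances(self, rng):
        asm, _ = generate_assemblage(SimulationParams(n_individuals=6, seed=9))
        query = asm.acetabula[0]
        ref = rank_candidates(query, asm.femora)
        femora = list(asm.femora)
        moved = 3.0 * femora[2].coords @ random_rotation(rng).T + np.array([9.0, 0, -4])
        femora[2] = femora[2].with_coords(moved)
        out = rank_candidates(query, femora)
        assert out.candidate_ids == ref.candidate_ids
        for (_, da), (_, db) in zip(ref.candidates, out.candidates):
            assert db == pytest.approx(da, abs=1e-8)

    def test_ranking_matches_independent_recomputation(self):
        asm, _ = generate_assemblage(SimulationParams(n_individuals=10, seed=77))
        query = asm.acetabula[0]
        ranking = rank_candidates(query, asm.femora)

        arrays = [query.coords] + [f.coords for f in asm.femora]
        shapes = _naive_gpa_unit_shapes(arrays)
        dists = {
            f.specimen_id: float(np.abs(shapes[0] - shapes[i + 1]).sum())
            for i, f in enumerate(asm.femora)
        }
        expected = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
        assert ranking.candidate_ids == tuple(k for k, _ in expected)
        for (cid, d), (cid2, d2) in zip(ranking.candidates, expected):
            assert d == pytest.approx(d2, abs=1e-8)

    def test_bone_type_and_side_errors(self, rng):
        acet = make_config(rng, "A", BoneType.ACETABULUM)
        fem = make_config(rng, "F", BoneType.FEMUR)
        with pytest.raises(ComputationError, match="not an acetabulum"):
            rank_candidates(fem, [fem])
        with pytest.raises(ComputationError, match="not a femur"):
            rank_candidates(acet, [acet])
        with pytest.raises(ComputationError, match="at least one"):
            rank_candidates(acet, [])
        left_fem = make_config(rng, "F2", BoneType.FEMUR, side=Side.LEFT)
        with pytest.raises(ComputationError, match="mixed sides"):
            rank_candidates(acet, [fem, left_fem])


class TestSizeConfound:
    def test_scaling_removes_the_size_confound(self, rng):
        """Same-size/different-shape decoy wins without scaling; scaling fixes it.

        The true femur shares the query's articular shape but is 30% larger;
        the decoy has a clearly different shape at exactly the query's size.
        In raw (unscaled) coordinate space near-identical size dominates the
        distance, so the decoy outranks the true match; removing size by
        scaling reverses the ranking.
        """
        acet_t, fem_t = template_pair()
        query = LandmarkConfiguration("Q", BoneType.ACETABULUM, Side.RIGHT, acet_t.coords)
        true_fem = LandmarkConfiguration(
            "F_true", BoneType.FEMUR, Side.RIGHT, acet_t.coords * 1.3
        )
        decoy_coords = acet_t.coords.copy()
        decoy_coords[:, 2] *= 0.3  # flatten the cup: clearly different shape
        decoy_coords[:, 0] *= 1.15
        from osteomatch import centroid_size

        decoy_coords *= centroid_size(acet_t.coords) / centroid_size(decoy_coords)
        decoy = LandmarkConfiguration("F_decoy", BoneType.FEMUR, Side.RIGHT, decoy_coords)

        unscaled = rank_candidates(query, [true_fem, decoy], scale=False)
        assert unscaled.candidates[0][0] == "F_decoy"
        scaled = rank_candidates(query, [true_fem, decoy], scale=True)
        assert scaled.candidates[0][0] == "F_true"


class TestRankAll:
    def test_single_pair_assemblage(self, rng):
        asm = Assemblage(
            [make_config(rng, "A", BoneType.ACETABULUM), make_config(rng, "F", BoneType.FEMUR)]
        )
        rankings = rank_all(asm)
        assert len(rankings) == 1
        assert rankings[0].candidate_ids == ("F",)

    def test_zero_noise_all_true_matches_rank_first(self, zero_noise_assemblage):
        asm, gt = zero_noise_assemblage
        report = evaluate_rankings(rank_all(asm), gt.acetabulum_to_femur())
        assert report.first_indication_rate == 100.0
        assert report.mean_rank_error == 0.0

    def test_shared_gpa_mode_agrees_at_zero_noise(self, zero_noise_assemblage):
        asm, gt = zero_noise_assemblage
        report = evaluate_rankings(
            rank_all(asm, shared_gpa=True), gt.acetabulum_to_femur()
        )
        assert report.first_indication_rate == 100.0

    def test_requires_both_bone_types(self, rng):
        only_fem = Assemblage([make_config(rng, "F", BoneType.FEMUR)])
        with pytest.raises(ComputationError, match="no acetabula"):
            rank_all(only_fem)
        only_acet = Assemblage([make_config(rng, "A", BoneType.ACETABULUM)])
        with pytest.raises(ComputationError, match="no femora"):
            rank_all(only_acet)


class TestEvaluateRankings:
    @staticmethod
    def _ranking(query, ordered_ids):
        return MatchRanking(
            query, tuple((cid, float(i)) for i, cid in enumerate(ordered_ids)), True
        )

    def test_all_first_indications(self):
        rankings = [self._ranking("A1", ["F1", "F2"]), self._ranking("A2", ["F2", "F1"])]
        report = evaluate_rankings(rankings, {"A1": "F1", "A2": "F2"})
        assert report.first_indication_rate == 100.0
        assert report.mean_rank_error == 0.0
        assert report.rank_histogram == {1: 2}

    def test_hand_counted_mixed_ranks(self):
        truth = {f"A{i}": f"F{i}" for i in range(1, 5)}
        rankings = [
            self._ranking("A1", ["F1", "F2", "F3", "F4"]),
            self._ranking("A2", ["F3", "F2", "F1", "F4"]),
            self._ranking("A3", ["F1", "F3", "F2", "F4"]),
            self._ranking("A4", ["F4", "F1", "F2", "F3"]),
        ]
        report = evaluate_rankings(rankings, truth)
        assert report.first_indication_rate == 50.0
        assert report.within_top_k_rate[2] == 100.0
        assert report.mean_rank_error == 0.5
        assert report.rank_histogram == {1: 2, 2: 2}
        assert report.per_query_ranks == {"A1": 1, "A2": 2, "A3": 2, "A4": 1}

    def test_simulated_report_matches_hand_tally(self):
        asm, gt = generate_assemblage(
            SimulationParams(n_individuals=8, digitization_sd=1.5, seed=13)
        )
        truth = gt.acetabulum_to_femur()
        rankings = rank_all(asm)
        report = evaluate_rankings(rankings, truth)
        tally: dict[int, int] = {}
        for r in rankings:
            rank = list(r.candidate_ids).index(truth[r.query_id]) + 1
            tally[rank] = tally.get(rank, 0) + 1
        assert report.rank_histogram == tally
        assert report.n_queries == 8

    def test_absent_true_match_is_unmatchable(self):
        rankings = [self._ranking("A1", ["F2", "F3"])]
        report = evaluate_rankings(rankings, {"A1": "F1"})
        assert report.n_queries == 0
        assert report.n_unmatchable == 1
        assert report.unmatchable_ids == ("A1",)


class TestGlobalAssignment:
    def test_two_by_two_diagonal(self):
        rows, cols, total = minimum_cost_assignment(np.array([[1.0, 10.0], [10.0, 1.0]]))
        assert total == 2.0
        assert dict(zip(rows, cols)) == {0: 0, 1: 1}

    def test_matches_exhaustive_search_on_random_matrices(self, rng):
        for _ in range(50):
            cost = rng.uniform(0, 10, size=(6, 6))
            _, _, total = minimum_cost_assignment(cost)
            brute = min(
                sum(cost[i, p[i]] for i in range(6))
                for p in itertools.permutations(range(6))
            )
            assert total == pytest.approx(brute, rel=1e-12)

    def test_zero_noise_assignment_recovers_truth(self, zero_noise_assemblage):
        asm, gt = zero_noise_assemblage
        out = global_assignment(asm.acetabula, asm.femora)
        assert out.pairs == gt.acetabulum_to_femur()
        assert out.note == "extension"
        assert not out.unassigned_acetabula and not out.unassigned_femora

    def test_unequal_counts_leave_excess_unassigned(self, zero_noise_assemblage):
        asm, _ = zero_noise_assemblage
        out = global_assignment(asm.acetabula, asm.femora[:7])
        assert len(out.pairs) == 7
        assert len(out.unassigned_acetabula) == 3

    def test_total_cost_not_above_greedy_matching(self, rng):
        """The optimal assignment never costs more than greedy first-come matching.

        Each query in turn takes its closest *remaining* femur (first
        indication among candidates not yet claimed), which yields a feasible
        one-to-one matching; the optimal assignment can only do better.
        """
        asm, _ = generate_assemblage(
            SimulationParams(n_individuals=8, digitization_sd=2.0, seed=21)
        )
        out = global_assignment(asm.acetabula, asm.femora)
        rankings = rank_all(asm, shared_gpa=True)
        taken: set[str] = set()
        greedy = 0.0
        for r in rankings:
            cid, d = next(c for c in r.candidates if c[0] not in taken)
            taken.add(cid)
            greedy += d
        assert out.total_cost <= greedy + 1e-9


class TestNoiseDegradation:
    def test_accuracy_degrades_with_digitization_noise(self):
        """Mean first-indication rate falls (weakly) as placement noise grows."""
        levels = [0.0, 1.0, 4.0]
        means = []
        for sd in levels:
            rates = []
            for s in range(8):
                asm, gt = generate_assemblage(
                    SimulationParams(n_individuals=10, digitization_sd=sd, seed=300 + s)
                )
                rep = evaluate_rankings(rank_all(asm), gt.acetabulum_to_femur())
                rates.append(rep.first_indication_rate)
            means.append(np.mean(rates))
        assert means[0] == 100.0
        assert means[0] >= means[1] >= means[2]
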