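"""Density-diversity prototype selection and expert review."""

import numpy as np
import pytest

from gliomavote.embedding import similarity_matrix
from gliomavote.prototypes import (
    DegenerateCategoryError,
    ExpertReview,
    PrototypeSet,
    SelectionConfig,
    apply_expert_review,
    auto_review,
    build_prototype_set,
    density,
    diversity,
    priority_order,
    select_prototypes,
    similarity_threshold,
)

THREE = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)  # s12=1, s13=s23=0


def brute_density(S, s_t):
    m = len(S)
    return np.array([sum(1 for j in range(m) if j != i and S[i, j] > s_t) for i in range(m)])


def brute_diversity(S, rho):
    m = len(S)
    order = sorted(range(m), key=lambda i: (-rho[i], i))
    delta = np.empty(m)
    for pos, i in enumerate(order):
        if pos == 0:
            continue
        delta[i] = min(1 - S[i, j] for j in order[:pos])
    delta[order[0]] = max(delta[i] for i in order[1:]) if m > 1 else 1.0
    return delta


class TestSimilarityThreshold:
    def test_mean_of_off_diagonal_pairs(self):
        assert similarity_threshold(similarity_matrix(THREE)) == pytest.approx(1 / 3)

    def test_identical_vectors_give_one(self):
        S = similarity_matrix(np.ones((4, 3)))
        assert similarity_threshold(S) == pytest.approx(1.0)

    def test_single_pair(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert similarity_threshold(S) == pytest.approx(0.4)

    def test_too_small_matrix_errors(self):
        with pytest.raises(ValueError):
            similarity_threshold(np.ones((1, 1)))


class TestDensity:
    def test_three_vector_hand_case(self):
        S = similarity_matrix(THREE)
        assert density(S, similarity_threshold(S)).tolist() == [1, 1, 0]

    def test_all_identical_vectors_strict_inequality(self):
        S = similarity_matrix(np.ones((5, 3)))
        assert density(S, 1.0).tolist() == [0] * 5

    def test_two_patch_boundary_is_strict(self):
        S = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert density(S, 0.9).tolist() == [0, 0]

    def test_signed_variant_is_affine_in_count(self):
        rng = np.random.default_rng(3)
        S = similarity_matrix(rng.normal(size=(15, 6)))
        s_t = similarity_threshold(S)
        count = density(S, s_t)
        signed = density(S, s_t, signed=True)
        assert np.allclose(signed, 2 * count - (len(S) - 1))

    def test_duplicate_patch_never_decreases_density(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        S = similarity_matrix(X)
        rho = density(S, similarity_threshold(S))
        X2 = np.vstack([X, X[0]])
        S2 = similarity_matrix(X2)
        rho2 = density(S2, similarity_threshold(S))  # same threshold, larger set
        assert np.all(rho2[:10] >= rho)


class TestDiversity:
    def test_three_vector_hand_case(self):
        S = similarity_matrix(THREE)
        rho = density(S, similarity_threshold(S))
        assert diversity(S, rho) == pytest.approx([1.0, 0.0, 1.0])

    def test_identical_vectors_all_zero_with_max_rule_head(self):
        S = similarity_matrix(np.ones((4, 3)))
        delta = diversity(S, density(S, 1.0))
        assert delta == pytest.approx([0.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        X = np.random.default_rng(seed).normal(size=(20, 6))
        S = similarity_matrix(X)
        rho = density(S, similarity_threshold(S))
        assert np.max(np.abs(diversity(S, rho) - brute_diversity(S, rho))) < 1e-12

    def test_head_of_ranking_has_maximal_rho_and_delta(self):
        X = np.random.default_rng(77).normal(size=(25, 5))
        S = similarity_matrix(X)
        rho = density(S, similarity_threshold(S))
        delta = diversity(S, rho)
        head = priority_order(rho)[0]
        assert rho[head] == rho.max()
        assert delta[head] == delta.max()
        assert np.all((delta >= 0) & (delta <= 2))


class TestSelectPrototypes:
    def test_three_vector_walkthrough(self):
        S = similarity_matrix(THREE)
        rho = density(S, similarity_threshold(S))
        delta = diversity(S, rho)
        selected = select_prototypes(S, rho, delta, SelectionConfig(k_prototypes=2))
        assert selected == [0, 2]

    def test_identical_vectors_select_only_head(self):
        S = similarity_matrix(np.ones((6, 3)))
        rho = density(S, 1.0)
        delta = diversity(S, rho)
        assert select_prototypes(S, rho, delta, SelectionConfig(k_prototypes=5)) == [0]

    def test_respects_budget_and_gate(self):
        X = np.random.default_rng(5).normal(size=(40, 6))
        S = similarity_matrix(X)
        rho = density(S, similarity_threshold(S))
        delta = diversity(S, rho)
        cfg = SelectionConfig(k_prototypes=10)
        selected = select_prototypes(S, rho, delta, cfg)
        assert len(selected) <= 10
        thr = delta.mean()
        head = priority_order(rho)[0]
        for i in selected:
            if i != head:
                assert delta[i] > thr

    def test_fixed_threshold_mode(self):
        X = np.random.default_rng(6).normal(size=(30, 4))
        S = similarity_matrix(X)
        rho = density(S, similarity_threshold(S))
        delta = diversity(S, rho)
        loose = select_prototypes(S, rho, delta,
                                  SelectionConfig(k_prototypes=30, delta_threshold_mode="fixed",
                                                  delta_threshold_value=0.0))
        tight = select_prototypes(S, rho, delta,
                                  SelectionConfig(k_prototypes=30, delta_threshold_mode="fixed",
                                                  delta_threshold_value=1.9))
        assert len(loose) >= len(tight)

    def test_empty_category_errors(self):
        with pytest.raises(DegenerateCategoryError):
            select_prototypes(np.zeros((0, 0)), np.array([]), np.array([]))

    def test_permutation_equivariance(self):
        # ties in the integer densities are broken by original index, so the
        # selection is equivariant under permutations that keep tied patches
        # in their original relative order
        X = np.random.default_rng(9).normal(size=(15, 5))
        S = similarity_matrix(X)
        s_t = similarity_threshold(S)
        rho = density(S, s_t)
        delta = diversity(S, rho)
        sel = select_prototypes(S, rho, delta, SelectionConfig(k_prototypes=6))

        raw = np.random.default_rng(10).permutation(15)
        perm = raw.copy()
        positions: dict[int, list[int]] = {}
        for p, i in enumerate(raw):
            positions.setdefault(int(rho[i]), []).append(p)
        for ps in positions.values():
            for p, i in zip(sorted(ps), sorted(raw[p] for p in ps)):
                perm[p] = i

        Sp = S[np.ix_(perm, perm)]
        rho_p = density(Sp, s_t)
        assert np.array_equal(rho_p, rho[perm])
        delta_p = diversity(Sp, rho_p)
        assert np.allclose(delta_p, delta[perm])
        sel_p = select_prototypes(Sp, rho_p, delta_p, SelectionConfig(k_prototypes=6))
        assert sorted(int(perm[i]) for i in sel_p) == sorted(sel)


class TestExpertReview:
    @pytest.fixture()
    def sets(self, class_features):
        out = {}
        for cat in ("A", "O", "G"):
            X = class_features[cat]
            ids = [f"{cat}{i}" for i in range(len(X))]
            out[cat] = build_prototype_set(cat, X, ids, SelectionConfig(k_prototypes=10))
        return out

    def test_empty_review_is_identity(self, sets):
        revised = apply_expert_review(sets, ExpertReview())
        assert {c: ps.tile_ids for c, ps in revised.items()} == {
            c: ps.tile_ids for c, ps in sets.items()
        }

    def test_reassignment_moves_counts_to_category_i(self, sets):
        movers = sets["G"].tile_ids[:3]
        before = len(sets["G"])
        revised = apply_expert_review(sets, ExpertReview(reassignments=tuple((t, "I") for t in movers)))
        assert len(revised["G"]) == before - 3
        assert revised["I"].tile_ids == movers
        assert revised["I"].provenance == "expert-reviewed"

    def test_counts_conserved_under_exclusions(self, sets):
        dropped = (sets["A"].tile_ids[0], sets["O"].tile_ids[1])
        revised = apply_expert_review(sets, ExpertReview(exclusions=dropped))
        assert sum(map(len, revised.values())) == sum(map(len, sets.values())) - 2

    def test_unknown_tile_or_category_errors(self, sets):
        with pytest.raises(KeyError):
            apply_expert_review(sets, ExpertReview(exclusions=("nope",)))
        with pytest.raises(ValueError):
            apply_expert_review(sets, ExpertReview(reassignments=((sets["A"].tile_ids[0], "X"),)))

    def test_auto_review_flags_weakly_cohesive_prototypes(self, sets):
        review = auto_review(sets, percentile=20.0)
        assert review.exclusions  # something is always in the bottom quintile
        revised = apply_expert_review(sets, review)
        assert sum(map(len, revised.values())) < sum(map(len, sets.values()))


class TestBuildPrototypeSet:
    def test_metadata_records_selection_state(self, class_features):
        X = class_features["A"]
        ps = build_prototype_set("A", X, [f"a{i}" for i in range(len(X))],
                                 SelectionConfig(k_prototypes=5))
        assert ps.category == "A"
        assert 1 <= len(ps) <= 5
        assert set(ps.metadata) >= {"s_t", "delta_threshold", "rho", "delta", "n_candidates"}
        assert ps.metadata["n_candidates"] == len(X)

    def test_prototype_set_shape_validation(self):
        with pytest.raises(ValueError):
            PrototypeSet(category="A", features=np.ones((2, 3)), tile_ids=["a"])
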