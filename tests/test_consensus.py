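import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvevents.consensus import (
    TrajectoryFactors,
    assign_events,
    build_consensus,
    match_factors,
    tucker_congruence,
)
from cvevents.ordering import FactorSequence
from cvevents.pipeline import analyze_dataset
from cvevents.synth import default_dataset


def block_loadings(noise=0.0, rng=None, permute=None):
    """8 CVs on 2 factors in clean blocks, optionally permuted / perturbed."""
    base = np.zeros((8, 2))
    base[:4, 0] = [0.9, 0.85, 0.8, 0.88]
    base[4:, 1] = [0.87, 0.9, 0.82, 0.86]
    if permute is not None:
        base = base[:, permute]
    if noise and rng is not None:
        base = base + rng.normal(0, noise, base.shape)
    return base


def trajectory_factors(tid, loadings, order=None):
    k = loadings.shape[1]
    fids = [f"f{j}" for j in range(k)]
    groups = [frozenset({f}) for f in (order or fids)]
    return TrajectoryFactors(
        trajectory_id=tid,
        cv_ids=[f"cv{i}" for i in range(loadings.shape[0])],
        factor_ids=fids,
        loadings=loadings,
        sequence=FactorSequence(groups),
    )


class TestTuckerCongruence:
    def test_identical_vectors(self):
        v = np.array([0.9, 0.1, -0.3])
        assert tucker_congruence(v, v) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 1000))
    def test_scale_invariance(self, scale, seed):
        g = np.random.default_rng(seed)
        a = g.normal(size=6)
        b = g.normal(size=6)
        assert tucker_congruence(a, scale * b) == pytest.approx(
            tucker_congruence(a, b), abs=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tucker_congruence(np.zeros(4), np.ones(4))


class TestMatchFactors:
    def test_duplicated_model_matches_perfectly(self):
        models = [trajectory_factors(f"t{i}", block_loadings()) for i in range(3)]
        match = match_factors(models)
        for t in ("t0", "t1", "t2"):
            assert set(match.mapping[t].values()) == {"CF1", "CF2"}
            for phi in match.congruence[t].values():
                assert abs(phi) == pytest.approx(1.0)

    def test_sign_flipped_column_still_matches(self):
        flipped = block_loadings().copy()
        flipped[:, 1] *= -1.0
        models = [
            trajectory_factors("ref", block_loadings()),
            trajectory_factors("flip", flipped),
        ]
        match = match_factors(models)
        assert set(match.mapping["flip"].values()) == {"CF1", "CF2"}
        assert abs(list(match.congruence["flip"].values())[0]) == pytest.approx(1.0)

    def test_permuted_noisy_replicates_recover_planted_permutation(self):
        wins = 0
        for seed in range(50):
            g = np.random.default_rng(seed)
            ref = trajectory_factors("ref", block_loadings(0.05, g))
            perm = [1, 0]
            other = trajectory_factors("p", block_loadings(0.05, g, permute=perm))
            match = match_factors([ref, other], threshold=0.85)
            fmap = match.mapping["p"]
            ref_map = match.mapping[match.reference_trajectory]
            # factor j of "p" is planted factor perm[j] of the reference
            ok = all(
                fmap.get(f"f{j}") == ref_map.get(f"f{perm[j]}")
                for j in range(2)
                if f"f{j}" in fmap
            ) and len(fmap) == 2
            wins += ok
        assert wins / 50 >= 0.95


class TestAssignEvents:
    def _models(self, n=4):
        return [trajectory_factors(f"t{i}", block_loadings()) for i in range(n)]

    def test_block_diagonal_replicates_give_two_events(self):
        models = self._models()
        match = match_factors(models)
        events = assign_events(match, models)
        sets = sorted(sorted(c) for c in events.events.values())
        assert sets == [
            ["cv0", "cv1", "cv2", "cv3"],
            ["cv4", "cv5", "cv6", "cv7"],
        ]
        assert events.residual_cvs == []

    def test_cv_with_wandering_peak_goes_residual(self):
        models = []
        for i in range(5):
            loadings = block_loadings().copy()
            # cv3's peak alternates between the two factors across replicates
            loadings[3] = [0.9, 0.0] if i % 2 == 0 else [0.0, 0.9]
            models.append(trajectory_factors(f"t{i}", loadings))
        match = match_factors(models)
        events = assign_events(match, models, q=0.8)
        assert "cv3" in events.residual_cvs

    def test_default_dataset_events_equal_planted_sets(self):
        ds = default_dataset(seed=2)
        result = analyze_dataset(ds.replicates)
        recovered = {frozenset(c) for c in result.events.events.values()}
        assert recovered == set(ds.event_cvs.values())
        assert result.events.residual_cvs == []


class TestBuildConsensus:
    def test_identical_orders_reproduced_with_full_support(self):
        order = [frozenset({"B"}), frozenset({"C"}), frozenset({"D"})]
        seq = {f"t{i}": order for i in range(5)}
        cons = build_consensus(seq)
        assert cons.stages == order
        assert cons.support[("B", "C")] == pytest.approx(1.0)
        assert cons.support[("C", "D")] == pytest.approx(1.0)

    def test_flipping_pair_is_tied(self):
        orders = {}
        for i in range(10):
            pair = [frozenset({"x"}), frozenset({"y"})]
            if i % 2:
                pair.reverse()
            orders[f"t{i}"] = [frozenset({"a"})] + pair
        cons = build_consensus(orders)
        assert cons.stages == [frozenset({"a"}), frozenset({"x", "y"})]

    def test_paper_style_rendering(self):
        seq = {
            f"t{i}": [
                frozenset({"B"}),
                frozenset({"C1", "D1"}),
                frozenset({"E"}),
                frozenset({"D2", "F"}),
                frozenset({"G"}),
            ]
            for i in range(4)
        }
        cons = build_consensus(seq)
        assert str(cons) == "(1) B; (2) C1 and D1; (3) E; (4) D2 and F; (5) G"

    def test_raising_majority_never_creates_precedences(self):
        g = np.random.default_rng(0)
        orders = {}
        for i in range(9):
            labels = ["a", "b", "c", "d"]
            # noisy orders: occasionally swap neighbours
            if g.random() < 0.35:
                j = g.integers(0, 3)
                labels[j], labels[j + 1] = labels[j + 1], labels[j]
            orders[f"t{i}"] = [frozenset({l}) for l in labels]

        def precedences(cons):
            pos = {e: k for k, s in enumerate(cons.stages) for e in s}
            return {
                (e, f)
                for e in pos
                for f in pos
                if pos[e] < pos[f]
            }

        loose = precedences(build_consensus(orders, majority=0.6))
        strict = precedences(build_consensus(orders, majority=0.85))
        assert strict <= loose

    def test_equivariant_under_trajectory_relabeling(self):
        ds = default_dataset(seed=2, n_replicates=6, T=2000)
        result = analyze_dataset(ds.replicates)
        shuffled = dict(reversed(list(result.event_sequences.items())))
        assert build_consensus(shuffled).stages == result.consensus.stages

    def test_needs_three_trajectories(self):
        with pytest.raises(ValueError):
            build_consensus({"a": [frozenset({"x"})], "b": [frozenset({"x"})]})

    def test_never_co_observed_pairs_are_reported(self):
        orders = {
            "t0": [frozenset({"a"}), frozenset({"b"})],
            "t1": [frozenset({"a"}), frozenset({"b"})],
            "t2": [frozenset({"c"})],
        }
        cons = build_consensus(orders)
        reported = {frozenset(p) for p in cons.unobserved_pairs}
        assert frozenset({"a", "c"}) in reported
        assert frozenset({"b", "c"}) in reported
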