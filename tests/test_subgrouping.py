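import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from gradientnet.errors import ConfigError, ValidationError
from gradientnet.gradient_grouping import GradientGroup
from gradientnet.subgrouping import (
    DegenerateProfileError,
    Profile3,
    Subgroup,
    between_subgroup_r2,
    cluster_subgroups,
    loo_group_sum_r2,
    pairwise_r2,
    pearson_r3,
    profiles_to_3point,
)
from tests.conftest import make_profile, p3


def brute_r2(a, b):
    """Independent oracle: squared Pearson r via numpy's corrcoef."""
    return float(np.corrcoef(a, b)[0, 1]) ** 2


def angle_profile(gene_id, theta, scale=1.0, offset=10.0):
    """Triple whose centered part sits at angle ``theta`` in the 2-D
    centered subspace; Pearson r between two such triples is
    cos(theta1 - theta2)."""
    e1 = np.array([1.0, 0.0, -1.0]) / math.sqrt(2)
    e2 = np.array([-1.0, 2.0, -1.0]) / math.sqrt(6)
    v = offset + scale * (math.cos(theta) * e1 + math.sin(theta) * e2)
    return Profile3(gene_id, tuple(v))


finite_triples = st.tuples(
    st.floats(min_value=-1e3, max_value=1e3),
    st.floats(min_value=-1e3, max_value=1e3),
    st.floats(min_value=-1e3, max_value=1e3),
)


class TestPairwiseR2:
    def test_exact_proportionality(self):
        assert pairwise_r2(p3("a", (1, 2, 3)), p3("b", (2, 4, 6))) == pytest.approx(1.0)

    def test_negative_relation_also_one(self):
        assert pairwise_r2(p3("a", (1, 2, 3)), p3("b", (3, 2, 1))) == pytest.approx(1.0)

    def test_hand_derived_three_quarters(self):
        # cov = 1.5, var_a = 1, var_b = 3 -> r^2 = 2.25/3 = 0.75
        a, b = p3("a", (0, 1, 2)), p3("b", (1, 1, 4))
        assert pairwise_r2(a, b) == pytest.approx(0.75, abs=1e-12)
        assert pairwise_r2(a, b) == pytest.approx(brute_r2(a.values, b.values), abs=1e-12)

    def test_degenerate_flagged_not_zero(self):
        with pytest.raises(DegenerateProfileError, match="flat"):
            pairwise_r2(p3("flat", (5, 5, 5)), p3("b", (1, 2, 3)))

    @given(finite_triples, finite_triples)
    def test_symmetry_and_oracle_agreement(self, va, vb):
        # spreads near the float floor lose precision in both routes
        assume(max(va) - min(va) > 1e-6 and max(vb) - min(vb) > 1e-6)
        a, b = p3("a", va), p3("b", vb)
        forward = pairwise_r2(a, b)
        assert forward == pytest.approx(pairwise_r2(b, a), abs=1e-12)
        assert 0.0 <= forward <= 1.0
        assert forward == pytest.approx(brute_r2(va, vb), abs=1e-9)

    @given(
        finite_triples,
        finite_triples,
        st.floats(min_value=-100, max_value=100).filter(lambda a: abs(a) > 1e-2),
        st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, va, vb, scale, shift):
        # spreads far below float precision degenerate under a shift
        assume(max(va) - min(va) > 1e-3 and max(vb) - min(vb) > 1e-3)
        a, b = p3("a", va), p3("b", vb)
        base = pairwise_r2(a, b)
        transformed = p3("a2", tuple(scale * x + shift for x in va))
        assert pairwise_r2(transformed, b) == pytest.approx(base, abs=1e-6)

    def test_clipped_to_unit_interval(self):
        r = pearson_r3(p3("a", (1, 2, 3)), p3("b", (1e-8, 2e-8, 3e-8)))
        assert -1.0 <= r <= 1.0


def oracle_partition(vectors, r2_min, linkage="complete"):
    """Plain re-implementation of the greedy rule, numpy-based.

    Kept deliberately separate from the package code path: recomputes
    every admission score from scratch with corrcoef.
    """
    unassigned = sorted(vectors)
    parts = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        while True:
            best_score, best_gene = -1.0, None
            for g in unassigned:
                targets = members if linkage == "complete" else members[:1]
                score = min(brute_r2(vectors[g], vectors[m]) for m in targets)
                if score > best_score:
                    best_score, best_gene = score, g
            if best_gene is None or best_score < r2_min:
                break
            members.append(best_gene)
            unassigned.remove(best_gene)
        parts.append(sorted(members))
    return sorted(parts)


def run_clustering(vectors, r2_min=0.9, **kwargs):
    genes = sorted(vectors)
    group = GradientGroup("G1", "down", "up", tuple(genes))
    profiles = {g: p3(g, vectors[g]) for g in genes}
    return cluster_subgroups(group, profiles, r2_min=r2_min, **kwargs)


class TestClusterSubgroups:
    def test_two_proportional_pairs_orthogonal_across(self):
        # centered (1,2,3) ~ (-1,0,1); centered (2,1,2) ~ (1,-2,1): orthogonal
        vectors = {
            "At1g00001": (1, 2, 3),
            "At1g00002": (2, 4, 6),
            "At1g00003": (2, 1, 2),
            "At1g00004": (4, 2, 4),
        }
        assert brute_r2((1, 2, 3), (2, 1, 2)) == pytest.approx(0.0, abs=1e-12)
        subgroups = run_clustering(vectors)
        members = sorted(sg.members for sg in subgroups)
        assert members == [
            ("At1g00001", "At1g00002"),
            ("At1g00003", "At1g00004"),
        ]
        # brute-force check: this is the only 2+2 split satisfying all-pairs
        assert oracle_partition(vectors, 0.9) == [list(m) for m in members]

    def test_identical_profiles_single_subgroup(self):
        vectors = {f"At1g{10000 + i:05d}": (1, 2, 3) for i in range(5)}
        subgroups = run_clustering(vectors)
        assert len(subgroups) == 1
        assert len(subgroups[0]) == 5
        assert subgroups[0].subgroup_id == "G1A"

    def test_r2_min_one_generic_noise_gives_singletons(self):
        rng = np.random.default_rng(5)
        vectors = {
            f"At1g{10000 + i:05d}": tuple(rng.uniform(1, 100, 3)) for i in range(6)
        }
        subgroups = run_clustering(vectors, r2_min=1.0)
        assert all(len(sg) == 1 for sg in subgroups)

    def test_invalid_r2_min(self):
        with pytest.raises(ConfigError):
            run_clustering({"At1g00001": (1, 2, 3)}, r2_min=1.5)

    def test_labels_by_decreasing_size(self):
        vectors = {
            "At1g00001": (2, 1, 2),
            "At1g00002": (1, 2, 3),
            "At1g00003": (2, 4, 6),
            "At1g00004": (3, 6, 9),
        }
        subgroups = run_clustering(vectors)
        by_id = {sg.subgroup_id: sg for sg in subgroups}
        assert by_id["G1A"].members == ("At1g00002", "At1g00003", "At1g00004")
        assert by_id["G1B"].members == ("At1g00001",)

    def test_single_linkage_admits_via_reference_only(self):
        # b and c both within ~13 deg of the seed but ~26 deg of each other
        vectors = {
            "At1g00001": tuple(angle_profile("s", 0.0).values),
            "At1g00002": tuple(angle_profile("b", math.radians(13)).values),
            "At1g00003": tuple(angle_profile("c", math.radians(-13)).values),
        }
        assert brute_r2(vectors["At1g00002"], vectors["At1g00003"]) < 0.9
        assert brute_r2(vectors["At1g00001"], vectors["At1g00002"]) >= 0.9
        complete = run_clustering(vectors, linkage="complete")
        single = run_clustering(vectors, linkage="single")
        assert max(len(sg) for sg in complete) == 2
        assert max(len(sg) for sg in single) == 3

    def test_positive_slope_constraint_splits_anticorrelated(self):
        vectors = {"At1g00001": (1, 2, 3), "At1g00002": (3, 2, 1)}
        merged = run_clustering(vectors, sign_constraint="any")
        assert len(merged) == 1
        split = run_clustering(vectors, sign_constraint="positive_slope_only")
        assert len(split) == 2

    def test_degenerate_members_excluded_with_warning(self):
        vectors = {"At1g00001": (1, 2, 3), "At1g00002": (4, 4, 4)}
        with pytest.warns(UserWarning, match="At1g00002"):
            subgroups = run_clustering(vectors)
        assert [sg.members for sg in subgroups] == [("At1g00001",)]

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("r2_min", [0.5, 0.9])
    def test_oracle_equivalence_small_instances(self, seed, r2_min):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        vectors = {
            f"At1g{10000 + i:05d}": tuple(rng.uniform(1, 100, 3)) for i in range(n)
        }
        subgroups = run_clustering(vectors, r2_min=r2_min)
        assert sorted(list(sg.members) for sg in subgroups) == oracle_partition(
            vectors, r2_min
        )
        # exhaustive all-pairs constraint on every emitted subgroup
        for sg in subgroups:
            for a, b in itertools.combinations(sg.members, 2):
                assert brute_r2(vectors[a], vectors[b]) >= r2_min - 1e-12
            assert sg.min_pairwise_r2 >= r2_min - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_input_order_invariance(self, seed):
        rng = random.Random(seed)
        np_rng = np.random.default_rng(seed)
        vectors = {
            f"At1g{10000 + i:05d}": tuple(np_rng.uniform(1, 100, 3))
            for i in range(10)
        }
        baseline = run_clustering(vectors)
        items = list(vectors.items())
        rng.shuffle(items)
        shuffled = dict(items)
        assert run_clustering(shuffled) == baseline


class TestLeaveOneOut:
    def _subgroup(self, vectors):
        members = tuple(sorted(vectors))
        profiles = {g: p3(g, v) for g, v in vectors.items()}
        r2s = [
            pairwise_r2(profiles[a], profiles[b])
            for a, b in itertools.combinations(members, 2)
        ]
        sg = Subgroup("G1A", "G1", members, min(r2s) if r2s else 1.0)
        return sg, profiles

    def test_proportional_members_give_one(self):
        sg, profiles = self._subgroup(
            {"a": (1, 2, 3), "b": (2, 4, 6), "c": (0.5, 1, 1.5)}
        )
        for gene in sg.members:
            assert loo_group_sum_r2(sg, profiles, gene) == pytest.approx(1.0)

    def test_two_members_reduces_to_pairwise(self):
        vectors = {"a": (0, 1, 2), "b": (1, 1, 4)}
        sg, profiles = self._subgroup(vectors)
        expected = pairwise_r2(profiles["a"], profiles["b"])
        assert loo_group_sum_r2(sg, profiles, "a") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.75, abs=1e-12)

    def test_errors(self):
        sg, profiles = self._subgroup({"a": (1, 2, 3), "b": (2, 4, 6)})
        with pytest.raises(ValidationError):
            loo_group_sum_r2(sg, profiles, "zz")
        lone, lone_profiles = self._subgroup({"a": (1, 2, 3)})
        with pytest.raises(ValidationError):
            loo_group_sum_r2(lone, lone_profiles, "a")

    def test_planted_noisy_subgroup_monte_carlo(self):
        # 7 genes proportional to one base, 5% multiplicative noise:
        # leave-one-out R^2 >= 0.90 in at least 95% of 1000 draws.
        # Bound verified against an independent numpy-only oracle run
        # (observed fraction 1.0 at this seed).
        rng = np.random.default_rng(42)
        sigma = math.sqrt(math.log(1 + 0.05**2))
        base = np.array([100.0, 40.0, 7.0])
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            scales = rng.uniform(0.5, 2.0, 7)[:, None]
            noise = np.exp(rng.normal(0.0, sigma, (7, 3)))
            mat = scales * base[None, :] * noise
            vectors = {f"g{i}": tuple(mat[i]) for i in range(7)}
            sg, profiles = self._subgroup(vectors)
            if loo_group_sum_r2(sg, profiles, "g0") >= 0.90:
                hits += 1
        assert hits / n_sim >= 0.95


class TestBetweenSubgroups:
    def test_same_base_gives_one(self):
        sg_a = Subgroup("G1A", "G1", ("a1", "a2"), 1.0)
        sg_b = Subgroup("G1B", "G1", ("b1", "b2"), 1.0)
        profiles = {
            "a1": p3("a1", (1, 2, 3)),
            "a2": p3("a2", (2, 4, 6)),
            "b1": p3("b1", (3, 6, 9)),
            "b2": p3("b2", (0.5, 1, 1.5)),
        }
        assert between_subgroup_r2(sg_a, sg_b, profiles, "a1", "b1") == pytest.approx(1.0)

    def test_mirror_profiles_give_one(self):
        # sums (1,2,3) vs (3,2,1): perfect negative linear relation
        sg_a = Subgroup("G1A", "G1", ("a1", "a2"), 1.0)
        sg_b = Subgroup("G1B", "G1", ("b1", "b2"), 1.0)
        profiles = {
            "a1": p3("a1", (9, 9, 9)),
            "a2": p3("a2", (1, 2, 3)),
            "b1": p3("b1", (9, 9, 9)),
            "b2": p3("b2", (3, 2, 1)),
        }
        assert between_subgroup_r2(sg_a, sg_b, profiles, "a1", "b1") == pytest.approx(1.0)

    def test_orthogonal_sums_give_zero(self):
        # centered (1,2,3) and (2,1,2) have zero sample covariance
        sg_a = Subgroup("G1A", "G1", ("a1", "a2"), 1.0)
        sg_b = Subgroup("G1B", "G1", ("b1", "b2"), 1.0)
        profiles = {
            "a1": p3("a1", (1, 2, 3)),
            "a2": p3("a2", (2, 4, 6)),
            "b1": p3("b1", (2, 1, 2)),
            "b2": p3("b2", (4, 2, 4)),
        }
        assert between_subgroup_r2(sg_a, sg_b, profiles, "a1", "b1") == pytest.approx(
            0.0, abs=1e-9
        )


class TestProfilesTo3Point:
    def test_requires_dsc_norm(self):
        with pytest.raises(ValidationError, match="normalize"):
            profiles_to_3point([make_profile("At1g00001", 1, 2, 3)])

    def test_uses_normalized_dsc(self):
        triples = profiles_to_3point(
            [make_profile("At1g00001", 1, 2, 268, dsc_norm=10.0)]
        )
        assert triples["At1g00001"].values == (1.0, 2.0, 10.0)
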