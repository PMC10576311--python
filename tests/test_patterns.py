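"""Growth-pattern clustering, VAT ordering, LOESS curves, agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from growthguard.cohort import ConfigError, to_matrix
from growthguard.inject import InjectionSpec
from growthguard.patterns import (
    Partition,
    agreement,
    group_curve,
    impact_study,
    tsc,
    vat_order,
)
from growthguard.simulate import GroupSpec, CohortSpec, generate, preset

from .conftest import make_matrix


class TestTSC:
    def test_exact_recovery_of_separated_groups(self):
        vals = np.vstack([np.full((15, 5), 0.0), np.full((10, 5), 4.0)])
        m = make_matrix(vals)
        part = tsc(m, 2)
        labels = [part.assignment[s] for s in m.subject_ids]
        assert len(set(labels[:15])) == 1
        assert len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self):
        m = make_matrix(np.arange(12.0).reshape(4, 3))
        part = tsc(m, 4)
        assert sorted(part.assignment.values()) == [1, 2, 3, 4]

    def test_k_above_n_rejected(self):
        with pytest.raises(ConfigError):
            tsc(make_matrix(np.zeros((3, 2))), 5)

    def test_preset_clusters_are_ordered_in_z(self):
        """On the two-group primary-care preset the recovered cluster mean
        curves do not cross: one group tracks uniformly below the other."""
        cohort = generate(preset("targetkids_zwfl", subject_sd=0.4), seed=2)
        m = to_matrix(cohort)
        part = tsc(m, 2)
        curves = []
        for lab in (1, 2):
            rows = [i for i, s in enumerate(m.subject_ids)
                    if part.assignment[s] == lab]
            curves.append(m.values[rows].mean(axis=0))
        diff = curves[0] - curves[1]
        assert np.all(diff > 0) or np.all(diff < 0)

    def test_two_group_preset_recovery_against_generative_labels(self):
        """Hierarchical clustering recovers the latent groups when the
        group curves are well separated and noise is moderate."""
        spec = CohortSpec(
            n_subjects=300, schedule=(0.0, 3.0, 6.0, 9.0, 12.0),
            groups=(GroupSpec(-2.0, 0.02), GroupSpec(0.0, 0.02)),
            group_weights=(0.5, 0.5), noise_sd=0.15, subject_sd=0.2,
        )
        cohort, truth = generate(spec, seed=8, return_groups=True)
        part = tsc(cohort, 2)
        true_part = Partition(
            {s: g + 1 for s, g in truth.items()}, k=2)
        assert agreement(part, true_part).agreement >= 0.95


class TestVATOrder:
    def test_blocks_stay_contiguous(self):
        vals = np.vstack([np.zeros((6, 3)), np.full((5, 3), 5.0)])
        d = squareform(pdist(vals))
        order = vat_order(d)
        groups = [0 if i < 6 else 1 for i in order]
        assert groups == sorted(groups) or groups == sorted(groups, reverse=True)

    def test_single_element_identity(self):
        assert vat_order(np.zeros((1, 1))).tolist() == [0]

    @given(st.integers(0, 2**31 - 1))
    def test_output_is_permutation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((8, 8))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        order = vat_order(d)
        assert sorted(order.tolist()) == list(range(8))

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ConfigError):
            vat_order(d)


class TestGroupCurve:
    def _partition(self, m):
        return Partition({s: 1 for s in m.subject_ids}, k=1)

    def test_constant_cluster_gives_constant_curve(self):
        m = make_matrix(np.full((10, 6), 1.25))
        curve = group_curve(m, self._partition(m), 1)
        np.testing.assert_allclose(curve["zscore"], 1.25, atol=1e-12)

    def test_linear_means_reproduced_exactly(self):
        ages = np.array([2.0, 4.0, 6.0, 9.0, 12.0, 15.0])
        line = 0.1 * ages - 1.0
        m = make_matrix(np.tile(line, (8, 1)), schedule=tuple(ages))
        curve = group_curve(m, self._partition(m), 1)
        np.testing.assert_allclose(curve["zscore"], line, atol=1e-6)

    def test_noisy_curve_tracks_per_visit_means(self):
        rng = np.random.default_rng(3)
        ages = np.linspace(0, 14, 8)
        vals = 0.2 * ages + rng.normal(0, 0.3, size=(200, 8))
        m = make_matrix(vals, schedule=tuple(ages))
        curve = group_curve(m, self._partition(m), 1)
        se = 0.3 / np.sqrt(200)
        # smoother stays within a few SEs of the (linear) truth
        assert np.max(np.abs(curve["zscore"] - 0.2 * ages)) < 6 * se

    def test_empty_cluster_rejected(self):
        m = make_matrix(np.zeros((3, 3)))
        with pytest.raises(ConfigError):
            group_curve(m, self._partition(m), 99)


class TestAgreement:
    def test_identical_partitions(self):
        p = Partition({"a": 1, "b": 2, "c": 1}, k=2)
        assert agreement(p, p).agreement == 1.0

    def test_label_permutation_invariance(self):
        p = Partition({"a": 1, "b": 2, "c": 1}, k=2)
        q = Partition({"a": 2, "b": 1, "c": 2}, k=2)
        assert agreement(p, q).agreement == 1.0

    def test_contingency_example(self):
        # 2x2 table [[40,10],[10,40]] -> best matching recovers 80/100
        assign_p, assign_q = {}, {}
        i = 0
        for pl, ql, count in [(1, 1, 40), (1, 2, 10), (2, 1, 10), (2, 2, 40)]:
            for _ in range(count):
                assign_p[f"s{i}"] = pl
                assign_q[f"s{i}"] = ql
                i += 1
        res = agreement(Partition(assign_p, 2), Partition(assign_q, 2))
        assert res.agreement == pytest.approx(0.8)
        assert res.label_map == {1: 1, 2: 2}

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        subjects = [f"s{i}" for i in range(50)]
        p = Partition({s: int(l) for s, l in
                       zip(subjects, rng.integers(1, 4, 50))}, 3)
        q = Partition({s: int(l) for s, l in
                       zip(subjects, rng.integers(1, 3, 50))}, 2)
        assert agreement(p, q).agreement == agreement(q, p).agreement

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            agreement(Partition({"a": 1}, 1), Partition({"b": 1}, 1))

    def test_random_partition_agreement_above_chance_floor(self):
        rng = np.random.default_rng(1)
        subjects = [f"s{i}" for i in range(400)]
        k = 4
        ps = []
        for _ in range(2):
            labels = rng.integers(1, k + 1, len(subjects))
            ps.append(Partition(dict(zip(subjects, map(int, labels))), k))
        assert agreement(*ps).agreement >= 1 / k


class TestImpact:
    def test_negligible_perturbation_preserves_membership(self):
        cohort = generate(preset("targetkids_zwfl"), seed=4)
        res, p_clean, p_dirty = impact_study(
            cohort,
            InjectionSpec(error_types=("a", "c"), intensity=1e-9, seed=2),
            k=2,
        )
        assert res.agreement == 1.0
        assert p_clean.assignment == p_dirty.assignment

    def test_strong_contamination_disrupts_membership(self):
        cohort = generate(preset("targetkids_zwfl"), seed=4)
        res, _, _ = impact_study(cohort, InjectionSpec(intensity=5.0, seed=2),
                                 k=2)
        assert res.agreement < 1.0
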