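"""Measurement-level detectors: sBIV, mBIV, SMOM, MMOM."""

import numpy as np
import pytest

from growthguard.cohort import ConfigError, from_matrix, to_matrix
from growthguard.detect import BIVCutoffs, MBIVParams, mbiv, mmom, sbiv, smom
from growthguard.inject import InjectionSpec, inject
from growthguard.simulate import generate, preset

from .conftest import make_cohort, make_matrix


class TestSBIV:
    def test_flags_beyond_who_limits(self):
        vals = np.full((40, 8), 0.3)
        vals[0, 0] = 6.0
        assert sbiv(make_cohort(vals)).flags == {("S000", 0)}

    def test_all_in_range_no_flags(self, flat_cohort):
        assert sbiv(flat_cohort).flags == frozenset()

    def test_boundary_value_not_flagged(self):
        cohort = make_cohort([[5.0, 0.0], [-5.0, 0.0]])
        assert sbiv(cohort).flags == frozenset()
        just_over = make_cohort([[5.0 + 1e-9, 0.0], [0.0, 0.0]])
        assert sbiv(just_over).flags == {("S000", 0)}

    def test_measure_specific_cutoffs(self):
        cohort = make_cohort([[-5.5, 0.0], [0.0, 0.0]], measure="zWA")
        assert sbiv(cohort).flags == frozenset()  # zWA lower limit is -6
        cohort = make_cohort([[-5.5, 0.0], [0.0, 0.0]], measure="zWFL")
        assert sbiv(cohort).flags == {("S000", 0)}

    def test_unknown_measure_is_config_error(self):
        cohort = make_cohort([[0.0, 0.0]], measure="other")
        with pytest.raises(ConfigError, match="other"):
            sbiv(cohort)


class TestMBIV:
    def _cohort(self, row0):
        vals = np.vstack([row0, np.zeros((5, len(row0)))])
        return make_cohort(vals, schedule=tuple(3.0 * j for j in range(1, len(row0) + 1)))

    def test_candidate_cleared_by_close_neighbour(self):
        # 6.0 at month 12 with 5.5 at month 9: within 2 z-units and 2 years
        cohort = self._cohort([0.0, 0.0, 5.5, 6.0, 0.0, 0.0, 0.0, 0.0])
        assert ("S000", 3) in sbiv(cohort).flags
        assert mbiv(cohort).flags == frozenset()

    def test_candidate_confirmed_without_neighbour(self):
        cohort = self._cohort([0.0, 0.0, 0.0, 6.0, 0.0, 0.0, 0.0, 0.0])
        assert mbiv(cohort).flags == {("S000", 3)}

    def test_single_visit_subject_confirmed_vacuously(self):
        cohort = make_cohort([[6.0], [0.0]], schedule=(12.0,))
        assert mbiv(cohort).flags == {("S000", 0)}

    def test_window_excludes_distant_neighbours(self):
        # close-in-z neighbour sits 30 months away -> outside 24-month window
        cohort = make_cohort(
            [[4.5, 0.0, 0.0, 6.0], [0.0, 0.0, 0.0, 0.0]],
            schedule=(6.0, 12.0, 24.0, 36.0),
        )
        assert mbiv(cohort).flags == {("S000", 3)}
        wide = MBIVParams(window=36.0)
        assert mbiv(cohort, params=wide).flags == frozenset()

    def test_mbiv_subset_of_sbiv_on_contaminated_cohort(self):
        cohort = generate(preset("targetkids_zwfl"), seed=3)
        dirty = inject(cohort, InjectionSpec(intensity=5.0, seed=8)).cohort
        assert mbiv(dirty).flags <= sbiv(dirty).flags


class TestSMOM:
    def test_zero_sd_column_flags_nothing(self, flat_cohort):
        assert smom(flat_cohort).flags == frozenset()

    def test_cell_beyond_two_sd_flagged(self):
        vals = np.zeros((50, 4))
        vals[7, 2] = 1.0  # lone deviation, ~7 column SDs from the mean
        assert smom(make_matrix(vals)).flags == {("S007", 2)}

    def test_matches_brute_force_per_column_scan(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(60, 5)))
        expected = set()
        for j in range(5):
            col = m.values[:, j]
            mu, sd = col.mean(), col.std()
            for i in range(60):
                if abs(col[i] - mu) > 2 * sd:
                    expected.add((m.subject_ids[i], j))
        assert smom(m).flags == expected

    def test_needs_two_subjects(self):
        with pytest.raises(ConfigError):
            smom(make_matrix([[0.0, 0.0]]))


class TestMMOM:
    def test_k1_reduces_exactly_to_smom(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(size=(80, 6)))
        for seed in (0, 99):
            assert mmom(m, k=1, seed=seed).flags == smom(m).flags

    def test_displaced_cell_flagged_within_its_cluster(self):
        """Two separated groups; one cell displaced by 4 within-cluster SDs
        is caught, and the subject stays in its own group."""
        rng = np.random.default_rng(2)
        g1 = rng.normal(0.0, 0.25, size=(30, 6))
        g2 = rng.normal(3.0, 0.25, size=(30, 6)) + 0.0
        vals = np.vstack([g1, g2])
        within_sd = vals[:30, 2].std()
        vals[5, 2] = vals[:30, 2].mean() + 4.5 * within_sd
        m = make_matrix(vals)
        flags = mmom(m, k=2, seed=0).flags
        assert (m.subject_ids[5], 2) in flags
        # brute-force per-cluster oracle with the same k-means labels
        from growthguard.detect.points import kmeans_labels
        labels = kmeans_labels(m.values, 2, seed=0)
        assert labels[5] == labels[0]
        expected = set()
        for lab in np.unique(labels):
            rows = np.nonzero(labels == lab)[0]
            sub = m.values[rows]
            mu, sd = sub.mean(axis=0), sub.std(axis=0)
            for ii, i in enumerate(rows):
                for j in range(6):
                    if sd[j] > 0 and abs(sub[ii, j] - mu[j]) > 2 * sd[j]:
                        expected.add((m.subject_ids[i], j))
        assert flags == expected

    def test_identical_cluster_flags_nothing(self):
        vals = np.vstack([np.full((20, 4), 0.0), np.full((20, 4), 3.0)])
        m = make_matrix(vals)
        assert mmom(m, k=2, seed=0).flags == frozenset()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigError):
            mmom(make_matrix(np.zeros((3, 2))), k=5)


class TestDetectorInvariants:
    def test_permutation_equivariance(self):
        """Reordering subjects permutes the flags accordingly."""
        rng = np.random.default_rng(5)
        vals = np.vstack([rng.normal(0, 0.3, (25, 5)),
                          rng.normal(3, 0.3, (25, 5))])
        vals[3, 1] = 8.0
        m = make_matrix(vals)
        perm = rng.permutation(50)
        m_perm = make_matrix(vals[perm])
        rename = {m_perm.subject_ids[i]: m.subject_ids[perm[i]]
                  for i in range(50)}
        for detector in (
            lambda x: sbiv(from_matrix(x)),
            lambda x: mbiv(from_matrix(x)),
            lambda x: smom(x),
            lambda x: mmom(x, k=2, seed=0),
        ):
            base = detector(m).flags
            permuted = {(rename[s], v) for s, v in detector(m_perm).flags}
            assert permuted == base

    def test_single_extreme_outlier_caught_by_all_four(self):
        """A lone extreme perturbation in an otherwise noiseless
        population is flagged by every measurement-level method."""
        vals = np.full((40, 8), 0.3)
        vals[0, 3] = abs(0.3) + 5.0  # extreme positive error, intensity 5
        one_group = make_cohort(vals)
        for det in (sbiv, mbiv):
            assert det(one_group).flags == {("S000", 3)}
        assert smom(to_matrix(one_group)).flags == {("S000", 3)}
        # the multi-model screen, on a two-group population where the
        # contaminated subject stays inside its own cluster
        two_group = np.vstack([np.full((20, 8), 0.3), np.full((20, 8), 3.3)])
        two_group[0, 3] = abs(0.3) + 5.0
        m = make_matrix(two_group)
        assert mmom(m, k=2, seed=0).flags == {("S000", 3)}
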