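"""Forward/binning peak matching, consensus building and the peak matrix."""

import numpy as np
import pytest

from maldikd.exceptions import ConflictError, ParameterError
from maldikd.matching import (
    bin_match,
    build_consensus,
    forward_match,
    intersample_match,
)

from conftest import make_peaklist
from oracles import forward_reference


def random_peaklists(rng, max_spectra=4, max_peaks=5, lo=100.0, hi=110.0):
    """Small pools with frequent m/z collisions to stress the matchers."""
    lists = []
    for k in range(rng.integers(1, max_spectra + 1)):
        n = int(rng.integers(1, max_peaks + 1))
        mz = np.unique(np.round(rng.uniform(lo, hi, n), 2))
        lists.append(make_peaklist(f"s{k}", mz, rng.uniform(1, 10, len(mz))))
    return lists


class TestForwardMatch:
    def test_hand_traced_sliding_window(self):
        s1 = make_peaklist("S1", [100.00, 200.00])
        s2 = make_peaklist("S2", [100.05, 300.00])
        clusters = forward_match([s1, s2], tolerance=0.2)
        got = [sorted(p.mz for p in c.members) for c in clusters]
        assert got == [[100.00, 100.05], [200.00], [300.00]]

    def test_empty_input(self):
        assert forward_match([], tolerance=0.2) == []

    def test_same_spectrum_peaks_never_share_a_cluster(self):
        s1 = make_peaklist("S1", [100.00, 100.05])
        clusters = forward_match([s1], tolerance=0.2)
        assert len(clusters) == 2
        assert all(len(c) == 1 for c in clusters)

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ParameterError):
            forward_match([], tolerance=0.0)

    def test_matches_literal_reference_on_random_pools(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            lists = random_peaklists(rng)
            tol = float(rng.uniform(0.05, 2.0))
            got = forward_match(lists, tolerance=tol)
            expected = forward_reference(
                [(pl.spectrum_id, float(m)) for pl in lists for m in pl.mz], tol
            )
            got_sets = sorted(
                sorted((p.spectrum_id, p.mz) for p in c.members) for c in got
            )
            exp_sets = sorted(sorted(c) for c in expected)
            assert got_sets == exp_sets

    def test_ppm_tolerance_scales_with_mass(self):
        a = make_peaklist("a", [1000.0, 2000.0])
        b = make_peaklist("b", [1000.4, 2000.9])
        clusters = forward_match([a, b], tolerance=500.0, unit="ppm")
        sizes = sorted(len(c) for c in clusters)
        # 0.4 Da @1000 < 0.5 Da window; 0.9 Da @2000 < 1.0 Da window
        assert sizes == [2, 2]


class TestBinMatch:
    def test_gap_split_by_hand(self):
        a = make_peaklist("a", [100.00, 105.00])
        b = make_peaklist("b", [100.01])
        clusters = bin_match([a, b], tolerance=1e-3)
        got = [sorted(p.mz for p in c.members) for c in clusters]
        assert got == [[100.00, 100.01], [105.00]]

    def test_single_peak_singleton(self):
        clusters = bin_match([make_peaklist("a", [100.0])], tolerance=1e-3)
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_same_spectrum_pair_within_tolerance_split(self):
        a = make_peaklist("a", [100.00, 100.01])
        clusters = bin_match([a], tolerance=1e-3)
        assert len(clusters) == 2


@pytest.mark.parametrize("matcher", [forward_match, bin_match])
def test_matcher_invariants_on_random_inputs(matcher):
    """Same-spectrum exclusion, completeness, and the tolerance bound hold
    on many random seeded pools for both matchers."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        lists = random_peaklists(rng)
        n_in = sum(len(pl) for pl in lists)
        if matcher is forward_match:
            tol = float(rng.uniform(0.05, 2.0))
            clusters = matcher(lists, tolerance=tol)
            bound = lambda c: tol  # noqa: E731
        else:
            tol = float(rng.uniform(1e-5, 5e-3))
            clusters = matcher(lists, tolerance=tol)
            bound = lambda c: tol * c.center  # noqa: E731
        assert sum(len(c) for c in clusters) == n_in
        for c in clusters:
            sids = [p.spectrum_id for p in c.members]
            assert len(set(sids)) == len(sids)
        for c in clusters:
            if matcher is bin_match and len(c) > 1:
                assert max(abs(p.mz - c.center) for p in c.members) <= bound(c) + 1e-12


class TestBuildConsensus:
    def test_pop_two_of_three_kept_at_threshold_50(self):
        reps = [
            make_peaklist("r1", [100.0, 200.0]),
            make_peaklist("r2", [100.02, 200.01]),
            make_peaklist("r3", [100.01]),
        ]
        cs = build_consensus(reps, "s", tolerance=0.3, pop_threshold=50)
        assert len(cs) == 2
        assert cs.pop[0] == pytest.approx(100.0)
        assert cs.pop[1] == pytest.approx(200 / 3)

    def test_pop_below_threshold_removed(self):
        reps = [
            make_peaklist("r1", [100.0, 200.0]),
            make_peaklist("r2", [100.02, 200.01]),
            make_peaklist("r3", [100.01]),
        ]
        cs = build_consensus(reps, "s", tolerance=0.3, pop_threshold=70)
        assert len(cs) == 1
        assert cs.mz[0] == pytest.approx(100.01)

    def test_single_replicate_identity_with_pop_100(self):
        pl = make_peaklist("r1", [100.0, 300.0], [1.0, 2.0])
        cs = build_consensus([pl], "s", pop_threshold=90)
        np.testing.assert_allclose(cs.mz, pl.mz)
        np.testing.assert_allclose(cs.intensity, pl.intensity)
        np.testing.assert_allclose(cs.pop, 100.0)

    def test_pop_threshold_domain(self):
        with pytest.raises(ParameterError):
            build_consensus([make_peaklist("r", [1.0])], "s", pop_threshold=0.0)
        with pytest.raises(ParameterError):
            build_consensus([make_peaklist("r", [1.0])], "s", pop_threshold=101)

    def test_consensus_intensity_is_member_mean(self):
        reps = [
            make_peaklist("r1", [100.0], [0.4]),
            make_peaklist("r2", [100.1], [0.8]),
        ]
        cs = build_consensus(reps, "s", tolerance=0.3, pop_threshold=50)
        assert cs.intensity[0] == pytest.approx(0.6)

    def test_pop_conservation(self):
        """Sum of pop * n_rep / 100 equals the surviving member count."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            reps = random_peaklists(rng, max_spectra=4, max_peaks=6)
            if not reps:
                continue
            thr = float(rng.uniform(1, 100))
            cs = build_consensus(reps, "s", tolerance=0.5, pop_threshold=thr)
            members = np.round(cs.pop * len(reps) / 100).sum()
            clusters = forward_match(reps, tolerance=0.5)
            surviving = sum(
                len(c) for c in clusters if 100 * len(c) / len(reps) >= thr
            )
            assert int(members) == surviving


class TestIntersampleMatch:
    def _two_samples(self):
        from maldikd.matching import ConsensusSpectrum

        c1 = ConsensusSpectrum("s1", [100.0, 200.0], [100.0, 100.0], [0.5, 1.0])
        c2 = ConsensusSpectrum("s2", [100.05, 300.0], [100.0, 100.0], [0.7, 1.0])
        return c1, c2

    def test_shared_and_private_columns(self):
        c1, c2 = self._two_samples()
        m = intersample_match([c1, c2], {"s1": "A", "s2": "B"}, tolerance=0.2, unit="da")
        assert m.values.shape == (2, 3)
        np.testing.assert_array_equal(m.values.sum(axis=1), [2, 2])
        np.testing.assert_array_equal(m.values.sum(axis=0), [2, 1, 1])
        assert m.mz[0] == pytest.approx(100.025)

    def test_all_samples_shared_column_is_all_ones(self):
        from maldikd.matching import ConsensusSpectrum

        cs = [ConsensusSpectrum(f"s{i}", [500.0 + 0.01 * i], [100.0], [1.0])
              for i in range(4)]
        m = intersample_match(cs, {f"s{i}": "A" for i in range(4)},
                              tolerance=0.2, unit="da")
        np.testing.assert_array_equal(m.values, np.ones((4, 1)))

    def test_intensity_mode_passes_through(self):
        c1, c2 = self._two_samples()
        m = intersample_match([c1, c2], {"s1": "A", "s2": "B"},
                              tolerance=0.2, unit="da", mode="intensity")
        assert m.values[0, 0] == pytest.approx(0.5)
        assert m.values[1, 0] == pytest.approx(0.7)

    def test_duplicate_sample_ids_conflict(self):
        c1, _ = self._two_samples()
        with pytest.raises(ConflictError):
            intersample_match([c1, c1], {"s1": "A"})

    def test_needs_two_samples(self):
        c1, _ = self._two_samples()
        with pytest.raises(ParameterError):
            intersample_match([c1], {"s1": "A"})
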