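"""Circular statistics for periodic dihedral angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdspectra.angular import (
    AngleSeries,
    angle_histogram,
    circular_mean,
    circular_mean_trace,
    concat_replicas,
    time_window,
    wrap_angle,
)
from mdspectra.errors import ValidationError
from mdspectra.fixtures import gen_dihedral
from mdspectra.gromacs_io import read_xvg


def _aseries(angles, time=None, rid=""):
    angles = np.asarray(angles, dtype=float)
    t = np.arange(len(angles), dtype=float) if time is None else np.asarray(time)
    return AngleSeries(t, angles, angle_name="chi", replica_id=rid)


class TestWrapAngle:
    @pytest.mark.parametrize(
        "deg,expected",
        [(270, -90), (-180, -180), (180, -180), (0, 0), (359, -1), (-541, 179)],
    )
    def test_known_values(self, deg, expected):
        assert wrap_angle(deg) == pytest.approx(expected)

    def test_wrap_preserves_angle_mod_360(self, rng):
        x = rng.uniform(-1e4, 1e4, size=10_000)
        w = wrap_angle(x)
        assert np.all(w >= -180) and np.all(w < 180)
        k = (w - x) / 360.0
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            wrap_angle(float("nan"))


class TestCircularMean:
    def test_symmetric_about_zero(self):
        mean, r = circular_mean([10.0, 350.0])
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert 0 < r <= 1

    def test_identical_angles(self):
        mean, _ = circular_mean([90.0, 90.0, 90.0])
        assert mean == pytest.approx(90.0)

    def test_zero_resultant_is_undefined(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            mean, r = circular_mean([0.0, 180.0])
        assert np.isnan(mean)
        assert r < 1e-9

    def test_von_mises_recovery(self):
        rng = np.random.default_rng(42)
        draws = np.degrees(rng.vonmises(np.radians(45.0), 4.0, size=10_000))
        mean, r = circular_mean(draws)
        assert mean == pytest.approx(45.0, abs=2.0)
        assert r > 0.5

    @given(
        shift_mask=st.lists(st.booleans(), min_size=5, max_size=5),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_360_shifts(self, shift_mask):
        base = np.array([-170.0, -35.0, 10.0, 88.0, 150.0])
        shifted = base + 360.0 * np.array(shift_mask)
        m0, _ = circular_mean(base)
        m1, _ = circular_mean(shifted)
        assert m1 == pytest.approx(m0, abs=1e-9)

    @given(theta=st.floats(min_value=-180.0, max_value=179.999))
    @settings(max_examples=50, deadline=None)
    def test_singleton_identity(self, theta):
        mean, r = circular_mean([theta])
        assert mean == pytest.approx(theta, abs=1e-9)
        assert r == pytest.approx(1.0)


class TestCircularMeanTrace:
    def test_two_point_example(self):
        a = _aseries([10.0, 20.0])
        b = _aseries([350.0, 40.0])
        out = circular_mean_trace([a, b])
        np.testing.assert_allclose(out.angles, [0.0, 30.0], atol=1e-9)

    def test_single_replica_identity(self):
        a = _aseries([5.0, 15.0])
        assert circular_mean_trace([a]) is a

    def test_matches_scalar_circular_mean(self, rng):
        reps = [_aseries(rng.uniform(-180, 180, size=50)) for _ in range(3)]
        out = circular_mean_trace(reps)
        for t in range(50):
            expected, _ = circular_mean([r.angles[t] for r in reps])
            assert out.angles[t] == pytest.approx(expected, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        a = _aseries([1.0, 2.0])
        b = _aseries([1.0, 2.0], time=[0.0, 2.0])
        with pytest.raises(ValidationError):
            circular_mean_trace([a, b])


class TestConcatReplicas:
    def test_pooled_length(self):
        pairs = [
            (_aseries(np.zeros(100)), _aseries(np.ones(100))),
            (_aseries(np.zeros(100)), _aseries(np.ones(100))),
        ]
        phi, psi = concat_replicas(pairs)
        assert len(phi) == len(psi) == 200

    def test_single_replica_identity(self):
        a, b = _aseries([1.0, 2.0]), _aseries([3.0, 4.0])
        phi, psi = concat_replicas([(a, b)])
        np.testing.assert_array_equal(phi, a.angles)
        np.testing.assert_array_equal(psi, b.angles)

    def test_multiset_equality(self, rng):
        pairs = [
            (
                _aseries(rng.uniform(-180, 180, size=n)),
                _aseries(rng.uniform(-180, 180, size=n)),
            )
            for n in (30, 50, 20)
        ]
        phi, _ = concat_replicas(pairs)
        expected = np.concatenate([p.angles for p, _ in pairs])
        np.testing.assert_array_equal(np.sort(phi), np.sort(expected))

    def test_length_mismatch_within_replica(self):
        with pytest.raises(ValidationError, match="mismatch"):
            concat_replicas([(_aseries([1.0]), _aseries([1.0, 2.0]))])


class TestTimeWindow:
    def test_full_window_identity(self):
        s = _aseries([1.0, 2.0, 3.0])
        out = time_window(s, -1.0, 10.0)
        np.testing.assert_array_equal(out.angles, s.angles)

    def test_point_window_closed(self):
        s = _aseries(np.arange(10.0))
        out = time_window(s, 5.0, 5.0)
        assert len(out) == 1 and out.time[0] == 5.0

    def test_matches_bruteforce_filter(self, rng):
        t = np.sort(rng.uniform(0, 50, size=200))
        s = _aseries(rng.uniform(-180, 180, size=200), time=t)
        for _ in range(10):
            t0, t1 = np.sort(rng.uniform(0, 50, size=2))
            out = time_window(s, t0, t1)
            keep = [(ti, ai) for ti, ai in zip(s.time, s.angles) if t0 <= ti <= t1]
            np.testing.assert_array_equal(out.time, [ti for ti, _ in keep])
            np.testing.assert_array_equal(out.angles, [ai for _, ai in keep])

    def test_empty_window_warns(self):
        s = _aseries([1.0], time=[0.0])
        with pytest.warns(UserWarning, match="no samples"):
            out = time_window(s, 5.0, 6.0)
        assert len(out) == 0


class TestAngleHistogram:
    def test_one_count_per_bin(self):
        edges, counts = angle_histogram([-170.0, -80.0, 10.0, 100.0], 4)
        np.testing.assert_array_equal(counts, [1, 1, 1, 1])
        assert edges[0] == -180 and edges[-1] == 180

    def test_counts_conserved(self, rng):
        a = rng.uniform(-180, 180, size=1234)
        _, counts = angle_histogram(a, 17)
        assert counts.sum() == 1234

    def test_matches_bruteforce_binning(self, rng):
        a = rng.uniform(-180, 180, size=500)
        n_bins = 12
        edges, counts = angle_histogram(a, n_bins)
        width = 360.0 / n_bins
        brute = np.zeros(n_bins, dtype=int)
        for x in a:
            k = min(int((x + 180.0) // width), n_bins - 1)
            brute[k] += 1
        np.testing.assert_array_equal(counts, brute)


class TestDihedralFixture:
    def test_high_concentration_recovers_mu(self, tmp_path):
        gen_dihedral(tmp_path / "d.xvg", seed=9, n_frames=2000, mu_deg=60.0, kappa=1e6)
        table = read_xvg(tmp_path / "d.xvg")
        mean, _ = circular_mean(table.columns[1])
        assert mean == pytest.approx(60.0, abs=0.1)

    def test_wrap_near_boundary(self, tmp_path):
        gen_dihedral(tmp_path / "d.xvg", seed=9, n_frames=500, mu_deg=179.0, kappa=2.0)
        table = read_xvg(tmp_path / "d.xvg")
        assert np.all(table.columns[1] >= -180) and np.all(table.columns[1] < 180)
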