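import warnings

import numpy as np
import pytest
from scipy import stats

from impactkin import dataio, metrics
from impactkin.errors import ConfigError, DegenerateDataWarning

FS = 1000.0


def _record(lin=None, ang=None, ang_acc=None, m=100):
    t = np.arange(m) / FS
    return dataio.KinematicRecord(
        "r",
        t,
        np.zeros((3, m)) if lin is None else lin,
        np.zeros((3, m)) if ang is None else ang,
        FS,
        ang_acc=ang_acc,
    )


def _brute_force_windowed(trace, fs, w_max):
    """O(m^2) reference search over all sample-aligned windows."""
    m = len(trace)
    dt = 1.0 / fs
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (trace[1:] + trace[:-1]) * dt)]
    )
    best = 0.0
    for i in range(m):
        for j in range(i + 1, min(i + w_max, m - 1) + 1):
            span = (j - i) * dt
            best = max(best, span * ((cum[j] - cum[i]) / span) ** 2.5)
    return best


class TestHIC:
    def test_constant_100g_closed_form(self):
        lin = np.zeros((3, 100))
        lin[0] = 100.0 * metrics.GRAVITY
        assert metrics.hic15(_record(lin=lin)) == pytest.approx(1500.0)

    def test_zero_acceleration_gives_zero(self):
        assert metrics.hic15(_record()) == 0.0

    def test_matches_brute_force_window_search(self, rng):
        for _ in range(25):
            lin = np.zeros((3, 100))
            lin[0] = np.abs(rng.normal(size=100)) * 30 * metrics.GRAVITY
            rec = _record(lin=lin)
            expected = _brute_force_windowed(lin[0] / metrics.GRAVITY, FS, 15)
            assert metrics.hic15(rec) == pytest.approx(expected, rel=1e-12)

    def test_sign_flip_invariance_and_power_scaling(self, rng):
        lin = rng.normal(size=(3, 100)) * 50
        assert metrics.hic15(_record(lin=lin)) == pytest.approx(
            metrics.hic15(_record(lin=-lin))
        )
        assert metrics.hic15(_record(lin=3 * lin)) == pytest.approx(
            3**2.5 * metrics.hic15(_record(lin=lin))
        )


class TestRIC:
    def test_constant_resultant_closed_form(self):
        aac = np.zeros((3, 100))
        aac[1] = 1000.0
        val = metrics.ric36(_record(ang_acc=aac))
        assert val == pytest.approx(1000.0**2.5 * 0.036)

    def test_matches_brute_force_window_search(self, rng):
        for _ in range(10):
            aac = np.zeros((3, 100))
            aac[2] = np.abs(rng.normal(size=100)) * 2000
            expected = _brute_force_windowed(aac[2], FS, 36)
            assert metrics.ric36(_record(ang_acc=aac)) == pytest.approx(
                expected, rel=1e-12
            )


class TestBrIC:
    def test_single_axis_at_critical_is_one(self):
        ang = np.zeros((3, 100))
        ang[0, 40] = metrics.BRIC_CRITICAL_DEFAULT[0]
        assert metrics.bric(_record(ang=ang)) == pytest.approx(1.0)

    def test_all_axes_at_critical_is_sqrt3(self):
        ang = np.zeros((3, 100))
        for d in range(3):
            ang[d, 30 + d] = metrics.BRIC_CRITICAL_DEFAULT[d]
        assert metrics.bric(_record(ang=ang)) == pytest.approx(np.sqrt(3.0))

    def test_zero_motion_gives_zero(self):
        assert metrics.bric(_record()) == 0.0

    def test_monotone_in_each_axis_peak(self, rng):
        ang = np.abs(rng.normal(size=(3, 100))) * 10
        base = metrics.bric(_record(ang=ang))
        bumped = ang.copy()
        bumped[1] *= 1.5
        assert metrics.bric(_record(ang=bumped)) >= base

    def test_nonpositive_critical_rejected(self):
        with pytest.raises(ConfigError):
            metrics.bric(_record(), critical_values=(1.0, 0.0, 1.0))


class TestBAM:
    params = metrics.BAMParams(
        inertia=(0.016,) * 3, stiffness=(142.0,) * 3, damping=(0.9,) * 3
    )

    def test_rest_stays_at_rest(self):
        assert metrics.bam(_record(), self.params) == 0.0

    def test_steady_state_under_constant_forcing(self):
        # critically damped so the response settles monotonically at
        # theta = I*alpha0 / k
        I, k = 0.016, 142.0
        crit = metrics.BAMParams(
            inertia=(I,) * 3,
            stiffness=(k,) * 3,
            damping=(2 * np.sqrt(k * I),) * 3,
        )
        aac = np.zeros((3, 1000))
        aac[0] = 500.0
        val = metrics.bam(_record(ang_acc=aac, m=1000), crit)
        assert val == pytest.approx(I * 500.0 / k, rel=1e-3)

    def test_step_halving_self_convergence(self):
        aac = np.zeros((3, 100))
        aac[1] = 800.0 * np.sin(2 * np.pi * 30 * np.arange(100) / FS)
        rec = _record(ang_acc=aac)
        coarse = metrics.bam(
            rec, metrics.BAMParams((0.016,) * 3, (142.0,) * 3, (0.9,) * 3, substeps=2)
        )
        fine = metrics.bam(
            rec, metrics.BAMParams((0.016,) * 3, (142.0,) * 3, (0.9,) * 3, substeps=4)
        )
        assert abs(coarse - fine) / fine < 1e-3

    def test_rigid_coupling_limit(self):
        aac = np.zeros((3, 200))
        aac[0] = 500.0
        soft = metrics.bam(_record(ang_acc=aac, m=200), self.params)
        rigid = metrics.bam(
            _record(ang_acc=aac, m=200),
            metrics.BAMParams(
                (0.016,) * 3, (142.0e6,) * 3, (0.9,) * 3, substeps=200
            ),
        )
        assert rigid < 1e-4 * soft

    def test_divergent_integration_is_reported(self):
        aac = np.zeros((3, 100))
        aac[0] = 500.0
        unstable = metrics.BAMParams(
            (0.016,) * 3, (142.0e6,) * 3, (0.9,) * 3, substeps=1
        )
        with pytest.raises(ConfigError, match="diverged"):
            metrics.bam(_record(ang_acc=aac), unstable)


class TestErrorAndClassification:
    def test_percent_error_examples(self):
        assert metrics.metric_error(1.0, 1.0) == 0.0
        assert metrics.metric_error(1.1, 1.0) == pytest.approx(10.0)
        with pytest.raises(ConfigError):
            metrics.metric_error(1.0, 0.0)

    def test_vectorized_errors_exclude_zero_ground_truth(self):
        errs, n_excluded = metrics.metric_errors(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 2.0])
        )
        np.testing.assert_allclose(errs, [0.0, 50.0])
        assert n_excluded == 1

    def test_perfect_agreement(self):
        rep = metrics.classify_and_confuse(
            np.array([1, 5, 2, 7.0]), np.array([1, 5, 2, 7.0]), 4.0
        )
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_all_negative_predictions_zero_sensitivity(self):
        rep = metrics.classify_and_confuse(
            np.array([10.0, 1.0]), np.array([0.0, 0.0]), 4.0
        )
        assert rep.sensitivity == 0.0

    def test_hand_counted_two_by_two_table(self):
        rep = metrics.classify_and_confuse(
            np.array([1, 3, 5, 7.0]), np.array([1, 5, 3, 7.0]), 4.0
        )
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (1, 1, 1, 1)
        assert rep.sensitivity == 0.5 and rep.specificity == 0.5
        assert rep.n == 4

    def test_undefined_rates_when_class_absent(self):
        rep = metrics.classify_and_confuse(
            np.array([1.0, 2.0]), np.array([1.0, 2.0]), 10.0
        )
        assert rep.sensitivity is None
        assert rep.specificity == 1.0


class TestFriedman:
    def test_identical_columns_degenerate(self):
        with pytest.warns(DegenerateDataWarning):
            chi2, p = metrics.friedman_test(np.ones((5, 3)))
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_strict_ordering_table(self):
        # 4 records, 3 methods, method order identical in every record:
        # rank sums (4, 8, 12) -> chi2 = 12*4/(3*4) * [(1-2)^2 + 0 + (3-2)^2] = 8
        X = np.array([[1.0, 2.0, 3.0]] * 4) + 10 * np.arange(4)[:, None]
        chi2, p = metrics.friedman_test(X)
        assert chi2 == pytest.approx(8.0)
        assert p == pytest.approx(float(stats.chi2.sf(8.0, 2)))

    def test_matches_reference_implementation_with_ties(self, rng):
        X = rng.normal(size=(20, 3))
        X[3, 1] = X[3, 2]  # plant a tie
        chi2, p = metrics.friedman_test(X)
        ref = stats.friedmanchisquare(*X.T)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_rejects_tiny_inputs(self):
        with pytest.raises(ConfigError):
            metrics.friedman_test(np.ones((1, 3)))
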