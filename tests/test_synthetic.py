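"""Regime-switching generator and cohort construction."""

import numpy as np
import pytest
from scipy import signal as sps

from eegstates.synthetic import (
    CohortSpec,
    GroupSpec,
    RegimeSpec,
    ar2_coefficients,
    make_cohort,
    make_coupled_cohort,
    make_regime_signal,
)


def two_oscillators():
    return [
        RegimeSpec(0, "ar2_oscillator", (6.0, 0.95)),
        RegimeSpec(1, "ar2_oscillator", (11.0, 0.95)),
    ]


def cohort_spec(**overrides):
    base = dict(
        n_subjects=6,
        groups=[GroupSpec("g1", 10.0), GroupSpec("g2", 11.5), GroupSpec("g3", 13.0)],
        conditions=["eyes_open", "eyes_closed"],
        n_channels=4,
        focal_channels=(0, 1),
        epoch_length_s=4.0,
        fs=128.0,
        n_epochs_per_condition=2,
        regimes_by_group={"g1": 2, "g2": 2, "g3": 2},
        dwell_by_group={"g1": 2.0, "g2": 1.5, "g3": 1.0},
        seed=0,
    )
    base.update(overrides)
    return CohortSpec(**base)


class TestMakeRegimeSignal:
    def test_single_regime_single_run(self):
        x, truth = make_regime_signal(two_oscillators()[:1], 2.0, 10.0, 128.0, seed=0)
        assert truth.n_runs == 1
        assert truth.run_lengths(len(x)).sum() == len(x)
        assert truth.true_k == 1

    def test_two_regimes_fixed_dwell_alternate(self):
        x, truth = make_regime_signal(two_oscillators(), 2.0, 10.0, 128.0, seed=0)
        assert truth.n_runs == 5
        assert truth.run_labels.tolist() == [0, 1, 0, 1, 0]
        np.testing.assert_array_equal(truth.switch_times, [256, 512, 768, 1024])

    def test_logistic_recurrence_holds_within_run(self):
        regime = RegimeSpec(0, "polynomial_map", (0.0, 3.9, -3.9))
        x, truth = make_regime_signal([regime], 64.0, 64.0, 1.0, seed=2)
        np.testing.assert_allclose(x[1:], 3.9 * x[:-1] * (1 - x[:-1]), atol=1e-12)

    def test_reproducible_under_seed(self):
        a, ta = make_regime_signal(two_oscillators(), 1.5, 8.0, 128.0, seed=42)
        b, tb = make_regime_signal(two_oscillators(), 1.5, 8.0, 128.0, seed=42)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ta.labels, tb.labels)

    def test_run_lengths_cover_every_sample(self, rng):
        for seed in range(5):
            x, truth = make_regime_signal(
                two_oscillators(), 1.0, 7.3, 128.0, seed=seed, dwell_model="exponential"
            )
            lens = truth.run_lengths(len(x))
            assert lens.sum() == len(x)
            assert (lens > 0).all()

    def test_ar2_periodogram_peak_near_centre_frequency(self):
        fs = 128.0
        for freq in (6.0, 11.0, 21.0):
            regime = RegimeSpec(0, "ar2_oscillator", (freq, 0.95))
            x, _ = make_regime_signal([regime], 120.0, 120.0, fs, seed=1)
            f, pxx = sps.welch(x, fs=fs, nperseg=256)
            peak = f[np.argmax(pxx)]
            assert abs(peak - freq) <= fs / 256 + 1e-9  # within one bin

    def test_divergent_polynomial_map_rejected(self):
        bad = RegimeSpec(7, "polynomial_map", (0.0, 5.5))  # |x| grows without bound
        with pytest.raises(ValueError, match="regime 7 diverged"):
            make_regime_signal([bad], 50.0, 50.0, 1.0, seed=0)

    def test_sub_3_sample_dwell_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            make_regime_signal(two_oscillators(), 0.01, 1.0, 128.0)

    def test_frequency_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ar2_coefficients(80.0, 0.95, 128.0)


class TestMakeCohort:
    def test_epoch_counting(self):
        epochs, truth = make_cohort(cohort_spec())
        # 6 subjects x 3 visits x 2 conditions x 2 epochs
        assert len(epochs) == 72
        per_group = truth.summary.groupby("group").apply(
            lambda g: len(g[["subject", "condition", "epoch"]].drop_duplicates()),
            include_groups=False,
        )
        assert (per_group == 24).all()

    def test_dwell_effect_decreases_across_groups(self):
        _, truth = make_cohort(cohort_spec())
        dwell = truth.summary.groupby("group")["true_mean_dwell_s"].mean()
        assert dwell["g1"] > dwell["g2"] > dwell["g3"]

    def test_focal_k_effect_limited_to_focal_channels(self):
        spec = cohort_spec(
            regimes_by_group={"g1": 2, "g2": 3, "g3": 4},
            dwell_by_group={"g1": 1.5, "g2": 1.5, "g3": 1.5},
            epoch_length_s=8.0,
        )
        _, truth = make_cohort(spec)
        s = truth.summary
        focal = s[s.channel.isin(["ch00", "ch01"])]
        nonfocal = s[~s.channel.isin(["ch00", "ch01"])]
        assert focal.groupby("group")["true_k"].mean().is_monotonic_increasing
        assert (nonfocal.groupby("group")["true_k"].mean() == 2).all()

    def test_same_spec_different_seed_same_truth_structure(self):
        e1, t1 = make_cohort(cohort_spec(seed=1))
        e2, t2 = make_cohort(cohort_spec(seed=2))
        assert not np.allclose(e1[0].data, e2[0].data)
        cols = ["subject", "group", "condition", "epoch", "channel", "true_k"]
        assert t1.summary[cols].equals(t2.summary[cols])

    def test_byte_identical_under_same_seed(self):
        e1, _ = make_cohort(cohort_spec(seed=3))
        e2, _ = make_cohort(cohort_spec(seed=3))
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.data, b.data)

    def test_inconsistent_group_keys_rejected(self):
        with pytest.raises(ValueError, match="regimes_by_group"):
            make_cohort(cohort_spec(regimes_by_group={"g1": 2, "wrong": 2, "g3": 2}))

    def test_epochs_are_mean_free(self):
        epochs, _ = make_cohort(cohort_spec())
        for ep in epochs[:5]:
            np.testing.assert_allclose(ep.data.mean(axis=1), 0.0, atol=1e-10)

    def test_between_design_assigns_each_subject_one_group(self):
        epochs, truth = make_cohort(cohort_spec(design="between"))
        groups_per_subject = truth.summary.groupby("subject")["group"].nunique()
        assert (groups_per_subject == 1).all()


class TestCoupledCohort:
    def test_truth_table_and_shapes(self):
        epochs, truth = make_coupled_cohort(n_subjects=4, n_epochs_per_condition=1, seed=0)
        assert len(truth) == 4
        assert len(epochs) == 8  # 4 subjects x 2 conditions
        assert set(truth.columns) == {"subject", "dwell_s", "k_focal"}
        assert truth.dwell_s.between(1.4, 2.6).all()

    def test_alpha_power_rises_with_k_on_focal_channels(self):
        from eegstates.spectral import relative_power
        import pandas as pd

        epochs, truth = make_coupled_cohort(n_subjects=9, n_epochs_per_condition=1, seed=1)
        power = pd.concat([relative_power(ep) for ep in epochs], ignore_index=True)
        alpha = power[(power.freq_hz >= 9) & (power.freq_hz <= 11)]
        alpha = alpha[alpha.channel.isin(["ch00", "ch01", "ch02"])]
        merged = alpha.groupby("subject", as_index=False)["rel_power"].mean().merge(truth)
        by_k = merged.groupby("k_focal")["rel_power"].mean()
        assert by_k.loc[4] > by_k.loc[2]
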