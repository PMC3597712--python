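"""Piecewise-stationary signal and cohort simulation with known ground truth.

Real resting EEG is modelled here only at the level the analysis pipeline
cares about: each channel is a piecewise process that switches between a small
repertoire of quasi-stationary dynamical regimes.  Two regime families are
provided:

* ``ar2_oscillator`` — a damped stochastic oscillator (AR(2) process with a
  spectral peak at a chosen centre frequency), the default building block for
  multichannel cohorts because distinct frequencies give cleanly separable
  windowed model coefficients;
* ``polynomial_map`` — a deterministic scalar polynomial map (e.g. the
  logistic map), useful for exact single-channel recovery tests.

Cohorts encode the two mechanisms of increasing non-stationarity: a growing
number of states ``K`` (localised to a set of focal channels by default) and a
shrinking mean dwell time (global by default), both varying with an age-like
group covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import EpochRecord

__all__ = [
    "RegimeSpec",
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "CohortTruth",
    "ar2_coefficients",
    "make_regime_signal",
    "make_cohort",
    "make_coupled_cohort",
    "default_regime_palette",
]

#: default AR(2) centre frequencies (Hz) handed out to a channel's K regimes
DEFAULT_FREQS: tuple[float, ...] = (6.0, 11.0, 16.0, 21.0, 26.0, 31.0)

_DIVERGENCE_BOUND = 1e6


@dataclass
class RegimeSpec:
    """One quasi-stationary dynamical regime.

    For ``ar2_oscillator`` the params are ``(centre_freq_hz, damping)`` with an
    optional third entry, the innovation SD (default 1.0).  For
    ``polynomial_map`` the params are the map coefficients ``a_k`` of
    ``x[n+1] = sum_k a_k * x[n]**k``; trajectories start uniformly inside
    ``init_range`` and must stay bounded.
    """

    regime_id: int
    dynamics_kind: str  # "polynomial_map" | "ar2_oscillator"
    params: tuple[float, ...]
    noise_sd: float = 0.0
    init_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.dynamics_kind not in ("polynomial_map", "ar2_oscillator"):
            raise ValueError(f"unknown dynamics_kind {self.dynamics_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroupSpec:
    """An age group (or visit): label plus the age distribution it represents."""

    label: str
    age_mean: float
    age_sd: float = 0.4


@dataclass
class GroundTruth:
    """Generation record for one channel of one epoch.

    ``labels[t]`` is the index (into the regime list) active at sample ``t``;
    ``run_starts`` are the start samples of the maximal constant-regime runs
    (the first is always 0, the rest are the switch times).
    """

    labels: np.ndarray
    run_starts: np.ndarray
    run_labels: np.ndarray
    true_k: int
    mean_dwell_samples: float

    @property
    def switch_times(self) -> np.ndarray:
        return self.run_starts[1:]

    @property
    def n_runs(self) -> int:
        return len(self.run_starts)

    def run_lengths(self, n_samples: int) -> np.ndarray:
        bounds = np.append(self.run_starts, n_samples)
        return np.diff(bounds)


def ar2_coefficients(freq_hz: float, damping: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients of a stochastic oscillator with a peak near ``freq_hz``.

    ``x[t] = phi1*x[t-1] + phi2*x[t-2] + e[t]`` with complex roots of modulus
    ``damping`` at angle ``2*pi*freq_hz/fs``.
    """
    if not 0.0 < freq_hz < fs / 2.0:
        raise ValueError(f"centre frequency {freq_hz} Hz outside (0, Nyquist={fs / 2})")
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    theta = 2.0 * np.pi * freq_hz / fs
    return 2.0 * damping * np.cos(theta), -damping**2


def _simulate_ar2(
    phi1: float,
    phi2: float,
    n: int,
    rng: np.random.Generator,
    state: tuple[float, float] | None,
    innovation_sd: float,
) -> tuple[np.ndarray, tuple[float, float]]:
    x = np.empty(n + 2)
    if state is None:
        x[0] = x[1] = 0.0
        burn = rng.standard_normal(200) * innovation_sd
        b0 = b1 = 0.0
        for e in burn:
            b0, b1 = b1, phi1 * b1 + phi2 * b0 + e
        x[0], x[1] = b0, b1
    else:
        x[0], x[1] = state
    eps = rng.standard_normal(n) * innovation_sd
    for t in range(n):
        x[t + 2] = phi1 * x[t + 1] + phi2 * x[t] + eps[t]
    return x[2:], (x[-2], x[-1])


def _simulate_poly_map(
    coefs: tuple[float, ...],
    n: int,
    rng: np.random.Generator,
    init_range: tuple[float, float],
    regime_id: int,
) -> np.ndarray:
    a = np.asarray(coefs, dtype=float)
    x = np.empty(n)
    x[0] = rng.uniform(*init_range)
    powers = np.arange(len(a))
    for t in range(1, n):
        x[t] = float(np.sum(a * x[t - 1] ** powers))
        if not np.isfinite(x[t]) or abs(x[t]) > _DIVERGENCE_BOUND:
            raise ValueError(
                f"polynomial_map regime {regime_id} diverged at step {t} "
                f"(|x| > {_DIVERGENCE_BOUND:g}); check its coefficients/init_range"
            )
    return x


def _run_lengths(
    n: int, dwell_samples: float, dwell_model: str, rng: np.random.Generator
) -> list[int]:
    lengths: list[int] = []
    total = 0
    while total < n:
        if dwell_model == "fixed":
            d = int(round(dwell_samples))
        elif dwell_model == "exponential":
            d = max(3, int(round(rng.exponential(dwell_samples))))
        else:
            raise ValueError(f"unknown dwell_model {dwell_model!r}")
        d = min(d, n - total)
        lengths.append(d)
        total += d
    return lengths


def make_regime_signal(
    regimes: list[RegimeSpec],
    dwell_s: float,
    length_s: float,
    fs: float,
    seed: int = 0,
    dwell_model: str = "fixed",
    regime_order: str = "cyclic",
) -> tuple[np.ndarray, GroundTruth]:
    """Generate one channel alternating between regimes, with exact ground truth.

    Regimes follow each other cyclically (default, deterministic) or in a
    uniform random order without immediate repeats.  Dwell segments have fixed
    length ``dwell_s`` or exponentially distributed lengths with that mean.
    AR(2) regimes continue from the running signal state so switches do not
    introduce jumps; polynomial-map regimes restart inside their ``init_range``.
    """
    if not regimes:
        raise ValueError("need at least one regime")
    if dwell_s <= 0:
        raise ValueError("dwell_s must be positive")
    if length_s < dwell_s:
        raise ValueError("length_s must be at least dwell_s")
    dwell_samples = dwell_s * fs
    if dwell_samples < 3:
        raise ValueError(f"dwell of {dwell_samples:.1f} samples is shorter than 3 samples")

    rng = np.random.default_rng(seed)
    n = int(round(length_s * fs))
    lengths = _run_lengths(n, dwell_samples, dwell_model, rng)
    k = len(regimes)

    # regime index per run
    order: list[int] = []
    prev = -1
    for r in range(len(lengths)):
        if regime_order == "cyclic":
            idx = r % k
        elif regime_order == "random":
            if k == 1:
                idx = 0
            else:
                choices = [i for i in range(k) if i != prev]
                idx = int(rng.choice(choices))
        else:
            raise ValueError(f"unknown regime_order {regime_order!r}")
        order.append(idx)
        prev = idx

    x = np.empty(n)
    labels = np.empty(n, dtype=int)
    ar_state: tuple[float, float] | None = None
    pos = 0
    for run_len, idx in zip(lengths, order):
        spec = regimes[idx]
        if spec.dynamics_kind == "ar2_oscillator":
            freq, damping = spec.params[0], spec.params[1]
            inn = spec.params[2] if len(spec.params) > 2 else 1.0
            phi1, phi2 = ar2_coefficients(freq, damping, fs)
            seg, ar_state = _simulate_ar2(phi1, phi2, run_len, rng, ar_state, inn)
        else:
            seg = _simulate_poly_map(spec.params, run_len, rng, spec.init_range, spec.regime_id)
            ar_state = (seg[-2] if run_len > 1 else seg[-1], seg[-1])
        x[pos : pos + run_len] = seg
        labels[pos : pos + run_len] = idx
        pos += run_len

    # observation noise, per-regime SD
    sds = np.array([r.noise_sd for r in regimes])
    if np.any(sds > 0):
        x = x + rng.standard_normal(n) * sds[labels]

    # merge adjacent runs of the same regime for the truth record
    change = np.flatnonzero(np.diff(labels)) + 1
    run_starts = np.concatenate(([0], change))
    run_labels = labels[run_starts]
    run_lens = np.diff(np.append(run_starts, n))
    truth = GroundTruth(
        labels=labels,
        run_starts=run_starts,
        run_labels=run_labels,
        true_k=len(np.unique(labels)),
        mean_dwell_samples=float(run_lens.mean()),
    )
    return x, truth


def default_regime_palette(
    k: int, fs: float, freqs: tuple[float, ...] = DEFAULT_FREQS, damping: float = 0.95
) -> list[RegimeSpec]:
    """K AR(2) oscillator regimes at distinct centre frequencies."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > len(freqs):
        raise ValueError(f"palette has only {len(freqs)} frequencies, K={k} requested")
    return [
        RegimeSpec(regime_id=i, dynamics_kind="ar2_oscillator", params=(freqs[i], damping))
        for i in range(k)
    ]


@dataclass
class CohortSpec:
    """A whole synthetic cohort: who is measured, and which effects are built in.

    ``groups`` are age groups; with ``design="longitudinal"`` every subject is
    seen once per group (the groups act as visits, ages jittered around the
    group mean), with ``design="between"`` subjects are split across groups.
    ``regimes_by_group`` sets the true number of regimes K per group and
    ``dwell_by_group`` the mean dwell time (s); each applies either to the
    ``focal_channels`` only or to all channels, controlled by ``k_scope`` and
    ``dwell_scope``.  Channels are generated independently (no mixing) unless
    ``mixing_strength > 0``, which blends each channel with the channel mean to
    emulate volume-conduction spread.
    """

    n_subjects: int
    groups: list[GroupSpec]
    conditions: list[str]
    n_channels: int
    focal_channels: tuple[int, ...]
    epoch_length_s: float
    fs: float
    n_epochs_per_condition: int
    regimes_by_group: dict[str, int]
    dwell_by_group: dict[str, float]
    seed: int = 0
    design: str = "longitudinal"  # or "between"
    k_scope: str = "focal"  # or "global"
    dwell_scope: str = "global"  # or "focal"
    dwell_model: str = "fixed"
    regime_order: str = "cyclic"
    noise_frac: float = 0.1  # observation-noise SD as a fraction of clean signal SD
    regime_freqs: tuple[float, ...] = DEFAULT_FREQS
    damping: float = 0.95
    mixing_strength: float = 0.0

    def validate(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        for name, mapping in (("regimes_by_group", self.regimes_by_group),
                              ("dwell_by_group", self.dwell_by_group)):
            if set(mapping) != set(labels):
                raise ValueError(
                    f"{name} keys {sorted(mapping)} do not match group labels {sorted(labels)}"
                )
        if any(k < 1 for k in self.regimes_by_group.values()):
            raise ValueError("every group needs K >= 1")
        if not set(self.focal_channels) <= set(range(self.n_channels)):
            raise ValueError("focal_channels outside the channel range")
        if self.design not in ("longitudinal", "between"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class CohortTruth:
    """Tidy per-epoch/channel generation record plus optional sample labels."""

    summary: pd.DataFrame
    labels: dict[tuple, GroundTruth] = field(default_factory=dict)


def _value_for_channel(
    by_group: dict, group: str, base_group: str, scope: str, ch: int, focal: set[int]
):
    if scope == "global" or ch in focal:
        return by_group[group]
    return by_group[base_group]


def make_cohort(
    spec: CohortSpec, keep_labels: bool = False
) -> tuple[list[EpochRecord], CohortTruth]:
    """Generate every epoch of a cohort, deterministic under ``spec.seed``.

    Returns the epochs (per-channel mean already removed) and the ground-truth
    record.  Localised effects touch only ``focal_channels``; global effects
    touch every channel.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base_group = spec.groups[0].label
    focal = set(spec.focal_channels)

    if spec.design == "between":
        group_of_subject = {
            s: spec.groups[s % len(spec.groups)].label for s in range(spec.n_subjects)
        }

    epochs: list[EpochRecord] = []
    rows = []
    truth_labels: dict[tuple, GroundTruth] = {}
    for s in range(spec.n_subjects):
        subject = f"sub{s:03d}"
        for g in spec.groups:
            if spec.design == "between" and group_of_subject[s] != g.label:
                continue
            age = float(g.age_mean + rng.normal(0.0, g.age_sd))
            for cond in spec.conditions:
                for ep in range(spec.n_epochs_per_condition):
                    data = np.empty((spec.n_channels, int(round(spec.epoch_length_s * spec.fs))))
                    for ch in range(spec.n_channels):
                        k = _value_for_channel(
                            spec.regimes_by_group, g.label, base_group, spec.k_scope, ch, focal
                        )
                        dwell = _value_for_channel(
                            spec.dwell_by_group, g.label, base_group, spec.dwell_scope, ch, focal
                        )
                        regimes = default_regime_palette(
                            k, spec.fs, spec.regime_freqs, spec.damping
                        )
                        child_seed = int(rng.integers(0, 2**31 - 1))
                        x, truth = make_regime_signal(
                            regimes,
                            dwell_s=dwell,
                            length_s=spec.epoch_length_s,
                            fs=spec.fs,
                            seed=child_seed,
                            dwell_model=spec.dwell_model,
                            regime_order=spec.regime_order,
                        )
                        if spec.noise_frac > 0:
                            x = x + rng.standard_normal(len(x)) * (spec.noise_frac * x.std())
                        data[ch] = x
                        key = (subject, g.label, cond, ep, ch)
                        rows.append(
                            {
                                "subject": subject,
                                "group": g.label,
                                "age": age,
                                "condition": cond,
                                "epoch": ep,
                                "channel": f"ch{ch:02d}",
                                "true_k": truth.true_k,
                                "true_mean_dwell_s": truth.mean_dwell_samples / spec.fs,
                                "n_switches": len(truth.switch_times),
                            }
                        )
                        if keep_labels:
                            truth_labels[key] = truth
                    if spec.mixing_strength > 0:
                        common = data.mean(axis=0, keepdims=True)
                        data = (1.0 - spec.mixing_strength) * data + spec.mixing_strength * common
                    data -= data.mean(axis=1, keepdims=True)
                    epochs.append(
                        EpochRecord(
                            data=data,
                            fs=spec.fs,
                            subject_id=subject,
                            group=g.label,
                            condition=cond,
                            epoch_index=ep,
                            channel_names=[f"ch{c:02d}" for c in range(spec.n_channels)],
                            age=age,
                        )
                    )
    return epochs, CohortTruth(summary=pd.DataFrame(rows), labels=truth_labels)


def make_coupled_cohort(
    n_subjects: int = 20,
    conditions: tuple[str, ...] = ("eyes_open", "eyes_closed"),
    n_channels: int = 6,
    focal_channels: tuple[int, ...] = (0, 1, 2),
    fs: float = 128.0,
    epoch_length_s: float = 16.0,
    n_epochs_per_condition: int = 3,
    seed: int = 0,
    dwell_range_s: tuple[float, float] = (1.4, 3.2),
    k_choices: tuple[int, ...] = (2, 3, 4),
    lowfreq_hz: float = 3.5,
    alpha_hz: float = 10.0,
    lowfreq_gain: float = 0.35,
    alpha_gain: float = 0.4,
    noise_frac: float = 0.1,
) -> tuple[list[EpochRecord], pd.DataFrame]:
    """Cohort coupling non-stationarity to spectral power, for association tests.

    Two couplings are built in, mirroring the two mechanisms of
    non-stationarity and their spectral signatures:

    * globally, each subject's regime dwell time varies, and a low-frequency
      oscillatory component is added to **all** channels with amplitude
      proportional to the switch rate (1/dwell) — faster alternation goes with
      more low-frequency power;
    * on the focal channels only, the number of regimes K varies across
      subjects, and an alpha-band component is added with amplitude growing
      with K — a richer state repertoire goes with more alpha power.

    Regime centre frequencies (5, 12, 16, 20 Hz) avoid the low (1-4 Hz) and
    alpha (9-11 Hz) bands being tested.  Returns the epochs and a per-subject
    truth table (dwell_s, k_focal).
    """
    rng = np.random.default_rng(seed)
    focal = set(focal_channels)
    palette = (5.0, 12.0, 16.0, 20.0)
    dwell_ref = float(np.mean(dwell_range_s))
    n = int(round(epoch_length_s * fs))

    epochs: list[EpochRecord] = []
    rows = []
    for s in range(n_subjects):
        subject = f"sub{s:03d}"
        dwell = float(rng.uniform(*dwell_range_s))
        k_focal = int(k_choices[s % len(k_choices)])
        rows.append({"subject": subject, "dwell_s": dwell, "k_focal": k_focal})
        w_lf = lowfreq_gain * dwell_ref / dwell
        w_alpha = alpha_gain * (k_focal - 1)
        for cond in conditions:
            for ep in range(n_epochs_per_condition):
                data = np.empty((n_channels, n))
                for ch in range(n_channels):
                    k = k_focal if ch in focal else 2
                    regimes = default_regime_palette(k, fs, palette, damping=0.95)
                    x, _ = make_regime_signal(
                        regimes,
                        dwell_s=dwell,
                        length_s=epoch_length_s,
                        fs=fs,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    x = x / x.std()
                    lf, _ = _component(lowfreq_hz, fs, n, rng)
                    x = x + w_lf * lf
                    if ch in focal and w_alpha > 0:
                        al, _ = _component(alpha_hz, fs, n, rng)
                        x = x + w_alpha * al
                    x = x + rng.standard_normal(n) * (noise_frac * x.std())
                    data[ch] = x
                data -= data.mean(axis=1, keepdims=True)
                epochs.append(
                    EpochRecord(
                        data=data,
                        fs=fs,
                        subject_id=subject,
                        group="all",
                        condition=cond,
                        epoch_index=ep,
                        channel_names=[f"ch{c:02d}" for c in range(n_channels)],
                    )
                )
    return epochs, pd.DataFrame(rows)


def _component(freq: float, fs: float, n: int, rng: np.random.Generator) -> tuple[np.ndarray, None]:
    """Unit-SD AR(2) oscillator component at ``freq`` Hz."""
    phi1, phi2 = ar2_coefficients(freq, 0.95, fs)
    x, _ = _simulate_ar2(phi1, phi2, n, rng, None, 1.0)
    sd = x.std()
    return (x / sd if sd > 0 else x), None
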