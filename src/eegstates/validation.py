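"""Canonical synthetic validation scenarios with known ground truth.

Each function builds one study condition from the synthetic generator, runs
the analysis pipeline on it, and reports recovery statistics against the
generative truth.  The same scenarios back the test suite and the
reproduction script, so the numbers they print are always recomputed from
scratch.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .clustering import ClusterConfig
from .pipeline import SegmentationConfig, measures_table, process_channel
from .pls import (
    bootstrap_ratios,
    linear_trend_contrast,
    permutation_test,
    pls_data_from_table,
)
from .segmentation import fit_poly_map
from .spectral import power_nonstat_correlation, relative_power
from .synthetic import (
    CohortSpec,
    GroundTruth,
    GroupSpec,
    RegimeSpec,
    make_cohort,
    make_coupled_cohort,
    make_regime_signal,
)

__all__ = [
    "two_tone_signal",
    "regime_recovery",
    "label_agreement",
    "random_blob_instance",
    "exhaustive_net_similarity",
    "logistic_map_recovery",
    "null_cohort_spec",
    "null_calibration",
    "age_effect_cohort_spec",
    "age_effect_recovery",
    "spectral_association",
]


def two_tone_signal(seed: int = 0) -> tuple[np.ndarray, GroundTruth, float]:
    """30 s single channel at 256 Hz alternating 6 Hz and 11 Hz AR(2) regimes.

    Fixed 2 s dwell; observation noise with SD equal to 10% of the clean
    signal's SD.  Returns (noisy demeaned signal, ground truth, fs).
    """
    fs = 256.0
    regimes = [
        RegimeSpec(0, "ar2_oscillator", (6.0, 0.95)),
        RegimeSpec(1, "ar2_oscillator", (11.0, 0.95)),
    ]
    x, truth = make_regime_signal(regimes, dwell_s=2.0, length_s=30.0, fs=fs, seed=seed)
    rng = np.random.default_rng(seed + 1_000_003)
    x = x + rng.standard_normal(len(x)) * 0.1 * x.std()
    return x - x.mean(), truth, fs


def label_agreement(labels: np.ndarray, true_labels: np.ndarray, max_k: int = 7) -> float:
    """Best-permutation window-label agreement between two labelings."""
    labels = np.asarray(labels)
    true_labels = np.asarray(true_labels)
    k = max(labels.max(), true_labels.max()) + 1
    if k > max_k:
        return 0.0
    best = 0.0
    for perm in permutations(range(k)):
        mapped = np.array([perm[l] for l in labels])
        best = max(best, float((mapped == true_labels).mean()))
    return best


def regime_recovery(seed: int = 0) -> dict:
    """Run the default pipeline on the two-tone signal; compare with truth.

    Ground-truth window labels are the majority sample label inside each
    window (at the analysis rate).  Returns the recovered state count and the
    best-permutation agreement.
    """
    x, truth, fs = two_tone_signal(seed)
    seg_cfg = SegmentationConfig()
    labels, assignment, grid, fs_an = process_channel(x, fs, seg_cfg, ClusterConfig(), seed)
    stride = int(round(fs / fs_an))
    tl = truth.labels[::stride]
    window_truth = np.array(
        [np.bincount(tl[s : s + grid.window_len]).argmax() for s in grid.starts]
    )
    return {
        "n_states": assignment.n_clusters,
        "agreement": label_agreement(labels, window_truth),
        "n_windows": grid.n_windows,
    }


def random_blob_instance(
    rng: np.random.Generator,
    spread: float = 0.1,
    separation: float = 1.0,
    min_ratio: float = 5.0,
) -> np.ndarray:
    """Two well-separated 2-D blobs of 2-4 points each.

    The within-blob deviations are rescaled until the smallest between-blob
    point distance is at least ``min_ratio`` times the largest within-blob
    pairwise distance (separation ratio >= ``min_ratio`` by construction).
    Returns the pairwise distance matrix.
    """
    from scipy.spatial.distance import cdist, pdist, squareform

    n1 = int(rng.integers(2, 5))
    n2 = int(rng.integers(2, 5))
    c1 = rng.normal(0.0, 1.0, 2)
    c2 = c1 + np.array([separation, 0.0])
    dev1 = spread * rng.normal(0.0, 1.0, (n1, 2))
    dev2 = spread * rng.normal(0.0, 1.0, (n2, 2))
    for _ in range(20):
        max_within = max(pdist(dev1).max(), pdist(dev2).max())
        min_between = cdist(c1 + dev1, c2 + dev2).min()
        if min_between >= min_ratio * max_within:
            break
        shrink = min_between / (min_ratio * max_within)
        dev1 *= shrink
        dev2 *= shrink
    pts = np.vstack([c1 + dev1, c2 + dev2])
    return squareform(pdist(pts))


def exhaustive_net_similarity(s: np.ndarray, preference: float) -> float:
    """Exhaustive exemplar-subset optimum of the net similarity (N <= ~12)."""
    from itertools import combinations

    from .clustering import _assign_to_exemplars, net_similarity

    n = s.shape[0]
    best = -np.inf
    for r in range(1, n + 1):
        for ex in combinations(range(n), r):
            ex = np.array(ex)
            labels = _assign_to_exemplars(s.copy(), ex)
            best = max(best, net_similarity(s, np.full(n, preference), labels, ex))
    return best


def logistic_map_recovery(seed: int = 0, window: int = 128) -> dict:
    """Fit m=1, p=2 to a noise-free logistic-map window; report coefficient error.

    The generating map is x[n+1] = 3.9 x[n] (1 - x[n]), i.e. coefficients
    (0, 3.9, -3.9) in the monomial basis.
    """
    regime = RegimeSpec(0, "polynomial_map", (0.0, 3.9, -3.9))
    x, _ = make_regime_signal([regime], dwell_s=window, length_s=window, fs=1.0, seed=seed)
    coefs, rvar, degenerate = fit_poly_map(x, m=1, p=2, ridge=1e-8)
    target = np.array([0.0, 3.9, -3.9])
    return {
        "coefs": coefs,
        "max_coef_error": float(np.max(np.abs(coefs - target))),
        "residual_var": rvar,
        "degenerate": degenerate,
    }


def null_cohort_spec(seed: int) -> CohortSpec:
    """12 subjects in 3 between-subject groups, 2 conditions, 8 channels, no effects."""
    return CohortSpec(
        n_subjects=12,
        groups=[GroupSpec("g1", 10.0), GroupSpec("g2", 11.5), GroupSpec("g3", 13.0)],
        conditions=["eyes_open", "eyes_closed"],
        n_channels=8,
        focal_channels=(),
        epoch_length_s=4.0,
        fs=128.0,
        n_epochs_per_condition=1,
        regimes_by_group={"g1": 2, "g2": 2, "g3": 2},
        dwell_by_group={"g1": 1.5, "g2": 1.5, "g3": 1.5},
        seed=seed,
        design="between",
    )


def null_first_lv_p(seed: int, n_perm: int = 200) -> float:
    """First-LV permutation p of mean-centered PLS on one null cohort."""
    epochs, _ = make_cohort(null_cohort_spec(seed))
    _, avg = measures_table(
        epochs, SegmentationConfig(), ClusterConfig(), base_seed=seed
    )
    data = pls_data_from_table(avg, "n_states", group_within_subject=False)
    p = permutation_test(data, mode="mean_centered", n_perm=n_perm, seed=seed + 10_000)
    return float(p[0])


def null_calibration(n_cohorts: int = 200, seed: int = 0, n_perm: int = 200) -> dict:
    """Fraction of null cohorts with first-LV perm_p < 0.05 (nominal 5%)."""
    base = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31 - 1)
    ps = np.array([null_first_lv_p(int(s), n_perm=n_perm) for s in base])
    return {
        "p_values": ps,
        "rejection_rate": float((ps < 0.05).mean()),
        "n_cohorts": n_cohorts,
    }


def age_effect_cohort_spec(seed: int) -> CohortSpec:
    """Longitudinal cohort with both built-in age effects.

    The number of regimes K grows with visit (2 -> 3 -> 4) on three focal
    channels; the mean dwell time shrinks with visit (2.4 -> 1.8 -> 1.4 s) on
    all channels — the two mechanisms of rising non-stationarity.
    """
    return CohortSpec(
        n_subjects=12,
        groups=[GroupSpec("visit1", 10.0), GroupSpec("visit2", 11.5), GroupSpec("visit3", 13.0)],
        conditions=["eyes_open", "eyes_closed"],
        n_channels=8,
        focal_channels=(0, 1, 2),
        epoch_length_s=12.0,
        fs=128.0,
        n_epochs_per_condition=2,
        regimes_by_group={"visit1": 2, "visit2": 3, "visit3": 4},
        dwell_by_group={"visit1": 2.4, "visit2": 1.8, "visit3": 1.4},
        seed=seed,
    )


def age_effect_recovery(seed: int = 0, n_perm: int = 300, n_boot: int = 300) -> dict:
    """Contrast PLS (linear age trend) on the age-effect cohort.

    Reports, per measure: the first-LV permutation p, the count of focal
    channels with |BSR| >= 2 (for the state-count effect) and the count of all
    channels with |BSR| >= 2 (for the duration effect).
    """
    spec = age_effect_cohort_spec(seed)
    epochs, _ = make_cohort(spec)
    _, avg = measures_table(epochs, SegmentationConfig(), ClusterConfig(), base_seed=seed)
    focal_names = {f"ch{c:02d}" for c in spec.focal_channels}
    out: dict = {"measures_table": avg}
    for measure in ("n_states", "mean_seg_len_s"):
        data = pls_data_from_table(avg, measure)
        design = linear_trend_contrast(data)
        p = permutation_test(
            data, mode="contrast", design=design, n_perm=n_perm, seed=seed + 1
        )
        lvs = bootstrap_ratios(
            data, mode="contrast", design=design, n_boot=n_boot, seed=seed + 2
        )
        bsr = lvs[0].bootstrap_ratios
        focal_idx = [i for i, c in enumerate(data.electrodes) if c in focal_names]
        out[measure] = {
            "perm_p": float(p[0]),
            "n_focal_stable": int((np.abs(bsr[focal_idx]) >= 2).sum()),
            "n_focal": len(focal_idx),
            "n_stable": int((np.abs(bsr) >= 2).sum()),
            "n_channels": len(data.electrodes),
            "bsr": bsr,
        }
    return out


def spectral_association(
    seed: int = 0,
    low_band: tuple[float, float] = (1.0, 4.0),
    alpha_band: tuple[float, float] = (9.0, 11.0),
) -> dict:
    """Partial-correlation directions on the spectrally coupled cohort.

    Returns per-channel band-mean partial correlations: mean segment length
    vs low-frequency power (expected negative everywhere) and state count vs
    alpha power (expected positive, concentrated on the focal channels).
    """
    epochs, truth = make_coupled_cohort(seed=seed)
    _, avg = measures_table(epochs, SegmentationConfig(), ClusterConfig(), base_seed=seed)
    power = pd.concat(
        [relative_power(ep, band=(1.0, 30.0), window_s=2.0) for ep in epochs],
        ignore_index=True,
    )
    out: dict = {"truth": truth}
    for key, which, band in (
        ("seg_len_vs_low", "mean_seg_len_s", low_band),
        ("n_states_vs_alpha", "n_states", alpha_band),
    ):
        pmap = power_nonstat_correlation(avg, power, which=which)
        sel = pmap[(pmap.freq_hz >= band[0]) & (pmap.freq_hz <= band[1])]
        out[key] = sel.groupby("channel")["partial_r"].mean()
    out["focal_channels"] = ["ch00", "ch01", "ch02"]
    return out
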