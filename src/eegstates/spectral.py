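"""Relative spectral power and its partial correlation with non-stationarity.

Power is estimated with an averaged modified periodogram (Welch: tapered,
half-overlapping windows) and normalised per channel so the bins of the
analysis band sum to one.  Each non-stationarity measure is then correlated
with relative power on an electrode-by-frequency basis across pooled
subject x condition observations, controlling the other measure with a
first-order partial correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .segmentation import EpochRecord

__all__ = [
    "relative_power",
    "partial_correlation",
    "power_nonstat_correlation",
]


def relative_power(
    epoch: EpochRecord,
    band: tuple[float, float] = (1.0, 30.0),
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Relative power per frequency bin for every channel of one epoch.

    Welch estimate with Hann-tapered, 50%-overlapping windows of ``window_s``
    seconds, restricted to ``band`` and normalised to sum to one per channel.
    Returns a tidy frame: subject, condition, channel, freq_hz, rel_power.
    """
    lo, hi = band
    nyq = epoch.fs / 2.0
    if not (0.0 < lo < hi <= nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}]")
    nperseg = int(round(window_s * epoch.fs))
    if epoch.n_samples < nperseg:
        raise ValueError(
            f"epoch of {epoch.n_samples} samples shorter than one spectral window ({nperseg})"
        )
    freqs, pxx = sps.welch(
        epoch.data, fs=epoch.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    keep = (freqs >= lo) & (freqs <= hi)
    freqs = freqs[keep]
    pxx = pxx[:, keep]
    pxx = pxx / pxx.sum(axis=1, keepdims=True)
    rows = []
    for ch, name in enumerate(epoch.channel_names):
        for f, p in zip(freqs, pxx[ch]):
            rows.append(
                {
                    "subject": epoch.subject_id,
                    "group": epoch.group,
                    "condition": epoch.condition,
                    "epoch": epoch.epoch_index,
                    "channel": name,
                    "freq_hz": float(f),
                    "rel_power": float(p),
                }
            )
    return pd.DataFrame(rows)


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial Pearson correlation of x and y controlling z.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z must have equal lengths")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("control variable is perfectly correlated with x or y")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        raise ValueError("zero-variance input to correlation")
    return float((a @ b) / denom)


def power_nonstat_correlation(
    measures: pd.DataFrame,
    power: pd.DataFrame,
    which: str = "n_states",
) -> pd.DataFrame:
    """Partial correlation of one measure with relative power, per channel x bin.

    ``measures`` is the tidy per-subject/condition/channel measures table with
    columns ``n_states`` and ``mean_seg_len_s``; ``power`` is the tidy output
    of :func:`relative_power` (averaged over epochs if several).  Observations
    are pooled across subjects and conditions (groups merged).  Cells with
    fewer than 4 matched observations are reported as missing (NaN).
    """
    if which not in ("n_states", "mean_seg_len_s"):
        raise ValueError("which must be 'n_states' or 'mean_seg_len_s'")
    other = "mean_seg_len_s" if which == "n_states" else "n_states"
    pw = (
        power.groupby(["subject", "condition", "channel", "freq_hz"], as_index=False)[
            "rel_power"
        ].mean()
    )
    merged = pw.merge(
        measures[["subject", "condition", "channel", "n_states", "mean_seg_len_s"]],
        on=["subject", "condition", "channel"],
        how="inner",
    )
    rows = []
    for (channel, freq), grp in merged.groupby(["channel", "freq_hz"]):
        x = grp[which].to_numpy()
        y = grp["rel_power"].to_numpy()
        z = grp[other].to_numpy()
        if len(grp) < 4:
            r = np.nan
        elif np.ptp(z) == 0.0 and np.ptp(x) > 0 and np.ptp(y) > 0:
            # constant control carries no information; plain correlation
            r = _pearson(x, y)
        else:
            try:
                r = partial_correlation(x, y, z)
            except ValueError:
                r = np.nan
        rows.append({"channel": channel, "freq_hz": freq, "partial_r": r, "n": len(grp)})
    return pd.DataFrame(rows)
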