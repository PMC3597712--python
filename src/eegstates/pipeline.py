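"""End-to-end orchestration: epochs -> fits -> clusters -> measures -> PLS/correlations.

A run is fully described by a :class:`RunConfig`; all defaults are
materialised into the saved config, and every output file carries the config
hash in its header, so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .clustering import ClusterConfig, two_stage_cluster
from .pls import (
    bootstrap_ratios,
    linear_trend_contrast,
    permutation_test,
    pls_data_from_table,
)
from .segmentation import EpochRecord, distance_matrix, fit_segments, segment_series
from .spectral import power_nonstat_correlation, relative_power
from .state_metrics import compute_measures, glue_segments

__all__ = [
    "SegmentationConfig",
    "ResamplingConfig",
    "SpectraConfig",
    "RunConfig",
    "channel_seed",
    "process_channel",
    "measures_table",
    "run_pipeline",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing and model-fit settings.

    The window length and embedding delay are set in time units and converted
    per channel from the sampling rate: windows of ``window_s`` seconds and a
    delay of about one sample at ``embed_rate_hz`` (so consecutive embedding
    lags sit roughly a quarter period of the faster EEG rhythms apart).
    ``window_len``/``tau`` (samples) override the automatic choice when set.
    """

    window_s: float = 0.7
    overlap_fraction: float = 0.5
    m: int = 2
    p: int = 1
    ridge: float = 1e-8
    embed_rate_hz: float = 40.0
    normalize: bool = True
    analysis_rate_hz: float | None = 128.0
    window_len: int | None = None
    tau: int | None = None

    def window_samples(self, fs: float) -> int:
        return self.window_len if self.window_len else int(round(self.window_s * fs))

    def tau_samples(self, fs: float) -> int:
        return self.tau if self.tau else max(1, int(round(fs / self.embed_rate_hz)))

    def decimation(self, fs: float) -> int:
        """Stride that brings ``fs`` down to the analysis rate (1 = no decimation).

        Channels sampled above ``analysis_rate_hz`` are decimated by an integer
        stride before fitting; rhythms of interest sit well below the analysis
        Nyquist and white observation noise stays white under decimation, so no
        anti-alias filter is applied.
        """
        if not self.analysis_rate_hz or fs <= self.analysis_rate_hz:
            return 1
        ratio = fs / self.analysis_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"sampling rate {fs} is not an integer multiple of the "
                f"analysis rate {self.analysis_rate_hz}"
            )
        return int(round(ratio))


@dataclass(frozen=True)
class ResamplingConfig:
    n_perm: int = 500
    n_boot: int = 500
    seed: int = 0


@dataclass(frozen=True)
class SpectraConfig:
    band_lo: float = 1.0
    band_hi: float = 30.0
    window_s: float = 2.0


@dataclass
class RunConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    manifest: str = ""
    out_dir: str = "run"
    jobs: int = 1

    REQUIRED_SECTIONS = ("segmentation", "clustering", "resampling", "spectra")

    def to_dict(self) -> dict:
        return {
            "segmentation": asdict(self.segmentation),
            "clustering": asdict(self.clustering),
            "resampling": asdict(self.resampling),
            "spectra": asdict(self.spectra),
            "manifest": self.manifest,
            "out_dir": self.out_dir,
            "jobs": self.jobs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        for section in cls.REQUIRED_SECTIONS:
            if section not in d:
                raise ValueError(f"config is missing required section: {section!r}")
        return cls(
            segmentation=SegmentationConfig(**d["segmentation"]),
            clustering=ClusterConfig(**d["clustering"]),
            resampling=ResamplingConfig(**d["resampling"]),
            spectra=SpectraConfig(**d["spectra"]),
            manifest=d.get("manifest", ""),
            out_dir=d.get("out_dir", "run"),
            jobs=int(d.get("jobs", 1)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis parameters only (paths and jobs excluded)."""
        d = self.to_dict()
        blob = json.dumps(
            {k: d[k] for k in self.REQUIRED_SECTIONS}, sort_keys=True
        ).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def channel_seed(base_seed: int, epoch_idx: int, channel_idx: int) -> int:
    """Deterministic per-(epoch, channel) seed derived from the run seed."""
    ss = np.random.SeedSequence([int(base_seed), int(epoch_idx), int(channel_idx)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def process_channel(
    x: np.ndarray,
    fs: float,
    seg_cfg: SegmentationConfig,
    clus_cfg: ClusterConfig,
    seed: int,
) -> tuple[np.ndarray, "object"]:
    """Segment, fit, cluster one channel; return (window labels, assignment).

    The channel is first decimated to the configured analysis rate; the
    returned window grid (``assignment`` labels refer to it) lives at that
    rate.
    """
    stride = seg_cfg.decimation(fs)
    if stride > 1:
        x = np.asarray(x)[::stride]
        fs = fs / stride
    grid = segment_series(len(x), seg_cfg.window_samples(fs), seg_cfg.overlap_fraction)
    models = fit_segments(
        x,
        grid,
        m=seg_cfg.m,
        p=seg_cfg.p,
        ridge=seg_cfg.ridge,
        tau=seg_cfg.tau_samples(fs),
        normalize=seg_cfg.normalize,
    )
    if grid.n_windows < 2:
        return np.zeros(1, dtype=int), None, grid, fs
    D = distance_matrix(models)
    cfg = replace(clus_cfg, seed=seed)
    assignment = two_stage_cluster(D, cfg)
    return assignment.labels, assignment, grid, fs


def _epoch_rows(
    i_ep: int, epoch: EpochRecord, seg_cfg: SegmentationConfig, clus_cfg: ClusterConfig, base_seed: int
) -> list[dict]:
    rows = []
    assign_rows = []
    for ch in range(epoch.n_channels):
        labels, assignment, grid, fs_an = process_channel(
            epoch.data[ch], epoch.fs, seg_cfg, clus_cfg, channel_seed(base_seed, i_ep, ch)
        )
        if assignment is not None:
            exemplar_windows = set(assignment.exemplars.tolist())
            s1 = assignment.stage1_labels
            for w, start in enumerate(grid.starts):
                assign_rows.append(
                    {
                        "subject": epoch.subject_id,
                        "condition": epoch.condition,
                        "epoch": epoch.epoch_index,
                        "channel": epoch.channel_names[ch],
                        "window_start": int(start),
                        "window_end": int(start + grid.window_len),
                        "stage1_label": int(s1[w]) if s1 is not None else int(labels[w]),
                        "final_label": int(labels[w]),
                        "is_exemplar": w in exemplar_windows,
                    }
                )
        seq = glue_segments(labels, grid, fs_an)
        meas = compute_measures(
            seq,
            subject_id=epoch.subject_id,
            condition=epoch.condition,
            channel=epoch.channel_names[ch],
        )
        rows.append(
            {
                "subject": epoch.subject_id,
                "group": epoch.group,
                "age": epoch.age,
                "condition": epoch.condition,
                "epoch": epoch.epoch_index,
                "channel": epoch.channel_names[ch],
                "n_states": meas.n_states,
                "mean_seg_len_s": meas.mean_seg_len_s,
            }
        )
    return rows, assign_rows


def measures_table(
    epochs: list[EpochRecord],
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    clus_cfg: ClusterConfig = ClusterConfig(),
    base_seed: int = 0,
    jobs: int = 1,
    return_assignments: bool = False,
):
    """Per-epoch measures and their epoch averages for a whole cohort.

    Returns ``(per_epoch, averaged)`` tidy frames; ``averaged`` has one row per
    subject x group x condition x channel with ``n_epochs`` recorded.  With
    ``return_assignments=True`` a third frame holds the per-window cluster
    assignments (window bounds, stage-1 and final labels, exemplar flag).
    """
    if jobs > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=jobs)(
            delayed(_epoch_rows)(i, ep, seg_cfg, clus_cfg, base_seed)
            for i, ep in enumerate(epochs)
        )
    else:
        chunks = [_epoch_rows(i, ep, seg_cfg, clus_cfg, base_seed) for i, ep in enumerate(epochs)]
    per_epoch = pd.DataFrame([r for chunk, _ in chunks for r in chunk])
    averaged = (
        per_epoch.groupby(["subject", "group", "condition", "channel"], as_index=False)
        .agg(
            age=("age", "mean"),
            n_states=("n_states", "mean"),
            mean_seg_len_s=("mean_seg_len_s", "mean"),
            n_epochs=("epoch", "count"),
        )
    )
    if return_assignments:
        assignments = pd.DataFrame([r for _, chunk in chunks for r in chunk])
        return per_epoch, averaged, assignments
    return per_epoch, averaged


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Full run: cohort manifest -> measures, PLS summaries, correlation maps.

    Creates one directory per run with stage-named subdirectories and a
    machine-readable run log.  Returns the run directory.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(out / "config.yaml")
    log: dict = {"config_hash": cfg_hash, "warnings": [], "timings_s": {}}

    epochs = eio.read_epochs(config.manifest)
    epochs = [ep.demeaned() for ep in epochs]
    log["n_epochs"] = len(epochs)

    t = time.time()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        per_epoch, averaged, assignments = measures_table(
            epochs,
            config.segmentation,
            config.clustering,
            base_seed=config.resampling.seed,
            jobs=config.jobs,
            return_assignments=True,
        )
    log["warnings"].extend(str(w.message) for w in caught)
    log["timings_s"]["measures"] = round(time.time() - t, 3)

    meas_dir = out / "measures"
    meas_dir.mkdir(exist_ok=True)
    _write_table(per_epoch, meas_dir / "per_epoch.tsv", cfg_hash)
    _write_table(averaged, meas_dir / "measures.tsv", cfg_hash)
    _write_table(assignments, meas_dir / "assignments.tsv", cfg_hash)

    # PLS: mean-centered for both measures; contrast (linear group trend) when
    # there are >= 2 groups
    t = time.time()
    pls_dir = out / "pls"
    pls_dir.mkdir(exist_ok=True)
    pls_summary_rows = []
    for measure in ("n_states", "mean_seg_len_s"):
        data = pls_data_from_table(averaged, measure)
        for mode in ("mean_centered", "contrast"):
            if mode == "contrast" and len(data.group_order) < 2:
                continue
            design = linear_trend_contrast(data) if mode == "contrast" else None
            pvals = permutation_test(
                data, mode=mode, design=design,
                n_perm=config.resampling.n_perm, seed=config.resampling.seed,
            )
            lvs = bootstrap_ratios(
                data, mode=mode, design=design,
                n_boot=config.resampling.n_boot, seed=config.resampling.seed + 1,
            )
            bsr_rows = []
            for k, lv in enumerate(lvs):
                pls_summary_rows.append(
                    {
                        "measure": measure,
                        "mode": mode,
                        "lv": k,
                        "singular_value": lv.singular_value,
                        "perm_p": float(pvals[k]),
                        "condition_loadings": json.dumps(lv.condition_loadings.tolist()),
                    }
                )
                for e, name in enumerate(data.electrodes):
                    bsr_rows.append(
                        {
                            "measure": measure,
                            "mode": mode,
                            "lv": k,
                            "channel": name,
                            "electrode_loading": lv.electrode_loadings[e],
                            "bootstrap_ratio": lv.bootstrap_ratios[e],
                            "stable": bool(lv.bsr_stable[e]),
                        }
                    )
            _write_table(
                pd.DataFrame(bsr_rows), pls_dir / f"bsr_{measure}_{mode}.tsv", cfg_hash
            )
    _write_table(pd.DataFrame(pls_summary_rows), pls_dir / "lv_summary.tsv", cfg_hash)
    log["timings_s"]["pls"] = round(time.time() - t, 3)

    # spectral association
    t = time.time()
    spec_dir = out / "spectral"
    spec_dir.mkdir(exist_ok=True)
    power = pd.concat(
        [
            relative_power(
                ep, band=(config.spectra.band_lo, config.spectra.band_hi),
                window_s=config.spectra.window_s,
            )
            for ep in epochs
        ],
        ignore_index=True,
    )
    for measure in ("n_states", "mean_seg_len_s"):
        pmap = power_nonstat_correlation(averaged, power, which=measure)
        wide = pmap.pivot(index="channel", columns="freq_hz", values="partial_r")
        _write_table(wide.reset_index(), spec_dir / f"partial_corr_{measure}.tsv", cfg_hash)
    log["timings_s"]["spectral"] = round(time.time() - t, 3)

    log["timings_s"]["total"] = round(time.time() - t0, 3)
    log["seed"] = config.resampling.seed
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
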