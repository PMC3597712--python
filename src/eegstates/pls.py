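"""Mean-centered and contrast Partial Least Squares over electrodes.

The data matrix has one row per participant within condition within group and
one column per electrode, holding one non-stationarity measure.  Mean-centered
PLS decomposes (by SVD) the group x condition cell means after removing the
grand column mean; contrast PLS decomposes the covariance between a set of a
priori orthogonal contrasts over the cells and the cell means.  Each latent
variable (LV) pairs a singular value with unit-norm condition and electrode
loadings.  Significance of an LV is the plain exceedance proportion of its
singular value under permutation of the condition/group labels; stability of
each electrode loading is its bootstrap ratio — the loading divided by the
standard error of its bootstrap distribution, |BSR| >= 2 corresponding roughly
to a 95% confidence criterion.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSData",
    "LatentVariable",
    "pls_data_from_table",
    "build_cell_means",
    "mean_centered_pls",
    "contrast_pls",
    "linear_trend_contrast",
    "permutation_test",
    "bootstrap_ratios",
]

BSR_STABLE_THRESHOLD = 2.0


@dataclass
class PLSData:
    """Participant x electrode measures with row metadata.

    ``group_within_subject=True`` means every subject appears in every group
    (longitudinal visits); permutations then reshuffle each subject's rows
    among that subject's cells.  With ``False`` (between-subject groups) group
    labels are permuted across subjects and condition labels within subjects.
    """

    values: np.ndarray  # n_rows x n_electrodes
    subjects: np.ndarray
    groups: np.ndarray
    conditions: np.ndarray
    electrodes: list[str]
    group_order: list[str] = field(default_factory=list)
    condition_order: list[str] = field(default_factory=list)
    group_within_subject: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.groups = np.asarray(self.groups)
        self.conditions = np.asarray(self.conditions)
        n = self.values.shape[0]
        if not (len(self.subjects) == len(self.groups) == len(self.conditions) == n):
            raise ValueError("row metadata lengths do not match the data matrix")
        if not self.group_order:
            self.group_order = list(pd.unique(self.groups))
        if not self.condition_order:
            self.condition_order = list(pd.unique(self.conditions))
        seen = set()
        for s, g, c in zip(self.subjects, self.groups, self.conditions):
            key = (s, g, c)
            if key in seen:
                raise ValueError(f"duplicate (subject, group, condition) row: {key}")
            seen.add(key)

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [(g, c) for g in self.group_order for c in self.condition_order]

    def replaced(self, values: np.ndarray) -> "PLSData":
        out = PLSData.__new__(PLSData)
        out.values = values
        out.subjects = self.subjects
        out.groups = self.groups
        out.conditions = self.conditions
        out.electrodes = self.electrodes
        out.group_order = self.group_order
        out.condition_order = self.condition_order
        out.group_within_subject = self.group_within_subject
        return out


@dataclass
class LatentVariable:
    """One PLS component."""

    singular_value: float
    condition_loadings: np.ndarray  # over group x condition cells (or contrasts)
    electrode_loadings: np.ndarray
    perm_p: float | None = None
    bootstrap_ratios: np.ndarray | None = None
    bsr_stable: np.ndarray | None = None
    bsr_degenerate: np.ndarray | None = None


def pls_data_from_table(
    table: pd.DataFrame,
    measure: str,
    group_within_subject: bool = True,
) -> PLSData:
    """Pivot a tidy measures table (subject, group, condition, channel, value)."""
    wide = table.pivot_table(
        index=["subject", "group", "condition"], columns="channel", values=measure
    )
    if wide.isna().any().any():
        raise ValueError("missing subject/group/condition/channel combinations")
    idx = wide.index.to_frame(index=False)
    return PLSData(
        values=wide.to_numpy(),
        subjects=idx["subject"].to_numpy(),
        groups=idx["group"].to_numpy(),
        conditions=idx["condition"].to_numpy(),
        electrodes=list(wide.columns),
        group_order=sorted(table["group"].unique()),
        condition_order=sorted(table["condition"].unique()),
        group_within_subject=group_within_subject,
    )


def build_cell_means(data: PLSData) -> np.ndarray:
    """Column means within each group x condition cell, cells ordered as ``data.cells``."""
    cells = data.cells
    if len(cells) < 2:
        raise ValueError("need at least 2 group x condition cells")
    M = np.empty((len(cells), data.values.shape[1]))
    for i, (g, c) in enumerate(cells):
        mask = (data.groups == g) & (data.conditions == c)
        if not mask.any():
            raise ValueError(f"empty cell: group={g!r}, condition={c!r}")
        M[i] = data.values[mask].mean(axis=0)
    return M


def _svd_lvs(M: np.ndarray) -> list[LatentVariable]:
    U, svals, Vt = np.linalg.svd(M, full_matrices=False)
    return [
        LatentVariable(
            singular_value=float(svals[k]),
            condition_loadings=U[:, k].copy(),
            electrode_loadings=Vt[k].copy(),
        )
        for k in range(len(svals))
    ]


def mean_centered_pls(data: PLSData) -> list[LatentVariable]:
    """SVD of the cell-mean matrix centered by the grand column mean across cells."""
    M = build_cell_means(data)
    Mc = M - M.mean(axis=0, keepdims=True)
    return _svd_lvs(Mc)


def _check_contrasts(design: np.ndarray) -> None:
    design = np.asarray(design, dtype=float)
    if design.ndim != 2:
        raise ValueError("design must be 2-D (cells x contrasts)")
    if not np.allclose(design.sum(axis=0), 0.0, atol=1e-10):
        raise ValueError("every contrast must sum to zero over cells")
    gram = design.T @ design
    off = gram - np.diag(np.diag(gram))
    if not np.allclose(off, 0.0, atol=1e-10):
        raise ValueError("contrast columns must be mutually orthogonal")


def contrast_pls(data: PLSData, design: np.ndarray) -> list[LatentVariable]:
    """SVD of the covariance between a priori contrasts and the cell means.

    ``design`` has one row per group x condition cell (in ``data.cells`` order)
    and one column per contrast; columns must be zero-sum and mutually
    orthogonal.
    """
    M = build_cell_means(data)
    design = np.asarray(design, dtype=float)
    if design.shape[0] != M.shape[0]:
        raise ValueError(
            f"design has {design.shape[0]} rows for {M.shape[0]} cells"
        )
    _check_contrasts(design)
    cov = design.T @ M
    return _svd_lvs(cov)


def linear_trend_contrast(data: PLSData) -> np.ndarray:
    """Zero-sum linear trend over groups, constant across conditions (cells x 1)."""
    n_g = len(data.group_order)
    n_c = len(data.condition_order)
    trend = np.arange(n_g, dtype=float) - (n_g - 1) / 2.0
    col = np.repeat(trend, n_c)
    return (col / np.linalg.norm(col))[:, None]


def _compute_svals(data: PLSData, mode: str, design: np.ndarray | None) -> np.ndarray:
    if mode == "mean_centered":
        lvs = mean_centered_pls(data)
    elif mode == "contrast":
        if design is None:
            raise ValueError("contrast mode needs a design matrix")
        lvs = contrast_pls(data, design)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.array([lv.singular_value for lv in lvs])


def _permuted_values(data: PLSData, rng: np.random.Generator) -> np.ndarray:
    """One random relabelling of the rows, scheme chosen by the design metadata."""
    values = data.values.copy()
    if data.group_within_subject:
        # reshuffle each subject's rows among that subject's cells
        for s in pd.unique(data.subjects):
            idx = np.flatnonzero(data.subjects == s)
            values[idx] = values[rng.permutation(idx)]
    else:
        # permute group labels across subjects: swap whole subjects' row blocks
        # between group slots, then conditions within subjects
        subj = pd.unique(data.subjects)
        perm = rng.permutation(len(subj))
        new_values = values.copy()
        # subjects are exchangeable only via their rows; permute subject blocks
        blocks = [np.flatnonzero(data.subjects == s) for s in subj]
        for b_dst, b_src in zip(blocks, (blocks[p] for p in perm)):
            take = min(len(b_dst), len(b_src))
            new_values[b_dst[:take]] = values[b_src[:take]]
        values = new_values
        for s in subj:
            idx = np.flatnonzero(data.subjects == s)
            values[idx] = values[rng.permutation(idx)]
    return values


def _n_distinct_permutations(data: PLSData) -> float:
    total = 1.0
    for s in pd.unique(data.subjects):
        r = int((data.subjects == s).sum())
        total *= math.factorial(r)
        if total > 1e9:
            return np.inf
    if not data.group_within_subject:
        return np.inf  # block scheme; treat as effectively unbounded
    return total


def permutation_test(
    data: PLSData,
    mode: str = "mean_centered",
    design: np.ndarray | None = None,
    n_perm: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Per-LV permutation p-values: P(permuted singular value > observed).

    The p-value is the plain exceedance proportion, with no add-one
    correction.  For tiny within-subject designs with fewer distinct
    permutations than ``n_perm``, the permutation distribution is enumerated
    exhaustively instead (with a warning).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = _compute_svals(data, mode, design)
    rng = np.random.default_rng(seed)

    n_distinct = _n_distinct_permutations(data)
    if n_distinct < n_perm:
        warnings.warn(
            f"only {int(n_distinct)} distinct permutations exist; enumerating exhaustively",
            RuntimeWarning,
            stacklevel=2,
        )
        perms = _exhaustive_permutations(data)
    else:
        perms = (_permuted_values(data, rng) for _ in range(n_perm))

    exceed = np.zeros(len(observed))
    count = 0
    for values in perms:
        svals = _compute_svals(data.replaced(values), mode, design)
        exceed += svals[: len(observed)] > observed
        count += 1
    return exceed / count


def _exhaustive_permutations(data: PLSData):
    subj = list(pd.unique(data.subjects))
    blocks = [np.flatnonzero(data.subjects == s) for s in subj]
    per_subject = [list(itertools.permutations(range(len(b)))) for b in blocks]
    for combo in itertools.product(*per_subject):
        values = data.values.copy()
        for b, p in zip(blocks, combo):
            values[b] = data.values[b[list(p)]]
        yield values


def bootstrap_ratios(
    data: PLSData,
    mode: str = "mean_centered",
    design: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> list[LatentVariable]:
    """Bootstrap stability of the electrode loadings.

    Participants are resampled with replacement within each group x condition
    cell; the PLS is recomputed and each resampled electrode-loading vector is
    sign-aligned to the original by the sign of their inner product.  The
    bootstrap ratio is the original loading divided by the bootstrap standard
    error.  A zero standard error yields a +/-inf sentinel flagged in
    ``bsr_degenerate``.  Returns the original LVs with ``bootstrap_ratios``,
    ``bsr_stable`` (|BSR| >= 2) and ``bsr_degenerate`` filled in.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    cells = data.cells
    cell_rows = []
    for g, c in cells:
        idx = np.flatnonzero((data.groups == g) & (data.conditions == c))
        if len(idx) == 0:
            raise ValueError(f"empty cell: group={g!r}, condition={c!r}")
        if len(idx) < 3:
            raise ValueError(f"cell group={g!r}, condition={c!r} has fewer than 3 participants")
        cell_rows.append(idx)

    if mode == "mean_centered":
        orig = mean_centered_pls(data)
    else:
        if design is None:
            raise ValueError("contrast mode needs a design matrix")
        orig = contrast_pls(data, design)

    rng = np.random.default_rng(seed)
    n_lv = len(orig)
    boot_loadings = np.empty((n_boot, n_lv, len(data.electrodes)))
    for b in range(n_boot):
        values = data.values.copy()
        for idx in cell_rows:
            values[idx] = data.values[rng.choice(idx, size=len(idx), replace=True)]
        lvs = _compute_lvs(data.replaced(values), mode, design)
        for k in range(n_lv):
            v = lvs[k].electrode_loadings
            if float(v @ orig[k].electrode_loadings) < 0:
                v = -v
            boot_loadings[b, k] = v

    out = []
    for k, lv in enumerate(orig):
        se = boot_loadings[:, k, :].std(axis=0, ddof=1)
        degenerate = se == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = np.where(degenerate, np.sign(lv.electrode_loadings) * np.inf,
                           lv.electrode_loadings / se)
        bsr = np.where(degenerate & (lv.electrode_loadings == 0), np.inf, bsr)
        out.append(
            LatentVariable(
                singular_value=lv.singular_value,
                condition_loadings=lv.condition_loadings,
                electrode_loadings=lv.electrode_loadings,
                perm_p=lv.perm_p,
                bootstrap_ratios=bsr,
                bsr_stable=np.abs(bsr) >= BSR_STABLE_THRESHOLD,
                bsr_degenerate=degenerate,
            )
        )
    return out


def _compute_lvs(data: PLSData, mode: str, design: np.ndarray | None) -> list[LatentVariable]:
    if mode == "mean_centered":
        return mean_centered_pls(data)
    return contrast_pls(data, design)
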