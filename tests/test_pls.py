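"""Mean-centered / contrast PLS, permutation significance, bootstrap ratios."""

import numpy as np
import pandas as pd
import pytest

from eegstates.pls import (
    PLSData,
    bootstrap_ratios,
    build_cell_means,
    contrast_pls,
    linear_trend_contrast,
    mean_centered_pls,
    permutation_test,
    pls_data_from_table,
)


def make_data(values, n_subj, groups, conditions, within=True):
    rows_meta = [
        (f"s{i}", g, c)
        for i in range(n_subj)
        for g in groups
        for c in conditions
    ]
    subjects, gs, cs = zip(*rows_meta)
    return PLSData(
        values=np.asarray(values, dtype=float),
        subjects=np.array(subjects),
        groups=np.array(gs),
        conditions=np.array(cs),
        electrodes=[f"e{j}" for j in range(np.asarray(values).shape[1])],
        group_order=list(groups),
        condition_order=list(conditions),
        group_within_subject=within,
    )


def random_data(rng, n_subj=5, n_el=4, groups=("g1", "g2"), conditions=("a", "b")):
    n_rows = n_subj * len(groups) * len(conditions)
    return make_data(rng.standard_normal((n_rows, n_el)), n_subj, groups, conditions)


class TestCellMeans:
    def test_matches_brute_force(self, rng):
        data = random_data(rng)
        M = build_cell_means(data)
        for i, (g, c) in enumerate(data.cells):
            mask = (data.groups == g) & (data.conditions == c)
            np.testing.assert_allclose(M[i], data.values[mask].mean(axis=0))

    def test_single_participant_cells_equal_raw_rows(self, rng):
        data = random_data(rng, n_subj=1)
        M = build_cell_means(data)
        assert M.shape == (4, 4)
        for i, (g, c) in enumerate(data.cells):
            row = data.values[(data.groups == g) & (data.conditions == c)]
            np.testing.assert_allclose(M[i], row[0])

    def test_duplicating_participants_leaves_cell_means_unchanged(self, rng):
        data = random_data(rng)
        doubled = PLSData(
            values=np.vstack([data.values, data.values]),
            subjects=np.concatenate([data.subjects, np.char.add(data.subjects.astype(str), "_dup")]),
            groups=np.concatenate([data.groups, data.groups]),
            conditions=np.concatenate([data.conditions, data.conditions]),
            electrodes=data.electrodes,
            group_order=data.group_order,
            condition_order=data.condition_order,
        )
        np.testing.assert_allclose(build_cell_means(data), build_cell_means(doubled))

    def test_empty_cell_rejected(self, rng):
        data = random_data(rng)
        data.groups = np.where(data.groups == "g2", "g1", data.groups)
        with pytest.raises(ValueError, match="empty cell"):
            build_cell_means(data)


class TestMeanCenteredPLS:
    def test_identical_cells_give_zero_singular_values(self):
        values = np.tile([1.0, 2.0, 3.0], (8, 1))
        data = make_data(values, 2, ("g1", "g2"), ("a", "b"))
        lvs = mean_centered_pls(data)
        assert all(lv.singular_value < 1e-12 for lv in lvs)

    def test_rank_one_structure_recovered(self):
        # 2 cells x 3 electrodes differing only on electrode 0
        values = np.array([[1.0, 5.0, 2.0]] * 3 + [[3.0, 5.0, 2.0]] * 3)
        data = make_data(values[:6], 3, ("g1",), ("a", "b"))
        lvs = mean_centered_pls(data)
        assert lvs[0].singular_value > 1e-8
        assert all(lv.singular_value < 1e-12 for lv in lvs[1:])
        load = np.abs(lvs[0].electrode_loadings)
        np.testing.assert_allclose(load, [1.0, 0.0, 0.0], atol=1e-12)
        # condition loadings antisymmetric across the two cells
        np.testing.assert_allclose(
            lvs[0].condition_loadings[0], -lvs[0].condition_loadings[1], atol=1e-12
        )

    def test_svd_energy_conservation(self, rng):
        data = random_data(rng)
        M = build_cell_means(data)
        Mc = M - M.mean(axis=0, keepdims=True)
        lvs = mean_centered_pls(data)
        np.testing.assert_allclose(
            sum(lv.singular_value**2 for lv in lvs), np.sum(Mc**2), rtol=1e-10
        )

    def test_loadings_unit_norm_and_svals_sorted(self, rng):
        lvs = mean_centered_pls(random_data(rng))
        svals = [lv.singular_value for lv in lvs]
        assert svals == sorted(svals, reverse=True)
        for lv in lvs:
            assert np.linalg.norm(lv.electrode_loadings) == pytest.approx(1.0)
            assert np.linalg.norm(lv.condition_loadings) == pytest.approx(1.0)


class TestContrastPLS:
    def test_non_orthogonal_contrasts_rejected(self, rng):
        data = random_data(rng)
        design = np.array([[1, 1], [1, -1], [-1, 1], [-1, 1]], dtype=float)
        with pytest.raises(ValueError, match="orthogonal|sum to zero"):
            contrast_pls(data, design)

    def test_contrast_orthogonal_to_effect_gives_zero(self):
        # cell means differ only between conditions; a pure group contrast sees nothing
        values = np.array(
            [[1.0, 1.0]] * 3 + [[2.0, 2.0]] * 3 + [[1.0, 1.0]] * 3 + [[2.0, 2.0]] * 3
        )
        data = make_data(values, 3, ("g1", "g2"), ("a", "b"))
        design = np.array([[1.0], [1.0], [-1.0], [-1.0]]) / 2.0  # group contrast
        lvs = contrast_pls(data, design)
        assert lvs[0].singular_value < 1e-12

    def test_linear_trend_recovers_focal_electrode(self):
        # cell means increase linearly over 3 groups on electrode 1 only;
        # rows are subject-major: each subject contributes (g1, g2, g3)
        rows = []
        for _ in range(3):
            for gi in range(3):
                rows.append([5.0, float(gi), 2.0])
        data = make_data(rows, 3, ("g1", "g2", "g3"), ("a",))
        design = linear_trend_contrast(data)
        lvs = contrast_pls(data, design)
        assert lvs[0].singular_value > 0.1
        np.testing.assert_allclose(
            np.abs(lvs[0].electrode_loadings), [0.0, 1.0, 0.0], atol=1e-10
        )

    def test_electrode_permutation_equivariance(self, rng):
        data = random_data(rng, groups=("g1", "g2", "g3"))
        design = linear_trend_contrast(data)
        lvs = contrast_pls(data, design)
        perm = rng.permutation(4)
        data_p = PLSData(
            values=data.values[:, perm],
            subjects=data.subjects,
            groups=data.groups,
            conditions=data.conditions,
            electrodes=[data.electrodes[i] for i in perm],
            group_order=data.group_order,
            condition_order=data.condition_order,
        )
        lvs_p = contrast_pls(data_p, design)
        assert lvs_p[0].singular_value == pytest.approx(lvs[0].singular_value)
        np.testing.assert_allclose(
            np.abs(lvs_p[0].electrode_loadings),
            np.abs(lvs[0].electrode_loadings[perm]),
            atol=1e-10,
        )


class TestPermutationTest:
    def test_deterministic_under_seed(self, rng):
        data = random_data(rng)
        p1 = permutation_test(data, n_perm=150, seed=5)
        p2 = permutation_test(data, n_perm=150, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_overwhelming_effect_gives_zero_p(self, rng):
        values = rng.standard_normal((20, 3)) * 0.01
        data = make_data(values, 5, ("g1", "g2"), ("a", "b"))
        data.values[(data.groups == "g2")] += 100.0
        p = permutation_test(data, mode="mean_centered", n_perm=200, seed=1)
        assert p[0] == 0.0

    def test_tiny_design_enumerated_exhaustively_with_warning(self, rng):
        values = rng.standard_normal((4, 3))
        data = make_data(values, 1, ("g1", "g2"), ("a", "b"))
        with pytest.warns(RuntimeWarning, match="exhaustively"):
            p = permutation_test(data, n_perm=100, seed=0)
        assert 0.0 <= p[0] <= 1.0

    def test_minimum_permutation_count_enforced(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(random_data(rng), n_perm=10)


class TestBootstrapRatios:
    def test_deterministic_under_seed(self, rng):
        data = random_data(rng)
        lvs1 = bootstrap_ratios(data, n_boot=120, seed=3)
        lvs2 = bootstrap_ratios(data, n_boot=120, seed=3)
        np.testing.assert_array_equal(lvs1[0].bootstrap_ratios, lvs2[0].bootstrap_ratios)

    def test_zero_variance_loading_flagged_with_sentinel(self):
        # one electrode identical across all participants: its resampled
        # loading never varies, SE = 0
        values = np.zeros((12, 2))
        values[:, 1] = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        data = make_data(values, 3, ("g1", "g2"), ("a", "b"))
        lvs = bootstrap_ratios(data, n_boot=100, seed=0)
        assert lvs[0].bsr_degenerate[0]
        assert np.isinf(lvs[0].bootstrap_ratios[0])

    def test_cells_need_three_participants(self, rng):
        data = random_data(rng, n_subj=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            bootstrap_ratios(data, n_boot=100, seed=0)

    def test_strong_focal_effect_yields_stable_ratio(self, rng):
        # group difference carried by electrode 0 only
        values = rng.standard_normal((24, 4)) * 0.3
        data = make_data(values, 6, ("g1", "g2"), ("a", "b"))
        data.values[data.groups == "g2", 0] += 5.0
        lvs = bootstrap_ratios(data, n_boot=200, seed=2)
        assert abs(lvs[0].bootstrap_ratios[0]) >= 2.0


class TestFromTable:
    def test_pivot_round_trip(self, rng):
        rows = []
        for s in range(3):
            for g in ("g1", "g2"):
                for c in ("a", "b"):
                    for ch in ("ch0", "ch1"):
                        rows.append(
                            {"subject": f"s{s}", "group": g, "condition": c,
                             "channel": ch, "n_states": rng.uniform(1, 4)}
                        )
        table = pd.DataFrame(rows)
        data = pls_data_from_table(table, "n_states")
        assert data.values.shape == (12, 2)
        assert data.electrodes == ["ch0", "ch1"]
        row = table[(table.subject == "s0") & (table.group == "g1") &
                    (table.condition == "a") & (table.channel == "ch0")]
        idx = np.flatnonzero(
            (data.subjects == "s0") & (data.groups == "g1") & (data.conditions == "a")
        )[0]
        assert data.values[idx, 0] == pytest.approx(float(row.n_states.iloc[0]))

    def test_duplicate_rows_rejected(self, rng):
        data = random_data(rng)
        with pytest.raises(ValueError, match="duplicate"):
            PLSData(
                values=np.vstack([data.values, data.values[:1]]),
                subjects=np.append(data.subjects, data.subjects[0]),
                groups=np.append(data.groups, data.groups[0]),
                conditions=np.append(data.conditions, data.conditions[0]),
                electrodes=data.electrodes,
            )
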