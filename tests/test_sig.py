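"""Spatial information gain: cell MI, smoothing, ROI extraction."""

import numpy as np
import pandas as pd
import pytest

from emsig.embedding import Embedding2D, GridSpec, build_grid, embed_pca
from emsig.factors import compute_factor_scores, pcc_matrix, select_k
from emsig.profiling import correlation_screen
from emsig.schema import reverse_score
from emsig.sig import (
    aggregate_sig,
    assign_cells,
    cell_sig_factor,
    compute_sig_surface,
    extract_rois,
    sig_surfaces,
    smooth_surface,
)
from emsig.simulate import (
    ROI_RECOVERY_ANALYSIS,
    generate_dataset,
    roi_recovery_config,
)


def brute_force_mi(split, doses):
    """Independent oracle: explicit double sum over the 2 x L joint table."""
    split = np.asarray(split)
    doses = np.asarray(doses)
    n = len(doses)
    mi = 0.0
    for a in (False, True):
        for d in np.unique(doses):
            p_ad = np.mean((split == a) & (doses == d))
            if p_ad == 0:
                continue
            mi += p_ad * np.log(p_ad / (np.mean(split == a) * np.mean(doses == d)))
    return mi


def grid_over(coords, step=0.5):
    emb = Embedding2D(
        respondent_ids=pd.RangeIndex(len(coords)), coords=np.asarray(coords, float)
    )
    return emb, build_grid(emb, step=step)


class TestAssignCells:
    def test_point_example(self):
        emb, _ = grid_over([[0.0, 0.0], [0.6, 0.7], [2.0, 2.0]])
        grid = GridSpec(x_min=0, x_max=2, y_min=0, y_max=2, step=0.5)
        cells = assign_cells(emb, grid)
        assert 1 in cells[(1, 1)]

    def test_max_point_in_last_cell(self):
        emb, grid = grid_over([[0.0, 0.0], [2.0, 1.0]])
        cells = assign_cells(emb, grid)
        assert 1 in cells[(grid.nx - 1, grid.ny - 1)]

    def test_membership_is_a_partition(self):
        rng = np.random.default_rng(5)
        emb, grid = grid_over(rng.normal(size=(200, 2)))
        cells = assign_cells(emb, grid)
        all_members = np.concatenate(list(cells.values()))
        assert len(all_members) == 200
        assert len(np.unique(all_members)) == 200


class TestCellSig:
    def test_constant_dose_gives_zero(self):
        rng = np.random.default_rng(0)
        assert cell_sig_factor(rng.normal(size=20), np.full(20, 3)) == 0.0

    def test_independent_split_gives_zero(self):
        factor = np.array([1.0] * 10 + [2.0] * 10)
        doses = np.array([0, 5] * 10)  # same dose mix in both halves
        assert cell_sig_factor(factor, doses) == pytest.approx(0.0, abs=1e-15)

    def test_perfect_split_gives_ln2(self):
        factor = np.concatenate([np.zeros(10), np.ones(10)])
        doses = np.concatenate([np.zeros(10, int), np.full(10, 5)])
        assert cell_sig_factor(factor, doses) == pytest.approx(np.log(2), abs=1e-12)

    def test_below_occupancy_floor_is_zero(self):
        factor = np.array([0.0, 1.0, 0.0, 1.0])
        doses = np.array([0, 5, 0, 5])
        assert cell_sig_factor(factor, doses, floor=5) == 0.0
        assert cell_sig_factor(factor, doses, floor=2) > 0

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(5, 40)
            factor = rng.normal(size=m)
            doses = rng.integers(0, 6, size=m)
            split = factor > np.median(factor)
            if split.all() or not split.any():
                continue
            got = cell_sig_factor(factor, doses, floor=1)
            want = brute_force_mi(split, doses)
            assert got == pytest.approx(want, abs=1e-12)

    def test_nonnegative_always(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = int(rng.integers(5, 25))
            sig = cell_sig_factor(
                rng.normal(size=m), rng.integers(0, 6, size=m), floor=1
            )
            assert sig >= 0.0


class TestAggregate:
    def test_linearity_and_weights(self):
        a = np.arange(6.0).reshape(2, 3)
        b = np.ones((2, 3))
        assert np.allclose(aggregate_sig({"x": a, "y": b}), a + b)
        assert np.allclose(
            aggregate_sig({"x": a, "y": b}, weights={"x": 2.0, "y": 0.0}), 2 * a
        )
        assert np.allclose(
            aggregate_sig({"x": np.zeros((2, 3)), "y": np.zeros((2, 3))}), 0.0
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            aggregate_sig({"x": np.zeros((2, 3)), "y": np.zeros((3, 2))})


class TestSmoothing:
    def unit_grid(self):
        # step 1 so adjacent cell centers are one embedding unit apart
        return GridSpec(x_min=0, x_max=5, y_min=0, y_max=5, step=1.0)

    def test_impulse_response_values(self):
        grid = self.unit_grid()
        raw = np.zeros((grid.nx, grid.ny))
        raw[2, 2] = 1.0
        sm = smooth_surface(raw, grid, sigma=1.0)
        assert sm[2, 2] == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-12)
        assert sm[3, 2] == pytest.approx(
            np.exp(-0.5) / np.sqrt(2 * np.pi), abs=1e-12
        )

    def test_all_zero_raw(self):
        grid = self.unit_grid()
        assert np.allclose(smooth_surface(np.zeros((grid.nx, grid.ny)), grid), 0.0)

    def test_linearity(self):
        grid = self.unit_grid()
        rng = np.random.default_rng(3)
        a = rng.random((grid.nx, grid.ny))
        b = rng.random((grid.nx, grid.ny))
        lhs = smooth_surface(2.0 * a + 3.0 * b, grid)
        rhs = 2.0 * smooth_surface(a, grid) + 3.0 * smooth_surface(b, grid)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_sigma_validation(self):
        grid = self.unit_grid()
        with pytest.raises(ValueError):
            smooth_surface(np.zeros((grid.nx, grid.ny)), grid, sigma=0.0)


class TestExtractRois:
    def _cells_for(self, members_by_cell):
        return {c: np.array(m, dtype=int) for c, m in members_by_cell.items()}

    def test_single_supra_threshold_cell(self):
        grid = GridSpec(x_min=0, x_max=2.5, y_min=0, y_max=2.5, step=0.5)
        smoothed = np.zeros((grid.nx, grid.ny))
        smoothed[2, 2] = 1.0
        cells = self._cells_for({(2, 2): list(range(12))})
        dose = pd.Series(np.arange(12) % 6)
        rois = extract_rois(smoothed, grid, cells, dose)
        assert len(rois) == 1
        assert rois[0].n == 12

    def test_disconnected_components_are_separate_rois(self):
        grid = GridSpec(x_min=0, x_max=5, y_min=0, y_max=5, step=0.5)
        smoothed = np.zeros((grid.nx, grid.ny))
        smoothed[0, 0] = 1.0
        smoothed[8, 8] = 0.9
        cells = self._cells_for(
            {(0, 0): list(range(15)), (8, 8): list(range(15, 27))}
        )
        dose = pd.Series(np.arange(27) % 6)
        rois = extract_rois(smoothed, grid, cells, dose)
        assert len(rois) == 2
        masks = rois[0].cell_mask & rois[1].cell_mask
        assert not masks.any()

    def test_all_zero_surface_yields_empty_list(self):
        grid = GridSpec(x_min=0, x_max=1, y_min=0, y_max=1, step=0.5)
        assert extract_rois(np.zeros((2, 2)), grid, {}, pd.Series(dtype=int)) == []

    def test_small_components_dropped(self):
        grid = GridSpec(x_min=0, x_max=2.5, y_min=0, y_max=2.5, step=0.5)
        smoothed = np.zeros((grid.nx, grid.ny))
        smoothed[1, 1] = 1.0
        cells = self._cells_for({(1, 1): list(range(4))})
        rois = extract_rois(smoothed, grid, cells, pd.Series(np.zeros(4, int)))
        assert rois == []

    def test_roi_cells_at_or_above_cutoff(self):
        rng = np.random.default_rng(9)
        grid = GridSpec(x_min=0, x_max=5, y_min=0, y_max=5, step=0.5)
        smoothed = rng.random((grid.nx, grid.ny))
        cells = self._cells_for(
            {(i, j): list(range(100)) for i in range(grid.nx) for j in range(grid.ny)}
        )
        dose = pd.Series(np.zeros(100, int))
        rois = extract_rois(smoothed, grid, cells, dose, min_members=1)
        cutoff = 0.34 * smoothed.max()
        for roi in rois:
            assert smoothed[roi.cell_mask].min() >= cutoff


class TestPlantedRecoveryQuick:
    """Three-seed smoke check of the end-to-end ROI machinery; the 25-seed
    acceptance version lives in test_acceptance.py."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_subgroup_becomes_top_roi(self, seed):
        ds, truth = generate_dataset(roi_recovery_config(seed=seed))
        ds = reverse_score(ds)
        solutions = {
            sc.scale_id: select_k(
                pcc_matrix(ds, sc.scale_id),
                pcc_floor=ROI_RECOVERY_ANALYSIS["pcc_floor"],
                scale_id=sc.scale_id,
                prefix=sc.prefix,
            )
            for sc in ds.scales
        }
        scores = compute_factor_scores(ds, solutions)
        emb = embed_pca(scores, seed=42)
        grid = build_grid(emb)
        surface, cells = compute_sig_surface(
            scores,
            ds.dose,
            emb,
            grid,
            floor=ROI_RECOVERY_ANALYSIS["occupancy_floor"],
        )
        rois = extract_rois(surface.smoothed, grid, cells, ds.dose)
        assert rois, "no ROI found on planted data"
        planted = set(truth.subgroup_members(0))
        got = set(rois[0].member_indices)
        jaccard = len(got & planted) / len(got | planted)
        assert jaccard >= 0.8
        screen = correlation_screen(rois[0], scores, ds.dose)
        assert any(r.flagged and r.factor_id == "C-c1" for r in screen)
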