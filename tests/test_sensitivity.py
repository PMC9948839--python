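import numpy as np
import pytest

from segsense.demo import orientation_bank, rotation_subgrid
from segsense.sensitivity import (
    ParameterGrid,
    SensitivityMap,
    aggregate_maps,
    custom_grid,
    intensity_grid_case1,
    map_summary,
    plot_heatmap,
    rotation_grid_case1,
    rotation_grid_case2,
    run_sensitivity,
)
from segsense.synthetic import (
    make_constant_segmenter,
    make_oracle_segmenter,
    make_template_segmenter,
    make_threshold_segmenter,
)
from segsense.transforms import mirror_volume


class TestGridConstruction:
    def test_full_circle_rotation_grid(self):
        g = rotation_grid_case1()
        assert g.shape == (19, 19) and g.size == 361
        xs = g.axes[0][1]
        assert xs[0] == -180 and xs[-1] == 180
        assert np.allclose(np.diff(xs), 20)

    def test_intensity_grid(self):
        g = intensity_grid_case1()
        assert g.shape == (17, 17) and g.size == 289
        scales = g.axes[0][1]
        assert scales[8] == 1.0
        assert scales[0] == pytest.approx(1 / 5)
        assert scales[-1] == 5.0
        offsets = g.axes[1][1]
        assert offsets[0] == -3.0 and offsets[-1] == 3.0
        assert np.allclose(np.diff(offsets), 3 / 8)

    def test_small_angle_rotation_grid(self):
        g = rotation_grid_case2()
        assert g.shape == (17, 17) and g.size == 289
        xs = g.axes[0][1]
        assert xs[0] == -16 and xs[-1] == 16 and xs[8] == 0
        assert np.allclose(np.diff(xs), 2)

    def test_identity_index(self):
        assert rotation_grid_case2().identity_index() == (8, 8)
        assert intensity_grid_case1().identity_index() == (8, 8)

    def test_duplicate_axis_names_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(axes=(("a", (1.0,)), ("a", (2.0,))))

    def test_points_row_major_order(self):
        g = custom_grid({"a": (0.0, 1.0), "b": (5.0, 6.0)})
        pts = list(g.points())
        assert [idx for idx, _ in pts] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_dict_round_trip(self):
        g = intensity_grid_case1()
        assert ParameterGrid.from_dict(g.to_dict()) == g


@pytest.fixture(scope="module")
def small_grid():
    return rotation_subgrid(span=20, step=20)  # 3 x 3


class TestRunSensitivity:
    def test_oracle_segmenter_scores_one_everywhere(self, phantom32, small_grid):
        m = run_sensitivity(phantom32, make_oracle_segmenter(phantom32), small_grid)
        ident = small_grid.identity_index()
        assert m.scores[1][ident] == 1.0
        assert np.all(m.scores[1] >= 0.95)

    def test_constant_background_scores_zero(self, phantom32, small_grid):
        m = run_sensitivity(phantom32, make_constant_segmenter(), small_grid)
        assert np.all(m.scores[1] == 0.0)
        assert not m.degenerate[1].any()

    def test_identity_point_equals_direct_dice(self, phantom32):
        from segsense.metrics import dice

        seg = make_threshold_segmenter(0.7, 1.3)
        grid = custom_grid({"scale": (0.5, 1.0), "offset": (0.0,)},
                           kind="intensity_scale_offset")
        m = run_sensitivity(phantom32, seg, grid)
        direct = dice(phantom32.labels == 1, seg(phantom32.image) == 1).dsc
        assert m.scores[1][1, 0] == direct

    def test_determinism_bit_identical(self, phantom32, small_grid):
        seg = make_template_segmenter(phantom32, "identity_only")
        a = run_sensitivity(phantom32, seg, small_grid)
        b = run_sensitivity(phantom32, seg, small_grid)
        np.testing.assert_array_equal(a.scores[1], b.scores[1])

    def test_segmenter_shape_contract_error_names_grid_point(self, phantom32, small_grid):
        def bad(image, **_):
            return np.zeros((4, 4, 4), dtype=int)

        with pytest.raises(ValueError, match="grid point"):
            run_sensitivity(phantom32, bad, small_grid)

    def test_mirror_symmetric_templates_give_mirrored_maps(self, phantom32):
        # left/right mirrored structures produce y-mirrored DSC patterns
        grid = rotation_subgrid(span=16, step=8)
        phantom_m = mirror_volume(phantom32, {"x"})
        m_left = run_sensitivity(
            phantom32, make_template_segmenter(phantom32, "identity_only"), grid
        )
        m_right = run_sensitivity(
            phantom_m, make_template_segmenter(phantom_m, "identity_only"), grid
        )
        np.testing.assert_allclose(
            m_right.scores[1], m_left.scores[1][:, ::-1], atol=0.02
        )

    def test_rotation_augmented_bank_flattens_map(self, phantom48):
        grid = rotation_subgrid(span=40, step=40)  # 3 x 3, wide angles
        naive = run_sensitivity(
            phantom48, make_template_segmenter(phantom48, "identity_only"), grid
        )
        bank = run_sensitivity(
            phantom48, make_template_segmenter(phantom48, orientation_bank(grid)), grid
        )
        assert np.var(bank.scores[1]) < np.var(naive.scores[1])

    def test_staple_reference_mode(self, phantom32, small_grid):
        seg = make_template_segmenter(phantom32, orientation_bank(small_grid))
        m = run_sensitivity(phantom32, seg, small_grid, reference_mode="staple")
        assert np.all(m.scores[1] >= 0.9)
        assert m.provenance["common_fov_voxels"] > 0


class TestAggregation:
    def _uniform_map(self, grid, value, subject="s"):
        shape = grid.shape
        return SensitivityMap(
            grid=grid,
            scores={1: np.full(shape, float(value))},
            degenerate={1: np.zeros(shape, dtype=bool)},
            reference_mode="ground_truth",
            subject_id=subject,
        )

    def test_aggregate_of_identical_maps_is_idempotent(self, small_grid):
        m = self._uniform_map(small_grid, 0.7)
        agg = aggregate_maps([m, m, m])
        np.testing.assert_allclose(agg.scores[1], m.scores[1])

    def test_mean_of_two_maps(self, small_grid):
        agg = aggregate_maps(
            [self._uniform_map(small_grid, 0.2, "a"), self._uniform_map(small_grid, 0.8, "b")]
        )
        np.testing.assert_allclose(agg.scores[1], 0.5)

    def test_degenerate_cell_excluded_from_mean(self, small_grid):
        maps = [self._uniform_map(small_grid, v, s) for v, s in [(0.4, "a"), (0.6, "b"), (1.0, "c")]]
        deg = maps[2].degenerate[1].copy()
        deg[0, 0] = True
        maps[2] = SensitivityMap(
            grid=small_grid,
            scores=maps[2].scores,
            degenerate={1: deg},
            reference_mode="ground_truth",
            subject_id="c",
        )
        agg = aggregate_maps(maps)
        assert agg.scores[1][0, 0] == pytest.approx(0.5)  # mean of 0.4, 0.6
        assert agg.scores[1][1, 1] == pytest.approx(2 / 3, abs=1e-9)

    def test_grid_mismatch_rejected(self, small_grid):
        other = rotation_subgrid(span=10, step=10)
        with pytest.raises(ValueError):
            aggregate_maps([self._uniform_map(small_grid, 1), self._uniform_map(other, 1)])

    def test_aggregate_over_labels(self, small_grid):
        shape = small_grid.shape
        m = SensitivityMap(
            grid=small_grid,
            scores={1: np.full(shape, 0.2), 2: np.full(shape, 0.8)},
            degenerate={1: np.zeros(shape, bool), 2: np.zeros(shape, bool)},
            reference_mode="ground_truth",
            subject_id="s",
        )
        agg = aggregate_maps([m], over="labels")
        np.testing.assert_allclose(agg.scores["mean"], 0.5)


class TestMapSummary:
    def _map_from(self, grid, arr):
        return SensitivityMap(
            grid=grid,
            scores={1: np.asarray(arr, dtype=float)},
            degenerate={1: np.zeros(grid.shape, dtype=bool)},
            reference_mode="ground_truth",
            subject_id="s",
        )

    def test_uniform_map(self, small_grid):
        s = map_summary(self._map_from(small_grid, np.ones(small_grid.shape)), label=1)
        assert s["mean"] == 1.0 and s["std"] == 0.0
        assert s["argmax_index"] == (0, 0)  # first maximum in row-major order
        assert len(s["argmax_ties"]) == small_grid.size

    def test_single_peak_argmax_offset(self):
        grid = custom_grid(
            {"x_angle_deg": (-20.0, 0.0, 20.0), "y_angle_deg": (-20.0, 0.0, 20.0)},
            kind="rotation_xy",
        )
        arr = np.zeros((3, 3))
        arr[2, 1] = 1.0  # peak at x=+20, y=0
        s = map_summary(self._map_from(grid, arr), label=1)
        assert s["argmax_values"] == (20.0, 0.0)
        assert s["argmax_offset"] == (20.0, 0.0)

    def test_mean_std_population_convention(self):
        # values {0.6, 1.0} in equal counts: mean 0.8, population std 0.2
        grid = custom_grid({"offset": (0.0, 1.0)})
        s = map_summary(self._map_from(grid, [0.6, 1.0]), label=1)
        assert s["mean"] == pytest.approx(0.8)
        assert s["std"] == pytest.approx(0.2)

    def test_tsv_round_trip_columns(self, phantom32, small_grid, tmp_path):
        m = run_sensitivity(phantom32, make_constant_segmenter(), small_grid)
        m.to_tsv(tmp_path / "scores.tsv")
        import pandas as pd

        frame = pd.read_csv(tmp_path / "scores.tsv", sep="\t")
        assert list(frame.columns) == [
            "subject_id", "label_id", "x_angle_deg", "y_angle_deg", "dsc", "degenerate_flag",
        ]
        assert len(frame) == small_grid.size

    def test_heatmap_renders(self, small_grid, tmp_path):
        m = self._map_from(small_grid, np.random.default_rng(0).random(small_grid.shape))
        plot_heatmap(m, label=1, path=tmp_path / "map.png")
        assert (tmp_path / "map.png").stat().st_size > 0
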