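"""Spatial world geometry, motor coding and retinal encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neglectsim.stimuli import (
    CONDITIONS,
    EncoderConfig,
    PostureState,
    batch_encode,
    camera_azimuth,
    encode_motor,
    encode_stimulus,
    hemisphere_inputs,
    in_view,
    make_condition,
    make_training_grid,
    make_training_set,
)


class TestTrainingGrid:
    def test_sixteen_areas_split_evenly_across_the_midline(self):
        areas = make_training_grid()
        assert len(areas) == 16
        assert sum(a.side == "left" for a in areas) == 8
        assert sum(a.side == "right" for a in areas) == 8
        assert all(a.side == ("left" if a.azimuth_deg < 0 else "right") for a in areas)

    def test_azimuths_are_symmetric_about_zero(self):
        azs = sorted(a.azimuth_deg for a in make_training_grid())
        assert azs == sorted(-a for a in azs)
        assert set(abs(a) for a in azs) == {7.5, 22.5, 37.5, 52.5}

    def test_area_id_is_a_bijection_of_row_and_column(self):
        areas = make_training_grid()
        assert sorted(a.area_id for a in areas) == list(range(16))
        assert len({(a.row, a.column) for a in areas}) == 16
        near_left = next(a for a in areas if a.row == 0 and a.column == 0)
        assert near_left.azimuth_deg == -52.5


class TestConditions:
    def test_condition_a_straddles_the_midline_with_head_straight(self):
        layout = make_condition("A")
        grid = {a.area_id: a for a in make_training_grid()}
        sides = [grid[i].side for i in layout.target_area_ids]
        assert sides.count("left") == 4 and sides.count("right") == 4
        assert layout.neck_angle_deg == 0

    def test_b_and_c_share_right_hemispace_targets(self):
        b, c = make_condition("B"), make_condition("C")
        grid = {a.area_id: a for a in make_training_grid()}
        assert b.target_area_ids == c.target_area_ids
        assert all(grid[i].side == "right" for i in c.target_area_ids)
        assert b.neck_angle_deg == 0 and c.neck_angle_deg == 40

    def test_d_returns_targets_to_the_a_layout_with_head_turned(self):
        a, d = make_condition("A"), make_condition("D")
        assert d.target_area_ids == a.target_area_ids
        assert d.neck_angle_deg == 40

    def test_unknown_condition_is_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            make_condition("E")


class TestMotorCoding:
    @pytest.mark.parametrize(
        "angle, expected_right, expected_left",
        [(40, -1.0, 1.0), (0, 0.0, 0.0), (-40, 1.0, -1.0), (20, -0.5, 0.5)],
    )
    def test_antagonist_muscle_pair(self, angle, expected_right, expected_left):
        right, left = encode_motor(angle)
        assert right == pytest.approx(expected_right)
        assert left == pytest.approx(expected_left)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError, match="out of"):
            encode_motor(61)

    @given(angle=st.floats(-60, 60, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_muscle_inputs_always_sum_to_zero(self, angle):
        right, left = encode_motor(angle)
        assert right + left == 0.0
        if abs(angle) >= 1e-6:
            assert np.sign(right) == -np.sign(angle)


class TestCameraFrame:
    @pytest.mark.parametrize(
        "trunk, neck, eye, expected",
        [(22.5, 0, "left", 22.5), (22.5, 40, "left", -17.5), (-22.5, 40, "right", -62.5)],
    )
    def test_head_rotation_shifts_the_camera_frame(self, trunk, neck, eye, expected):
        assert camera_azimuth(trunk, neck, eye) == pytest.approx(expected)

    def test_interocular_offset_splits_the_eyes(self):
        left = camera_azimuth(10, 0, "left", interocular_offset_deg=4)
        right = camera_azimuth(10, 0, "right", interocular_offset_deg=4)
        assert left - right == pytest.approx(4)


class TestRetinalEncoding:
    def test_peak_on_own_cell_at_neutral_posture(self, enc_config):
        grid = {a.azimuth_deg: a for a in make_training_grid() if a.row == 0}
        stim = encode_stimulus(grid[7.5], PostureState.from_angle(0), enc_config)
        peak = np.argmax(stim.left_visual)
        assert enc_config.column_azimuths[peak % 8] == 7.5
        assert np.array_equal(stim.left_visual, stim.right_visual)  # zero interocular offset
        assert stim.left_visual.max() == pytest.approx(1.0)
        assert np.all((0 <= stim.left_visual) & (stim.left_visual <= 1))

    def test_head_turn_shifts_the_peak_to_the_nearest_camera_cell(self, enc_config):
        # trunk +7.5 with neck 40 lands at camera -32.5: nearest cell center is -37.5
        area = next(a for a in make_training_grid() if a.row == 0 and a.azimuth_deg == 7.5)
        stim = encode_stimulus(area, PostureState.from_angle(40), enc_config)
        peak = np.argmax(stim.left_visual)
        assert enc_config.column_azimuths[peak % 8] == -37.5

    def test_retinotopy_is_monotone_in_trunk_azimuth(self, enc_config):
        peaks = []
        for a in sorted(make_training_grid(), key=lambda a: a.azimuth_deg):
            if a.row != 0:
                continue
            stim = encode_stimulus(a, PostureState.from_angle(0), enc_config)
            peaks.append(int(np.argmax(stim.left_visual)))
        assert peaks == sorted(peaks)
        assert len(set(peaks)) == len(peaks)

    def test_target_outside_field_of_view_is_rejected(self, enc_config):
        area = next(a for a in make_training_grid() if a.azimuth_deg == -52.5)
        with pytest.raises(ValueError, match="field of view"):
            encode_stimulus(area, PostureState.from_angle(40), enc_config)

    def test_one_hot_visual_code_activates_a_single_cell(self):
        cfg = EncoderConfig(visual_code="one_hot")
        area = next(a for a in make_training_grid(cfg) if a.row == 1 and a.azimuth_deg == 22.5)
        stim = encode_stimulus(area, PostureState.from_angle(0), cfg)
        assert stim.left_visual.sum() == 1.0 and stim.left_visual.max() == 1.0


class TestHemisphereRouting:
    def test_contralateral_field_passes_at_full_gain(self, enc_config):
        area = next(a for a in make_training_grid() if a.row == 0 and a.azimuth_deg == -22.5)
        stim = encode_stimulus(area, PostureState.from_angle(0), enc_config)
        x_l, x_r = hemisphere_inputs(stim, enc_config)
        # left-hemispace target: RH carries the full bump, LH only the gain-scaled copy
        assert x_r[:16].max() == pytest.approx(1.0)
        assert x_l[:16].max() <= enc_config.ipsilateral_gain + 1e-12
        assert x_l[16] == stim.left_motor and x_r[16] == stim.right_motor

    def test_crossing_off_passes_full_images(self):
        cfg = EncoderConfig(hemifield_crossing=False)
        area = next(a for a in make_training_grid(cfg) if a.row == 0 and a.azimuth_deg == -22.5)
        stim = encode_stimulus(area, PostureState.from_angle(0), cfg)
        x_l, x_r = hemisphere_inputs(stim, cfg)
        assert np.array_equal(x_l[:16], stim.left_visual)
        assert np.array_equal(x_r[:16], stim.right_visual)


class TestTrainingSet:
    def test_covers_every_area_and_both_postures_within_view(self, enc_config):
        ts = make_training_set(enc_config)
        areas = make_training_grid(enc_config)
        # every area trained at least once; in-view areas at 40 degrees trained twice
        by_id: dict[int, int] = {}
        for s in ts:
            by_id[s.teacher_area_id] = by_id.get(s.teacher_area_id, 0) + 1
        assert set(by_id) == set(range(16))
        for a in areas:
            expected = 1 + int(in_view(a, 40.0, enc_config))
            assert by_id[a.area_id] == expected
        assert len(ts) == sum(1 + int(in_view(a, 40.0, enc_config)) for a in areas)

    def test_every_test_condition_pair_is_trained(self, enc_config):
        trained = set()
        for s in make_training_set(enc_config):
            neck = 0.0 if s.right_motor == 0 else 40.0
            trained.add((s.teacher_area_id, neck))
        for c in CONDITIONS:
            layout = make_condition(c, enc_config)
            for i in layout.target_area_ids:
                assert (i, layout.neck_angle_deg) in trained

    def test_teachers_are_one_hot_and_recover_the_area(self, enc_config):
        batch = batch_encode(make_training_set(enc_config), enc_config)
        assert np.allclose(batch.teachers.sum(axis=1), 1.0)
        assert np.array_equal(np.argmax(batch.teachers, axis=1), batch.area_ids)


class TestExports:
    def test_layout_exports_to_frame_and_json(self):
        import json

        from neglectsim.stimuli import layout_to_frame, layout_to_json

        layout = make_condition("C")
        df = layout_to_frame(layout)
        assert len(df) == 8
        assert set(df["side"]) == {"right"}
        assert (df["neck_angle_deg"] == 40.0).all()
        back = json.loads(layout_to_json(layout))
        assert back["condition"] == "C" and len(back["target_area_ids"]) == 8
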