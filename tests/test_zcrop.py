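"""Floating-window crop: plan arithmetic and the chunked-vs-naive oracle."""

import json
import os

import numpy as np
import pytest

from agardrift import (
    DriftModel,
    HyperStack,
    apply_crop,
    plan_crop,
    read_hyperstack,
    reduction_report,
)
from agardrift.synth import drift_only_config, generate
from agardrift.zcrop import CropPlan


def naive_crop(pixels, plan):
    """Oracle: whole-stack fancy indexing in memory."""
    w = plan.window_thickness
    return np.stack([pixels[t, :, s : s + w] for t, s in enumerate(plan.start_slices)])


class TestPlan:
    def test_half_away_rounding(self, random_stack_factory):
        stack = random_stack_factory(dims=(4, 1, 150, 4, 4))
        model = DriftModel(0.5, 5.0, 0, "user_specified")
        plan = plan_crop(model, stack, 20, offset=0)
        assert plan.start_slices == [5, 6, 6, 7]
        assert plan.clamped_timepoints == []

    def test_zero_drift_equal_starts(self, random_stack_factory):
        stack = random_stack_factory(dims=(5, 1, 30, 4, 4))
        plan = plan_crop(DriftModel(0.0, 12.0, 0, "user_specified"), stack, 10, offset=0)
        assert plan.start_slices == [12] * 5

    def test_clamped_at_top_edge(self, random_stack_factory):
        stack = random_stack_factory(dims=(3, 1, 150, 4, 4))
        plan = plan_crop(DriftModel(1.0, 140.0, 0, "user_specified"), stack, 20, offset=0)
        assert plan.start_slices == [130, 130, 130]
        assert plan.clamped_timepoints == [0, 1, 2]

    def test_default_offset_places_surface_quarter_window_up(self, random_stack_factory):
        stack = random_stack_factory(dims=(1, 1, 100, 4, 4))
        plan = plan_crop(DriftModel(0.0, 40.0, 0, "user_specified"), stack, 20)
        assert plan.start_slices == [35]  # 40 - 20/4

    def test_monotone_when_drift_sign_constant(self, random_stack_factory):
        stack = random_stack_factory(dims=(30, 1, 60, 4, 4))
        plan = plan_crop(DriftModel(-0.37, 50.0, 0, "user_specified"), stack, 8, offset=0)
        assert all(a >= b for a, b in zip(plan.start_slices, plan.start_slices[1:]))

    def test_window_wider_than_stack_rejected(self, random_stack_factory):
        stack = random_stack_factory(dims=(2, 1, 10, 4, 4))
        with pytest.raises(ValueError, match="window_thickness"):
            plan_crop(DriftModel(0.0, 5.0, 0, "user_specified"), stack, 11)

    def test_json_round_trip(self, tmp_path, random_stack_factory):
        stack = random_stack_factory(dims=(4, 1, 30, 4, 4))
        plan = plan_crop(DriftModel(0.5, 3.0, 0, "user_specified"), stack, 6)
        path = plan.save(tmp_path / "plan.json")
        with open(path) as fh:
            again = CropPlan.from_dict(json.load(fh))
        assert again.start_slices == plan.start_slices


class TestApply:
    def test_identity_crop(self, tmp_path, random_stack_factory):
        stack = random_stack_factory(dims=(3, 2, 12, 8, 8), seed=5)
        plan = plan_crop(DriftModel(0.0, 0.0, 0, "user_specified"), stack, 12, offset=0)
        with apply_crop(stack, plan, tmp_path / "id.ome.tif") as out:
            np.testing.assert_array_equal(out.asarray(), stack.pixels)

    @pytest.mark.parametrize("seed", range(6))
    def test_chunked_equals_naive_oracle(self, tmp_path, random_stack_factory, seed):
        stack = random_stack_factory(dims=(6, 2, 40, 10, 10), seed=seed)
        model = DriftModel(1.5, 4.0 + seed, 0, "user_specified")
        plan = plan_crop(model, stack, 8, offset=0)
        with apply_crop(stack, plan, tmp_path / f"c{seed}.ome.tif") as out:
            got = out.asarray()
        np.testing.assert_array_equal(got, naive_crop(stack.pixels, plan))
        assert got.shape == (6, 2, 8, 10, 10)

    def test_output_metadata_copied(self, tmp_path, random_stack_factory):
        stack = random_stack_factory(dims=(2, 2, 10, 6, 6), seed=1)
        plan = plan_crop(DriftModel(0.0, 2.0, 0, "user_specified"), stack, 5, offset=0)
        with apply_crop(stack, plan, tmp_path / "m.ome.tif") as out:
            assert [ch.color for ch in out.channels] == [ch.color for ch in stack.channels]
            assert out.calibration.z_step == stack.calibration.z_step

    def test_surface_stays_fixed_in_output(self, tmp_path):
        """After cropping a noiseless drifting-surface stack, the slab sits at a
        constant output Z (±1 slice from rounding) at every timepoint."""
        cfg = drift_only_config(t_dim=25, z_dim=40)
        stack, truth = generate(cfg)
        model = DriftModel(truth.displacement_slices_per_timepoint, truth.surface_slice[0], 0, "user_specified")
        plan = plan_crop(model, stack, 8, offset=-4)
        with apply_crop(stack, plan, tmp_path / "s.ome.tif") as out:
            arr = out.asarray()
        unclamped = [t for t in range(arr.shape[0]) if t not in plan.clamped_timepoints]
        surface_z = [int(np.argmax(arr[t, 0].mean(axis=(1, 2)))) for t in unclamped]
        assert max(surface_z) - min(surface_z) <= 1

    def test_resume_from_manifest(self, tmp_path, random_stack_factory):
        """A run interrupted after staging some timepoints completes correctly."""
        stack = random_stack_factory(dims=(5, 1, 20, 8, 8), seed=9)
        plan = plan_crop(DriftModel(1.0, 2.0, 0, "user_specified"), stack, 6, offset=0)
        out_path = tmp_path / "res.ome.tif"

        # simulate an interrupted first run: stage t=0,1 only, leave manifest
        import tifffile

        tmp_dir = str(out_path) + ".tmp"
        os.makedirs(tmp_dir)
        for t in (0, 1):
            s = plan.start_slices[t]
            tifffile.imwrite(
                os.path.join(tmp_dir, f"t{t:05d}.tif"),
                stack.pixels[t, :, s : s + 6],
                photometric="minisblack",
            )
        with open(str(out_path) + ".manifest.json", "w") as fh:
            json.dump({"plan": plan.to_dict(), "completed": [0, 1]}, fh)

        with apply_crop(stack, plan, out_path) as out:
            np.testing.assert_array_equal(out.asarray(), naive_crop(stack.pixels, plan))
        assert not os.path.exists(tmp_dir)  # temp files removed on success
        assert not os.path.exists(str(out_path) + ".manifest.json")

    def test_stale_manifest_discarded(self, tmp_path, random_stack_factory):
        stack = random_stack_factory(dims=(3, 1, 20, 8, 8), seed=2)
        plan = plan_crop(DriftModel(1.0, 2.0, 0, "user_specified"), stack, 6, offset=0)
        other = plan_crop(DriftModel(0.0, 2.0, 0, "user_specified"), stack, 6, offset=0)
        out_path = tmp_path / "stale.ome.tif"
        os.makedirs(str(out_path) + ".tmp")
        with open(str(out_path) + ".manifest.json", "w") as fh:
            json.dump({"plan": other.to_dict(), "completed": [0]}, fh)
        with apply_crop(stack, plan, out_path) as out:
            np.testing.assert_array_equal(out.asarray(), naive_crop(stack.pixels, plan))

    def test_plane_count_reduction_on_disk(self, tmp_path, random_stack_factory):
        import tifffile

        stack = random_stack_factory(dims=(2, 1, 30, 6, 6), seed=3)
        plan = plan_crop(DriftModel(0.0, 10.0, 0, "user_specified"), stack, 6, offset=0)
        out_path = tmp_path / "red.ome.tif"
        apply_crop(stack, plan, out_path).close()
        with tifffile.TiffFile(out_path) as tf:
            assert len(tf.series[0].pages) == 2 * 1 * 6  # T*C*W planes stored
        read_hyperstack(out_path).dims == (2, 1, 6, 6, 6)


class TestReport:
    def test_report_numbers(self):
        plan = CropPlan(window_thickness=15, start_slices=[0] * 10, source_dims=(10, 3, 150, 512, 512))
        report = reduction_report(plan, bytes_per_plane=262144)
        assert report["slice_ratio"] == pytest.approx(10.0)
        assert report["input_planes"] == 4500
        assert report["output_planes"] == 450
        assert report["output_bytes"] == 450 * 262144

    def test_identity_window_ratio_one(self):
        plan = CropPlan(window_thickness=20, start_slices=[0], source_dims=(1, 1, 20, 8, 8))
        assert reduction_report(plan)["slice_ratio"] == 1.0
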