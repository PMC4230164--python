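"""Synthetic cohort generator: signal model, matching invariants, determinism."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from roamlight import (CohortSpec, NoiseParams, default_ground_truth,
                       ellipsoid_brain_mask, make_design, make_ground_truth,
                       simulate_cohort, simulate_subject)
from roamlight.simulate import BASELINE

QUIET = NoiseParams(white_sd=0.0, drift_amplitude=0.0, ar1_coefficient=0.0, seed=0)


class TestGroundTruth:
    def test_no_group_effect_when_separability_is_one(self, micro_design):
        truth = default_ground_truth(micro_design, seed=4,
                                     cp_separability_factor=1.0)
        cats = micro_design.condition_names
        wc = truth.weight_maps("control", cats, subject_seed=9)
        wp = truth.weight_maps("cp", cats, subject_seed=9)
        assert np.array_equal(wc, wp)

    def test_zero_separability_collapses_face_and_object_in_cp(self, micro_design):
        truth = default_ground_truth(micro_design, seed=4,
                                     cp_separability_factor=0.0)
        cats = micro_design.condition_names
        wp = truth.weight_maps("cp", cats, subject_seed=9)
        assert np.allclose(wp[cats.index("face")], wp[cats.index("object")])

    def test_pattern_difference_has_zero_roi_mean(self, micro_design):
        for seed in range(10):
            truth = default_ground_truth(micro_design, seed=seed)
            cats = micro_design.condition_names
            W = truth.weight_maps("control", cats, subject_seed=seed + 100)
            diff = W[cats.index("face")] - W[cats.index("object")]
            for roi in truth.roi_masks.values():
                assert abs(diff[roi].mean()) < 1e-10

    def test_separability_scales_pattern_distance_monotonically(self, micro_design):
        """Within-ROI face-object pattern distance shrinks with the CP factor."""
        factors = [1.0, 0.6, 0.2]
        cats = micro_design.condition_names
        dists = []
        for f in factors:
            per_seed = []
            for seed in range(20):
                truth = default_ground_truth(micro_design, seed=0,
                                             cp_separability_factor=f)
                W = truth.weight_maps("cp", cats, subject_seed=seed)
                d = W[cats.index("face")] - W[cats.index("object")]
                roi = next(iter(truth.roi_masks.values()))
                per_seed.append(np.linalg.norm(d[roi]))
            dists.append(np.mean(per_seed))
        assert dists[0] > dists[1] > dists[2]

    def test_rois_lie_inside_brain_mask(self, micro_design):
        truth = default_ground_truth(micro_design, seed=0)
        for roi in truth.roi_masks.values():
            assert not np.any(roi & ~truth.brain_mask)

    def test_empty_roi_rejected(self, micro_design):
        geom = micro_design.geometry
        brain = ellipsoid_brain_mask(geom.grid_dims)
        with pytest.raises(ValueError, match="empty"):
            make_ground_truth(geom, [("corner", (0, 0, 0), 0.1)],
                              brain_mask=brain)

    def test_center_outside_grid_rejected(self, micro_design):
        geom = micro_design.geometry
        with pytest.raises(ValueError, match="outside grid"):
            make_ground_truth(geom, [("oob", (99, 0, 0), 3.0)])


class TestSimulateSubject:
    def test_null_signal_gives_constant_baseline(self, micro_design):
        truth = default_ground_truth(micro_design, seed=0, mean_amplitude=0.0,
                                     pattern_sd=0.0)
        runs = simulate_subject(micro_design, truth, "control", QUIET, 5)
        for vol in runs:
            assert np.allclose(vol, BASELINE)

    def test_noiseless_time_course_is_weighted_convolved_boxcar(self, micro_design):
        truth = default_ground_truth(micro_design, seed=1)
        runs = simulate_subject(micro_design, truth, "control", QUIET, 7)
        cats = micro_design.condition_names
        W = truth.weight_maps("control", cats, subject_seed=7)
        geom = micro_design.geometry
        # independent oracle: re-convolve boxcars with the analytic
        # double-gamma on a fine grid, sampled at scan times
        dt = 0.1
        tt = np.arange(0, geom.run_length_s + dt, dt)
        kernel = stats.gamma.pdf(tt[tt <= 32], 6) - stats.gamma.pdf(tt[tt <= 32], 16) / 6
        scan_idx = np.round(geom.frame_times_s / dt).astype(int)
        for run in range(geom.n_runs):
            regs = []
            for cond in cats:
                box = np.zeros_like(tt)
                for e in micro_design.run_events(run):
                    if e.condition == cond:
                        box[(tt >= e.onset_s) & (tt < e.onset_s + e.duration_s)] = 1
                regs.append(np.convolve(box, kernel)[:len(tt)][scan_idx] * dt)
            regs = np.array(regs)
            vox = next(iter(truth.roi_masks.values())).nonzero()
            i, j, k = vox[0][0], vox[1][0], vox[2][0]
            expected = BASELINE + W[:, i, j, k] @ regs
            assert np.allclose(runs[run][i, j, k], expected, atol=1e-9)

    def test_same_seed_reproduces_bit_for_bit(self, micro_design):
        truth = default_ground_truth(micro_design, seed=2)
        noise = NoiseParams(white_sd=1.0, drift_amplitude=1.0,
                            ar1_coefficient=0.3, seed=2)
        a = simulate_subject(micro_design, truth, "cp", noise, 11)
        b = simulate_subject(micro_design, truth, "cp", noise, 11)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_noise_parameters_validated(self):
        with pytest.raises(ValueError):
            NoiseParams(white_sd=np.nan)
        with pytest.raises(ValueError):
            NoiseParams(ar1_coefficient=1.0)

    def test_ar1_noise_has_target_marginal_sd_and_autocorrelation(self, micro_design):
        truth = default_ground_truth(micro_design, seed=0, mean_amplitude=0.0,
                                     pattern_sd=0.0)
        noise = NoiseParams(white_sd=2.0, drift_amplitude=0.0,
                            ar1_coefficient=0.5, seed=0)
        run = simulate_subject(micro_design, truth, "control", noise, 3)[0]
        resid = run - BASELINE
        flat = resid.reshape(-1, resid.shape[-1])
        assert flat.std() == pytest.approx(2.0, rel=0.05)
        r1 = np.mean([np.corrcoef(ts[:-1], ts[1:])[0, 1] for ts in flat[:200]])
        assert r1 == pytest.approx(0.5, abs=0.08)


class TestMeanAmplitudeMatching:
    def test_block_averaged_roi_signal_identical_across_pair(self, tiny_design):
        """In the noiseless limit the face and object ROI-mean responses match.

        The mean-centered patterns drop out of the ROI average, so the
        ROI-mean trajectory is category-independent; the 8-run rotation
        balances serial positions, making block averages equal exactly.
        """
        for group in ("control", "cp"):
            truth = default_ground_truth(tiny_design, seed=6,
                                         cp_separability_factor=0.3)
            runs = simulate_subject(tiny_design, truth, group, QUIET, 21)
            geom = tiny_design.geometry
            t = geom.frame_times_s
            for roi in truth.roi_masks.values():
                means = {}
                for cond in ("face", "object"):
                    vals = []
                    for run_idx, vol in enumerate(runs):
                        for e in tiny_design.run_events(run_idx):
                            # sample the plateau of each block (shifted for
                            # haemodynamic lag, within-block seconds 8-16)
                            if e.condition == cond:
                                sel = (t >= e.onset_s + 8) & (t < e.onset_s + 16)
                                vals.append(vol[roi][:, sel].mean())
                    means[cond] = np.mean(vals)
                assert abs(means["face"] - means["object"]) \
                    < 1e-6 * truth.mean_amplitude


class TestSimulateCohort:
    def _tiny_spec(self, seed=4):
        design = make_design({"grid_dims": (8, 8, 6), "n_volumes_per_run": 50,
                              "n_runs": 1})
        truth = default_ground_truth(design, seed=seed)
        return CohortSpec(n_controls=2, n_cps=2, design=design, truth=truth,
                         noise=NoiseParams(seed=seed))

    def test_layout_and_manifest(self, tmp_path):
        root = simulate_cohort(self._tiny_spec(), tmp_path / "cohort")
        manifest = json.loads((root / "manifest.json").read_text())
        assert len(manifest["subjects"]) == 4
        groups = [s["group"] for s in manifest["subjects"]]
        assert groups.count("control") == 2 and groups.count("cp") == 2
        bolds = list(root.rglob("*_bold.nii.gz"))
        assert len(bolds) == 4  # 4 subjects x 1 run
        assert (root / "brain_mask.nii.gz").exists()
        assert (root / "sub-01" / "func" /
                "sub-01_task-blocks_run-01_events.tsv").exists()
        assert (root / "ground_truth" / "params.json").exists()

    def test_events_tsv_is_bids_flavoured(self, tmp_path):
        import pandas as pd

        root = simulate_cohort(self._tiny_spec(), tmp_path / "cohort")
        ev = pd.read_csv(root / "sub-01" / "func" /
                         "sub-01_task-blocks_run-01_events.tsv", sep="\t")
        assert list(ev.columns) == ["onset", "duration", "trial_type"]
        assert (ev.onset.diff().dropna() > 0).all()

    def test_regeneration_is_byte_identical(self, tmp_path):
        def digest(root):
            h = hashlib.sha256()
            for p in sorted(Path(root).rglob("*.nii.gz")):
                h.update(p.read_bytes())
            return h.hexdigest()

        a = simulate_cohort(self._tiny_spec(), tmp_path / "a")
        b = simulate_cohort(self._tiny_spec(), tmp_path / "b")
        assert digest(a) == digest(b)

    def test_default_cohort_counts(self):
        spec = CohortSpec()
        assert len(spec.groups) == 17
        assert spec.groups.count("control") == 10
        assert spec.groups.count("cp") == 7
        assert spec.design.geometry.n_runs == 8  # 136 4-D files when written
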