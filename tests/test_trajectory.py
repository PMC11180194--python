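"""Trajectory inclusion, safe boundaries, subregion averaging, container
round-trip, and the end-to-end pipeline contract."""

import numpy as np
import pytest

from stnio import cohort, io, spectral, trajectory


def _site(depth, sub, pid="P0", tid="T0", k=0, n=64):
    return io.SiteRecord(patient=pid, trajectory=tid, site_index=k,
                         depth_mm=depth, subregion=sub, fs=4096.0,
                         lfp=np.zeros(n, np.float32),
                         spk=np.zeros(n, np.float32))


def _profile(pre_mm=4.0, motor_mm=3.0, nonmotor_mm=2.0, step=0.5):
    sites, k = [], 0
    for d in np.arange(-pre_mm, 0, step):
        sites.append(_site(round(d, 3), "pre", k=k)); k += 1
    for d in np.arange(0, motor_mm, step):
        sites.append(_site(round(d, 3), "motor", k=k)); k += 1
    for d in np.arange(motor_mm, motor_mm + nonmotor_mm, step):
        sites.append(_site(round(d, 3), "nonmotor", k=k)); k += 1
    return trajectory.build_profile(sites)


class TestInclusion:
    def test_all_subregions_long_enough_accepted(self):
        ok, reason = trajectory.include_trajectory(_profile(4.0, 3.0, 2.0))
        assert ok, reason

    def test_short_motor_rejected(self):
        ok, reason = trajectory.include_trajectory(_profile(motor_mm=0.8))
        assert not ok and "motor" in reason

    def test_missing_nonmotor_rejected(self):
        profile = _profile()
        profile.sites = [s for s in profile.sites
                         if s.subregion != "nonmotor"]
        profile = trajectory.build_profile(profile.sites)
        ok, reason = trajectory.include_trajectory(profile)
        assert not ok and "nonmotor" in reason


class TestSafeBoundaries:
    def test_motor_trimmed_half_mm_both_ends(self):
        profile = trajectory.apply_safe_boundaries(_profile(step=0.25))
        depths = profile.depths
        motor = profile.labels == "motor"
        kept = depths[motor & ~profile.boundary_flag]
        # motor borders sit at -0.125 and 2.875 (midpoints); 0.5 mm margins
        assert kept.min() >= profile.entry_mm + 0.5
        assert kept.max() <= profile.motor_exit_mm - 0.5

    def test_pre_stn_final_half_mm_excluded_only(self):
        profile = trajectory.apply_safe_boundaries(_profile(step=0.25))
        pre = profile.labels == "pre"
        flagged = profile.depths[pre & profile.boundary_flag]
        unflagged = profile.depths[pre & ~profile.boundary_flag]
        assert flagged.min() > profile.entry_mm - 0.5 - 1e-9
        assert (unflagged < profile.entry_mm - 0.5 + 1e-9).all()
        assert unflagged.min() == profile.depths[pre].min()  # top kept

    def test_tiny_motor_fully_consumed(self):
        profile = _profile(motor_mm=1.0, step=0.25)
        profile = trajectory.apply_safe_boundaries(profile)
        motor = profile.labels == "motor"
        assert profile.boundary_flag[motor].all()

    def test_normalized_distance_affine_and_ordered(self):
        profile = _profile()
        nd = profile.normalized_distance()
        assert (np.diff(nd) > 0).all()
        assert nd[profile.labels == "pre"].max() < 0


class TestSubregionAverage:
    def test_identical_sites_average_to_themselves(self):
        freqs = np.arange(3, 70.5, 0.5)
        psds = [spectral.SitePSD(freqs=freqs, power=np.full_like(freqs, v))
                for v in (1.0, 3.0)]
        out = trajectory.subregion_average_psd(
            psds, np.array(["motor", "motor"]), np.array([True, True]))
        np.testing.assert_allclose(out["motor"].power, 2.0)

    def test_empty_subregion_missing(self):
        freqs = np.arange(3, 70.5, 0.5)
        psds = [spectral.SitePSD(freqs=freqs, power=np.ones_like(freqs))]
        out = trajectory.subregion_average_psd(
            psds, np.array(["motor"]), np.array([False]))
        assert "motor" not in out


class TestCohortGenerator:
    def test_bit_reproducible(self):
        cfg = cohort.SyntheticStudyConfig(n_patients=1, seed=99)
        a_sites, a_clin, a_truth = cohort.simulate_study(cfg)
        b_sites, b_clin, b_truth = cohort.simulate_study(cfg)
        assert a_truth == b_truth
        assert a_clin.equals(b_clin)
        for sa, sb in zip(a_sites, b_sites):
            np.testing.assert_array_equal(sa.lfp, sb.lfp)
            np.testing.assert_array_equal(sa.spk, sb.spk)

    def test_subregion_below_one_mm_rejected(self):
        with pytest.raises(ValueError, match="1 mm"):
            cohort.SyntheticStudyConfig(subregion_lengths=(4.0, 0.8, 1.5))


class TestContainerRoundTrip:
    def test_lossless(self, small_study, tmp_path):
        _, sites, clinical, truth = small_study
        paths = cohort.save_study(tmp_path, sites, clinical, truth)
        back = io.read_container(paths["container"])
        assert len(back) == len(sites)
        orig = {(s.patient, s.trajectory, s.site_index): s for s in sites}
        for b in back:
            o = orig[(b.patient, b.trajectory, b.site_index)]
            np.testing.assert_array_equal(b.lfp, o.lfp)
            np.testing.assert_array_equal(b.spk, o.spk)
            assert b.subregion == o.subregion
            assert b.depth_mm == o.depth_mm
        truth_back = io.read_sidecar(paths["truth"])
        assert truth_back["trajectories"].keys() == truth["trajectories"].keys()


class TestPipeline:
    def test_site_counts_reconcile(self, pipeline_results):
        """raw = retained + flagged(any of outlier/too-short/boundary)."""
        st = pipeline_results["site_table"]
        for _, g in st.groupby(["patient", "trajectory", "stream"]):
            flagged = (g.outlier | g.too_short | g.boundary)
            assert (flagged == ~g.retained).all()

    def test_lfp_exponent_exceeds_spk(self, pipeline_results):
        fits = pipeline_results["fits"]
        means = fits.groupby("stream")["exponent"].mean()
        assert means["LFP"] > means["SPK"] + 1.0

    def test_downshift_dominates_by_construction(self, pipeline_results):
        s = pipeline_results["downshift_trajectory"]
        assert s.fraction_down > s.fraction_up

    def test_deterministic_rerun(self, small_study):
        _, sites, _, _ = small_study
        a = trajectory.run_pipeline(sites[:100])
        b = trajectory.run_pipeline(sites[:100])
        for key in ("fits", "site_table", "trajectory_beta_cf"):
            assert a[key].equals(b[key])

    def test_distance_normalized_variant_preserves_downshift(self, small_study):
        """Z-scoring against the pre-STN baseline shrinks the volume-
        conducted LFP beta but keeps the trajectory βCFs near truth and
        the downshift intact."""
        _, sites, _, truth = small_study
        two = [s for s in sites if s.patient in ("P000", "P001")]
        res = trajectory.run_pipeline(two, norm="freqdist")
        tb = res["trajectory_beta_cf"]
        for _, row in tb.dropna(subset=["beta_cf"]).iterrows():
            t = truth["trajectories"][f"{row.patient}/{row.trajectory}"]
            key = "lfp_beta_cf" if row.stream == "LFP" else "spk_beta_cf"
            assert abs(row.beta_cf - t[key]) <= 1.0
        s = res["downshift_trajectory"]
        assert s.fraction_down > s.fraction_up

    def test_anova_separates_streams(self, pipeline_results):
        res = pipeline_results["anova_exponent"]
        assert res["p_signal"] < 1e-10
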