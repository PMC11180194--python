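"""Trajectory assembly and the end-to-end analysis pipeline.

A trajectory is an ordered sequence of recording sites descending through
pre-STN, STN motor and STN non-motor subregions.  This module applies the
inclusion criteria (all three subregions present, each longer than 1 mm),
trims 0.5 mm "safe boundaries" around the detected subregion borders,
averages spectra within subregions, and orchestrates the full study
pipeline: preprocessing → spectra → spectral parameterization → whitening →
beta features → downshift and ANOVA tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import betafeat, clinstats, preprocess, spectral, whiten
from .io import SiteRecord
from .specparam import FitSettings, fit_spectrum

__all__ = ["TrajectoryProfile", "build_profile", "include_trajectory",
           "apply_safe_boundaries", "subregion_average_psd", "run_pipeline",
           "write_results"]

STREAMS = ("LFP", "SPK")
SAFE_MARGIN_MM = 0.5


@dataclass
class TrajectoryProfile:
    """Ordered sites of one trajectory with border depths and flags."""

    patient: str
    trajectory: str
    sites: list[SiteRecord]                 # depth-ordered
    entry_mm: float                         # pre/motor border
    motor_exit_mm: float                    # motor/non-motor border
    exit_mm: float                          # non-motor exit
    subregion_lengths: dict[str, float]
    boundary_flag: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth_mm for s in self.sites])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.subregion for s in self.sites])

    def normalized_distance(self) -> np.ndarray:
        return (self.depths - self.entry_mm) / (self.exit_mm - self.entry_mm)


def build_profile(sites: list[SiteRecord]) -> TrajectoryProfile:
    """Order sites by penetration depth and locate the subregion borders
    (midpoints between adjacent sites of different labels; the exit border
    extends half a step beyond the last site)."""
    sites = sorted(sites, key=lambda s: s.depth_mm)
    depths = np.array([s.depth_mm for s in sites])
    labels = [s.subregion for s in sites]

    def border(a: str, b: str) -> float | None:
        for i in range(len(sites) - 1):
            if labels[i] == a and labels[i + 1] == b:
                return 0.5 * (depths[i] + depths[i + 1])
        return None

    entry = border("pre", "motor")
    motor_exit = border("motor", "nonmotor")
    stn_depths = depths[[l != "pre" for l in labels]]
    half_step = (np.median(np.diff(stn_depths)) / 2
                 if stn_depths.size > 1 else 0.0)
    exit_mm = depths[-1] + half_step if labels[-1] == "nonmotor" else None

    lengths: dict[str, float] = {}
    if entry is not None:
        lengths["pre"] = entry - depths[0]
    if entry is not None and motor_exit is not None:
        lengths["motor"] = motor_exit - entry
    if motor_exit is not None and exit_mm is not None:
        lengths["nonmotor"] = exit_mm - motor_exit

    return TrajectoryProfile(
        patient=sites[0].patient, trajectory=sites[0].trajectory,
        sites=sites, entry_mm=entry if entry is not None else np.nan,
        motor_exit_mm=motor_exit if motor_exit is not None else np.nan,
        exit_mm=exit_mm if exit_mm is not None else np.nan,
        subregion_lengths=lengths,
        boundary_flag=np.zeros(len(sites), bool))


def include_trajectory(profile: TrajectoryProfile) -> tuple[bool, str]:
    """Accept iff pre-STN, motor and non-motor are all present and each is
    longer than 1 mm (strict)."""
    present = set(profile.labels)
    for sub in ("pre", "motor", "nonmotor"):
        if sub not in present:
            return False, f"missing subregion {sub}"
    for sub in ("pre", "motor", "nonmotor"):
        length = profile.subregion_lengths.get(sub)
        if length is None or not np.isfinite(length):
            return False, f"undetermined length of subregion {sub}"
        if length <= 1.0:
            return False, f"subregion {sub} is {length:.2f} mm (needs > 1 mm)"
    return True, "ok"


def apply_safe_boundaries(profile: TrajectoryProfile,
                          margin: float = SAFE_MARGIN_MM
                          ) -> TrajectoryProfile:
    """Flag sites within ``margin`` of the subregion borders: both edges of
    motor and non-motor, and the final ``margin`` of pre-STN before its
    exit."""
    depths = profile.depths
    labels = profile.labels
    flag = np.zeros(depths.size, bool)
    pre = labels == "pre"
    flag[pre] = depths[pre] > profile.entry_mm - margin
    motor = labels == "motor"
    flag[motor] = ((depths[motor] < profile.entry_mm + margin)
                   | (depths[motor] > profile.motor_exit_mm - margin))
    non = labels == "nonmotor"
    flag[non] = ((depths[non] < profile.motor_exit_mm + margin)
                 | (depths[non] > profile.exit_mm - margin))
    profile.boundary_flag = flag
    return profile


def subregion_average_psd(psds: list[spectral.SitePSD],
                          labels: np.ndarray,
                          retained: np.ndarray,
                          band: tuple[float, float] = (3.0, 70.0)
                          ) -> dict[str, spectral.SitePSD]:
    """Unweighted mean of retained site PSDs per subregion, restricted to
    the analysis band; subregions with no retained sites are missing."""
    out: dict[str, spectral.SitePSD] = {}
    for sub in ("pre", "motor", "nonmotor"):
        idx = [i for i in range(len(psds))
               if labels[i] == sub and retained[i] and not psds[i].excluded]
        if not idx:
            continue
        mask = spectral.band_slice(psds[idx[0]].freqs, *band)
        mean = np.mean([psds[i].power[mask] for i in idx], axis=0)
        out[sub] = spectral.SitePSD(freqs=psds[idx[0]].freqs[mask],
                                    power=mean,
                                    norm_state=psds[idx[0]].norm_state,
                                    stream=psds[idx[0]].stream,
                                    meta={"subregion": sub, "n_sites": len(idx)})
    return out


def _stream_signal(site: SiteRecord, stream: str) -> np.ndarray:
    return site.lfp if stream == "LFP" else site.spk


def run_pipeline(sites: list[SiteRecord],
                 settings: FitSettings = FitSettings(),
                 norm: str = "freq") -> dict:
    """Run the full per-study pipeline on a recordings container.

    Per trajectory and stream: RMS/NRMS and outlier flags, Welch NPSDs with
    line-noise repair, subregion-averaged spectral-parameterization fits,
    per-site whitening of the motor domain, trajectory- and site-level beta
    center frequencies, the LFP→SPK downshift summary, beta bandwidths, and
    two-way ANOVAs of the aperiodic parameters.  ``norm`` selects the PSD
    normalization for beta analysis: ``freq`` (NPSD) or ``freqdist``
    (additionally z-scored against the pre-STN baseline).

    Deterministic: identical inputs give identical output tables.
    """
    by_traj: dict[tuple[str, str], list[SiteRecord]] = {}
    for s in sites:
        by_traj.setdefault((s.patient, s.trajectory), []).append(s)

    site_rows, fit_rows, traj_beta_rows, site_beta_rows, bw_rows = \
        [], [], [], [], []
    rejected = []

    for (pid, tid), traj_sites in sorted(by_traj.items()):
        profile = build_profile(traj_sites)
        ok, reason = include_trajectory(profile)
        if not ok:
            rejected.append({"patient": pid, "trajectory": tid,
                             "reason": reason})
            continue
        apply_safe_boundaries(profile)
        labels = profile.labels
        depths = profile.depths
        n_sites = len(profile.sites)

        for stream in STREAMS:
            signals = [_stream_signal(s, stream) for s in profile.sites]
            fs = profile.sites[0].fs

            x_rms = np.array([preprocess.rms(x) for x in signals])
            outlier = preprocess.flag_outliers(x_rms)
            nrms = preprocess.normalize_rms(
                x_rms, baseline_mask=~outlier[:10])

            psds = []
            for x in signals:
                psd = spectral.welch_psd(x, fs, stream=stream)
                psd = spectral.repair_line_noise(psd)
                if not psd.excluded:
                    psd = spectral.normalize_by_frequency(psd)
                psds.append(psd)
            if norm == "freqdist":
                pre_idx = [i for i in range(n_sites)
                           if labels[i] == "pre" and not psds[i].excluded]
                beta_psds = spectral.normalize_by_distance(
                    psds, [psds[i] for i in pre_idx[:10]])
            else:
                beta_psds = psds

            too_short = np.array([p.excluded for p in psds])
            retained = ~outlier & ~too_short & ~profile.boundary_flag

            for i in range(n_sites):
                site_rows.append({
                    "patient": pid, "trajectory": tid, "site": i,
                    "depth_mm": depths[i], "subregion": labels[i],
                    "stream": stream, "rms": x_rms[i], "nrms": nrms[i],
                    "outlier": bool(outlier[i]),
                    "too_short": bool(too_short[i]),
                    "boundary": bool(profile.boundary_flag[i]),
                    "retained": bool(retained[i]),
                })

            # subregion-averaged NPSD fits (aperiodic statistics)
            averages = subregion_average_psd(psds, labels, retained)
            for sub, avg in averages.items():
                fit = fit_spectrum(avg.freqs, avg.power, settings)
                fit_rows.append({
                    "patient": pid, "trajectory": tid, "subregion": sub,
                    "stream": stream, "offset": fit.offset,
                    "exponent": fit.exponent, "n_peaks": fit.n_peaks,
                    "r2": fit.r_squared, "mae": fit.mae,
                    "converged": fit.converged,
                    "n_sites": avg.meta["n_sites"],
                })

            # per-site whitening of motor sites, then beta features
            motor_idx = [i for i in range(n_sites)
                         if labels[i] == "motor" and retained[i]
                         and not beta_psds[i].excluded]
            whitened = {}
            for i in motor_idx:
                alpha = fit_spectrum(psds[i].freqs, psds[i].power,
                                     settings).exponent
                if norm == "freqdist":
                    # z-scored spectra can be negative; whiten the NPSD and
                    # z-score the whitened spectra against pre-STN instead
                    whitened[i] = whiten.whiten_frequency(psds[i], alpha)
                else:
                    whitened[i] = whiten.whiten_frequency(beta_psds[i], alpha)

            if norm == "freqdist" and motor_idx:
                pre_white = []
                for i in pre_idx[:10]:
                    alpha = fit_spectrum(psds[i].freqs, psds[i].power,
                                         settings).exponent
                    pre_white.append(whiten.whiten_frequency(psds[i], alpha))
                all_white = spectral.normalize_by_distance(
                    [whitened[i] for i in motor_idx], pre_white)
                whitened = dict(zip(motor_idx, all_white))

            for i, w in whitened.items():
                pk = betafeat.detect_beta_cf(w.freqs, w.power,
                                             level="site", stream=stream)
                site_beta_rows.append({
                    "patient": pid, "trajectory": tid, "site": i,
                    "stream": stream, "norm": norm,
                    "beta_cf": pk.beta_cf, "peak_power": pk.peak_power,
                })

            if whitened:
                stack = np.mean([w.power for w in whitened.values()], axis=0)
                freqs = next(iter(whitened.values())).freqs
                pk = betafeat.detect_beta_cf(freqs, stack,
                                             level="trajectory",
                                             stream=stream)
                traj_beta_rows.append({
                    "patient": pid, "trajectory": tid, "stream": stream,
                    "norm": norm, "beta_cf": pk.beta_cf,
                    "peak_power": pk.peak_power,
                    "n_sites": len(whitened),
                })
                if pk.found:
                    bw = betafeat.measure_bandwidth(freqs, stack,
                                                    beta_cf=pk.beta_cf)
                    if bw is not None:
                        bw_rows.append({
                            "patient": pid, "trajectory": tid,
                            "stream": stream, "level": "trajectory",
                            "beta_cf": pk.beta_cf,
                            "half_band_width": bw.half_band_width,
                            "left_half_side": bw.left_half_side,
                            "right_half_side": bw.right_half_side,
                            "quarter_band_width": bw.quarter_band_width,
                            "three_quarter_band_width":
                                bw.three_quarter_band_width,
                            "censored": bw.censored,
                        })

    results = {
        "site_table": pd.DataFrame(site_rows),
        "fits": pd.DataFrame(fit_rows),
        "trajectory_beta_cf": pd.DataFrame(traj_beta_rows),
        "site_beta_cf": pd.DataFrame(site_beta_rows),
        "bandwidths": pd.DataFrame(bw_rows),
        "rejected_trajectories": pd.DataFrame(rejected),
    }

    # trajectory-level downshift
    tb = results["trajectory_beta_cf"]
    if len(tb):
        wide = tb.pivot_table(index=["patient", "trajectory"],
                              columns="stream", values="beta_cf",
                              aggfunc="first").dropna()
        if len(wide):
            results["downshift_trajectory"] = betafeat.summarize_downshift(
                wide["LFP"].to_numpy(), wide["SPK"].to_numpy())
    sb = results["site_beta_cf"]
    if len(sb):
        wide = sb.pivot_table(index=["patient", "trajectory", "site"],
                              columns="stream", values="beta_cf",
                              aggfunc="first").dropna()
        if len(wide):
            results["downshift_site"] = betafeat.summarize_downshift(
                wide["LFP"].to_numpy(), wide["SPK"].to_numpy())

    # patient-level features for the clinical GLM layer
    fits = results["fits"]
    if len(fits):
        motor = fits[fits.subregion == "motor"]
        feats = motor.pivot_table(index="patient", columns="stream",
                                  values=["offset", "exponent"],
                                  aggfunc="mean")
        feat_df = pd.DataFrame({
            "LO": feats[("offset", "LFP")], "SO": feats[("offset", "SPK")],
            "LE": feats[("exponent", "LFP")], "SE": feats[("exponent", "SPK")],
        })
        if len(tb):
            cfw = tb.pivot_table(index="patient", columns="stream",
                                 values=["beta_cf", "peak_power"],
                                 aggfunc="mean")
            for col, key in [("LCF", ("beta_cf", "LFP")),
                             ("SCF", ("beta_cf", "SPK")),
                             ("LP", ("peak_power", "LFP")),
                             ("SP", ("peak_power", "SPK"))]:
                if key in cfw.columns:
                    feat_df[col] = cfw[key]
        results["features"] = feat_df.reset_index()

        # two-way ANOVAs of the aperiodic parameters
        for param in ("exponent", "offset"):
            try:
                results[f"anova_{param}"] = clinstats.anova_aperiodic(
                    fits[param].to_numpy(), fits["stream"].to_numpy(),
                    fits["subregion"].to_numpy())
            except ValueError:
                pass
    return results


def write_results(outdir: str | Path, results: dict) -> list[Path]:
    """Write every tabular result as CSV plus a manifest of artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=False)
            written.append(path)
        elif isinstance(obj, betafeat.DownshiftSummary):
            path = outdir / f"{name}.csv"
            pd.DataFrame([obj.__dict__]).to_csv(path, index=False)
            written.append(path)
    manifest = outdir / "manifest.csv"
    pd.DataFrame({"artifact": [p.name for p in written]}).to_csv(
        manifest, index=False)
    written.append(manifest)
    return written
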