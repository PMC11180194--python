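"""Synthetic study generator: trajectory-structured LFP/SPK recordings plus
a clinical table with known ground-truth coefficients.

The generator emulates the statistical structure of the intraoperative
micro-electrode mapping study it stands in for:

* each trajectory descends through pre-STN (internal capsule), then the STN
  motor and non-motor subregions, with 400 µm steps before the STN and
  100 µm steps inside it, 4 s of signal per site;
* LFP is colored noise with a per-trajectory exponent drawn around 2.20
  (Brown-like) carrying a beta sine at the trajectory's LFP beta center
  frequency (βCF) — present in all subregions, weaker outside the motor
  domain, mimicking volume conduction;
* SPK is a near-white rate signal (exponent around 0.11) whose beta
  modulation exists only in the motor subregion, at a βCF downshifted
  relative to the LFP βCF;
* clinical responses are linear in a z-scored predictor family with known
  coefficients plus Gaussian noise.

Every drawn parameter is recorded in a ground-truth sidecar so recovery can
be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SiteRecord, write_container, write_manifest, write_sidecar
from .synthsig import colored_noise

__all__ = ["SyntheticStudyConfig", "simulate_study",
           "simulate_clinical_table", "save_study",
           "CLINICAL_COLUMNS", "RESPONSE_COLUMNS"]

RESPONSE_COLUMNS = ("DRT_Off", "DRT_Diff", "DRT_Per",
                    "DBS_Diff", "DBS_Per", "DBS_Eva")
CLINICAL_COLUMNS = ("LD", "Ag", "DD", "Gd") + RESPONSE_COLUMNS


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level generator settings.

    Subregion lengths are in mm, in penetration order
    pre-STN → motor → non-motor; each must exceed 1 mm so the generated
    trajectories meet the inclusion criteria.  Exponent and βCF settings are
    (mean, SD) of per-trajectory Gaussian draws; βCFs are snapped to the
    0.5 Hz analysis grid.  The SPK βCF is the LFP βCF minus a positive
    downshift, so LFP exponents and βCFs exceed their SPK counterparts in
    expectation by construction.
    """

    n_patients: int = 30
    n_trajectories_per_patient: int = 1
    site_duration_s: float = 4.0
    fs: float = 4096.0
    pre_step_mm: float = 0.4
    stn_step_mm: float = 0.1
    n_pre_sites: int = 10
    subregion_lengths: tuple[float, float, float] = (4.0, 2.5, 1.5)
    lfp_exponent_mean_sd: tuple[float, float] = (2.20, 0.40)
    spk_exponent_mean_sd: tuple[float, float] = (0.11, 0.22)
    lfp_beta_cf_mean_sd: tuple[float, float] = (26.0, 2.5)  # HiBeta-centered
    beta_downshift_mean_sd: tuple[float, float] = (8.0, 1.5)
    lfp_beta_amp_motor: float = 0.5      # × signal SD
    lfp_beta_amp_outside: float = 0.25   # volume-conducted beta
    spk_beta_amp_motor: float = 0.5
    stn_spk_gain: float = 2.0            # NRMS rise of SPK inside the STN
    rms_jitter_sd: float = 0.25          # lognormal SD of per-site gain
    clinical_family: str = "DeF"
    clinical_coefficients: tuple[float, ...] = (0.5, -0.3, 0.4, 0.2)
    noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(l < 1.0 for l in self.subregion_lengths):
            raise ValueError("each subregion must be at least 1 mm")
        if self.n_pre_sites < 10:
            raise ValueError("need >= 10 pre-STN sites for the NRMS baseline")
        if len(self.clinical_coefficients) != 4:
            raise ValueError("clinical_coefficients must have 4 members")


def _snap(x: float, step: float = 0.5) -> float:
    return round(x / step) * step


def _draw_trajectory_truth(cfg: SyntheticStudyConfig,
                           rng: np.random.Generator) -> dict:
    lfp_alpha = rng.normal(*cfg.lfp_exponent_mean_sd)
    spk_alpha = rng.normal(*cfg.spk_exponent_mean_sd)
    lfp_cf = _snap(float(np.clip(rng.normal(*cfg.lfp_beta_cf_mean_sd),
                                 21.5, 31.5)))
    shift = float(np.clip(rng.normal(*cfg.beta_downshift_mean_sd), 2.0, None))
    spk_cf = _snap(float(np.clip(lfp_cf - shift, 13.5, 20.0)))
    return {"lfp_exponent": float(lfp_alpha), "spk_exponent": float(spk_alpha),
            "lfp_beta_cf": lfp_cf, "spk_beta_cf": spk_cf,
            "downshift": lfp_cf - spk_cf}


def _site_signal(n: int, fs: float, exponent: float, beta_cf: float,
                 beta_amp: float, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    x = colored_noise(n, exponent, rng, sd=sd)
    if beta_amp > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        x = x + beta_amp * sd * np.sin(2 * np.pi * beta_cf * t + phase)
    return x


def simulate_study(cfg: SyntheticStudyConfig
                   ) -> tuple[list[SiteRecord], pd.DataFrame, dict]:
    """Generate the full synthetic cohort.

    Returns ``(sites, clinical_table, truth)`` where ``truth`` records every
    drawn per-trajectory parameter and the clinical generator coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.site_duration_s * cfg.fs))
    pre_len, motor_len, nonmotor_len = cfg.subregion_lengths

    sites: list[SiteRecord] = []
    truth: dict = {"config_seed": cfg.seed, "trajectories": {}}

    for p in range(cfg.n_patients):
        pid = f"P{p:03d}"
        for t in range(cfg.n_trajectories_per_patient):
            tid = f"T{t}"
            key = f"{pid}/{tid}"
            tt = _draw_trajectory_truth(cfg, rng)
            truth["trajectories"][key] = tt

            # depth grid: entry of STN at depth 0
            pre_depths = -cfg.pre_step_mm * np.arange(cfg.n_pre_sites, 0, -1)
            n_motor = int(round(motor_len / cfg.stn_step_mm))
            n_nonmotor = int(round(nonmotor_len / cfg.stn_step_mm))
            stn_depths = cfg.stn_step_mm * np.arange(n_motor + n_nonmotor)
            depths = np.r_[pre_depths, stn_depths]
            labels = (["pre"] * cfg.n_pre_sites + ["motor"] * n_motor
                      + ["nonmotor"] * n_nonmotor)

            for k, (depth, sub) in enumerate(zip(depths, labels)):
                lfp_amp = (cfg.lfp_beta_amp_motor if sub == "motor"
                           else cfg.lfp_beta_amp_outside)
                lfp_sd = rng.lognormal(0.0, cfg.rms_jitter_sd)
                lfp = _site_signal(n, cfg.fs, tt["lfp_exponent"],
                                   tt["lfp_beta_cf"], lfp_amp, lfp_sd, rng)
                spk_amp = cfg.spk_beta_amp_motor if sub == "motor" else 0.0
                spk_sd = ((1.0 if sub == "pre" else cfg.stn_spk_gain)
                          * rng.lognormal(0.0, cfg.rms_jitter_sd))
                spk = _site_signal(n, cfg.fs, tt["spk_exponent"],
                                   tt["spk_beta_cf"], spk_amp, spk_sd, rng)
                sites.append(SiteRecord(
                    patient=pid, trajectory=tid, site_index=k,
                    depth_mm=float(depth), subregion=sub, fs=cfg.fs,
                    lfp=lfp.astype(np.float32), spk=spk.astype(np.float32)))

    clinical, clin_truth = simulate_clinical_table(
        cfg.n_patients, cfg.clinical_coefficients, cfg.noise_sd, rng,
        family=cfg.clinical_family)
    truth["clinical"] = clin_truth
    return sites, clinical, truth


def simulate_clinical_table(n_patients: int,
                            coefficients: tuple[float, ...],
                            noise_sd: float,
                            rng: np.random.Generator,
                            family: str = "DeF") -> tuple[pd.DataFrame, dict]:
    """Clinical/demographic table with responses linked to known coefficients.

    Demographics are drawn from plausible marginals (levodopa-equivalent
    dose in mg, age and disease duration in years, gender as 0/1).  Each
    response equals the z-scored demographic family times ``coefficients``
    plus ``noise_sd`` Gaussian noise; DBS_Eva is additionally discretized to
    the ordinal −2…+2 grading.
    """
    if family != "DeF":
        raise NotImplementedError(
            "only the demographic family is wired as clinical ground truth")
    ld = rng.normal(600.0, 150.0, n_patients)
    ag = rng.normal(62.0, 8.0, n_patients)
    dd = np.clip(rng.normal(10.0, 4.0, n_patients), 1.0, None)
    gd = (rng.uniform(size=n_patients) < 0.6).astype(float)

    X = np.column_stack([ld, ag, dd, gd])
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    coef = np.asarray(coefficients, float)

    df = pd.DataFrame({"LD": ld, "Ag": ag, "DD": dd, "Gd": gd})
    for resp in RESPONSE_COLUMNS:
        y = Z @ coef + noise_sd * rng.standard_normal(n_patients)
        if resp == "DBS_Eva":
            y = np.clip(np.round(y), -2, 2)
        df[resp] = y
    df = df[list(CLINICAL_COLUMNS)]
    clin_truth = {"family": family, "members": ["LD", "Ag", "DD", "Gd"],
                  "coefficients": coef.tolist(), "noise_sd": noise_sd}
    return df, clin_truth


def save_study(outdir: str | Path, sites: list[SiteRecord],
               clinical: pd.DataFrame, truth: dict) -> dict[str, Path]:
    """Write container + manifest + clinical CSV + ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "container": outdir / "recordings.h5",
        "manifest": outdir / "manifest.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.json",
    }
    write_container(paths["container"], sites)
    write_manifest(paths["manifest"], sites)
    clinical.to_csv(paths["clinical"], index=False)
    write_sidecar(paths["truth"], truth)
    return paths
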