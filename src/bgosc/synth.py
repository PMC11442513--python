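"""Synthetic three-nucleus LFP cohort generator with known ground truth.

Each hemisphere is an eight-contact monopolar recording whose adjacent-pair
bipolar derivation yields one channel each in striatum (STR), external
pallidum (GPe) and internal pallidum (GPi). Every retained channel is a sum
of

* 1/f^alpha background noise (default alpha = 1),
* a low-frequency oscillation — narrowband-filtered Gaussian noise
  (bandwidth ~2 Hz) at a hemisphere-specific peak between 3 and 12 Hz; a
  band-limited *process*, not a sinusoid, so coherence stays below one and
  surrogate statistics are non-degenerate,
* optionally an analogous beta oscillation (13-35 Hz),
* directional coupling as delayed linear mixing: the GPi (and, at a smaller
  gain, the GPe) receives a copy of the striatal low-frequency component
  delayed by ``coupling_lag_ms`` (default 25 ms, about a quarter cycle at
  10 Hz, keeping the imaginary part of coherency large at the peak),
* a shared zero-lag component in all channels emulating volume conduction,
* 50 Hz line noise.

Subject severity scores (BFMDRS-like, clamped non-negative) are an affine
function of the subject's mean GPi low-frequency power gain and mean
STR-GPi coupling gain plus Gaussian noise. STR power and STR-GPe coupling
carry no severity weight by construction, providing a designed null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .io import Recording


@dataclass
class SeverityModel:
    """severity = intercept + w_gpi_power * <GPi LF gain> + w_str_gpi * <STR-GPi gain> + noise."""

    intercept: float = 2.0
    w_gpi_power: float = 8.0
    w_str_gpi_coupling: float = 20.0
    noise_sd: float = 0.75

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("severity noise sd must be non-negative")


@dataclass
class GroundTruth:
    """Generative parameters of one hemisphere."""

    subject_id: str
    hemisphere: str
    lf_peak_hz: float = 8.5
    beta_peak_hz: float | None = 20.0
    lf_power_gain: dict[str, float] = field(
        default_factory=lambda: {"STR": 1.0, "GPe": 1.0, "GPi": 0.6}
    )
    beta_power_gain: dict[str, float] = field(
        default_factory=lambda: {"STR": 0.3, "GPe": 0.3, "GPi": 0.3}
    )
    coupling_gain: dict[str, float] = field(
        default_factory=lambda: {"str_gpi": 0.8, "str_gpe": 0.3, "gpe_gpi": 0.2}
    )
    coupling_lag_ms: float = 25.0
    common_source_gain: float = 0.3
    line_noise_amp: float = 0.2
    background_gain: float = 1.0
    alpha: float = 1.0
    severity_model: SeverityModel = field(default_factory=SeverityModel)

    def __post_init__(self) -> None:
        if not (3.0 <= self.lf_peak_hz <= 12.0):
            raise ValueError(f"lf_peak_hz must lie in [3, 12], got {self.lf_peak_hz}")
        if self.beta_peak_hz is not None and not (13.0 <= self.beta_peak_hz <= 35.0):
            raise ValueError(f"beta_peak_hz must lie in [13, 35], got {self.beta_peak_hz}")
        for d in (self.lf_power_gain, self.beta_power_gain, self.coupling_gain):
            if any(v < 0 for v in d.values()):
                raise ValueError("all gains must be non-negative")
        if self.common_source_gain < 0 or self.line_noise_amp < 0 or self.background_gain < 0:
            raise ValueError("all gains must be non-negative")
        if self.coupling_lag_ms <= 0:
            raise ValueError("coupling_lag_ms must be positive (non-instantaneous interaction)")


def _pink_noise(n: int, rng: np.random.Generator, alpha: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power spectral density proportional to 1/f^alpha."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _narrowband(n: int, rng: np.random.Generator, f0: float, fs: float, bw: float = 2.0) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed around f0 (width ~bw Hz)."""
    lo = max(f0 - bw / 2.0, 0.1)
    hi = min(f0 + bw / 2.0, fs / 2.0 * 0.99)
    sos = signal.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_hemisphere(
    truth: GroundTruth,
    duration_s: float = 180.0,
    fs: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> Recording:
    """Generate one hemisphere's eight-contact monopolar recording.

    Contacts are ordered ventral to dorsal: contacts 1-2 in GPi, 3-4 in
    intermediate tissue ("other"), 5-6 in GPe, 7-8 in striatum — the montage
    whose bipolar derivation retains exactly one channel per nucleus.
    Within a pair, the nucleus signal is injected differentially so the
    bipolar derivation recovers it while the shared reference (common-mode
    pink noise) cancels.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    highest = max(truth.lf_peak_hz, truth.beta_peak_hz or 0.0, 50.0 if truth.line_noise_amp > 0 else 0.0)
    if fs < 4.0 * highest:
        raise ValueError(f"fs = {fs} Hz is below 4x the highest oscillation frequency ({highest} Hz)")
    lag = int(round(truth.coupling_lag_ms * fs / 1000.0))
    if lag < 1:
        raise ValueError(
            f"coupling lag {truth.coupling_lag_ms} ms is shorter than one sample at {fs} Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    pad = lag  # generate longer latents so delayed copies stay in-range

    z_str = _narrowband(n + pad, rng, truth.lf_peak_hz, fs)
    z_gpe = _narrowband(n + pad, rng, truth.lf_peak_hz, fs)
    z_gpi = _narrowband(n + pad, rng, truth.lf_peak_hz, fs)
    now = slice(pad, pad + n)
    ago = slice(0, n)  # the same latent, coupling_lag samples earlier

    g = truth.coupling_gain
    lf = truth.lf_power_gain
    osc = {
        "STR": lf["STR"] * z_str[now],
        "GPe": lf["GPe"] * z_gpe[now] + g["str_gpe"] * z_str[ago] + g["gpe_gpi"] * z_gpi[ago],
        "GPi": lf["GPi"] * z_gpi[now] + g["str_gpi"] * z_str[ago] + g["gpe_gpi"] * z_gpe[ago],
    }
    if truth.beta_peak_hz is not None:
        for s in osc:
            osc[s] = osc[s] + truth.beta_power_gain[s] * _narrowband(n, rng, truth.beta_peak_hz, fs)
    common = truth.common_source_gain * _narrowband(n, rng, truth.lf_peak_hz, fs)
    t = np.arange(n) / fs
    line = truth.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    chan = {
        s: truth.background_gain * _pink_noise(n, rng, truth.alpha) + osc[s] + common + line
        for s in ("STR", "GPe", "GPi")
    }

    refs = [truth.background_gain * _pink_noise(n, rng, truth.alpha) for _ in range(5)]
    contacts = [f"c{i}" for i in range(1, 9)]
    samples = np.stack(
        [
            refs[0] + chan["GPi"],  # c1 (most ventral)
            refs[0],                # c2
            refs[1],                # c3
            refs[2],                # c4
            refs[3] + chan["GPe"],  # c5
            refs[3],                # c6
            refs[4] + chan["STR"],  # c7
            refs[4],                # c8 (most dorsal)
        ]
    )
    structure = {
        "c1": "GPi", "c2": "GPi", "c3": "other", "c4": "other",
        "c5": "GPe", "c6": "GPe", "c7": "STR", "c8": "STR",
    }
    return Recording(
        subject_id=truth.subject_id,
        hemisphere=truth.hemisphere,
        fs=fs,
        contacts=contacts,
        samples=samples,
        contact_structure=structure,
    )


@dataclass
class CohortConfig:
    """Sampling distributions for per-hemisphere ground truth.

    A subject-level latent u in [0, 1] drives the STR-GPi coupling gain,
    the disease covariate. The GPi low-frequency signal is largely
    *inherited* from the delayed striatal drive, so a stronger coupling
    raises both the measured GPi low-frequency power and the STR-GPi
    coherence — mirroring the joint severity association of the two
    estimates. GPi intrinsic gain, STR/GPe power and STR-GPe coupling are
    drawn independently of u (the last two are designed nulls).
    ``jitter_sd`` perturbs the latent, ``hemi_jitter_sd`` multiplies
    per-hemisphere values by 1 + noise.
    """

    duration_s: float = 180.0
    fs: float = 1000.0
    lf_peak_mean: float = 8.5
    lf_peak_sd: float = 2.5
    #: truncation bounds keep the ~2 Hz-wide bump fully inside the 3-12 Hz
    #: band, so band summaries are not clipped by the band edges
    lf_peak_bounds: tuple[float, float] = (4.5, 11.5)
    beta_prob: float = 13.0 / 19.0
    beta_peak_range: tuple[float, float] = (15.0, 30.0)
    lf_gain_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"STR": (0.8, 1.3), "GPe": (0.8, 1.3), "GPi": (0.45, 0.75)}
    )
    coupling_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"str_gpi": (0.2, 1.0), "str_gpe": (0.1, 0.5), "gpe_gpi": (0.1, 0.3)}
    )
    jitter_sd: float = 0.1
    hemi_jitter_sd: float = 0.08
    coupling_lag_ms: float = 25.0
    common_source_gain: float = 0.3
    line_noise_amp: float = 0.2
    severity: SeverityModel = field(default_factory=SeverityModel)
    #: hemispheres excluded from the cohort, e.g. no striatal contact pair
    exclude: tuple[tuple[str, str], ...] = (("sub-07", "left"),)

    def __post_init__(self) -> None:
        if self.lf_peak_sd < 0 or self.jitter_sd < 0 or self.hemi_jitter_sd < 0:
            raise ValueError("distribution spreads must be non-negative")
        if not (0.0 <= self.beta_prob <= 1.0):
            raise ValueError("beta_prob must lie in [0, 1]")
        for name, (lo, hi) in {**self.lf_gain_range, **self.coupling_range}.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid gain range for {name}: ({lo}, {hi})")


@dataclass
class SyntheticCohort:
    recordings: list[Recording]
    truths: list[GroundTruth]
    severity: pd.DataFrame  # one row per subject: subject_id, severity + true covariates
    seed: int
    config: CohortConfig

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.truths):
            raise ValueError("recordings and truths must align one-to-one")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_cohort(
    n_subjects: int = 10,
    hemispheres_per_subject: int = 2,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a cohort of hemisphere recordings with aligned ground truth.

    The default configuration emulates the study layout: 10 subjects, two
    hemispheres each, one hemisphere excluded, giving 19 recordings.
    Severity is computed per subject from the mean (across that subject's
    included hemispheres) GPi low-frequency gain and STR-GPi coupling gain,
    plus Gaussian noise, clamped at zero.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    hemis = ("left", "right")[:hemispheres_per_subject]
    recordings, truths = [], []
    subj_rows = []
    # stratified severity latent: one subject per decile of the disease
    # spectrum (in random order), emulating recruitment across the full
    # severity range rather than an unconstrained random draw
    us = rng.permutation((np.arange(n_subjects) + rng.uniform(size=n_subjects)) / n_subjects)
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        u = float(us[i])

        def scaled(rg: tuple[float, float], latent: float) -> float:
            lo, hi = rg
            return lo + (hi - lo) * float(np.clip(latent, 0.0, 1.0))

        u_coup = u + rng.normal(0, cfg.jitter_sd)
        strgpi_subj = scaled(cfg.coupling_range["str_gpi"], u_coup)
        gpi_gain_subj = rng.uniform(*cfg.lf_gain_range["GPi"])
        str_gain_subj = rng.uniform(*cfg.lf_gain_range["STR"])
        gpe_gain_subj = rng.uniform(*cfg.lf_gain_range["GPe"])
        strgpe_subj = rng.uniform(*cfg.coupling_range["str_gpe"])
        gpegpi_subj = rng.uniform(*cfg.coupling_range["gpe_gpi"])

        used_gpi_gain, used_strgpi = [], []
        for h in hemis:
            lf_peak = _trunc_normal(rng, cfg.lf_peak_mean, cfg.lf_peak_sd, *cfg.lf_peak_bounds)
            beta_peak = float(rng.uniform(*cfg.beta_peak_range)) if rng.uniform() < cfg.beta_prob else None
            jit = lambda v: float(max(v * (1.0 + rng.normal(0, cfg.hemi_jitter_sd)), 0.0))
            truth = GroundTruth(
                subject_id=sid,
                hemisphere=h,
                lf_peak_hz=lf_peak,
                beta_peak_hz=beta_peak,
                lf_power_gain={"STR": jit(str_gain_subj), "GPe": jit(gpe_gain_subj), "GPi": jit(gpi_gain_subj)},
                coupling_gain={"str_gpi": jit(strgpi_subj), "str_gpe": jit(strgpe_subj), "gpe_gpi": jit(gpegpi_subj)},
                coupling_lag_ms=cfg.coupling_lag_ms,
                common_source_gain=cfg.common_source_gain,
                line_noise_amp=cfg.line_noise_amp,
                severity_model=cfg.severity,
            )
            # hemisphere draws stay in the stream even when excluded, so the
            # remaining cohort is unchanged by an exclusion
            child = np.random.default_rng(rng.integers(2**31))
            if (sid, h) in set(map(tuple, cfg.exclude)):
                continue
            rec = generate_hemisphere(truth, cfg.duration_s, cfg.fs, seed=child)
            recordings.append(rec)
            truths.append(truth)
            used_gpi_gain.append(truth.lf_power_gain["GPi"])
            used_strgpi.append(truth.coupling_gain["str_gpi"])
        if not used_gpi_gain:
            continue
        sm = cfg.severity
        sev = (
            sm.intercept
            + sm.w_gpi_power * float(np.mean(used_gpi_gain))
            + sm.w_str_gpi_coupling * float(np.mean(used_strgpi))
            + rng.normal(0, sm.noise_sd)
        )
        subj_rows.append(
            {
                "subject_id": sid,
                "severity": float(max(sev, 0.0)),
                "true_gpi_lf_gain": float(np.mean(used_gpi_gain)),
                "true_str_gpi_coupling": float(np.mean(used_strgpi)),
                "n_hemispheres": len(used_gpi_gain),
            }
        )
    return SyntheticCohort(
        recordings=recordings,
        truths=truths,
        severity=pd.DataFrame(subj_rows),
        seed=seed,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write recordings (native binary + sidecars), ground-truth CSV, and a
    YAML provenance file (config + seed). Returns the output directory."""
    from .io import write_recording

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, truth in zip(cohort.recordings, cohort.truths):
        stem = f"{rec.subject_id}_{rec.hemisphere}"
        write_recording(rec, outdir / f"{stem}.dat")
        row = {
            "subject_id": truth.subject_id,
            "hemisphere": truth.hemisphere,
            "lf_peak_hz": truth.lf_peak_hz,
            "beta_peak_hz": truth.beta_peak_hz,
            "coupling_lag_ms": truth.coupling_lag_ms,
            "common_source_gain": truth.common_source_gain,
            "line_noise_amp": truth.line_noise_amp,
        }
        row.update({f"lf_gain_{k}": v for k, v in truth.lf_power_gain.items()})
        row.update({f"coupling_{k}": v for k, v in truth.coupling_gain.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "ground_truth.csv", index=False)
    cohort.severity.to_csv(outdir / "severity.csv", index=False)
    cfg = asdict(cohort.config)
    cfg["exclude"] = [list(t) for t in cohort.config.exclude]
    (outdir / "generator_config.yaml").write_text(
        yaml.safe_dump({"seed": cohort.seed, "config": cfg}, sort_keys=False)
    )
    return outdir
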