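"""Synthetic cohorts, EEG sessions and unpleasantness ratings.

The generator emulates the study conditions the analysis assumes: a cohort of
147 women with correlated menstrual-pain, somatic-symptom and bladder-pain
covariates; per participant, a 34-channel (32 scalp + 2 mastoid) 500 Hz EEG
session of five 20 s stimulation blocks carrying a 25 Hz steady-state response
topographically peaked at Oz whose post-pipeline CSD power in dB rises
linearly with brightness code; and per-block Gracely Box Scale (0-20)
unpleasantness ratings produced by the two-level moderation model with
plantable coefficients.  All stochastic operations take explicit seeds.

Planted effect defaults are the published point estimates of the analysis
this package reimplements (intercept 8.0 GBS, brightness slope 0.36 GBS/step,
PSD slope 0.11 GBS/dB, bladder-pain moderation 0.06 and 0.01, SSVEP slope
2.05 dB/step at Oz), so every downstream stage is testable against known
truth without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csd import CsdKernel, apply_laplacian, build_kernel
from .montage import MASTOID_LABELS, SCALP_LABELS, Montage, make_montage
from .preprocess import Marker, Recording, preprocess_recording
from .spectral import ssvep_power

__all__ = [
    "CohortParams",
    "PlantedModel",
    "SessionSpec",
    "generate_cohort",
    "generate_session_eeg",
    "generate_ratings",
    "simulate_ratings_study",
    "ssvep_topography",
    "calibrate_session_db",
]

COVARIATES = ("menstrual_pain", "somatic_symptoms", "bladder_pain")


@dataclass
class CohortParams:
    """Cohort covariate distribution (defaults: the study's sample moments).

    Covariates are drawn from a Gaussian copula (correlated latent normals),
    affinely mapped to the target mean/SD and truncated at the scale bounds
    (VAS 0-100 for menstrual and bladder pain; 0 to ``somatic_max`` for the
    somatic symptom sum).  Truncation slightly biases the realized moments
    and attenuates correlations (about 0.02 at the defaults); this is
    documented and tested with tolerance rather than corrected.
    """

    n_participants: int = 147
    covariate_means: tuple[float, float, float] = (62.5, 2.37, 12.2)
    covariate_sds: tuple[float, float, float] = (26.1, 2.4, 16.0)
    covariate_corrs: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 0.16, 0.28], [0.16, 1.0, 0.28], [0.28, 0.28, 1.0]]
        )
    )
    somatic_max: float = 59.0
    seed: int | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.covariate_corrs, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig.min() <= 0:
            raise ValueError(
                f"correlation matrix not positive definite (min eigenvalue {eig.min():.3g})"
            )
        if any(s < 0 for s in self.covariate_sds):
            raise ValueError("covariate SDs must be non-negative")
        self.covariate_corrs = R

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return ((0.0, 100.0), (0.0, self.somatic_max), (0.0, 100.0))


@dataclass
class PlantedModel:
    """Plantable two-level coefficients and SSVEP parameters.

    Level-2 gammas are in GBS units per moderator unit; ``random_effect_sds``
    are the SDs of participant deviations of the level-1 intercept, brightness
    slope and PSD slope.  SSVEP parameters are on the post-pipeline dB scale
    at Oz; ``ssvep_block_sd_db`` is per-block measurement noise of the dB
    estimate, and ``topography_decay`` (radians) is the Gaussian angular
    falloff of SSVEP amplitude away from Oz.
    """

    gamma00: float = 8.0
    gamma01: float = 0.01
    gamma02: float = -0.14
    gamma03: float = 0.06
    gamma10: float = 0.36
    gamma11: float = 0.01
    gamma12: float = -0.03
    gamma13: float = -0.003
    gamma20: float = 0.11
    gamma21: float = -0.001
    gamma22: float = -0.005
    gamma23: float = 0.01
    level1_residual_sd: float = 0.5
    random_effect_sds: tuple[float, float, float] = (3.85, 0.78, 0.40)
    ssvep_base_db: float = -23.76
    ssvep_slope_db: float = 2.05
    ssvep_base_sd_db: float = 5.5
    ssvep_slope_sd_db: float = 0.57
    ssvep_block_sd_db: float = 3.0
    topography_decay: float = 0.9
    moderator_means: tuple[float, float, float] = (62.5, 2.37, 12.2)

    def __post_init__(self) -> None:
        sds = (
            self.level1_residual_sd,
            *self.random_effect_sds,
            self.ssvep_base_sd_db,
            self.ssvep_slope_sd_db,
            self.ssvep_block_sd_db,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all planted SDs must be non-negative")

    @classmethod
    def null_moderation(cls, **kwargs) -> "PlantedModel":
        """All moderator gammas zero: a null dataset for calibration checks."""
        zeros = {
            g: 0.0
            for g in (
                "gamma01", "gamma02", "gamma03",
                "gamma11", "gamma12", "gamma13",
                "gamma21", "gamma22", "gamma23",
            )
        }
        zeros.update(kwargs)
        return cls(**zeros)

    def gammas(self) -> np.ndarray:
        """(3, 4) array: rows b0/b1/b2 models, columns intercept + moderators."""
        return np.array(
            [
                [self.gamma00, self.gamma01, self.gamma02, self.gamma03],
                [self.gamma10, self.gamma11, self.gamma12, self.gamma13],
                [self.gamma20, self.gamma21, self.gamma22, self.gamma23],
            ]
        )


@dataclass
class SessionSpec:
    """EEG session layout and noise levels.

    Five 20 s blocks of 25 Hz stimulation at brightness codes -2..2 (lux 1,
    30, 60, 90, 120), recorded at 500 Hz with inter-block gaps.  Noise
    amplitudes are in uV: pink (1/f) background RMS, 60 Hz line amplitude and
    blink transients at ``blink_rate`` per second (off by default: the
    artifact-light mode standing in for component-based cleaning).
    """

    sampling_rate: float = 500.0
    block_duration: float = 20.0
    n_blocks: int = 5
    stim_freq: float = 25.0
    brightness_codes: tuple[int, ...] = (-2, -1, 0, 1, 2)
    lux_levels: tuple[float, ...] = (1.0, 30.0, 60.0, 90.0, 120.0)
    gap_duration: float = 5.0
    lead_in: float = 2.0
    pink_amp: float = 10.0
    line_amp: float = 1.0
    line_freq: float = 60.0
    blink_rate: float = 0.0
    blink_amp: float = 150.0
    downsampled_rate: float = 256.0

    def __post_init__(self) -> None:
        if self.stim_freq >= self.downsampled_rate / 2:
            raise ValueError("stimulation frequency at or above post-downsampling Nyquist")
        if self.n_blocks != len(self.brightness_codes):
            raise ValueError("n_blocks must equal the number of brightness levels")

    @property
    def n_samples(self) -> int:
        total = (
            2 * self.lead_in
            + self.n_blocks * self.block_duration
            + (self.n_blocks - 1) * self.gap_duration
        )
        return int(round(total * self.sampling_rate))

    def block_onsets(self) -> np.ndarray:
        """Block onset sample indices."""
        step = self.block_duration + self.gap_duration
        t0 = self.lead_in + step * np.arange(self.n_blocks)
        return np.round(t0 * self.sampling_rate).astype(int)


def generate_cohort(params: CohortParams, seed: int | None = None) -> pd.DataFrame:
    """Draw a participant covariate table from the Gaussian copula.

    Returns one row per participant with columns ``participant``,
    ``menstrual_pain``, ``somatic_symptoms``, ``bladder_pain``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    L = np.linalg.cholesky(params.covariate_corrs)
    z = rng.standard_normal((params.n_participants, 3)) @ L.T
    x = np.asarray(params.covariate_means) + np.asarray(params.covariate_sds) * z
    for j, (lo, hi) in enumerate(params.bounds):
        x[:, j] = np.clip(x[:, j], lo, hi)
    out = pd.DataFrame(x, columns=list(COVARIATES))
    out.insert(0, "participant", np.arange(1, params.n_participants + 1))
    return out


def ssvep_topography(montage: Montage, decay: float, peak: str = "Oz") -> np.ndarray:
    """Gaussian amplitude falloff with angular distance from the peak channel."""
    theta = montage.angular_distance_from(peak)
    return np.exp(-(theta**2) / (2 * decay**2))


_CAL_CACHE: dict[tuple, float] = {}


def calibrate_session_db(
    spec: SessionSpec,
    montage: Montage | None = None,
    kernel: CsdKernel | None = None,
    topography_decay: float = 0.9,
) -> float:
    """Post-pipeline dB at Oz for a unit-amplitude planted topography.

    The full chain (re-reference, filter, downsample, notch, epoch,
    Laplacian, tapered PSD) is linear, so one noise-free run fixes the gain:
    scaling block amplitudes by ``10**((target - this)/20)`` plants any target
    dB exactly.  Results are cached per (session geometry, kernel settings).
    """
    montage = montage or make_montage()
    kernel = kernel or build_kernel(montage)
    key = (
        spec.sampling_rate, spec.block_duration, spec.n_blocks, spec.stim_freq,
        spec.gap_duration, spec.lead_in, spec.downsampled_rate,
        topography_decay, kernel.m, kernel.n_terms, kernel.lam,
        kernel.head_radius_cm,
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    rec = _build_recording(
        spec, montage, amp_scales=np.ones(spec.n_blocks),
        topography_decay=topography_decay, rng=None,
    )
    eset = preprocess_recording(
        rec,
        target_rate=spec.downsampled_rate,
        block_duration=spec.block_duration,
        line_freq=spec.line_freq,
    )
    csd = apply_laplacian(eset, kernel)
    tab = ssvep_power(csd, f0=spec.stim_freq)
    db = tab.loc[tab["electrode"] == montage.a_priori_channel, "psd_db"].mean()
    _CAL_CACHE[key] = float(db)
    return float(db)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_s: int, fs: float, rms: float) -> np.ndarray:
    """1/f-amplitude noise with the requested per-channel RMS."""
    white = rng.standard_normal((n_ch, n_s))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_s, 1 / fs)
    shape = np.zeros_like(f)
    shape[1:] = 1 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n=n_s, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return rms * x


def _build_recording(
    spec: SessionSpec,
    montage: Montage,
    amp_scales: np.ndarray,
    topography_decay: float,
    rng: np.random.Generator | None,
    participant: str | int | None = None,
) -> Recording:
    """Assemble the continuous 34-channel record (scalp + mastoids)."""
    labels = list(SCALP_LABELS) + list(MASTOID_LABELS)
    n_ch, n_s = len(labels), spec.n_samples
    fs = spec.sampling_rate
    t = np.arange(n_s) / fs
    data = np.zeros((n_ch, n_s))

    topo = ssvep_topography(montage, topography_decay)
    oz = montage.positions[montage.index("Oz")]
    mast_topo = [
        float(np.exp(-np.arccos(np.clip(pos @ oz, -1, 1)) ** 2 / (2 * topography_decay**2)))
        for pos in montage.mastoid_positions.values()
    ]
    full_topo = np.concatenate([topo, mast_topo])

    onsets = spec.block_onsets()
    blk = int(round(spec.block_duration * fs))
    for b, (onset, scale) in enumerate(zip(onsets, amp_scales)):
        seg = slice(onset, onset + blk)
        phase = 2 * np.pi * spec.stim_freq * (t[seg] - t[onset])
        data[:, seg] += scale * full_topo[:, None] * np.sin(phase)[None, :]

    if rng is not None:
        if spec.pink_amp > 0:
            data += _pink_noise(rng, n_ch, n_s, fs, spec.pink_amp)
        if spec.line_amp > 0:
            ph = rng.uniform(0, 2 * np.pi)
            data += spec.line_amp * np.sin(2 * np.pi * spec.line_freq * t + ph)[None, :]
        if spec.blink_rate > 0:
            frontal = np.array(
                [np.exp(-montage.angular_distance_from("Fp1") ** 2 / (2 * 0.6**2)),
                 np.exp(-montage.angular_distance_from("Fp2") ** 2 / (2 * 0.6**2))]
            ).max(axis=0)
            frontal = np.concatenate([frontal, [0.05, 0.05]])
            n_blinks = rng.poisson(spec.blink_rate * n_s / fs)
            centers = rng.uniform(0.5, n_s / fs - 0.5, size=n_blinks)
            width = 0.15  # s, Gaussian half-width of the blink transient
            for c in centers:
                bump = spec.blink_amp * np.exp(-((t - c) ** 2) / (2 * width**2))
                data += frontal[:, None] * bump[None, :]

    markers = [
        Marker(int(s), b + 1, int(code))
        for b, (s, code) in enumerate(zip(onsets, spec.brightness_codes))
    ]
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_labels=labels,
        markers=markers,
        reference="M1",
        participant=participant,
    )


def generate_session_eeg(
    participant_row: pd.Series | dict,
    planted: PlantedModel,
    spec: SessionSpec,
    seed: int | None = None,
    montage: Montage | None = None,
    kernel: CsdKernel | None = None,
    return_targets: bool = False,
):
    """Simulate one participant's continuous EEG session.

    The embedded 25 Hz sinusoid is scaled per block so the post-pipeline CSD
    power at Oz follows ``ssvep_base_db + participant deviation +
    (ssvep_slope_db + slope deviation) * code + block noise``; pink noise,
    line noise and blinks are added per ``spec``.  With
    ``return_targets=True`` also returns the planted per-block dB values
    (keyed by brightness code), e.g. to drive rating generation.
    """
    montage = montage or make_montage()
    kernel = kernel or build_kernel(montage)
    rng = np.random.default_rng(seed)
    db0 = calibrate_session_db(spec, montage, kernel, planted.topography_decay)
    codes = np.asarray(spec.brightness_codes, dtype=float)
    target_db = _session_targets_db(planted, codes, rng)
    amp_scales = 10 ** ((target_db - db0) / 20)
    pid = (
        participant_row.get("participant")
        if hasattr(participant_row, "get")
        else None
    )
    rec = _build_recording(
        spec, montage, amp_scales, planted.topography_decay, rng, participant=pid
    )
    if return_targets:
        return rec, dict(zip(spec.brightness_codes, target_db))
    return rec


def _session_targets_db(
    planted: PlantedModel, codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one participant's planted per-block dB values at Oz."""
    base_dev = rng.normal(0, planted.ssvep_base_sd_db) if planted.ssvep_base_sd_db else 0.0
    slope_dev = rng.normal(0, planted.ssvep_slope_sd_db) if planted.ssvep_slope_sd_db else 0.0
    return (
        planted.ssvep_base_db
        + base_dev
        + (planted.ssvep_slope_db + slope_dev) * codes
        + (
            rng.normal(0, planted.ssvep_block_sd_db, size=codes.size)
            if planted.ssvep_block_sd_db
            else np.zeros(codes.size)
        )
    )


def generate_ratings(
    participant_row: pd.Series | dict,
    psd_by_block: pd.Series | dict,
    planted: PlantedModel,
    seed: int | None = None,
    clip: bool = True,
    round_to_int: bool = False,
    brightness_codes: tuple[int, ...] = (-2, -1, 0, 1, 2),
) -> pd.DataFrame:
    """Per-block Gracely Box Scale ratings from the planted two-level model.

    ``psd_by_block`` maps each brightness code to the participant's 25 Hz dB
    power (typically at Oz).  Level-1 coefficients are the planted gammas
    evaluated at the participant's (population-mean-centered) moderators plus
    Gaussian random effects; ratings add residual noise and are clipped to
    the 0-20 scale unless ``clip=False``.
    """
    rng = np.random.default_rng(seed)
    row = pd.Series(participant_row)
    psd = pd.Series(psd_by_block)
    missing = [c for c in brightness_codes if c not in psd.index or not np.isfinite(psd[c])]
    if missing:
        raise ValueError(f"missing PSD for block(s) with brightness code {missing}")
    mods = np.array([row[c] for c in COVARIATES], dtype=float)
    mods_c = mods - np.asarray(planted.moderator_means)
    design = np.concatenate([[1.0], mods_c])
    u = np.array(
        [rng.normal(0, s) if s > 0 else 0.0 for s in planted.random_effect_sds]
    )
    b0, b1, b2 = planted.gammas() @ design + u
    codes = np.asarray(brightness_codes, dtype=float)
    psd_vals = psd.loc[list(brightness_codes)].to_numpy(dtype=float)
    psd_c = psd_vals - psd_vals.mean()
    eps = (
        rng.normal(0, planted.level1_residual_sd, size=codes.size)
        if planted.level1_residual_sd
        else np.zeros(codes.size)
    )
    ratings = b0 + b1 * codes + b2 * psd_c + eps
    if clip:
        ratings = np.clip(ratings, 0.0, 20.0)
    if round_to_int:
        ratings = np.round(ratings)
    return pd.DataFrame(
        {
            "participant": row.get("participant"),
            "brightness": brightness_codes,
            "unpleasantness": ratings,
        }
    )


def simulate_ratings_study(
    planted: PlantedModel | None = None,
    cohort: CohortParams | None = None,
    seed: int | None = None,
    electrode: str = "Oz",
    clip: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast statistics-level simulation: covariates, Oz PSD and ratings.

    Skips the EEG chain by drawing each participant's five dB values directly
    from the planted SSVEP model (the quantity the pipeline estimates), then
    generating ratings from them.  Returns ``(participants, long_table)``
    where the long table has one row per participant x block with columns
    ``participant, electrode, brightness, psd_db, unpleasantness`` plus the
    moderators.
    """
    planted = planted or PlantedModel()
    cohort = cohort or CohortParams()
    root = np.random.default_rng(seed)
    participants = generate_cohort(cohort, seed=int(root.integers(2**31)))
    codes = np.array([-2, -1, 0, 1, 2], dtype=float)
    rows = []
    for _, prow in participants.iterrows():
        rng = np.random.default_rng(int(root.integers(2**31)))
        psd = _session_targets_db(planted, codes, rng)
        ratings = generate_ratings(
            prow,
            dict(zip(codes, psd)),
            planted,
            seed=int(root.integers(2**31)),
            clip=clip,
        )
        for c, pv, uv in zip(codes, psd, ratings["unpleasantness"]):
            rows.append(
                {
                    "participant": prow["participant"],
                    "electrode": electrode,
                    "brightness": c,
                    "psd_db": pv,
                    "unpleasantness": uv,
                    **{k: prow[k] for k in COVARIATES},
                }
            )
    return participants, pd.DataFrame(rows)
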