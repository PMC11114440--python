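"""Surrogate EEG cohorts with planted band-specific hub structure.

No clinical recordings accompany the study design this pipeline serves,
so verification rests on surrogate data whose ground truth is known.  A
synthetic subject is the sum of four parts, per channel:

* **Background oscillations** — one narrowband oscillator per band and
  channel, realized as a constant-amplitude cosine whose phase performs a
  biased random walk (mean step = band-center frequency, Gaussian jitter
  scaled to spread the linewidth over roughly a quarter of the band).
  Pure sinusoids would make every phase statistic degenerate; wandering
  phase gives PLI values strictly inside (0, 1) and epoch-to-epoch
  variability.
* **Hub coupling** — for each :class:`HubSpec`, every target channel's
  oscillation in that band is replaced by the convex mixture
  ``(1 - c) * own + c * hub_at_lag``: at coupling ``c = 1`` the target
  carries the hub's oscillation at a fixed nonzero lag (PLI -> 1), at
  ``c = 0`` channels are independent (PLI -> 0).  The lag is a phase
  offset of the narrowband carrier; 0 or pi lags are disallowed when
  ``c > 0`` because the phase lag index cannot see them by construction.
* **Common source** — a single pink-noise trace added identically to all
  channels, mimicking instantaneous volume conduction of one deep source.
  It inflates amplitude correlation but, being zero-lag, must leave PLI
  untouched.
* **Channel noise** — independent pink (1/f) noise per channel.

Group differences are encoded as coupling-strength differences at chosen
(electrode, band) sites.  The default scenario plants a frontal beta hub
and a parietal gamma hub that are strong in controls and weak in
patients, plus an occipital gamma hub strong only in patients — the
qualitative pattern the pipeline is expected to recover (lower
betweenness at Fz-beta and Pz-gamma, higher at O1-gamma in patients).

Every subject draws from an independent random substream keyed by
(seed, group index, subject index), so cohorts are bit-reproducible and
stable under changes of subject count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .montage_io import DEFAULT_MONTAGE, EEGRecording, Montage, SubjectMeta
from .preprocess import BANDS, BAND_BY_NAME, BandSpec

#: Typical resting (eyes-closed) band amplitudes, microvolts.
BAND_AMPLITUDE_UV = {
    "delta": 20.0,
    "theta": 10.0,
    "alpha": 15.0,
    "beta": 5.0,
    "gamma": 2.0,
}

#: Pink-noise RMS per channel at noise_gain = 1, microvolts.
NOISE_RMS_UV = 5.0

#: Common-source RMS at common_source_gain = 1, microvolts.
COMMON_RMS_UV = 5.0


@dataclass(frozen=True)
class HubSpec:
    """One planted hub: a source electrode coupled into target channels."""

    electrode: str
    band: str
    targets: tuple[str, ...]
    coupling: float = 0.8
    lag: float = math.pi / 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.electrode in self.targets:
            raise ValueError(f"hub electrode {self.electrode} cannot target itself")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must be in [0, 1], got {self.coupling}")
        if self.band not in BAND_BY_NAME:
            raise ValueError(f"unknown band {self.band!r}")
        if self.coupling > 0:
            wrapped = self.lag % (2.0 * math.pi)
            if min(wrapped, abs(wrapped - math.pi), abs(wrapped - 2 * math.pi)) < 1e-9:
                raise ValueError(
                    "a 0 or pi lag is invisible to the phase lag index; "
                    "choose a lag strictly between"
                )


_FRONTAL_TARGETS = ("Fp1", "Fp2", "F3", "F4", "C3", "C4")
_PARIETAL_TARGETS = ("P3", "P4", "C3", "C4", "O1", "O2")
_OCCIPITAL_TARGETS = ("P3", "P4", "Pz", "T5", "T6", "O2")

#: Coupling strengths for the default group-contrast scenario.  The strong
#: value is calibrated so a planted hub dominates shortest-path structure
#: (mean betweenness at the hub exceeds all other electrodes) and the
#: group contrast is recoverable by the gated ANOVA -> FDR pipeline with
#: high power at the cohort sizes used in the power studies.
STRONG_COUPLING = 0.85
WEAK_COUPLING = 0.15


def default_hubs_by_group(
    strong: float = STRONG_COUPLING, weak: float = WEAK_COUPLING
) -> dict[str, tuple[HubSpec, ...]]:
    """The default planted-contrast scenario (see module docstring)."""
    return {
        "control": (
            HubSpec("Fz", "beta", _FRONTAL_TARGETS, strong),
            HubSpec("Pz", "gamma", _PARIETAL_TARGETS, strong),
            HubSpec("O1", "gamma", _OCCIPITAL_TARGETS, weak),
        ),
        "patient": (
            HubSpec("Fz", "beta", _FRONTAL_TARGETS, weak),
            HubSpec("Pz", "gamma", _PARIETAL_TARGETS, weak),
            HubSpec("O1", "gamma", _OCCIPITAL_TARGETS, strong),
        ),
    }


@dataclass(frozen=True)
class BprsModel:
    """Clinical-score model: score = mean + sd * latent, where the latent is
    correlated (target rho) with the subject's coupling multiplier."""

    mean: float = 50.0
    sd: float = 12.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("target correlation must be in [-1, 1]")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Study-shaped cohort: two groups of 16-channel, 200 Hz recordings.

    Defaults mirror the study conditions: 31 controls vs 21 patients,
    600-s records at 200 Hz, and the default planted-hub contrast.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 31, "patient": 21}
    )
    duration_s: float = 600.0
    fs: float = 200.0
    hubs_by_group: Mapping[str, tuple[HubSpec, ...]] = field(
        default_factory=default_hubs_by_group
    )
    common_source_gain: float = 1.0
    noise_gain: float = 1.0
    band_amplitude_uv: Mapping[str, float] = field(
        default_factory=lambda: dict(BAND_AMPLITUDE_UV)
    )
    coupling_jitter_sd: float = 0.15
    bprs_model: BprsModel = field(default_factory=BprsModel)
    seed: int = 0
    montage: Montage = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        if self.duration_s < 10:
            raise ValueError("duration must be at least 10 s (two 5-s epochs)")
        if self.common_source_gain < 0 or self.noise_gain < 0:
            raise ValueError("gains must be nonnegative")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


#: Correlation time of the oscillators' frequency wander, seconds.
FREQ_WANDER_TAU_S = 0.15


def _phase_walks(rng: np.random.Generator, band: BandSpec, fs: float,
                 n: int, n_ch: int) -> np.ndarray:
    """Phases of n_ch independent narrowband oscillators.

    Instantaneous frequency performs a mean-reverting (AR(1)) wander around
    the band center with stationary sd = bandwidth/6 and correlation time
    ~0.15 s, then phase is its integral.  The frequency therefore stays
    inside the band (the signal is genuinely narrowband and its quadrature
    is a faithful Hilbert pair, so planted phase lags survive filtering),
    while the integrated wander still decorrelates phases across channels,
    keeping PLI < 1 attainable and epoch-to-epoch variability alive."""
    from scipy.signal import lfilter

    sd_f = (band.high_hz - band.low_hz) / 6.0
    rho = math.exp(-1.0 / (FREQ_WANDER_TAU_S * fs))
    innov_sd = sd_f * math.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal((n_ch, n), dtype=np.float32)
    eps[:, 0] *= np.float32(sd_f / innov_sd)  # stationary start
    delta = lfilter([np.float32(innov_sd)], [1.0, -np.float32(rho)], eps, axis=-1)
    freq = band.center_hz + delta
    phase = np.cumsum(2.0 * math.pi * freq / fs, axis=-1, dtype=np.float64)
    return np.mod(phase, 2.0 * math.pi).astype(np.float32)


def _pink_noise(rng: np.random.Generator, n: int, shape_rows: int) -> np.ndarray:
    """1/f-amplitude noise, unit RMS, per row."""
    white = rng.standard_normal((shape_rows, n), dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale.astype(np.complex64), n=n, axis=-1)
    rms = np.sqrt(np.mean(pink**2, axis=-1, keepdims=True))
    return (pink / rms).astype(np.float32)


def _subject_rng(seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_index, subject_index))
    )


def generate_subject(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "",
    coupling_multiplier: float = 1.0,
) -> EEGRecording:
    """One synthetic recording for *group* drawn from *rng*.

    *coupling_multiplier* scales every hub coupling of this subject
    (clipped to [0, 1]); it is the per-subject trait the clinical score
    can be made to track.
    """
    montage = config.montage
    n_ch = len(montage)
    n = int(round(config.duration_s * config.fs))
    hubs = tuple(config.hubs_by_group.get(group, ()))
    for hub in hubs:
        montage.index(hub.electrode)  # raises if absent
        for t in hub.targets:
            montage.index(t)

    # Per-band, per-channel oscillator phases.
    phases = {
        band.name: _phase_walks(rng, band, config.fs, n, n_ch) for band in BANDS
    }

    data = np.zeros((n_ch, n), dtype=np.float32)
    for band in BANDS:
        amp = np.float32(config.band_amplitude_uv.get(band.name, 0.0))
        osc = amp * np.cos(phases[band.name])
        weight = np.ones(n_ch, dtype=np.float32)  # share of the channel's own oscillator
        inject = np.zeros((n_ch, n), dtype=np.float32)
        for hub in hubs:
            if hub.band != band.name:
                continue
            c = float(np.clip(hub.coupling * coupling_multiplier, 0.0, 1.0))
            if c == 0.0:
                continue
            hi = montage.index(hub.electrode)
            lagged = amp * np.cos(phases[band.name][hi] - np.float32(hub.lag))
            for tgt in hub.targets:
                ti = montage.index(tgt)
                weight[ti] *= np.float32(1.0 - c)  # multiplicative under overlap
                inject[ti] += np.float32(c) * lagged
        data += weight[:, None] * osc + inject

    if config.common_source_gain > 0:
        common = _pink_noise(rng, n, 1)[0] * np.float32(COMMON_RMS_UV * config.common_source_gain)
        data += common[None, :]
    if config.noise_gain > 0:
        data += _pink_noise(rng, n, n_ch) * np.float32(NOISE_RMS_UV * config.noise_gain)

    return EEGRecording(montage=montage, data=data, fs=config.fs, subject_id=subject_id)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[EEGRecording], list[SubjectMeta]]:
    """Full two-group cohort with metadata; bit-reproducible from the seed.

    Patients receive a BPRS score built from the same latent trait that
    multiplies their hub couplings, with correlation ``bprs_model.rho``;
    controls have no score.  Ages are drawn uniform 20-50 for both groups.
    """
    recs: list[EEGRecording] = []
    metas: list[SubjectMeta] = []
    for gi, group in enumerate(sorted(config.n_per_group)):
        n_sub = config.n_per_group[group]
        for si in range(n_sub):
            rng = _subject_rng(config.seed, gi, si)
            sid = f"{group}-{si:03d}"
            u = rng.standard_normal()  # latent trait -> coupling multiplier
            v = rng.standard_normal()  # score-specific noise
            age = float(rng.uniform(20, 50))
            mult = float(np.clip(1.0 + config.coupling_jitter_sd * u, 0.0, 2.0))
            rec = generate_subject(config, group, rng, subject_id=sid,
                                   coupling_multiplier=mult)
            bprs = None
            if group == "patient":
                m = config.bprs_model
                latent = m.rho * u + math.sqrt(max(0.0, 1 - m.rho**2)) * v
                bprs = float(max(0.0, m.mean + m.sd * latent))
            recs.append(rec)
            metas.append(SubjectMeta(subject_id=sid, group=group, session="none",
                                     bprs=bprs, age=age))
    return recs, metas


def generate_paired_sessions(
    config: CohortConfig,
    post_hubs_by_group: Mapping[str, tuple[HubSpec, ...]],
    group: str = "patient",
) -> tuple[list[EEGRecording], list[EEGRecording], list[SubjectMeta]]:
    """Pre/post recordings for one group, paired by subject substream.

    The post-session record of a subject reuses the subject's random
    substream with the post hub specification, so the pre and post signals
    share per-subject traits and differ only through coupling (plus
    independent noise realizations within the stream)."""
    gi = sorted(config.n_per_group).index(group)
    n_sub = config.n_per_group[group]
    post_config = replace(config, hubs_by_group=dict(post_hubs_by_group))
    pre, post, metas = [], [], []
    for si in range(n_sub):
        sid = f"{group}-{si:03d}"
        rng = _subject_rng(config.seed, gi, si)
        u = rng.standard_normal()
        v = rng.standard_normal()
        age = float(rng.uniform(20, 50))
        mult = float(np.clip(1.0 + config.coupling_jitter_sd * u, 0.0, 2.0))
        state = rng.bit_generator.state
        pre.append(generate_subject(config, group, rng, subject_id=sid,
                                    coupling_multiplier=mult))
        rng.bit_generator.state = state  # same signal stream, new coupling
        post.append(generate_subject(post_config, group, rng, subject_id=sid,
                                     coupling_multiplier=mult))
        m = config.bprs_model
        latent = m.rho * u + math.sqrt(max(0.0, 1 - m.rho**2)) * v
        metas.append(SubjectMeta(subject_id=sid, group=group, session="pre",
                                 bprs=float(max(0.0, m.mean + m.sd * latent)),
                                 age=age))
    return pre, post, metas
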