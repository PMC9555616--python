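"""Synthetic cohort generation: trial schedules and raw dual-wavelength recordings.

The generator emulates the statistical structure the downstream analysis
assumes: a rest-like hemodynamic baseline made of narrow-band systemic
oscillations (Mayer-wave, respiratory and cardiac bands) that are partly
global and partly spatially local, 1/f channel noise, and optional
task-evoked systemic activity shared between regular channels and
short-distance channels.  Hemodynamics are converted to raw light
intensities through the forward modified Beer-Lambert law, so the
preprocessing inversion is exact up to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import FS, WAVELENGTHS, pathlength_matrix
from .probe import ProbeLayout


# ---------------------------------------------------------------------------
# trial schedules


@dataclass(frozen=True)
class TrialSchedule:
    """A blocked design: 15 s task periods separated by jittered rest."""

    task_label: str
    onsets: np.ndarray  # seconds
    task_duration: float = 15.0
    rest_durations: np.ndarray | None = None  # inter-trial gaps incl. lead-in
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def end_time(self) -> float:
        """Time at which the last task block plus its trailing rest ends."""
        tail = float(self.rest_durations[-1]) if self.rest_durations is not None else 20.0
        return float(self.onsets[-1]) + self.task_duration + tail


@dataclass(frozen=True)
class Session:
    """A multi-condition run: several interleaved schedules on one timeline."""

    schedules: tuple[TrialSchedule, ...]
    instructions: np.ndarray  # onset seconds of 2 s instruction cues
    breaks: np.ndarray  # (n, 2) start/duration of relaxation breaks
    duration_s: float

    def schedule(self, label: str) -> TrialSchedule:
        for s in self.schedules:
            if s.task_label == label:
                return s
        raise KeyError(label)


def make_trial_schedule(
    task_label: str,
    n_trials: int,
    seed: int,
    task_duration: float = 15.0,
    rest_range: tuple[float, float] = (18.0, 22.0),
) -> TrialSchedule:
    """Blocked design with ``n_trials`` task periods and jittered rest.

    Rest durations (including the lead-in before the first trial) are drawn
    uniformly from ``rest_range``; identical seeds give identical schedules.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rests = rng.uniform(*rest_range, size=n_trials + 1)
    onsets = np.empty(n_trials)
    t = rests[0]
    for i in range(n_trials):
        onsets[i] = t
        t += task_duration + rests[i + 1]
    return TrialSchedule(task_label, onsets, task_duration, rests, seed)


def make_session(
    condition_labels: tuple[str, ...],
    n_trials_per: int,
    seed: int,
    task_duration: float = 15.0,
    rest_range: tuple[float, float] = (18.0, 22.0),
    break_every: int = 6,
    break_duration: float = 15.0,
    instruction_lead_s: float = 3.0,
) -> Session:
    """Pseudorandomized multi-condition run with instruction cues and breaks.

    Trial order is shuffled with the constraint that no condition occurs more
    than twice in a row; a relaxation break is inserted every ``break_every``
    trials.  Each trial is preceded by a short instruction cue.
    """
    if n_trials_per < 1:
        raise ValueError("n_trials_per must be >= 1")
    rng = np.random.default_rng(seed)
    order = [lab for lab in condition_labels for _ in range(n_trials_per)]
    for _ in range(200):
        rng.shuffle(order)
        if all(
            not (order[i] == order[i + 1] == order[i + 2]) for i in range(len(order) - 2)
        ):
            break

    onsets: dict[str, list[float]] = {lab: [] for lab in condition_labels}
    instructions: list[float] = []
    breaks: list[tuple[float, float]] = []
    t = rng.uniform(*rest_range)
    for i, lab in enumerate(order):
        if i > 0 and i % break_every == 0:
            breaks.append((t, break_duration))
            t += break_duration + rng.uniform(*rest_range)
        instructions.append(t - instruction_lead_s)
        onsets[lab].append(t)
        t += task_duration + rng.uniform(*rest_range)

    schedules = tuple(
        TrialSchedule(lab, np.array(onsets[lab]), task_duration, seed=seed)
        for lab in condition_labels
    )
    return Session(
        schedules,
        np.array(instructions),
        np.array(breaks).reshape(-1, 2),
        duration_s=t + 10.0,
    )


# ---------------------------------------------------------------------------
# systemic-activity model


@dataclass(frozen=True)
class SAComponent:
    center_hz: float
    amplitude_um: float  # SD of the band-limited process in HbO, uM
    bandwidth_hz: float


@dataclass(frozen=True)
class SAParams:
    """Parameters of the synthetic systemic-activity model.

    The defaults emulate "strong shared systemic activity": a slow vasomotion
    band inside the 0.01-0.09 Hz analysis band, Mayer-wave, respiratory and
    cardiac bands, amplitudes comparable to the injected 10 uM response.
    Systemic activity is heterogeneous: each channel mixes a head-wide global
    oscillation with a spatially local field (correlation scale 25 mm) and
    carries its own per-band gain, so no single short channel is an exact
    copy of any regular channel's systemic activity.
    """

    components: tuple[SAComponent, ...] = (
        SAComponent(0.04, 4.0, 0.02),  # slow vasomotion (in analysis band)
        SAComponent(0.10, 3.0, 0.03),  # Mayer waves
        SAComponent(0.25, 1.5, 0.06),  # respiration
        SAComponent(1.10, 1.0, 0.15),  # cardiac
    )
    spatial_correlation_scale: float = 25.0  # mm
    global_share: float = 0.5  # variance fraction of the head-wide component
    gain_heterogeneity: float = 0.5  # per-channel band gains ~ U[1-h, 1+h]
    species_coupling: float = 0.7  # HbO/HbR shared fraction of the SA field
    noise_sd: float = 1.0  # 1/f channel noise SD, uM
    task_evoked_sa_amplitude: float | dict = 0.0  # uM peak, scalar or {"regular","sdc"}
    task_evoked_peak_s: float = 5.0
    hbo_hbr_sa_ratio: float = 0.3

    def __post_init__(self) -> None:
        for c in self.components:
            if c.amplitude_um < 0:
                raise ValueError("component amplitudes must be >= 0")
            if not 0 < c.center_hz < FS / 2:
                raise ValueError("component frequency outside (0, fs/2)")


@dataclass
class RawRecording:
    """Raw dual-wavelength intensities plus the generating hemodynamic truth."""

    intensity: dict[int, np.ndarray]  # wavelength -> (24, T), strictly positive
    fs: float
    layout: ProbeLayout
    subject_age: float
    hbo_truth: np.ndarray | None = None  # (24, T) uM
    hbr_truth: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.intensity[WAVELENGTHS[0]].shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _narrowband(rng: np.random.Generator, n: int, fs: float, center: float, bw: float,
                shape=(), k: int = 8) -> np.ndarray:
    """Unit-SD narrow-band process: sum of k random-phase sinusoids in the band."""
    t = np.arange(n) / fs
    freqs = rng.uniform(center - bw, center + bw, size=shape + (k,))
    phases = rng.uniform(0, 2 * np.pi, size=shape + (k,))
    sig = np.zeros(shape + (n,))
    # broadcast over leading axes
    for idx in np.ndindex(shape) if shape else [()]:
        s = np.sum(
            np.sin(2 * np.pi * freqs[idx][:, None] * t[None, :] + phases[idx][:, None]),
            axis=0,
        )
        sig[idx] = s / np.sqrt(k / 2)  # each sinusoid has variance 1/2
    return sig


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """Unit-SD 1/f-shaped noise per channel."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _spatial_mixing(layout: ProbeLayout, scale_mm: float) -> np.ndarray:
    """Row-unit-norm Gaussian mixing matrix over all 24 positions.

    Mixing independent per-position processes with this matrix yields a field
    whose inter-channel correlation decays with Euclidean distance at
    ``scale_mm`` while each channel keeps unit variance.
    """
    pos = layout.all_positions()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    k = np.exp(-(d**2) / (2.0 * scale_mm**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def _truth_to_intensity(
    hbo: np.ndarray, hbr: np.ndarray, layout: ProbeLayout, age: float
) -> dict[int, np.ndarray]:
    """Forward mBLL: concentrations (uM) -> raw intensities around 1.0."""
    n_ch = hbo.shape[0]
    out = {wl: np.empty_like(hbo) for wl in WAVELENGTHS}
    for row in range(n_ch):
        d_cm = layout.source_detector_distance(row) / 10.0
        E = pathlength_matrix(age, d_cm)
        for i, wl in enumerate(WAVELENGTHS):
            od = E[i, 0] * hbo[row] + E[i, 1] * hbr[row]
            out[wl][row] = np.exp(-od)
    return out


def simulate_rest_recording(
    layout: ProbeLayout,
    duration_s: float,
    sa_params: SAParams | None = None,
    age: float = 65.0,
    seed: int = 0,
) -> RawRecording:
    """Simulate a rest recording with spatially structured systemic activity.

    Each systemic band contributes a head-wide global oscillation (variance
    share ``global_share``) plus a spatially correlated local field, scaled
    per channel by a seeded gain in ``[1-h, 1+h]``
    (``h = gain_heterogeneity``), so no channel's systemic activity is an
    exact copy of another's.  HbR carries a partially coupled field: fraction
    ``species_coupling`` of each band is shared with HbO (scaled by
    ``hbo_hbr_sa_ratio``), the remainder is an independent oscillation of the
    same band.  1/f noise is added per channel.  Output intensities are
    strictly positive and reproducible under ``seed``.
    """
    if duration_s <= 30:
        raise ValueError("duration_s must exceed 30 s")
    sa = sa_params or SAParams()
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * FS))
    n_ch = layout.n_total

    mix = _spatial_mixing(layout, sa.spatial_correlation_scale)
    c = float(np.clip(sa.species_coupling, 0.0, 1.0))
    hbo = np.zeros((n_ch, n))
    hbr = np.zeros((n_ch, n))
    for comp in sa.components:
        g = _narrowband(rng, n, FS, comp.center_hz, comp.bandwidth_hz)
        local = _narrowband(rng, n, FS, comp.center_hz, comp.bandwidth_hz, shape=(n_ch,))
        field = np.sqrt(sa.global_share) * g[None, :] + np.sqrt(1 - sa.global_share) * (
            mix @ local
        )
        h = sa.gain_heterogeneity
        gains = rng.uniform(1.0 - h, 1.0 + h, size=n_ch) if h > 0 else np.ones(n_ch)
        band = comp.amplitude_um * gains[:, None] * field
        hbo += band
        if c >= 1.0:
            hbr += sa.hbo_hbr_sa_ratio * band
        else:
            g2 = _narrowband(rng, n, FS, comp.center_hz, comp.bandwidth_hz)
            local2 = _narrowband(
                rng, n, FS, comp.center_hz, comp.bandwidth_hz, shape=(n_ch,)
            )
            field2 = np.sqrt(sa.global_share) * g2[None, :] + np.sqrt(
                1 - sa.global_share
            ) * (mix @ local2)
            band2 = comp.amplitude_um * gains[:, None] * field2
            hbr += sa.hbo_hbr_sa_ratio * (c * band + np.sqrt(1 - c**2) * band2)
    if sa.noise_sd > 0:
        hbo = hbo + sa.noise_sd * _pink_noise(rng, n_ch, n)
        hbr = hbr + 0.3 * sa.noise_sd * _pink_noise(rng, n_ch, n)

    intensity = _truth_to_intensity(hbo, hbr, layout, age)
    return RawRecording(intensity, FS, layout, age, hbo_truth=hbo, hbr_truth=hbr)


def task_evoked_waveform(fs: float, duration_s: float = 25.0, peak_s: float = 5.0) -> np.ndarray:
    """Unit-peak gamma-shaped waveform modelling task-locked scalp hemodynamics."""
    t = np.arange(int(round(duration_s * fs))) / fs
    shape = 4.0
    scale = peak_s / (shape - 1.0)
    w = t ** (shape - 1.0) * np.exp(-t / scale)
    return w / w.max()


def add_task_evoked_sa(
    recording: RawRecording,
    onsets_s: np.ndarray | TrialSchedule,
    sa_params: SAParams,
    seed: int = 0,
) -> RawRecording:
    """Add a task-locked systemic waveform to every channel and SDC.

    The waveform is gamma-shaped (peak at ``task_evoked_peak_s``) and scaled
    per channel by ``task_evoked_sa_amplitude`` times a seeded heterogeneity
    factor in [0.5, 1.5]; HbR receives the negated ``hbo_hbr_sa_ratio`` copy,
    mimicking activation-like scalp responses.  Amplitude 0 returns the input
    unchanged.
    """
    if isinstance(onsets_s, TrialSchedule):
        onsets_s = onsets_s.onsets
    if recording.hbo_truth is None:
        raise ValueError("recording lacks a hemodynamic truth layer")
    amp = sa_params.task_evoked_sa_amplitude
    if isinstance(amp, dict):
        amp_reg, amp_sdc = amp.get("regular", 0.0), amp.get("sdc", 0.0)
    else:
        amp_reg = amp_sdc = float(amp)
    if amp_reg == 0.0 and amp_sdc == 0.0:
        return recording

    n = recording.n_samples
    layout = recording.layout
    wave = task_evoked_waveform(recording.fs, peak_s=sa_params.task_evoked_peak_s)
    locked = np.zeros(n)
    for onset in onsets_s:
        i0 = int(round(onset * recording.fs))
        if i0 + len(wave) > n:
            raise ValueError("schedule overruns recording")
        locked[i0 : i0 + len(wave)] += wave

    rng = np.random.default_rng(seed)
    hetero = rng.uniform(0.5, 1.5, size=layout.n_total)
    amps = np.where(np.arange(layout.n_total) < layout.n_regular, amp_reg, amp_sdc) * hetero

    hbo = recording.hbo_truth + amps[:, None] * locked[None, :]
    hbr = recording.hbr_truth - sa_params.hbo_hbr_sa_ratio * amps[:, None] * locked[None, :]
    intensity = _truth_to_intensity(hbo, hbr, layout, recording.subject_age)
    return replace(recording, intensity=intensity, hbo_truth=hbo, hbr_truth=hbr)
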