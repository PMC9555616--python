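"""Preprocessing chain: intensity -> optical density -> motion repair ->
hemoglobin concentrations -> (optional HRF injection) -> band-pass.

Order of operations mirrors the standard fNIRS pipeline used here:
quality check on raw intensity, OD conversion, temporal derivative
distribution repair (TDDR), modified Beer-Lambert law with an age-dependent
DPF and PVF = 1/60, canonical-HRF injection for semisimulation (in uM, after
the mBLL), and finally a zero-phase Butterworth band-pass (low-pass 0.09 Hz
then high-pass 0.01 Hz, order 2 each).

Pruned channels are carried as NaN rows from the point of pruning onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .constants import FS, WAVELENGTHS, pathlength_matrix
from .probe import ProbeLayout
from .synth import RawRecording, TrialSchedule


@dataclass
class ODSeries:
    od: dict[int, np.ndarray]  # wavelength -> (channels, samples)
    fs: float
    layout: ProbeLayout
    pruned_mask: np.ndarray  # (channels,) bool, True = pruned

    @property
    def n_samples(self) -> int:
        return self.od[WAVELENGTHS[0]].shape[1]


@dataclass
class HemoSeries:
    hbo: np.ndarray  # (channels, samples), uM
    hbr: np.ndarray
    fs: float
    layout: ProbeLayout
    pruned_mask: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def species(self, name: str) -> np.ndarray:
        if name == "hbo":
            return self.hbo
        if name == "hbr":
            return self.hbr
        raise KeyError(name)

    def copy(self) -> "HemoSeries":
        return HemoSeries(
            self.hbo.copy(), self.hbr.copy(), self.fs, self.layout, self.pruned_mask.copy()
        )


# ---------------------------------------------------------------------------
# optical density


def intensity_to_od(raw: RawRecording) -> ODSeries:
    """Convert raw intensities to optical density changes.

    ``OD = -ln(I / mean_t(I))`` per channel and wavelength; scale-invariant in
    the raw intensity.
    """
    od = {}
    for wl, I in raw.intensity.items():
        if np.any(I <= 0):
            raise ValueError("intensities must be strictly positive")
        od[wl] = -np.log(I / I.mean(axis=1, keepdims=True))
    mask = np.zeros(raw.layout.n_total, dtype=bool)
    return ODSeries(od, raw.fs, raw.layout, mask)


# ---------------------------------------------------------------------------
# channel quality (scalp coupling index / peak spectral power)

CARDIAC_BAND = (0.5, 2.5)


@dataclass
class QualityReport:
    table: pd.DataFrame  # per channel: sci, psp, q, pruned
    sci_threshold: float
    psp_threshold: float
    q_threshold: float

    @property
    def pruned_mask(self) -> np.ndarray:
        return self.table["pruned"].to_numpy()


def _cardiac_filter(x: np.ndarray, fs: float) -> np.ndarray:
    sos = sps.butter(3, CARDIAC_BAND, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _window_sci_psp(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """SCI and PSP of one window of cardiac-band signals from two wavelengths."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0, 0.0
    xz = (x - x.mean()) / sx
    yz = (y - y.mean()) / sy
    n = len(xz)
    sci = float(np.dot(xz, yz) / n)
    cc = sps.correlate(xz, yz, mode="full") / n
    psp = float(np.max(np.abs(np.fft.rfft(cc))) / n)
    return sci, psp


def assess_channel_quality(
    raw: RawRecording,
    sci_threshold: float = 0.6,
    psp_threshold: float = 0.1,
    q_threshold: float = 0.65,
    window_s: float = 5.0,
) -> QualityReport:
    """Windowed scalp-coupling quality check on the raw recording.

    Per non-overlapping window the cardiac-band (0.5-2.5 Hz) signals of the
    two wavelengths are compared: SCI is their zero-lag correlation and PSP
    the peak of the normalized cross-correlation power spectrum.  A window
    passes iff both exceed their thresholds; a channel is pruned iff the
    fraction q of passing windows falls below ``q_threshold``.
    """
    n = raw.n_samples
    win = int(round(window_s * raw.fs))
    if n < win:
        raise ValueError("recording too short for one quality window")
    od = intensity_to_od(raw)
    f1 = _cardiac_filter(od.od[WAVELENGTHS[0]], raw.fs)
    f2 = _cardiac_filter(od.od[WAVELENGTHS[1]], raw.fs)

    rows = []
    for ch in range(raw.layout.n_total):
        scis, psps, passes = [], [], []
        for start in range(0, n - win + 1, win):
            sci, psp = _window_sci_psp(f1[ch, start : start + win], f2[ch, start : start + win])
            scis.append(sci)
            psps.append(psp)
            passes.append(sci >= sci_threshold and psp >= psp_threshold)
        q = float(np.mean(passes))
        rows.append(
            {
                "channel": ch,
                "sci": float(np.mean(scis)),
                "psp": float(np.mean(psps)),
                "q": q,
                "pruned": q < q_threshold,
            }
        )
    return QualityReport(pd.DataFrame(rows), sci_threshold, psp_threshold, q_threshold)


def apply_pruning(od: ODSeries, report: QualityReport) -> ODSeries:
    """Replace pruned channels by NaN."""
    mask = report.pruned_mask
    out = {wl: x.copy() for wl, x in od.od.items()}
    for wl in out:
        out[wl][mask, :] = np.nan
    return ODSeries(out, od.fs, od.layout, mask.copy())


# ---------------------------------------------------------------------------
# temporal derivative distribution repair (motion artifacts)


def _tddr_1d(x: np.ndarray, fs: float, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    if np.all(x == x[0]):
        return x.copy()
    # isolate the low-frequency band the artifact model applies to
    nyq = fs / 2.0
    sos = sps.butter(3, 0.5 / nyq, btype="lowpass", output="sos")
    x_lo = sps.sosfiltfilt(sos, x)
    x_hi = x - x_lo

    deriv = np.diff(x_lo)
    w = np.ones_like(deriv)
    mu = 0.0
    c = 4.685  # Tukey bisquare tuning constant
    for _ in range(max_iter):
        mu = np.sum(w * deriv) / np.sum(w)
        dev = deriv - mu
        sigma = 1.4826 * np.median(np.abs(dev))
        if sigma == 0:
            w_new = np.ones_like(w)
        else:
            r = dev / (sigma * c)
            w_new = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    repaired = np.concatenate([[0.0], np.cumsum(w * (deriv - mu))])
    repaired += np.mean(x_lo) - np.mean(repaired)
    return repaired + x_hi


def tddr(od: ODSeries) -> ODSeries:
    """Temporal derivative distribution repair, per channel and wavelength.

    Iteratively reweights the centered temporal derivative of the <=0.5 Hz
    band with Tukey bisquare weights (c = 4.685) until convergence, rebuilds
    the signal by cumulative summation, and restores the high-frequency
    residual.  Pruned (NaN) channels pass through.
    """
    out = {}
    for wl, x in od.od.items():
        if x.shape[1] < 3:
            raise ValueError("need at least 3 samples")
        y = x.copy()
        for ch in range(x.shape[0]):
            if np.any(np.isnan(x[ch])):
                continue
            y[ch] = _tddr_1d(x[ch], od.fs)
        out[wl] = y
    return ODSeries(out, od.fs, od.layout, od.pruned_mask.copy())


# ---------------------------------------------------------------------------
# modified Beer-Lambert law


def od_to_hemoglobin(od: ODSeries, age: float) -> HemoSeries:
    """Invert the mBLL per channel: OD at two wavelengths -> (dHbO, dHbR) uM.

    Uses the tabulated extinction coefficients, the age/wavelength DPF and
    PPF = DPF * (1/60); the per-channel source-detector distance comes from
    the layout (30 mm regular, 8 mm SDC).
    """
    n_ch = od.layout.n_total
    n = od.n_samples
    hbo = np.full((n_ch, n), np.nan)
    hbr = np.full((n_ch, n), np.nan)
    stacked = np.stack([od.od[wl] for wl in WAVELENGTHS])  # (2, ch, T)
    for ch in range(n_ch):
        if od.pruned_mask[ch] or np.any(np.isnan(stacked[:, ch, :])):
            continue
        d_cm = od.layout.source_detector_distance(ch) / 10.0
        E = pathlength_matrix(age, d_cm)
        if abs(np.linalg.det(E)) < 1e-12:
            raise ValueError("degenerate wavelength pair: extinction matrix singular")
        conc = np.linalg.solve(E, stacked[:, ch, :])
        hbo[ch], hbr[ch] = conc[0], conc[1]
    return HemoSeries(hbo, hbr, od.fs, od.layout, od.pruned_mask.copy())


# ---------------------------------------------------------------------------
# canonical HRF and semisimulation injection


def canonical_hrf(fs: float, duration_s: float = 30.0, peak_s: float = 6.0) -> np.ndarray:
    """Double-gamma canonical HRF sampled at ``fs``, renormalized to unit peak.

    The positive lobe peaks at ``peak_s``; an undershoot (1/6 relative weight)
    follows, as in the standard canonical shape.
    """
    if duration_s < peak_s:
        raise ValueError("duration must cover the peak")
    t = np.arange(int(round(duration_s * fs))) / fs

    def gamma_pdf(t, shape, scale):
        from scipy.stats import gamma

        return gamma.pdf(t, a=shape, scale=scale)

    main = gamma_pdf(t, 7.0, peak_s / 6.0)
    undershoot = gamma_pdf(t, 16.0, 1.0)
    h = main / main.max() - undershoot / undershoot.max() / 6.0
    return h / h.max()


@dataclass(frozen=True)
class HRFSpec:
    """Injection specification: unit-peak template plus per-channel amplitudes."""

    amplitudes_um: dict[int, float]  # channel_id -> HbO amplitude, uM
    peak_s: float = 6.0
    duration_s: float = 30.0
    hbr_fraction: float = 1.0 / 3.0  # HbR amplitude = -amplitude * fraction

    def template(self, fs: float) -> np.ndarray:
        return canonical_hrf(fs, self.duration_s, self.peak_s)


def inject_canonical_hrf(
    hemo: HemoSeries, schedule: TrialSchedule, spec: HRFSpec
) -> HemoSeries:
    """Add canonical HRFs at every trial onset to the specified channels.

    HbO receives ``amplitude * template`` and HbR ``-amplitude * hbr_fraction
    * template``; all other channels are untouched.
    """
    out = hemo.copy()
    if not spec.amplitudes_um:
        return out
    tpl = spec.template(hemo.fs)
    n = hemo.n_samples
    for cid, amp in spec.amplitudes_um.items():
        row = cid - 1
        if row < 0 or row >= hemo.layout.n_regular:
            raise ValueError(f"channel {cid} does not exist")
        for onset in schedule.onsets:
            i0 = int(round(onset * hemo.fs))
            i1 = i0 + len(tpl)
            if i0 < 0 or i1 > n:
                raise ValueError("onset plus template overruns the recording")
            out.hbo[row, i0:i1] += amp * tpl
            out.hbr[row, i0:i1] += -amp * spec.hbr_fraction * tpl
    return out


# ---------------------------------------------------------------------------
# band-pass filtering


def bandpass(
    hemo: HemoSeries, low: float = 0.01, high: float = 0.09, order: int = 2
) -> HemoSeries:
    """Sequential zero-phase Butterworth filtering: low-pass then high-pass.

    Each pass is a forward-backward order-``order`` design, matching the
    0.01-0.09 Hz analysis band; NaN (pruned) channels pass through.
    """
    if not 0 < low < high < hemo.fs / 2:
        raise ValueError("cutoffs must satisfy 0 < low < high < fs/2")
    sos_lp = sps.butter(order, high, btype="lowpass", fs=hemo.fs, output="sos")
    sos_hp = sps.butter(order, low, btype="highpass", fs=hemo.fs, output="sos")

    def run(x: np.ndarray) -> np.ndarray:
        y = x.copy()
        ok = ~np.any(np.isnan(x), axis=1)
        if ok.any():
            z = sps.sosfiltfilt(sos_lp, x[ok], axis=1)
            y[ok] = sps.sosfiltfilt(sos_hp, z, axis=1)
        return y

    return HemoSeries(run(hemo.hbo), run(hemo.hbr), hemo.fs, hemo.layout, hemo.pruned_mask.copy())


# ---------------------------------------------------------------------------
# convenience chain


def preprocess_recording(
    raw: RawRecording,
    prune: bool = True,
    schedule: TrialSchedule | None = None,
    hrf_spec: HRFSpec | None = None,
    filter_band: tuple[float, float] | None = (0.01, 0.09),
) -> tuple[HemoSeries, QualityReport | None]:
    """Full chain: quality check, OD, TDDR, mBLL, optional injection, band-pass."""
    report = assess_channel_quality(raw) if prune else None
    od = intensity_to_od(raw)
    if report is not None:
        od = apply_pruning(od, report)
    od = tddr(od)
    hemo = od_to_hemoglobin(od, raw.subject_age)
    if hrf_spec is not None:
        if schedule is None:
            raise ValueError("injection requires a schedule")
        hemo = inject_canonical_hrf(hemo, schedule, hrf_spec)
    if filter_band is not None:
        hemo = bandpass(hemo, *filter_band)
    return hemo, report
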