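"""Readers and writers for raw recordings and schedules.

Raw intensities can be exchanged either as a minimal SNIRF (HDF5) file or as
a plain long-format TSV (channel, wavelength, sample_index, intensity);
schedules as a three-column TSV stimulus table (onset, duration, label).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .constants import WAVELENGTHS
from .preprocess import HemoSeries, QualityReport
from .probe import ProbeLayout, make_probe_layout
from .synth import RawRecording, TrialSchedule


def write_raw_tsv(recording: RawRecording, path: str | Path) -> None:
    """Long-format TSV: one row per (channel, wavelength, sample)."""
    frames = []
    for wl, I in recording.intensity.items():
        n_ch, n = I.shape
        frames.append(
            pd.DataFrame(
                {
                    "channel": np.repeat(np.arange(n_ch), n),
                    "wavelength": wl,
                    "sample_index": np.tile(np.arange(n), n_ch),
                    "intensity": I.ravel(),
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_raw_tsv(
    path: str | Path, fs: float, age: float, layout: ProbeLayout | None = None
) -> RawRecording:
    df = pd.read_csv(path, sep="\t")
    layout = layout or make_probe_layout()
    intensity = {}
    for wl, grp in df.groupby("wavelength"):
        wide = grp.pivot(index="channel", columns="sample_index", values="intensity")
        intensity[int(wl)] = wide.to_numpy()
    return RawRecording(intensity, fs, layout, age)


def write_schedule_tsv(schedule: TrialSchedule, path: str | Path) -> None:
    """Stimulus table: onset, duration, label."""
    pd.DataFrame(
        {
            "onset": schedule.onsets,
            "duration": schedule.task_duration,
            "label": schedule.task_label,
        }
    ).to_csv(path, sep="\t", index=False)


def read_schedule_tsv(path: str | Path) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t")
    labels = df["label"].unique()
    if len(labels) != 1:
        raise ValueError("schedule TSV must hold a single condition")
    return TrialSchedule(
        str(labels[0]), df["onset"].to_numpy(), float(df["duration"].iloc[0])
    )


def write_hemo_csv(hemo: HemoSeries, path: str | Path) -> None:
    """Wide CSV: one column per channel/species (hbo_1..hbo_24, hbr_1..)."""
    cols = {}
    for sp in ("hbo", "hbr"):
        data = hemo.species(sp)
        for ch in range(data.shape[0]):
            cols[f"{sp}_{ch + 1}"] = data[ch]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_hemo_csv(
    path: str | Path, fs: float, layout: ProbeLayout | None = None
) -> HemoSeries:
    df = pd.read_csv(path)
    layout = layout or make_probe_layout()
    hbo = np.stack([df[f"hbo_{ch + 1}"].to_numpy() for ch in range(layout.n_total)])
    hbr = np.stack([df[f"hbr_{ch + 1}"].to_numpy() for ch in range(layout.n_total)])
    pruned = np.all(np.isnan(hbo), axis=1)
    return HemoSeries(hbo, hbr, fs, layout, pruned)


def write_quality_csv(report: QualityReport, path: str | Path) -> None:
    """Per-channel SCI/PSP/Q table with the thresholds used as extra columns."""
    table = report.table.copy()
    table["sci_threshold"] = report.sci_threshold
    table["psp_threshold"] = report.psp_threshold
    table["q_threshold"] = report.q_threshold
    table.to_csv(path, index=False)


def write_snirf(recording: RawRecording, path: str | Path) -> None:
    """Write a minimal SNIRF (HDF5) file with raw intensities and the probe.

    The layout follows the SNIRF group structure: one data block whose
    columns are (channel x wavelength) measurements, a measurementList entry
    per column, and 3-D optode positions.
    """
    layout = recording.layout
    n = recording.n_samples
    n_ch = layout.n_total
    series = np.empty((n, n_ch * len(WAVELENGTHS)))
    col = 0
    meas = []
    for wi, wl in enumerate(WAVELENGTHS, start=1):
        for ch in range(n_ch):
            series[:, col] = recording.intensity[wl][ch]
            meas.append((ch + 1, ch + 1, wi))
            col += 1

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n) / recording.fs)
        for i, (src, det, wi) in enumerate(meas, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=src)
            ml.create_dataset("detectorIndex", data=det)
            ml.create_dataset("wavelengthIndex", data=wi)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(WAVELENGTHS, dtype=float))
        probe.create_dataset("sourcePos3D", data=layout.all_positions())
        probe.create_dataset("detectorPos3D", data=layout.all_positions())
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")


def read_snirf(path: str | Path, age: float, layout: ProbeLayout | None = None) -> RawRecording:
    layout = layout or make_probe_layout()
    with h5py.File(path, "r") as f:
        data = f["nirs1/data1"]
        series = data["dataTimeSeries"][()]
        time = data["time"][()]
        wavelengths = f["nirs1/probe/wavelengths"][()].astype(int)
    fs = 1.0 / float(np.median(np.diff(time)))
    n_ch = series.shape[1] // len(wavelengths)
    intensity = {
        int(wl): series[:, wi * n_ch : (wi + 1) * n_ch].T
        for wi, wl in enumerate(wavelengths)
    }
    return RawRecording(intensity, fs, layout, age)
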