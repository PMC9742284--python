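"""File I/O: SNIRF (HDF5), long-format CSV, layout and metadata tables.

The SNIRF writer emits a minimal standard-layout file per subject
(`/nirs/data1` with a dataTimeSeries block, per-measurement metadata
lists, and a probe group). Because the stored series are
optical-density changes rather than raw intensities, measurements carry
``dataTypeLabel = "dOD"`` with the processed-data type code. The reader
only supports files with this structure (one data block, two wavelengths
per channel).

The long-format CSV dialect is a self-describing plain-text alternative:
columns ``subject, channel, wavelength, sample_index, value`` with the
sampling rate recorded in a header comment.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .containers import ChannelLayout, RawRecording, SubjectMeta

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_long_csv",
    "read_long_csv",
    "write_layout_csv",
    "read_layout_csv",
    "write_metadata_csv",
    "read_metadata_csv",
]

_PROCESSED_DATA_TYPE = 99999  # SNIRF code for processed data


def _str_ds(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(rec: RawRecording, path: str | Path) -> Path:
    """Write one subject's recording as a minimal SNIRF (HDF5) file."""
    path = Path(path)
    layout = rec.layout
    n_ch = layout.n_channels
    n_t = rec.n_samples
    # measurement order: channel-major, wavelength-minor
    series = rec.delta_od.reshape(n_ch * 2, n_t).T  # (n_t, n_meas)
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_ds(meta, "SubjectID", rec.subject_id)
        _str_ds(meta, "MeasurementDate", "unknown")
        _str_ds(meta, "MeasurementTime", "unknown")
        _str_ds(meta, "LengthUnit", "cm")
        _str_ds(meta, "TimeUnit", "s")
        _str_ds(meta, "FrequencyUnit", "Hz")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_t) / rec.fs)
        m = 0
        for i in range(n_ch):
            for w in range(2):
                m += 1
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=int(layout.source_ids[i]))
                ml.create_dataset("detectorIndex", data=int(layout.detector_ids[i]))
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=_PROCESSED_DATA_TYPE)
                ml.create_dataset("dataTypeIndex", data=1)
                _str_ds(ml, "dataTypeLabel", "dOD")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))
        half = layout.separation / 2.0
        src = layout.positions + np.array([-half, 0.0])
        det = layout.positions + np.array([half, 0.0])
        probe.create_dataset("sourcePos2D", data=src)
        probe.create_dataset("detectorPos2D", data=det)
    return path


def read_snirf(path: str | Path, layout: ChannelLayout | None = None) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf`.

    If ``layout`` is omitted it is reconstructed from the probe group
    (channel positions = source/detector midpoints).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        series = np.asarray(data["dataTimeSeries"])  # (n_t, n_meas)
        time = np.asarray(data["time"])
        subject_id = f["nirs/metaDataTags/SubjectID"][()].decode()
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"], dtype=float))
        if len(time) < 2:
            raise ValueError("SNIRF file has fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(time)))
        n_meas = series.shape[1]
        if n_meas % 2 != 0:
            raise ValueError("expected two wavelengths per channel")
        n_ch = n_meas // 2
        if layout is None:
            src = np.asarray(f["nirs/probe/sourcePos2D"])
            det = np.asarray(f["nirs/probe/detectorPos2D"])
            positions = (src + det) / 2.0
            sep = float(np.linalg.norm(det[0] - src[0]))
            srcs = np.empty(n_ch, dtype=int)
            dets = np.empty(n_ch, dtype=int)
            for i in range(n_ch):
                ml = data[f"measurementList{2 * i + 1}"]
                srcs[i] = int(ml["sourceIndex"][()])
                dets[i] = int(ml["detectorIndex"][()])
            layout = ChannelLayout(
                channel_ids=np.arange(1, n_ch + 1),
                source_ids=srcs,
                detector_ids=dets,
                positions=positions,
                separation=sep,
            )
    delta_od = series.T.reshape(n_ch, 2, -1)
    return RawRecording(
        subject_id=subject_id,
        layout=layout,
        delta_od=delta_od,
        fs=fs,
        wavelengths=wavelengths,
    )


def write_long_csv(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as self-describing long-format CSV."""
    path = Path(path)
    n_ch, _, n_t = rec.delta_od.shape
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs_hz={rec.fs}\n")
        writer = csv.writer(fh)
        writer.writerow(["subject", "channel", "wavelength", "sample_index", "value"])
        for i in range(n_ch):
            cid = int(rec.layout.channel_ids[i])
            for w, wl in enumerate(rec.wavelengths):
                for s in range(n_t):
                    writer.writerow([rec.subject_id, cid, int(wl), s, rec.delta_od[i, w, s]])
    return path


def read_long_csv(path: str | Path, layout: ChannelLayout) -> RawRecording:
    """Read a long-format CSV recording (requires the channel layout)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fs = None
    if first.startswith("#"):
        for tok in first.lstrip("#").strip().split():
            if tok.startswith("fs_hz="):
                fs = float(tok.split("=", 1)[1])
    if fs is None:
        raise ValueError("long CSV is missing the '# fs_hz=' header")
    df = pd.read_csv(path, comment="#")
    subject = str(df["subject"].iloc[0])
    wavelengths = tuple(sorted(df["wavelength"].unique().astype(float)))
    if len(wavelengths) != 2:
        raise ValueError(f"expected 2 wavelengths, found {wavelengths}")
    n_t = int(df["sample_index"].max()) + 1
    n_ch = layout.n_channels
    delta_od = np.zeros((n_ch, 2, n_t))
    for (cid, wl), g in df.groupby(["channel", "wavelength"]):
        i = layout.index_of(int(cid))
        w = 0 if float(wl) == wavelengths[0] else 1
        g = g.sort_values("sample_index")
        delta_od[i, w, g["sample_index"].to_numpy(int)] = g["value"].to_numpy(float)
    return RawRecording(
        subject_id=subject, layout=layout, delta_od=delta_od, fs=fs, wavelengths=wavelengths
    )


def write_layout_csv(layout: ChannelLayout, path: str | Path) -> Path:
    path = Path(path)
    layout.to_frame().to_csv(path, index=False)
    return path


def read_layout_csv(path: str | Path) -> ChannelLayout:
    return ChannelLayout.from_frame(pd.read_csv(path))


def write_metadata_csv(metas: Sequence[SubjectMeta], path: str | Path) -> Path:
    """Write subject metadata (subject_id, group, one column per test score)."""
    path = Path(path)
    score_names = sorted({name for m in metas for name in m.test_scores})
    rows = []
    for m in metas:
        row = {"subject_id": m.subject_id, "group": m.group}
        for name in score_names:
            row[name] = m.test_scores.get(name, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_metadata_csv(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path)
    score_names = [c for c in df.columns if c not in ("subject_id", "group")]
    metas = []
    for _, row in df.iterrows():
        scores = {
            name: float(row[name]) for name in score_names if pd.notna(row[name])
        }
        metas.append(
            SubjectMeta(subject_id=str(row["subject_id"]), group=str(row["group"]), test_scores=scores)
        )
    return metas
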