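"""Core data containers shared across the pipeline stages.

These classes carry the data as it flows through the analysis:
raw dual-wavelength optical-density changes -> hemoglobin concentration
changes -> windowed activation statistics -> a subjects x channels
feature matrix. They validate the structural invariants each stage
relies on (matching shapes, finite values, non-degenerate labels) but
contain no analysis logic themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Number of long-separation optical channels on the forehead probe.
N_CHANNELS = 48

#: Source-detector separation of the deep-sampling channels, in cm.
SEPARATION_CM = 3.35

#: Operating wavelengths of the continuous-wave device, in nm.
WAVELENGTHS = (780.0, 850.0)


@dataclass(frozen=True)
class ChannelLayout:
    """Positions of the 48 long-separation channels on a flattened forehead plane.

    Each channel is one source-detector pair; it samples the cortex under
    the pair's midpoint, which is the coordinate stored in ``positions``.
    All separations are equal by construction of the probe.

    Parameters
    ----------
    channel_ids : ndarray of int, shape (48,)
        Channel identifiers, 1..48.
    source_ids, detector_ids : ndarray of int, shape (48,)
        Optode identifiers for each pair.
    positions : ndarray of float, shape (48, 2)
        Channel midpoint coordinates in cm on the forehead plane.
    separation : float
        Source-detector distance in cm (3.35 for the deep channels).
    """

    channel_ids: np.ndarray
    source_ids: np.ndarray
    detector_ids: np.ndarray
    positions: np.ndarray
    separation: float = SEPARATION_CM

    def __post_init__(self) -> None:
        cid = np.asarray(self.channel_ids, dtype=int)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "channel_ids", cid)
        object.__setattr__(self, "source_ids", np.asarray(self.source_ids, dtype=int))
        object.__setattr__(self, "detector_ids", np.asarray(self.detector_ids, dtype=int))
        object.__setattr__(self, "positions", pos)
        if cid.shape != (N_CHANNELS,):
            raise ValueError(f"layout must have exactly {N_CHANNELS} channels, got {cid.shape}")
        if len(np.unique(cid)) != N_CHANNELS:
            raise ValueError("channel_ids must be unique")
        if pos.shape != (N_CHANNELS, 2):
            raise ValueError(f"positions must have shape ({N_CHANNELS}, 2), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        # uniqueness of positions
        uniq = np.unique(pos, axis=0)
        if uniq.shape[0] != N_CHANNELS:
            raise ValueError("channel positions must be unique")

    @property
    def n_channels(self) -> int:
        return int(self.channel_ids.shape[0])

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the channel positions, in cm."""
        x, y = self.positions[:, 0], self.positions[:, 1]
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())

    def index_of(self, channel_id: int) -> int:
        """Row index of a channel id in the layout arrays."""
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise KeyError(f"channel {channel_id} not in layout")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "source_id": self.source_ids,
                "detector_id": self.detector_ids,
                "x_cm": self.positions[:, 0],
                "y_cm": self.positions[:, 1],
                "separation_cm": self.separation,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChannelLayout":
        sep = float(df["separation_cm"].iloc[0])
        return cls(
            channel_ids=df["channel_id"].to_numpy(),
            source_ids=df["source_id"].to_numpy(),
            detector_ids=df["detector_id"].to_numpy(),
            positions=df[["x_cm", "y_cm"]].to_numpy(float),
            separation=sep,
        )


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata: group membership and neuropsychological scores.

    ``test_scores`` maps test names (e.g. ``"BNT"``, ``"MMSE"``,
    ``"VerbalMemoryTotalRecall"``) to numeric scores; controls typically
    have no scores.
    """

    subject_id: str
    group: str  # "patient" | "control"
    test_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")


@dataclass
class RawRecording:
    """Dual-wavelength optical-density-change time series for one subject.

    ``delta_od`` has shape (n_channels, 2, n_samples): axis 1 indexes the
    wavelengths in the order given by ``wavelengths``. Values are
    dimensionless log-attenuation changes relative to baseline.
    """

    subject_id: str
    layout: ChannelLayout
    delta_od: np.ndarray
    fs: float
    wavelengths: tuple[float, float] = WAVELENGTHS

    def __post_init__(self) -> None:
        self.delta_od = np.asarray(self.delta_od, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.delta_od.ndim != 3 or self.delta_od.shape[:2] != (self.layout.n_channels, 2):
            raise ValueError(
                "delta_od must have shape (n_channels, 2, n_samples); "
                f"got {self.delta_od.shape}"
            )
        if not np.all(np.isfinite(self.delta_od)):
            raise ValueError("delta_od contains non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.delta_od.shape[2])


@dataclass
class HemoSeries:
    """Per-channel hemoglobin concentration-change time series, in mM.

    ``filter_state`` records whether the series has been band-pass
    filtered; artifact detection and feature extraction expect
    ``"filtered"``.
    """

    subject_id: str
    channel_ids: np.ndarray
    hbo: np.ndarray  # (n_channels, n_samples), mM
    hbr: np.ndarray
    fs: float
    filter_state: str = "raw"

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have the same shape")
        if self.hbo.ndim != 2 or self.hbo.shape[0] != self.channel_ids.shape[0]:
            raise ValueError("hbo must have shape (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.filter_state not in ("raw", "filtered"):
            raise ValueError("filter_state must be 'raw' or 'filtered'")

    @property
    def n_samples(self) -> int:
        return int(self.hbo.shape[1])


@dataclass
class WindowTable:
    """Standard deviations of the signal in nonoverlapping windows, with outlier mask.

    One row per channel, one column per complete window. ``is_outlier``
    flags windows whose SD deviates from the channel median of window SDs
    by strictly more than ``threshold_multiplier`` times the (raw) median
    absolute deviation of those SDs.
    """

    channel_ids: np.ndarray
    window_s: float
    window_samples: int
    sds: np.ndarray  # (n_channels, n_windows)
    medians: np.ndarray  # (n_channels,)
    mads: np.ndarray  # (n_channels,)
    is_outlier: np.ndarray  # bool, same shape as sds
    threshold_multiplier: float = 4.5

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        self.sds = np.asarray(self.sds, dtype=float)
        self.is_outlier = np.asarray(self.is_outlier, dtype=bool)
        if self.sds.shape != self.is_outlier.shape:
            raise ValueError("sds and is_outlier must have the same shape")

    @property
    def n_windows(self) -> int:
        return int(self.sds.shape[1])

    def to_frame(self) -> pd.DataFrame:
        n_ch, n_w = self.sds.shape
        return pd.DataFrame(
            {
                "channel_id": np.repeat(self.channel_ids, n_w),
                "window_index": np.tile(np.arange(n_w), n_ch),
                "sd_value": self.sds.ravel(),
                "is_outlier": self.is_outlier.ravel(),
            }
        )


@dataclass
class FeatureMatrix:
    """Subjects x channels matrix of session-averaged activation, with labels.

    ``values`` is a DataFrame indexed by subject id with channel-id
    columns; entries are mean retained-window SDs of the oxyhemoglobin
    signal, in mM. ``label`` is 1 for patients (or high scorers) and 0
    for controls (or low scorers). ``label_definition`` records how the
    labels were derived (group split, or test name + cut-off + tie rule).
    """

    values: pd.DataFrame
    label: np.ndarray
    label_definition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate subject ids in feature matrix")
        if self.values.shape[1] > N_CHANNELS:
            raise ValueError(f"feature matrix may have at most {N_CHANNELS} channel columns")
        if self.label.shape[0] != self.values.shape[0]:
            raise ValueError("label length must equal number of subjects")
        if not set(np.unique(self.label)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.label)) < 2:
            raise ValueError("both classes must be nonempty")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def channel_ids(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=int)

    @property
    def X(self) -> np.ndarray:
        """Feature values as a float array (subjects x channels)."""
        return self.values.to_numpy(float)

    def select_channels(self, channel_ids: Sequence[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[list(channel_ids)].copy(),
            label=self.label.copy(),
            label_definition=dict(self.label_definition),
        )

    def to_csv(self, path: str | Path, provenance: str | None = None) -> None:
        """Write the matrix as CSV plus a JSON sidecar with the label definition."""
        path = Path(path)
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# provenance: {provenance}\n")
            out = self.values.copy()
            out.insert(0, "label", self.label)
            out.to_csv(fh, index_label="subject_id")
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump({"label_definition": self.label_definition}, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, comment="#", index_col="subject_id")
        label = df.pop("label").to_numpy(int)
        df.columns = df.columns.astype(int)
        label_definition: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                label_definition = json.load(fh).get("label_definition", {})
        return cls(values=df, label=label, label_definition=label_definition)
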