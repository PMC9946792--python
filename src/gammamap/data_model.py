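"""Core domain containers and readers/writers for the pipeline's formats.

The pipeline moves four kinds of objects around: multichannel LFP
recordings (:class:`Recording`), trial annotations (:class:`EventTable`),
electrode geometry (:class:`ElectrodeTable`) and volumetric network
parcellations (:class:`LabelVolume`).  Derived per-band quantities live in
:class:`BandPowerSeries` and :class:`PermutationResult`.

Conventions
-----------
* All electrode and voxel coordinates are MNI millimetres; voxel indices
  are 0-based and converted only through the affine.
* Signals are float64 microvolts internally regardless of on-disk
  precision, so long filter chains stay numerically stable.
* Event times are seconds relative to recording start; trial intervals
  are half-open ``[onset, offset)`` so exclusion arithmetic reduces to
  exact sample counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "CONDITIONS",
    "Recording",
    "EventTable",
    "ElectrodeTable",
    "LabelVolume",
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandPowerSeries",
    "ConditionPower",
    "PermutationResult",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_electrodes",
    "write_electrodes",
    "read_label_volume",
    "write_label_volume",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


#: Task conditions of the intraoperative protocol: quiet wakeful baseline,
#: simple counting, and alternation between counting and the alphabet.
CONDITIONS = ("rest", "count", "switch")

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A block of multichannel LFP data.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One label per row of ``data``.
    reference
        Text descriptor of the referencing scheme, e.g. ``"scalp-Fz"``
        (common scalp reference) or ``"bipolar"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    reference: str = "scalp-Fz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{self.data.shape[0]} channels but {len(self.channel_names)} channel names"
            )
        if np.isnan(self.data).any():
            raise ValidationError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray, *, fs: float | None = None,
                  channel_names: Sequence[str] | None = None,
                  reference: str | None = None) -> "Recording":
        """Copy of this recording with some fields replaced."""
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            channel_names=list(self.channel_names if channel_names is None else channel_names),
            reference=self.reference if reference is None else reference,
        )


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Ordered trial annotations: onset/offset seconds plus condition.

    Trials are stored in performed (temporal) order.  ``performed_order``
    maps storage order to the order in which trials were actually run and
    is the identity after construction; it is kept explicit because the
    rotation surrogate builds its loop in performed order.
    """

    trials: pd.DataFrame  # columns: onset_s, offset_s, condition, trial_index

    REQUIRED = ("onset_s", "offset_s", "condition")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.trials).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"event table missing required column {col!r}")
        if "trial_index" not in df.columns:
            df["trial_index"] = np.arange(len(df))
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        bad = df["condition"][~df["condition"].isin(CONDITIONS)]
        if len(bad):
            raise ValidationError(f"unknown condition labels: {sorted(set(bad))}")
        if not (df["onset_s"] < df["offset_s"]).all():
            raise ValidationError("every trial must satisfy onset_s < offset_s")
        if len(df) > 1 and (df["onset_s"].to_numpy()[1:] < df["offset_s"].to_numpy()[:-1]).any():
            raise ValidationError("trials overlap")
        self.trials = df

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def performed_order(self) -> np.ndarray:
        """Permutation mapping row order to temporal order (identity here,
        because rows are kept sorted by onset)."""
        return np.argsort(self.trials["onset_s"].to_numpy(), kind="stable")

    def of_condition(self, *conditions: str) -> "EventTable":
        keep = self.trials[self.trials["condition"].isin(conditions)]
        return EventTable(keep.reset_index(drop=True))

    def check_within(self, duration_s: float) -> None:
        if (self.trials["offset_s"] > duration_s + 1e-9).any():
            raise ValidationError("events extend beyond the end of the recording")


# ---------------------------------------------------------------------------
# ElectrodeTable
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeTable:
    """Per-contact geometry and labels.

    One row per contact: name, strip membership, 1-based contact index
    along the strip, MNI millimetre coordinates, hemisphere, and optional
    gyrus / network labels.  Contacts on a four-contact strip are 10 mm
    apart centre to centre (kept as metadata in ``pitch_mm``).
    """

    contacts: pd.DataFrame
    pitch_mm: float = 10.0

    REQUIRED = ("name", "strip_id", "contact_index", "x", "y", "z")
    OPTIONAL = ("hemisphere", "gyrus", "network")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.contacts).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"electrode table missing required column {col!r}")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("electrode coordinates must be finite")
        if df.duplicated(subset=["strip_id", "contact_index"]).any():
            dup = df[df.duplicated(subset=["strip_id", "contact_index"], keep=False)]
            raise ValidationError(
                f"duplicate (strip_id, contact_index) pairs: {dup[['strip_id', 'contact_index']].to_dict('records')}"
            )
        if "hemisphere" not in df.columns or df["hemisphere"].isna().any():
            # MNI convention: x > 0 is the right hemisphere
            hemi = np.where(df["x"].to_numpy(dtype=float) > 0, "R", "L")
            if "hemisphere" in df.columns:
                df["hemisphere"] = df["hemisphere"].where(df["hemisphere"].notna(), pd.Series(hemi))
            else:
                df["hemisphere"] = hemi
        if not df["hemisphere"].isin(["L", "R"]).all():
            raise ValidationError("hemisphere must be 'L' or 'R'")
        for col in ("gyrus", "network"):
            if col not in df.columns:
                df[col] = pd.NA
        self.contacts = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def names(self) -> list[str]:
        return self.contacts["name"].tolist()

    @property
    def coords(self) -> np.ndarray:
        """``(n_contacts, 3)`` millimetre coordinates."""
        return self.contacts[["x", "y", "z"]].to_numpy(dtype=float)

    def strips(self) -> dict[str, pd.DataFrame]:
        """Contacts grouped by strip, ordered by contact_index."""
        out = {}
        for sid, grp in self.contacts.groupby("strip_id", sort=True):
            out[sid] = grp.sort_values("contact_index")
        return out

    def with_contacts(self, contacts: pd.DataFrame) -> "ElectrodeTable":
        return ElectrodeTable(contacts, pitch_mm=self.pitch_mm)


# ---------------------------------------------------------------------------
# LabelVolume
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Volumetric network parcellation: integer labels on a voxel grid.

    ``affine`` maps 0-based voxel indices to millimetres.  Label 0 is
    reserved for background/unlabelled tissue.  ``label_names`` maps each
    nonzero label id to a network name (e.g. FPN, DMN, CON, LANG, MOT).
    """

    grid: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValidationError(f"label grid must be 3-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValidationError(f"label grid must be integer-valued, got dtype {self.grid.dtype}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        if 0 in self.label_names:
            raise ValidationError("label 0 is reserved for background")

    @property
    def labels_present(self) -> set[int]:
        return set(np.unique(self.grid)) - {0}

    def name_of(self, label: int) -> str:
        return self.label_names.get(int(label), str(int(label)))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n, 3) to mm coordinates (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates (n, 3) to fractional voxel indices (n, 3)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def labelled_voxel_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates (mm) and labels of every nonzero voxel centre."""
        ijk = np.argwhere(self.grid != 0)
        labels = self.grid[self.grid != 0] if ijk.size else np.empty(0, dtype=self.grid.dtype)
        # argwhere order matches boolean ravel order, keep them aligned
        labels = self.grid[tuple(ijk.T)] if ijk.size else labels
        return self.voxel_to_mm(ijk) if ijk.size else np.empty((0, 3)), labels


# ---------------------------------------------------------------------------
# Bands and band power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo_hz, hi_hz]``."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValidationError(f"band {self.name}: need 0 < lo < hi, got [{self.lo_hz}, {self.hi_hz}]")


#: The six classical bands used throughout: delta 1-4, theta 4-8, alpha
#: 8-12, beta 12-30, low gamma 30-70 and high gamma 70-250 Hz.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("LG", 30.0, 70.0),
    BandDefinition("HG", 70.0, 250.0),
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


@dataclass
class BandPowerSeries:
    """Per-channel instantaneous power for one band (squared Hilbert
    envelope), hence non-negative everywhere."""

    band: BandDefinition
    power: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2:
            raise ValidationError("power must be 2-D (channels x samples)")
        if np.isnan(self.power).any():
            raise ValidationError("power series contains NaN")
        if (self.power < 0).any():
            raise ValidationError("instantaneous power must be non-negative")
        if len(self.channel_names) != self.power.shape[0]:
            raise ValidationError("channel name count mismatch")


@dataclass
class ConditionPower:
    """Per-condition scalar power and per-contrast percent change.

    ``means`` has columns electrode, band, condition, mean_power, n_samples;
    ``contrasts`` has columns electrode, band, contrast, percent_change.
    """

    means: pd.DataFrame
    contrasts: pd.DataFrame


@dataclass
class PermutationResult:
    """Outcome of the rotation surrogate test for one electrode/band/contrast."""

    observed_ratio: float
    n_permutations: int
    q_low: float   # 2.5th percentile of the surrogate ratio distribution
    q_high: float  # 97.5th percentile
    p_two_tailed: float
    significant: bool
    direction: str  # "increase" | "decrease" | "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValidationError(f"p must be in [0, 1], got {self.p_two_tailed}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Load a recording from EDF or raw float32 binary + JSON sidecar.

    EDF files (``.edf``) are read with :mod:`mne` and converted to
    microvolts.  Anything else is interpreted as little-endian float32
    samples in channel-major order, described by a JSON sidecar with keys
    ``fs`` and ``channels`` (defaults to ``<path>.json``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        return Recording(data=data, fs=float(raw.info["sfreq"]), channel_names=list(raw.ch_names))

    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"sidecar not found for raw recording: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "channels"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required field {key!r}")
    channels = list(meta["channels"])
    flat = np.fromfile(path, dtype="<f4")
    n_ch = len(channels)
    if n_ch == 0 or flat.size % n_ch != 0:
        raise FormatError(
            f"raw file length {flat.size} not divisible by channel count {n_ch}"
        )
    data = flat.reshape(n_ch, flat.size // n_ch).astype(np.float64)
    return Recording(data=data, fs=float(meta["fs"]), channel_names=channels,
                     reference=str(meta.get("reference", "scalp-Fz")))


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording as raw little-endian float32 plus a JSON sidecar."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"fs": rec.fs, "channels": rec.channel_names, "reference": rec.reference}, indent=1
    ))


def read_events(path: str | Path) -> EventTable:
    """Read a BIDS-style events table (onset, duration, trial_type[, order])."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise FormatError(f"events table missing required column {col!r}")
    trials = pd.DataFrame({
        "onset_s": df["onset"].astype(float),
        "offset_s": df["onset"].astype(float) + df["duration"].astype(float),
        "condition": df["trial_type"].astype(str),
        "trial_index": df["order"].astype(int) if "order" in df.columns else np.arange(len(df)),
    })
    return EventTable(trials)


def write_events(path: str | Path, events: EventTable) -> None:
    df = events.trials
    out = pd.DataFrame({
        "onset": df["onset_s"],
        "duration": df["offset_s"] - df["onset_s"],
        "trial_type": df["condition"],
        "order": df["trial_index"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_electrodes(path: str | Path) -> ElectrodeTable:
    """Read an electrodes.tsv (name, strip_id, contact_index, x, y, z, ...)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ElectrodeTable(df)


def write_electrodes(path: str | Path, electrodes: ElectrodeTable) -> None:
    cols = ["name", "strip_id", "contact_index", "x", "y", "z", "hemisphere", "gyrus", "network"]
    electrodes.contacts[cols].to_csv(path, sep="\t", index=False, na_rep="n/a",
                                     float_format="%.17g")


def read_label_volume(path: str | Path, labels_tsv: str | Path | None = None) -> LabelVolume:
    """Load a NIfTI label image plus an optional labels.tsv lookup
    (columns ``label``, ``name``)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        # NIfTI label maps are sometimes stored as float; accept only if
        # every value is integral, otherwise it is not a label volume.
        if not np.equal(np.mod(data, 1), 0).all():
            raise ValidationError(f"{path} holds non-integer values; not a label volume")
        data = data.astype(np.int32)
    label_names: dict[int, str] = {}
    if labels_tsv is not None:
        lut = pd.read_csv(labels_tsv, sep="\t")
        for col in ("label", "name"):
            if col not in lut.columns:
                raise FormatError(f"labels table missing required column {col!r}")
        label_names = dict(zip(lut["label"].astype(int), lut["name"].astype(str)))
    return LabelVolume(grid=data, affine=np.asarray(img.affine), label_names=label_names)


def write_label_volume(path: str | Path, volume: LabelVolume,
                       labels_tsv: str | Path | None = None) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(volume.grid.astype(np.int16), volume.affine)
    nib.save(img, str(path))
    if labels_tsv is not None:
        pd.DataFrame(
            {"label": list(volume.label_names), "name": list(volume.label_names.values())}
        ).to_csv(labels_tsv, sep="\t", index=False)
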