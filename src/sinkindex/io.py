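"""Reading and writing EEG recordings and cohort metadata.

Recordings are held as a :class:`Recording` — a channels × samples float
matrix in microvolts with ordered 10–20 channel labels and a sampling rate.
EDF and EEGLAB ``.set`` files are read through :mod:`mne`; plain CSV
matrices and BIDS-style ``participants.tsv`` tables through :mod:`pandas`.

A minimal 16-bit EDF writer is included for exporting recordings; EDF is a
fixed-layout ASCII-header format and the writer covers exactly the subset
this package produces (continuous multichannel data, one physical unit).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, FormatError, MetadataError, ValidationError

#: Canonical 19-channel 10–20 montage, in the conventional dataset order.
CANONICAL_19 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

_CANONICAL_LOOKUP = {name.lower(): name for name in CANONICAL_19}

#: Old-nomenclature aliases used by some montage definitions.
_ALIASES = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}

_GROUPS = ("FTD", "AD", "HC")
_GROUP_ALIASES = {
    "f": "FTD", "ftd": "FTD", "frontotemporal dementia": "FTD",
    "a": "AD", "ad": "AD", "alzheimer": "AD", "alzheimer's disease": "AD",
    "c": "HC", "hc": "HC", "control": "HC", "healthy": "HC",
}


def canonical_label(raw: str) -> str:
    """Map a raw channel label to its canonical 10–20 name.

    Strips ``EEG `` prefixes and reference suffixes (``-REF``, ``-LE``),
    matches case-insensitively, and resolves old/new temporal-chain aliases.
    Unrecognized labels are returned stripped but otherwise untouched.
    """
    name = raw.strip()
    name = re.sub(r"^EEG\s+", "", name, flags=re.IGNORECASE)
    name = re.sub(r"-(REF|LE|AVG|A1|A2)$", "", name, flags=re.IGNORECASE)
    key = name.lower()
    if key in _CANONICAL_LOOKUP:
        return _CANONICAL_LOOKUP[key]
    if key in _ALIASES:
        return _ALIASES[key]
    return name


@dataclass
class Recording:
    """A channel-labelled multichannel EEG time series in microvolts."""

    subject_id: str
    channel_labels: list[str]
    fs: float
    data: np.ndarray  # channels × samples, microvolts

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels × samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise MetadataError(
                f"{self.data.shape[0]} data rows but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise MetadataError("duplicate channel labels")
        if self.data.shape[0] < 2:
            raise DegenerateInputError("fewer than 2 channels")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".set":
        return "eeglab_set"
    if suffix == ".csv":
        return "array_csv"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def read_recording(path, format: str | None = None, subject_id: str | None = None) -> Recording:
    """Read an EEG recording from EDF, EEGLAB ``.set``, or CSV.

    Channel labels are mapped to canonical 10–20 names case-insensitively;
    data are returned in microvolts with the sampling rate from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if subject_id is None:
        subject_id = path.stem
    if fmt == "edf":
        return _read_mne(path, "edf", subject_id)
    if fmt == "eeglab_set":
        return _read_mne(path, "eeglab_set", subject_id)
    if fmt == "array_csv":
        return _read_csv(path, subject_id)
    raise FormatError(f"unknown format {fmt!r}")


def _read_mne(path: Path, fmt: str, subject_id: str) -> Recording:
    import mne

    try:
        if fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc
    labels = [canonical_label(name) for name in raw.ch_names]
    if not labels:
        raise MetadataError(f"{path}: no channel labels")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(subject_id, labels, float(raw.info["sfreq"]), data_uv)


def _read_csv(path: Path, subject_id: str) -> Recording:
    fs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"fs\s*=\s*([0-9.]+)", first)
            if m:
                fs = float(m.group(1))
            table = pd.read_csv(fh)
        else:
            table = pd.read_csv(path)
    if fs is None:
        raise MetadataError(f"{path}: missing '# fs=<Hz>' header line")
    labels = [canonical_label(c) for c in table.columns]
    data = table.to_numpy(dtype=np.float64).T  # stored samples × channels
    return Recording(subject_id, labels, fs, data)


def write_csv(rec: Recording, path) -> None:
    """Write a recording as a samples × channels CSV with a ``# fs=`` line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(fh, index=False)


def _edf_field(value, width: int) -> bytes:
    text = f"{value}"[:width]
    return text.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF.

    Uses 1-second data records when the sample count divides evenly at an
    integer rate, otherwise a single record spanning the whole recording.
    Physical min/max are set per channel from the data range, so values
    round-trip to within one 16-bit quantization step.
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) < 1e-9 and n_samp % fs_int == 0:
        n_records, spr, rec_dur = n_samp // fs_int, fs_int, 1.0
    else:
        n_records, spr, rec_dur = 1, n_samp, n_samp / rec.fs

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((rec.data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    head = b"".join(
        [
            _edf_field(0, 8),
            _edf_field(rec.subject_id, 80),
            _edf_field("sinkindex export", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(header_bytes, 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(f"{rec_dur:g}"[:8], 8),
            _edf_field(n_ch, 4),
        ]
    )
    per_signal = [
        b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_edf_field(dmin, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dmax, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(head)
        for block in per_signal:
            fh.write(block)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())


def read_cohort(directory) -> pd.DataFrame:
    """Read a BIDS-style cohort directory into a participants table.

    Expects ``participants.tsv`` with participant id, sex, age, group and
    MMSE columns (case-insensitive; single-letter group codes A/F/C are
    accepted). Returns one row per subject with columns
    ``subject_id, group, sex, age, mmse, recording_path``.
    """
    directory = Path(directory)
    tsv = directory / "participants.tsv"
    if not tsv.exists():
        raise MetadataError(f"no participants.tsv in {directory}")
    table = pd.read_csv(tsv, sep="\t")
    cols = {c.lower(): c for c in table.columns}

    def _col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise MetadataError(f"participants.tsv missing a required column ({names[0]})")

    pid_c = _col("participant_id", "subject_id")
    group_c = _col("group", "diagnosis", "condition")
    sex_c = _col("gender", "sex")
    age_c = _col("age")
    mmse_c = _col("mmse")

    rows = []
    for _, row in table.iterrows():
        pid = str(row[pid_c])
        raw_group = str(row[group_c]).strip().lower()
        if raw_group not in _GROUP_ALIASES:
            raise ValidationError(f"unknown group label {row[group_c]!r} for {pid}")
        mmse = row[mmse_c]
        if pd.notna(mmse) and not 0 <= float(mmse) <= 30:
            raise ValidationError(f"MMSE {mmse!r} out of [0, 30] for {pid}")
        rows.append(
            {
                "subject_id": pid,
                "group": _GROUP_ALIASES[raw_group],
                "sex": str(row[sex_c]),
                "age": float(row[age_c]) if pd.notna(row[age_c]) else np.nan,
                "mmse": float(mmse) if pd.notna(mmse) else np.nan,
                "recording_path": _find_recording(directory, pid),
            }
        )
    cohort = pd.DataFrame(rows)
    if cohort["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_id in participants.tsv")
    return cohort


def _find_recording(directory: Path, pid: str) -> str:
    candidates = [
        directory / f"{pid}{ext}" for ext in (".edf", ".set", ".csv")
    ] + [
        directory / pid / "eeg" / f"{pid}_task-eyesclosed_eeg{ext}"
        for ext in (".set", ".edf")
    ]
    for cand in candidates:
        if cand.exists():
            return str(cand)
    found = sorted(directory.glob(f"{pid}/**/*_eeg.*"))
    return str(found[0]) if found else ""


def write_cohort(cohort: pd.DataFrame, directory) -> Path:
    """Write a cohort table as BIDS-style ``participants.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = cohort.rename(
        columns={
            "subject_id": "participant_id",
            "sex": "Gender",
            "age": "Age",
            "group": "Group",
            "mmse": "MMSE",
        }
    )
    keep = [c for c in ("participant_id", "Gender", "Age", "Group", "MMSE") if c in out]
    out[keep].to_csv(directory / "participants.tsv", sep="\t", index=False)
    return directory / "participants.tsv"
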