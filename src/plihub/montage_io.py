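"""Montage definition, EEG recording I/O, and tabular result output.

The canonical montage is the 16-site subset of the International 10-20
system used throughout the pipeline: Fp1, Fp2, F3, F4, Fz, F7, F8, C3, C4,
P3, P4, Pz, T5, T6, O1, O2 (linked-earlobe reference at acquisition; no
software re-reference is applied).

Recordings are accepted either as EDF (read through :mod:`mne`) or as a
plain tab-delimited text matrix with a channel-label column.  All tabular
outputs are delimited text keyed by subject, band and electrode so results
diff cleanly.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: The 16 scalp sites of the default montage, in canonical order.
CANONICAL_LABELS = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8", "C3",
    "C4", "P3", "P4", "Pz", "T5", "T6", "O1", "O2",
)

GROUPS = ("control", "patient")
SESSIONS = ("pre", "post", "none")


def _norm(label: str) -> str:
    return label.strip().lower()


@dataclass(frozen=True)
class Montage:
    """Ordered, unique set of channel labels."""

    labels: tuple[str, ...] = CANONICAL_LABELS

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if not labels:
            raise ValueError("montage must have at least one channel")
        if any(not lbl.strip() for lbl in labels):
            raise ValueError("montage labels must be non-empty")
        norm = [_norm(lbl) for lbl in labels]
        if len(set(norm)) != len(norm):
            raise ValueError("montage labels must be unique")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        """Position of *label*, matched case-insensitively and stripped."""
        target = _norm(label)
        for i, lbl in enumerate(self.labels):
            if _norm(lbl) == target:
                return i
        raise KeyError(f"channel {label!r} not in montage {self.labels}")

    def permutation_from(self, labels: Sequence[str]) -> np.ndarray:
        """Index array mapping rows ordered as *labels* into montage order.

        Raises ``KeyError`` naming the first montage channel absent from
        *labels*.
        """
        have = {_norm(l): i for i, l in enumerate(labels)}
        perm = np.empty(len(self.labels), dtype=np.intp)
        for i, lbl in enumerate(self.labels):
            j = have.get(_norm(lbl))
            if j is None:
                raise KeyError(f"required channel {lbl!r} missing from input")
            perm[i] = j
        return perm


DEFAULT_MONTAGE = Montage()


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples, rows ordered as ``montage.labels``.
    """

    montage: Montage
    data: np.ndarray
    fs: float = 200.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data shape {self.data.shape} does not match the "
                f"{len(self.montage)}-channel montage"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata row: group label, session, optional clinical score."""

    subject_id: str
    group: str
    session: str = "none"
    bprs: Optional[float] = None
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.bprs is not None and self.bprs < 0:
            raise ValueError("BPRS score must be nonnegative")


# ---------------------------------------------------------------------------
# Recording readers / writers
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    expected_montage: Montage = DEFAULT_MONTAGE,
    fs_expected: Optional[float] = None,
) -> EEGRecording:
    """Read an EDF file or a delimited text matrix into canonical channel order.

    Channels are matched case-insensitively against *expected_montage* and
    reordered; a montage channel absent from the file raises ``KeyError``.
    If *fs_expected* is given and disagrees with the file's sampling rate,
    a ``ValueError`` is raised.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        labels, data, fs = _read_edf(path)
    else:
        labels, data, fs = _read_text_recording(path)
    if fs_expected is not None and abs(fs - fs_expected) > 1e-9:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz does not match expected {fs_expected} Hz"
        )
    perm = expected_montage.permutation_from(labels)
    return EEGRecording(
        montage=expected_montage,
        data=np.ascontiguousarray(data[perm]),
        fs=fs,
        subject_id=path.stem,
    )


def _read_edf(path: Path) -> tuple[list[str], np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; the pipeline works in uV
    # EDF convention prefixes the signal type ("EEG Fp1"); drop it for matching
    labels = [n[4:] if n.upper().startswith("EEG ") else n for n in raw.ch_names]
    return labels, data, float(raw.info["sfreq"])


def _read_text_recording(path: Path) -> tuple[list[str], np.ndarray, float]:
    """Plain-text recording: ``# fs=<Hz>`` header line, then one
    tab-delimited row per channel (label followed by samples)."""
    fs = None
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path, "r", newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].replace(",", " ").split():
                    if tok.startswith("fs="):
                        fs = float(tok[3:])
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append(np.array([float(v) for v in parts[1:]]))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
    if not rows:
        raise ValueError(f"{path}: no channel rows")
    n = {r.size for r in rows}
    if len(n) != 1:
        raise ValueError(f"{path}: channels have unequal sample counts")
    return labels, np.vstack(rows), fs


def write_recording_text(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the plain-text format read by ``read_recording``.

    Floats use shortest round-trip ``repr`` so read(write(x)) is bit-exact.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs!r} subject={rec.subject_id}\n")
        for lbl, row in zip(rec.montage.labels, rec.data):
            fh.write(lbl + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Minimal EDF writer
# ---------------------------------------------------------------------------
# EDF stores 16-bit integers scaled per channel between a physical min/max;
# records are 1 s long.  This writer emits plain EDF (not EDF+), enough for
# interchange of continuous resting-state data, and is validated against the
# mne reader.  Written here because no installed library exports EDF.

def write_recording_edf(rec: EEGRecording, path: str | Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s data record
    n_ch = len(rec.montage)
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    data = rec.data[:, : n_rec * spr]

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    hdr = io.BytesIO()
    hdr.write(pad("0", 8))
    hdr.write(pad(f"subject {rec.subject_id}"[:80], 80))
    hdr.write(pad("plihub synthetic recording"[:80], 80))
    hdr.write(pad("01.01.00", 8))
    hdr.write(pad("00.00.00", 8))
    hdr.write(pad(str(256 * (1 + n_ch)), 8))
    hdr.write(pad("", 44))
    hdr.write(pad(str(n_rec), 8))
    hdr.write(pad("1", 8))  # record duration, seconds
    hdr.write(pad(str(n_ch), 4))
    for lbl in rec.montage.labels:
        hdr.write(pad(f"EEG {lbl}", 16))
    for _ in range(n_ch):
        hdr.write(pad("", 80))  # transducer
    for _ in range(n_ch):
        hdr.write(pad("uV", 8))
    for v in phys_min:
        hdr.write(pad(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        hdr.write(pad(f"{v:.8g}"[:8], 8))
    for _ in range(n_ch):
        hdr.write(pad(str(dig_min), 8))
    for _ in range(n_ch):
        hdr.write(pad(str(dig_max), 8))
    for _ in range(n_ch):
        hdr.write(pad("", 80))  # prefiltering
    for _ in range(n_ch):
        hdr.write(pad(str(spr), 8))
    for _ in range(n_ch):
        hdr.write(pad("", 32))

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())  # channel-sequential within record


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Dispatch on suffix: ``.edf`` binary EDF, anything else plain text."""
    if Path(path).suffix.lower() == ".edf":
        write_recording_edf(rec, path)
    else:
        write_recording_text(rec, path)


# ---------------------------------------------------------------------------
# Labelled matrices and tidy tables
# ---------------------------------------------------------------------------

def write_matrix(
    matrix: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    path: str | Path,
) -> None:
    """Write a labelled matrix as tab-delimited text.

    Floats use shortest round-trip ``repr`` so ``read_matrix`` recovers the
    exact float64 values.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(row_labels), len(col_labels)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(row_labels)} row / {len(col_labels)} column labels"
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["", *col_labels])
        for lbl, row in zip(row_labels, matrix):
            w.writerow([lbl, *[repr(float(v)) for v in row]])


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_matrix`."""
    with open(path, "r", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    col_labels = rows[0][1:]
    row_labels = [r[0] for r in rows[1:]]
    matrix = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return matrix, row_labels, col_labels


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    """Metadata CSV with columns subject_id, group, session, bprs, age."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    metas = []
    for _, row in df.iterrows():
        bprs = row.get("bprs")
        age = row.get("age")
        metas.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                session=str(row.get("session", "none")),
                bprs=None if pd.isna(bprs) else float(bprs),
                age=None if pd.isna(age) else float(age),
            )
        )
    return metas


def write_metadata(metas: Sequence[SubjectMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in metas],
            "group": [m.group for m in metas],
            "session": [m.session for m in metas],
            "bprs": [m.bprs for m in metas],
            "age": [m.age for m in metas],
        }
    )
    df.to_csv(path, index=False)
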