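"""Readers and writers for EEG and task-log interchange formats.

BrainVision (.vhdr/.vmrk/.eeg, IEEE float32 multiplexed, microvolts) and EDF
(16-bit) files are written with minimal standard-conforming writers and read
back through MNE's readers.  An internal HDF5 container round-trips the full
:class:`~envconn.recording.SensorRecording` including processing history.
Electrode positions travel in whitespace-delimited text sidecars
(label x y z, millimetres); keypress logs in TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import KeypressLog
from .recording import SensorRecording


# ---------------------------------------------------------------------------
# electrode position sidecars
# ---------------------------------------------------------------------------

def write_positions(path: str | Path, labels: list[str], positions: np.ndarray) -> None:
    with open(path, "w") as fh:
        for lbl, (x, y, z) in zip(labels, positions):
            fh.write(f"{lbl} {x:.3f} {y:.3f} {z:.3f}\n")


def read_positions(path: str | Path) -> tuple[list[str], np.ndarray]:
    labels, rows = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 4:
            raise ValueError(f"malformed position line: {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return labels, np.asarray(rows)


def _sidecar_positions(
    path: Path, labels: list[str]
) -> np.ndarray | None:
    sidecar = path.with_suffix(".pos")
    if not sidecar.exists():
        return None
    lbls, pos = read_positions(sidecar)
    order = [lbls.index(l) for l in labels]
    return pos[order]


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def write_brainvision(rec: SensorRecording, vhdr_path: str | Path) -> None:
    """Write .vhdr/.vmrk/.eeg (binary multiplexed IEEE float32, microvolts)."""
    vhdr = Path(vhdr_path)
    if vhdr.suffix != ".vhdr":
        raise ValueError("BrainVision header path must end in .vhdr")
    stem = vhdr.with_suffix("")
    eeg = stem.with_suffix(".eeg")
    vmrk = stem.with_suffix(".vmrk")
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.rate:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lbl in enumerate(rec.labels):
        lines.append(f"Ch{i + 1}={lbl},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)
    if rec.positions is not None:
        write_positions(stem.with_suffix(".pos"), rec.labels, rec.positions)


def read_brainvision(vhdr_path: str | Path) -> SensorRecording:
    import mne

    vhdr = Path(vhdr_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE volts -> microvolts
    labels = list(raw.ch_names)
    return SensorRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        labels=labels,
        positions=_sidecar_positions(vhdr, labels),
        history=[f"read BrainVision {vhdr.name}"],
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(rec: SensorRecording, path: str | Path) -> None:
    """Minimal EDF writer: 16-bit samples, 1-second data records.

    The duration is truncated to whole seconds (EDF records are fixed
    length); physical scaling is per channel from the data range.
    """
    path = Path(path)
    spr = int(round(rec.rate))
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data = rec.data[:, : n_rec * spr]
    raw_min = data.min(axis=1)
    raw_max = data.max(axis=1)
    span = np.where(raw_max - raw_min <= 0, 1.0, raw_max - raw_min)
    # physical min/max live as 8-char ASCII: digitize against the *rounded*
    # header values (padded outward) or reader and writer scales disagree
    pmin = np.array([float(f"{v:.5g}") for v in raw_min - 0.001 * span])
    pmax = np.array([float(f"{v:.5g}") for v in raw_max + 0.001 * span])
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * scale[:, None]) + dmin, dmin, dmax
    ).astype("<i2")

    def pad(value: str, width: int) -> bytes:
        s = value[:width].ljust(width)
        return s.encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (nch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(nch), 4),
    ])
    header += b"".join(pad(lbl, 16) for lbl in rec.labels)
    header += b"".join(pad("", 80) for _ in range(nch))          # transducer
    header += b"".join(pad("uV", 8) for _ in range(nch))
    header += b"".join(pad(f"{v:.5g}", 8) for v in pmin)
    header += b"".join(pad(f"{v:.5g}", 8) for v in pmax)
    header += b"".join(pad(str(dmin), 8) for _ in range(nch))
    header += b"".join(pad(str(dmax), 8) for _ in range(nch))
    header += b"".join(pad("", 80) for _ in range(nch))          # prefiltering
    header += b"".join(pad(str(spr), 8) for _ in range(nch))
    header += b"".join(pad("", 32) for _ in range(nch))
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr: (r + 1) * spr].tobytes())
    if rec.positions is not None:
        write_positions(path.with_suffix(".pos"), rec.labels, rec.positions)


def read_edf(path: str | Path) -> SensorRecording:
    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    labels = list(raw.ch_names)
    return SensorRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        labels=labels,
        positions=_sidecar_positions(path, labels),
        history=[f"read EDF {path.name}"],
    )


# ---------------------------------------------------------------------------
# internal HDF5 container
# ---------------------------------------------------------------------------

def write_recording_h5(rec: SensorRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", shuffle=True)
        f.attrs["rate"] = rec.rate
        f.attrs["labels"] = rec.labels
        f.attrs["reference"] = rec.reference
        f.attrs["history"] = rec.history or [""]
        f.create_dataset("bad_mask", data=rec.bad_mask)
        if rec.positions is not None:
            f.create_dataset("positions", data=rec.positions)


def read_recording_h5(path: str | Path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        history = [h for h in list(f.attrs["history"]) if h]
        return SensorRecording(
            data=f["data"][()],
            rate=float(f.attrs["rate"]),
            labels=list(f.attrs["labels"]),
            positions=f["positions"][()] if "positions" in f else None,
            bad_mask=f["bad_mask"][()],
            reference=str(f.attrs["reference"]),
            history=history,
        )


def read_sensor_recording(path: str | Path, fmt: str | None = None) -> SensorRecording:
    """Dispatch by format: brainvision | edf | hdf5 (inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".vhdr": "brainvision", ".edf": "edf", ".h5": "hdf5",
               ".hdf5": "hdf5"}.get(path.suffix.lower())
    if fmt == "brainvision":
        return read_brainvision(path)
    if fmt == "edf":
        return read_edf(path)
    if fmt == "hdf5":
        return read_recording_h5(path)
    raise ValueError(f"unsupported recording format for {path.name}")


# ---------------------------------------------------------------------------
# keypress logs and connectivity containers
# ---------------------------------------------------------------------------

def write_keypress_tsv(log: KeypressLog, path: str | Path) -> None:
    log.events.to_csv(path, sep="\t", index=False)


def read_keypress_tsv(path: str | Path) -> KeypressLog:
    return KeypressLog(events=pd.read_csv(path, sep="\t"))


def write_band_connectivity_h5(conn, path: str | Path) -> None:
    """Store /subject/session/band matrices with ROI labels."""
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"{conn.subject or 'subject'}/{conn.session or 'session'}")
        grp.attrs["roi_names"] = list(conn.roi_names)
        for band, mat in conn.z.items():
            if band in grp:
                del grp[band]
            grp.create_dataset(band, data=mat)


def band_connectivity_long(conn) -> pd.DataFrame:
    """Flattened long format: subject, session, band, roi_i, roi_j, z."""
    rows = []
    names = conn.roi_names
    for band, mat in conn.z.items():
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append((conn.subject, conn.session, band,
                             names[i], names[j], mat[i, j]))
    return pd.DataFrame(
        rows, columns=["subject", "session", "band", "roi_i", "roi_j", "z"]
    )
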