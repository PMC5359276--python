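"""Readers and writers for the formats the platform touches.

EEG travels as BrainVision triplets (.vhdr INI header, .vmrk marker file,
.eeg 32-bit float multiplexed binary) -- the most interoperable dialect of
the format.  BOLD series travel as 4-D NIfTI-1 with the TR in the time
pixdim.  All writes are atomic (temp file + rename), so an aborted session
never leaves truncated files behind.  Sample indices are 0-based
internally; the 1-based convention of .vmrk files is confined to this
module.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
import warnings
from contextlib import contextmanager
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import EegStream, MarkerEvent, VolumeSeries, MARKER_KINDS
from .protocol import Block, ProtocolSpec, validate_protocol
from .synthetic import SimConfig


@contextmanager
def atomic_write(path, mode="w", **kwargs):
    """Write to a temp file in the target directory, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, mode, **kwargs) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision(stream: EegStream, basepath) -> Path:
    """Write a stream as a BrainVision triplet; returns the .vhdr path.

    Data are stored as IEEE float32, multiplexed.  Marker kinds map to the
    .vmrk type field and labels to the description field; positions are
    converted to the file's 1-based convention.
    """
    if stream.n_channels == 0:
        raise ValueError("refusing to write a stream with no channels")
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    interval_us = 1e6 / stream.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={stream.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(stream.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,1,µV")
    with atomic_write(vhdr, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for n, m in enumerate(stream.markers, start=2):
        mlines.append(f"Mk{n}={m.kind},{m.label},{m.sample + 1},1,0")
    with atomic_write(vmrk, "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")

    with atomic_write(eeg, "wb") as fh:
        fh.write(np.asfortranarray(
            stream.data.astype(np.float32)
        ).T.tobytes(order="C"))  # multiplexed: sample-major
    return vhdr


def _parse_ini(path) -> dict:
    sections: dict = {}
    current = None
    for ln, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(";") or line.startswith("Brain Vision"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line:
            if current is None:
                raise ValueError(f"{path}: line {ln}: key outside any section")
            k, v = line.split("=", 1)
            sections[current][k.strip()] = v.strip()
        else:
            raise ValueError(f"{path}: line {ln}: malformed entry {line!r}")
    return sections


def read_brainvision(vhdr_path) -> EegStream:
    """Read a BrainVision triplet back into an :class:`EegStream`."""
    vhdr_path = Path(vhdr_path)
    hdr = _parse_ini(vhdr_path)
    try:
        common = hdr["Common Infos"]
        n_ch = int(common["NumberOfChannels"])
        fs = 1e6 / float(common["SamplingInterval"])
        data_file = vhdr_path.parent / common["DataFile"]
        fmt = hdr["Binary Infos"]["BinaryFormat"]
        orientation = common.get("DataOrientation", "MULTIPLEXED")
    except KeyError as e:
        raise ValueError(f"{vhdr_path}: missing required header key {e}") from e
    if fmt != "IEEE_FLOAT_32":
        raise ValueError(f"unsupported BinaryFormat {fmt!r} (writer emits IEEE_FLOAT_32)")
    if orientation != "MULTIPLEXED":
        raise ValueError(f"unsupported DataOrientation {orientation!r}")
    labels = []
    for i in range(1, n_ch + 1):
        entry = hdr["Channel Infos"][f"Ch{i}"]
        labels.append(entry.split(",")[0])
    if not data_file.exists():
        raise FileNotFoundError(f"header references missing data file {data_file}")
    raw = np.fromfile(data_file, dtype=np.float32)
    if raw.size % n_ch:
        raise ValueError("data file length is not a multiple of the channel count")
    data = raw.reshape(-1, n_ch).T.astype(np.float64)

    markers = []
    vmrk = vhdr_path.parent / common.get("MarkerFile", vhdr_path.stem + ".vmrk")
    if not vmrk.exists():
        warnings.warn(f"marker file {vmrk} missing: stream loaded without markers")
    else:
        mhdr = _parse_ini(vmrk)
        for key in sorted(mhdr.get("Marker Infos", {}),
                          key=lambda k: int(k[2:])):
            fields = mhdr["Marker Infos"][key].split(",")
            kind, label, pos = fields[0], fields[1], int(fields[2])
            if kind in MARKER_KINDS:
                markers.append(MarkerEvent(kind, pos - 1, label))
    return EegStream(data, fs, labels, markers)


# ---------------------------------------------------------------------------
# NIfTI-1


def write_nifti(series: VolumeSeries, path) -> Path:
    """Write a volume series as 4-D NIfTI-1 with the TR in pixdim[4]."""
    path = Path(path)
    img_data = np.transpose(series.data, (1, 2, 3, 0))
    img = nib.Nifti1Image(img_data, series.affine)
    vx = series.voxel_sizes()
    img.header.set_zooms((*vx, series.tr))
    img.header.set_xyzt_units("mm", "sec")
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_nifti(path) -> VolumeSeries:
    """Read a 3-D or 4-D NIfTI-1 image into a :class:`VolumeSeries`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected a 3-D or 4-D image, got {data.ndim}-D")
    tr = float(img.header["pixdim"][4]) or 1.0
    series = VolumeSeries(np.transpose(data, (3, 0, 1, 2)), tr=tr,
                          affine=np.asarray(img.affine))
    return series


def write_volume(volume: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a single 3-D map (activation map, ROI mask) as NIfTI-1."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("write_volume expects a 3-D array")
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.astype(np.float64), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# configuration


def _load_yaml_checked(path, allowed: set, kind: str) -> dict:
    raw = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(raw) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: {kind} config must be a mapping")
    unknown = sorted(set(doc) - allowed)
    if unknown:
        raise ValueError(
            f"{path}: unknown {kind} config keys: {', '.join(unknown)}"
        )
    doc["__hash__"] = hashlib.sha256(raw.encode()).hexdigest()
    return doc


_SIM_KEYS = {
    "seed", "n_channels", "fs_eeg", "tr", "n_volumes", "grid_shape",
    "artifact_gain", "heart_rate", "heart_jitter_sd", "erd_depth",
    "drift_slope", "noise_sd_eeg", "noise_sd_bold", "osc_amp", "bcg_amp",
    "bold_beta", "bold_baseline",
}


def load_sim_config(path) -> SimConfig:
    doc = _load_yaml_checked(path, _SIM_KEYS, "simulation")
    source_hash = doc.pop("__hash__")
    if "grid_shape" in doc:
        doc["grid_shape"] = tuple(doc["grid_shape"])
    cfg = SimConfig(**doc)
    cfg.source_hash = source_hash
    return cfg


_PROTOCOL_KEYS = {"mode", "update_period", "repetitions", "blocks"}
_BLOCK_KEYS = {"kind", "duration", "range"}


def load_protocol(path) -> ProtocolSpec:
    doc = _load_yaml_checked(path, _PROTOCOL_KEYS, "protocol")
    source_hash = doc.pop("__hash__")
    blocks = []
    for i, b in enumerate(doc.pop("blocks", [])):
        unknown = sorted(set(b) - _BLOCK_KEYS)
        if unknown:
            raise ValueError(
                f"{path}: block {i}: unknown keys: {', '.join(unknown)}"
            )
        rng = b.get("range")
        blocks.append(Block(
            kind=b["kind"],
            duration=b.get("duration"),
            duration_range=tuple(rng) if rng is not None else None,
        ))
    spec = validate_protocol(ProtocolSpec(blocks=blocks, **doc))
    spec.source_hash = source_hash
    return spec


# ---------------------------------------------------------------------------
# logs and sidecars


def write_event_log(rows, path) -> Path:
    """TSV event log: tick, time_s, event, detail."""
    path = Path(path)
    with atomic_write(path, "w", encoding="utf-8") as fh:
        fh.write("tick\ttime_s\tevent\tdetail\n")
        for tick, t, event, detail in rows:
            fh.write(f"{tick}\t{t:.6f}\t{event}\t{detail}\n")
    return path


def write_nfb_log(frame, path) -> Path:
    """Tidy CSV feedback log (one row per modality per update tick)."""
    path = Path(path)
    with atomic_write(path, "w", encoding="utf-8", newline="") as fh:
        frame.to_csv(fh, index=False, float_format="%.10g")
    return path


def save_ground_truth(truth, path) -> Path:
    """Sidecar archive of the generator's ground truth (npz)."""
    path = Path(path)
    payload = {k: v for k, v in vars(truth).items() if v is not None}
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".npz")
    os.close(fd)
    try:
        np.savez_compressed(tmp, **payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path
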