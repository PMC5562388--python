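"""File formats: SNIRF (HDF5), flat CSV, and YAML run configuration.

SNIRF files follow the shared-format layout (formatVersion, nirs/data1 with
dataTimeSeries + per-channel measurementList entries, probe geometry,
metaDataTags); raw recordings additionally carry the backlight slot as an
aux series.  CSV files are plain comma-separated tables with a time column
and one column per channel x wavelength, preceded by ``#`` comment lines
holding sampling and channel metadata so they round-trip.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .acquisition import RawRecording
from .instrument import Channel

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_snirf_concentrations",
    "read_snirf_concentrations",
    "write_raw_csv",
    "read_raw_csv",
    "write_concentration_csv",
    "read_concentration_csv",
    "load_config",
    "dump_config",
    "config_hash",
]

_SNIRF_VERSION = "1.0"


def _str_ds(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(recording: RawRecording, path) -> Path:
    """Write a raw recording as a SNIRF-conformant HDF5 file.

    Validates the data model before touching the file: a recording with no
    samples or no channels is rejected as a schema violation.
    """
    n_ch, n_wl, n_t = recording.intensity.shape
    if n_t == 0 or n_ch == 0:
        raise ValueError("empty recording violates the SNIRF schema")
    path = Path(path)
    # module ids -> 1-based probe indices
    mod_ids = sorted({c.source_module for c in recording.channels}
                     | {c.detector_module for c in recording.channels})
    mod_index = {m: i + 1 for i, m in enumerate(mod_ids)}
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", _SNIRF_VERSION)
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        _str_ds(meta, "SubjectID", str(recording.meta.get("subject", "sim")))
        _str_ds(meta, "MeasurementDate", "unknown")
        _str_ds(meta, "MeasurementTime", "unknown")
        _str_ds(meta, "LengthUnit", "mm")
        _str_ds(meta, "TimeUnit", "s")
        _str_ds(meta, "FrequencyUnit", "Hz")
        _str_ds(meta, "seed", str(recording.meta.get("seed", "")))
        data = nirs.create_group("data1")
        series = recording.intensity.reshape(n_ch * n_wl, n_t).T  # (T, M)
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=recording.time)
        m = 0
        for ch in recording.channels:
            for j in range(n_wl):
                m += 1
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=mod_index[ch.source_module])
                ml.create_dataset("detectorIndex", data=mod_index[ch.detector_module])
                ml.create_dataset("wavelengthIndex", data=j + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths))
        pos = np.zeros((len(mod_ids), 2))
        probe.create_dataset("sourcePos2D", data=pos)
        probe.create_dataset("detectorPos2D", data=pos)
        aux = nirs.create_group("aux1")
        _str_ds(aux, "name", "backlight")
        aux.create_dataset("dataTimeSeries", data=recording.backlight.T)
        aux.create_dataset("time", data=recording.time)
        # channel metadata needed to reconstruct the data model exactly
        ext = nirs.create_group("nirstwin")
        ext.create_dataset("channel_sds", data=[c.sds for c in recording.channels])
        ext.create_dataset(
            "channel_kinds", data=[np.bytes_(c.kind) for c in recording.channels]
        )
        ext.create_dataset(
            "channel_sources", data=[c.source_module for c in recording.channels]
        )
        ext.create_dataset(
            "channel_detectors", data=[c.detector_module for c in recording.channels]
        )
        ext.create_dataset("active", data=recording.active.astype(np.uint8))
    return path


def read_snirf(path) -> RawRecording:
    """Read back a recording written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        time = np.asarray(nirs["data1/time"])
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        ext = nirs["nirstwin"]
        channels = [
            Channel(int(s), int(d), float(sds), k.decode())
            for s, d, sds, k in zip(
                ext["channel_sources"],
                ext["channel_detectors"],
                ext["channel_sds"],
                ext["channel_kinds"],
            )
        ]
        n_ch, n_wl = len(channels), len(wavelengths)
        series = np.asarray(nirs["data1/dataTimeSeries"]).T.reshape(
            n_ch, n_wl, len(time)
        )
        backlight = np.asarray(nirs["aux1/dataTimeSeries"]).T
        active = np.asarray(ext["active"]).astype(bool)
        seed = nirs["metaDataTags/seed"][()].decode()
    fs = 1.0 / (time[1] - time[0]) if len(time) > 1 else 0.0
    meta = {"seed": int(seed)} if seed else {}
    return RawRecording(
        channels=channels,
        wavelengths=wavelengths,
        time=time,
        intensity=series,
        backlight=backlight,
        active=active,
        fs=fs,
        meta=meta,
    )


def write_snirf_concentrations(
    time_s: np.ndarray, conc_um: np.ndarray, path, wavelengths=(774.0, 817.0, 865.0, 892.0)
) -> Path:
    """Write reconstructed chromophore series as a SNIRF processed block
    (dataType 99999, one measurement list entry per chromophore)."""
    conc = np.atleast_2d(np.asarray(conc_um, dtype=float))
    if conc.shape[1] == 0:
        raise ValueError("empty concentration series violates the SNIRF schema")
    path = Path(path)
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", _SNIRF_VERSION)
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        _str_ds(meta, "SubjectID", "sim")
        _str_ds(meta, "MeasurementDate", "unknown")
        _str_ds(meta, "MeasurementTime", "unknown")
        _str_ds(meta, "LengthUnit", "mm")
        _str_ds(meta, "TimeUnit", "s")
        _str_ds(meta, "FrequencyUnit", "Hz")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=conc.T)
        data.create_dataset("time", data=np.asarray(time_s))
        for m in range(conc.shape[0]):
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=1)
            ml.create_dataset("detectorIndex", data=1)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeIndex", data=m + 1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths))
        probe.create_dataset("sourcePos2D", data=np.zeros((1, 2)))
        probe.create_dataset("detectorPos2D", data=np.zeros((1, 2)))
    return path


def read_snirf_concentrations(path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        time = np.asarray(f["nirs1/data1/time"])
        conc = np.asarray(f["nirs1/data1/dataTimeSeries"]).T
    return time, conc


def _meta_header(recording: RawRecording) -> list[str]:
    lines = [
        "# nirstwin raw recording",
        f"# fs={float(recording.fs)!r}",
        f"# seed={recording.meta.get('seed', '')}",
        "# wavelengths=" + ",".join(f"{w:g}" for w in recording.wavelengths),
    ]
    for ch in recording.channels:
        lines.append(f"# channel {ch.label} kind={ch.kind} sds={float(ch.sds)!r}")
    return lines


def write_raw_csv(recording: RawRecording, path) -> Path:
    """Flat CSV: time column + one column per channel x wavelength +
    per-channel backlight, with ``#`` metadata lines for round-tripping."""
    path = Path(path)
    buf = _io.StringIO()
    recording.to_dataframe().to_csv(buf, index=False, lineterminator="\n")
    path.write_text("\n".join(_meta_header(recording)) + "\n" + buf.getvalue())
    return path


def read_raw_csv(path) -> RawRecording:
    path = Path(path)
    fs = None
    seed = ""
    wavelengths: tuple[float, ...] = ()
    channels: list[Channel] = []
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("seed="):
                seed = body[5:]
            elif body.startswith("wavelengths="):
                wavelengths = tuple(float(w) for w in body[12:].split(","))
            elif body.startswith("channel "):
                _, label, kind_kv, sds_kv = body.split()
                src, det = label[1:].split("D")
                channels.append(
                    Channel(int(src), int(det), float(sds_kv.split("=")[1]),
                            kind_kv.split("=")[1])
                )
    df = pd.read_csv(path, comment="#")
    n_t = len(df)
    intensity = np.empty((len(channels), len(wavelengths), n_t))
    backlight = np.empty((len(channels), n_t))
    for i, ch in enumerate(channels):
        for j, wl in enumerate(wavelengths):
            intensity[i, j] = df[f"{ch.label}_{wl:.0f}nm"].to_numpy()
        backlight[i] = df[f"{ch.label}_backlight"].to_numpy()
    meta = {"seed": int(seed)} if seed else {}
    return RawRecording(
        channels=channels,
        wavelengths=wavelengths,
        time=df.time_s.to_numpy(),
        intensity=intensity,
        backlight=backlight,
        active=np.ones_like(backlight, dtype=bool),
        fs=fs if fs else 1.0 / (df.time_s[1] - df.time_s[0]),
        meta=meta,
    )


def write_concentration_csv(time_s, conc_um: np.ndarray, path, meta: dict | None = None) -> Path:
    """Chromophore series (rows O2Hb, HHb[, oxCCO], muM) to CSV."""
    path = Path(path)
    names = ["o2hb_um", "hhb_um", "oxcco_um"][: conc_um.shape[0]]
    df = pd.DataFrame({"time_s": time_s, **dict(zip(names, conc_um))})
    header = ["# nirstwin concentrations"]
    for k, v in (meta or {}).items():
        header.append(f"# {k}={v}")
    buf = _io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text("\n".join(header) + "\n" + buf.getvalue())
    return path


def read_concentration_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    conc = df[[c for c in df.columns if c != "time_s"]].to_numpy().T
    return df.time_s.to_numpy(), conc


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping (provenance tag)."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
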