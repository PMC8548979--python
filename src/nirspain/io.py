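"""Recording containers: SNIRF-style HDF5 and a plain CSV/JSON directory.

Two interchangeable on-disk forms are supported:

* ``*.snirf`` / ``*.h5`` — an HDF5 file following the SNIRF layout
  (``/nirs/data1`` intensity block with per-measurement source/detector/
  wavelength lists, a probe group, one stim group per condition).
* a directory — one CSV intensity matrix per wavelength (time x channels),
  an events CSV, and a JSON metadata file; handy for dependency-free
  inspection and text-only fixtures.

Both round-trip :class:`~nirspain.probe.RawIntensityRecording` losslessly
(metadata exactly, samples to float64 representation).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from nirspain.probe import (
    EventDesign,
    FormatError,
    ProbeLayout,
    RawIntensityRecording,
)

_FORMAT_VERSION = "1.0"


def save_recording(rec: RawIntensityRecording, path: str | Path) -> None:
    """Write a recording; HDF5 for ``.snirf``/``.h5`` paths, else a directory."""
    path = Path(path)
    if path.suffix.lower() in (".snirf", ".h5"):
        _save_hdf5(rec, path)
    else:
        _save_directory(rec, path)


def load_recording(path: str | Path) -> RawIntensityRecording:
    """Read a recording written by :func:`save_recording` and validate it."""
    path = Path(path)
    if path.suffix.lower() in (".snirf", ".h5"):
        if not path.exists():
            raise FormatError(f"{path} does not exist")
        return _load_hdf5(path)
    if path.is_dir():
        return _load_directory(path)
    raise FormatError(f"{path} is neither an HDF5 recording nor a directory")


def _layout_meta(layout: ProbeLayout) -> dict:
    return {
        "emitters": list(layout.emitters),
        "detectors": list(layout.detectors),
        "channels": [list(p) for p in layout.channels],
        "wavelengths_nm": list(layout.wavelengths),
        "nominal_separation_mm": layout.nominal_separation,
        "region_map": {str(k): v for k, v in layout.region_map.items()},
    }


def _layout_from_meta(meta: dict) -> ProbeLayout:
    try:
        return ProbeLayout(
            emitters=tuple(meta["emitters"]),
            detectors=tuple(meta["detectors"]),
            channels=tuple((int(e), int(d)) for e, d in meta["channels"]),
            wavelengths=tuple(float(w) for w in meta["wavelengths_nm"]),
            nominal_separation=float(meta["nominal_separation_mm"]),
            region_map={int(k): str(v) for k, v in meta["region_map"].items()},
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"probe metadata missing field {exc}") from exc


# ---------------------------------------------------------------------------
# SNIRF-style HDF5
# ---------------------------------------------------------------------------


def _save_hdf5(rec: RawIntensityRecording, path: Path) -> None:
    n_ch, n_wl, n_t = rec.intensities.shape
    # measurement columns ordered channel-major, wavelength-minor
    data = rec.intensities.reshape(n_ch * n_wl, n_t).T
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_FORMAT_VERSION)
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.array([0.0, 1.0 / rec.sampling_rate]))
        for m, (ch, wl) in enumerate(
            (ch, wl) for ch in range(n_ch) for wl in range(n_wl)
        ):
            ml = d1.create_group(f"measurementList{m + 1}")
            e, d = rec.layout.channels[ch]
            ml.create_dataset("sourceIndex", data=int(e))
            ml.create_dataset("detectorIndex", data=int(d))
            ml.create_dataset("wavelengthIndex", data=int(wl + 1))
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.layout.wavelengths))
        probe.create_dataset(
            "sourcePos2D", data=np.zeros((len(rec.layout.emitters), 2))
        )
        probe.create_dataset(
            "detectorPos2D", data=np.zeros((len(rec.layout.detectors), 2))
        )
        for i, cond in enumerate(rec.events.conditions):
            mask = [lab == cond for lab in rec.events.labels]
            stim = nirs.create_group(f"stim{i + 1}")
            stim.create_dataset("name", data=cond)
            block = np.column_stack(
                [
                    rec.events.onsets[mask],
                    rec.events.durations[mask],
                    np.ones(int(np.sum(mask))),
                ]
            )
            stim.create_dataset("data", data=block)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset(
            "nirspain",
            data=json.dumps(
                {
                    "subject": rec.subject,
                    "group": rec.group,
                    "visit": rec.visit,
                    "sampling_rate_hz": rec.sampling_rate,
                    "phases": {k: list(v) for k, v in rec.phases.items()},
                    "layout": _layout_meta(rec.layout),
                }
            ),
        )


def _read_scalar(ds) -> str:
    val = ds[()]
    if isinstance(val, bytes):
        return val.decode()
    return str(val)


def _load_hdf5(path: Path) -> RawIntensityRecording:
    with h5py.File(path, "r") as f:
        try:
            nirs = f["nirs"]
            d1 = nirs["data1"]
            data = np.asarray(d1["dataTimeSeries"], dtype=float)
            meta = json.loads(_read_scalar(nirs["metaDataTags"]["nirspain"]))
            if "probe" not in nirs or "wavelengths" not in nirs["probe"]:
                raise FormatError(f"{path}: missing probe wavelength table")
        except KeyError as exc:
            raise FormatError(f"{path}: malformed container, missing {exc}") from exc
        layout = _layout_from_meta(meta["layout"])
        n_ch = layout.n_channels
        n_wl = len(layout.wavelengths)
        if data.shape[1] != n_ch * n_wl:
            raise FormatError(
                f"{path}: dataTimeSeries has {data.shape[1]} measurement "
                f"columns, expected {n_ch * n_wl} (channels x wavelengths)"
            )
        intensities = data.T.reshape(n_ch, n_wl, -1)
        onsets, durations, labels = [], [], []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            cond = _read_scalar(nirs[key]["name"])
            block = np.atleast_2d(np.asarray(nirs[key]["data"], dtype=float))
            for row in block:
                onsets.append(row[0])
                durations.append(row[1])
                labels.append(cond)
    order = np.argsort(onsets) if onsets else []
    events = EventDesign(
        onsets=np.asarray(onsets, float)[order] if len(onsets) else np.array([]),
        durations=np.asarray(durations, float)[order] if len(onsets) else np.array([]),
        labels=[labels[i] for i in order] if len(onsets) else [],
    )
    return RawIntensityRecording(
        layout=layout,
        sampling_rate=float(meta["sampling_rate_hz"]),
        intensities=intensities,
        events=events,
        subject=meta_subject(meta, path),
        group=meta["group"],
        visit=int(meta["visit"]),
        phases={k: (float(a), float(b)) for k, (a, b) in meta["phases"].items()},
    )


def meta_subject(meta: dict, path: Path) -> str:
    # SubjectID lives in metaDataTags for SNIRF readers; the JSON sidecar is
    # authoritative for the rest, so recover the id from the file name when
    # older files lack it.
    return meta.get("subject") or path.stem


# ---------------------------------------------------------------------------
# CSV/JSON directory fallback
# ---------------------------------------------------------------------------


def _save_directory(rec: RawIntensityRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    n_ch, n_wl, _ = rec.intensities.shape
    for w in range(n_wl):
        df = pd.DataFrame(
            rec.intensities[:, w, :].T,
            columns=[f"ch{c}" for c in rec.layout.channel_ids],
        )
        df.to_csv(path / f"intensity_{int(rec.layout.wavelengths[w])}nm.csv",
                  index=False, float_format="%.17g")
    rec.events.to_frame().to_csv(path / "events.csv", index=False,
                                 float_format="%.17g")
    meta = {
        "subject": rec.subject,
        "group": rec.group,
        "visit": rec.visit,
        "sampling_rate_hz": rec.sampling_rate,
        "phases": {k: list(v) for k, v in rec.phases.items()},
        "layout": _layout_meta(rec.layout),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def _load_directory(path: Path) -> RawIntensityRecording:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"{path}: missing metadata.json")
    meta = json.loads(meta_path.read_text())
    if "layout" not in meta or "wavelengths_nm" not in meta["layout"]:
        raise FormatError(f"{path}: metadata missing wavelength table")
    layout = _layout_from_meta(meta["layout"])
    blocks = []
    for w in layout.wavelengths:
        f = path / f"intensity_{int(w)}nm.csv"
        if not f.exists():
            raise FormatError(f"{path}: missing intensity file for {w} nm")
        blocks.append(
            pd.read_csv(f, float_precision="round_trip").to_numpy(float).T
        )
    intensities = np.stack(blocks, axis=1)
    events_df = pd.read_csv(path / "events.csv", float_precision="round_trip")
    events = (
        EventDesign.from_frame(events_df)
        if len(events_df)
        else EventDesign(np.array([]), np.array([]), [])
    )
    return RawIntensityRecording(
        layout=layout,
        sampling_rate=float(meta["sampling_rate_hz"]),
        intensities=intensities,
        events=events,
        subject=str(meta["subject"]),
        group=meta["group"],
        visit=int(meta["visit"]),
        phases={k: (float(a), float(b)) for k, (a, b) in meta["phases"].items()},
    )
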