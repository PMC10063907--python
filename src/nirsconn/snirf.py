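"""SNIRF (HDF5) reader/writer for raw-intensity scans.

Implements the subset of the SNIRF v1.0 layout the pipeline consumes:
``/nirs/data1`` with ``dataTimeSeries``/``time`` and one ``measurementListN``
group per (channel, wavelength) column, ``/nirs/probe`` with optode positions
and wavelengths, and ``/nirs/stimN`` blocks for stimulation events. Channel
region labels, which core SNIRF does not model, travel as a JSON entry in
``metaDataTags``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .probe import Probe
from .scan import INTENSITY, Scan

_STR = h5py.string_dtype(encoding="utf-8")


def write_snirf(path: str | Path, scan: Scan) -> Path:
    """Write a raw-intensity scan as a SNIRF file."""
    if scan.kind != INTENSITY:
        raise ValueError("SNIRF export is defined for raw intensity scans")
    path = Path(path)
    probe = scan.probe
    nch, nwl = probe.n_channels, probe.n_wavelengths
    # columns ordered channel-major: (ch0,wl0), (ch0,wl1), ...
    flat = scan.data.reshape(scan.n_samples, nch * nwl)

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID",
                            data=str(scan.meta.get("subject", "sim")), dtype=_STR)
        meta.create_dataset("MeasurementDate", data="2000-01-01", dtype=_STR)
        meta.create_dataset("MeasurementTime", data="00:00:00", dtype=_STR)
        meta.create_dataset("LengthUnit", data="mm", dtype=_STR)
        meta.create_dataset("TimeUnit", data="s", dtype=_STR)
        meta.create_dataset("FrequencyUnit", data="Hz", dtype=_STR)
        meta.create_dataset("ChannelRegions",
                            data=json.dumps(list(probe.regions)), dtype=_STR)
        meta.create_dataset("Provenance", data=json.dumps(
            {k: scan.meta[k] for k in ("subject", "group", "week", "stimulus")
             if k in scan.meta}), dtype=_STR)

        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=flat)
        data1.create_dataset("time", data=scan.times)
        m = 1
        for ch, (s, d) in enumerate(probe.channels):
            for w in range(nwl):
                ml = data1.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=s + 1)
                ml.create_dataset("detectorIndex", data=d + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)        # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1

        pg = nirs.create_group("probe")
        pg.create_dataset("wavelengths", data=np.asarray(probe.wavelengths))
        src3 = np.column_stack([probe.source_pos, np.zeros(len(probe.source_pos))])
        det3 = np.column_stack([probe.detector_pos, np.zeros(len(probe.detector_pos))])
        pg.create_dataset("sourcePos2D", data=probe.source_pos)
        pg.create_dataset("detectorPos2D", data=probe.detector_pos)
        pg.create_dataset("sourcePos3D", data=src3)
        pg.create_dataset("detectorPos3D", data=det3)
        pg.create_dataset("sourceLabels", data=[f"S{i+1}" for i in
                                                range(len(probe.source_pos))],
                          dtype=_STR)
        pg.create_dataset("detectorLabels", data=[f"D{i+1}" for i in
                                                  range(len(probe.detector_pos))],
                          dtype=_STR)

        for i, (onset, dur) in enumerate(scan.events, start=1):
            st = nirs.create_group(f"stim{i}")
            st.create_dataset("name", data="stimulation", dtype=_STR)
            st.create_dataset("data", data=np.array([[onset, dur, 1.0]]))
    return path


def _require(group, name: str):
    if name not in group:
        raise ValueError(f"malformed SNIRF file: missing {group.name}/{name}")
    return group[name]


def read_snirf(path: str | Path) -> Scan:
    """Read a SNIRF file into a raw-intensity Scan (probe and events included)."""
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs")
        data1 = _require(nirs, "data1")
        flat = np.asarray(_require(data1, "dataTimeSeries"))
        time = np.asarray(_require(data1, "time"))
        if len(time) > 1:
            fs = 1.0 / float(np.median(np.diff(time)))
        else:
            fs = 1.0

        pg = _require(nirs, "probe")
        wavelengths = tuple(float(w) for w in np.asarray(_require(pg, "wavelengths")))
        src = np.asarray(_require(pg, "sourcePos2D"))
        det = np.asarray(_require(pg, "detectorPos2D"))

        # measurement lists define the column layout
        mls = sorted((k for k in data1 if k.startswith("measurementList")),
                     key=lambda k: int(k[len("measurementList"):]))
        if not mls:
            raise ValueError("malformed SNIRF file: missing /nirs/data1/measurementList")
        cols = []
        for k in mls:
            ml = data1[k]
            cols.append((int(ml["sourceIndex"][()]) - 1,
                         int(ml["detectorIndex"][()]) - 1,
                         int(ml["wavelengthIndex"][()]) - 1))
        channels = []
        for s, d, _ in cols:
            if (s, d) not in channels:
                channels.append((s, d))
        nch, nwl = len(channels), len(wavelengths)

        data = np.empty((flat.shape[0], nch, nwl))
        for col_idx, (s, d, w) in enumerate(cols):
            data[:, channels.index((s, d)), w] = flat[:, col_idx]

        meta_g = nirs.get("metaDataTags")
        regions = None
        meta: dict = {}
        if meta_g is not None:
            if "ChannelRegions" in meta_g:
                regions = tuple(json.loads(meta_g["ChannelRegions"].asstr()[()]))
            if "Provenance" in meta_g:
                meta.update(json.loads(meta_g["Provenance"].asstr()[()]))
        if regions is None:
            regions = tuple("M1_S1" for _ in channels)

        events = []
        for k in sorted(k for k in nirs if k.startswith("stim")):
            st = np.asarray(nirs[k]["data"]).reshape(-1, 3)
            events.extend([(row[0], row[1]) for row in st])
        if not events:
            warnings.warn(f"{path}: no stimulation blocks found; empty event list")

    probe = Probe(source_pos=src, detector_pos=det, channels=tuple(channels),
                  regions=regions, wavelengths=wavelengths)
    return Scan(kind=INTENSITY, data=data, sampling_rate=fs, probe=probe,
                events=np.asarray(events, float).reshape(-1, 2), meta=meta)
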