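"""In-memory recording container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .probe import Probe

#: data kinds a Scan can hold
INTENSITY = "intensity"
OD = "od"
HB = "hb"

HB_TYPES = ("HbO2", "HbR", "HbT")


@dataclass
class Scan:
    """One fNIRS recording at some stage of processing.

    ``kind == "intensity"`` or ``"od"``: ``data`` is an array of shape
    (n_samples, n_channels, n_wavelengths).
    ``kind == "hb"``: ``data`` is a dict mapping hemoglobin type
    ("HbO2"/"HbR"/"HbT") to arrays of shape (n_samples, n_channels), in µM.

    ``events`` is an (n_events, 2) array of (onset_s, duration_s) stimulation
    marks. ``meta`` carries provenance (subject, group, week, stimulus, seed)
    and stage annotations.
    """

    kind: str
    data: np.ndarray | dict[str, np.ndarray]
    sampling_rate: float
    probe: Probe
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (INTENSITY, OD, HB):
            raise ValueError(f"unknown scan kind {self.kind!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 2)
        if self.kind == HB:
            if not isinstance(self.data, Mapping):
                raise TypeError("hb scans hold a dict of hemoglobin arrays")
            self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        else:
            self.data = np.asarray(self.data, dtype=float)
            if self.data.ndim != 3:
                raise ValueError(
                    "intensity/od data must be (n_samples, n_channels, n_wavelengths)"
                )

    @property
    def n_samples(self) -> int:
        if self.kind == HB:
            return next(iter(self.data.values())).shape[0]
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.probe.n_channels

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def hb(self, hb_type: str) -> np.ndarray:
        if self.kind != HB:
            raise ValueError("not a hemoglobin scan")
        if hb_type not in self.data:
            raise KeyError(f"hemoglobin type {hb_type!r} not present")
        return self.data[hb_type]

    def with_data(self, data, kind: str | None = None, **meta) -> "Scan":
        """Copy of this scan carrying new data (and optionally a new kind)."""
        new = replace(self, data=data, kind=kind or self.kind)
        new.meta = {**self.meta, **meta}
        return new
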