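"""Optode montage and channel geometry.

A probe is the coordinate frame of every downstream network: an ordered list
of source-detector channels, the wavelengths measured on each, and a region
label (``PFC`` or ``M1_S1``) per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PFC = "PFC"
M1S1 = "M1_S1"
REGIONS = (PFC, M1S1)

DEFAULT_WAVELENGTHS = (780.0, 805.0, 830.0)


@dataclass(frozen=True)
class Probe:
    """Grid montage: optode positions, channel pairings and region labels.

    Channels are (source_index, detector_index) pairs (0-based into
    ``source_pos`` / ``detector_pos``); ``regions[k]`` labels channel ``k``.
    """

    source_pos: np.ndarray          # (n_sources, 2) mm
    detector_pos: np.ndarray        # (n_detectors, 2) mm
    channels: tuple[tuple[int, int], ...]
    regions: tuple[str, ...]
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    nominal_distance: float = 30.0  # mm

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.channels):
            raise ValueError("one region label per channel required")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)

    @property
    def channel_names(self) -> list[str]:
        return [f"S{s + 1}_D{d + 1}" for s, d in self.channels]

    def region_indices(self, region: str) -> np.ndarray:
        """Channel indices belonging to ``region``."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.array([i for i, r in enumerate(self.regions) if r == region])

    def channel_distances(self) -> np.ndarray:
        """Euclidean source-detector distance (mm) per channel."""
        s = self.source_pos[[c[0] for c in self.channels]]
        d = self.detector_pos[[c[1] for c in self.channels]]
        return np.linalg.norm(s - d, axis=1)


def make_default_probe(pitch: float = 30.0) -> Probe:
    """Build the default 8-source / 8-detector grid montage with 20 channels.

    Optodes occupy a 4x4 grid at ``pitch`` mm spacing, sources and detectors
    alternating in a checkerboard, so every nearest-neighbour pair is a
    source-detector pair at the nominal separation. The top two rows cover the
    prefrontal cortex (PFC), the bottom two the primary motor/somatosensory
    strip (M1_S1). Of the 24 nearest-neighbour pairings the instrument
    measures 20: the outer-column vertical pairs inside the PFC patch and at
    the region boundary are not enumerated, which yields the 8 PFC / 12 M1_S1
    channel split used throughout.
    """
    n_rows = n_cols = 4
    src_pos, det_pos = [], []
    kind = {}       # (row, col) -> ("S"|"D", index)
    for r in range(n_rows):
        for c in range(n_cols):
            xy = (c * pitch, -r * pitch)
            if (r + c) % 2 == 0:
                kind[(r, c)] = ("S", len(src_pos))
                src_pos.append(xy)
            else:
                kind[(r, c)] = ("D", len(det_pos))
                det_pos.append(xy)

    def channel(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
        (ka, ia), (kb, ib) = kind[a], kind[b]
        assert ka != kb, "adjacent grid cells alternate source/detector"
        return (ia, ib) if ka == "S" else (ib, ia)

    channels: list[tuple[int, int]] = []
    regions: list[str] = []
    # horizontal pairs: all 12 measured
    for r in range(n_rows):
        for c in range(n_cols - 1):
            channels.append(channel((r, c), (r, c + 1)))
            regions.append(PFC if r <= 1 else M1S1)
    # vertical pairs: inner columns only for row 0-1 (PFC) and the 1-2 bridge
    for r in range(n_rows - 1):
        cols = (1, 2) if r <= 1 else range(n_cols)
        for c in cols:
            channels.append(channel((r, c), (r + 1, c)))
            regions.append(PFC if r == 0 else M1S1)

    return Probe(
        source_pos=np.asarray(src_pos, dtype=float),
        detector_pos=np.asarray(det_pos, dtype=float),
        channels=tuple(channels),
        regions=tuple(regions),
        wavelengths=DEFAULT_WAVELENGTHS,
        nominal_distance=pitch,
    )
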