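"""Modified Beer-Lambert law: optical density <-> hemoglobin conversion.

The forward model relates optical-density change at wavelength λ to
concentration changes of oxy- and deoxy-hemoglobin:

    ΔOD_λ = (ε_HbO2(λ)·ΔHbO2 + ε_HbR(λ)·ΔHbR) · d · DPF(λ)

with ε in cm⁻¹/M, ΔHb in µM, source-detector distance d in mm, and the
differential pathlength factor DPF scaling geometric to effective photon
path. The inverse solves the (overdetermined, 3-wavelength) linear system by
least squares per sample and channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# (ε_HbO2, ε_HbR) in cm^-1 / M at the instrument wavelengths; rounded values
# consistent with the standard compiled hemoglobin absorption spectra (HbO2
# rising and HbR falling over 780-830 nm, near-isosbestic around 805 nm).
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    780.0: (735.0, 1102.0),
    805.0: (880.0, 750.0),
    830.0: (974.0, 693.0),
}

#: unit conversion: ε[cm^-1/M] · ΔHb[µM] · path[mm·DPF] -> OD
_OD_SCALE = 1e-6 * 0.1  # µM->M and mm->cm


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients, DPF, and source-detector distance.

    ``coefficients`` maps wavelength (nm) to (ε_HbO2, ε_HbR) in cm⁻¹/M;
    ``dpf`` maps wavelength to the dimensionless differential pathlength
    factor; ``distance`` is the source-detector separation in mm.
    """

    coefficients: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    dpf: dict[float, float] | float = 6.0
    distance: float = 30.0

    def __post_init__(self) -> None:
        for wl, (eo, er) in self.coefficients.items():
            if eo <= 0 or er <= 0:
                raise ValueError(f"non-positive extinction coefficient at {wl} nm")
        if self.distance <= 0:
            raise ValueError("distance must be positive")

    def dpf_at(self, wavelength: float) -> float:
        if isinstance(self.dpf, dict):
            return self.dpf[wavelength]
        return float(self.dpf)

    def design_matrix(self, wavelengths) -> np.ndarray:
        """(n_wavelengths, 2) matrix mapping (ΔHbO2, ΔHbR) in µM to OD."""
        rows = []
        for wl in wavelengths:
            if wl not in self.coefficients:
                raise KeyError(f"wavelength {wl} nm missing from extinction table")
            eo, er = self.coefficients[wl]
            path = self.distance * self.dpf_at(wl)
            rows.append((eo * path * _OD_SCALE, er * path * _OD_SCALE))
        E = np.asarray(rows, dtype=float)
        if np.linalg.matrix_rank(E) < 2:
            raise ValueError("singular extinction matrix: wavelengths not independent")
        return E


def hb_to_od(hbo2: np.ndarray, hbr: np.ndarray, wavelengths, table: ExtinctionTable) -> np.ndarray:
    """Forward model: (n_samples, n_channels) µM pair -> (n_samples, n_channels, n_wl) OD."""
    E = table.design_matrix(wavelengths)          # (n_wl, 2)
    hb = np.stack([hbo2, hbr], axis=-1)           # (n, ch, 2)
    return hb @ E.T


def od_to_hb(od: np.ndarray, wavelengths, table: ExtinctionTable) -> tuple[np.ndarray, np.ndarray]:
    """Inverse model by least squares over the available wavelengths.

    Parameters
    ----------
    od : (n_samples, n_channels, n_wavelengths) array of ΔOD.

    Returns
    -------
    (ΔHbO2, ΔHbR) arrays of shape (n_samples, n_channels), in µM.
    """
    if len(wavelengths) < 2:
        raise ValueError("at least two wavelengths required for MBLL inversion")
    E = table.design_matrix(wavelengths)
    pinv = np.linalg.pinv(E)                      # (2, n_wl)
    hb = od @ pinv.T                              # (n, ch, 2)
    return hb[..., 0], hb[..., 1]
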