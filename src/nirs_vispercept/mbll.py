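"""Modified Beer–Lambert law: intensities -> chromophore concentration changes.

For each wavelength the optical-density change relative to baseline is

    dOD(lambda) = log10( I_b(lambda) / I_t(lambda) )
                = [ eps_HbO2(lambda) dHbO2 + eps_Hb(lambda) dHb ] * d * DPF

with eps in 1/(mM cm) and d*DPF the effective path length in cm.  Measuring
at two wavelengths gives a 2x2 linear system per sample, solved in closed
form.  Concentrations are returned in µM-equivalent relative units (they
carry the 1/(d*DPF) scale of the configured optics); every downstream
statistic is invariant to this common scale after min–max normalization.
"""

from __future__ import annotations

import numpy as np

from .config import MBLLConfig
from .containers import HemoglobinSeries, RawIntensityRecording
from .errors import ConfigurationError, DataError


def _baseline_intensity(rec: RawIntensityRecording, optics: MBLLConfig) -> np.ndarray:
    if rec.baseline is not None:
        return rec.baseline
    mask = rec.time <= rec.time[0] + optics.baseline_window_s
    if not mask.any():
        mask = np.zeros_like(rec.time, dtype=bool)
        mask[0] = True
    return rec.intensity[:, mask, :].mean(axis=1)


def invert_mbll(rec: RawIntensityRecording, optics: MBLLConfig) -> HemoglobinSeries:
    """Invert the two-wavelength Beer–Lambert system sample by sample.

    Raises :class:`DataError` naming the first offending channel/timestamp if
    any intensity is non-positive, and :class:`ConfigurationError` if the
    extinction matrix is singular (checked by ``MBLLConfig`` itself).
    """
    if rec.intensity.min() <= 0:
        ch, ti, _ = np.unravel_index(np.argmin(rec.intensity), rec.intensity.shape)
        raise DataError(
            f"non-positive intensity on channel {rec.channels[ch]!r} at t={rec.time[ti]:g} s"
        )
    baseline = _baseline_intensity(rec, optics)
    if baseline.min() <= 0:
        ch = int(np.argmin(baseline.min(axis=1)))
        raise DataError(f"non-positive baseline intensity on channel {rec.channels[ch]!r}")

    # dOD: (n_channels, n_samples, 2)
    dod = np.log10(baseline[:, None, :] / rec.intensity)
    e11, e12 = optics.eps_hbo2[0], optics.eps_hb[0]  # wavelength 1
    e21, e22 = optics.eps_hbo2[1], optics.eps_hb[1]  # wavelength 2
    det = optics.determinant
    if abs(det) < 1e-12:
        raise ConfigurationError("extinction coefficient matrix is singular")
    scale = optics.pathlength_cm * det
    # Cramer's rule on [dOD1, dOD2] = eps @ [dHbO2, dHb] * d * DPF; mM -> µM
    hbo2 = (dod[:, :, 0] * e22 - dod[:, :, 1] * e12) / scale * 1e3
    hb = (dod[:, :, 1] * e11 - dod[:, :, 0] * e21) / scale * 1e3
    return HemoglobinSeries(time=rec.time, channels=rec.channels, hbo2=hbo2, hb=hb)


def total_hemoglobin(hbo2: np.ndarray, hb: np.ndarray) -> np.ndarray:
    """Elementwise total hemoglobin dHbt = dHbO2 + dHb."""
    hbo2 = np.asarray(hbo2, dtype=float)
    hb = np.asarray(hb, dtype=float)
    if hbo2.shape != hb.shape:
        raise DataError(f"grid mismatch: {hbo2.shape} vs {hb.shape}")
    return hbo2 + hb
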