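"""Detector forward model for the cuvette geometry.

Maps a depth-resolved initial pressure profile onto a band-limited,
time-resolved detector waveform.  The planar detector faces the back window
of the cuvette, so a plane wave launched at depth ``z`` (measured from the
illuminated front window) arrives at ``t = t0 + (L - z)/c_s``: the back
window arrives first (the "early" wave caused by the step in p0 there) and
the strongly heated layers at the front window arrive last.

The detection operator is a time derivative followed by a zero-phase
Butterworth bandpass (AC-coupled velocity-potential sensing).  Modeling the
detector as differentiating makes the downstream time-integration step of
:mod:`pppa.signal_processing` a first-order inverse by construction: the
integrated waveform recovers the band-limited p0 profile.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from pppa.photophysics import DepthProfile, MediumGeometry

__all__ = ["DetectorModel", "PASignal", "cuvette_forward", "add_noise",
           "band_limit"]


@dataclass(frozen=True)
class DetectorModel:
    """Band-limited, AC-coupled planar detector.

    ``minus6dB_MHz`` documents the nominal -6 dB bandwidth; the realized
    response is a first-order high-pass at ``band_lowcut_MHz`` (RC-type AC
    coupling; kept gentle so time integration of the output remains a
    faithful first-order inverse over the cuvette transit) cascaded with a
    Butterworth low-pass of order ``order`` at ``band_highcut_MHz``, applied
    zero-phase.
    """

    band_lowcut_MHz: float = 0.02
    band_highcut_MHz: float = 37.0
    minus6dB_MHz: float = 20.0
    distance_mm: float = 10.0
    sample_rate_MHz: float = 125.0
    order: int = 4
    ac_order: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.band_lowcut_MHz < self.band_highcut_MHz:
            raise ValueError("require 0 < lowcut < highcut")
        if self.sample_rate_MHz <= 2.0 * self.band_highcut_MHz:
            raise ValueError("sample rate must exceed twice the highcut")

    def sos(self) -> np.ndarray:
        return np.vstack([
            sps.butter(self.ac_order, self.band_lowcut_MHz, btype="high",
                       fs=self.sample_rate_MHz, output="sos"),
            sps.butter(self.order, self.band_highcut_MHz, btype="low",
                       fs=self.sample_rate_MHz, output="sos"),
        ])


@dataclass
class PASignal:
    """A time-resolved detector waveform with full acquisition metadata."""

    t_us: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.t_us.shape != self.amplitude.shape:
            raise ValueError("t and amplitude must have equal shape")
        dt = np.diff(self.t_us)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform")

    @property
    def dt_us(self) -> float:
        return float(self.t_us[1] - self.t_us[0])

    def copy(self) -> "PASignal":
        return PASignal(self.t_us.copy(), self.amplitude.copy(),
                        copy.deepcopy(self.meta))


def _retarded_p0(profile: DepthProfile, t_us: np.ndarray, t0_us: float,
                 c_mm_us: float) -> np.ndarray:
    L = float(profile.meta["pathlength_mm"])
    z = L - c_mm_us * (t_us - t0_us)
    inside = (z >= 0.0) & (z <= L)
    p = np.zeros_like(t_us)
    p[inside] = np.interp(z[inside], profile.z_mm, profile.p0)
    return p


def cuvette_forward(profile: DepthProfile, det: DetectorModel | None = None,
                    geom: MediumGeometry | None = None) -> PASignal:
    """Project a depth profile onto the detector time axis.

    The emitted waveform is the time derivative of the retarded p0 profile
    convolved with the detector band response.  Raises if the depth grid is
    coarser than the acoustic resolution c_s / (2 * highcut).
    """
    det = det or DetectorModel()
    c_m_s = (geom.sound_speed_m_s if geom is not None
             else float(profile.meta.get("sound_speed_m_s", 1480.0)))
    c_mm_us = c_m_s / 1000.0
    L = float(profile.meta["pathlength_mm"])

    dz_mm = float(profile.z_mm[1] - profile.z_mm[0])
    res_mm = c_mm_us / (2.0 * det.band_highcut_MHz)
    if dz_mm > res_mm:
        raise ValueError(
            f"depth grid ({dz_mm:.4f} mm) coarser than acoustic resolution "
            f"({res_mm:.4f} mm); increase n_depth"
        )

    dt_us = 1.0 / det.sample_rate_MHz
    t0_us = det.distance_mm / c_mm_us
    t_end = t0_us + L / c_mm_us + 1.0
    t_us = np.arange(0.0, t_end, dt_us)

    p_t = _retarded_p0(profile, t_us, t0_us, c_mm_us)
    raw = np.gradient(p_t, dt_us)
    amp = sps.sosfiltfilt(det.sos(), raw)

    meta = dict(profile.meta)
    meta.update({
        "t0_us": t0_us,
        "distance_mm": det.distance_mm,
        "sample_rate_MHz": det.sample_rate_MHz,
        "band_lowcut_MHz": det.band_lowcut_MHz,
        "band_highcut_MHz": det.band_highcut_MHz,
        "sound_speed_m_s": c_m_s,
    })
    return PASignal(t_us=t_us, amplitude=amp, meta=meta)


def band_limit(x: np.ndarray, det: DetectorModel) -> np.ndarray:
    """Apply the detector band response (zero-phase) to an arbitrary trace."""
    return sps.sosfiltfilt(det.sos(), np.asarray(x, dtype=float))


def add_noise(sig: PASignal, snr_db: float, seed: int) -> PASignal:
    """Add white Gaussian noise at a target SNR (dB) relative to signal RMS.

    Reproducible per seed; ``snr_db=inf`` returns an unchanged copy.
    """
    out = sig.copy()
    out.meta.update({"seed": seed, "snr_db": snr_db})
    if np.isinf(snr_db):
        return out
    rms = float(np.sqrt(np.mean(sig.amplitude ** 2)))
    sd = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    out.amplitude = out.amplitude + rng.normal(0.0, sd, size=out.amplitude.shape)
    return out
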