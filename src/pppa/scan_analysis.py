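"""Scan protocols: pump-wavelength, probe-wavelength and delay scans.

Each scan point runs the full synthetic chain — dual-pulse rate-equation
simulation, detector projection, pulse-energy normalization, low-pass
filtering, time integration — and extracts the TIDSA (time-integrated
difference signal amplitude) of the simultaneous-minus-delayed difference
signal.  Also provides the fluence series (single-pulse vs pump-probe
spectra at several fluence levels) and excited-state lifetime recovery from
delay scans via a Gaussian-convolved exponential decay fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erfc

from pppa import signal_processing as sp
from pppa.acquisition import DetectorModel, PASignal, add_noise, cuvette_forward
from pppa.photophysics import MediumGeometry, PulsePair, simulate_dual_pulse

__all__ = [
    "ScanResult", "LifetimeFit",
    "run_pump_scan", "run_probe_scan", "run_delay_scan",
    "fit_lifetime", "fluence_series", "gaussian_exponential_decay",
    "DEFAULT_PUMP_GRID", "DEFAULT_PROBE_GRID", "DEFAULT_DELAY_GRID",
]

#: Scan grids: pump across the absorption band, probe across the emission
#: band (5 nm steps), delays 0-10 ns in 1 ns increments.
DEFAULT_PUMP_GRID = np.arange(500.0, 661.0, 5.0)
DEFAULT_PROBE_GRID = np.arange(570.0, 681.0, 5.0)
DEFAULT_DELAY_GRID = np.arange(0.0, 11.0, 1.0)

#: Fixed wavelengths: probe at 650 nm for pump scans, pump at 580 nm for
#: probe and delay scans.
DEFAULT_PROBE_NM = 650.0
DEFAULT_PUMP_NM = 580.0
#: Reference ("long") delay, well beyond all preset lifetimes.
DEFAULT_DELAY_LONG_NS = 10.0
#: Default unattenuated fluence, mJ/cm^2.
DEFAULT_FLUENCE = 12.0


@dataclass
class ScanResult:
    """TIDSA statistic versus one scanned variable."""

    variable: str                   # pump_nm | probe_nm | delay_ns | fluence
    grid: np.ndarray
    tidsa: np.ndarray
    stderr: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.tidsa = np.asarray(self.tidsa, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise ValueError("scan grid must be strictly ascending")
        if not np.all(np.isfinite(self.tidsa)):
            raise ValueError("TIDSA values must be finite")

    @property
    def peak_position(self) -> float:
        return float(self.grid[int(np.argmax(self.tidsa))])

    def normalized(self, reference: float | None = None) -> "ScanResult":
        """Copy with tidsa scaled by ``reference`` (default: its maximum)."""
        ref = float(np.max(np.abs(self.tidsa))) if reference is None \
            else float(reference)
        scale = 1.0 / ref if ref != 0 else 1.0
        out = ScanResult(self.variable, self.grid.copy(),
                         self.tidsa * scale, self.stderr * scale,
                         dict(self.config))
        out.config["normalized"] = True
        return out


@dataclass
class LifetimeFit:
    """Excited-state lifetime recovered from a delay scan."""

    tau_ns: float
    tau_stderr: float
    pulse_fwhm_ns: float
    residual_rms: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau_ns <= 0:
            raise ValueError("recovered lifetime must be positive")


def _acquire(model, pulses: PulsePair, geom, det, cutoff_MHz,
             snr_db=None, seed=0, repeats=1) -> tuple[PASignal, float]:
    """Simulate + detect + normalize + filter one acquisition setting.

    Returns the (averaged) processed signal and a scalar noise standard
    error (0 for noiseless runs).
    """
    profile = simulate_dual_pulse(model, pulses, geom)
    sig = cuvette_forward(profile, det, geom)
    mua_pu = float(model.mua(pulses.lambda_pump_nm))
    mua_pr = float(model.mua(pulses.lambda_probe_nm))
    if snr_db is None:
        reps = [sig]
    elif repeats <= 1:
        reps = [add_noise(sig, snr_db, seed)]
    else:
        reps = [add_noise(sig, snr_db, seed + i) for i in range(repeats)]
    processed = []
    for r in reps:
        r = sp.normalize_signal(r, mua_pu, mua_pr,
                                pulses.fluence_pump, pulses.fluence_probe)
        processed.append(sp.lowpass_filter(r, cutoff_MHz))
    if len(processed) == 1:
        return processed[0], 0.0
    mean, stderr = sp.average_repeats(processed)
    return mean, float(np.median(stderr))


def _scan_point(model, lambda_pu, lambda_pr, delay_long_ns, fluences,
                fwhm_ns, geom, det, cutoff_MHz, snr_db, seed, repeats):
    """TIDSA of the (dt=0) - (dt=long) difference at one scan setting."""
    common = dict(lambda_pump_nm=lambda_pu, lambda_probe_nm=lambda_pr,
                  fwhm_ns=fwhm_ns, fluence_pump=fluences[0],
                  fluence_probe=fluences[1])
    s0, e0 = _acquire(model, PulsePair(delay_ns=0.0, **common),
                      geom, det, cutoff_MHz, snr_db, seed, repeats)
    s1, e1 = _acquire(model, PulsePair(delay_ns=delay_long_ns, **common),
                      geom, det, cutoff_MHz, snr_db, seed + 10_000, repeats)
    rec = sp.difference_and_tidsa(s0, s1, stderr=float(np.hypot(e0, e1)))
    return rec.tidsa, rec.stderr


def _scan_config(**kw):
    return {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in kw.items()}


def run_pump_scan(model, pump_grid: Sequence[float] = DEFAULT_PUMP_GRID,
                  probe_nm: float = DEFAULT_PROBE_NM,
                  fluences: tuple[float, float] = (DEFAULT_FLUENCE,
                                                   DEFAULT_FLUENCE),
                  delay_long_ns: float = DEFAULT_DELAY_LONG_NS,
                  fwhm_ns: float = 3.0,
                  geom: MediumGeometry | None = None,
                  det: DetectorModel | None = None,
                  cutoff_MHz: float = 15.0,
                  snr_db: float | None = None, seed: int = 0,
                  repeats: int = 1, normalize: bool = True,
                  energy_profile: Callable[[float], float] | None = None,
                  ) -> ScanResult:
    """Pump-wavelength scan of the TIDSA at a fixed probe wavelength.

    ``energy_profile``, if given, multiplies the pump fluence by a
    wavelength-dependent factor (emulating the source pulse-energy
    spectrum); the realized fluence is what enters the normalization, as in
    a calibrated measurement.
    """
    grid = np.asarray(pump_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty pump grid")
    geom = geom or MediumGeometry()
    det = det or DetectorModel()
    tidsa, err = [], []
    for i, lam in enumerate(grid):
        fl = (fluences[0] * (energy_profile(lam) if energy_profile else 1.0),
              fluences[1])
        t, e = _scan_point(model, float(lam), probe_nm, delay_long_ns, fl,
                           fwhm_ns, geom, det, cutoff_MHz, snr_db,
                           seed + 100 * i, repeats)
        tidsa.append(t)
        err.append(e)
    res = ScanResult("pump_nm", grid, np.array(tidsa), np.array(err),
                     _scan_config(probe_nm=probe_nm, fluences=fluences,
                                  delay_long_ns=delay_long_ns,
                                  fwhm_ns=fwhm_ns, snr_db=snr_db,
                                  repeats=repeats, seed=seed,
                                  model=model.name, normalized=False))
    return res.normalized() if normalize else res


def run_probe_scan(model, probe_grid: Sequence[float] = DEFAULT_PROBE_GRID,
                   pump_nm: float = DEFAULT_PUMP_NM,
                   fluences: tuple[float, float] = (DEFAULT_FLUENCE,
                                                    DEFAULT_FLUENCE),
                   delay_long_ns: float = DEFAULT_DELAY_LONG_NS,
                   fwhm_ns: float = 3.0,
                   geom: MediumGeometry | None = None,
                   det: DetectorModel | None = None,
                   cutoff_MHz: float = 15.0,
                   snr_db: float | None = None, seed: int = 0,
                   repeats: int = 1, normalize: bool = True,
                   energy_profile: Callable[[float], float] | None = None,
                   ) -> ScanResult:
    """Probe-wavelength scan of the TIDSA at a fixed pump wavelength."""
    grid = np.asarray(probe_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty probe grid")
    geom = geom or MediumGeometry()
    det = det or DetectorModel()
    tidsa, err = [], []
    for i, lam in enumerate(grid):
        fl = (fluences[0],
              fluences[1] * (energy_profile(lam) if energy_profile else 1.0))
        t, e = _scan_point(model, pump_nm, float(lam), delay_long_ns, fl,
                           fwhm_ns, geom, det, cutoff_MHz, snr_db,
                           seed + 100 * i, repeats)
        tidsa.append(t)
        err.append(e)
    res = ScanResult("probe_nm", grid, np.array(tidsa), np.array(err),
                     _scan_config(pump_nm=pump_nm, fluences=fluences,
                                  delay_long_ns=delay_long_ns,
                                  fwhm_ns=fwhm_ns, snr_db=snr_db,
                                  repeats=repeats, seed=seed,
                                  model=model.name, normalized=False))
    return res.normalized() if normalize else res


def run_delay_scan(model, delay_grid: Sequence[float] = DEFAULT_DELAY_GRID,
                   pump_nm: float = DEFAULT_PUMP_NM,
                   probe_nm: float = DEFAULT_PROBE_NM,
                   fluences: tuple[float, float] = (DEFAULT_FLUENCE,
                                                    DEFAULT_FLUENCE),
                   fwhm_ns: float = 3.0,
                   geom: MediumGeometry | None = None,
                   det: DetectorModel | None = None,
                   cutoff_MHz: float = 15.0,
                   snr_db: float | None = None, seed: int = 0,
                   repeats: int = 1, normalize: bool = True) -> ScanResult:
    """Delay scan: TIDSA versus pump-probe delay.

    Each delay is differenced against the longest delay in the grid (the
    reference measurement); with ``normalize=True`` the curve is scaled by
    its value at the smallest delay.
    """
    grid = np.sort(np.asarray(delay_grid, dtype=float))
    if grid.size < 2 or grid[-1] <= grid[0]:
        raise ValueError("delay grid must span a positive range")
    if np.any(grid < 0):
        raise ValueError("delays must be nonnegative")
    geom = geom or MediumGeometry()
    det = det or DetectorModel()

    common = dict(lambda_pump_nm=pump_nm, lambda_probe_nm=probe_nm,
                  fwhm_ns=fwhm_ns, fluence_pump=fluences[0],
                  fluence_probe=fluences[1])
    ref, _ = _acquire(model, PulsePair(delay_ns=float(grid[-1]), **common),
                      geom, det, cutoff_MHz, snr_db, seed + 999_000, repeats)
    tidsa, err = [], []
    for i, dt in enumerate(grid):
        s, e = _acquire(model, PulsePair(delay_ns=float(dt), **common),
                        geom, det, cutoff_MHz, snr_db, seed + 100 * i,
                        repeats)
        rec = sp.difference_and_tidsa(s, ref, stderr=e)
        tidsa.append(rec.tidsa)
        err.append(rec.stderr)
    res = ScanResult("delay_ns", grid, np.array(tidsa), np.array(err),
                     _scan_config(pump_nm=pump_nm, probe_nm=probe_nm,
                                  fluences=fluences, fwhm_ns=fwhm_ns,
                                  snr_db=snr_db, repeats=repeats, seed=seed,
                                  model=model.name, normalized=False))
    if normalize and res.tidsa[0] != 0:
        return res.normalized(reference=res.tidsa[0])
    return res


# ---------------------------------------------------------------------------
# Lifetime recovery
# ---------------------------------------------------------------------------

def gaussian_exponential_decay(dt_ns, amplitude, tau_ns, sigma_ns,
                               offset=0.0):
    """Exponential decay convolved with a Gaussian of width ``sigma_ns``.

    Closed form of exp(-t/tau) (for t > 0) convolved with a unit-area
    Gaussian:

        f(t) = A/2 * exp(sigma^2/(2 tau^2) - t/tau)
                   * erfc((sigma/tau - t/sigma) / sqrt(2)) + offset
    """
    dt_ns = np.asarray(dt_ns, dtype=float)
    arg = (sigma_ns / tau_ns - dt_ns / sigma_ns) / np.sqrt(2.0)
    log_pref = sigma_ns ** 2 / (2.0 * tau_ns ** 2) - dt_ns / tau_ns
    return amplitude * 0.5 * np.exp(log_pref) * erfc(arg) + offset


def fit_lifetime(scan: ScanResult, pulse_fwhm_ns: float = 3.0) -> LifetimeFit:
    """Recover the excited-state lifetime from a delay scan.

    The delay-scan decay is the cross-correlation of two equal Gaussian
    pulses (effective width sigma_eff = sqrt(2) * FWHM / 2.355) with the
    exponential excited-state decay, so the fit model is
    ``A * [Gaussian(sigma_eff) (*) exp(-dt/tau)] + offset``.
    """
    if scan.variable != "delay_ns":
        raise ValueError("lifetime fits require a delay scan")
    if scan.grid.size < 6:
        raise ValueError("need at least 6 delay points")
    sigma_eff = (np.sqrt(2.0) * pulse_fwhm_ns
                 / (2.0 * np.sqrt(2.0 * np.log(2.0))))
    x, y = scan.grid, scan.tidsa
    span = float(y.max() - y.min())
    if span == 0.0:
        raise ValueError("delay scan has no dynamic range")

    def model(t, a, tau, off):
        return gaussian_exponential_decay(t, a, tau, sigma_eff, off)

    p0 = (span, 1.5, float(y.min()))
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=p0,
            bounds=([0.0, 0.05, -np.inf], [np.inf, 50.0, np.inf]),
            maxfev=20_000)
    except RuntimeError as exc:
        resid = y - model(x, *p0)
        raise RuntimeError(
            f"lifetime fit failed to converge: {exc}; initial residual "
            f"RMS {np.sqrt(np.mean(resid ** 2)):.3g}") from exc
    resid = y - model(x, *popt)
    tau_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return LifetimeFit(
        tau_ns=float(popt[1]), tau_stderr=tau_err,
        pulse_fwhm_ns=pulse_fwhm_ns,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        params={"amplitude": float(popt[0]), "offset": float(popt[2]),
                "sigma_eff_ns": float(sigma_eff)},
    )


# ---------------------------------------------------------------------------
# Fluence series
# ---------------------------------------------------------------------------

def _single_pulse_spectrum(model, grid, fluence, fwhm_ns, geom, det,
                           cutoff_MHz):
    """Single-pulse TISA spectrum (time-integrated signal amplitude)."""
    tisa = []
    for lam in grid:
        pulses = PulsePair(lambda_pump_nm=float(lam),
                           lambda_probe_nm=float(lam), delay_ns=0.0,
                           fwhm_ns=fwhm_ns, fluence_pump=fluence,
                           fluence_probe=0.0)
        profile = simulate_dual_pulse(model, pulses, geom)
        sig = cuvette_forward(profile, det, geom)
        sig = sp.normalize_signal(sig, float(model.mua(float(lam))), 0.0,
                                  fluence, 0.0)
        sig = sp.lowpass_filter(sig, cutoff_MHz)
        tisa.append(sp.tidsa_metric(sp.time_integrate(sig), mode="peak"))
    return np.array(tisa)


def fluence_series(model, mode: str = "pumpprobe",
                   levels: Sequence[float] = (DEFAULT_FLUENCE,
                                              DEFAULT_FLUENCE / 2,
                                              DEFAULT_FLUENCE / 4),
                   pump_grid: Sequence[float] = DEFAULT_PUMP_GRID,
                   probe_nm: float = DEFAULT_PROBE_NM,
                   delay_long_ns: float = DEFAULT_DELAY_LONG_NS,
                   fwhm_ns: float = 3.0,
                   geom: MediumGeometry | None = None,
                   det: DetectorModel | None = None,
                   cutoff_MHz: float = 15.0,
                   ) -> tuple[list[ScanResult], np.ndarray]:
    """Spectra at several fluence levels plus their pairwise shape distance.

    ``mode='pumpprobe'`` runs pump scans of the difference signal (both
    fluences scaled together); ``mode='single'`` runs conventional
    single-pulse spectra.  The shape distance is the RMS difference between
    unit-peak-normalized spectra: pump-probe difference spectra are nearly
    fluence-invariant while single-pulse spectra distort (blue-shift) with
    increasing fluence.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("empty fluence levels")
    if any(lvl <= 0 for lvl in levels):
        raise ValueError("fluence levels must be positive")
    if sorted(levels, reverse=True) != levels:
        raise ValueError("fluence levels must be descending")
    if mode not in ("single", "pumpprobe"):
        raise ValueError("mode must be 'single' or 'pumpprobe'")
    geom = geom or MediumGeometry()
    det = det or DetectorModel()
    grid = np.asarray(pump_grid, dtype=float)

    results = []
    for lvl in levels:
        if mode == "pumpprobe":
            res = run_pump_scan(model, grid, probe_nm=probe_nm,
                                fluences=(lvl, lvl),
                                delay_long_ns=delay_long_ns, fwhm_ns=fwhm_ns,
                                geom=geom, det=det, cutoff_MHz=cutoff_MHz,
                                normalize=True)
            res.config["fluence_level"] = lvl
            res.config["mode"] = "pumpprobe"
        else:
            tisa = _single_pulse_spectrum(model, grid, lvl, fwhm_ns, geom,
                                          det, cutoff_MHz)
            res = ScanResult("pump_nm", grid, tisa, np.zeros_like(tisa),
                             {"mode": "single", "fluence_level": lvl,
                              "model": model.name}).normalized()
        results.append(res)

    n = len(results)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = np.sqrt(np.mean(
                (results[i].tidsa - results[j].tidsa) ** 2))
    return results, dist
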