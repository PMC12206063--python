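"""HDF5 / CSV / YAML persistence for simulation products.

Layout conventions:

* ``DepthProfile`` -> one HDF5 group with datasets ``z_mm``, ``H``, ``p0``
  and the full configuration echoed as attributes.
* ``PASignal`` sets -> one group per acquisition (``signal_000`` ...), each
  with ``t_us`` and ``amplitude`` datasets and metadata attributes.
* ``ScanResult`` -> CSV (columns variable, tidsa, stderr) or an HDF5 group.
* ``TomogramImage`` / ``ChannelData`` -> groups with axis datasets.
* Phantom specs -> YAML (see :func:`load_phantom_yaml`).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from pppa.acquisition import PASignal
from pppa.fluorophores import build_nonfluorescent, build_preset
from pppa.photophysics import DepthProfile
from pppa.scan_analysis import ScanResult
from pppa.tomography import (ChannelData, Inclusion, Phantom2D, RingArray,
                             TomogramImage, build_phantom)

__all__ = [
    "save_depth_profile", "load_depth_profile",
    "save_signals", "load_signals",
    "scan_to_csv", "scan_from_csv",
    "save_image", "load_image",
    "save_channels", "load_channels",
    "load_phantom_yaml",
]


def _write_meta(obj, meta: dict) -> None:
    for k, v in meta.items():
        if v is None:
            continue
        try:
            obj.attrs[k] = v
        except TypeError:
            obj.attrs[k] = json.dumps(v)


def _read_meta(obj) -> dict:
    out = {}
    for k, v in obj.attrs.items():
        if isinstance(v, bytes):
            v = v.decode()
        if isinstance(v, str) and v[:1] in "[{":
            try:
                v = json.loads(v)
            except json.JSONDecodeError:
                pass
        out[k] = v
    return out


# -- depth profiles ---------------------------------------------------------

def save_depth_profile(path, profile: DepthProfile, group: str = "profile"):
    with h5py.File(path, "a") as fh:
        g = fh.require_group(group)
        for name in ("z_mm", "H", "p0"):
            if name in g:
                del g[name]
            g.create_dataset(name, data=getattr(profile, name
                                                if name != "H" else "H"))
        _write_meta(g, profile.meta)
        _write_meta(g, {f"budget_{k}": v for k, v in profile.budget.items()})


def load_depth_profile(path, group: str = "profile") -> DepthProfile:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        meta = _read_meta(g)
        budget = {k[7:]: meta.pop(k) for k in list(meta) if k.startswith("budget_")}
        return DepthProfile(z_mm=g["z_mm"][:], H=g["H"][:], p0=g["p0"][:],
                            budget=budget, meta=meta)


# -- signal sets ------------------------------------------------------------

def save_signals(path, signals: list[PASignal]):
    with h5py.File(path, "w") as fh:
        for i, sig in enumerate(signals):
            g = fh.create_group(f"signal_{i:03d}")
            g.create_dataset("t_us", data=sig.t_us)
            g.create_dataset("amplitude", data=sig.amplitude)
            _write_meta(g, sig.meta)


def load_signals(path) -> list[PASignal]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            out.append(PASignal(g["t_us"][:], g["amplitude"][:],
                                _read_meta(g)))
    return out


def signal_to_csv(path, sig: PASignal):
    pd.DataFrame({"t_us": sig.t_us, "amplitude": sig.amplitude}).to_csv(
        path, index=False)


# -- scan results -----------------------------------------------------------

def scan_to_csv(path, scan: ScanResult):
    pd.DataFrame({scan.variable: scan.grid, "tidsa": scan.tidsa,
                  "stderr": scan.stderr}).to_csv(path, index=False)


def scan_from_csv(path) -> ScanResult:
    df = pd.read_csv(path)
    variable = df.columns[0]
    return ScanResult(variable, df[variable].to_numpy(),
                      df["tidsa"].to_numpy(), df["stderr"].to_numpy())


# -- tomography products ----------------------------------------------------

def save_image(path, image: TomogramImage, group: str = "image"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("x_mm", data=image.x_mm)
        g.create_dataset("y_mm", data=image.y_mm)
        g.create_dataset("intensity", data=image.intensity)
        _write_meta(g, image.meta)


def load_image(path, group: str = "image") -> TomogramImage:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return TomogramImage(g["x_mm"][:], g["y_mm"][:], g["intensity"][:],
                             _read_meta(g))


def save_channels(path, channels: ChannelData, group: str = "channels"):
    arr = channels.array
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("data", data=channels.data)
        _write_meta(g, channels.meta)
        _write_meta(g, {
            "array_n_elements": arr.n_elements,
            "array_radius_mm": arr.radius_mm,
            "array_center_MHz": arr.center_MHz,
            "array_fractional_bandwidth": arr.fractional_bandwidth,
            "array_sound_speed_m_s": arr.sound_speed_m_s,
            "array_sample_rate_MHz": arr.sample_rate_MHz,
            "array_n_samples": arr.n_samples,
        })


def load_channels(path, group: str = "channels") -> ChannelData:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        meta = _read_meta(g)
        array = RingArray(
            n_elements=int(meta.pop("array_n_elements")),
            radius_mm=float(meta.pop("array_radius_mm")),
            center_MHz=float(meta.pop("array_center_MHz")),
            fractional_bandwidth=float(meta.pop("array_fractional_bandwidth")),
            sound_speed_m_s=float(meta.pop("array_sound_speed_m_s")),
            sample_rate_MHz=float(meta.pop("array_sample_rate_MHz")),
            n_samples=int(meta.pop("array_n_samples")),
        )
        return ChannelData(data=g["data"][:], array=array, meta=meta)


# -- phantom YAML -----------------------------------------------------------

def _model_from_spec(spec):
    if isinstance(spec, str):
        if spec.lower() in ("crcl3_cocl2", "absorber"):
            return build_nonfluorescent()
        return build_preset(spec)
    if isinstance(spec, dict) and "absorber_mua" in spec:
        return build_nonfluorescent(level=float(spec["absorber_mua"]))
    raise ValueError(f"cannot interpret model spec {spec!r}")


def load_phantom_yaml(path) -> Phantom2D:
    """Build a phantom from a YAML spec.

    Schema::

        fov_mm: 16.0
        pixel_mm: 0.1
        background_mua: 0.0
        inclusions:
          - center_mm: [0.0, 4.0]
            inner_radius_mm: 0.735
            model: katushka            # preset name, 'absorber', or
          - center_mm: [3.46, -2.0]    # {absorber_mua: <cm^-1>}
            inner_radius_mm: 0.735
            model: {absorber_mua: 2.0}
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    incs = [Inclusion(center_mm=tuple(i["center_mm"]),
                      inner_radius_mm=float(i["inner_radius_mm"]),
                      model=_model_from_spec(i["model"]))
            for i in spec.get("inclusions", [])]
    return build_phantom(inclusions=incs or None,
                         fov_mm=float(spec.get("fov_mm", 16.0)),
                         pixel_mm=float(spec.get("pixel_mm", 0.1)),
                         background_mua=float(spec.get("background_mua", 0.0)))
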