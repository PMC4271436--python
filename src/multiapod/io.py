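"""Text, HDF5 and raster export of windows, spectra, phantoms, RF and images."""

from __future__ import annotations

import os

import h5py
import numpy as np
from PIL import Image

from .beamformer import BModeImage
from .exceptions import StageOrderError
from .simulator import ArrayConfig, Phantom, RFChannelData
from .windows import ApodizationProfile, SpectralResponse

__all__ = [
    "save_window_text",
    "save_spectrum_text",
    "save_phantom_text",
    "save_rf_h5",
    "load_rf_h5",
    "save_image_png",
]


def save_window_text(profile: ApodizationProfile, path: str) -> None:
    """Two columns: sample index, weight."""
    data = np.column_stack([np.arange(profile.N), profile.weights])
    header = f"window family={profile.family} param={profile.param} N={profile.N}\nn\tweight"
    np.savetxt(path, data, fmt="%d\t%.12g", header=header)


def save_spectrum_text(resp: SpectralResponse, path: str) -> None:
    """Two columns: bin, dB (plotting parity with the impulse-response figures)."""
    data = np.column_stack([resp.bins, resp.magnitude_db])
    header = f"impulse response N={resp.N} pad_factor={resp.pad_factor}\nbin\tdB"
    np.savetxt(path, data, fmt="%.6f\t%.6f", header=header)


def save_phantom_text(phantom: Phantom, path: str) -> None:
    """Three columns: axial (m), lateral (m), amplitude."""
    data = np.column_stack([phantom.axial_m, phantom.lateral_m, phantom.amplitude])
    np.savetxt(
        path,
        data,
        fmt="%.9e",
        header=f"phantom label={phantom.label} seed={phantom.seed}\naxial_m lateral_m amplitude",
    )


def save_rf_h5(rf: RFChannelData, config: ArrayConfig, path: str) -> None:
    """RF channel data with the array configuration embedded as attributes."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("samples", data=rf.samples, compression="gzip")
        dset.attrs["t0"] = rf.t0
        dset.attrs["fs"] = rf.fs
        grp = f.create_group("active_elements")
        for i, el in enumerate(rf.active_elements):
            grp.create_dataset(str(i), data=el)
        cfg = f.create_group("config")
        for name in (
            "n_elements", "n_sub", "n_scanlines", "f0", "pitch",
            "c", "tx_focus", "fs", "n_cycles", "dynamic_range_db",
        ):
            cfg.attrs[name] = getattr(config, name)


def load_rf_h5(path: str) -> tuple[RFChannelData, ArrayConfig]:
    with h5py.File(path, "r") as f:
        dset = f["samples"]
        samples = dset[()]
        t0 = float(dset.attrs["t0"])
        fs = float(dset.attrs["fs"])
        grp = f["active_elements"]
        active = tuple(grp[str(i)][()] for i in range(samples.shape[0]))
        attrs = dict(f["config"].attrs)
    config = ArrayConfig(
        n_elements=int(attrs["n_elements"]),
        n_sub=int(attrs["n_sub"]),
        n_scanlines=int(attrs["n_scanlines"]),
        f0=float(attrs["f0"]),
        pitch=float(attrs["pitch"]),
        c=float(attrs["c"]),
        tx_focus=float(attrs["tx_focus"]),
        fs=float(attrs["fs"]),
        n_cycles=int(attrs["n_cycles"]),
        dynamic_range_db=float(attrs["dynamic_range_db"]),
    )
    return RFChannelData(samples=samples, t0=t0, fs=fs, active_elements=active), config


def save_image_png(img: BModeImage, path: str) -> None:
    """8-bit grayscale raster mapping [-dynamic_range, 0] dB to [0, 255]."""
    if img.stage != "log_compressed":
        raise StageOrderError("PNG export expects a log-compressed image")
    dr = img.dynamic_range_db or 60.0
    gray = np.round((img.pixels + dr) / dr * 255.0).clip(0, 255).astype(np.uint8)
    Image.fromarray(gray, mode="L").save(path)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
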