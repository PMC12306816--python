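"""HDF5 on-disk layout and validation.

One hierarchical layout carries the whole pipeline:

* acquisition file — ``/kspace/data`` [coil, ky, kx, frame] complex64,
  ``/kspace/mask`` [ky, frame] uint8, ``/acs/data`` [coil, ky, kx] complex64,
  ``/noise/samples`` [coil, n] complex64, ``/labels/<name>`` uint8 masks,
  root attributes ``accel``, ``n_acs``, ``seed``,
  ``fft_convention="unitary-centered"``;
* reconstruction file — ``/recon/data`` [H, W, frame] complex64,
  ``/recon/native_g`` [H, W] float32, ``/recon/meta`` JSON attribute,
  ``/gmaps/R<n>`` [H, W] float32;
* pairs file — ``/pairs/<i>/{clean,noisy}`` [T, H, W] complex64,
  ``/pairs/<i>/gmap`` [H, W] float32, per-pair ``provenance`` JSON attribute.

``content_hash`` digests datasets and attributes (not raw file bytes), so
reruns with identical settings compare equal regardless of HDF5 allocation
details.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .gfactor import GFactorMap, GFactorSet
from .phantom import MultiCoilKSpace, NoisePreScan
from .recon import ReconImage

__all__ = [
    "write_acquisition", "read_acquisition",
    "write_recon", "read_recon", "append_gmaps", "read_gmaps",
    "write_pairs", "read_pair_arrays",
    "content_hash", "validate_file",
]

FFT_CONVENTION = "unitary-centered"


def write_acquisition(path: str | Path, ksp: MultiCoilKSpace,
                      prescan: NoisePreScan,
                      labels: dict[str, np.ndarray] | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace/data", data=ksp.data.astype(np.complex64))
        f.create_dataset("kspace/mask", data=ksp.mask.astype(np.uint8))
        f.create_dataset("acs/data", data=ksp.acs.astype(np.complex64))
        f.create_dataset("noise/samples",
                         data=prescan.samples.astype(np.complex64))
        if labels:
            for name, m in labels.items():
                f.create_dataset(f"labels/{name}", data=m.astype(np.uint8))
        f.attrs["accel"] = ksp.accel
        f.attrs["n_acs"] = ksp.n_acs
        f.attrs["seed"] = int(ksp.meta.get("seed", -1))
        f.attrs["dwell_scale"] = ksp.dwell_scale
        f.attrs["fft_convention"] = FFT_CONVENTION


def read_acquisition(path: str | Path) -> tuple[MultiCoilKSpace, NoisePreScan,
                                                dict[str, np.ndarray]]:
    with h5py.File(path, "r") as f:
        ksp = MultiCoilKSpace(
            data=f["kspace/data"][()].astype(complex),
            mask=f["kspace/mask"][()],
            acs=f["acs/data"][()].astype(complex),
            accel=int(f.attrs["accel"]),
            n_acs=int(f.attrs["n_acs"]),
            dwell_scale=float(f.attrs.get("dwell_scale", 1.0)),
            meta={"seed": int(f.attrs.get("seed", -1)),
                  "fft_convention": str(f.attrs.get("fft_convention", ""))},
        )
        prescan = NoisePreScan(samples=f["noise/samples"][()].astype(complex))
        labels = {}
        if "labels" in f:
            labels = {name: f[f"labels/{name}"][()].astype(bool)
                      for name in f["labels"]}
    return ksp, prescan, labels


def write_recon(path: str | Path, recon: ReconImage) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("recon/data", data=recon.data.astype(np.complex64))
        f.create_dataset("recon/native_g",
                         data=recon.native_g.astype(np.float32))
        f["recon"].attrs["meta"] = json.dumps(recon.meta, default=str,
                                              sort_keys=True)
        f.attrs["fft_convention"] = FFT_CONVENTION


def read_recon(path: str | Path) -> ReconImage:
    with h5py.File(path, "r") as f:
        meta = json.loads(f["recon"].attrs.get("meta", "{}"))
        return ReconImage(data=f["recon/data"][()].astype(complex),
                          native_g=f["recon/native_g"][()].astype(float),
                          meta=meta)


def append_gmaps(path: str | Path, gset: GFactorSet) -> None:
    with h5py.File(path, "a") as f:
        if "gmaps" in f:
            del f["gmaps"]
        for m in gset.maps:
            d = f.create_dataset(f"gmaps/R{m.accel}",
                                 data=m.g.astype(np.float32))
            d.attrs["accel"] = m.accel
        f["gmaps"].attrs["source"] = gset.source


def read_gmaps(path: str | Path) -> GFactorSet:
    with h5py.File(path, "r") as f:
        maps = [GFactorMap(g=f[f"gmaps/{k}"][()].astype(float),
                           accel=int(f[f"gmaps/{k}"].attrs["accel"]))
                for k in sorted(f["gmaps"])]
        return GFactorSet(maps=maps, source=str(f["gmaps"].attrs.get("source", "")))


def write_pairs(path: str | Path, pairs: list) -> None:
    """Write TrainingPair records under /pairs/<i>."""
    with h5py.File(path, "w") as f:
        f.create_group("pairs")
        for i, p in enumerate(pairs):
            grp = f.create_group(f"pairs/{i}")
            grp.create_dataset(
                "clean", data=np.transpose(p.clean.data, (2, 0, 1)).astype(np.complex64))
            grp.create_dataset(
                "noisy", data=np.transpose(p.noisy.data, (2, 0, 1)).astype(np.complex64))
            grp.create_dataset("gmap", data=p.gmap_used.g.astype(np.float32))
            grp.attrs["provenance"] = json.dumps(p.provenance, sort_keys=True)
        f.attrs["n_pairs"] = len(pairs)


def read_pair_arrays(path: str | Path, index: int) -> dict:
    with h5py.File(path, "r") as f:
        grp = f[f"pairs/{index}"]
        return {
            "clean": grp["clean"][()].astype(complex),
            "noisy": grp["noisy"][()].astype(complex),
            "gmap": grp["gmap"][()].astype(float),
            "provenance": json.loads(grp.attrs["provenance"]),
        }


def content_hash(path: str | Path) -> str:
    """SHA-256 over dataset contents and attributes, in name order."""
    h = hashlib.sha256()

    def visit(name: str, obj) -> None:
        h.update(name.encode())
        for k in sorted(obj.attrs):
            h.update(k.encode())
            h.update(str(obj.attrs[k]).encode())
        if isinstance(obj, h5py.Dataset):
            h.update(np.ascontiguousarray(obj[()]).tobytes())

    with h5py.File(path, "r") as f:
        for k in sorted(f.attrs):
            h.update(k.encode())
            h.update(str(f.attrs[k]).encode())
        f.visititems(visit)
    return h.hexdigest()


def validate_file(path: str | Path) -> list[str]:
    """Check an HDF5 product against the layout; return violations found."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    violations: list[str] = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    with f:
        is_acq = "kspace" in f
        is_recon = "recon" in f
        is_pairs = "pairs" in f
        if not (is_acq or is_recon or is_pairs):
            violations.append("unrecognized layout: none of /kspace, /recon, /pairs")
        if is_acq:
            if "fft_convention" not in f.attrs:
                violations.append("missing fft_convention attribute")
            elif f.attrs["fft_convention"] != FFT_CONVENTION:
                violations.append(
                    f"unexpected fft_convention {f.attrs['fft_convention']!r}")
            for name, dtype in [("kspace/data", "c"), ("kspace/mask", "u"),
                                ("acs/data", "c"), ("noise/samples", "c")]:
                if name not in f:
                    violations.append(f"missing dataset /{name}")
                elif f[name].dtype.kind != dtype:
                    violations.append(
                        f"/{name} has dtype {f[name].dtype}, expected kind '{dtype}'")
            for attr in ("accel", "n_acs", "seed"):
                if attr not in f.attrs:
                    violations.append(f"missing attribute {attr}")
            if "kspace/data" in f and "kspace/mask" in f:
                data = f["kspace/data"][()]
                mask = f["kspace/mask"][()]
                if mask.shape != (data.shape[1], data.shape[3]):
                    violations.append("mask shape inconsistent with data")
                else:
                    energy = np.abs(data).sum(axis=(0, 2))  # [ky, frame]
                    if np.any((mask == 0) & (energy > 1e-6)):
                        violations.append(
                            "data nonzero on phase-encode lines the mask marks unacquired")
                    if np.any((mask == 1) & (energy == 0)):
                        violations.append(
                            "mask marks lines acquired but data rows are all-zero")
        if is_recon:
            for name in ("recon/data", "recon/native_g"):
                if name not in f:
                    violations.append(f"missing dataset /{name}")
            if "recon" in f and "meta" not in f["recon"].attrs:
                violations.append("missing /recon meta attribute")
            if "recon/native_g" in f and np.any(f["recon/native_g"][()] <= 0):
                violations.append("native_g contains non-positive values")
        if is_pairs:
            n = int(f.attrs.get("n_pairs", -1))
            if n < 0:
                violations.append("missing n_pairs attribute")
            for i in range(max(n, 0)):
                grp = f.get(f"pairs/{i}")
                if grp is None:
                    violations.append(f"missing group /pairs/{i}")
                    continue
                for name in ("clean", "noisy", "gmap"):
                    if name not in grp:
                        violations.append(f"missing dataset /pairs/{i}/{name}")
                if "provenance" not in grp.attrs:
                    violations.append(f"missing provenance on /pairs/{i}")
    return violations
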