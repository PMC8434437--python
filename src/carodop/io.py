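"""File I/O: B-mode sequences (multi-page TIFF + JSON sidecar), IQ ensembles
(HDF5), and result/detection JSON documents."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .segmentation import BModeSequence, LumenDetection
from .spectral import IQEnsemble


def write_bmode(seq: BModeSequence, tiff_path, meta_path=None, truth=None) -> None:
    """Write a B-mode sequence as multi-page TIFF plus a JSON sidecar.

    The sidecar carries pixel spacing, lateral origin, side, and (for
    synthetic data) the ground-truth record.
    """
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, seq.frames.astype(np.uint8))
    meta = {
        "pixel_spacing_mm": list(seq.pixel_spacing),
        "lateral_origin_mm": seq.lateral_origin,
        "side": seq.side,
        "n_frames": int(seq.n_frames),
    }
    if truth is not None:
        meta["truth"] = dataclasses.asdict(truth)
    meta_path = Path(meta_path) if meta_path else tiff_path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))


def read_bmode(tiff_path, meta_path=None) -> BModeSequence:
    tiff_path = Path(tiff_path)
    meta_path = Path(meta_path) if meta_path else tiff_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    return BModeSequence(
        frames=frames,
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        lateral_origin=meta["lateral_origin_mm"],
        side=meta.get("side", "left"),
    )


def write_iq_pair(path, left: IQEnsemble, right: IQEnsemble,
                  truth: dict | None = None, seed: int | None = None) -> None:
    """Write the dual-beam IQ ensembles to HDF5 (groups /left and /right)."""
    with h5py.File(path, "w") as f:
        for ens in (left, right):
            g = f.create_group(ens.side)
            g.create_dataset("iq", data=ens.samples.astype(np.complex64))
            g.attrs["prf"] = ens.prf
            g.attrs["gate_spacing_mm"] = ens.gate_spacing_mm
            g.attrs["first_gate_depth_mm"] = ens.first_gate_depth_mm
            g.attrs["side"] = ens.side
            if seed is not None:
                g.attrs["seed"] = seed
        if truth:
            t = f.create_group("truth")
            for k, v in truth.items():
                t.attrs[k] = v


def read_iq_pair(path) -> tuple[IQEnsemble, IQEnsemble]:
    out = {}
    with h5py.File(path, "r") as f:
        for side in ("left", "right"):
            g = f[side]
            out[side] = IQEnsemble(
                samples=g["iq"][()].astype(np.complex128),
                prf=float(g.attrs["prf"]),
                gate_spacing_mm=float(g.attrs["gate_spacing_mm"]),
                first_gate_depth_mm=float(g.attrs["first_gate_depth_mm"]),
                side=side,
            )
    return out["left"], out["right"]


def write_detection(det: LumenDetection, path) -> None:
    doc = {
        "xc_mm": None if np.isnan(det.xc) else det.xc,
        "yc_mm": None if np.isnan(det.yc) else det.yc,
        "rc_mm": None if np.isnan(det.rc) else det.rc,
        "n_supporting_frames": det.n_supporting_frames,
        "status": det.status,
        "per_frame": [
            {"frame": c.frame_index, "x_mm": c.x, "y_mm": c.y, "r_mm": c.r,
             "darkness": c.darkness}
            for c in det.per_frame_candidates
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_detection(path) -> LumenDetection:
    doc = json.loads(Path(path).read_text())
    nan = float("nan")
    return LumenDetection(
        xc=doc["xc_mm"] if doc["xc_mm"] is not None else nan,
        yc=doc["yc_mm"] if doc["yc_mm"] is not None else nan,
        rc=doc["rc_mm"] if doc["rc_mm"] is not None else nan,
        n_supporting_frames=doc["n_supporting_frames"],
        status=doc["status"],
    )
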