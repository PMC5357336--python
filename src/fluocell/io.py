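"""Dataset readers/writers.

Layout per dataset directory:

    img_0000.tif           grayscale intensity image (8- or 16-bit)
    img_0000_labels.tif    instance label map (16-bit; 32-bit on overflow)
    img_0000_gt.json       per-cell ground truth + provenance sidecar
    manifest.json          per-image seeds, config hash, format version

Per-cell masks are stored run-length encoded in the JSON sidecar so that
overlapping cells remain individually recoverable; write-then-read is a
bit-exact round trip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .placement import LayoutSpec
from .scene import CellTruth, PerlinParams, SceneConfig, SimulatedScene
from .texture import WarpWeights

__all__ = ["write_dataset", "read_dataset", "rle_encode", "rle_decode"]

_FORMAT_VERSION = 1


def rle_encode(mask: np.ndarray) -> dict:
    """Row-major run-length encoding of a binary mask."""
    flat = np.asarray(mask, dtype=bool).reshape(-1)
    edges = np.flatnonzero(np.diff(flat))
    bounds = np.concatenate([[-1], edges, [flat.size - 1]])
    runs = np.diff(bounds).tolist()
    return {"shape": list(mask.shape), "first": bool(flat[0]) if flat.size else False,
            "runs": runs}


def rle_decode(doc: dict) -> np.ndarray:
    vals = []
    val = doc["first"]
    for r in doc["runs"]:
        vals.append(np.full(r, val, dtype=bool))
        val = not val
    flat = np.concatenate(vals) if vals else np.zeros(0, dtype=bool)
    return flat.reshape(doc["shape"])


def _config_doc(config: SceneConfig) -> dict:
    return asdict(config)


def _config_from_doc(doc: dict) -> SceneConfig:
    return SceneConfig(
        layout=LayoutSpec(**{**doc["layout"],
                             "image_size": tuple(doc["layout"]["image_size"])}),
        background=PerlinParams(**doc["background"]),
        gaussian_noise_sigma=doc["gaussian_noise_sigma"],
        bit_depth=doc["bit_depth"],
        composition_mode=doc["composition_mode"],
        n_images=doc["n_images"],
        n_points=doc["n_points"],
        warp_weights=WarpWeights(**doc["warp_weights"]),
        fixation_stride=doc["fixation_stride"],
        rng_seed=doc["rng_seed"],
    )


def write_dataset(scenes, outdir, manifest: dict | None = None,
                  label_dtype: str = "uint16") -> Path:
    """Write scenes to ``outdir``; removes partial output on failure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _imwrite(path, data):
        tifffile.imwrite(path, data)
        created.append(path)

    try:
        entries = []
        for i, sc in enumerate(scenes):
            stem = f"img_{i:04d}"
            max_label = int(sc.label_map.max())
            if label_dtype == "uint16":
                if max_label > np.iinfo(np.uint16).max:
                    raise ValueError(
                        "label overflow: more than 65535 cells; use 32-bit mode "
                        "(label_dtype='uint32')"
                    )
                lab = sc.label_map.astype(np.uint16)
            else:
                lab = sc.label_map.astype(np.uint32)
            _imwrite(outdir / f"{stem}.tif", sc.image)
            _imwrite(outdir / f"{stem}_labels.tif", lab)
            gt = {
                "format_version": _FORMAT_VERSION,
                "rng_seed": sc.rng_seed,
                "clipped_fraction": sc.clipped_fraction,
                "config": _config_doc(sc.config),
                "cells": [
                    {
                        "mask_rle": rle_encode(c.mask),
                        "offset": list(c.offset),
                        "polygon": np.asarray(c.polygon).tolist(),
                        "cluster_id": int(c.cluster_id),
                        "source_patch_id": c.source_patch_id,
                    }
                    for c in sc.cells
                ],
            }
            gt_path = outdir / f"{stem}_gt.json"
            with open(gt_path, "w") as fh:
                json.dump(gt, fh)
            created.append(gt_path)
            entries.append({"image": f"{stem}.tif", "labels": f"{stem}_labels.tif",
                            "gt": f"{stem}_gt.json", "seed": sc.rng_seed})
        doc = dict(manifest or {})
        doc.update({
            "format_version": _FORMAT_VERSION,
            "n_images": len(entries),
            "entries": entries,
        })
        doc["config_hash"] = hashlib.sha256(
            json.dumps(_config_doc(scenes[0].config), sort_keys=True).encode()
        ).hexdigest() if scenes else ""
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(doc, fh, indent=1)
    except Exception:
        for path in created:               # remove partial output, keep the dir
            path.unlink(missing_ok=True)
        raise
    return outdir


def read_dataset(indir) -> list[SimulatedScene]:
    """Read a dataset written by :func:`write_dataset` (bit-exact round trip)."""
    indir = Path(indir)
    mpath = indir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unknown format version in {mpath}")
    scenes = []
    for entry in manifest["entries"]:
        for key in ("image", "labels", "gt"):
            if not (indir / entry[key]).exists():
                raise FileNotFoundError(f"missing file: {indir / entry[key]}")
        image = tifffile.imread(indir / entry["image"])
        labels = tifffile.imread(indir / entry["labels"]).astype(np.int32)
        with open(indir / entry["gt"]) as fh:
            gt = json.load(fh)
        if gt.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unknown format version in {indir / entry['gt']}")
        if image.shape != labels.shape:
            raise ValueError(f"extent mismatch between {entry['image']} and {entry['labels']}")
        cells = [
            CellTruth(
                mask=rle_decode(c["mask_rle"]),
                offset=tuple(c["offset"]),
                polygon=np.asarray(c["polygon"], dtype=float).reshape(-1, 2),
                cluster_id=c["cluster_id"],
                source_patch_id=c["source_patch_id"],
            )
            for c in gt["cells"]
        ]
        scenes.append(SimulatedScene(
            image=image, label_map=labels, cells=cells,
            config=_config_from_doc(gt["config"]),
            rng_seed=gt["rng_seed"], clipped_fraction=gt["clipped_fraction"],
        ))
    return scenes
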