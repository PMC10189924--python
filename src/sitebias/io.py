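"""On-disk stores: patch directories (PNG + index) and feature stores (npy + index).

Layouts
-------
Patch store: ``<dir>/<slide_id>_<patch_index>.png`` plus ``patches.tsv`` with
columns ``slide_id, patch_index, x, y, level``.  Coordinates are 0-based,
top-left origin, half-open patch extents, referenced to the stated level.

Feature store: ``<dir>/<slide_id>.npy`` (n_patches × d float64) plus
``index.tsv`` with columns ``slide_id, n_patches, dim, extractor, version``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import SlideFeatures
from .synthetic import SlidePatches


def save_patch_store(store: dict[str, SlidePatches], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, sp in store.items():
        for i, (raster, (x, y, level)) in enumerate(zip(sp.rasters, sp.coords)):
            img = Image.fromarray((np.clip(raster, 0, 1) * 255).astype(np.uint8))
            img.save(out / f"{sid}_{i}.png")
            rows.append({"slide_id": sid, "patch_index": i, "x": x, "y": y, "level": level})
    pd.DataFrame(rows).to_csv(out / "patches.tsv", sep="\t", index=False)


def load_patch_store(in_dir) -> dict[str, SlidePatches]:
    d = Path(in_dir)
    index = pd.read_csv(d / "patches.tsv", sep="\t")
    store: dict[str, SlidePatches] = {}
    for sid, sub in index.groupby("slide_id"):
        sub = sub.sort_values("patch_index")
        rasters, coords = [], []
        for row in sub.itertuples():
            img = np.asarray(Image.open(d / f"{sid}_{row.patch_index}.png"), dtype=float)
            rasters.append(img / 255.0)
            coords.append((int(row.x), int(row.y), int(row.level)))
        store[sid] = SlidePatches(sid, rasters, coords)
    return store


def save_feature_store(store: dict[str, SlideFeatures], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, sf in store.items():
        np.save(out / f"{sid}.npy", sf.X)
        rows.append(
            {
                "slide_id": sid,
                "n_patches": sf.n_patches,
                "dim": sf.dim,
                "extractor": sf.extractor,
                "version": sf.version,
            }
        )
    pd.DataFrame(rows).to_csv(out / "index.tsv", sep="\t", index=False)


def load_feature_store(in_dir) -> dict[str, SlideFeatures]:
    d = Path(in_dir)
    index = pd.read_csv(d / "index.tsv", sep="\t")
    return {
        row.slide_id: SlideFeatures(
            row.slide_id, np.load(d / f"{row.slide_id}.npy"),
            extractor=row.extractor, version=str(row.version),
        )
        for row in index.itertuples()
    }
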