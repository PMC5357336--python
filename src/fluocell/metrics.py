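"""Objective image measurements: mean cell intensity and SMD edge strength.

Both statistics weight cells equally regardless of size.  The summed mean
difference (SMD) is a texture/edge-strength proxy:

    SMD = (1/N_C) sum_c (1/N_c) sum_{p in c} |I(p) - A_c|,

the per-cell mean absolute deviation of pixel intensities from the cell's own
mean ``A_c``, averaged over the ``N_C`` cells.  A pixel lying inside two
overlapping cells contributes to both cells' sums.  Dataset summaries average
per image first, then across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "mean_cell_intensity", "smd", "summarize_dataset",
           "overlap_series_table"]


@dataclass
class MetricsReport:
    per_image: list[tuple[float, float]]    # (mean_cell_intensity, smd)
    dataset_mean_intensity: float
    dataset_mean_smd: float
    n_cells_total: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_image, columns=["mean_cell_intensity", "smd"])
        df.index.name = "image"
        return df


def _check_masks(image, cell_masks):
    image = np.asarray(image, dtype=float)
    masks = [np.asarray(m, dtype=bool) for m in cell_masks]
    if not masks:
        raise ValueError("need at least one cell mask")
    for m in masks:
        if m.shape != image.shape:
            raise ValueError("mask extent does not match image")
        if not m.any():
            raise ValueError("empty cell mask")
    return image, masks


def mean_cell_intensity(image, cell_masks) -> float:
    """Mean over cells of each cell's mean interior intensity."""
    image, masks = _check_masks(image, cell_masks)
    return float(np.mean([image[m].mean() for m in masks]))


def smd(image, cell_masks) -> float:
    """Summed mean difference: per-cell MAD from the cell mean, cell-averaged."""
    image, masks = _check_masks(image, cell_masks)
    vals = []
    for m in masks:
        px = image[m]
        vals.append(np.abs(px - px.mean()).mean())
    return float(np.mean(vals))


def summarize_dataset(scenes) -> MetricsReport:
    """Per-image and dataset-mean metrics for a list of scenes.

    Each scene must expose ``image`` and ``cell_masks()`` (full-frame per-cell
    masks, overlap pixels included in every owning cell).
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("need at least one scene")
    per_image = []
    n_cells = 0
    for sc in scenes:
        masks = sc.cell_masks()
        n_cells += len(masks)
        per_image.append((mean_cell_intensity(sc.image, masks), smd(sc.image, masks)))
    arr = np.asarray(per_image)
    return MetricsReport(
        per_image=per_image,
        dataset_mean_intensity=float(arr[:, 0].mean()),
        dataset_mean_smd=float(arr[:, 1].mean()),
        n_cells_total=n_cells,
    )


def overlap_series_table(series: dict[str, list]) -> pd.DataFrame:
    """One row per metric, one column per overlap degree (the usual layout of
    intensity/SMD tables over an overlap series)."""
    cols = {}
    for degree, scenes in series.items():
        rep = summarize_dataset(scenes)
        cols[degree] = [rep.dataset_mean_intensity, rep.dataset_mean_smd]
    return pd.DataFrame(cols, index=["mean_cell_intensity", "smd"])
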