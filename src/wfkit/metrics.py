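"""Viral-labeling specificity/sensitivity and laminar depth profiles.

Specificity of a promoter-driven AAV is the fraction of reporter-positive
cells that carry the marker transcript; sensitivity is the fraction of
marker-positive cells expressing the reporter.  Depth profiles summarise
where labeled cells sit across the superficial colliculus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SpecificitySensitivity:
    per_image: pd.DataFrame  # image_id, specificity, sensitivity
    specificity_mean: float
    specificity_sem: float
    sensitivity_mean: float
    sensitivity_sem: float


def specificity_sensitivity(
    table: pd.DataFrame, group_key: str = "image_id"
) -> SpecificitySensitivity:
    """Per-image specificity/sensitivity with mean +/- SEM across images.

    ``table`` needs columns n_reporter, n_marker, n_double (plus the group
    key).  specificity = 100 x double/reporter; sensitivity = 100 x
    double/marker.  Images with a zero denominator are excluded with a
    warning.  Aggregation is across images by default (``group_key``
    configurable, e.g. ``animal_id``).
    """
    required = {group_key, "n_reporter", "n_marker", "n_double"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    bad = (table["n_double"] > table[["n_reporter", "n_marker"]].min(axis=1))
    if bad.any():
        raise ValueError("n_double exceeds a marginal count in some rows")

    rows = []
    for key, grp in table.groupby(group_key, sort=True):
        rep = int(grp["n_reporter"].sum())
        mark = int(grp["n_marker"].sum())
        dbl = int(grp["n_double"].sum())
        if rep == 0 or mark == 0:
            warnings.warn(f"{group_key}={key!r} excluded: zero denominator")
            continue
        rows.append(
            {
                group_key: key,
                "specificity": 100.0 * dbl / rep,
                "sensitivity": 100.0 * dbl / mark,
            }
        )
    if not rows:
        raise ValueError("no image with positive denominators")
    per_image = pd.DataFrame(rows)

    def mean_sem(col: str) -> tuple[float, float]:
        vals = per_image[col].to_numpy()
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return mean, sem

    sp_mean, sp_sem = mean_sem("specificity")
    se_mean, se_sem = mean_sem("sensitivity")
    return SpecificitySensitivity(
        per_image=per_image,
        specificity_mean=sp_mean,
        specificity_sem=sp_sem,
        sensitivity_mean=se_mean,
        sensitivity_sem=se_sem,
    )


@dataclass
class DepthProfile:
    bin_edges: np.ndarray  # microns (or normalized depth)
    percents: np.ndarray  # per-bin percent of labeled cells

    @property
    def modal_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.percents))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


def depth_profile(
    cell_depths: Sequence[float],
    bins: int | Sequence[float] = 20,
    normalize_depth: float | None = None,
) -> DepthProfile:
    """Histogram of labeled-cell depths normalized to percent of total.

    ``normalize_depth`` divides depths by a reference thickness first
    (e.g. the SGS depth) to express the profile as a fraction instead of
    absolute microns.
    """
    depths = np.asarray(cell_depths, dtype=float)
    if depths.size == 0:
        raise ValueError("no cell depths given")
    if np.any(depths < 0):
        raise ValueError("depths must be >= 0")
    if normalize_depth is not None:
        if normalize_depth <= 0:
            raise ValueError("normalize_depth must be > 0")
        depths = depths / normalize_depth
    counts, edges = np.histogram(depths, bins=bins)
    return DepthProfile(bin_edges=edges, percents=100.0 * counts / depths.size)
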