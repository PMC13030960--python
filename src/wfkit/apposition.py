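"""3D synaptic-apposition quantification on labeled dendrites.

Binary confocal channels (reporter-filled dendrite, VGluT1, VGluT2, PSD95)
are combined voxelwise: an apposition is a connected component of
``bouton AND dendrite``.  Components below a calibrated volume cutoff are
discarded as false positives.  Per-lamina summaries report bouton density
(per 100 um^3 of ROI), apposition frequency (per 100 um of traced
dendrite), and the relative density index (VGluT2 share of glutamatergic
input).

Preprocessing mirrors the slice-wise ImageJ operations applied upstream of
quantification: binarize, fill holes, distance-transform watershed, erode,
3x3 median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

DEFAULT_VOXEL_SIZE = (0.06, 0.06, 0.3)  # (x, y, z) microns
DEFAULT_CUTOFF_UM3 = 0.0218
PREPROCESS_STEPS = ("binarize", "fill_holes", "watershed", "erode", "median")
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class LabelVolume:
    """A binary 3D voxel grid (z, y, x) with anisotropic voxel size in um."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a non-empty 3D array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def voxel_volume_um3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    def astype_bool(self) -> np.ndarray:
        return self.grid.astype(bool)


@dataclass
class Component:
    """A connected voxel set with physical volume and centroid (in um)."""

    label: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, float, float]  # (x, y, z)
    lamina: str | None = None


@dataclass
class DendriteTrace:
    """Polyline paths in microns with per-point radii (SWC semantics)."""

    paths: list[np.ndarray]  # each (n, 4): x, y, z, radius
    name: str = ""

    def __post_init__(self) -> None:
        for p in self.paths:
            if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 2:
                raise ValueError("each path needs >= 2 points of (x, y, z, radius)")

    def total_length_um(self) -> float:
        return sum(
            float(np.linalg.norm(np.diff(p[:, :3], axis=0), axis=1).sum())
            for p in self.paths
        )


@dataclass
class LaminaMetrics:
    """Per-lamina density/frequency/ratio metrics."""

    lamina: str
    vglut1_density: float = math.nan  # boutons per 100 um^3
    vglut2_density: float = math.nan
    vglut1_freq: float = math.nan  # appositions per 100 um dendrite
    vglut2_freq: float = math.nan
    rdi_appositions: float = math.nan  # percent
    rdi_overall: float = math.nan
    mean_caliber_um: float = math.nan


# --- preprocessing ---


def preprocess_binary(vol: LabelVolume, steps: Sequence[str]) -> LabelVolume:
    """Apply slice-wise 2D cleanup operations in the given order.

    ``fill_holes`` fills background not connected to the slice border;
    ``watershed`` splits touching blobs along 2D distance-transform ridge
    lines; ``erode`` is one 8-neighborhood iteration; ``median`` uses a
    3x3 window.
    """
    for step in steps:
        if step not in PREPROCESS_STEPS:
            raise ValueError(f"unknown preprocessing step {step!r}; choose from {PREPROCESS_STEPS}")
    grid = vol.grid.copy()
    for step in steps:
        if step == "binarize":
            grid = grid > 0
            continue
        grid = grid.astype(bool)
        out = np.empty_like(grid)
        for z in range(grid.shape[0]):
            out[z] = _apply_2d(grid[z], step)
        grid = out
    return LabelVolume(grid=grid.astype(bool), voxel_size=vol.voxel_size, channel=vol.channel)


def _apply_2d(sl: np.ndarray, step: str) -> np.ndarray:
    if step == "fill_holes":
        return ndi.binary_fill_holes(sl)
    if step == "erode":
        return ndi.binary_erosion(sl, structure=np.ones((3, 3), dtype=bool))
    if step == "median":
        return ndi.median_filter(sl.astype(np.uint8), size=3).astype(bool)
    if step == "watershed":
        return _watershed_2d(sl)
    raise AssertionError(step)


def _watershed_2d(sl: np.ndarray) -> np.ndarray:
    if not sl.any():
        return sl.copy()
    dist = ndi.distance_transform_edt(sl)
    peaks = peak_local_max(dist, labels=sl, min_distance=2, exclude_border=False)
    if len(peaks) == 0:
        return sl.copy()
    markers = np.zeros(sl.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-dist, markers, mask=sl, watershed_line=True)
    return labels > 0


# --- colocalization and components ---


def colocalize_and(volA: LabelVolume, volB: LabelVolume) -> LabelVolume:
    """Voxelwise AND of two binary channels (e.g. bouton within dendrite)."""
    if volA.grid.shape != volB.grid.shape:
        raise ValueError(
            f"shape mismatch: {volA.grid.shape} vs {volB.grid.shape}"
        )
    if not np.allclose(volA.voxel_size, volB.voxel_size):
        raise ValueError("voxel sizes differ between channels")
    grid = volA.astype_bool() & volB.astype_bool()
    channel = f"{volA.channel}&{volB.channel}" if volA.channel or volB.channel else ""
    return LabelVolume(grid=grid, voxel_size=volA.voxel_size, channel=channel)


def label_components(vol: LabelVolume, connectivity: int = 26) -> list[Component]:
    """Connected components under 6/18/26-connectivity with physical volumes."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndi.label(vol.astype_bool(), structure=structure)
    if n == 0:
        return []
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)
    zz, yy, xx = np.nonzero(labels)
    lab = labels[zz, yy, xx]
    sum_z = np.bincount(lab, weights=zz, minlength=n + 1)
    sum_y = np.bincount(lab, weights=yy, minlength=n + 1)
    sum_x = np.bincount(lab, weights=xx, minlength=n + 1)
    vx, vy, vz = vol.voxel_size
    vox_vol = vol.voxel_volume_um3
    comps = []
    for k in range(1, n + 1):
        c = counts[k]
        comps.append(
            Component(
                label=k,
                voxel_count=int(c),
                volume_um3=float(c * vox_vol),
                centroid_um=(
                    float(sum_x[k] / c * vx),
                    float(sum_y[k] / c * vy),
                    float(sum_z[k] / c * vz),
                ),
            )
        )
    return comps


def filter_by_volume(
    components: Iterable[Component], cutoff_um3: float = DEFAULT_CUTOFF_UM3
) -> list[Component]:
    """Drop components strictly smaller than the volume cutoff."""
    if cutoff_um3 < 0:
        raise ValueError("cutoff must be >= 0")
    return [c for c in components if c.volume_um3 >= cutoff_um3]


def assign_lamina(
    components: Iterable[Component],
    lamina_bounds: Mapping[str, tuple[float, float]],
    depth_axis: str = "y",
) -> list[Component]:
    """Assign each component to a lamina by centroid depth.

    ``lamina_bounds`` maps lamina name -> [lo, hi) depth in microns along
    ``depth_axis`` (one of x/y/z in physical coordinates).
    """
    ax = {"x": 0, "y": 1, "z": 2}[depth_axis]
    out = []
    for c in components:
        depth = c.centroid_um[ax]
        lamina = next(
            (name for name, (lo, hi) in lamina_bounds.items() if lo <= depth < hi),
            None,
        )
        out.append(
            Component(
                label=c.label,
                voxel_count=c.voxel_count,
                volume_um3=c.volume_um3,
                centroid_um=c.centroid_um,
                lamina=lamina,
            )
        )
    return out


# --- dendrite traces ---


def read_swc(path: str | Path) -> DendriteTrace:
    """Read an SWC morphology file into polyline paths.

    Each parent->child edge chain is collected into a path; the SWC radius
    column is half the dendrite caliber.
    """
    nodes: dict[int, tuple[float, float, float, float, int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"{path}: SWC rows need 7 columns, got {line!r}")
        nid = int(parts[0])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        nodes[nid] = (x, y, z, r, parent)

    children: dict[int, list[int]] = {}
    for nid, (_, _, _, _, parent) in nodes.items():
        children.setdefault(parent, []).append(nid)
    roots = children.get(-1, [])
    if not roots:
        raise ValueError(f"{path}: no root node (parent -1)")

    paths: list[np.ndarray] = []

    def walk(start: int) -> None:
        # follow unbranched chains; branch points start new daughter paths
        chain = [start]
        while True:
            kids = sorted(children.get(chain[-1], []))
            if len(kids) == 1:
                chain.append(kids[0])
            else:
                if len(chain) >= 2:
                    paths.append(
                        np.array([nodes[n][:4] for n in chain], dtype=float)
                    )
                for kid in kids:
                    walk_from_parent(chain[-1], kid)
                return

    def walk_from_parent(parent: int, start: int) -> None:
        chain = [parent, start]
        while True:
            kids = sorted(children.get(chain[-1], []))
            if len(kids) == 1:
                chain.append(kids[0])
            else:
                paths.append(np.array([nodes[n][:4] for n in chain], dtype=float))
                for kid in kids:
                    walk_from_parent(chain[-1], kid)
                return

    for root in sorted(roots):
        walk(root)
    return DendriteTrace(paths=paths, name=Path(path).stem)


def write_swc(trace: DendriteTrace, path: str | Path) -> None:
    """Write paths as a minimal SWC (type 3 = dendrite)."""
    lines = ["# generated by wfkit"]
    nid = 0
    for p in trace.paths:
        parent = -1
        for x, y, z, r in p:
            nid += 1
            lines.append(f"{nid} 3 {x:.4f} {y:.4f} {z:.4f} {r:.4f} {parent}")
            parent = nid
    Path(path).write_text("\n".join(lines) + "\n")


def dendrite_length_and_caliber(
    trace: DendriteTrace,
    lamina_bounds: Mapping[str, tuple[float, float]],
    depth_axis: str = "y",
) -> dict[str, dict[str, float]]:
    """Per-lamina dendrite length (um) and mean caliber (2 x radius, um).

    Segment lengths are clipped to each lamina along the depth axis, with
    boundary-crossing segments split proportionally.  Caliber averages
    point diameters over the points falling in each lamina.
    """
    ax = {"x": 0, "y": 1, "z": 2}[depth_axis]
    length = {name: 0.0 for name in lamina_bounds}
    diam_sum = {name: 0.0 for name in lamina_bounds}
    diam_n = {name: 0 for name in lamina_bounds}

    for p in trace.paths:
        for name, (lo, hi) in lamina_bounds.items():
            in_lam = (p[:, ax] >= lo) & (p[:, ax] < hi)
            diam_sum[name] += float((2.0 * p[in_lam, 3]).sum())
            diam_n[name] += int(in_lam.sum())
        for a, b in zip(p[:-1], p[1:]):
            seg = float(np.linalg.norm(b[:3] - a[:3]))
            if seg == 0.0:
                continue
            da, db = a[ax], b[ax]
            lo_d, hi_d = min(da, db), max(da, db)
            for name, (lo, hi) in lamina_bounds.items():
                if hi_d == lo_d:
                    frac = 1.0 if lo <= lo_d < hi else 0.0
                else:
                    ov = max(0.0, min(hi, hi_d) - max(lo, lo_d))
                    frac = ov / (hi_d - lo_d)
                length[name] += seg * frac

    return {
        name: {
            "length_um": length[name],
            "mean_caliber_um": (diam_sum[name] / diam_n[name]) if diam_n[name] else math.nan,
        }
        for name in lamina_bounds
    }


# --- per-lamina metrics ---


def lamina_metrics(
    appositions: Mapping[str, Mapping[str, Sequence[Component]]],
    boutons: Mapping[str, Mapping[str, Sequence[Component]]],
    dendrite_lengths_um: Mapping[str, float],
    roi_volumes_um3: Mapping[str, float],
    calibers_um: Mapping[str, float] | None = None,
) -> dict[str, LaminaMetrics]:
    """Density, frequency, and relative-density-index metrics per lamina.

    * density  = 100 x bouton count / ROI volume (um^3)
    * frequency = 100 x apposition count / dendrite length (um)
    * rdi = 100 x nVGluT2 / (nVGluT1 + nVGluT2), computed separately for
      dendrite-apposed counts and overall bouton counts.

    ``appositions``/``boutons`` map lamina -> channel ('vglut1'/'vglut2')
    -> component list.
    """
    laminae = sorted(
        set(appositions) | set(boutons) | set(dendrite_lengths_um) | set(roi_volumes_um3)
    )
    out: dict[str, LaminaMetrics] = {}
    for lam in laminae:
        m = LaminaMetrics(lamina=lam)
        roi = roi_volumes_um3.get(lam)
        if lam in boutons:
            if roi is None or roi <= 0:
                raise ValueError(f"lamina {lam!r}: ROI volume must be > 0 for densities")
            m.vglut1_density = 100.0 * len(boutons[lam].get("vglut1", ())) / roi
            m.vglut2_density = 100.0 * len(boutons[lam].get("vglut2", ())) / roi
            n1 = len(boutons[lam].get("vglut1", ()))
            n2 = len(boutons[lam].get("vglut2", ()))
            if n1 + n2 > 0:
                m.rdi_overall = 100.0 * n2 / (n1 + n2)
        if lam in appositions:
            dlen = dendrite_lengths_um.get(lam)
            if dlen is None or dlen <= 0:
                raise ValueError(f"lamina {lam!r}: dendrite length must be > 0 for frequencies")
            a1 = len(appositions[lam].get("vglut1", ()))
            a2 = len(appositions[lam].get("vglut2", ()))
            m.vglut1_freq = 100.0 * a1 / dlen
            m.vglut2_freq = 100.0 * a2 / dlen
            if a1 + a2 > 0:
                m.rdi_appositions = 100.0 * a2 / (a1 + a2)
        if calibers_um and lam in calibers_um:
            m.mean_caliber_um = calibers_um[lam]
        out[lam] = m
    return out


# --- TIFF I/O ---


def read_label_tiff(
    path: str | Path,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    channel: str = "",
) -> LabelVolume:
    """Read a multi-page 8-bit TIFF (pages = z) as a binary volume."""
    grid = tifffile.imread(str(path))
    if grid.ndim == 2:
        grid = grid[None, ...]
    return LabelVolume(grid=grid > 0, voxel_size=voxel_size, channel=channel)


def write_label_tiff(vol: LabelVolume, path: str | Path) -> None:
    """Write a binary volume as multi-page 8-bit TIFF (0/255)."""
    data = (vol.astype_bool().astype(np.uint8)) * 255
    tifffile.imwrite(str(path), data)
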