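"""Ground-truthed synthetic inputs for both pipeline arms.

Three generators, all bit-reproducible given a seed:

* :func:`simulate_promoter_trio` — a human "ancestral" promoter plus two
  derived species at tunable target identities, with planted motif sites
  whose per-species conservation status (intact vs scrambled) is known.
* :func:`simulate_benchmark` — (volume, PSD95 flag) apposition pairs with
  lognormal volumes for the two populations the benchmark separates:
  large PSD95+ appositions (mean 0.8647 um^3) and small PSD95- false
  positives (mean 0.0881 um^3), at the observed 83.6% colocalization
  fraction.
* :func:`simulate_label_volumes` — binary 3D channels containing a
  dendrite tube, ellipsoidal boutons placed by a Poisson process at
  per-lamina densities, surface appositions at per-length frequencies,
  and a PSD95 co-label on a true-positive fraction of VGluT2 appositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from wfkit.apposition import DendriteTrace, LabelVolume
from wfkit.calibration import BenchmarkApposition

BASES = "ACGT"

# Study-condition defaults: PSD95 benchmark populations and colocalization
DEFAULT_TP_FRACTION = 0.836
DEFAULT_TP_VOLUME_MEAN = 0.8647
DEFAULT_FP_VOLUME_MEAN = 0.0881
DEFAULT_VOLUME_CV = 0.5

# Per-lamina bouton densities (per 100 um^3) and apposition frequencies
# (per 100 um dendrite) observed in the superficial colliculus sublayers.
DEFAULT_BOUTON_DENSITIES: dict[str, dict[str, float]] = {
    "uSGSd": {"vglut1": 1.0, "vglut2": 8.0},
    "uSGSv": {"vglut1": 3.0, "vglut2": 6.0},
    "lSGS": {"vglut1": 7.0, "vglut2": 6.0},
}
DEFAULT_APPOSITION_FREQS: dict[str, dict[str, float]] = {
    "uSGSd": {"vglut1": 1.57, "vglut2": 18.0},
    "uSGSv": {"vglut1": 8.76, "vglut2": 18.0},
    "lSGS": {"vglut1": 11.05, "vglut2": 19.0},
}


# ---------------------------------------------------------------------------
# promoter trios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedMotif:
    """A motif consensus planted on the human promoter.

    ``status_ts``/``status_ms`` are ``intact`` (copied unchanged into that
    species) or ``scrambled`` (a shuffled permutation, guaranteed to
    differ when the consensus has >= 2 distinct bases).
    """

    name: str
    consensus: str
    position: int  # 1-based start on the human sequence
    strand: str = "+"
    status_ts: str = "intact"
    status_ms: str = "intact"

    def __post_init__(self) -> None:
        for status in (self.status_ts, self.status_ms):
            if status not in ("intact", "scrambled"):
                raise ValueError(f"status must be intact/scrambled, got {status!r}")

    @property
    def end(self) -> int:
        return self.position + len(self.consensus) - 1


@dataclass
class PromoterTrioTruth:
    sequences: dict[str, str]
    realized_identity_ts: float
    realized_identity_ms: float
    motifs: list[PlantedMotif] = field(default_factory=list)
    seed: int = 0


def _scramble(rng: np.random.Generator, site: str) -> str:
    """A permutation of ``site`` with low residual similarity.

    Among sampled permutations, the first leaving at most half the
    characters in place is returned (otherwise the least similar seen);
    a plain random shuffle of a low-complexity site could stay above the
    conservation threshold by accident, defeating its planted status.
    """
    chars = list(site)
    if len(set(chars)) < 2:
        return site
    best, best_matches = site[::-1], sum(a == b for a, b in zip(site, site[::-1]))
    for _ in range(200):
        perm = rng.permutation(len(chars))
        out = "".join(chars[i] for i in perm)
        matches = sum(a == b for a, b in zip(site, out))
        if matches <= len(site) // 2 and out != site:
            return out
        if matches < best_matches and out != site:
            best, best_matches = out, matches
    return best


def _derive_species(
    rng: np.random.Generator,
    human: str,
    identity: float,
    indel_rate: float,
    protected: list[tuple[int, int]],
    scrambled: list[tuple[int, int, str]],
) -> tuple[str, float]:
    """Apply substitutions/indels to a copy of the human sequence.

    Returns the derived sequence and the realized identity: the fraction
    of retained (non-deleted) human positions whose base survived
    unsubstituted, which is what a correct alignment should recover as
    both-non-gap identity.
    """
    n = len(human)
    sub_rate = 1.0 - identity
    prot = np.zeros(n, dtype=bool)
    for lo, hi in protected:
        prot[lo - 1 : hi] = True
    scram_positions = np.zeros(n, dtype=bool)
    replacement = list(human)
    for lo, hi, text in scrambled:
        scram_positions[lo - 1 : hi] = True
        replacement[lo - 1 : hi] = list(text)

    substitute = (rng.random(n) < sub_rate) & ~prot & ~scram_positions
    deleted = np.zeros(n, dtype=bool)
    insertions: dict[int, str] = {}
    if indel_rate > 0:
        events = (rng.random(n) < indel_rate) & ~prot & ~scram_positions
        for pos in np.flatnonzero(events):
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                hi = min(n, pos + length)
                span = slice(pos, hi)
                if not (prot[span].any() or scram_positions[span].any()):
                    deleted[span] = True
            else:
                insertions[pos] = "".join(rng.choice(list(BASES), size=length))

    out: list[str] = []
    matches = retained = 0
    for i in range(n):
        if i in insertions:
            out.append(insertions[i])
        if deleted[i]:
            continue
        base = replacement[i]
        if substitute[i]:
            base = rng.choice([b for b in BASES if b != human[i]])
        out.append(base)
        retained += 1
        matches += base == human[i]
    realized = matches / retained if retained else 0.0
    return "".join(out), realized


def simulate_promoter_trio(
    length: int = 1800,
    identities: tuple[float, float] = (0.76, 0.53),
    indel_rate: float = 0.01,
    motifs: Sequence[PlantedMotif] = (),
    seed: int = 0,
) -> PromoterTrioTruth:
    """Simulate a human/tree shrew/mouse promoter trio with known truth.

    The human sequence is drawn uniformly over ACGT, planted motifs are
    written in at their stated positions (overlap is an error), and each
    non-human species is derived by i.i.d. substitutions at rate
    ``1 - identity`` plus geometric-length indels at ``indel_rate`` per
    site.  Intact motif sites are protected from all mutation; scrambled
    sites are permuted.
    """
    for lo, hi in ((identities[0], "hu-ts"), (identities[1], "hu-ms")):
        if not 0.0 < lo <= 1.0:
            raise ValueError(f"identity {hi} must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    spans = sorted((m.position, m.end) for m in motifs)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
        if b_lo <= a_hi:
            raise ValueError("planted motifs overlap")
    if spans and (spans[0][0] < 1 or spans[-1][1] > length):
        raise ValueError("planted motifs fall outside the sequence")

    human = list(rng.choice(list(BASES), size=length))
    for m in motifs:
        human[m.position - 1 : m.end] = list(m.consensus.upper())
    human_seq = "".join(human)

    sequences = {"human": human_seq}
    realized = {}
    for species, identity, status_attr in (
        ("treeshrew", identities[0], "status_ts"),
        ("mouse", identities[1], "status_ms"),
    ):
        protected = [
            (m.position, m.end) for m in motifs if getattr(m, status_attr) == "intact"
        ]
        scrambled = [
            (m.position, m.end, _scramble(rng, human_seq[m.position - 1 : m.end]))
            for m in motifs
            if getattr(m, status_attr) == "scrambled"
        ]
        seq, ident = _derive_species(rng, human_seq, identity, indel_rate, protected, scrambled)
        sequences[species] = seq
        realized[species] = ident

    return PromoterTrioTruth(
        sequences=sequences,
        realized_identity_ts=realized["treeshrew"],
        realized_identity_ms=realized["mouse"],
        motifs=list(motifs),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PSD95 benchmark sets
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def simulate_benchmark(
    n: int = 438,
    tp_fraction: float = DEFAULT_TP_FRACTION,
    tp_volume_mean: float = DEFAULT_TP_VOLUME_MEAN,
    fp_volume_mean: float = DEFAULT_FP_VOLUME_MEAN,
    cv: float = DEFAULT_VOLUME_CV,
    seed: int = 0,
) -> list[BenchmarkApposition]:
    """Simulate a PSD95 dual-label benchmark set.

    Class labels are Bernoulli(``tp_fraction``); volumes are lognormal
    with the given means and coefficient of variation for the PSD95+
    (genuine synapse) and PSD95- (false positive) populations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= tp_fraction <= 1.0:
        raise ValueError("tp_fraction must lie in [0, 1]")
    if tp_volume_mean <= 0 or fp_volume_mean <= 0 or cv <= 0:
        raise ValueError("volume means and cv must be > 0")
    rng = np.random.default_rng(seed)
    positive = rng.random(n) < tp_fraction
    tp_vols = _lognormal(rng, tp_volume_mean, cv, int(positive.sum()))
    fp_vols = _lognormal(rng, fp_volume_mean, cv, int((~positive).sum()))
    out: list[BenchmarkApposition] = []
    it_tp, it_fp = iter(tp_vols), iter(fp_vols)
    for flag in positive:
        vol = next(it_tp) if flag else next(it_fp)
        out.append(BenchmarkApposition(volume_um3=float(vol), psd95_positive=bool(flag)))
    return out


# ---------------------------------------------------------------------------
# 3D label volumes
# ---------------------------------------------------------------------------


@dataclass
class VolumeTruth:
    """Planted parameters for a simulated multi-channel volume.

    Depth is the y axis; laminae are depth slabs.  The dendrite is a
    straight tube along x at mid-depth of the volume (its per-lamina
    length is its x extent when its lamina is queried).
    """

    lamina_bounds: dict[str, tuple[float, float]]
    bouton_densities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BOUTON_DENSITIES.items()}
    )
    apposition_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_APPOSITION_FREQS.items()}
    )
    tp_fraction: float = DEFAULT_TP_FRACTION
    dendrite_radius_um: float = 1.0
    bouton_semi_axes_um: tuple[float, float, float] = (0.25, 0.25, 0.45)
    apposition_semi_axes_um: tuple[float, float, float] = (0.35, 0.35, 0.45)
    min_separation_um: float = 1.5
    include_dendrite: bool = True

    def __post_init__(self) -> None:
        for channel_rates in (*self.bouton_densities.values(), *self.apposition_freqs.values()):
            if any(v < 0 for v in channel_rates.values()):
                raise ValueError("rates must be >= 0")
        if not 0.0 <= self.tp_fraction <= 1.0:
            raise ValueError("tp_fraction must lie in [0, 1]")


@dataclass
class SimulatedVolumes:
    volumes: dict[str, LabelVolume]
    trace: DendriteTrace | None
    truth: VolumeTruth
    realized_bouton_counts: dict[str, dict[str, int]]
    realized_apposition_counts: dict[str, dict[str, int]]
    realized_psd95_positive: int
    dims_um: tuple[float, float, float]
    seed: int

    def roi_volumes_um3(self) -> dict[str, float]:
        dx, _, dz = self.dims_um
        return {
            lam: dx * (hi - lo) * dz
            for lam, (lo, hi) in self.truth.lamina_bounds.items()
        }


def _add_ellipsoid(
    grid: np.ndarray,
    center_um: tuple[float, float, float],
    semi_um: tuple[float, float, float],
    voxel: tuple[float, float, float],
) -> None:
    """Set voxels whose centers fall inside the ellipsoid (in-place OR)."""
    nz, ny, nx = grid.shape
    vx, vy, vz = voxel
    cx, cy, cz = center_um
    sx, sy, sz = semi_um
    x0 = max(0, int(math.floor((cx - sx) / vx - 0.5)))
    x1 = min(nx - 1, int(math.ceil((cx + sx) / vx)))
    y0 = max(0, int(math.floor((cy - sy) / vy - 0.5)))
    y1 = min(ny - 1, int(math.ceil((cy + sy) / vy)))
    z0 = max(0, int(math.floor((cz - sz) / vz - 0.5)))
    z1 = min(nz - 1, int(math.ceil((cz + sz) / vz)))
    if x1 < x0 or y1 < y0 or z1 < z0:
        return
    xs = ((np.arange(x0, x1 + 1) + 0.5) * vx - cx) / sx
    ys = ((np.arange(y0, y1 + 1) + 0.5) * vy - cy) / sy
    zs = ((np.arange(z0, z1 + 1) + 0.5) * vz - cz) / sz
    mask = (
        zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
    ) <= 1.0
    grid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] |= mask


def _place_points(
    rng: np.random.Generator,
    n: int,
    lows: np.ndarray,
    highs: np.ndarray,
    min_sep: float,
    existing: list[np.ndarray],
    forbidden_axis: tuple[float, float, float] | None = None,
    max_attempts_factor: int = 500,
) -> np.ndarray:
    """Random sequential placement of n points with a minimum separation.

    ``forbidden_axis`` = (y0, z0, clearance): candidates within
    ``clearance`` of the dendrite axis in the (y, z) plane are rejected
    (keeps background boutons off the dendrite).
    """
    accepted: list[np.ndarray] = []
    pool = np.vstack(existing) if existing else np.empty((0, 3))
    consecutive = 0
    limit = max(2000, max_attempts_factor)
    while len(accepted) < n:
        if consecutive > limit:
            raise RuntimeError(
                f"packing failure: placed {len(accepted)}/{n} points "
                f"({limit} consecutive rejections)"
            )
        cand = lows + rng.random(3) * (highs - lows)
        if forbidden_axis is not None:
            y0, z0, clearance = forbidden_axis
            if math.hypot(cand[1] - y0, cand[2] - z0) < clearance:
                consecutive += 1
                continue
        others = np.vstack([pool] + [np.array(accepted)]) if accepted else pool
        if others.size and np.min(np.linalg.norm(others - cand, axis=1)) < min_sep:
            consecutive += 1
            continue
        accepted.append(cand)
        consecutive = 0
    return np.array(accepted) if accepted else np.empty((0, 3))


def simulate_label_volumes(
    truth: VolumeTruth,
    dims_um: tuple[float, float, float] = (250.0, 250.0, 50.0),
    voxel_size: tuple[float, float, float] = (0.06, 0.06, 0.3),
    seed: int = 0,
) -> SimulatedVolumes:
    """Render binary dendrite/VGluT1/VGluT2/PSD95 channels with known truth.

    Bouton counts per lamina are Poisson draws at the planted density
    (per 100 um^3 of lamina slab); apposition counts are Poisson at the
    planted per-length frequency (per 100 um of dendrite) restricted to
    the dendrite's span through each lamina.  All objects of one channel
    respect a minimum center separation so they label as distinct
    components; background boutons keep clear of the dendrite so the
    only bouton-dendrite contacts are the planted appositions.
    """
    rng = np.random.default_rng(seed)
    dx, dy, dz = dims_um
    vx, vy, vz = voxel_size
    nx, ny, nz = (int(round(dx / vx)), int(round(dy / vy)), int(round(dz / vz)))
    shape = (nz, ny, nx)

    for lam, (lo, hi) in truth.lamina_bounds.items():
        if not 0.0 <= lo < hi <= dy + 1e-9:
            raise ValueError(f"lamina {lam!r} bounds outside the volume depth")

    channels = ("vglut1", "vglut2")
    grids = {ch: np.zeros(shape, dtype=bool) for ch in channels}
    grids["psd95"] = np.zeros(shape, dtype=bool)
    grids["dendrite"] = np.zeros(shape, dtype=bool)

    # dendrite: straight tube along x at mid-depth
    y_axis = dy / 2.0
    z_axis = dz / 2.0
    trace = None
    if truth.include_dendrite:
        yc = (np.arange(ny) + 0.5) * vy
        zc = (np.arange(nz) + 0.5) * vz
        cross = (
            (yc[None, :] - y_axis) ** 2 + (zc[:, None] - z_axis) ** 2
        ) <= truth.dendrite_radius_um**2
        grids["dendrite"] |= cross[:, :, None]
        trace = DendriteTrace(
            paths=[
                np.array(
                    [
                        [0.0, y_axis, z_axis, truth.dendrite_radius_um],
                        [dx, y_axis, z_axis, truth.dendrite_radius_um],
                    ]
                )
            ],
            name="synthetic-dendrite",
        )

    margin = max(truth.bouton_semi_axes_um + truth.apposition_semi_axes_um)
    app_sep = truth.min_separation_um
    bouton_counts: dict[str, dict[str, int]] = {}
    app_counts: dict[str, dict[str, int]] = {}
    psd95_positive = 0
    apposition_centers: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}

    dend_lamina = None
    if truth.include_dendrite:
        dend_lamina = next(
            (
                lam
                for lam, (lo, hi) in truth.lamina_bounds.items()
                if lo <= y_axis < hi
            ),
            None,
        )

    # appositions on the dendrite surface
    for lam, freqs in truth.apposition_freqs.items():
        app_counts[lam] = {}
        if not truth.include_dendrite or lam != dend_lamina:
            app_counts[lam] = {ch: 0 for ch in channels}
            continue
        for ch in channels:
            freq = freqs.get(ch, 0.0)
            n = int(rng.poisson(freq / 100.0 * dx)) if freq > 0 else 0
            placed: list[np.ndarray] = []
            consecutive = 0
            while len(placed) < n:
                if consecutive > 2000:
                    raise RuntimeError(f"packing failure for {ch} appositions in {lam}")
                consecutive += 1
                x = margin + rng.random() * (dx - 2 * margin)
                theta = rng.random() * 2.0 * math.pi
                cand = np.array(
                    [
                        x,
                        y_axis + truth.dendrite_radius_um * math.cos(theta),
                        z_axis + truth.dendrite_radius_um * math.sin(theta),
                    ]
                )
                if not (
                    margin <= cand[1] <= dy - margin and margin <= cand[2] <= dz - margin
                ):
                    continue
                pool = apposition_centers[ch] + placed
                if pool and np.min(
                    np.linalg.norm(np.array(pool) - cand, axis=1)
                ) < app_sep:
                    continue
                placed.append(cand)
                consecutive = 0
            for c in placed:
                _add_ellipsoid(grids[ch], tuple(c), truth.apposition_semi_axes_um, voxel_size)
                if ch == "vglut2" and rng.random() < truth.tp_fraction:
                    _add_ellipsoid(grids["psd95"], tuple(c), truth.apposition_semi_axes_um, voxel_size)
                    psd95_positive += 1
            apposition_centers[ch].extend(placed)
            app_counts[lam][ch] = len(placed)

    # background boutons per lamina slab
    clearance = (
        truth.dendrite_radius_um + max(truth.bouton_semi_axes_um) + 0.5
        if truth.include_dendrite
        else None
    )
    for lam, (lo, hi) in truth.lamina_bounds.items():
        bouton_counts[lam] = {}
        densities = truth.bouton_densities.get(lam, {})
        for ch in channels:
            dens = densities.get(ch, 0.0)
            if dens <= 0:
                bouton_counts[lam][ch] = 0
                continue
            slab_vol = dx * (hi - lo) * dz
            n = int(rng.poisson(dens / 100.0 * slab_vol))
            lows = np.array([margin, max(lo, margin), margin])
            highs = np.array([dx - margin, min(hi, dy - margin), dz - margin])
            forbidden = (
                (y_axis, z_axis, clearance)
                if clearance is not None and lo <= y_axis < hi
                else None
            )
            pts = _place_points(
                rng,
                n,
                lows,
                highs,
                truth.min_separation_um,
                existing=apposition_centers[ch],
                forbidden_axis=forbidden,
            )
            for c in pts:
                _add_ellipsoid(grids[ch], tuple(c), truth.bouton_semi_axes_um, voxel_size)
            bouton_counts[lam][ch] = n

    volumes = {
        name: LabelVolume(grid=g, voxel_size=voxel_size, channel=name)
        for name, g in grids.items()
    }
    return SimulatedVolumes(
        volumes=volumes,
        trace=trace,
        truth=truth,
        realized_bouton_counts=bouton_counts,
        realized_apposition_counts=app_counts,
        realized_psd95_positive=psd95_positive,
        dims_um=dims_um,
        seed=seed,
    )
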