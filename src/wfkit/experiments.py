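"""Seeded end-to-end recovery experiments.

Each routine generates ground-truthed synthetic inputs, runs the relevant
pipeline stages, and reports how well the planted quantity is recovered.
They are used both by the test suite and by the reproduction script, at
problem sizes chosen so that Poisson/binomial sampling error of the mean
stays well inside the recovery tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from wfkit.apposition import (
    DEFAULT_CUTOFF_UM3,
    assign_lamina,
    colocalize_and,
    dendrite_length_and_caliber,
    filter_by_volume,
    label_components,
    lamina_metrics,
)
from wfkit.calibration import prediction_accuracy
from wfkit.synthetic import (
    VolumeTruth,
    simulate_benchmark,
    simulate_label_volumes,
)


@dataclass
class RecoveryResult:
    planted: float
    recovered_mean: float
    per_seed: list[float]
    n: int  # problem size (appositions, boutons, or um of dendrite)


def recover_benchmark_fraction(
    seeds: Sequence[int],
    n: int = 438,
    tp_fraction: float = 0.836,
) -> RecoveryResult:
    """Simulate PSD95 benchmark sets and recover the positive percentage.

    Each seeded set of ``n`` appositions is passed through the PSD95
    classing (prediction accuracy at cutoff 0 = percent flagged
    positive); the mean recovered percentage estimates the planted
    colocalization fraction.
    """
    per_seed = []
    for seed in seeds:
        data = simulate_benchmark(n=n, tp_fraction=tp_fraction, seed=seed)
        per_seed.append(prediction_accuracy(data, cutoff=0.0))
    return RecoveryResult(
        planted=100.0 * tp_fraction,
        recovered_mean=float(np.mean(per_seed)),
        per_seed=per_seed,
        n=n,
    )


def recover_bouton_density(
    seeds: Sequence[int],
    planted_density: float = 7.0,
    lamina: str = "lSGS",
    channel: str = "vglut1",
    dims_um: tuple[float, float, float] = (30.0, 30.0, 15.0),
    voxel_size: tuple[float, float, float] = (0.06, 0.06, 0.3),
) -> RecoveryResult:
    """Plant boutons at a per-100-um^3 density and recover it.

    Non-overlapping boutons are rendered into a single-lamina volume;
    26-connected component labeling, the standard volume filter, and the
    per-lamina density computation recover the planted density.
    """
    depth = dims_um[1]
    per_seed = []
    total = 0
    for seed in seeds:
        truth = VolumeTruth(
            lamina_bounds={lamina: (0.0, depth)},
            bouton_densities={lamina: {channel: planted_density}},
            apposition_freqs={lamina: {}},
            include_dendrite=False,
        )
        sim = simulate_label_volumes(truth, dims_um=dims_um, voxel_size=voxel_size, seed=seed)
        comps = label_components(sim.volumes[channel], connectivity=26)
        comps = filter_by_volume(comps, DEFAULT_CUTOFF_UM3)
        comps = assign_lamina(comps, truth.lamina_bounds, depth_axis="y")
        boutons = {lamina: {channel: [c for c in comps if c.lamina == lamina]}}
        metrics = lamina_metrics(
            appositions={},
            boutons=boutons,
            dendrite_lengths_um={},
            roi_volumes_um3=sim.roi_volumes_um3(),
        )
        per_seed.append(getattr(metrics[lamina], f"{channel}_density"))
        total += len(boutons[lamina][channel])
    return RecoveryResult(
        planted=planted_density,
        recovered_mean=float(np.mean(per_seed)),
        per_seed=per_seed,
        n=total,
    )


def recover_apposition_frequency(
    seeds: Sequence[int],
    planted_freq: float = 18.0,
    lamina: str = "uSGSd",
    channel: str = "vglut2",
    dendrite_length_um: float = 800.0,
    cutoff_um3: float = DEFAULT_CUTOFF_UM3,
    voxel_size: tuple[float, float, float] = (0.06, 0.06, 0.3),
) -> RecoveryResult:
    """Plant surface appositions at a per-100-um frequency and recover it.

    A straight dendrite tube spans the volume; bouton ellipsoids touch
    its surface at the planted Poisson frequency.  The imaging arm (AND
    colocalization, 26-connected labeling, volume filter, per-length
    frequency) recovers the planted value.
    """
    dims_um = (dendrite_length_um, 12.0, 9.0)
    per_seed = []
    total = 0
    for seed in seeds:
        truth = VolumeTruth(
            lamina_bounds={lamina: (0.0, dims_um[1])},
            bouton_densities={lamina: {}},
            apposition_freqs={lamina: {channel: planted_freq}},
        )
        sim = simulate_label_volumes(truth, dims_um=dims_um, voxel_size=voxel_size, seed=seed)
        overlap = colocalize_and(sim.volumes[channel], sim.volumes["dendrite"])
        comps = label_components(overlap, connectivity=26)
        comps = filter_by_volume(comps, cutoff_um3)
        comps = assign_lamina(comps, truth.lamina_bounds, depth_axis="y")
        lengths = dendrite_length_and_caliber(sim.trace, truth.lamina_bounds, depth_axis="y")
        appositions = {lamina: {channel: [c for c in comps if c.lamina == lamina]}}
        metrics = lamina_metrics(
            appositions=appositions,
            boutons={},
            dendrite_lengths_um={lam: v["length_um"] for lam, v in lengths.items()},
            roi_volumes_um3={},
        )
        per_seed.append(getattr(metrics[lamina], f"{channel}_freq"))
        total += len(appositions[lamina][channel])
    return RecoveryResult(
        planted=planted_freq,
        recovered_mean=float(np.mean(per_seed)),
        per_seed=per_seed,
        n=int(dendrite_length_um * len(list(seeds))),
    )
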