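"""Runnable pipelines: the sequence arm and the imaging arm.

Both arms read a plain-text INI config, write CSV/JSON artifacts plus a
log into an output directory, and are deterministic given the config (the
resolved config and seed are always part of the outputs; no timestamps
are written, so re-runs are byte-identical).
"""

from __future__ import annotations

import configparser
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import wfkit
from wfkit.alignment import (
    align_promoters,
    alignment_statistics,
    write_alignment_fasta,
)
from wfkit.apposition import (
    DEFAULT_CUTOFF_UM3,
    DEFAULT_VOXEL_SIZE,
    assign_lamina,
    colocalize_and,
    dendrite_length_and_caliber,
    filter_by_volume,
    label_components,
    lamina_metrics,
    preprocess_binary,
    read_label_tiff,
    read_swc,
)
from wfkit.calibration import calibrate_cutoff, read_benchmark_csv
from wfkit.synthetic import VolumeTruth, simulate_label_volumes, simulate_promoter_trio
from wfkit.tfbs import call_conservation, calls_to_frame, read_jaspar, scan_pwm, summarize_conservation

logger = logging.getLogger("wfkit")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    stage: str  # "sequence" or "imaging"
    out_dir: Path
    seed: int = 0
    options: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(f"config not found: {path}")
        if "sequence" in parser:
            stage, section = "sequence", parser["sequence"]
        elif "imaging" in parser:
            stage, section = "imaging", parser["imaging"]
        else:
            raise ValueError(f"{path}: need a [sequence] or [imaging] section")
        options = dict(section)
        out_dir = Path(options.pop("out_dir", "wfkit-run"))
        seed = int(options.pop("seed", "0"))
        cfg = cls(stage=stage, out_dir=out_dir, seed=seed, options=options)
        for key in ("fasta", "jaspar", "dendrite", "vglut1", "vglut2", "trace", "bench"):
            val = options.get(key)
            if val and not Path(val).exists():
                raise FileNotFoundError(f"config {key} path does not exist: {val}")
        return cfg

    def dump(self) -> str:
        lines = [f"[{self.stage}]", f"out_dir = {self.out_dir}", f"seed = {self.seed}"]
        lines += [f"{k} = {v}" for k, v in sorted(self.options.items())]
        return "\n".join(lines) + "\n"


def _setup_run(cfg: RunConfig) -> Path:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    (cfg.out_dir / "run.cfg").write_text(cfg.dump())
    handler = logging.FileHandler(cfg.out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers = [handler, logging.StreamHandler(sys.stderr)]
    logger.setLevel(logging.INFO)
    logger.info("wfkit %s | stage=%s seed=%d", wfkit.__version__, cfg.stage, cfg.seed)
    return cfg.out_dir


def run_sequence_arm(cfg: RunConfig) -> dict:
    """Align promoters, scan TFBSs, classify conservation, write artifacts.

    Inputs come either from ``fasta`` (2-3 records ordered human, tree
    shrew, mouse) or from the synthetic trio generator when ``simulate``
    is set.  A ``jaspar`` matrix file enables the TFBS stage.
    """
    out = _setup_run(cfg)
    opts = cfg.options
    try:
        if opts.get("simulate", "").lower() in ("1", "true", "yes"):
            trio = simulate_promoter_trio(
                length=int(opts.get("length", "1800")),
                identities=(
                    float(opts.get("identity_ts", "0.76")),
                    float(opts.get("identity_ms", "0.53")),
                ),
                seed=cfg.seed,
            )
            seqs = [trio.sequences[s] for s in ("human", "treeshrew", "mouse")]
            species = ["human", "treeshrew", "mouse"]
        elif "fasta" in opts:
            from Bio import SeqIO

            records = list(SeqIO.parse(opts["fasta"], "fasta"))
            if len(records) < 2:
                raise ValueError(f"{opts['fasta']}: need >= 2 FASTA records")
            species = [r.id for r in records]
            seqs = [str(r.seq).upper().replace("-", "") for r in records]
        else:
            raise ValueError("sequence arm needs 'fasta' or 'simulate = true'")

        logger.info("aligning %d sequences (%s)", len(seqs), ",".join(species))
        aln = align_promoters(seqs, species_ids=species)
        write_alignment_fasta(aln, out / "alignment.fasta")
        reference = opts.get("ref", species[0])
        stats = alignment_statistics(aln, reference=reference)

        stat_rows = [
            {"pair": f"{a}-{b}", "identity_pct": stats.pairwise_identity[(a, b)]}
            for i, a in enumerate(species)
            for b in species[i + 1 :]
        ]
        stats_df = pd.DataFrame(stat_rows)
        stats_df["coverage_pct"] = [
            stats.coverage.get(row["pair"].split("-")[1], float("nan"))
            for _, row in stats_df.iterrows()
        ]
        stats_df.to_csv(out / "alignment_stats.csv", index=False)
        pd.DataFrame(stats.track.flags).to_csv(out / "identity_track.tsv", sep="\t", index=False)

        summary: dict = {
            "seed": cfg.seed,
            "species": species,
            "pairwise_identity_pct": {
                f"{a}-{b}": stats.pairwise_identity[(a, b)]
                for i, a in enumerate(species)
                for b in species[i + 1 :]
            },
            "coverage_pct": stats.coverage,
        }

        if "jaspar" in opts:
            pfms = read_jaspar(opts["jaspar"])
            tau = float(opts.get("tau", "0.70"))
            min_rel = float(opts.get("min_rel_score", "0.85"))
            human_seq = aln.ungapped(reference)
            hits = [h for pfm in pfms for h in scan_pwm(human_seq, pfm, min_rel)]
            logger.info("scanned %d matrices: %d hits", len(pfms), len(hits))
            if len(species) >= 3:
                calls = call_conservation(
                    hits, aln, tau=tau, human=reference,
                    treeshrew=species[1], mouse=species[2],
                )
                calls_to_frame(calls).to_csv(out / "conservation_calls.csv", index=False)
                summ = summarize_conservation(calls, aln, human=reference)
                summary["tfbs"] = {"counts": summ.counts, "percents": summ.percents}

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    except Exception as exc:
        logger.error("sequence arm failed: %s", exc)
        raise


def _parse_lamina_bounds(text: str) -> dict[str, tuple[float, float]]:
    """Parse 'uSGSd:0-100,uSGSv:100-175,lSGS:175-250' into bounds."""
    bounds = {}
    for part in text.split(","):
        name, rng = part.split(":")
        lo, hi = rng.split("-")
        bounds[name.strip()] = (float(lo), float(hi))
    return bounds


def run_imaging_arm(cfg: RunConfig) -> dict:
    """Preprocess, colocalize, label, filter and summarise per lamina.

    Channels come from TIFF paths (``dendrite``, ``vglut1``, ``vglut2``)
    or the synthetic volume generator (``simulate = true``).  ``cutoff``
    is a volume in um^3 or ``calibrate`` with a ``bench`` CSV.
    """
    out = _setup_run(cfg)
    opts = cfg.options
    try:
        voxel = tuple(
            float(v) for v in opts.get("voxel", "0.06,0.06,0.3").split(",")
        )
        if len(voxel) != 3:
            raise ValueError("voxel must be 'vx,vy,vz' in microns")
        bounds = _parse_lamina_bounds(opts["lamina_bounds"]) if "lamina_bounds" in opts else None

        if opts.get("simulate", "").lower() in ("1", "true", "yes"):
            dims = tuple(float(v) for v in opts.get("dims", "40,12,9").split(","))
            bounds = bounds or {"lSGS": (0.0, dims[1])}
            truth = VolumeTruth(
                lamina_bounds=bounds,
                bouton_densities={lam: {"vglut1": 7.0, "vglut2": 6.0} for lam in bounds},
                apposition_freqs={lam: {"vglut1": 11.05, "vglut2": 19.0} for lam in bounds},
            )
            sim = simulate_label_volumes(truth, dims_um=dims, voxel_size=voxel, seed=cfg.seed)
            vols = sim.volumes
            trace = sim.trace
            roi_volumes = sim.roi_volumes_um3()
        else:
            vols = {
                name: read_label_tiff(opts[name], voxel_size=voxel, channel=name)
                for name in ("dendrite", "vglut1", "vglut2")
                if name in opts
            }
            if "dendrite" not in vols:
                raise ValueError("imaging arm needs a dendrite channel (or simulate = true)")
            trace = read_swc(opts["trace"]) if "trace" in opts else None
            if bounds is None:
                dy = vols["dendrite"].grid.shape[1] * voxel[1]
                bounds = {"all": (0.0, dy)}
            any_vol = next(iter(vols.values()))
            dx = any_vol.grid.shape[2] * voxel[0]
            dz = any_vol.grid.shape[0] * voxel[2]
            roi_volumes = {lam: dx * (hi - lo) * dz for lam, (lo, hi) in bounds.items()}

        shapes = {v.grid.shape for v in vols.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

        steps = [s.strip() for s in opts.get("steps", "").split(",") if s.strip()]
        if steps:
            for name in ("vglut1", "vglut2"):
                if name in vols:
                    vols[name] = preprocess_binary(vols[name], steps)
            logger.info("preprocessing steps applied: %s", ",".join(steps))

        cutoff_opt = opts.get("cutoff", str(DEFAULT_CUTOFF_UM3))
        calibration = None
        if cutoff_opt == "calibrate":
            bench = read_benchmark_csv(opts["bench"])
            calibration = calibrate_cutoff(bench)
            cutoff = calibration.cutoff_um3
            logger.info("calibrated cutoff: %.4f um^3", cutoff)
        else:
            cutoff = float(cutoff_opt)

        appositions: dict[str, dict[str, list]] = {lam: {} for lam in bounds}
        boutons: dict[str, dict[str, list]] = {lam: {} for lam in bounds}
        stage_counts: dict[str, dict[str, int]] = {}
        for ch in ("vglut1", "vglut2"):
            if ch not in vols:
                continue
            overlap = colocalize_and(vols[ch], vols["dendrite"])
            comps_all = label_components(overlap, connectivity=26)
            comps = filter_by_volume(comps_all, cutoff)
            comps = assign_lamina(comps, bounds, depth_axis="y")
            stage_counts[ch] = {
                "appositions_raw": len(comps_all),
                "appositions_kept": len(comps),
            }
            logger.info(
                "%s: %d raw appositions, %d after %.4f um^3 filter",
                ch, len(comps_all), len(comps), cutoff,
            )
            b_all = label_components(vols[ch], connectivity=26)
            b_kept = assign_lamina(filter_by_volume(b_all, cutoff), bounds, depth_axis="y")
            for lam in bounds:
                appositions[lam][ch] = [c for c in comps if c.lamina == lam]
                boutons[lam][ch] = [c for c in b_kept if c.lamina == lam]

        lengths = calibers = None
        if trace is not None:
            per_lam = dendrite_length_and_caliber(trace, bounds, depth_axis="y")
            lengths = {lam: v["length_um"] for lam, v in per_lam.items()}
            calibers = {lam: v["mean_caliber_um"] for lam, v in per_lam.items()}

        metrics = lamina_metrics(
            appositions=appositions if lengths else {},
            boutons=boutons,
            dendrite_lengths_um=lengths or {},
            roi_volumes_um3=roi_volumes,
            calibers_um=calibers,
        )
        rows = [vars(m) for m in (metrics[lam] for lam in sorted(metrics))]
        pd.DataFrame(rows).to_csv(out / "lamina_metrics.csv", index=False)

        report: dict = {
            "seed": cfg.seed,
            "cutoff_um3": cutoff,
            "stage_counts": stage_counts,
            "laminae": sorted(bounds),
        }
        if calibration is not None:
            report["calibration"] = calibration.to_dict()
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report
    except Exception as exc:
        logger.error("imaging arm failed: %s", exc)
        raise
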