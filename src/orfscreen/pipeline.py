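"""Pipeline orchestration: simulate → QC → hit-call → validate.

A flat YAML config drives a reproducible end-to-end run; every stage writes
plain TSV/bedGraph outputs, and a manifest records seeds, wall times and
SHA-256 checksums so that re-running an identical config provably reproduces
identical deterministic outputs. Screen-design calculators (cells per ORF at
a given bottleneck, genome equivalents per ORF in a PCR input) live here
too, since they are planning arithmetic rather than analysis.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as covmod
from . import doseresponse as drmod
from . import hits as hitmod
from . import simulate as simmod
from .errors import ParameterError, PipelineError

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_screen_pipeline",
    "cells_per_orf",
    "genomes_per_orf",
]

log = logging.getLogger("orfscreen")


def cells_per_orf(total_cells: int, n_orfs: int, rounding: str = "exact"):
    """Average cells per library member at a bottleneck.

    ``rounding``: ``exact`` (float), ``nearest`` (int), or ``sig2``
    (2 significant figures, the convention for planning numbers).
    """
    if n_orfs < 1:
        raise ParameterError("n_orfs must be >= 1")
    if total_cells < 0:
        raise ParameterError("total_cells must be >= 0")
    value = total_cells / n_orfs
    if rounding == "exact":
        return value
    if rounding == "nearest":
        return int(round(value))
    if rounding == "sig2":
        if value == 0:
            return 0.0
        ndigits = 1 - int(math.floor(math.log10(abs(value))))
        return round(value, ndigits)
    raise ParameterError(f"unknown rounding mode {rounding!r}")


def genomes_per_orf(
    mass_gdna_ug: float,
    genome_mass_pg: float = 6.6,
    n_orfs: int = 12212,
) -> float:
    """Genome equivalents per library member in a PCR input.

    ``mass_gdna_ug`` micrograms of genomic DNA divided by the per-genome mass
    (default 6.6 pg for a diploid human genome) and by the library size.
    """
    if mass_gdna_ug <= 0 or genome_mass_pg <= 0:
        raise ParameterError("masses must be > 0")
    if n_orfs < 1:
        raise ParameterError("n_orfs must be >= 1")
    return (mass_gdna_ug * 1e6 / genome_mass_pg) / n_orfs


@dataclass
class PipelineConfig:
    """Flat configuration for a full screen run; round-trips through YAML."""

    seed: int = 0
    outdir: str = "orfscreen_run"
    # library / scenario
    n_orfs: int = 376
    pool_size: int = 376
    cells_per_orf: int = 41
    n_replicates: int = 2
    resistant_orf_index: int | None = 0
    bleed_pairs: list = field(default_factory=list)  # [probe_idx, source_idx, weight]
    # simulation parameters
    beta: float = 1.0
    moi: float = 0.3
    n_doublings: int = 25
    drug_kill_prob: float = 0.6
    noise_sigma: float = 0.5
    intensity_floor: float = 1.0
    carrying_capacity: int = 1_000_000
    drug_channel: bool = True
    # ingest mode (skip simulation of the readout)
    intensities_path: str | None = None
    samples_path: str | None = None
    # sequencing QC
    n_reads: int = 100_000
    read_len: int = 50
    min_fraction: float = 0.95
    min_depth: int = 10
    # hit calling
    y_min: float = 3.0
    x_min: float = 6.0
    min_support: int = 2
    normalize: bool = False
    flag_threshold: float = 0.2

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    """Per-stage provenance: seeds, wall times and output checksums."""

    seed: int
    stages: list = field(default_factory=list)

    def record(self, stage: str, seconds: float, outputs: dict[str, str]) -> None:
        for path, digest in outputs.items():
            self.stages.append(
                {"stage": stage, "output": path, "sha256": digest,
                 "seconds": round(seconds, 3), "seed": self.seed}
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "output", "sha256", "seconds", "seed"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _bleed_tuples(cfg: PipelineConfig):
    return [(int(i), int(j), float(w)) for i, j, w in cfg.bleed_pairs]


def run_screen_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline under one master seed.

    Stage order: simulate (or ingest) → library QC → hit calling →
    validation. Any stage failure raises :class:`PipelineError` naming the
    stage; outputs written before the failure remain on disk and are listed
    in the partial manifest attached to the exception.
    """
    outdir = Path(config.outdir)
    manifest = RunManifest(seed=config.seed)

    # -- startup validation: fail before any compute
    for attr in ("intensities_path", "samples_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise ParameterError(f"{attr} {p!r} does not exist")
    if (config.intensities_path is None) != (config.samples_path is None):
        raise ParameterError(
            "intensities_path and samples_path must be given together"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    seeds = simmod.child_seeds(config.seed, 4)

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 - named-stage abort contract
            manifest.to_tsv(outdir / "manifest_partial.tsv")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, time.perf_counter() - t0,
                        {str(p): _sha256(Path(p)) for p in outputs})
        log.info("stage %s done (%d outputs)", stage, len(outputs))
        return outputs

    state = {}

    def simulate_stage():
        library = simmod.make_library(
            config.n_orfs, config.pool_size, seed=np.random.default_rng(seeds[0])
        )
        effects = (
            {config.resistant_orf_index: 1.0 / (1.0 - config.drug_kill_prob)}
            if config.resistant_orf_index is not None else None
        )
        crosshyb = (
            simmod.crosshyb_bleed_matrix(config.n_orfs, _bleed_tuples(config))
            if config.bleed_pairs else None
        )
        sim_cfg = simmod.SimConfig(
            seed=config.seed, moi=config.moi,
            size_bias_exponent=config.beta, n_doublings=config.n_doublings,
            drug_kill_prob=config.drug_kill_prob, resistance_effects=effects,
            noise_sigma=config.noise_sigma, intensity_floor=config.intensity_floor,
            crosshyb=crosshyb, carrying_capacity=config.carrying_capacity,
        )
        total_cells = config.cells_per_orf * config.n_orfs
        t0 = simmod.simulate_initial_representation(
            library, total_cells, config.beta, np.random.default_rng(seeds[1])
        )
        profiles = simmod.simulate_read_coverage(
            t0, library, config.n_reads, config.read_len,
            np.random.default_rng(seeds[2]),
        )
        state.update(library=library, sim_cfg=sim_cfg, t0=t0, profiles=profiles)

        lib_path = outdir / "library.tsv"
        library.to_csv(lib_path, sep="\t", index=False)
        t0_path = outdir / "t0_counts.tsv"
        pd.DataFrame({"orf_id": library["orf_id"], "count": t0.counts}).to_csv(
            t0_path, sep="\t", index=False
        )
        cov_path = outdir / "coverage.bedgraph"
        covmod.write_bedgraph(profiles, cov_path)
        outputs = [lib_path, t0_path, cov_path]

        if config.intensities_path is not None:
            state["intensities"] = pd.read_csv(
                config.intensities_path, sep="\t", index_col="orf_id"
            )
            state["samples"] = pd.read_csv(config.samples_path, sep="\t")
        elif config.drug_channel:
            intensities, samples = simmod.simulate_screen(
                library, sim_cfg, total_cells, config.n_replicates
            )
            state["intensities"], state["samples"] = intensities, samples
            int_path = outdir / "intensities.tsv"
            intensities.to_csv(int_path, sep="\t")
            smp_path = outdir / "samples.tsv"
            samples.to_csv(smp_path, sep="\t", index=False)
            outputs += [int_path, smp_path]
        return outputs

    def qc_stage():
        summaries = [
            covmod.summarize_coverage(d, orf_id=orf)
            for orf, d in state["profiles"].items()
        ]
        report = covmod.presence_report(
            summaries, min_fraction=config.min_fraction, min_depth=config.min_depth
        )
        rate = covmod.library_presence_rate(report)
        trend = covmod.size_abundance_trend(state["t0"], state["library"])
        rep_path = outdir / "presence_report.tsv"
        report.to_csv(rep_path, sep="\t", index=False)
        qc_path = outdir / "qc_summary.tsv"
        pd.DataFrame(
            [{"presence_rate": rate, "spearman_rho_length_vs_count":
              trend["spearman_rho"], "n_orfs": len(report)}]
        ).to_csv(qc_path, sep="\t", index=False)
        state["presence_rate"] = rate
        return [rep_path, qc_path]

    def hits_stage():
        hits_path = outdir / "hits.tsv"
        if "intensities" not in state:
            empty = pd.DataFrame(
                columns=["orf_id", "mean_x", "mean_y", "support",
                         "crosshyb_flag", "rank"]
            )
            empty.to_csv(hits_path, sep="\t", index=False)
            state["hit_table"] = empty
            return [hits_path]
        orf_ids = list(state["library"]["orf_id"])
        pairs = [
            (orf_ids[i], orf_ids[j], w) for i, j, w in _bleed_tuples(config)
        ]
        table = hitmod.call_hits_pipeline(
            state["intensities"], state["samples"],
            y_min=config.y_min, x_min=config.x_min,
            min_support=config.min_support, floor=config.intensity_floor,
            normalize=config.normalize, similarity_pairs=pairs or None,
            flag_threshold=config.flag_threshold,
        )
        table.to_csv(hits_path, sep="\t", index=False)
        state["hit_table"] = table
        return [hits_path]

    def validate_stage():
        """Dose-response validation of the top hit on simulated SRB curves."""
        val_path = outdir / "validation.tsv"
        table = state["hit_table"]
        if table.empty:
            pd.DataFrame(
                columns=["orf_id", "ic50_uninduced", "ic50_induced",
                         "fold_shift", "rescue_efficiency_pct"]
            ).to_csv(val_path, sep="\t", index=False)
            return [val_path]
        rng = np.random.default_rng(seeds[3])
        top = table.iloc[0]["orf_id"]
        conc = np.geomspace(0.1, 100.0, 8)
        truth = {"uninduced": 2.0, "induced": 8.0}  # 4x IC50 shift on rescue
        fits = {}
        for cond, ic50 in truth.items():
            viab = drmod.four_pl(conc, 5.0, 100.0, ic50, 1.5)
            data = pd.DataFrame({
                "concentration": np.tile(conc, 3),
                "viability_pct": np.tile(viab, 3) + rng.normal(0, 2.0, conc.size * 3),
            })
            fits[cond] = drmod.fit_dose_response(data)
        fold = drmod.ic50_fold_shift(fits["uninduced"].ic50, fits["induced"].ic50)
        mid = float(np.sqrt(truth["uninduced"] * truth["induced"]))
        rescue = drmod.rescue_efficiency(
            float(fits["induced"].predict(mid)),
            float(np.clip(fits["uninduced"].predict(mid), 0, 99.9)),
        )
        pd.DataFrame(
            [{"orf_id": top,
              "ic50_uninduced": fits["uninduced"].ic50,
              "ic50_induced": fits["induced"].ic50,
              "fold_shift": fold,
              "rescue_efficiency_pct": rescue}]
        ).to_csv(val_path, sep="\t", index=False)
        return [val_path]

    _run("simulate", simulate_stage)
    _run("qc", qc_stage)
    _run("call-hits", hits_stage)
    _run("validate", validate_stage)

    manifest.to_tsv(outdir / "manifest.tsv")
    return manifest
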