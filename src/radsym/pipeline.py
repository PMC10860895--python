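"""Umbrella workflow: build-db -> profile -> diversity -> stats -> SEM.

``run_pipeline`` executes the full analysis on a directory of inputs
and writes a manifest (inputs, thresholds, seeds) sufficient to
reproduce every output bit-for-bit.  Any stage failure aborts with the
stage named.  When no environment table is supplied the statistical
stage runs group tests only and the SEM stage is skipped with a notice.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc_stats import GroupedData, gate_test
from .diversity import alpha_diversity_table, distance_matrix, pcoa, upgma
from .enzyme import BCGI, EnzymeSpec
from .io import read_sequences, read_table, write_table
from .markerdb import GenomeRecord, MarkerDB, build_marker_db
from .path_sem import PathModel, prepare_covariates
from .profiler import (DEFAULT_DETECT_THRESHOLD, DEFAULT_G_THRESHOLD,
                       merge_profiles, profile_sample)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("radsym")
if not log.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[radsym:%(stage)s] %(message)s"))
    log.addHandler(h)
    log.setLevel(logging.INFO)


def _info(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    genomes_fasta: str
    labels_tsv: str
    reads: dict[str, str]                  # sample_id -> FASTA/FASTQ path
    sample_populations: dict[str, str]     # sample_id -> population
    outdir: str
    env_table: str | None = None           # per-population covariates TSV
    sem_model: str | None = None           # plain-text edge list path
    enzyme: EnzymeSpec = BCGI
    g_threshold: float = DEFAULT_G_THRESHOLD
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD
    alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "radsym_version": __version__,
            "genomes_fasta": self.genomes_fasta,
            "labels_tsv": self.labels_tsv,
            "reads": self.reads,
            "sample_populations": self.sample_populations,
            "env_table": self.env_table,
            "sem_model": self.sem_model,
            "enzyme": {"name": self.enzyme.name,
                       "recognition": self.enzyme.recognition,
                       "flank_len": self.enzyme.flank_len},
            "g_threshold": self.g_threshold,
            "detect_threshold": self.detect_threshold,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def load_genomes(fasta: str, labels_tsv: str) -> list[GenomeRecord]:
    labels = pd.read_csv(labels_tsv, sep="\t",
                         names=["genome_id", "species_id"], header=None)
    lab = dict(zip(labels.genome_id, labels.species_id))
    out = []
    for rid, seq in read_sequences(fasta):
        if rid not in lab:
            raise ValueError(f"genome {rid} has no species label")
        out.append(GenomeRecord(genome_id=rid, species_id=lab[rid],
                                sequence=seq))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict of output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    # ---------------------------------------------------------- build-db
    stage = "build-db"
    try:
        _info(stage, "digesting genomes")
        genomes = load_genomes(config.genomes_fasta, config.labels_tsv)
        db = build_marker_db(genomes, config.enzyme)
        db.save(outdir / "db")
        report["stages"][stage] = {
            "species": len(db.markers),
            "dropped_species": db.dropped_species,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ----------------------------------------------------------- profile
    stage = "profile"
    try:
        profiles = []
        for sid, path in sorted(config.reads.items()):
            reads = [seq for _, seq in read_sequences(path)]
            prof = profile_sample(
                reads, db, sample_id=sid,
                g_threshold=config.g_threshold,
                detect_threshold=config.detect_threshold)
            profiles.append(prof)
        (outdir / "profiles").mkdir(exist_ok=True)
        per_sample = pd.concat([p.to_frame() for p in profiles])
        write_table(per_sample, outdir / "profiles" / "per_sample.tsv")
        abundance = merge_profiles(profiles)
        counts = pd.DataFrame(
            {p.sample_id: {r.species_id: r.S for r in p.records
                           if r.passed_g} for p in profiles}
        ).T.fillna(0).astype(int)
        write_table(abundance, outdir / "profiles" / "abundance.tsv",
                    index_label="sample_id")
        _info(stage, f"profiled {len(profiles)} samples, "
                     f"{abundance.shape[1]} taxa")
        report["stages"][stage] = {"samples": len(profiles),
                                   "taxa": int(abundance.shape[1])}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --------------------------------------------------------- diversity
    stage = "diversity"
    try:
        div = alpha_diversity_table(abundance, counts)
        div["population"] = [config.sample_populations.get(s, "NA")
                             for s in div.index]
        write_table(div, outdir / "diversity.tsv", index_label="sample_id")
        D = distance_matrix(abundance)
        write_table(D, outdir / "bray_curtis.tsv", index_label="sample_id")
        if len(D) >= 3:
            ord_res = pcoa(D)
            write_table(ord_res.coordinates, outdir / "pcoa.tsv",
                        index_label="sample_id")
        if len(D) >= 2:
            (outdir / "upgma.nwk").write_text(upgma(D) + "\n")
        _info(stage, f"alpha/beta diversity for {len(div)} samples")
        report["stages"][stage] = {"samples": len(div)}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ------------------------------------------------------------- stats
    stage = "stats"
    try:
        rows = []
        pops = div["population"]
        if pops.nunique() >= 2 and (pops.value_counts() >= 2).all():
            for metric in ("shannon", "simpson", "chao1"):
                vals = div[metric].dropna()
                if vals.empty:
                    continue
                gd = GroupedData(vals.to_numpy(),
                                 pops.loc[vals.index].to_numpy())
                res = gate_test(gd, alpha=config.alpha)
                rows.append({"variable": metric, "test": res.test,
                             "branch": res.branch,
                             "statistic": res.statistic,
                             "p_value": res.p_value,
                             "letters": json.dumps(res.letters)})
        else:
            _info(stage, "insufficient replication for group tests")
        write_table(pd.DataFrame(rows), outdir / "stats.tsv",
                    index_label="row")
        report["stages"][stage] = {"tests": len(rows)}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --------------------------------------------------------------- sem
    stage = "sem"
    if config.env_table is None or config.sem_model is None:
        _info(stage, "no environment table or model: SEM skipped")
        report["stages"][stage] = {"skipped": True}
    else:
        try:
            env = read_table(config.env_table)
            if "precipitation" in env.columns:
                env = prepare_covariates(env)
            pop_div = div.groupby("population")[
                ["shannon", "simpson"]].mean()
            merged = env.join(pop_div, how="inner")
            model = PathModel.from_spec(Path(config.sem_model).read_text())
            fit = model.fit(merged, seed=config.seed)
            (outdir / "sem.json").write_text(json.dumps({
                "T_ML": fit.T_ML, "df": fit.df, "T_SB": fit.T_SB,
                "scaling_factor": fit.scaling_factor,
                "p_value": fit.p_value, "CFI": fit.CFI, "AIC": fit.AIC,
                "accepted": fit.accepted,
                "estimates": fit.params.to_dict(),
                "standardized": fit.standardized().to_dict(),
            }, indent=1))
            write_table(fit.to_frame(), outdir / "sem_coefficients.tsv",
                        index_label="parameter")
            _info(stage, f"SEM fitted: T_SB={fit.T_SB:.2f}, "
                         f"CFI={fit.CFI:.3f}")
            report["stages"][stage] = {"accepted": fit.accepted}
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    (outdir / "manifest.json").write_text(
        json.dumps(config.manifest(), indent=1))
    report["outdir"] = str(outdir)
    return report
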