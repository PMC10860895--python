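"""Synthetic data: planted-site genomes, mock-community reads, and
environment -> symbiont -> diversity tables with known path structure.

Every generator is a pure function of its spec + seed, so the whole
pipeline is testable against planted ground truth: genomes carry IIB
recognition sites whose flanking tags are unique across species (a
"registry" records them), reads are drawn so that the profiler's
marker-normalised abundance estimator is unbiased for the community
proportions, and population tables follow declared linear paths with
Gaussian noise (abundance-type variables squashed through a logistic
link, linear on the link scale).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enzyme import BCGI, EnzymeSpec, canonical_tag, find_tags, iupac_to_regex, revcomp
from .markerdb import GenomeRecord

__all__ = [
    "CommunitySpec",
    "EnvSimSpec",
    "generate_genomes",
    "simulate_reads",
    "generate_env_tables",
    "default_env_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CommunitySpec:
    """A mock community of known composition."""

    species: tuple[str, ...]
    proportions: tuple[float, ...]
    depth: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be >= 0 and sum to 1")
        if len(self.species) != len(p):
            raise ValueError("species/proportions length mismatch")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate in [0, 1)")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _fill_pattern(rng: np.random.Generator, pattern: str) -> str:
    """Draw a concrete site from an IUPAC pattern (N and degenerate codes)."""
    choices = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
               "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT",
               "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG"}
    return "".join(choices[c][rng.integers(len(choices[c]))]
                   for c in pattern.upper())


def generate_genomes(
    n_species: int,
    genome_len: int,
    sites_per_genome: int,
    enzyme: EnzymeSpec = BCGI,
    seed: int = 0,
    max_attempts: int = 200,
) -> tuple[list[GenomeRecord], dict[str, set[str]]]:
    """Random genomes with ``sites_per_genome`` planted recognition sites.

    Flanking tags are rejection-sampled so every planted canonical tag
    is unique across all species, and the background is scrubbed of
    accidental recognition sites; the returned registry (species ->
    canonical tags) is therefore exactly what ``build_marker_db``
    should recover.
    """
    tag_len = enzyme.tag_length
    spacing = genome_len // max(sites_per_genome, 1)
    if sites_per_genome and spacing < tag_len + 10:
        raise ValueError(
            f"genome_len {genome_len} too small for {sites_per_genome} "
            f"sites of tag length {tag_len}")
    rng = np.random.default_rng(seed)
    fwd = re.compile(iupac_to_regex(enzyme.recognition))
    rev = re.compile(iupac_to_regex(enzyme.recognition_rc))
    flank = enzyme.flank_len

    def site_free(s: str) -> bool:
        return not (fwd.search(s) or rev.search(s))

    registry: dict[str, set[str]] = {}
    all_tags: set[str] = set()
    genomes: list[GenomeRecord] = []
    for si in range(n_species):
        sp = f"sp{si:03d}"
        for attempt in range(max_attempts):
            tags: list[str] = []
            ok = True
            for _ in range(sites_per_genome):
                for _ in range(max_attempts):
                    cand = (_random_seq(rng, flank)
                            + _fill_pattern(rng, enzyme.recognition)
                            + _random_seq(rng, flank))
                    core_once = (len(fwd.findall(cand))
                                 + len(rev.findall(cand)) == 1)
                    ct = canonical_tag(cand)
                    if core_once and ct not in all_tags \
                            and ct not in {canonical_tag(t) for t in tags}:
                        tags.append(cand)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            # background chunks free of recognition sites
            n_chunks = sites_per_genome + 1
            chunk_len = max(
                (genome_len - sites_per_genome * tag_len) // n_chunks, 5)
            parts: list[str] = []
            for i in range(n_chunks):
                for _ in range(max_attempts):
                    bg = _random_seq(rng, chunk_len)
                    if site_free(bg):
                        parts.append(bg)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            pieces = [parts[0]]
            for t, bgp in zip(tags, parts[1:]):
                pieces.append(t)
                pieces.append(bgp)
            genome = "".join(pieces)
            # junctions may create accidental sites; verify and retry
            n_sites = len(find_tags(genome, enzyme))
            if n_sites != sites_per_genome:
                continue
            got = {canonical_tag(t) for _, _, t in find_tags(genome, enzyme)}
            want = {canonical_tag(t) for t in tags}
            if got != want:
                continue
            genomes.append(GenomeRecord(
                genome_id=f"GCF_{si:06d}.1", species_id=sp, sequence=genome))
            registry[sp] = want
            all_tags |= want
            break
        else:
            raise RuntimeError(
                f"could not plant {sites_per_genome} unique sites for {sp}; "
                "lower the density or enlarge the genome")
    return genomes, registry


def simulate_reads(
    registry: dict[str, set[str]],
    community: CommunitySpec,
) -> list[str]:
    """Draw tag reads from a mock community.

    Species are sampled with probability proportional to a_i * T_i and
    a marker uniformly within species, so E[S_i / T_i] is proportional
    to a_i and the profiler's abundance estimator is unbiased for the
    community proportions.  Per-base errors are applied at the stated
    rate and strands are randomised.
    """
    missing = [s for s in community.species if s not in registry]
    if missing:
        raise ValueError(f"community species not in registry: {missing}")
    rng = np.random.default_rng(community.seed)
    markers = {s: sorted(registry[s]) for s in community.species}
    T = np.array([len(markers[s]) for s in community.species], dtype=float)
    a = np.asarray(community.proportions, dtype=float)
    w = a * T
    if w.sum() == 0:
        raise ValueError("community has no markers to sample")
    w = w / w.sum()
    sp_draw = rng.choice(len(community.species), size=community.depth, p=w)
    reads: list[str] = []
    for k in sp_draw:
        tag_list = markers[community.species[k]]
        read = tag_list[rng.integers(len(tag_list))]
        if community.error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").copy()
            hit = rng.random(len(arr)) < community.error_rate
            if hit.any():
                for i in np.flatnonzero(hit):
                    alts = [b for b in b"ACGT" if bytes([b]) != arr[i]]
                    arr[i] = bytes([alts[rng.integers(3)]])
                read = arr.tobytes().decode()
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(read)
    return reads


@dataclass(frozen=True)
class EnvSimSpec:
    """Population-level environment -> symbiont -> diversity simulation.

    ``paths`` maps each endogenous variable to {cause: coefficient} on
    the (link) scale; ``logistic`` names the endogenous variables that
    are abundances in (0, 1), produced by a logistic squash of the
    linear predictor (the linear model is exact on the link scale and
    the table carries both ``<var>`` and ``<var>_link`` columns).
    """

    n_populations: int
    covariate_means: dict[str, float]
    covariate_sds: dict[str, float]
    paths: dict[str, dict[str, float]]
    residual_sds: dict[str, float]
    covariate_corr: float = 0.0
    logistic: tuple[str, ...] = ()
    seed: int = 0


def default_env_spec(n_populations: int = 18, seed: int = 0) -> EnvSimSpec:
    """Study-shaped defaults: 18 Asian populations, five covariates
    (annual mean temperature degC, annual precipitation mm, latitude,
    longitude, altitude m) driving two symbiont abundances."""
    return EnvSimSpec(
        n_populations=n_populations,
        covariate_means={"temperature": 22.0, "precipitation_log": 7.0,
                         "latitude": 20.0, "longitude": 105.0,
                         "altitude": 400.0},
        covariate_sds={"temperature": 4.0, "precipitation_log": 0.4,
                       "latitude": 6.0, "longitude": 8.0, "altitude": 300.0},
        paths={
            "Wolbachia": {"temperature": 0.05, "precipitation_log": 0.4,
                          "longitude": -0.05},
            "Cardinium": {"latitude": -0.08, "temperature": -0.03},
        },
        residual_sds={"Wolbachia": 0.5, "Cardinium": 0.5},
        covariate_corr=0.2,
        logistic=("Wolbachia", "Cardinium"),
        seed=seed,
    )


def generate_env_tables(spec: EnvSimSpec) -> pd.DataFrame:
    """Simulate a per-population table from the declared path structure.

    Exogenous covariates are multivariate normal (equicorrelated on the
    z scale at ``covariate_corr``); endogenous variables follow their
    linear path equations plus Gaussian noise, evaluated in topological
    order so endogenous causes are allowed.
    """
    rng = np.random.default_rng(spec.seed)
    cov_names = list(spec.covariate_means)
    k = len(cov_names)
    C = np.full((k, k), spec.covariate_corr)
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError("covariate correlation matrix not positive definite")
    Z = rng.multivariate_normal(np.zeros(k), C, size=spec.n_populations)
    table = pd.DataFrame(
        {name: spec.covariate_means[name] + spec.covariate_sds[name] * Z[:, i]
         for i, name in enumerate(cov_names)},
        index=[f"pop{i:02d}" for i in range(spec.n_populations)],
    )
    # topological evaluation of endogenous variables
    remaining = dict(spec.paths)
    resolved: set[str] = set(cov_names)
    while remaining:
        ready = [v for v, ps in remaining.items()
                 if set(ps) <= resolved]
        if not ready:
            raise ValueError(f"cyclic or dangling paths: {sorted(remaining)}")
        for v in sorted(ready):
            eta = np.zeros(spec.n_populations)
            for cause, b in remaining[v].items():
                src = (table[cause + "_link"]
                       if cause in spec.logistic else table[cause])
                eta = eta + b * src.to_numpy()
            eta = eta + spec.residual_sds[v] * rng.standard_normal(
                spec.n_populations)
            if v in spec.logistic:
                table[v + "_link"] = eta
                table[v] = 1.0 / (1.0 + np.exp(-eta))
            else:
                table[v] = eta
            resolved.add(v)
            del remaining[v]
    return table
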