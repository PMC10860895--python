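"""Read-to-marker assignment, G scores and marker-normalised abundances.

For each species the profiler reports

* ``S_i`` — reads assigned to any marker of species *i*,
* ``t_i`` — distinct species-*i* markers observed,
* ``T_i`` — theoretical marker count from the database,
* ``G_i = (S_i * t_i) ** exponent`` (default exponent 0.5, the geometric
  mean of read support and marker breadth) — species with ``G_i`` below
  a threshold (default 5) are treated as false positives,
* relative abundance ``RA_i = (S_i/T_i) / sum_j (S_j/T_j)`` over the
  species passing the G filter.

Species whose RA falls below a detection threshold (default 1e-4) are
flagged as below-detection but not removed, and abundances are not
renormalised after flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .enzyme import canonical_tag
from .markerdb import MarkerDB

__all__ = [
    "SpeciesRecord",
    "SampleProfile",
    "assign_reads",
    "g_score",
    "relative_abundance",
    "profile_sample",
]

DEFAULT_G_THRESHOLD = 5.0
DEFAULT_DETECT_THRESHOLD = 1e-4


@dataclass
class SpeciesRecord:
    species_id: str
    S: int
    t: int
    T: int
    g_score: float
    rel_abundance: float | None  # None if removed by the G filter
    passed_g: bool
    below_detection: bool


@dataclass
class SampleProfile:
    """Per-species profiling result for one sample."""

    sample_id: str
    records: list[SpeciesRecord]
    n_reads: int
    n_unmatched: int
    n_skipped_length: int = 0
    g_threshold: float = DEFAULT_G_THRESHOLD
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD
    warnings: list[str] = field(default_factory=list)

    def abundances(self, include_below_detection: bool = True) -> dict[str, float]:
        """species -> RA over G-passing species (sums to 1)."""
        return {
            r.species_id: r.rel_abundance
            for r in self.records
            if r.passed_g and (include_below_detection or not r.below_detection)
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_id": r.species_id,
                "S": r.S,
                "t": r.t,
                "T": r.T,
                "g_score": r.g_score,
                "rel_abundance": r.rel_abundance,
                "passed_g": r.passed_g,
                "below_detection": r.below_detection,
            }
            for r in self.records
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "species_id", "S", "t", "T", "g_score",
                "rel_abundance", "passed_g", "below_detection",
            ],
        )
        df.insert(0, "sample_id", self.sample_id)
        return df


def assign_reads(
    reads: list[str], db: MarkerDB
) -> tuple[dict[str, int], dict[str, int], int, int]:
    """Match reads to markers by exact canonical-form identity.

    Returns ``(S, t, n_unmatched, n_skipped_length)`` where ``S`` and
    ``t`` map species to read counts and distinct-marker counts.  Reads
    whose length differs from the DB tag length are skipped with a
    warning; if more than half the reads mismatch in length a hard
    error is raised (wrong enzyme suspected).
    """
    if not reads:
        raise ValueError("empty read set")
    L = db.tag_length
    index = db.tag_index()
    S: dict[str, int] = {}
    seen: dict[str, set[str]] = {}
    unmatched = 0
    skipped = 0
    for read in reads:
        read = read.upper()
        if len(read) != L:
            skipped += 1
            continue
        tag = canonical_tag(read)
        sp = index.get(tag)
        if sp is None:
            unmatched += 1
            continue
        S[sp] = S.get(sp, 0) + 1
        seen.setdefault(sp, set()).add(tag)
    if skipped > 0.5 * len(reads):
        raise ValueError(
            f"{skipped}/{len(reads)} reads differ from the tag length {L}; "
            "wrong enzyme suspected"
        )
    if skipped:
        warnings.warn(f"{skipped} reads skipped (length != {L})", stacklevel=2)
    t = {sp: len(tags) for sp, tags in seen.items()}
    return S, t, unmatched, skipped


def g_score(S: int, t: int, exponent: float = 0.5) -> float:
    """Per-species confidence score ``(S*t)**exponent``.

    The default exponent 0.5 gives the geometric mean of assigned reads
    and observed markers; zero iff the species received no reads.
    """
    if S < 0 or t < 0:
        raise ValueError("S and t must be nonnegative")
    return float(S * t) ** exponent


def relative_abundance(
    S: dict[str, int], T: dict[str, int]
) -> dict[str, float]:
    """RA_i = (S_i/T_i) / sum_j (S_j/T_j) over the given species."""
    if not S:
        warnings.warn("no species passed the G filter; empty profile",
                      stacklevel=2)
        return {}
    density = {sp: S[sp] / T[sp] for sp in S}
    total = sum(density.values())
    return {sp: d / total for sp, d in density.items()}


def profile_sample(
    reads: list[str],
    db: MarkerDB,
    sample_id: str = "sample",
    g_threshold: float = DEFAULT_G_THRESHOLD,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    g_exponent: float = 0.5,
) -> SampleProfile:
    """Full per-sample pipeline: assign -> G filter -> RA -> detection flag."""
    if g_threshold < 0 or detect_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    S, t, unmatched, skipped = assign_reads(reads, db)
    T = db.theoretical_count
    g = {sp: g_score(S[sp], t[sp], g_exponent) for sp in S}
    survivors = {sp for sp in S if g[sp] >= g_threshold}
    ra = relative_abundance(
        {sp: S[sp] for sp in survivors}, {sp: T[sp] for sp in survivors}
    )
    records = []
    for sp in sorted(S):
        passed = sp in survivors
        ra_i = ra.get(sp) if passed else None
        records.append(
            SpeciesRecord(
                species_id=sp,
                S=S[sp],
                t=t[sp],
                T=T[sp],
                g_score=g[sp],
                rel_abundance=ra_i,
                passed_g=passed,
                below_detection=passed and ra_i < detect_threshold,
            )
        )
    prof = SampleProfile(
        sample_id=sample_id,
        records=records,
        n_reads=len(reads),
        n_unmatched=unmatched,
        n_skipped_length=skipped,
        g_threshold=g_threshold,
        detect_threshold=detect_threshold,
    )
    total = sum(prof.abundances().values())
    if prof.abundances():
        assert abs(total - 1.0) < 1e-9, "abundances must sum to 1"
    return prof


def merge_profiles(profiles: list[SampleProfile]) -> pd.DataFrame:
    """Samples x taxa relative-abundance matrix (G-passing species only)."""
    rows = {p.sample_id: p.abundances() for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return df.reindex(sorted(df.columns), axis=1)
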