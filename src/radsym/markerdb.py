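"""Species-specific 2bRAD marker database construction.

A canonical tag becomes a marker for species *i* iff it is single-copy
within every genome of species *i* in which it occurs, and it occurs in
no genome of any other species.  The theoretical marker count ``T_i``
is the size of the resulting per-species marker set; it normalises read
counts into abundances downstream.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .enzyme import BCGI, EnzymeSpec, canonical_tag, find_tags

__all__ = ["GenomeRecord", "MarkerDB", "build_marker_db"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """A labelled reference genome (accession + species + sequence)."""

    genome_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise ValueError(
                f"genome {self.genome_id}: invalid symbols {sorted(bad)}"
            )


@dataclass
class MarkerDB:
    """Per-species sets of canonical species-specific tags.

    Attributes
    ----------
    enzyme : EnzymeSpec
    markers : dict
        species_id -> frozenset of canonical tags.
    provenance : dict
        species_id -> list of genome ids that contributed.
    dropped_species : list
        Species whose marker set came out empty (diagnostics only).
    """

    enzyme: EnzymeSpec
    markers: dict[str, frozenset[str]]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    dropped_species: list[str] = field(default_factory=list)

    @property
    def theoretical_count(self) -> dict[str, int]:
        """T_i: number of species-specific markers per species."""
        return {sp: len(tags) for sp, tags in self.markers.items()}

    @property
    def tag_length(self) -> int:
        return self.enzyme.tag_length

    def tag_index(self) -> dict[str, str]:
        """Mapping canonical tag -> owning species (tags are disjoint)."""
        idx: dict[str, str] = {}
        for sp, tags in self.markers.items():
            for t in tags:
                idx[t] = sp
        return idx

    def validate(self) -> None:
        """Assert the DB invariants (disjointness, homogeneity, T_i > 0)."""
        seen: dict[str, str] = {}
        L = self.tag_length
        for sp, tags in self.markers.items():
            if not tags:
                raise AssertionError(f"species {sp} has an empty marker set")
            for t in tags:
                if len(t) != L:
                    raise AssertionError(f"tag length {len(t)} != {L}")
                if t in seen:
                    raise AssertionError(
                        f"tag shared by {seen[t]} and {sp}: not species-specific"
                    )
                seen[t] = sp

    # ---------------------------------------------------------------- io
    def save(self, outdir: str | Path, gz: bool = False) -> None:
        """Write the DB as a (species_id, tag) TSV plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        name = "markers.tsv.gz" if gz else "markers.tsv"
        opener = gzip.open if gz else open
        with opener(outdir / name, "wt") as fh:
            fh.write("species_id\ttag\n")
            for sp in sorted(self.markers):
                for t in sorted(self.markers[sp]):
                    fh.write(f"{sp}\t{t}\n")
        sidecar = {
            "enzyme": {
                "name": self.enzyme.name,
                "recognition": self.enzyme.recognition,
                "flank_len": self.enzyme.flank_len,
            },
            "theoretical_count": self.theoretical_count,
            "provenance": self.provenance,
            "dropped_species": self.dropped_species,
        }
        (outdir / "markers.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "MarkerDB":
        outdir = Path(outdir)
        meta = json.loads((outdir / "markers.json").read_text())
        enzyme = EnzymeSpec(**meta["enzyme"])
        markers: dict[str, set[str]] = defaultdict(set)
        path = outdir / "markers.tsv"
        opener = open
        if not path.exists():
            path = outdir / "markers.tsv.gz"
            opener = gzip.open
        with opener(path, "rt") as fh:
            next(fh)  # header
            for line in fh:
                sp, tag = line.rstrip("\n").split("\t")
                markers[sp].add(tag)
        db = cls(
            enzyme=enzyme,
            markers={sp: frozenset(t) for sp, t in markers.items()},
            provenance=meta.get("provenance", {}),
            dropped_species=meta.get("dropped_species", []),
        )
        db.validate()
        return db


def build_marker_db(
    genomes: list[GenomeRecord], enzyme: EnzymeSpec = BCGI
) -> MarkerDB:
    """Digest labelled genomes in silico and keep species-specific tags.

    A tag qualifies as a marker for species *i* iff (a) within each
    genome of species *i* where it occurs it occurs exactly once, and
    (b) it occurs in no genome of any other species.  Tags containing N
    never arise (dropped during digestion).  Species with no surviving
    marker are listed in ``dropped_species`` and omitted.
    """
    if not genomes:
        raise ValueError("empty genome set")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome_id(s): {dupes}")

    # canonical tag -> species -> max within-one-genome copy number
    copy_number: dict[str, dict[str, int]] = defaultdict(dict)
    provenance: dict[str, set[str]] = defaultdict(set)
    all_species: list[str] = []
    for g in sorted(genomes, key=lambda g: g.genome_id):
        if g.species_id not in all_species:
            all_species.append(g.species_id)
        provenance[g.species_id].add(g.genome_id)
        per_genome = Counter(
            canonical_tag(tag) for _, _, tag in find_tags(g.sequence, enzyme)
        )
        for tag, n in per_genome.items():
            prev = copy_number[tag].get(g.species_id, 0)
            copy_number[tag][g.species_id] = max(prev, n)

    markers: dict[str, set[str]] = defaultdict(set)
    for tag, by_species in copy_number.items():
        if len(by_species) != 1:
            continue  # shared across species
        (sp, n), = by_species.items()
        if n == 1:  # single-copy in every genome where present
            markers[sp].add(tag)

    kept = {sp: frozenset(t) for sp, t in markers.items() if t}
    dropped = sorted(sp for sp in all_species if sp not in kept)
    db = MarkerDB(
        enzyme=enzyme,
        markers=kept,
        provenance={sp: sorted(g) for sp, g in provenance.items() if sp in kept},
        dropped_species=dropped,
    )
    db.validate()
    return db
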