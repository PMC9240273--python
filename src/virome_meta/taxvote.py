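"""Majority-vote taxonomic assignment of phage genomes from ORF protein hits.

Each predicted ORF of a genome carries protein-database hits with bit
scores, e-values and a (possibly partial) lineage.  Annotation keeps, per
ORF, the best-scoring hit below the e-value cutoff, then votes rank by
rank: the plurality taxon among the retained ORFs wins; genomes with
fewer than two retained ORFs, and ranks with tied pluralities, are left
UNCLASSIFIED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "OrfHit",
    "GenomeAnnotation",
    "best_hit_per_orf",
    "vote_taxonomy",
    "annotate_genomes",
    "read_hits_tsv",
    "UNCLASSIFIED",
    "RANKS",
    "DEFAULT_EVALUE_MAX",
]

UNCLASSIFIED = "UNCLASSIFIED"
RANKS = ("family", "genus", "species")
#: conventional blastp significance cutoff
DEFAULT_EVALUE_MAX = 1e-5
#: genomes with fewer retained ORFs than this are unclassified at every rank
MIN_ORFS = 2


@dataclass(frozen=True)
class OrfHit:
    genome_id: str
    orf_id: str
    protein_id: str
    bit_score: float
    e_value: float
    lineage: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")


@dataclass(frozen=True)
class GenomeAnnotation:
    genome_id: str
    assignment: Mapping[str, str]   # rank -> taxon or UNCLASSIFIED
    support: Mapping[str, float]    # rank -> vote fraction; only for classified ranks
    n_orfs_used: int


def best_hit_per_orf(hits: Iterable[OrfHit], e_value_max: float = DEFAULT_EVALUE_MAX) -> dict[str, OrfHit]:
    """Best (highest bit score) surviving hit per ORF.

    Hits with e-value >= ``e_value_max`` are discarded; bit-score ties are
    broken by the lexicographically smallest protein id so the result is
    independent of input row order.
    """
    if e_value_max <= 0:
        raise ValueError("e_value_max must be positive")
    best: dict[str, OrfHit] = {}
    for hit in hits:
        if hit.e_value >= e_value_max:
            continue
        cur = best.get(hit.orf_id)
        if cur is None or (hit.bit_score, _neg_lex(hit.protein_id)) > (cur.bit_score, _neg_lex(cur.protein_id)):
            best[hit.orf_id] = hit
    return best


class _neg_lex(str):
    """Orders strings descending, so max() picks the lexicographically smallest."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def vote_taxonomy(best_hits: Mapping[str, OrfHit], genome_id: str,
                  ranks: tuple[str, ...] = RANKS) -> GenomeAnnotation:
    """Rank-wise plurality vote over the retained ORF hits of one genome.

    Each rank is voted independently over the ORFs whose lineage carries
    that rank.  Plurality ties and genomes with fewer than two retained
    ORFs are UNCLASSIFIED.
    """
    hits = list(best_hits.values())
    for h in hits:
        if h.genome_id != genome_id:
            raise ValueError(f"hit for {h.genome_id!r} mixed into genome {genome_id!r}")
    assignment: dict[str, str] = {}
    support: dict[str, float] = {}
    if len(hits) < MIN_ORFS:
        assignment = {r: UNCLASSIFIED for r in ranks}
        return GenomeAnnotation(genome_id, assignment, support, len(hits))
    for rank in ranks:
        votes: dict[str, int] = {}
        for h in hits:
            taxon = h.lineage.get(rank)
            if taxon:
                votes[taxon] = votes.get(taxon, 0) + 1
        if not votes:
            assignment[rank] = UNCLASSIFIED
            continue
        top = max(votes.values())
        winners = [t for t, c in votes.items() if c == top]
        if len(winners) != 1:
            assignment[rank] = UNCLASSIFIED
            continue
        total = sum(votes.values())
        assignment[rank] = winners[0]
        support[rank] = top / total
    return GenomeAnnotation(genome_id, assignment, support, len(hits))


def annotate_genomes(hits: Iterable[OrfHit],
                     e_value_max: float = DEFAULT_EVALUE_MAX) -> list[GenomeAnnotation]:
    """Full annotation: group hits by genome, pick best hits, vote per rank."""
    by_genome: dict[str, list[OrfHit]] = {}
    for hit in hits:
        by_genome.setdefault(hit.genome_id, []).append(hit)
    return [
        vote_taxonomy(best_hit_per_orf(genome_hits, e_value_max), gid)
        for gid, genome_hits in sorted(by_genome.items())
    ]


def read_hits_tsv(path) -> list[OrfHit]:
    """Read an ORF hit table (genome_id, orf_id, protein_id, bit_score,
    e_value, family, genus, species); empty lineage cells are absent ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "orf_id", "protein_id", "bit_score", "e_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        lineage = {
            rank: getattr(row, rank)
            for rank in RANKS
            if rank in df.columns and isinstance(getattr(row, rank), str) and getattr(row, rank)
        }
        hits.append(OrfHit(
            genome_id=row.genome_id,
            orf_id=row.orf_id,
            protein_id=row.protein_id,
            bit_score=float(row.bit_score),
            e_value=float(row.e_value),
            lineage=lineage,
        ))
    return hits


def annotations_to_frame(annotations: Iterable[GenomeAnnotation]) -> pd.DataFrame:
    """Flatten annotations to a table with per-rank assignment and support."""
    rows = []
    for ann in annotations:
        row: dict[str, object] = {"genome_id": ann.genome_id, "n_orfs_used": ann.n_orfs_used}
        for rank in RANKS:
            row[rank] = ann.assignment.get(rank, UNCLASSIFIED)
            row[f"{rank}_support"] = ann.support.get(rank, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
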