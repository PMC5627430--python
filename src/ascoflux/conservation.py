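"""Ortholog conservation calls from pairwise-alignment hit tables.

A reference proteome (the enzymes behind a metabolic model) is compared
against each surveyed strain by protein alignment; this module consumes the
standard 12-column tabular output (qseqid, sseqid, pident, length, mismatch,
gapopen, qstart, qend, sstart, send, evalue, bitscore). Per query and
strain, the top hit is the one with the lowest e-value, and the query is
called conserved when that hit clears all three thresholds:

    percent identity >= 40, aligned length >= 50% of the query length,
    e-value < 1e-5

(identity and coverage thresholds inclusive, e-value strictly below).
Fractions are aggregated per strain and per (strain, subsystem), and
non-conserved queries are further classified: rescued by a conserved
isozyme of the same reaction, annotation-similar (an externally curated
flag), or absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AlignmentHit",
    "ConservationCall",
    "ConservationThresholds",
    "ConservationSummary",
    "parse_hits",
    "parse_query_lengths",
    "parse_subsystem_map",
    "best_hit_per_query",
    "call_conservation",
    "summarize",
    "classify_nonhomologs",
]

TABULAR_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    subject_strain: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    query_length: int

    def __post_init__(self) -> None:
        if self.alignment_length <= 0 or self.query_length <= 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: lengths must be positive"
            )
        if self.e_value < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative e-value")


@dataclass(frozen=True)
class ConservationThresholds:
    min_identity: float = 40.0  # percent, inclusive
    min_coverage: float = 0.5  # fraction of query length aligned, inclusive
    max_e: float = 1e-5  # strict upper bound

    def passes(self, hit: AlignmentHit) -> bool:
        return (
            hit.percent_identity >= self.min_identity
            and hit.alignment_length >= self.min_coverage * hit.query_length
            and hit.e_value < self.max_e
        )


@dataclass
class ConservationCall:
    query_id: str
    subject_strain: str
    conserved: bool
    best_hit: AlignmentHit | None = None


@dataclass
class ConservationSummary:
    per_strain_fraction: dict[str, float]
    per_subsystem_matrix: dict[tuple[str, str], float]
    n_queries: int

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (strain, subsystem, fraction) table for heat-mapping."""
        records = [
            {"strain": s, "subsystem": sub, "fraction": f}
            for (s, sub), f in sorted(self.per_subsystem_matrix.items())
        ]
        return pd.DataFrame.from_records(
            records, columns=["strain", "subsystem", "fraction"]
        )


def parse_hits(
    path: str | Path, query_lengths: dict[str, int], strain: str
) -> list[AlignmentHit]:
    """Read a 12-column tabular alignment file for one subject strain."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            query = fields[0]
            if query not in query_lengths:
                raise KeyError(f"{path}:{lineno}: query {query!r} missing from query_lengths")
            try:
                hits.append(
                    AlignmentHit(
                        query_id=query,
                        subject_id=fields[1],
                        subject_strain=strain,
                        percent_identity=float(fields[2]),
                        alignment_length=int(float(fields[3])),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                        query_length=query_lengths[query],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def parse_query_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (query_id, length_aa) with header."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(int)))


def parse_subsystem_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (query_id, subsystem) with header."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def best_hit_per_query(hits: list[AlignmentHit], strain: str) -> dict[str, AlignmentHit]:
    """Lowest-e-value hit per query against one strain.

    Ties on e-value break to the higher bit score, then lexicographically
    smaller subject id, so the result is order-independent.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.subject_strain != strain:
            continue
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
            best[hit.query_id] = hit
    return best


def _hit_rank(hit: AlignmentHit) -> tuple[float, float, str]:
    return (hit.e_value, -hit.bit_score, hit.subject_id)


def call_conservation(
    best: dict[str, AlignmentHit],
    query_lengths: dict[str, int],
    strain: str,
    thresholds: ConservationThresholds = ConservationThresholds(),
) -> list[ConservationCall]:
    """One call per query in query_lengths; queries with no hit are not conserved."""
    calls = []
    for query in sorted(query_lengths):
        hit = best.get(query)
        conserved = hit is not None and thresholds.passes(hit)
        calls.append(
            ConservationCall(
                query_id=query, subject_strain=strain, conserved=conserved, best_hit=hit
            )
        )
    return calls


def summarize(
    calls: list[ConservationCall], subsystem_map: dict[str, str]
) -> ConservationSummary:
    """Per-strain and per-(strain, subsystem) conserved fractions.

    The per-strain fraction is the plain fraction over all queries, i.e. the
    query-count-weighted mean of that strain's subsystem rows.
    """
    missing = sorted({c.query_id for c in calls} - set(subsystem_map))
    if missing:
        raise KeyError(f"queries missing from subsystem map: {missing[:5]}")
    strain_counts: dict[str, list[int]] = {}
    cell_counts: dict[tuple[str, str], list[int]] = {}
    queries: set[str] = set()
    for call in calls:
        queries.add(call.query_id)
        strain_counts.setdefault(call.subject_strain, [0, 0])
        cell = (call.subject_strain, subsystem_map[call.query_id])
        cell_counts.setdefault(cell, [0, 0])
        strain_counts[call.subject_strain][1] += 1
        cell_counts[cell][1] += 1
        if call.conserved:
            strain_counts[call.subject_strain][0] += 1
            cell_counts[cell][0] += 1
    return ConservationSummary(
        per_strain_fraction={s: k / n for s, (k, n) in strain_counts.items()},
        per_subsystem_matrix={c: k / n for c, (k, n) in cell_counts.items()},
        n_queries=len(queries),
    )


def classify_nonhomologs(
    calls: list[ConservationCall],
    reaction_enzyme_map: dict[str, list[str]],
    annotation_similarity: dict[str, bool],
) -> dict[str, int]:
    """Classify each query of one strain's calls into exactly one class.

    homolog: conserved. isozyme_rescued: not conserved, but some other
    enzyme of one of its reactions is conserved in the strain.
    annotation_similar: neither, but flagged as annotation-similar.
    absent: everything else. Classes partition the queries.
    """
    conserved = {c.query_id for c in calls if c.conserved}
    enzyme_reactions: dict[str, list[str]] = {}
    for rxn, enzymes in reaction_enzyme_map.items():
        for enzyme in enzymes:
            enzyme_reactions.setdefault(enzyme, []).append(rxn)
    counts = {"homolog": 0, "isozyme_rescued": 0, "annotation_similar": 0, "absent": 0}
    for call in calls:
        query = call.query_id
        if query in conserved:
            counts["homolog"] += 1
            continue
        rescued = any(
            other in conserved
            for rxn in enzyme_reactions.get(query, [])
            for other in reaction_enzyme_map[rxn]
            if other != query
        )
        if rescued:
            counts["isozyme_rescued"] += 1
        elif annotation_similarity.get(query, False):
            counts["annotation_similar"] += 1
        else:
            counts["absent"] += 1
    return counts
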