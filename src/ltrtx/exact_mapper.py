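"""Exact-match placement of short reads and array probes on both strands.

Short reads (30-51 nt) and 60-mer probes are located in the genome by exact
string match only -- no mismatches, no indels.  A query is then classified
against a target feature set (e.g. the full-length element set) by the
exclusivity rule: *unique* means exactly one genome-wide hit, inside the set;
*exclusive* means several hits, all inside the set; anything else (any hit
outside the set, or no hit at all) is *excluded*.  Reads containing ambiguous
base calls (N) are dropped up front.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .genome_model import FeatureCatalog
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Query:
    """A read or probe to be placed in the genome.

    Probes carry the strand whose transcription they interrogate
    (``strand_tag`` '+' or '-') and optionally a log2 signal intensity;
    reads carry no strand tag (``strand_tag`` '.').
    """

    id: str
    sequence: str
    kind: str = "read"  # {"read", "probe"}
    strand_tag: str = "."
    signal: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty query sequence")
        if self.kind == "probe" and self.strand_tag not in ("+", "-"):
            raise ValueError("probes must carry a strand tag")


@dataclass(frozen=True, order=True)
class Hit:
    chrom: str
    start: int
    end: int
    genome_strand: str  # {"+", "-"}


@dataclass
class MappingRecord:
    query_id: str
    kind: str
    strand_tag: str
    signal: Optional[float]
    hits: List[Hit]
    in_set_hits: List[Hit]
    klass: str  # {"unique", "exclusive", "excluded"}
    reason: str = ""


def find_exact_matches(query: Query, catalog: FeatureCatalog) -> List[Hit]:
    """All verbatim occurrences of the query on either genome strand.

    A forward-strand hit means the query sequence itself occurs in the genome;
    a reverse-strand hit means its reverse complement does.  Queries containing
    N return no hits (ambiguous calls are omitted from the analysis).
    Palindromic queries report one deduplicated forward hit per position.
    """
    seq = query.sequence.upper()
    if "N" in seq:
        return []
    rc = revcomp(seq)
    hits: List[Hit] = []
    for chrom, genome in catalog.chromosomes.items():
        for pos in _find_all(genome, seq):
            hits.append(Hit(chrom, pos, pos + len(seq), "+"))
        if rc != seq:  # palindromes: forward hits only
            for pos in _find_all(genome, rc):
                hits.append(Hit(chrom, pos, pos + len(seq), "-"))
    hits.sort()
    return hits


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def classify(
    query: Query,
    hits: Sequence[Hit],
    target_set: Sequence[GenomicInterval],
    mode: str = "exclusive_ok",
) -> MappingRecord:
    """Classify genome-wide hits of a query against a target feature set.

    A hit is in-set iff its full interval lies within one target interval.
    ``mode="unique_only"`` demotes exclusive multi-hit records to excluded
    (the rule used for solitary-LTR probes and all non-LTR reference
    features); ``mode="exclusive_ok"`` keeps them.
    """
    if mode not in ("exclusive_ok", "unique_only"):
        raise ValueError(f"invalid mode {mode!r}")
    if "N" in query.sequence.upper():
        return _record(query, [], [], "excluded", "ambiguous")
    hits = list(hits)
    if not hits:
        return _record(query, hits, [], "excluded", "no_match")
    in_set = [
        h
        for h in hits
        if any(t.contains(GenomicInterval(h.chrom, h.start, h.end)) for t in target_set)
    ]
    if len(hits) == 1 and len(in_set) == 1:
        return _record(query, hits, in_set, "unique", "")
    if len(hits) >= 2 and len(in_set) == len(hits):
        if mode == "unique_only":
            return _record(query, hits, in_set, "excluded", "multi_hit")
        return _record(query, hits, in_set, "exclusive", "")
    return _record(query, hits, in_set, "excluded", "outside_set")


def _record(query, hits, in_set, klass, reason) -> MappingRecord:
    return MappingRecord(
        query_id=query.id,
        kind=query.kind,
        strand_tag=query.strand_tag,
        signal=query.signal,
        hits=list(hits),
        in_set_hits=list(in_set),
        klass=klass,
        reason=reason,
    )


def find_all_matches(
    queries: Sequence[Query], catalog: FeatureCatalog
) -> List[List[Hit]]:
    """Genome-wide hits for a batch of queries (one hit list per query).

    Useful when the same queries are classified against several target sets.
    """
    return [find_exact_matches(q, catalog) for q in queries]


def classify_all(
    queries: Sequence[Query],
    hits_per_query: Sequence[Sequence[Hit]],
    target_set: Sequence[GenomicInterval],
    mode: str = "exclusive_ok",
) -> List[MappingRecord]:
    records = [
        classify(q, h, target_set, mode) for q, h in zip(queries, hits_per_query)
    ]
    counts = Counter(r.klass for r in records)
    log.info("classified %d queries: %s", len(records), dict(counts))
    return records


def map_query_table(
    queries: Sequence[Query],
    catalog: FeatureCatalog,
    target_set: Sequence[GenomicInterval],
    mode: str = "exclusive_ok",
) -> List[MappingRecord]:
    """Map and classify a batch of queries; output order follows input order."""
    records = [classify(q, find_exact_matches(q, catalog), target_set, mode) for q in queries]
    counts = Counter(r.klass for r in records)
    reasons = Counter(r.reason for r in records if r.reason)
    log.info("mapped %d queries: %s (excluded reasons: %s)", len(records), dict(counts), dict(reasons))
    return records


# ---------------------------------------------------------------------------
# I/O


def read_fastq_queries(path: Path) -> List[Query]:
    """Load reads from FASTQ (quality values are ignored)."""
    return [
        Query(id=rec.id, sequence=str(rec.seq).upper(), kind="read")
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_probe_table(path: Path) -> pd.DataFrame:
    """Probe TSV with columns probe_id, sequence, strand, intensity_1..k."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    required = {"probe_id", "sequence", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe table {path} missing columns {required - set(df.columns)}")
    return df


def probes_from_table(df: pd.DataFrame, intensity_column: Optional[str] = None) -> List[Query]:
    """Turn a probe table into queries, attaching one intensity column as signal."""
    intensity_cols = [c for c in df.columns if c.startswith("intensity")]
    if intensity_column is None:
        intensity_column = intensity_cols[0] if intensity_cols else None
    out = []
    for row in df.itertuples(index=False):
        signal = float(getattr(row, intensity_column)) if intensity_column else None
        out.append(
            Query(
                id=str(row.probe_id),
                sequence=str(row.sequence).upper(),
                kind="probe",
                strand_tag=str(row.strand),
                signal=signal,
            )
        )
    return out


def write_mapping_table(records: Sequence[MappingRecord], path: Path) -> None:
    """TSV: query_id, n_hits, n_in_set, class, hit_list (chrom:start:end:strand;...)."""
    with open(path, "w") as fh:
        fh.write("query_id\tn_hits\tn_in_set\tclass\thit_list\n")
        for r in records:
            hit_list = ";".join(f"{h.chrom}:{h.start}:{h.end}:{h.genome_strand}" for h in r.hits)
            fh.write(f"{r.query_id}\t{len(r.hits)}\t{len(r.in_set_hits)}\t{r.klass}\t{hit_list}\n")
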