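"""Genome and annotation model: feature catalog, LTR partition, background set.

The central analysis distinction is between *full-length* LTR retrotransposons
(an internal gag/pol sequence flanked by two near-identical LTRs) and
*solitary* LTRs (single terminal repeats left behind by LTR-LTR
recombination).  This module parses a genome (FASTA) plus annotation (GFF3),
partitions the annotated LTR features into those two sets, and constructs the
background reference compartments (intergenic and intronic sequence) used to
calibrate transcription signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from .intervals import GenomicInterval, clip, complement, merge_intervals

log = logging.getLogger(__name__)

FEATURE_KINDS = ("ltr", "retro_internal", "gene", "intron", "trna", "snorna", "other")

#: canonical GFF3 ``type`` column per internal feature kind
KIND_TO_GFF = {
    "ltr": "long_terminal_repeat",
    "retro_internal": "retrotransposon_internal",
    "gene": "gene",
    "intron": "intron",
    "trna": "tRNA",
    "snorna": "snoRNA",
    "other": "region",
}

_GFF_TO_KIND = {v: k for k, v in KIND_TO_GFF.items()}
_GFF_TO_KIND.update(
    {
        "LTR": "ltr",
        "ltr": "ltr",
        "LTR_retrotransposon": "retro_internal",
        "tRNA_gene": "trna",
        "snoRNA_gene": "snorna",
    }
)


@dataclass(frozen=True)
class Feature:
    id: str
    kind: str
    interval: GenomicInterval


@dataclass
class FeatureCatalog:
    """Chromosome sequences plus a flat list of annotated features."""

    chromosomes: Dict[str, str]
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for f in self.features:
            if f.id in seen:
                raise ValueError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)
            self._check_bounds(f)

    def _check_bounds(self, f: Feature) -> None:
        if f.interval.chrom not in self.chromosomes:
            raise ValueError(f"feature {f.id!r}: unknown chromosome {f.interval.chrom!r}")
        if f.interval.end > len(self.chromosomes[f.interval.chrom]):
            raise ValueError(
                f"feature {f.id!r} exceeds chromosome bounds "
                f"({f.interval.end} > {len(self.chromosomes[f.interval.chrom])})"
            )

    def add(self, feature: Feature) -> None:
        if any(f.id == feature.id for f in self.features):
            raise ValueError(f"duplicate feature id {feature.id!r}")
        self._check_bounds(feature)
        self.features.append(feature)

    def by_kind(self, kind: str) -> List[Feature]:
        return [f for f in self.features if f.kind == kind]

    def chrom_length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def sequence(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; reverse-complemented for '-' strand."""
        s = self.chromosomes[interval.chrom][interval.start : interval.end]
        if interval.strand == "-":
            return str(Seq(s).reverse_complement())
        return s


@dataclass
class LtrLocus:
    """A single annotated LTR, either solitary or flanking a full element.

    A chimeric [LTR-internal-LTR-internal-LTR] arrangement is modelled as two
    elements sharing the middle LTR, so ``element_ids`` may name two elements.
    """

    id: str
    interval: GenomicInterval
    role: str  # {"solitary", "flanking"}
    element_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("solitary", "flanking"):
            raise ValueError(f"invalid role {self.role!r}")
        if (self.role == "flanking") != bool(self.element_ids):
            raise ValueError("role=flanking iff element_ids set")

    @property
    def element_id(self) -> Optional[str]:
        return self.element_ids[0] if self.element_ids else None


@dataclass
class FullLengthElement:
    """Internal sequence flanked by (at least) two LTRs."""

    id: str
    ltrs: List[LtrLocus]
    internal: GenomicInterval
    span: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.ltrs) < 2:
            raise ValueError("a full-length element needs >= 2 LTRs")

    @property
    def parts(self) -> List[GenomicInterval]:
        """All constituent intervals (LTRs + internal)."""
        return [l.interval for l in self.ltrs] + [self.internal]

    @property
    def three_prime_ltr(self) -> LtrLocus:
        """Rightmost LTR of this element (forward-orientation convention)."""
        return max(self.ltrs, key=lambda l: l.interval.start)


@dataclass
class BackgroundSet:
    intergenic: List[GenomicInterval]
    intronic: List[GenomicInterval]
    utr_flank: int = 240
    min_len: int = 100


# ---------------------------------------------------------------------------
# I/O


def parse_annotation(genome_fasta: Path, annotation_gff: Path) -> FeatureCatalog:
    """Parse a FASTA genome plus GFF3 annotation into a FeatureCatalog.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Unknown chromosomes, malformed lines and out-of-bounds features raise
    ValueError naming the offending line.
    """
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    if not chroms:
        raise ValueError(f"no sequences found in {genome_fasta}")

    features: List[Feature] = []
    auto = 0
    with open(annotation_gff) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{annotation_gff}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{annotation_gff}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{annotation_gff}:{lineno}: end < start ({end1} < {start1})")
            if seqid not in chroms:
                raise ValueError(f"{annotation_gff}:{lineno}: unknown chromosome {seqid!r}")
            if end1 > len(chroms[seqid]):
                raise ValueError(
                    f"{annotation_gff}:{lineno}: feature exceeds chromosome bounds "
                    f"({end1} > {len(chroms[seqid])})"
                )
            kind = _GFF_TO_KIND.get(ftype, "other")
            fid = _attr_value(attrs, "ID")
            if fid is None:
                auto += 1
                fid = f"{ftype}_{auto:05d}"
            if strand not in ("+", "-", "."):
                strand = "."
            iv = GenomicInterval(seqid, start1 - 1, end1, strand)
            features.append(Feature(fid, kind, iv))
    return FeatureCatalog(chromosomes=chroms, features=features)


def _attr_value(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff(catalog: FeatureCatalog, path: Path) -> None:
    """Write the catalog back to GFF3 (round-trips with parse_annotation)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in catalog.chromosomes.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for f in catalog.features:
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "ltrtx",
                        KIND_TO_GFF[f.kind],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand in "+-" else ".",
                        ".",
                        f"ID={f.id}",
                    ]
                )
                + "\n"
            )


def write_fasta(catalog: FeatureCatalog, path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in catalog.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_ltr_table(
    elements: Sequence[FullLengthElement],
    solitary: Sequence[LtrLocus],
    path: Path,
) -> None:
    """TSV of all LTR loci: id, chrom, start, end, role, element_id."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\trole\telement_id\n")
        seen = set()
        for el in elements:
            for ltr in el.ltrs:
                if ltr.id in seen:
                    continue
                seen.add(ltr.id)
                iv = ltr.interval
                fh.write(
                    f"{ltr.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\tflanking\t"
                    f"{','.join(ltr.element_ids)}\n"
                )
        for ltr in solitary:
            iv = ltr.interval
            fh.write(f"{ltr.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\tsolitary\t\n")


# ---------------------------------------------------------------------------
# Partition


def partition_ltrs(
    catalog: FeatureCatalog, gap_tol: int = 50
) -> Tuple[List[FullLengthElement], List[LtrLocus]]:
    """Split annotated LTRs into full-length elements and solitary LTRs.

    An LTR within ``gap_tol`` bp of a retrotransposon-internal sequence on its
    correct side becomes a flanking LTR of that element; all others are
    solitary.  Chains LTR-int-LTR-int-LTR yield two elements sharing the
    middle LTR.  An internal sequence lacking an adjacent LTR on either side
    is excluded with a warning and its adjacent LTRs fall back to solitary.
    """
    ltr_feats = sorted(catalog.by_kind("ltr"), key=lambda f: (f.interval.chrom, f.interval.start))
    internals = sorted(
        catalog.by_kind("retro_internal"), key=lambda f: (f.interval.chrom, f.interval.start)
    )

    # candidate flanking LTR on each side of each internal sequence
    pairings: List[Tuple[Feature, Optional[Feature], Optional[Feature]]] = []
    for internal in internals:
        left = right = None
        for ltr in ltr_feats:
            if ltr.interval.chrom != internal.interval.chrom:
                continue
            lgap = internal.interval.start - ltr.interval.end
            rgap = ltr.interval.start - internal.interval.end
            if 0 <= lgap <= gap_tol and (left is None or ltr.interval.end > left.interval.end):
                left = ltr
            if 0 <= rgap <= gap_tol and (right is None or ltr.interval.start < right.interval.start):
                right = ltr
        pairings.append((internal, left, right))

    loci: Dict[str, LtrLocus] = {}
    flanking_ids = set()
    element_of: Dict[str, List[str]] = {}
    specs: List[Tuple[str, Feature, Feature, Feature]] = []

    for internal, left, right in pairings:
        if left is None or right is None:
            warnings.warn(
                f"internal sequence {internal.id!r} lacks two adjacent LTRs "
                f"(gap_tol={gap_tol}); excluded from the full-length set",
                stacklevel=2,
            )
            continue
        eid = f"FLE-{internal.id}"
        for ltr in (left, right):
            flanking_ids.add(ltr.id)
            element_of.setdefault(ltr.id, []).append(eid)
        specs.append((eid, internal, left, right))

    elements: List[FullLengthElement] = []
    for eid, internal, left, right in specs:
        pair = []
        for ltr_feat in (left, right):
            if ltr_feat.id not in loci:
                loci[ltr_feat.id] = LtrLocus(
                    id=ltr_feat.id,
                    interval=ltr_feat.interval,
                    role="flanking",
                    element_ids=tuple(element_of[ltr_feat.id]),
                )
            pair.append(loci[ltr_feat.id])
        span = GenomicInterval(
            internal.interval.chrom, left.interval.start, right.interval.end
        )
        elements.append(
            FullLengthElement(id=eid, ltrs=pair, internal=internal.interval, span=span)
        )

    solitary = [
        LtrLocus(id=f.id, interval=f.interval, role="solitary")
        for f in ltr_feats
        if f.id not in flanking_ids
    ]
    n_flanking = len({l.id for el in elements for l in el.ltrs})
    log.info(
        "partitioned %d LTR features: %d flanking (%d elements), %d solitary",
        len(ltr_feats), n_flanking, len(elements), len(solitary),
    )
    return elements, solitary


# ---------------------------------------------------------------------------
# Background


def build_background(
    catalog: FeatureCatalog, utr_flank: int = 240, min_len: int = 100
) -> BackgroundSet:
    """Intergenic and intronic background compartments.

    Intergenic sequence is everything outside protein-coding genes (padded by
    ``utr_flank`` bp on both sides to avoid UTRs), tRNAs, snoRNAs and LTR /
    retrotransposon-internal features; only stretches of at least ``min_len``
    bp are kept.
    """
    blocks: List[GenomicInterval] = []
    for f in catalog.features:
        iv = f.interval
        if f.kind == "gene":
            L = catalog.chrom_length(iv.chrom)
            s, e = clip(iv.start - utr_flank, iv.end + utr_flank, L)
            blocks.append(GenomicInterval(iv.chrom, s, e))
        elif f.kind in ("trna", "snorna", "ltr", "retro_internal"):
            blocks.append(GenomicInterval(iv.chrom, iv.start, iv.end))

    intergenic: List[GenomicInterval] = []
    for chrom, seq in catalog.chromosomes.items():
        for iv in complement(blocks, chrom, len(seq)):
            if iv.length >= min_len:
                intergenic.append(iv)

    intronic = [
        GenomicInterval(f.interval.chrom, f.interval.start, f.interval.end)
        for f in catalog.by_kind("intron")
        if f.interval.length >= min_len
    ]
    return BackgroundSet(
        intergenic=intergenic, intronic=intronic, utr_flank=utr_flank, min_len=min_len
    )


def nearest_upstream_gene(
    ltr: LtrLocus, catalog: FeatureCatalog
) -> Optional[Tuple[str, int]]:
    """Nearest protein-coding gene with the LTR in its upstream region.

    Upstream is defined relative to gene orientation: for a '+' gene the LTR
    must lie left of the gene start, for a '-' gene right of the gene end.
    Returns (gene_id, distance_bp) or None.
    """
    best: Optional[Tuple[str, int]] = None
    iv = ltr.interval
    for g in catalog.by_kind("gene"):
        gv = g.interval
        if gv.chrom != iv.chrom:
            continue
        if gv.strand == "-":
            if iv.start >= gv.end:
                d = iv.start - gv.end
            else:
                continue
        else:
            if iv.end <= gv.start:
                d = gv.start - iv.end
            else:
                continue
        if best is None or d < best[1]:
            best = (g.id, d)
    return best
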