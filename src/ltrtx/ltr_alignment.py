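"""Solitary-LTR clustering, alignment-column projection, flank frames,
sliding-window densities and the in-LTR vs flank intensity contrast.

The solitary LTRs of fission yeast are divergent descendants of a common
family ancestor.  To compare signal across loci they are clustered by global
pairwise identity (single-linkage at a 70% cut-off), the largest cluster is
multiply aligned (by an external aligner; the aligned FASTA is consumed
here), and individual probe/read mappings are projected onto alignment
columns via the midpoint of the mapped interval.  Flank frames extend each
LTR by up to 500 bp of genomic context (half-distance rule, 60 bp minimum)
to test whether transcription is confined to the LTR itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from Bio import Align, AlignIO

from .exact_mapper import MappingRecord
from .genome_model import FeatureCatalog, LtrLocus
from .intervals import GenomicInterval
from . import perm_stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alignment container


@dataclass
class Alignment:
    """A multiple alignment with per-row residue-to-column maps."""

    rows: List[Tuple[str, str]]  # (locus_id, gapped sequence)
    seq_to_col: Dict[str, np.ndarray]

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> List[str]:
        return [rid for rid, _ in self.rows]

    @classmethod
    def from_rows(cls, rows: Sequence[Tuple[str, str]]) -> "Alignment":
        rows = [(rid, seq.upper()) for rid, seq in rows]
        if len({len(seq) for _, seq in rows}) > 1:
            raise ValueError("alignment rows differ in length")
        seq_to_col = {
            rid: np.array([i for i, c in enumerate(seq) if c != "-"], dtype=int)
            for rid, seq in rows
        }
        return cls(rows=list(rows), seq_to_col=seq_to_col)

    @classmethod
    def from_fasta(cls, path: Path) -> "Alignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls.from_rows([(rec.id, str(rec.seq)) for rec in aln])

    def to_fasta(self, path: Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.rows:
                fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Pairwise identity and clustering

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment of *a* and *b*.

    Gap columns count in the denominator, so length differences are
    penalised.  Scores: match +1, mismatch -1, gap -2.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_ltrs(
    seqs: Mapping[str, str], threshold: float = 0.70
) -> List[List[str]]:
    """Single-linkage clusters of sequences at a pairwise-identity cut-off.

    Two sequences are linked if their identity is >= threshold; clusters are
    the connected components (so a cluster is collapsed with another whenever
    any member pair crosses the threshold).  Output is deterministic: clusters
    ordered by their smallest member id, members sorted.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    g = nx.Graph()
    ids = sorted(seqs)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(seqs[a], seqs[b]) >= threshold:
                g.add_edge(a, b)
    clusters = [sorted(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: c[0])
    return clusters


def cluster_size_sweep(
    seqs: Mapping[str, str], thresholds: Sequence[float]
) -> List[Tuple[float, int, int]]:
    """Diagnostic table (threshold, n_clusters, largest_cluster_size).

    The identity cut-off is chosen by eye from how cluster sizes change
    across thresholds; no automatic selection rule is applied.
    """
    out = []
    for t in thresholds:
        clusters = cluster_ltrs(seqs, threshold=t)
        out.append((t, len(clusters), max(len(c) for c in clusters)))
    return out


# ---------------------------------------------------------------------------
# Projection onto alignment columns


def project_to_alignment(
    record: MappingRecord,
    alignment: Alignment,
    set_order: Sequence[str],
    loci: Mapping[str, GenomicInterval],
) -> Optional[Tuple[int, str]]:
    """Project a mapping onto an alignment column via its midpoint.

    The first locus in ``set_order`` hit by the query is selected; the
    midpoint residue of the mapped interval on that locus (left-of-centre for
    even lengths) is transferred to its alignment column.  Returns
    (column, locus_id), or None if no hit locus is in the alignment.  When
    projecting within full-length elements, pass a ``set_order`` that lists
    each element's 3' LTR first: probes hitting both flanking LTRs are then
    conventionally placed on the 3' LTR.
    """
    for lid in set_order:
        if lid not in alignment.seq_to_col or lid not in loci:
            continue
        iv = loci[lid]
        for h in record.hits:
            hv = GenomicInterval(h.chrom, h.start, h.end)
            if iv.contains(hv):
                if iv.strand == "-":
                    s = iv.end - h.end
                    e = iv.end - h.start
                else:
                    s = h.start - iv.start
                    e = h.end - iv.start
                mid = (s + e - 1) // 2
                col_map = alignment.seq_to_col[lid]
                if mid >= len(col_map):
                    break
                return int(col_map[mid]), lid
    log.debug("query %s: no hit locus present in alignment", record.query_id)
    return None


def element_projection_order(elements) -> List[str]:
    """Locus order listing each element's 3' LTR before its 5' LTR."""
    order: List[str] = []
    for el in elements:
        three = el.three_prime_ltr.id
        order.append(three)
        order.extend(l.id for l in el.ltrs if l.id != three and l.id not in order)
    return order


# ---------------------------------------------------------------------------
# Flank frames


@dataclass
class FlankFrame:
    """Genomic windows immediately up-/downstream of a solitary LTR.

    Flank length follows the distance to the nearest annotated feature: the
    full ``max_flank`` if that distance is at least ``near_threshold``;
    otherwise half the distance, and no flank at all if that half falls below
    ``min_flank``.
    """

    locus_id: str
    ltr_interval: GenomicInterval
    up_flank: Optional[GenomicInterval]
    down_flank: Optional[GenomicInterval]
    max_flank: int = 500
    near_threshold: int = 1000
    min_flank: int = 60


def build_flank_frame(
    ltr: LtrLocus,
    catalog: FeatureCatalog,
    max_flank: int = 500,
    near_threshold: int = 1000,
    min_flank: int = 60,
) -> FlankFrame:
    """Flank windows for one LTR under the half-distance / minimum rules.

    Distances are measured to the nearest annotated feature on each side
    (introns are skipped: their genes already count).  At a chromosome edge
    the flank is truncated at the edge.
    """
    iv = ltr.interval
    chrom_len = catalog.chrom_length(iv.chrom)

    up_d: Optional[int] = None
    down_d: Optional[int] = None
    for f in catalog.features:
        fv = f.interval
        if fv.chrom != iv.chrom or f.id == ltr.id or f.kind == "intron":
            continue
        if fv.end <= iv.start:
            d = iv.start - fv.end
            up_d = d if up_d is None else min(up_d, d)
        elif fv.start >= iv.end:
            d = fv.start - iv.end
            down_d = d if down_d is None else min(down_d, d)

    def _flank_len(d: Optional[int]) -> Optional[int]:
        if d is None:
            return max_flank
        if d >= near_threshold:
            return max_flank
        half = d // 2
        return half if half >= min_flank else None

    up_len = _flank_len(up_d)
    down_len = _flank_len(down_d)

    up = None
    if up_len:
        s = max(0, iv.start - up_len)
        if s < iv.start:
            up = GenomicInterval(iv.chrom, s, iv.start)
    down = None
    if down_len:
        e = min(chrom_len, iv.end + down_len)
        if e > iv.end:
            down = GenomicInterval(iv.chrom, iv.end, e)
    return FlankFrame(ltr.id, iv, up, down, max_flank, near_threshold, min_flank)


def write_flank_table(frames: Sequence[FlankFrame], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tup_start\tup_end\tdown_start\tdown_end\n")
        for fr in frames:
            u = (fr.up_flank.start, fr.up_flank.end) if fr.up_flank else ("", "")
            d = (fr.down_flank.start, fr.down_flank.end) if fr.down_flank else ("", "")
            fh.write(f"{fr.locus_id}\t{u[0]}\t{u[1]}\t{d[0]}\t{d[1]}\n")


# ---------------------------------------------------------------------------
# Sliding-window density


def window_density(
    column_positions: Sequence[int],
    ncols: int,
    n_rows: int,
    window: int = 301,
    weights: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Centred moving average of per-column counts, per aligned sequence.

    Each position contributes its weight (default 1) to its column; the
    profile is the windowed mean divided by ``n_rows`` (reads mapped per
    sequence in the alignment).  The window is truncated at the alignment
    ends (the mean is over the columns actually covered).
    """
    if window % 2 != 1:
        raise ValueError("window length must be odd")
    if window > ncols:
        raise ValueError(f"window {window} exceeds alignment width {ncols}")
    counts = np.zeros(ncols)
    w = np.ones(len(column_positions)) if weights is None else np.asarray(weights, float)
    np.add.at(counts, np.asarray(column_positions, dtype=int), w)
    kernel = np.ones(window)
    sums = np.convolve(counts, kernel, mode="same")
    cover = np.convolve(np.ones(ncols), kernel, mode="same")
    return sums / cover / n_rows


def write_density_table(density: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tdensity\n")
        for i, d in enumerate(density):
            fh.write(f"{i}\t{d:.6g}\n")


# ---------------------------------------------------------------------------
# In-LTR vs flank contrast


@dataclass
class FlankContrast:
    median_in: float
    median_up: Optional[float]
    median_down: Optional[float]
    u_up: Optional[float]
    p_up: Optional[float]
    u_down: Optional[float]
    p_down: Optional[float]
    n_in: int
    n_up: int
    n_down: int


def flank_contrast(
    frames: Sequence[FlankFrame], probe_records: Sequence[MappingRecord]
) -> FlankContrast:
    """Compare probe intensities inside LTRs vs their up-/downstream flanks.

    Probes are assigned to compartments by full containment of their (single)
    genome-wide hit in the LTR interval or a flank window; multi-hit probes
    are skipped, so placement is unambiguous even for probes falling outside
    the LTR analysis set proper.  Mann-Whitney compares the in-LTR group
    against each flank group (U reported for the in-LTR group).  An empty
    flank compartment skips that comparison.
    """
    in_vals: List[float] = []
    up_vals: List[float] = []
    down_vals: List[float] = []
    for r in probe_records:
        if len(r.hits) != 1 or r.signal is None:
            continue
        for h in r.hits:
            hv = GenomicInterval(h.chrom, h.start, h.end)
            placed = False
            for fr in frames:
                if fr.ltr_interval.contains(hv):
                    in_vals.append(r.signal)
                    placed = True
                elif fr.up_flank and fr.up_flank.contains(hv):
                    up_vals.append(r.signal)
                    placed = True
                elif fr.down_flank and fr.down_flank.contains(hv):
                    down_vals.append(r.signal)
                    placed = True
                if placed:
                    break
            if placed:
                break

    def _compare(flank_vals):
        if not in_vals or not flank_vals:
            log.info("flank_contrast: empty compartment, comparison skipped")
            return None, None, None
        u, p = perm_stats.mann_whitney(in_vals, flank_vals)
        return float(np.median(flank_vals)), u, p

    median_up, u_up, p_up = _compare(up_vals)
    median_down, u_down, p_down = _compare(down_vals)
    return FlankContrast(
        median_in=float(np.median(in_vals)) if in_vals else float("nan"),
        median_up=median_up,
        median_down=median_down,
        u_up=u_up,
        p_up=p_up,
        u_down=u_down,
        p_down=p_down,
        n_in=len(in_vals),
        n_up=len(up_vals),
        n_down=len(down_vals),
    )
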