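"""Per-locus activity under multi-mapping ambiguity.

Because LTR sequences are highly redundant, most reads/probes hit several
loci and per-locus activity is only *bounded*, not measured.  Two bounding
scenarios are computed:

* ``equal_split`` -- every query's signal is divided evenly between the loci
  it hits (all loci equally active: the lower, "democratic" bound);
* ``single_locus_max`` -- every locus is granted the full signal of every
  query that could come from it (a per-locus upper bound, computed
  independently per locus, *not* a globally consistent allocation).

Unique evidence (queries with a single genome-wide hit) is a floor below
both.  A *locus* may consist of several genomic intervals (a full-length
element = two LTRs + internal sequence), so loci are given as a mapping
``locus_id -> list of intervals``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .exact_mapper import MappingRecord
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

LociMap = Mapping[str, Sequence[GenomicInterval]]


@dataclass
class LocusSignal:
    locus_id: str
    scenario: str  # {"equal_split", "single_locus_max", "unique_only"}
    value: float
    density: float  # value / total locus length in bp
    strand: str  # {"+", "-", "combined"}


def _locus_lengths(loci: LociMap) -> Dict[str, int]:
    return {lid: sum(iv.length for iv in ivs) for lid, ivs in loci.items()}


def _hit_loci(record: MappingRecord, loci: LociMap) -> List[str]:
    """Distinct loci containing at least one of the record's hits."""
    out = []
    for lid, ivs in loci.items():
        for h in record.hits:
            hv = GenomicInterval(h.chrom, h.start, h.end)
            if any(iv.contains(hv) for iv in ivs):
                out.append(lid)
                break
    return out


def _signal(record: MappingRecord) -> float:
    return 1.0 if record.signal is None else float(record.signal)


def _strand(record: MappingRecord) -> str:
    return record.strand_tag if record.kind == "probe" else "combined"


def equal_split(records: Sequence[MappingRecord], loci: LociMap) -> List[LocusSignal]:
    """Divide each query's signal evenly between the loci it hits.

    E.g. two LTR loci sharing one read are assigned 0.5 read each.  Only
    unique/exclusive records contribute; excluded records are counted and
    ignored.  Probes contribute per strand tag, reads to the combined strand.
    """
    return _assign(records, loci, split=True, scenario="equal_split")


def single_locus_max(records: Sequence[MappingRecord], loci: LociMap) -> List[LocusSignal]:
    """Upper bound: each locus claims the full signal of every shared query."""
    return _assign(records, loci, split=False, scenario="single_locus_max")


def unique_only(records: Sequence[MappingRecord], loci: LociMap) -> List[LocusSignal]:
    """Floor: only uniquely-mapping queries contribute."""
    uniq = [r for r in records if r.klass == "unique"]
    return _assign(uniq, loci, split=True, scenario="unique_only")


def _assign(records, loci: LociMap, split: bool, scenario: str) -> List[LocusSignal]:
    lengths = _locus_lengths(loci)
    acc: Dict[Tuple[str, str], float] = {}
    n_skipped = 0
    for r in records:
        if r.klass not in ("unique", "exclusive"):
            n_skipped += 1
            continue
        hit = _hit_loci(r, loci)
        if not hit:
            n_skipped += 1
            continue
        share = _signal(r) / len(hit) if split else _signal(r)
        for lid in hit:
            key = (lid, _strand(r))
            acc[key] = acc.get(key, 0.0) + share
    if n_skipped:
        log.info("%s: %d records skipped (excluded or outside loci)", scenario, n_skipped)
    out = []
    for lid, ivs in loci.items():
        strands = sorted({s for (l, s) in acc if l == lid}) or []
        for strand in strands:
            value = acc[(lid, strand)]
            out.append(
                LocusSignal(lid, scenario, value, value / lengths[lid], strand)
            )
    return out


def per_locus_mean_intensity(
    records: Sequence[MappingRecord], loci: LociMap
) -> Dict[Tuple[str, str], float]:
    """Mean intensity of uniquely-mapping probes per (locus, strand).

    Loci with no unique probes are omitted.
    """
    sums: Dict[Tuple[str, str], float] = {}
    counts: Dict[Tuple[str, str], int] = {}
    for r in records:
        if r.klass != "unique" or r.kind != "probe":
            continue
        for lid in _hit_loci(r, loci):
            key = (lid, r.strand_tag)
            sums[key] = sums.get(key, 0.0) + _signal(r)
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sorted(sums)}


@dataclass
class IntensityDistribution:
    bin_edges: np.ndarray
    fractions_forward: np.ndarray
    fractions_reverse: np.ndarray


def intensity_histogram(
    values_forward: Sequence[float],
    values_reverse: Sequence[float],
    bin_width: float,
) -> IntensityDistribution:
    """Binned fractions of probe intensities, per strand.

    Bin edges are multiples of ``bin_width`` covering the pooled data range;
    per-strand fractions each sum to 1 when that strand has any probe.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pooled = list(values_forward) + list(values_reverse)
    if not pooled:
        return IntensityDistribution(np.array([]), np.array([]), np.array([]))
    lo = math.floor(min(pooled) / bin_width) * bin_width
    hi = math.floor(max(pooled) / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    def _frac(vals):
        if len(vals) == 0:
            return np.zeros(len(edges) - 1)
        h, _ = np.histogram(vals, bins=edges)
        return h / len(vals)

    return IntensityDistribution(edges, _frac(list(values_forward)), _frac(list(values_reverse)))


def abundance_metrics(
    read_counts: Mapping[str, float],
    lengths: Mapping[str, int],
    pseudocount: float = 0.0,
) -> Dict[str, Tuple[float, float]]:
    """Per-locus (log10 read count, read density).

    Density (reads per bp) is biased against long loci under 3'-biased
    library preparation; the log10 absolute count is the length-unbiased
    abundance measure used for locus-level comparisons.
    """
    out = {}
    for lid, count in read_counts.items():
        L = lengths[lid]
        if L <= 0:
            raise ValueError(f"locus {lid!r} has non-positive length")
        if count + pseudocount <= 0:
            raise ValueError(
                f"locus {lid!r}: log10 undefined for count {count} with "
                f"pseudocount {pseudocount}; use pseudocount > 0"
            )
        out[lid] = (math.log10(count + pseudocount), count / L)
    return out


def write_signal_table(signals: Sequence[LocusSignal], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tscenario\tstrand\tvalue\tdensity\n")
        for s in signals:
            fh.write(f"{s.locus_id}\t{s.scenario}\t{s.strand}\t{s.value:.6g}\t{s.density:.6g}\n")


def write_histogram_table(dist: IntensityDistribution, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tfraction_forward\tfraction_reverse\n")
        for i in range(max(0, len(dist.bin_edges) - 1)):
            fh.write(
                f"{dist.bin_edges[i]:.6g}\t{dist.bin_edges[i+1]:.6g}\t"
                f"{dist.fractions_forward[i]:.6g}\t{dist.fractions_reverse[i]:.6g}\n"
            )
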