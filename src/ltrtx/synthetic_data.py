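"""Synthetic genomes, probe tables and staged read sets with known truth.

The generator emulates the structure of the fission-yeast data the pipeline
is built for: a compact genome carrying full-length LTR retrotransposons
(internal sequence flanked by two near-identical LTRs, optionally one
chimeric LTR-int-LTR-int-LTR arrangement), divergent solitary LTRs sharing
the same family ancestor (creating both multi-mapping and clusterability),
intron-containing protein-coding genes, small structural RNAs, strand-tagged
60-mer probe intensities with Gaussian noise, and 30-51 nt reads with a
tunable 3' positional bias and an optional poly(A)-selection mode that
suppresses non-polyadenylated transcripts (solitary LTRs, structural RNAs).

Every output is a deterministic function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exact_mapper import Query, find_exact_matches, revcomp
from .genome_model import Feature, FeatureCatalog, write_fasta, write_gff
from .intervals import GenomicInterval
from .perm_stats import MEIOSIS_STAGES, STAGES, StageProfile

BASES = np.array(list("ACGT"))


@dataclass
class ActivityModel:
    """Per-locus transcription rates, in units of the background rate."""

    element_rate: float = 4.0  # forward-strand rate per full-length element
    element_antisense: float = 0.3  # reverse-strand fraction of element rate
    solitary_rate: float = 1.0  # per strand (both strands equal)
    paired_solitary_rate: float = 8.0  # solitary LTRs placed upstream of genes
    gene_rate_mean: float = 4.0  # lognormal location for gene rates
    gene_rate_sigma: float = 1.0
    rna_gene_rate: float = 2.0  # tRNA / snoRNA
    hot_fraction: Optional[float] = None  # fraction of elements that are "hot"
    hot_share: float = 0.95  # share of total family rate carried by hot loci
    background_rate: float = 1.0


@dataclass
class SimConfig:
    seed: int
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_full_elements: int = 13
    include_chimeric: bool = True
    n_solitary: int = 40
    ltr_length: int = 350
    internal_length: int = 2000
    ltr_divergence: float = 0.10  # solitary LTRs vs family ancestor
    element_divergence: float = 0.0007  # full-length family members vs ancestor
    flank_ltr_divergence: float = 0.0005  # between the two LTRs of one element
    hot_extra_divergence: float = 0.007  # extra divergence of hot elements
    n_genes: int = 30
    gene_length: int = 1500
    intron_probability: float = 0.5
    intron_length: int = 80
    n_trna: int = 4
    n_snorna: int = 3
    upstream_pair_fraction: float = 0.3  # genes given an upstream solitary LTR
    probe_length: int = 60
    probe_tile_step: int = 60
    read_length_range: Tuple[int, int] = (30, 51)
    read_bias_beta: float = 2.0  # 3' positional bias strength (0 = uniform)
    polyA_selection: bool = True
    polyA_retention: float = 0.1  # rate factor for non-polyadenylated RNAs
    noise_sd: float = 0.3  # probe intensity Gaussian noise (log2 units)
    depth: float = 50.0  # expected reads per unit rate per stage
    background_reads_per_kb: float = 0.5
    n_injection_rate: float = 0.002  # fraction of reads given an N
    stage_sigma: float = 1.0  # SD of per-locus per-stage log2 factors
    gene_coupling_rho: float = 0.0  # LTR/neighbour-gene stage-factor coupling
    activity: ActivityModel = field(default_factory=ActivityModel)

    def __post_init__(self) -> None:
        for p in (
            self.ltr_divergence, self.element_divergence, self.flank_ltr_divergence,
            self.intron_probability, self.upstream_pair_fraction,
            self.polyA_retention, self.n_injection_rate,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.depth < 0 or self.noise_sd < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class Transcript:
    locus_id: str
    kind: str  # {"element", "solitary_ltr", "gene", "trna", "snorna"}
    chrom: str
    start: int
    end: int
    strand: str
    base_rate: float
    stage_factors: Dict[str, float]
    polyadenylated: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def rate(self, stage: str) -> float:
        return self.base_rate * self.stage_factors[stage]


@dataclass
class GroundTruth:
    transcripts: List[Transcript]
    locus_roles: Dict[str, str]  # locus_id -> {element, solitary, gene, ...}
    ltr_gene_pairs: List[Tuple[str, str, int]]  # (ltr_id, gene_id, distance)
    hot_elements: List[str]
    probe_truth: Dict[str, float] = field(default_factory=dict)

    def transcripts_of(self, locus_id: str) -> List[Transcript]:
        return [t for t in self.transcripts if t.locus_id == locus_id]


# ---------------------------------------------------------------------------
# Genome generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Independent per-site substitution with the given probability."""
    if divergence == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    idx = np.where(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_genome(config: SimConfig) -> Tuple[FeatureCatalog, GroundTruth]:
    """Build a toy genome + annotation + ground truth from the config.

    Full-length elements derive from one ancestral LTR/internal pair; the two
    flanking LTRs of each element are nearly identical; solitary LTRs descend
    from the same LTR ancestor at higher divergence.  A configurable fraction
    of genes receives an upstream solitary LTR within 1 kb (the loci used by
    the meiosis coupling analysis).  Raises if the planned features exceed the
    chromosome capacity.
    """
    rng = np.random.default_rng([config.seed, 11])
    act = config.activity

    ancestral_ltr = _random_seq(rng, config.ltr_length)
    ancestral_internal = _random_seq(rng, config.internal_length)

    # --- decide hot elements (few-hot-loci regime) -------------------------
    n_el = config.n_full_elements
    if config.include_chimeric and n_el < 2:
        raise ValueError("chimeric arrangement needs n_full_elements >= 2")
    element_ids = [f"el{i+1:02d}" for i in range(n_el)]
    if act.hot_fraction is not None:
        n_hot = max(1, round(act.hot_fraction * n_el))
        hot = list(rng.choice(element_ids, size=n_hot, replace=False))
        total = act.element_rate * n_el
        hot_rate = total * act.hot_share / n_hot
        cold_rate = total * (1 - act.hot_share) / max(1, n_el - n_hot)
        el_rate = {e: (hot_rate if e in hot else cold_rate) for e in element_ids}
    else:
        hot = []
        el_rate = {e: act.element_rate for e in element_ids}

    def _el_div(eid: str) -> float:
        return config.element_divergence + (
            config.hot_extra_divergence if eid in hot else 0.0
        )

    # --- build layout units ------------------------------------------------
    # each unit: list of (feature_id, kind, sequence, strand, extras)
    units: List[List[Tuple[str, str, str, str]]] = []

    def _element_unit(eids: Sequence[str]) -> List[Tuple[str, str, str, str]]:
        """LTR(-int-LTR)+ chain: one internal per element id, n+1 LTRs."""
        parts: List[Tuple[str, str, str, str]] = []
        base_ltrs = {e: _mutate(rng, ancestral_ltr, _el_div(e)) for e in eids}
        for j, eid in enumerate(eids):
            src = base_ltrs[eid]
            if j == 0:
                parts.append((f"LTR-{eid}-5p", "ltr",
                              _mutate(rng, src, config.flank_ltr_divergence), "+"))
            parts.append((f"INT-{eid}", "retro_internal",
                          _mutate(rng, ancestral_internal, _el_div(eid)), "+"))
            parts.append((f"LTR-{eid}-3p", "ltr",
                          _mutate(rng, src, config.flank_ltr_divergence), "+"))
        return parts

    chim_ids: List[str] = []
    rest = list(element_ids)
    if config.include_chimeric:
        chim_ids = rest[:2]
        rest = rest[2:]
        units.append(_element_unit(chim_ids))
    for eid in rest:
        units.append(_element_unit([eid]))

    solitary_seqs = {
        f"solo{i+1:03d}": _mutate(rng, ancestral_ltr, config.ltr_divergence)
        for i in range(config.n_solitary)
    }
    gene_ids = [f"gene{i+1:03d}" for i in range(config.n_genes)]
    n_paired = min(round(config.upstream_pair_fraction * config.n_genes), config.n_solitary)
    paired_genes = gene_ids[:n_paired]
    paired_solo = list(solitary_seqs)[:n_paired]
    pair_gap: Dict[str, int] = {}

    gene_units: List[List[Tuple[str, str, str, str]]] = []
    for gi, gid in enumerate(gene_ids):
        gseq = _random_seq(rng, config.gene_length)
        unit = []
        if gid in paired_genes:
            sid = paired_solo[gi]
            gap = int(rng.integers(100, 800))
            pair_gap[sid] = gap
            unit.append((sid, "ltr", solitary_seqs[sid], "+"))
            unit.append((f"__gap{gid}", "__gap", "", str(gap)))
        unit.append((gid, "gene", gseq, "+"))
        gene_units.append(unit)
    units.extend(gene_units)

    for sid in list(solitary_seqs)[n_paired:]:
        units.append([(sid, "ltr", solitary_seqs[sid], "+")])
    for i in range(config.n_trna):
        units.append([(f"trna{i+1:02d}", "trna", _random_seq(rng, 75), "+")])
    for i in range(config.n_snorna):
        units.append([(f"sno{i+1:02d}", "snorna", _random_seq(rng, 120), "+")])

    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # --- lay out on chromosomes -------------------------------------------
    chrom_names = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    per_chrom: Dict[str, List] = {c: [] for c in chrom_names}
    for i, u in enumerate(units):
        per_chrom[chrom_names[i % config.n_chromosomes]].append(u)

    chromosomes: Dict[str, str] = {}
    features: List[Feature] = []
    placed: Dict[str, GenomicInterval] = {}
    intron_of: Dict[str, GenomicInterval] = {}

    for chrom in chrom_names:
        cursor = int(rng.integers(400, 1200))
        segments: List[str] = []
        pos = 0

        def _advance_to(target: int):
            nonlocal pos
            if target > pos:
                segments.append(_random_seq(rng, target - pos))
                pos = target

        for unit in per_chrom[chrom]:
            _advance_to(cursor)
            for fid, kind, seq, strand in unit:
                if kind == "__gap":
                    cursor += int(strand)
                    _advance_to(cursor)
                    continue
                start = cursor
                segments.append(seq)
                pos = cursor = cursor + len(seq)
                iv = GenomicInterval(chrom, start, cursor, strand)
                placed[fid] = iv
                features.append(Feature(fid, kind, iv))
                if kind == "gene" and rng.random() < config.intron_probability:
                    ioff = int(rng.integers(200, len(seq) - 200 - config.intron_length))
                    intron_of[fid] = GenomicInterval(
                        chrom, start + ioff, start + ioff + config.intron_length, strand
                    )
            cursor += int(rng.integers(400, 1200))
        _advance_to(cursor + int(rng.integers(200, 600)))
        if pos > config.chrom_length:
            raise ValueError(
                f"planned features need {pos} bp on {chrom} but chrom_length is "
                f"{config.chrom_length}; increase chrom_length"
            )
        _advance_to(config.chrom_length)
        chromosomes[chrom] = "".join(segments)

    for gid, iv in intron_of.items():
        features.append(Feature(f"intron-{gid}", "intron", iv))

    catalog = FeatureCatalog(chromosomes=chromosomes, features=features)

    # --- transcripts and rates --------------------------------------------
    transcripts: List[Transcript] = []
    locus_roles: Dict[str, str] = {}

    def _stage_factors(z: Optional[np.ndarray] = None) -> Dict[str, float]:
        if z is None:
            z = rng.normal(0, config.stage_sigma, len(MEIOSIS_STAGES))
        f = {"growth": 1.0}
        f.update({s: float(2.0 ** z[i]) for i, s in enumerate(MEIOSIS_STAGES)})
        return f

    # full-length elements: transcript mid-5'LTR .. mid-3'LTR, both strands
    def _element_transcript(eid: str, ltr5: str, ltr3: str):
        iv5, iv3 = placed[ltr5], placed[ltr3]
        start = iv5.start + iv5.length // 2
        end = iv3.start + iv3.length // 2
        fac = _stage_factors()
        for strand, rate in (
            ("+", el_rate[eid]),
            ("-", el_rate[eid] * act.element_antisense),
        ):
            transcripts.append(
                Transcript(eid, "element", iv5.chrom, start, end, strand,
                           rate, fac, polyadenylated=True)
            )
        locus_roles[eid] = "element"

    if chim_ids:
        e1, e2 = chim_ids
        _element_transcript(e1, f"LTR-{e1}-5p", f"LTR-{e1}-3p")
        _element_transcript(e2, f"LTR-{e1}-3p", f"LTR-{e2}-3p")
    for eid in rest:
        _element_transcript(eid, f"LTR-{eid}-5p", f"LTR-{eid}-3p")

    # solitary LTRs: both strands, equal rates, not polyadenylated
    ltr_gene_pairs: List[Tuple[str, str, int]] = []
    z_by_solo: Dict[str, np.ndarray] = {}
    for sid in solitary_seqs:
        iv = placed[sid]
        paired = sid in pair_gap
        rate = act.paired_solitary_rate if paired else act.solitary_rate
        z = rng.normal(0, config.stage_sigma, len(MEIOSIS_STAGES))
        z_by_solo[sid] = z
        fac = _stage_factors(z)
        for strand in ("+", "-"):
            transcripts.append(
                Transcript(sid, "solitary_ltr", iv.chrom, iv.start, iv.end,
                           strand, rate, fac, polyadenylated=False)
            )
        locus_roles[sid] = "solitary"

    # genes: forward transcript over the gene span, coupled to upstream LTR
    rho = config.gene_coupling_rho
    for gi, gid in enumerate(gene_ids):
        iv = placed[gid]
        rate = float(rng.lognormal(math.log(act.gene_rate_mean), act.gene_rate_sigma))
        if gid in paired_genes:
            sid = paired_solo[gi]
            zl = z_by_solo[sid]
            z = rho * zl + math.sqrt(max(0.0, 1 - rho**2)) * rng.normal(
                0, config.stage_sigma, len(MEIOSIS_STAGES)
            )
            ltr_gene_pairs.append((sid, gid, pair_gap[sid]))
        else:
            z = rng.normal(0, config.stage_sigma, len(MEIOSIS_STAGES))
        transcripts.append(
            Transcript(gid, "gene", iv.chrom, iv.start, iv.end, "+",
                       rate, _stage_factors(z), polyadenylated=True)
        )
        locus_roles[gid] = "gene"

    for f in features:
        if f.kind in ("trna", "snorna"):
            transcripts.append(
                Transcript(f.id, f.kind, f.interval.chrom, f.interval.start,
                           f.interval.end, "+", act.rna_gene_rate,
                           _stage_factors(), polyadenylated=False)
            )
            locus_roles[f.id] = f.kind

    truth = GroundTruth(
        transcripts=transcripts,
        locus_roles=locus_roles,
        ltr_gene_pairs=ltr_gene_pairs,
        hot_elements=hot,
    )
    return catalog, truth


# ---------------------------------------------------------------------------
# Probes


def simulate_probes(
    catalog: FeatureCatalog,
    config: SimConfig,
    within_kinds: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tile strand-tagged probes across the genome (or selected features).

    Probes of ``probe_length`` are placed every ``probe_tile_step`` bp on
    both strands.  A '+' probe carries the forward genomic sequence and
    interrogates forward-strand transcripts; the '-' probe at the same
    position carries the reverse complement.  With ``within_kinds`` set, only
    regions covered by features of those kinds are tiled.
    """
    L = config.probe_length
    rows = []
    for chrom, seq in catalog.chromosomes.items():
        if within_kinds is None:
            regions = [(0, len(seq))]
        else:
            regions = [
                (f.interval.start, f.interval.end)
                for f in catalog.features
                if f.kind in within_kinds and f.interval.chrom == chrom
            ]
        for rs, re_ in regions:
            for pos in range(rs, re_ - L + 1, config.probe_tile_step):
                fwd = seq[pos : pos + L]
                rows.append((f"p_{chrom}_{pos}_f", fwd, "+", chrom, pos))
                rows.append((f"p_{chrom}_{pos}_r", revcomp(fwd), "-", chrom, pos))
    return pd.DataFrame(
        rows, columns=["probe_id", "sequence", "strand", "source_chrom", "source_pos"]
    )


def simulate_hybmap(
    probes: pd.DataFrame,
    catalog: FeatureCatalog,
    truth: GroundTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """Noise-free probe intensities from the rate model, plus Gaussian noise.

    A probe's noise-free intensity is log2((sum of growth rates of
    transcripts on the probe's strand that fully contain any of its exact
    hits + b) / b), with b the background rate -- i.e. log2 signal over an
    intergenic baseline.  Emitted intensity adds N(0, noise_sd).  Noise-free
    values are stored in ``truth.probe_truth``.
    """
    rng = np.random.default_rng([config.seed, 23])
    b = config.activity.background_rate
    if b <= 0:
        raise ValueError("background_rate must be > 0")
    by_strand: Dict[str, List[Transcript]] = {"+": [], "-": []}
    for t in truth.transcripts:
        by_strand[t.strand].append(t)

    out_rows = []
    for row in probes.itertuples(index=False):
        q = Query(id=row.probe_id, sequence=row.sequence, kind="probe",
                  strand_tag=row.strand)
        hits = find_exact_matches(q, catalog)
        lam = 0.0
        seen = set()
        for h in hits:
            for t in by_strand[row.strand]:
                if t.locus_id in seen:
                    continue
                if t.chrom == h.chrom and t.start <= h.start and h.end <= t.end:
                    lam += t.rate("growth")
                    seen.add(t.locus_id)
        clean = math.log2((lam + b) / b)
        truth.probe_truth[row.probe_id] = clean
        noisy = clean + (rng.normal(0, config.noise_sd) if config.noise_sd > 0 else 0.0)
        out_rows.append((row.probe_id, row.sequence, row.strand, noisy))
    return pd.DataFrame(out_rows, columns=["probe_id", "sequence", "strand", "intensity_1"])


# ---------------------------------------------------------------------------
# Reads


def simulate_rnaseq(
    catalog: FeatureCatalog,
    truth: GroundTruth,
    config: SimConfig,
    stage: str,
) -> Tuple[List[Tuple[str, str]], Dict[Tuple[str, str], int]]:
    """Reads for one stage: (id, sequence) pairs plus true per-locus counts.

    Per transcript, the read count is Poisson(rate * stage factor * depth);
    with poly(A) selection, non-polyadenylated transcripts are down-weighted
    by ``polyA_retention``.  Read start positions are weighted
    exp(beta * u) where u is the relative position toward the transcript's 3'
    end (beta = 0 gives uniform starts); read lengths are uniform on
    ``read_length_range``.  A small fraction of reads receives an injected N.
    Background reads are scattered uniformly over the genome.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng([config.seed, 37, STAGES.index(stage)])
    lmin, lmax = config.read_length_range
    beta = config.read_bias_beta
    reads: List[Tuple[str, str]] = []
    counts: Dict[Tuple[str, str], int] = {}

    for t in truth.transcripts:
        lam = t.rate(stage) * config.depth
        if config.polyA_selection and not t.polyadenylated:
            lam *= config.polyA_retention
        n = int(rng.poisson(lam))
        counts[(t.locus_id, t.strand)] = counts.get((t.locus_id, t.strand), 0) + n
        genome = catalog.chromosomes[t.chrom]
        for i in range(n):
            l = int(rng.integers(lmin, lmax + 1))
            if t.length <= l:
                off = 0
                l = min(l, t.length)
            else:
                span = t.length - l
                u = _biased_uniform(rng, beta)
                off = int(u * span) if t.strand == "+" else int((1 - u) * span)
            s = t.start + off
            seq = genome[s : s + l]
            if t.strand == "-":
                seq = revcomp(seq)
            if rng.random() < config.n_injection_rate:
                pos = int(rng.integers(0, len(seq)))
                seq = seq[:pos] + "N" + seq[pos + 1 :]
            reads.append((f"{stage}_{t.locus_id}_{t.strand}_{i}", seq))

    # background transcription: uniform reads over the genome
    total_kb = sum(len(s) for s in catalog.chromosomes.values()) / 1000
    n_bg = int(rng.poisson(config.background_reads_per_kb * total_kb))
    chroms = list(catalog.chromosomes)
    for i in range(n_bg):
        chrom = chroms[rng.integers(0, len(chroms))]
        genome = catalog.chromosomes[chrom]
        l = int(rng.integers(lmin, lmax + 1))
        s = int(rng.integers(0, len(genome) - l))
        seq = genome[s : s + l]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"{stage}_bg_{i}", seq))
    counts[("background", ".")] = n_bg
    return reads, counts


def _biased_uniform(rng: np.random.Generator, beta: float) -> float:
    """Sample u in [0,1] with density proportional to exp(beta * u)."""
    r = rng.random()
    if beta == 0:
        return r
    return math.log(1 + r * (math.exp(beta) - 1)) / beta


def write_fastq(reads: Sequence[Tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Direct stage-profile simulation (for statistical calibration at scale)


def simulate_meiosis_profiles(
    n_pairs: int,
    rho: float,
    seed: int,
    mean_growth: float = 50.0,
    stage_sigma: float = 1.0,
) -> List[Tuple[StageProfile, StageProfile]]:
    """LTR/gene stage-count profile pairs with coupling rho, without reads.

    Counts are Poisson around rates whose per-stage log2 factors are
    correlated (rho) between each LTR and its gene.  Used for permutation-
    test calibration runs where simulating sequences would add nothing.
    """
    rng = np.random.default_rng(seed)
    out = []
    k = len(MEIOSIS_STAGES)
    for i in range(n_pairs):
        zl = rng.normal(0, stage_sigma, k)
        zg = rho * zl + math.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, stage_sigma, k)
        lc = {"growth": max(1.0, float(rng.poisson(mean_growth)))}
        gc = {"growth": max(1.0, float(rng.poisson(mean_growth)))}
        for j, s in enumerate(MEIOSIS_STAGES):
            lc[s] = max(1.0, float(rng.poisson(mean_growth * 2.0 ** zl[j])))
            gc[s] = max(1.0, float(rng.poisson(mean_growth * 2.0 ** zg[j])))
        out.append((StageProfile(f"ltr{i}", lc), StageProfile(f"gene{i}", gc)))
    return out


def simulate_locus_intensities(
    n_loci: int = 20,
    probes_per_locus: int = 5,
    noise_sd: float = 1.0,
    locus_sd: float = 0.0,
    shift_locus: Optional[int] = None,
    shift: float = 0.0,
    seed: int = 0,
) -> Dict[str, List[float]]:
    """Per-locus probe intensities for variance-test calibration.

    Under the null (locus_sd = 0, shift = 0) all loci share one mean and
    probe intensities are exchangeable; ``shift_locus``/``shift`` moves one
    locus's mean (in units of the probe noise SD) for power runs.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, List[float]] = {}
    for i in range(n_loci):
        mu = rng.normal(0, locus_sd) if locus_sd > 0 else 0.0
        if shift_locus is not None and i == shift_locus:
            mu += shift * noise_sd
        out[f"L{i:03d}"] = list(rng.normal(mu, noise_sd, probes_per_locus))
    return out


# ---------------------------------------------------------------------------
# Bundle output


def write_bundle(
    catalog: FeatureCatalog,
    truth: GroundTruth,
    config: SimConfig,
    outdir: Path,
    stages: Sequence[str] = STAGES,
) -> Dict[str, Path]:
    """Emit FASTA, GFF3, probe/intensity TSV, per-stage FASTQ and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(catalog, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    write_gff(catalog, paths["annotation"])

    probes = simulate_probes(catalog, config)
    intens = simulate_hybmap(probes, catalog, truth, config)
    paths["probes"] = outdir / "probes.tsv"
    intens.to_csv(paths["probes"], sep="\t", index=False)

    true_counts: Dict[str, Dict[str, int]] = {}
    for stage in stages:
        reads, counts = simulate_rnaseq(catalog, truth, config, stage)
        p = outdir / f"reads_{stage}.fastq"
        write_fastq(reads, p)
        paths[f"reads_{stage}"] = p
        true_counts[stage] = {f"{lid}:{strand}": c for (lid, strand), c in counts.items()}

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": _config_dict(config),
                "locus_roles": truth.locus_roles,
                "hot_elements": truth.hot_elements,
                "ltr_gene_pairs": truth.ltr_gene_pairs,
                "transcripts": [
                    {
                        "locus_id": t.locus_id, "kind": t.kind, "chrom": t.chrom,
                        "start": t.start, "end": t.end, "strand": t.strand,
                        "base_rate": t.base_rate, "stage_factors": t.stage_factors,
                        "polyadenylated": t.polyadenylated,
                    }
                    for t in truth.transcripts
                ],
                "probe_truth": truth.probe_truth,
                "true_counts": true_counts,
            },
            fh,
            indent=1,
        )
    return paths


def _config_dict(config: SimConfig) -> Dict[str, object]:
    d = asdict(config)
    d["read_length_range"] = list(d["read_length_range"])
    return d
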