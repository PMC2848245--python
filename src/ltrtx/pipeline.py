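"""End-to-end orchestration of the growth-phase and meiosis analyses.

``run_growth_analysis`` composes: annotation parsing, LTR partition,
exact mapping of probes and reads with the exclusivity filters, the two
bounding assignment scenarios, intensity distributions and per-locus means,
flank frames with the in-LTR vs flank contrast, and the between-locus
variance permutation test.

``run_meiosis_analysis`` composes: per-stage read mapping, selection of
covered LTRs with upstream genes, stage log-ratio profiles, the concatenated
Pearson correlation, the within-time-point shuffle permutation test, and the
set-level stage profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import exact_mapper, ltr_alignment, perm_stats, signal_assignment
from .genome_model import (
    FeatureCatalog,
    build_background,
    nearest_upstream_gene,
    parse_annotation,
    partition_ltrs,
    write_ltr_table,
)
from .intervals import GenomicInterval
from .perm_stats import STAGES

log = logging.getLogger(__name__)


class ConfigError(Exception):
    """Bad or missing run configuration (exit code 2)."""


class DataError(Exception):
    """Inputs present but unusable (exit code 3)."""


@dataclass
class RunConfig:
    genome: Path
    annotation: Path
    outdir: Path
    seed: int = 0
    probe_table: Optional[Path] = None
    reads: Dict[str, Path] = field(default_factory=dict)  # stage -> FASTQ
    alignment: Optional[Path] = None  # aligned FASTA of LTR sequences
    gap_tol: int = 50
    utr_flank: int = 240
    min_len: int = 100
    bin_width: float = 0.5
    window: int = 301
    n_perm: int = 10000
    min_total: float = 30
    min_growth: float = 10
    upstream_within: int = 1000
    pseudocount: float = 0.0

    @classmethod
    def from_file(cls, path: Path) -> "RunConfig":
        """Parse a plain ``key = value`` config file.

        Read paths are given as ``reads.<stage> = <path>``.
        """
        raw: Dict[str, str] = {}
        try:
            with open(path) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    if "=" not in line:
                        raise ConfigError(f"{path}:{lineno}: expected key = value")
                    key, _, val = line.partition("=")
                    raw[key.strip()] = val.strip()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        for req in ("genome", "annotation", "outdir"):
            if req not in raw:
                raise ConfigError(f"config {path} missing required key {req!r}")
        reads = {
            k.split(".", 1)[1]: Path(v) for k, v in raw.items() if k.startswith("reads.")
        }
        kwargs = {}
        for k, conv in (
            ("seed", int), ("gap_tol", int), ("utr_flank", int), ("min_len", int),
            ("bin_width", float), ("window", int), ("n_perm", int),
            ("min_total", float), ("min_growth", float),
            ("upstream_within", int), ("pseudocount", float),
        ):
            if k in raw:
                kwargs[k] = conv(raw[k])
        return cls(
            genome=Path(raw["genome"]),
            annotation=Path(raw["annotation"]),
            outdir=Path(raw["outdir"]),
            probe_table=Path(raw["probe_table"]) if "probe_table" in raw else None,
            alignment=Path(raw["alignment"]) if "alignment" in raw else None,
            reads=reads,
            **kwargs,
        )

    def check_paths(self, need_probes: bool = False, need_stages: Sequence[str] = ()) -> None:
        for p in (self.genome, self.annotation):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if need_probes:
            if self.probe_table is None:
                raise ConfigError("probe_table is required for the growth analysis")
            if not Path(self.probe_table).exists():
                raise ConfigError(f"probe table does not exist: {self.probe_table}")
        for stage in need_stages:
            if stage not in self.reads:
                raise ConfigError(f"missing reads for stage {stage!r}")
            if not Path(self.reads[stage]).exists():
                raise ConfigError(f"reads file does not exist: {self.reads[stage]}")


def _locus_maps(elements, solitary):
    element_loci = {el.id: el.parts for el in elements}
    solitary_loci = {l.id: [l.interval] for l in solitary}
    return element_loci, solitary_loci


def _flatten(loci: Dict[str, List[GenomicInterval]]) -> List[GenomicInterval]:
    return [iv for ivs in loci.values() for iv in ivs]


def run_growth_analysis(config: RunConfig) -> Dict[str, object]:
    """Growth-phase analysis bundle; returns the stats report dict."""
    config.check_paths(need_probes=True)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_log(outdir / "run_growth.log")
    report: Dict[str, object] = {"seed": config.seed}

    catalog = parse_annotation(config.genome, config.annotation)
    elements, solitary = partition_ltrs(catalog, gap_tol=config.gap_tol)
    if not elements and not solitary:
        raise DataError("annotation contains no LTR features")
    write_ltr_table(elements, solitary, outdir / "ltr_partition.tsv")
    background = build_background(catalog, config.utr_flank, config.min_len)
    element_loci, solitary_loci = _locus_maps(elements, solitary)

    probe_df = exact_mapper.read_probe_table(config.probe_table)
    probes = exact_mapper.probes_from_table(probe_df)

    # exclusivity rules: exclusive within the full-length set, unique-only
    # within the solitary set
    probe_hits = exact_mapper.find_all_matches(probes, catalog)
    el_records = exact_mapper.classify_all(
        probes, probe_hits, _flatten(element_loci), mode="exclusive_ok"
    )
    so_records = exact_mapper.classify_all(
        probes, probe_hits, _flatten(solitary_loci), mode="unique_only"
    )
    exact_mapper.write_mapping_table(el_records, outdir / "probe_mapping_elements.tsv")
    exact_mapper.write_mapping_table(so_records, outdir / "probe_mapping_solitary.tsv")
    report["probe_filter_counts"] = _filter_counts(el_records, so_records)

    # two bounding scenarios for the element set
    signals = (
        signal_assignment.equal_split(el_records, element_loci)
        + signal_assignment.single_locus_max(el_records, element_loci)
        + signal_assignment.unique_only(el_records, element_loci)
        + signal_assignment.equal_split(so_records, solitary_loci)
    )
    signal_assignment.write_signal_table(signals, outdir / "locus_signals.tsv")

    # intensity distributions per compartment
    def _strand_values(records, klasses):
        f = [r.signal for r in records if r.klass in klasses and r.strand_tag == "+"]
        r_ = [r.signal for r in records if r.klass in klasses and r.strand_tag == "-"]
        return f, r_

    fvals, rvals = _strand_values(so_records, ("unique",))
    dist = signal_assignment.intensity_histogram(fvals, rvals, config.bin_width)
    signal_assignment.write_histogram_table(dist, outdir / "solitary_intensity_hist.tsv")

    means = signal_assignment.per_locus_mean_intensity(so_records, solitary_loci)
    with open(outdir / "solitary_locus_means.tsv", "w") as fh:
        fh.write("locus_id\tstrand\tmean_intensity\n")
        for (lid, strand), m in means.items():
            fh.write(f"{lid}\t{strand}\t{m:.6g}\n")

    # between-locus variance permutation test, per strand
    for strand in ("+", "-"):
        by_locus: Dict[str, List[float]] = {}
        for r in so_records:
            if r.klass != "unique" or r.strand_tag != strand:
                continue
            for lid, ivs in solitary_loci.items():
                if any(
                    iv.contains(GenomicInterval(h.chrom, h.start, h.end))
                    for h in r.hits
                    for iv in ivs
                ):
                    by_locus.setdefault(lid, []).append(r.signal)
        groups = {k: v for k, v in by_locus.items() if v}
        if len(groups) >= 2:
            res = perm_stats.variance_permutation_test(
                groups, n_perm=config.n_perm, seed=config.seed
            )
            report[f"variance_test_{'forward' if strand == '+' else 'reverse'}"] = (
                res.to_json_dict("variance_permutation")
            )

    # flank frames and in-LTR vs flank contrast
    frames = [
        ltr_alignment.build_flank_frame(l, catalog) for l in solitary
    ]
    ltr_alignment.write_flank_table(frames, outdir / "flank_frames.tsv")
    contrast = ltr_alignment.flank_contrast(frames, so_records)
    report["flank_contrast"] = {
        "median_in": contrast.median_in,
        "median_up": contrast.median_up,
        "median_down": contrast.median_down,
        "U_up": contrast.u_up,
        "p_up": contrast.p_up,
        "U_down": contrast.u_down,
        "p_down": contrast.p_down,
        "n": [contrast.n_in, contrast.n_up, contrast.n_down],
    }

    # optional: window density along a provided LTR alignment
    if config.alignment is not None:
        aln = ltr_alignment.Alignment.from_fasta(config.alignment)
        loci_iv = {
            **{lid: ivs[0] for lid, ivs in solitary_loci.items()},
        }
        growth_reads = config.reads.get("growth")
        if growth_reads is not None:
            queries = exact_mapper.read_fastq_queries(growth_reads)
            aln_set = [loci_iv[i] for i in aln.ids if i in loci_iv]
            recs = exact_mapper.map_query_table(queries, catalog, aln_set, "exclusive_ok")
            cols = []
            for r in recs:
                if r.klass not in ("unique", "exclusive"):
                    continue
                proj = ltr_alignment.project_to_alignment(r, aln, aln.ids, loci_iv)
                if proj is not None:
                    cols.append(proj[0])
            window = min(config.window, aln.ncols if aln.ncols % 2 else aln.ncols - 1)
            if window % 2 == 0:
                window -= 1
            dens = ltr_alignment.window_density(cols, aln.ncols, len(aln.ids), window)
            ltr_alignment.write_density_table(dens, outdir / "window_density.tsv")

    report["n_elements"] = len(elements)
    report["n_solitary"] = len(solitary)
    report["n_intergenic"] = len(background.intergenic)
    with open(outdir / "growth_stats.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_meiosis_analysis(config: RunConfig) -> Dict[str, object]:
    """Meiosis time-course analysis bundle; returns the stats report dict."""
    config.check_paths(need_stages=STAGES)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_log(outdir / "run_meiosis.log")
    report: Dict[str, object] = {"seed": config.seed}

    catalog = parse_annotation(config.genome, config.annotation)
    elements, solitary = partition_ltrs(catalog, gap_tol=config.gap_tol)
    element_loci, solitary_loci = _locus_maps(elements, solitary)

    # per-stage unique read counts for solitary LTRs and genes; exclusive
    # counts for the LTR sets; library totals
    gene_loci = {
        f.id: [f.interval] for f in catalog.by_kind("gene")
    }
    unique_counts: Dict[str, Dict[str, float]] = {}
    gene_counts: Dict[str, Dict[str, float]] = {}
    excl_counts = {"solitary": {}, "elements": {}}
    totals: Dict[str, float] = {}

    for stage in STAGES:
        queries = exact_mapper.read_fastq_queries(config.reads[stage])
        totals[stage] = float(len(queries))
        hits = exact_mapper.find_all_matches(queries, catalog)
        so_rec = exact_mapper.classify_all(
            queries, hits, _flatten(solitary_loci), "exclusive_ok"
        )
        ge_rec = exact_mapper.classify_all(
            queries, hits, _flatten(gene_loci), "unique_only"
        )
        el_rec = exact_mapper.classify_all(
            queries, hits, _flatten(element_loci), "exclusive_ok"
        )
        for sig in signal_assignment.unique_only(so_rec, solitary_loci):
            unique_counts.setdefault(sig.locus_id, {})[stage] = sig.value
        for sig in signal_assignment.unique_only(ge_rec, gene_loci):
            gene_counts.setdefault(sig.locus_id, {})[stage] = sig.value
        excl_counts["solitary"][stage] = sum(
            1 for r in so_rec if r.klass in ("unique", "exclusive")
        )
        excl_counts["elements"][stage] = sum(
            1 for r in el_rec if r.klass in ("unique", "exclusive")
        )

    def _profiles(counts: Dict[str, Dict[str, float]]) -> Dict[str, perm_stats.StageProfile]:
        out = {}
        for lid, c in counts.items():
            full = {s: float(c.get(s, 0.0)) for s in STAGES}
            out[lid] = perm_stats.StageProfile(lid, full)
        return out

    ltr_profiles = _profiles(unique_counts)
    gene_profiles = _profiles(gene_counts)

    upstream: Dict[str, Tuple[str, int]] = {}
    for l in solitary:
        hit = nearest_upstream_gene(l, catalog)
        if hit is not None:
            upstream[l.id] = hit

    selected = perm_stats.select_meiosis_ltrs(
        ltr_profiles, upstream,
        min_total=config.min_total, min_growth=config.min_growth,
        upstream_within=config.upstream_within,
    )
    selected = [(lid, gid) for lid, gid in selected if gid in gene_profiles]
    report["selected_pairs"] = selected

    with open(outdir / "stage_profiles.tsv", "w") as fh:
        fh.write("entity_id\tstage\tcount\tlog_ratio\n")
        for lid, gid in selected:
            for ent in (ltr_profiles[lid], gene_profiles[gid]):
                try:
                    lr = ent.log_ratios(config.pseudocount)
                except ValueError:
                    lr = {s: float("nan") for s in STAGES}
                for s in STAGES:
                    fh.write(f"{ent.entity_id}\t{s}\t{ent.counts[s]:.6g}\t{lr[s]:.6g}\n")

    pairs = [(ltr_profiles[lid], gene_profiles[gid]) for lid, gid in selected]
    if len(pairs) >= 2:
        try:
            report["concatenated_r"] = perm_stats.concatenated_pearson(
                pairs, pseudocount=config.pseudocount
            )
        except ValueError as exc:
            report["concatenated_r_error"] = str(exc)
        res = perm_stats.timepoint_permutation_test(
            pairs, n_perm=config.n_perm, seed=config.seed,
            pseudocount=config.pseudocount,
        )
        report["timepoint_permutation"] = res.to_json_dict("timepoint_permutation")
        report["significant_at_0.01"] = bool(res.p_value < 0.01)
    else:
        report["timepoint_permutation"] = None
        report["permutation_skipped"] = (
            f"only {len(pairs)} selected LTR-gene pair(s); need >= 2"
        )

    for key, counts in excl_counts.items():
        try:
            prof = perm_stats.set_level_stage_profile(
                counts, totals, pseudocount=config.pseudocount
            )
        except ValueError as exc:
            prof = {"error": str(exc)}
        report[f"set_level_{key}"] = prof

    with open(outdir / "meiosis_stats.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _filter_counts(*record_lists) -> Dict[str, Dict[str, int]]:
    out = {}
    for i, records in enumerate(record_lists):
        key = f"set_{i}"
        counts: Dict[str, int] = {}
        for r in records:
            label = r.klass if not r.reason else f"{r.klass}:{r.reason}"
            counts[label] = counts.get(label, 0) + 1
        out[key] = counts
    return out


def _setup_run_log(path: Path) -> None:
    root = logging.getLogger("ltrtx")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.addHandler(handler)
    root.setLevel(logging.INFO)
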