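"""Pairwise identity, clustering, projection, flank frames, window density."""

import itertools

import numpy as np
import pytest

from ltrtx.exact_mapper import Hit, MappingRecord
from ltrtx.genome_model import Feature, FeatureCatalog, LtrLocus
from ltrtx.intervals import GenomicInterval
from ltrtx.ltr_alignment import (
    Alignment,
    build_flank_frame,
    cluster_ltrs,
    flank_contrast,
    pairwise_identity,
    project_to_alignment,
    window_density,
)

from conftest import make_sequence


# --------------------------------------------------------------------------
# oracle: Needleman-Wunsch with traceback (match +1, mismatch -1, gap -2)


def nw_identity(a: str, b: str):
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = -2 * np.arange(n + 1)
    score[0, :] = -2 * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = score[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
            score[i, j] = max(sub, score[i - 1, j] - 2, score[i, j - 1] - 2)
    # traceback one optimal path, counting identities and columns
    i, j, ident, cols = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            1 if a[i - 1] == b[j - 1] else -1
        ):
            ident += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 2:
            i -= 1
        else:
            j -= 1
        cols += 1
    return ident / cols


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = make_sequence(rng, 100)
        assert pairwise_identity(s, s) == 1.0

    def test_single_substitution(self):
        a = "ACGTACGTAC"
        b = "ACGTTCGTAC"
        assert pairwise_identity(a, b) == pytest.approx(0.9)

    def test_gap_counts_in_denominator(self):
        # aligning a 10-mer against its 8-mer prefix: 8 matches / 10 columns
        a = "ACGTACGTAC"
        assert pairwise_identity(a, a[:8]) == pytest.approx(0.8)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(15):
            a = make_sequence(rng, int(rng.integers(15, 35)))
            b = make_sequence(rng, int(rng.integers(15, 35)))
            # co-optimal alignments may differ slightly in identity
            assert pairwise_identity(a, b) == pytest.approx(nw_identity(a, b), abs=0.08)

    def test_random_200mers_below_0p6(self, rng):
        for _ in range(100):
            a = make_sequence(rng, 200)
            b = make_sequence(rng, 200)
            assert pairwise_identity(a, b) < 0.6


def brute_force_closure(ids, edge):
    """Oracle: transitive closure by repeated pairwise merging."""
    clusters = [{i} for i in ids]
    changed = True
    while changed:
        changed = False
        for c1, c2 in itertools.combinations(clusters, 2):
            if any(edge(a, b) for a in c1 for b in c2):
                clusters.remove(c1)
                clusters.remove(c2)
                clusters.append(c1 | c2)
                changed = True
                break
    return sorted(sorted(c) for c in clusters)


class TestClustering:
    def test_chain_collapse(self, rng):
        base = make_sequence(rng, 100)

        def mutate(s, k, seed):
            r = np.random.default_rng(seed)
            arr = list(s)
            for i in r.choice(len(s), k, replace=False):
                arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
            return "".join(arr)

        # A-B ~0.85, B-C ~0.80, A-C ~0.65: chain collapses into one cluster
        seqs = {"A": base, "B": mutate(base, 15, 1), "C": mutate(mutate(base, 15, 1), 20, 2)}
        assert pairwise_identity(seqs["A"], seqs["C"]) < 0.75
        clusters = cluster_ltrs(seqs, threshold=0.75)
        assert clusters == [["A", "B", "C"]]

    def test_all_singletons_below_threshold(self, rng):
        seqs = {f"s{i}": make_sequence(rng, 80) for i in range(5)}
        clusters = cluster_ltrs(seqs, threshold=0.70)
        assert clusters == [[f"s{i}"] for i in range(5)]

    def test_matches_brute_force_closure(self, rng):
        base = make_sequence(rng, 120)
        seqs = {}
        for i in range(12):
            arr = list(base)
            k = int(rng.integers(0, 60))
            for j in rng.choice(len(arr), k, replace=False):
                arr[j] = "ACGT"[int(rng.integers(0, 4))]
            seqs[f"q{i:02d}"] = "".join(arr)
        ids = sorted(seqs)
        memo = {}
        for a, b in itertools.combinations(ids, 2):
            memo[(a, b)] = pairwise_identity(seqs[a], seqs[b]) >= 0.70
        edge = lambda a, b: memo.get((min(a, b), max(a, b)), False)
        assert cluster_ltrs(seqs, 0.70) == brute_force_closure(ids, edge)

    def test_input_order_invariance(self, rng):
        seqs = {f"s{i}": make_sequence(rng, 60) for i in range(6)}
        rev = dict(reversed(list(seqs.items())))
        assert cluster_ltrs(seqs) == cluster_ltrs(rev)


class TestProjection:
    def _record(self, hits):
        return MappingRecord("q", "probe", "+", 1.0, hits, hits, "exclusive")

    def test_ungapped_midpoint(self):
        aln = Alignment.from_rows([("L1", "A" * 100)])
        loci = {"L1": GenomicInterval("chr1", 1000, 1100)}
        rec = self._record([Hit("chr1", 1010, 1070, "+")])  # seq positions [10,70)
        col, row = project_to_alignment(rec, aln, ["L1"], loci)
        assert (col, row) == (39, "L1")

    def test_leading_gaps_shift_column(self):
        aln = Alignment.from_rows([("L1", "-" * 5 + "A" * 100)])
        loci = {"L1": GenomicInterval("chr1", 1000, 1100)}
        rec = self._record([Hit("chr1", 1010, 1070, "+")])
        col, _ = project_to_alignment(rec, aln, ["L1"], loci)
        assert col == 44

    def test_first_instance_rule(self):
        aln = Alignment.from_rows([("L1", "A" * 50), ("L2", "C" * 50), ("L3", "G" * 50)])
        loci = {
            "L1": GenomicInterval("chr1", 0, 50),
            "L3": GenomicInterval("chr1", 200, 250),
        }
        rec = self._record([Hit("chr1", 210, 220, "+"), Hit("chr1", 10, 20, "+")])
        _, row = project_to_alignment(rec, aln, ["L1", "L2", "L3"], loci)
        assert row == "L1"

    def test_monotone_in_position(self):
        gapped = "AC--GTAC--GTACGT--AC"
        aln = Alignment.from_rows([("L1", gapped)])
        n_res = sum(c != "-" for c in gapped)
        loci = {"L1": GenomicInterval("chr1", 0, n_res)}
        cols = []
        for s in range(n_res - 4):
            rec = self._record([Hit("chr1", s, s + 4, "+")])
            cols.append(project_to_alignment(rec, aln, ["L1"], loci)[0])
        assert all(a < b for a, b in zip(cols, cols[1:]))

    def test_absent_locus_skipped(self):
        aln = Alignment.from_rows([("L1", "A" * 50)])
        rec = self._record([Hit("chr1", 10, 20, "+")])
        assert project_to_alignment(rec, aln, ["LX"], {}) is None


def _cat_with_neighbor(rng, dist_left, dist_right, chrom_len=10_000):
    """LTR at [4000,4350) with features at the given distances."""
    seq = make_sequence(rng, chrom_len)
    feats = [Feature("ltr1", "ltr", GenomicInterval("chr1", 4000, 4350))]
    if dist_left is not None:
        feats.append(
            Feature("gL", "gene", GenomicInterval("chr1", 4000 - dist_left - 300, 4000 - dist_left))
        )
    if dist_right is not None:
        feats.append(
            Feature("gR", "gene", GenomicInterval("chr1", 4350 + dist_right, 4650 + dist_right))
        )
    cat = FeatureCatalog({"chr1": seq}, feats)
    ltr = LtrLocus("ltr1", feats[0].interval, "solitary")
    return cat, ltr


class TestFlankFrame:
    @pytest.mark.parametrize(
        "dist,expected_len",
        [(1200, 500), (1000, 500), (800, 400), (999, 499), (120, 60), (100, None), (119, None)],
    )
    def test_distance_rules(self, rng, dist, expected_len):
        cat, ltr = _cat_with_neighbor(rng, dist, dist)
        fr = build_flank_frame(ltr, cat)
        for flank, anchor in ((fr.up_flank, 4000), (fr.down_flank, 4350)):
            if expected_len is None:
                assert flank is None
            else:
                assert flank.length == expected_len

    def test_no_neighbor_gives_max_flank(self, rng):
        cat, ltr = _cat_with_neighbor(rng, None, None)
        fr = build_flank_frame(ltr, cat)
        assert fr.up_flank.length == 500 and fr.down_flank.length == 500

    def test_chromosome_edge_truncates(self, rng):
        seq = make_sequence(rng, 1000)
        iv = GenomicInterval("chr1", 200, 400)
        cat = FeatureCatalog({"chr1": seq}, [Feature("ltr1", "ltr", iv)])
        fr = build_flank_frame(LtrLocus("ltr1", iv, "solitary"), cat)
        assert (fr.up_flank.start, fr.up_flank.end) == (0, 200)
        assert (fr.down_flank.start, fr.down_flank.end) == (400, 900)

    def test_flanks_do_not_overlap_features(self, rng):
        cat, ltr = _cat_with_neighbor(rng, 700, 300)
        fr = build_flank_frame(ltr, cat)
        for f in cat.features:
            if f.id == "ltr1":
                continue
            for flank in (fr.up_flank, fr.down_flank):
                if flank is not None:
                    assert not flank.overlaps(f.interval)


class TestWindowDensity:
    def test_uniform_counts_constant_density(self):
        dens = window_density(list(range(50)), ncols=50, n_rows=4, window=7)
        assert np.allclose(dens, 1 / 4)

    def test_single_count_plateau(self):
        dens = window_density([25], ncols=51, n_rows=1, window=11)
        inner = dens[20:31]  # columns fully covering position 25
        assert np.allclose(inner, 1 / 11)
        assert dens[0] == 0

    def test_matches_naive_loop(self, rng):
        ncols, w, n_rows = 80, 9, 3
        positions = list(rng.integers(0, ncols, 200))
        weights = list(rng.random(200))
        dens = window_density(positions, ncols, n_rows, w, weights)
        counts = np.zeros(ncols)
        for p, wt in zip(positions, weights):
            counts[p] += wt
        half = w // 2
        for c in range(ncols):
            lo, hi = max(0, c - half), min(ncols, c + half + 1)
            assert dens[c] == pytest.approx(counts[lo:hi].mean() / n_rows)

    def test_window_larger_than_alignment_errors(self):
        with pytest.raises(ValueError):
            window_density([0], ncols=5, n_rows=1, window=7)
        with pytest.raises(ValueError):
            window_density([0], ncols=50, n_rows=1, window=10)  # even


def _probe(qid, start, end, signal):
    h = [Hit("chr1", start, end, "+")]
    return MappingRecord(qid, "probe", "+", signal, h, h, "unique")


class TestFlankContrast:
    def _frames(self):
        from ltrtx.ltr_alignment import FlankFrame

        return [
            FlankFrame(
                "ltr1",
                GenomicInterval("chr1", 1000, 1350),
                GenomicInterval("chr1", 500, 1000),
                GenomicInterval("chr1", 1350, 1850),
            )
        ]

    def test_separated_groups_minimal_p(self, rng):
        recs = [_probe(f"i{k}", 1010 + k * 5, 1070 + k * 5, 5.0 + rng.normal(0, 0.1))
                for k in range(20)]
        recs += [_probe(f"u{k}", 510 + k * 5, 570 + k * 5, rng.normal(0, 0.1))
                 for k in range(20)]
        recs += [_probe(f"d{k}", 1360 + k * 5, 1420 + k * 5, rng.normal(0, 0.1))
                 for k in range(20)]
        c = flank_contrast(self._frames(), recs)
        assert c.median_in > c.median_up and c.median_in > c.median_down
        assert c.u_up == 400  # in-group wins every pair
        assert c.p_up < 1e-5 and c.p_down < 1e-5

    def test_identical_distributions_not_significant(self, rng):
        vals = rng.normal(0, 1, 300)
        recs = [_probe(f"i{k}", 1010, 1070, vals[k]) for k in range(100)]
        recs += [_probe(f"u{k}", 510, 570, vals[100 + k]) for k in range(100)]
        recs += [_probe(f"d{k}", 1360, 1420, vals[200 + k]) for k in range(100)]
        c = flank_contrast(self._frames(), recs)
        assert c.p_up > 0.05 and c.p_down > 0.05

    def test_single_probe_per_compartment(self):
        recs = [
            _probe("i", 1010, 1070, 2.5),
            _probe("u", 510, 570, 1.5),
            _probe("d", 1360, 1420, -0.5),
        ]
        c = flank_contrast(self._frames(), recs)
        assert (c.median_in, c.median_up, c.median_down) == (2.5, 1.5, -0.5)

    def test_empty_flank_skips_comparison(self):
        recs = [_probe("i", 1010, 1070, 2.5)]
        c = flank_contrast(self._frames(), recs)
        assert c.p_up is None and c.median_up is None

    def test_recovers_ltr_confined_transcription(self):
        """Generator truth: solitary-LTR transcription spans the LTR only, so
        the in-LTR median must exceed both flank medians (p < 0.01)."""
        from ltrtx.exact_mapper import map_query_table, probes_from_table
        from ltrtx.genome_model import partition_ltrs
        from ltrtx.synthetic_data import (
            SimConfig, generate_genome, simulate_hybmap, simulate_probes,
        )

        cfg = SimConfig(
            seed=3, chrom_length=90_000, n_full_elements=0, n_solitary=50,
            include_chimeric=False, n_genes=8, noise_sd=0.4,
        )
        cfg.activity.solitary_rate = 3.0
        catalog, truth = generate_genome(cfg)
        _, solitary = partition_ltrs(catalog)
        probes = simulate_probes(catalog, cfg)
        intens = simulate_hybmap(probes, catalog, truth, cfg)
        queries = probes_from_table(intens)
        target = [l.interval for l in solitary]
        recs = map_query_table(queries, catalog, target, "unique_only")
        frames = [build_flank_frame(l, catalog) for l in solitary]
        c = flank_contrast(frames, recs)
        assert c.n_in >= 50 and c.n_up >= 20 and c.n_down >= 20
        assert c.median_in > c.median_up and c.median_in > c.median_down
        assert c.p_up < 0.01 and c.p_down < 0.01
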