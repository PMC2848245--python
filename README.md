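# ltrtx

Analysis of LTR retrotransposon transcription from exact-match transcriptome
data, built for compact genomes like that of fission yeast.

Most LTR (long terminal repeat) sequences in a genome exist as *solitary*
LTRs — single repeats left behind by recombination — while a minority flank
intact, potentially mobile *full-length* retrotransposons (LTR–internal
gag/pol–LTR).  Whether and where these elements are transcribed is hard to
establish because the sequences are nearly identical across loci: a short
read or tiling probe rarely maps to a single locus.  `ltrtx` implements a
complete, tested pipeline for this problem for two data types that admit
exact matching only: short sequencing reads (30–51 nt) and strand-tagged
60-mer probe intensities (log2 over an intergenic baseline).

For a query q with genome-wide exact hit set H(q) and a target locus set,
the classification is **unique** (|H| = 1, in-set), **exclusive** (|H| ≥ 2,
all in-set) or **excluded**.  Per-locus activity is then bracketed rather
than estimated: with S(q) the loci hit by q and w(q) its signal,

* equal-split: locus ℓ receives Σ_{q: ℓ∈S(q)} w(q)/|S(q)|
* single-locus max: locus ℓ receives Σ_{q: ℓ∈S(q)} w(q)  (per-locus ceiling)
* unique-only: the floor from |S(q)| = 1 evidence,

and unique-only ≤ equal-split ≤ single-locus-max holds per locus.  Two
bespoke permutation tests ask the biological questions: (i) do per-locus
mean probe intensities vary more between solitary LTR loci than
count-preserving reshuffles of the probes allow (10,000 replicates, p =
(1+k)/(N+1)); and (ii) are LTR and neighbour-gene meiotic log2(stage/growth)
profiles coupled, judged by the median per-pair Pearson r against a null
that shuffles LTR values among LTRs independently within each time point
(two-sided p = doubled smaller tail, so one exceedance in 10,000 reports
2 × 10⁻⁴).  Supporting machinery includes LTR partition (including chimeric
LTR–int–LTR–int–LTR chains as two elements sharing the middle LTR),
intergenic/intronic background construction, single-linkage clustering of
solitary LTRs at 70% global-alignment identity, projection of mappings onto
alignment columns, 500 bp flank frames with half-distance/60 bp rules, and a
fully seeded synthetic-data generator (genome, probes, staged reads) with
known ground truth.

See `docs/methods.md` for models, defaults and numerical conventions.

## Worked example

```python
import numpy as np
from ltrtx import SimConfig, generate_genome, partition_ltrs
from ltrtx.synthetic_data import (
    simulate_probes, simulate_hybmap, simulate_meiosis_profiles,
)
from ltrtx.exact_mapper import probes_from_table, map_query_table
from ltrtx.signal_assignment import _hit_loci
from ltrtx.perm_stats import timepoint_permutation_test

cfg = SimConfig(seed=7, chrom_length=150_000, n_full_elements=13,
                n_solitary=20, n_genes=10, probe_tile_step=20)
cfg.activity.hot_fraction = 3 / 13   # 3 hot elements carry 95% of the rate
catalog, truth = generate_genome(cfg)

elements, solitary = partition_ltrs(catalog)
print(f"{len(elements)} full-length elements, {len(solitary)} solitary LTRs")

loci = {el.id: el.parts for el in elements}
target = [iv for ivs in loci.values() for iv in ivs]
probes = simulate_probes(catalog, cfg, within_kinds=["ltr", "retro_internal"])
intens = simulate_hybmap(probes, catalog, truth, cfg)
records = map_query_table(probes_from_table(intens), catalog, target,
                          "exclusive_ok")

unique = [r.signal for r in records if r.klass == "unique"]
eqsplit = [r.signal / len(_hit_loci(r, loci))
           for r in records if r.klass in ("unique", "exclusive")]
print(f"median unique-probe intensity: {np.median(unique):.2f}")
print(f"90th pct of equal-split values: {np.percentile(eqsplit, 90):.2f}")

pairs = simulate_meiosis_profiles(n_pairs=8, rho=0.8, seed=101)
res = timepoint_permutation_test(pairs, n_perm=10_000, seed=1)
print(f"median LTR-gene correlation: {res.observed:.3f}"
      f"  (two-sided p = {res.p_value:.2e})")
```

Output:

```
13 full-length elements, 20 solitary LTRs
median unique-probe intensity: 2.73
90th pct of equal-split values: 0.51
median LTR-gene correlation: 0.817  (two-sided p = 4.00e-04)
```

The first two numbers are the "few hot loci" signature: most probes map to
many near-identical elements, so their equal-split values sit near the
intergenic baseline, while the uniquely mapping probes — concentrated on the
diverged, active loci — read far above it.  The last line shows the
within-time-point shuffle test recovering a planted LTR–gene coupling of
ρ = 0.8 at a two-sided significance of 4 × 10⁻⁴.

A `ltrtx` command-line interface wraps the same library for shell use:
`ltrtx simulate`, `ltrtx partition`, `ltrtx map`, `ltrtx run-growth`,
`ltrtx run-meiosis`, `ltrtx run-all`, driven by plain `key = value` config
files.  Exit codes: 0 success, 2 config error, 3 data error.

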