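"""Statistical machinery: Mann-Whitney comparisons and the two bespoke
permutation tests used for LTR transcription analysis.

* ``variance_permutation_test`` asks whether per-locus mean probe intensities
  differ more between solitary LTR loci than expected if probes were
  interchangeable: probe intensities are shuffled between loci while each
  locus keeps its observed number of probes, and the between-locus variance
  of means is recomputed for each shuffle.

* ``timepoint_permutation_test`` asks whether LTR and neighbouring-gene
  meiosis expression profiles are coupled: LTR log-ratio profiles are
  shuffled among LTRs independently within each meiotic time point, per-pair
  Pearson correlations against the (unshuffled) gene profiles are recomputed,
  and the median correlation is the statistic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

STAGES = ("growth", "M1", "M2", "M3", "M4", "M5")
MEIOSIS_STAGES = ("M1", "M2", "M3", "M4", "M5")


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U (for group *x*) and two-sided p.

    U_x counts pairs with x_i > y_j plus half the ties.  For small samples
    (n_x + n_y <= 12) the p-value is an exact enumeration over all rank
    assignments (ties handled by enumerating the pooled values themselves);
    otherwise the normal approximation with tie and continuity correction is
    used.  Degenerate input (all values identical) gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u_x = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u_x, 1.0
    if len(pooled) <= 12:
        p = _exact_p(pooled, len(x), u_x)
    else:
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u_x, p


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def _exact_p(pooled: np.ndarray, nx: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, nx) group assignments."""
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), nx):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    n_tot = len(us)
    p_le = np.sum(us <= u_obs + 1e-12) / n_tot
    p_ge = np.sum(us >= u_obs - 1e-12) / n_tot
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Permutation framework


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and empirical p-value."""

    observed: float
    null_values: np.ndarray
    n_perm: int
    p_value: float
    tail: str  # {"one_sided_ge", "two_sided"}
    seed: Optional[int] = None
    exhaustive: bool = False
    notes: Dict[str, object] = field(default_factory=dict)

    @property
    def null_min(self) -> float:
        return float(np.min(self.null_values))

    @property
    def null_max(self) -> float:
        return float(np.max(self.null_values))

    def null_quantiles(self, qs=(0.025, 0.5, 0.975)) -> List[float]:
        return [float(q) for q in np.quantile(self.null_values, qs)]

    def to_json_dict(self, test: str) -> Dict[str, object]:
        return {
            "test": test,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "p_value": self.p_value,
            "tail": self.tail,
            "exhaustive": self.exhaustive,
            "null_min": self.null_min,
            "null_max": self.null_max,
            "null_quantiles": self.null_quantiles(),
            **self.notes,
        }


def empirical_p_ge(n_ge: int, n_perm: int, exhaustive: bool = False) -> float:
    """One-sided empirical p: add-one for sampled nulls, exact for exhaustive."""
    if exhaustive:
        return n_ge / n_perm
    return (1 + n_ge) / (n_perm + 1)


def empirical_p_two_sided(n_ge: int, n_le: int, n_perm: int) -> float:
    """Two-sided empirical p: doubled smaller tail, floored at 1/n_perm.

    One exceedance among 10,000 permutations yields 2e-4.
    """
    p = 2.0 * min(n_ge, n_le) / n_perm
    return float(min(1.0, max(p, 1.0 / n_perm)))


# ---------------------------------------------------------------------------
# Between-locus variance test


def variance_permutation_test(
    intensities_by_locus: Mapping[str, Sequence[float]],
    n_perm: int = 10000,
    seed: Optional[int] = None,
    exhaustive_limit: int = 10**5,
) -> PermutationResult:
    """Between-locus variance of mean probe intensities vs a shuffled null.

    Observed statistic: sample variance (n-1 denominator) of per-locus mean
    intensities.  Null: pooled intensities reassigned to loci preserving each
    locus's probe count.  When the count-preserving assignment space is no
    larger than ``exhaustive_limit`` the full enumeration is used (exact
    p = k/N); otherwise ``n_perm`` sampled shuffles with the add-one
    convention p = (1+k)/(n_perm+1).  Forward- and reverse-strand probes are
    analysed in separate invocations.
    """
    groups = {
        lid: np.asarray(v, float)
        for lid, v in intensities_by_locus.items()
        if len(v) > 0
    }
    dropped = len(intensities_by_locus) - len(groups)
    if dropped:
        log.info("variance test: dropped %d loci with zero probes", dropped)
    if len(groups) < 2:
        raise ValueError("need >= 2 loci with at least one probe each")
    ids = sorted(groups)
    counts = np.array([len(groups[i]) for i in ids])
    pooled = np.concatenate([groups[i] for i in ids])
    n = len(pooled)
    observed = float(np.var([groups[i].mean() for i in ids], ddof=1))

    n_assign = _multinomial(n, counts)
    if n_assign <= exhaustive_limit:
        null = _exhaustive_variance_null(pooled, counts)
        n_ge = int(np.sum(null >= observed - 1e-12))
        p = empirical_p_ge(n_ge, len(null), exhaustive=True)
        return PermutationResult(
            observed, null, len(null), p, "one_sided_ge", seed, exhaustive=True
        )

    rng = np.random.default_rng(seed)
    offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
    indicator = np.zeros((n, len(ids)))
    start = 0
    for j, c in enumerate(counts):
        indicator[start : start + c, j] = 1.0 / c
        start += c
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(pooled, (k, 1)), axis=1)
        means = perm @ indicator  # (k, n_loci)
        null[done : done + k] = means.var(axis=1, ddof=1)
        done += k
    n_ge = int(np.sum(null >= observed - 1e-12))
    p = empirical_p_ge(n_ge, n_perm)
    return PermutationResult(observed, null, n_perm, p, "one_sided_ge", seed)


def _multinomial(n: int, counts: np.ndarray) -> float:
    out = math.lgamma(n + 1) - sum(math.lgamma(c + 1) for c in counts)
    return math.exp(out) if out < 50 else float("inf")


def _exhaustive_variance_null(pooled: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Variance of group means over every count-preserving index assignment."""
    n = len(pooled)
    null: List[float] = []

    def _recurse(remaining: Tuple[int, ...], group_means: List[float], ci: int):
        if ci == len(counts):
            null.append(float(np.var(group_means, ddof=1)))
            return
        for idx in itertools.combinations(remaining, int(counts[ci])):
            rest = tuple(i for i in remaining if i not in idx)
            _recurse(rest, group_means + [float(pooled[list(idx)].mean())], ci + 1)

    _recurse(tuple(range(n)), [], 0)
    return np.asarray(null)


# ---------------------------------------------------------------------------
# Meiosis stage profiles


@dataclass
class StageProfile:
    """Uniquely-mapped read counts per stage with log2 ratios vs growth."""

    entity_id: str
    counts: Dict[str, float]

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.counts]
        if missing:
            raise ValueError(f"profile {self.entity_id!r} missing stages {missing}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")

    def log_ratios(self, pseudocount: float = 0.0) -> Dict[str, float]:
        g = self.counts["growth"] + pseudocount
        if g <= 0:
            raise ValueError(
                f"profile {self.entity_id!r}: zero growth count; use pseudocount > 0"
            )
        out = {}
        for s in STAGES:
            c = self.counts[s] + pseudocount
            if c <= 0:
                raise ValueError(
                    f"profile {self.entity_id!r}: zero count at {s}; use pseudocount > 0"
                )
            out[s] = math.log2(c / g)
        return out

    def total(self) -> float:
        return sum(self.counts.values())


def select_meiosis_ltrs(
    profiles: Mapping[str, StageProfile],
    upstream_genes: Mapping[str, Tuple[str, int]],
    min_total: float = 30,
    min_growth: float = 10,
    upstream_within: int = 1000,
) -> List[Tuple[str, str]]:
    """LTRs with enough uniquely-mapped reads and an upstream-adjacent gene.

    Keeps LTRs with at least ``min_total`` reads over all stages combined and
    ``min_growth`` reads in growth phase, residing within ``upstream_within``
    bp upstream of a protein-coding gene; each is paired with that gene.
    """
    out = []
    for lid in sorted(profiles):
        prof = profiles[lid]
        if prof.total() < min_total or prof.counts["growth"] < min_growth:
            continue
        pair = upstream_genes.get(lid)
        if pair is None or pair[1] > upstream_within:
            continue
        out.append((lid, pair[0]))
    return out


def concatenated_pearson(
    pairs: Sequence[Tuple[StageProfile, StageProfile]],
    stages: Sequence[str] = MEIOSIS_STAGES,
    pseudocount: float = 0.0,
) -> float:
    """Pearson r over all pairs' concatenated stage log-ratios."""
    xs: List[float] = []
    ys: List[float] = []
    for ltr, gene in pairs:
        lr, gr = ltr.log_ratios(pseudocount), gene.log_ratios(pseudocount)
        xs.extend(lr[s] for s in stages)
        ys.extend(gr[s] for s in stages)
    if len(xs) < 2:
        raise ValueError("need >= 2 points")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in concatenated profile")
    return float(np.corrcoef(x, y)[0, 1])


def timepoint_permutation_test(
    pairs: Sequence[Tuple[StageProfile, StageProfile]],
    n_perm: int = 10000,
    seed: Optional[int] = None,
    pseudocount: float = 0.0,
    stages: Sequence[str] = MEIOSIS_STAGES,
) -> PermutationResult:
    """Median LTR-gene profile correlation vs a within-stage shuffled null.

    Observed statistic: the median over pairs of the Pearson correlation
    between an LTR's and its gene's stage log-ratios.  Null: LTR log-ratio
    values are shuffled among LTRs independently within each stage, per-pair
    correlations recomputed against the unshuffled gene profiles, and the
    median recorded.  Two-sided p doubles the smaller tail (count/n_perm),
    floored at 1/n_perm.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 LTR-gene pairs to shuffle within stages")
    L_rows, G_rows = [], []
    for ltr, gene in pairs:
        lr, gr = ltr.log_ratios(pseudocount), gene.log_ratios(pseudocount)
        lrow = [lr[s] for s in stages]
        grow = [gr[s] for s in stages]
        if np.ptp(lrow) == 0 or np.ptp(grow) == 0:
            log.info(
                "timepoint test: dropping pair (%s, %s) with constant profile",
                ltr.entity_id, gene.entity_id,
            )
            continue
        L_rows.append(lrow)
        G_rows.append(grow)
    if len(L_rows) < 2:
        raise ValueError("fewer than 2 usable pairs after dropping constants")
    L = np.asarray(L_rows)  # (n, k)
    G = np.asarray(G_rows)
    n, k = L.shape
    observed = float(np.median(_rowwise_pearson(L, G)))

    rng = np.random.default_rng(seed)
    # perm[t, s, :] is a permutation of the n LTR values within stage s
    perm = rng.permuted(np.tile(np.arange(n), (n_perm, k, 1)), axis=2)
    Lp = np.empty((n_perm, n, k))
    for s in range(k):
        Lp[:, :, s] = L[:, s][perm[:, s, :]]
    Gc = G - G.mean(axis=1, keepdims=True)
    g_ss = (Gc**2).sum(axis=1)
    Lc = Lp - Lp.mean(axis=2, keepdims=True)
    num = (Lc * Gc[None, :, :]).sum(axis=2)
    den = np.sqrt((Lc**2).sum(axis=2) * g_ss[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    null = np.nanmedian(r, axis=1)
    n_ge = int(np.sum(null >= observed - 1e-12))
    n_le = int(np.sum(null <= observed + 1e-12))
    p = empirical_p_two_sided(n_ge, n_le, n_perm)
    return PermutationResult(
        observed, null, n_perm, p, "two_sided", seed,
        notes={"n_pairs": n, "stages": list(stages)},
    )


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    return (ac * bc).sum(1) / np.sqrt((ac**2).sum(1) * (bc**2).sum(1))


def set_level_stage_profile(
    exclusive_counts: Mapping[str, float],
    totals: Mapping[str, float],
    pseudocount: float = 0.0,
) -> Dict[str, float]:
    """Set-level log2 ratio of relative exclusive-read levels vs growth.

    The relative level of a stage is (exclusive reads + pseudocount) divided
    by the stage's total library size; the profile is log2(stage relative /
    growth relative), with growth fixed at 0.
    """
    rel = {}
    for s in STAGES:
        if totals[s] <= 0:
            raise ValueError(f"non-positive library size for stage {s}")
        rel[s] = (exclusive_counts[s] + pseudocount) / totals[s]
    if rel["growth"] <= 0:
        raise ValueError("zero growth relative level; use pseudocount > 0")
    out = {}
    for s in STAGES:
        if rel[s] <= 0:
            raise ValueError(f"zero relative level at {s}; use pseudocount > 0")
        out[s] = math.log2(rel[s] / rel["growth"])
    return out
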