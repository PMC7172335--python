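"""Interval-overlap counting and permutation enrichment.

The permutation scheme preserves the number of intervals, each interval's
size, and its chromosome: every interval is independently re-placed
uniformly on its own chromosome.  Significance of the observed overlap
against the permuted distribution is a z-test; fold = observed / permuted
mean.  Exact 2x2 (Fisher) and hypergeometric tests cover the count-table
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .core_io import GenomeIndex, Interval, IntervalSet, ValidationError, merge_intervals


@dataclass
class EnrichmentResult:
    """Observed overlap against its permutation null."""

    observed: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    z: float                  # nan when degenerate
    p: float                  # nan when degenerate
    fold: float               # nan when perm_mean == 0
    degenerate: bool = False


def _merged_arrays(b: IntervalSet, chrom: str, slack: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    ivs = [iv.expanded(slack) if slack else iv for iv in b.on(chrom)]
    merged = merge_intervals(ivs)
    return (np.array([iv.start for iv in merged], dtype=np.int64),
            np.array([iv.end for iv in merged], dtype=np.int64))


def overlap_count(a: IntervalSet, b: IntervalSet, slack: int = 0) -> int:
    """Number of a-intervals overlapping (>= 1 bp) some b-interval expanded by slack.

    Each a-interval is counted at most once.
    """
    if slack < 0:
        raise ValidationError("slack must be >= 0")
    total = 0
    for chrom in a.chroms:
        a_starts, a_ends = a.arrays(chrom)
        if a_starts.size == 0:
            continue
        b_starts, b_ends = _merged_arrays(b, chrom, slack)
        if b_starts.size == 0:
            continue
        # first expanded b-interval ending strictly after the a-start
        idx = np.searchsorted(b_ends, a_starts, side="right")
        ok = idx < b_starts.size
        hit = np.zeros(a_starts.size, dtype=bool)
        hit[ok] = b_starts[idx[ok]] < a_ends[ok]
        total += int(hit.sum())
    return total


def shuffle_intervals(a: IntervalSet, genome: GenomeIndex,
                      rng: np.random.Generator | int | None = None) -> IntervalSet:
    """Re-place every interval uniformly on its own chromosome, same length.

    Shuffled intervals may overlap one another; each stays entirely within
    its chromosome.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: list[Interval] = []
    for iv in a:
        clen = genome[iv.chrom]
        length = len(iv)
        if length > clen:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} longer than its chromosome")
        start = int(rng.integers(0, clen - length + 1))
        out.append(Interval(iv.chrom, start, start + length, iv.name,
                            iv.score, iv.strand))
    return IntervalSet(out)


def _shuffled_starts(a: IntervalSet, genome: GenomeIndex,
                     rng: np.random.Generator
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Vectorised shuffle: per-chrom (starts, ends), unsorted."""
    out = {}
    for chrom in a.chroms:
        starts, ends = a.arrays(chrom)
        lengths = ends - starts
        caps = genome[chrom] - lengths
        if np.any(caps < 0):
            raise ValidationError("interval longer than its chromosome")
        new_starts = (rng.random(lengths.size) * (caps + 1)).astype(np.int64)
        out[chrom] = (new_starts, new_starts + lengths)
    return out


def permutation_enrichment(a: IntervalSet, b: IntervalSet, genome: GenomeIndex,
                           cfg: PipelineConfig | None = None,
                           slack: int | None = None,
                           n_perm: int | None = None,
                           rng: np.random.Generator | int | None = None,
                           alternative: str = "two-sided") -> EnrichmentResult:
    """Observed overlap vs. the chromosome/size-preserving permutation null.

    z = (observed - perm_mean) / perm_sd (sd with n-1 denominator);
    p is the normal two-sided tail by default.  A zero-spread null is
    flagged degenerate (p and z reported as NaN, never a fabricated 0).
    """
    cfg = cfg or PipelineConfig()
    slack = cfg.overlap_slack if slack is None else slack
    n_perm = cfg.n_perm if n_perm is None else n_perm
    if n_perm < 30:
        raise ValidationError("n_perm must be >= 30 for the z approximation")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    observed = overlap_count(a, b, slack)

    merged = {chrom: _merged_arrays(b, chrom, slack) for chrom in a.chroms}
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = _shuffled_starts(a, genome, rng)
        count = 0
        for chrom, (a_starts, a_ends) in shuffled.items():
            b_starts, b_ends = merged[chrom]
            if b_starts.size == 0 or a_starts.size == 0:
                continue
            idx = np.searchsorted(b_ends, a_starts, side="right")
            ok = idx < b_starts.size
            hit = np.zeros(a_starts.size, dtype=bool)
            hit[ok] = b_starts[idx[ok]] < a_ends[ok]
            count += int(hit.sum())
        null[i] = count

    perm_mean = float(null.mean())
    perm_sd = float(null.std(ddof=1))
    fold = observed / perm_mean if perm_mean > 0 else math.nan
    if perm_sd == 0:
        return EnrichmentResult(observed, n_perm, perm_mean, perm_sd,
                                math.nan, math.nan, fold, degenerate=True)
    z = (observed - perm_mean) / perm_sd
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(observed, n_perm, perm_mean, perm_sd, z, float(p), fold)


def fisher_exact_test(table: list[list[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of tables as or less likely)."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValidationError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p = P(X >= k).

    Drawing ``n`` items from a universe of ``N`` containing ``K``
    successes; ``k`` successes observed in the draw.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError("inconsistent hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))
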