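"""Anchored meta-profiles, domain tests, Pol II classification, per-gene tests.

Profiles place probe values at anchor-relative coordinates (reflected for
minus-strand anchors and for domain end-boundaries, so "downstream" /
"into the domain" always points the same way), compute a per-entity
sliding-window statistic stepping 1 bp, and aggregate across entities
per position, ignoring empty windows.

Pol II pausing classification compares the median mutant vs. control
signal over the paused region (TSS-30 .. TSS+300, strand-oriented) for
genes of at least 1 kb; per-gene region tests (Mann-Whitney or Welch t
over probes, BH-corrected) cover the histone-mark differential analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .core_io import (Domain, GeneModel, Interval, IntervalSet, ProbeTrack,
                      ValidationError, merge_intervals)


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# anchored profiles
# ---------------------------------------------------------------------------

Anchor = tuple[str, int, str]      # (chrom, position, strand)


@dataclass
class ProfileMatrix:
    """Anchor-relative position x entity matrix of windowed statistics."""

    positions: np.ndarray          # strictly increasing, bp relative to anchor
    matrix: np.ndarray             # (n_entities, n_positions), NaN = no probes
    aggregate: np.ndarray          # per-position stat across entities
    entity_ids: list[str]

    @property
    def n_entities(self) -> int:
        return self.matrix.shape[0]


def tss_anchors(genes: list[GeneModel]) -> list[Anchor]:
    return [(g.chrom, g.tss, g.strand) for g in genes]


def boundary_anchors(domains: IntervalSet | list[Domain]) -> list[Anchor]:
    """Two anchors per domain, oriented so +x points into the domain."""
    out: list[Anchor] = []
    for d in domains:
        iv = d.interval if isinstance(d, Domain) else d
        out.append((iv.chrom, iv.start, "+"))
        out.append((iv.chrom, iv.end - 1, "-"))
    return out


def center_anchors(domains: IntervalSet | list[Domain]) -> list[Anchor]:
    out: list[Anchor] = []
    for d in domains:
        iv = d.interval if isinstance(d, Domain) else d
        out.append((iv.chrom, (iv.start + iv.end) // 2, "+"))
    return out


def _window_bounds(window: int) -> tuple[int, int]:
    """Centered window of ``window`` bp: closed offsets [-(w//2), (w-1)//2]."""
    return -(window // 2), (window - 1) // 2


def _windowed_stat(relpos: np.ndarray, vals: np.ndarray, positions: np.ndarray,
                   window: int, stat: str) -> np.ndarray:
    """Sliding-window statistic of (relpos, vals) at each query position.

    Windows with no probes yield NaN.  Consecutive positions often share
    the same probe slice (probe spacing >> 1 bp step), so the statistic is
    evaluated once per distinct slice.
    """
    lo_off, hi_off = _window_bounds(window)
    lo = np.searchsorted(relpos, positions + lo_off, side="left")
    hi = np.searchsorted(relpos, positions + hi_off, side="right")
    out = np.full(positions.size, np.nan)
    if stat == "mean":
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        n = hi - lo
        ok = n > 0
        out[ok] = (csum[hi[ok]] - csum[lo[ok]]) / n[ok]
        return out
    if stat != "median":
        raise ValueError(f"unknown stat {stat!r}")
    start = 0
    while start < positions.size:
        end = start
        while (end + 1 < positions.size and lo[end + 1] == lo[start]
               and hi[end + 1] == hi[start]):
            end += 1
        if hi[start] > lo[start]:
            out[start:end + 1] = np.median(vals[lo[start]:hi[start]])
        start = end + 1
    return out


def _all_sample_values(track: ProbeTrack, chrom: str) -> np.ndarray:
    """One value per probe: mean across all samples of the track."""
    return track.values(chrom).mean(axis=1)


def anchored_profile(track: ProbeTrack, anchors: list[Anchor],
                     span: tuple[int, int], window: int = 10,
                     stat: str = "median", flip: bool = True,
                     agg: str | None = None,
                     entity_ids: list[str] | None = None) -> ProfileMatrix:
    """Anchor-relative sliding-window profile plus cross-entity aggregate.

    ``span`` is the closed anchor-relative range (e.g. ``(-2000, 5000)``);
    the window steps 1 bp.  With ``flip``, minus-strand anchors are
    reflected so that +x is downstream for every entity.  The aggregate
    applies ``agg`` (default: same as ``stat``) across entities per
    position, ignoring entities with no probes in the window.
    """
    if span[0] > span[1]:
        raise ValidationError("span inverted")
    if window < 1:
        raise ValidationError("window must be >= 1")
    if not anchors:
        raise ValidationError("need at least one anchor")
    agg = agg or stat
    positions = np.arange(span[0], span[1] + 1, dtype=np.int64)
    lo_off, hi_off = _window_bounds(window)
    rows = []
    for chrom, apos, strand in anchors:
        if chrom not in track.chroms:
            rows.append(np.full(positions.size, np.nan))
            continue
        ppos = track.positions(chrom)
        vals = _all_sample_values(track, chrom)
        if flip and strand == "-":
            rel = apos - ppos
        else:
            rel = ppos - apos
        sel = (rel >= span[0] + lo_off) & (rel <= span[1] + hi_off)
        rel, v = rel[sel], vals[sel]
        order = np.argsort(rel, kind="stable")
        rows.append(_windowed_stat(rel[order], v[order], positions, window, stat))
    matrix = np.vstack(rows) if rows else np.empty((0, positions.size))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        warnings.filterwarnings("ignore", "All-NaN slice")
        if agg == "mean":
            aggregate = np.nanmean(matrix, axis=0)
        elif agg == "median":
            aggregate = np.nanmedian(matrix, axis=0)
        else:
            raise ValueError(f"unknown aggregate {agg!r}")
    if entity_ids is None:
        entity_ids = [f"anchor_{i}" for i in range(len(anchors))]
    return ProfileMatrix(positions, matrix, aggregate, entity_ids)


def smooth_profile(curve: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    NaN positions are ignored within each window; length is preserved.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    curve = np.asarray(curve, dtype=np.float64)
    n = curve.size
    lo_off, hi_off = _window_bounds(window)
    finite = np.isfinite(curve)
    filled = np.where(finite, curve, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    idx = np.arange(n)
    lo = np.clip(idx + lo_off, 0, n)
    hi = np.clip(idx + hi_off + 1, 0, n)
    counts = ccnt[hi] - ccnt[lo]
    out = np.full(n, np.nan)
    ok = counts > 0
    out[ok] = (csum[hi[ok]] - csum[lo[ok]]) / counts[ok]
    return out


# ---------------------------------------------------------------------------
# domain signal test
# ---------------------------------------------------------------------------

def _pool_domain_values(track: ProbeTrack, domains: IntervalSet) -> np.ndarray:
    merged = merge_intervals(iv for iv in domains)
    per_chrom: dict[str, list[Interval]] = {}
    for iv in merged:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    chunks = []
    for chrom, ivs in per_chrom.items():
        if chrom not in track.chroms:
            continue
        pos = track.positions(chrom)
        vals = _all_sample_values(track, chrom)
        for iv in ivs:
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            chunks.append(vals[lo:hi])
    return np.concatenate(chunks) if chunks else np.empty(0)


def domain_signal_test(ctrl: ProbeTrack, mut: ProbeTrack,
                       domains: IntervalSet | list[Domain],
                       equal_var: bool = False,
                       ) -> tuple[float, float, float, float]:
    """Pooled-probe t-test of control vs. mutant signal inside domains.

    Pools every probe value inside any domain per condition and applies a
    two-sample t-test (Welch by default).  Returns
    ``(mean_ctrl, mean_mut, t, p)``.
    """
    if isinstance(domains, list):
        domains = IntervalSet(d.interval if isinstance(d, Domain) else d
                              for d in domains)
    x = _pool_domain_values(ctrl, domains)
    y = _pool_domain_values(mut, domains)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need >= 2 in-domain probes per condition")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # zero variance in both: identical means -> no evidence of change
        return float(x.mean()), float(y.mean()), 0.0, 1.0 if x[0] == y[0] else 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(x.mean()), float(y.mean()), float(t), float(p)


# ---------------------------------------------------------------------------
# Pol II pausing classification
# ---------------------------------------------------------------------------

@dataclass
class PolIICategory:
    """Pausing class of one gene: mutant paused signal lower (1) or higher (2)."""

    gene_id: str
    category: int | str            # 1, 2, or "excluded"
    paused_ctrl: float = np.nan
    paused_mut: float = np.nan
    body_ctrl: float = np.nan
    body_mut: float = np.nan
    reason: str = ""


def _region_values(track: ProbeTrack, gene: GeneModel,
                   rel: tuple[int, int]) -> np.ndarray:
    """Probe values in a TSS-relative closed interval, strand-oriented."""
    if gene.chrom not in track.chroms:
        return np.empty(0)
    lo, hi = gene.oriented_interval(*rel)
    pos = track.positions(gene.chrom)
    vals = _all_sample_values(track, gene.chrom)
    i = np.searchsorted(pos, lo, side="left")
    j = np.searchsorted(pos, hi, side="right")
    return vals[i:j]


def classify_polII(ctrl: ProbeTrack, mut: ProbeTrack, genes: list[GeneModel],
                   cfg: PipelineConfig | None = None) -> list[PolIICategory]:
    """Classify genes by mutant vs. control median paused-region signal.

    Category 1: mutant paused median below control (reduced recruitment);
    category 2: above control (increased pausing).  Genes shorter than
    ``min_gene_len``, with no paused-region probes in either condition, or
    with an exact tie are excluded with a reason.  Body medians
    (TSS+1000 .. TES) are reported alongside.
    """
    cfg = cfg or PipelineConfig()
    out: list[PolIICategory] = []
    for g in genes:
        if g.length < cfg.min_gene_len:
            out.append(PolIICategory(g.id, "excluded", reason="gene shorter than minimum"))
            continue
        pc = _region_values(ctrl, g, cfg.paused_region)
        pm = _region_values(mut, g, cfg.paused_region)
        if pc.size == 0 or pm.size == 0:
            out.append(PolIICategory(g.id, "excluded", reason="no probes in paused region"))
            continue
        body_rel = (cfg.gene_body_start, g.length - 1)
        bc = _region_values(ctrl, g, body_rel)
        bm = _region_values(mut, g, body_rel)
        paused_ctrl, paused_mut = float(np.median(pc)), float(np.median(pm))
        body_ctrl = float(np.median(bc)) if bc.size else np.nan
        body_mut = float(np.median(bm)) if bm.size else np.nan
        if paused_mut < paused_ctrl:
            cat: int | str = 1
            reason = ""
        elif paused_mut > paused_ctrl:
            cat = 2
            reason = ""
        else:
            cat, reason = "excluded", "tied paused medians"
        out.append(PolIICategory(g.id, cat, paused_ctrl, paused_mut,
                                 body_ctrl, body_mut, reason))
    return out


# ---------------------------------------------------------------------------
# per-gene region tests
# ---------------------------------------------------------------------------

@dataclass
class GeneTestResult:
    gene_id: str
    statistic: float
    p: float
    q: float                     # BH-adjusted; NaN when fdr=False
    direction: str               # "up" (mutant higher) or "down"


_REGION_RULES = ("paused", "body", "k4_interval", "k27_interval", "custom")


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2), 1.0     # all ties: no evidence
    exact = (min(x.size, y.size) <= 20
             and np.unique(pooled).size == pooled.size)
    method = "exact" if exact else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(u), float(p)


def region_test(ctrl: ProbeTrack, mut: ProbeTrack, genes: list[GeneModel],
                region: str = "k27_interval",
                test: str = "mannwhitney",
                fdr: bool = True,
                custom_interval: tuple[int, int] | None = None,
                cfg: PipelineConfig | None = None) -> list[GeneTestResult]:
    """Per-gene two-sided test of mutant vs. control probe signal in a region.

    ``region`` names a TSS-relative interval rule (``paused``, ``body``,
    ``k4_interval``, ``k27_interval``, or ``custom`` with
    ``custom_interval``).  The Mann-Whitney U test is exact for small
    tie-free samples and normal-approximated (tie-corrected) otherwise;
    ``test="ttest"`` uses Welch's t.  With ``fdr``, q-values are
    Benjamini-Hochberg over all tested genes.  Genes without enough probes
    in the region are skipped.
    """
    cfg = cfg or PipelineConfig()
    if region not in _REGION_RULES:
        raise ValidationError(f"unknown region rule {region!r}")
    results: list[GeneTestResult] = []
    for g in genes:
        if region == "paused":
            rel = cfg.paused_region
        elif region == "body":
            if g.length <= cfg.gene_body_start:
                continue                        # too short for body analysis
            rel = (cfg.gene_body_start, g.length - 1)
        elif region == "k4_interval":
            rel = cfg.k4_interval
        elif region == "k27_interval":
            rel = cfg.k27_interval
        else:
            if custom_interval is None:
                raise ValidationError("custom region requires custom_interval")
            rel = custom_interval
        x = _region_values(ctrl, g, rel)
        y = _region_values(mut, g, rel)
        min_n = 2 if test == "ttest" else 1
        if x.size < min_n or y.size < min_n:
            continue
        if test == "ttest":
            if np.ptp(x) == 0 and np.ptp(y) == 0:
                statistic, p = 0.0, (1.0 if x.mean() == y.mean() else 0.0)
            else:
                statistic, p = stats.ttest_ind(x, y, equal_var=False)
        elif test == "mannwhitney":
            statistic, p = _mannwhitney_p(x, y)
        else:
            raise ValidationError(f"unknown test {test!r}")
        direction = "up" if y.mean() > x.mean() else "down"
        results.append(GeneTestResult(g.id, float(statistic), float(p),
                                      np.nan, direction))
    if fdr and results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# fold and chromatin-change categories
# ---------------------------------------------------------------------------

FOLD_CATEGORIES = ("none", "moderate", "high", "maximal")


def fold_category(fold: float) -> str:
    """Upregulation category: moderate 2-5x, high >5-10x, maximal >10x."""
    if not fold > 0:
        raise ValidationError("fold must be > 0")
    if fold < 2:
        return "none"
    if fold <= 5:
        return "moderate"
    if fold <= 10:
        return "high"
    return "maximal"


CHROMATIN_CLASSES = ("K27depletedOnly", "K4enrichedOnly", "both", "unchanged")


def chromatin_change_class(k27: GeneTestResult, k4: GeneTestResult,
                           alpha: float = 0.05) -> str:
    """Combine per-gene H3K27me3 and H3K4me3 calls into one change class.

    K27 'depleted' iff q < alpha and direction down; K4 'enriched' iff
    q < alpha and direction up.  Any other significant combination counts
    as unchanged under the three-way scheme.
    """
    if k27.gene_id != k4.gene_id:
        raise ValidationError("mismatched gene ids")
    k27_dep = k27.q < alpha and k27.direction == "down"
    k4_enr = k4.q < alpha and k4.direction == "up"
    if k27_dep and k4_enr:
        return "both"
    if k27_dep:
        return "K27depletedOnly"
    if k4_enr:
        return "K4enrichedOnly"
    return "unchanged"
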