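"""Ranked feature assignment, TSS distances, and divergent-pair rules.

Feature calls use the fixed ranking promoter > exon > intron > intergenic,
with the promoter defined as the 200 bp immediately upstream of the TSS
(strand-symmetric).  Divergently paired genes (DPGs) are head-to-head gene
pairs whose TSSs are at most 1 kb apart; a pair is "bound" when a peak
falls within 500 bp downstream of either TSS or between the two TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .core_io import (GeneModel, Interval, IntervalSet, ValidationError,
                      overlaps_with_slack)

FEATURES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class DivergentPair:
    """A divergent (head-to-head) gene pair: minus gene left, plus gene right."""

    gene_minus: str
    gene_plus: str
    tss_gap: int

    def __post_init__(self) -> None:
        if self.tss_gap < 0:
            raise ValidationError("tss_gap must be >= 0")


def promoter_region(gene: GeneModel, upstream: int = 200) -> Interval:
    """The ``upstream`` bp immediately 5' of the TSS, in genome coordinates.

    For a + gene with TSS t this is [t - upstream, t); for a - gene the
    mirror image [t + 1, t + 1 + upstream).
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss
    else:
        start, end = gene.tss + 1, gene.tss + 1 + upstream
    return Interval(gene.chrom, max(0, start), max(1, end))


def assign_feature(peak: Interval, genes: list[GeneModel],
                   cfg: PipelineConfig | None = None) -> str:
    """First feature in rank order that the peak overlaps by >= 1 bp."""
    cfg = cfg or PipelineConfig()
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    for g in same_chrom:
        if peak.overlaps(promoter_region(g, cfg.promoter_upstream)):
            return "promoter"
    for g in same_chrom:
        if any(peak.overlaps(ex) for ex in g.exons):
            return "exon"
    for g in same_chrom:
        if peak.overlaps(Interval(g.chrom, g.txStart, g.txEnd)):
            return "intron"      # inside the gene but not in any exon's span
    return "intergenic"


def tss_distance(peak: Interval, genes: list[GeneModel]) -> int:
    """Signed distance from the peak midpoint to the nearest TSS.

    Negative upstream / positive downstream in the nearest gene's
    orientation.  Ties in absolute distance resolve to the first gene in
    input order.
    """
    if not genes:
        raise ValidationError("tss_distance requires at least one gene")
    best: int | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        mid = peak.midpoint
        d = mid - g.tss if g.strand == "+" else g.tss - mid
        if best is None or abs(d) < abs(best):
            best = d
    if best is None:
        raise ValidationError(f"no gene on chromosome {peak.chrom}")
    return int(best) if float(best).is_integer() else best


def find_dpgs(genes: list[GeneModel],
              cfg: PipelineConfig | None = None) -> list[DivergentPair]:
    """All divergent (minus, plus) pairs with TSS gap <= dpg_max_tss_gap.

    Divergent orientation: the minus gene's TSS lies at or left of the plus
    gene's TSS, so the transcribed bodies point away from the inter-TSS
    gap.  A gene may participate in several pairs; ids in
    ``cfg.dpg_exclude_ids`` (e.g. histone clusters) are skipped.
    """
    cfg = cfg or PipelineConfig()
    eligible = [g for g in genes if g.id not in cfg.dpg_exclude_ids]
    minus = [g for g in eligible if g.strand == "-"]
    plus = [g for g in eligible if g.strand == "+"]
    pairs: list[DivergentPair] = []
    for gm in minus:
        for gp in plus:
            if gp.chrom != gm.chrom:
                continue
            gap = gp.tss - gm.tss
            if 0 <= gap <= cfg.dpg_max_tss_gap:
                pairs.append(DivergentPair(gm.id, gp.id, gap))
    pairs.sort(key=lambda p: (p.gene_minus, p.gene_plus))
    return pairs


def dpg_region(pair: DivergentPair, genes_by_id: dict[str, GeneModel],
               cfg: PipelineConfig | None = None) -> list[Interval]:
    """The genomic region in which a peak makes the pair 'bound'.

    Union of 500 bp downstream of each TSS (in each gene's own reading
    direction) and the inter-TSS span.
    """
    cfg = cfg or PipelineConfig()
    gm, gp = genes_by_id[pair.gene_minus], genes_by_id[pair.gene_plus]
    f = cfg.dpg_peak_flank
    parts = [
        # downstream of the minus TSS = leftwards in genome coordinates
        Interval(gm.chrom, max(0, gm.tss - f), gm.tss + 1),
        # downstream of the plus TSS = rightwards
        Interval(gp.chrom, gp.tss, gp.tss + f + 1),
    ]
    if gp.tss > gm.tss:
        parts.append(Interval(gm.chrom, gm.tss, gp.tss + 1))
    return parts


def dpg_bound(peaks: IntervalSet, pair: DivergentPair,
              genes_by_id: dict[str, GeneModel],
              cfg: PipelineConfig | None = None) -> bool:
    """True iff some peak overlaps the pair's bound region by >= 1 bp."""
    region = dpg_region(pair, genes_by_id, cfg)
    chrom = region[0].chrom
    return any(pk.overlaps(part)
               for pk in peaks.on(chrom) for part in region)


def near_boundary(peaks: IntervalSet, boundaries: IntervalSet,
                  slack: int = 5000) -> tuple[list[bool], float]:
    """Per-boundary hit flags plus the fraction of boundaries hit.

    A boundary is hit iff a peak lies within +/- ``slack`` bp of it
    (boundary expanded by ``slack``, >= 1 bp overlap).
    """
    if slack < 0:
        raise ValidationError("slack must be >= 0")
    hits: list[bool] = []
    for b in boundaries:
        hits.append(any(overlaps_with_slack(pk, b, slack)
                        for pk in peaks.on(b.chrom)))
    frac = sum(hits) / len(hits) if hits else 0.0
    return hits, frac


def domain_edges_bound(peaks: IntervalSet, domains: IntervalSet,
                       slack: int = 5000, edge_width: int = 1,
                       ) -> tuple[list[str], float, float]:
    """Per-domain boundary binding: 'both', 'one', or 'none' edges hit.

    Each domain contributes two point boundaries (start and end); returns
    the per-domain labels, the fraction of domains with at least one edge
    hit, and the fraction with both hit.
    """
    labels: list[str] = []
    for dom in domains:
        edges = [Interval(dom.chrom, dom.start, dom.start + edge_width),
                 Interval(dom.chrom, max(0, dom.end - edge_width), dom.end)]
        n = sum(any(overlaps_with_slack(pk, e, slack)
                    for pk in peaks.on(dom.chrom)) for e in edges)
        labels.append({0: "none", 1: "one", 2: "both"}[n])
    total = len(labels) or 1
    at_least_one = sum(l != "none" for l in labels) / total
    both = sum(l == "both" for l in labels) / total
    return labels, at_least_one, both
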