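"""Markov backgrounds, PWM log-odds scanning, and IUPAC consensus scanning.

PWM hits are scored in bits against the background's order-0 marginal, and
each score's p-value is the probability of an equal-or-better score at a
random background position, computed from the exact score distribution by
dynamic programming on a discretized lattice (1e-3 bit granularity).  The
position-independent order-0 null is what makes a single per-position
p-value well defined; higher-order backgrounds refine only the estimated
marginal context.  Consensus motifs (e.g. YAACKG) are exact-match scans
whose per-position match probability is the product of admitted-base
marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .core_io import GeneModel, ValidationError
from .simulate import _IUPAC as IUPAC_CODES
from .simulate import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
LATTICE = 1e-3          # score-lattice granularity, bits


@dataclass
class MarkovBackground:
    """Order-k Markov model over {A,C,G,T} with per-context conditionals."""

    order: int
    conditionals: Mapping[str, np.ndarray]   # context (len k) -> P(base | context)
    marginal: np.ndarray                     # order-0 base distribution
    pseudocount: float

    def __post_init__(self) -> None:
        for ctx, dist in self.conditionals.items():
            if len(ctx) != self.order or abs(dist.sum() - 1.0) > 1e-9:
                raise ValidationError(f"bad conditional for context {ctx!r}")
        if abs(self.marginal.sum() - 1.0) > 1e-9:
            raise ValidationError("marginal does not sum to 1")


def fit_background(seqs: Iterable[str] | Mapping[str, str], order: int = 0,
                   pseudocount: float = 0.1,
                   add_revcomp: bool = False) -> MarkovBackground:
    """Estimate an order-k Markov background from sequences.

    Counts transitions over the literal text of the input (plus the
    reverse complement when ``add_revcomp``); ``pseudocount`` is added per
    (context, base) cell.  Positions containing non-ACGT characters are
    skipped.
    """
    if order < 0:
        raise ValidationError("order must be >= 0")
    if isinstance(seqs, Mapping):
        seqs = list(seqs.values())
    texts = [s.upper() for s in seqs]
    if add_revcomp:
        texts += [revcomp(s) for s in texts]
    counts: dict[str, np.ndarray] = {}
    mono = np.zeros(4)
    for text in texts:
        for i, ch in enumerate(text):
            bi = _BASE_INDEX.get(ch)
            if bi is None:
                continue
            mono[bi] += 1
            if i < order:
                continue
            ctx = text[i - order:i]
            if any(c not in _BASE_INDEX for c in ctx):
                continue
            counts.setdefault(ctx, np.zeros(4))[bi] += 1
    conditionals = {}
    for ctx in ("".join(t) for t in product(BASES, repeat=order)):
        c = counts.get(ctx, np.zeros(4)) + pseudocount
        if c.sum() == 0:
            c = np.ones(4)
        conditionals[ctx] = c / c.sum()
    marg = mono + pseudocount
    if marg.sum() == 0:
        marg = np.ones(4)
    return MarkovBackground(order, conditionals, marg / marg.sum(), pseudocount)


def uniform_background(order: int = 0) -> MarkovBackground:
    cond = {"".join(t): np.full(4, 0.25)
            for t in product(BASES, repeat=order)}
    return MarkovBackground(order, cond, np.full(4, 0.25), 0.0)


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """L x 4 probability matrix (rows over A, C, G, T)."""

    probs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValidationError("PWM must be L x 4")
        if np.any(self.probs < 0) or np.any(np.abs(self.probs.sum(axis=1) - 1) > 1e-9):
            raise ValidationError("PWM rows must be distributions")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.probs[::-1, ::-1].copy(), self.label + "_rc")


@dataclass
class MotifHit:
    """One motif occurrence on a scanned sequence."""

    seq_id: str
    position: int            # 0-based start on the forward sequence
    strand: str
    score: float             # log-odds, bits (lattice-quantized for PWM hits)
    p: float


_IMPOSSIBLE = np.int64(-(1 << 40))


def _quantized_scores(pwm: Pwm, bg: MarkovBackground) -> np.ndarray:
    """Integer lattice units of log2(pwm / marginal); impossible cells sentineled."""
    with np.errstate(divide="ignore"):
        bits = np.log2(pwm.probs / bg.marginal[None, :])
    q = np.where(np.isneginf(bits), _IMPOSSIBLE,
                 np.rint(bits / LATTICE).astype(np.int64))
    return q


def score_distribution(pwm: Pwm, bg: MarkovBackground
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact lattice distribution of scores of random background words.

    Returns ``(support_offset_sf, probs_sf, qmin)`` where entry ``t`` of
    the survival array is P(score >= qmin + t); words containing a
    zero-probability PWM cell carry score -inf and are excluded from the
    finite support (they can never reach a finite threshold).
    """
    q = _quantized_scores(pwm, bg)
    finite = q != _IMPOSSIBLE
    qmin = int(np.where(finite, q, 0).min(initial=0))
    # per-position finite score range
    mins = [int(q[i][finite[i]].min()) if finite[i].any() else 0
            for i in range(len(pwm))]
    maxs = [int(q[i][finite[i]].max()) if finite[i].any() else 0
            for i in range(len(pwm))]
    span = sum(mx - mn for mn, mx in zip(mins, maxs))
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    filled = 0
    for i in range(len(pwm)):
        new = np.zeros(span + 1)
        width = filled + 1
        for b in range(4):
            if not finite[i, b]:
                continue                     # -inf words drop out of the finite mass
            shift = q[i, b] - mins[i]
            new[shift:shift + width] += dist[:width] * bg.marginal[b]
        dist = new
        filled += maxs[i] - mins[i]
    sf = dist[::-1].cumsum()[::-1]
    return sf, dist, sum(mins)


def scan_pwm(seqs: Mapping[str, str], pwm: Pwm, bg: MarkovBackground,
             p_thresh: float = 0.01) -> list[MotifHit]:
    """Scan both strands for PWM hits with exact-distribution p < p_thresh."""
    if p_thresh <= 0:
        return []
    hits: list[MotifHit] = []
    variants = [("+", pwm), ("-", pwm.reverse_complement())]
    tables = []
    for strand, variant in variants:
        q = _quantized_scores(variant, bg)
        sf, _, qlow = score_distribution(variant, bg)
        tables.append((strand, q, sf, qlow))
    L = len(pwm)
    for seq_id, seq in seqs.items():
        codes = np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()],
                         dtype=np.int64)
        if codes.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = np.all(windows >= 0, axis=1)
        for strand, q, sf, qlow in tables:
            scores = np.full(windows.shape[0], _IMPOSSIBLE)
            v = np.flatnonzero(valid)
            if v.size:
                per_cell = q[np.arange(L)[None, :], windows[v]]
                ok = np.all(per_cell != _IMPOSSIBLE, axis=1)
                scores[v[ok]] = per_cell[ok].sum(axis=1)
            for pos in np.flatnonzero(scores != _IMPOSSIBLE):
                t = int(scores[pos]) - qlow
                p = float(sf[t]) if 0 <= t < sf.size else (1.0 if t < 0 else 0.0)
                if p < p_thresh:
                    hits.append(MotifHit(seq_id, int(pos), strand,
                                         float(scores[pos]) * LATTICE, p))
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# IUPAC consensus scanning
# ---------------------------------------------------------------------------

def consensus_match_prob(consensus: str, bg: MarkovBackground) -> float:
    """P(random background word matches): product of admitted-base marginals."""
    p = 1.0
    for code in consensus.upper():
        if code not in IUPAC_CODES:
            raise ValidationError(f"invalid IUPAC code {code!r}")
        p *= sum(bg.marginal[_BASE_INDEX[b]] for b in IUPAC_CODES[code])
    return p


def _consensus_matches(seq: str, consensus: str) -> list[int]:
    allowed = [set(IUPAC_CODES[c]) for c in consensus.upper()]
    L = len(allowed)
    out = []
    for i in range(len(seq) - L + 1):
        if all(seq[i + j] in allowed[j] for j in range(L)):
            out.append(i)
    return out


def scan_consensus(seqs: Mapping[str, str], consensus: str,
                   bg: MarkovBackground | None = None,
                   p_thresh: float = 0.001) -> list[MotifHit]:
    """Exact IUPAC-consensus matches on both strands, gated by match probability.

    A strand's matches are reported only if the probability that a random
    background word matches that strand's pattern is below ``p_thresh``.
    The hit score is -log2 of that probability.
    """
    bg = bg or uniform_background()
    for code in consensus.upper():
        if code not in IUPAC_CODES:
            raise ValidationError(f"invalid IUPAC code {code!r}")
    hits: list[MotifHit] = []
    patterns = [("+", consensus.upper()),
                ("-", _revcomp_consensus(consensus.upper()))]
    for strand, pattern in patterns:
        p = consensus_match_prob(pattern, bg)
        if p >= p_thresh:
            continue
        score = float(-np.log2(p))
        for seq_id, seq in seqs.items():
            for pos in _consensus_matches(seq.upper(), pattern):
                hits.append(MotifHit(seq_id, pos, strand, score, p))
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def _revcomp_consensus(consensus: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus))


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

def promoter_windows(genes: list[GeneModel], flank: int,
                     genome_seqs: Mapping[str, str] | str | Path
                     ) -> dict[str, str]:
    """Strand-oriented promoter windows (TSS +/- flank) from genome sequence.

    Minus-strand windows are reverse-complemented so position 0 is the
    upstream edge in the gene's reading direction.  Windows are truncated
    at chromosome edges.
    """
    if not isinstance(genome_seqs, Mapping):
        genome_seqs = {rec.id: str(rec.seq)
                       for rec in SeqIO.parse(str(genome_seqs), "fasta")}
    out: dict[str, str] = {}
    for g in genes:
        if g.chrom not in genome_seqs:
            raise ValidationError(f"gene {g.id} on missing chromosome {g.chrom}")
        chrom_seq = genome_seqs[g.chrom]
        lo = max(0, g.tss - flank)
        hi = min(len(chrom_seq), g.tss + flank + 1)
        window = chrom_seq[lo:hi].upper()
        out[g.id] = window if g.strand == "+" else revcomp(window)
    return out
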