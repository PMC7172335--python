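"""Per-probe significance and the per-array neighborhood-model peak caller.

The caller works on per-probe p-values.  Probe *significance* follows the
neighborhood rule: a probe is significant iff the average of its p-value
with at least one adjacent probe within ``neighbor_max_gap`` (1 kb) is
below ``probe_alpha``.  Peaks are maximal runs of significant probes in
which consecutive significant probes are at most ``peak_probe_gap``
(300 bp) apart, retained when the run contains at least ``min_sig_probes``
(4) significant probes.

The p-value construction itself is decoupled from the caller:
:func:`probe_significance` supplies a robust empirical-null upper-tail
p-value per probe, but externally computed p-values can be passed to
:func:`call_peaks` directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .core_io import Interval, ProbeTrack, ValidationError


class DegenerateNullError(ValueError):
    """The empirical null has zero spread; supply p-values directly."""


@dataclass
class ProbeSignificance:
    """Per-probe upper-tail p-values on the track's probe grid."""

    positions: dict[str, np.ndarray]   # chrom -> probe starts (bp, ascending)
    p: dict[str, np.ndarray]           # chrom -> p-values in [0, 1]
    probe_len: int = 50

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pv = self.p[chrom]
            if pv.shape != pos.shape:
                raise ValidationError(f"{chrom}: |p| != |positions|")
            if pv.size and (np.nanmin(pv) < 0 or np.nanmax(pv) > 1):
                raise ValidationError(f"{chrom}: p-values outside [0, 1]")
            if pos.size > 1 and np.any(np.diff(pos) <= 0):
                raise ValidationError(f"{chrom}: positions not strictly increasing")


@dataclass
class Peak:
    """A called peak: the significant-probe footprint and its score."""

    interval: Interval
    n_sig: int
    score: float                     # -log10(mean p over significant probes)


def probe_significance(track: ProbeTrack, condition: str | None = None) -> ProbeSignificance:
    """Robust one-sided upper-tail p-values against the array's empirical null.

    Genome-wide per sample: ``z_i = (x_i - median(x)) / (1.4826 * MAD(x))``
    and ``p_i = 1 - Phi(z_i)``, i.e. the array's own intensity distribution
    (median/MAD, robust to the enriched minority of probes) serves as the
    null for each probe.
    """
    if track.n_probes < 10:
        raise ValidationError("need >= 10 probes for a stable empirical null")
    if condition is None:
        condition = track.conditions()[0]
    values = {c: track.condition_values(c, condition) for c in track.chroms}
    pooled = np.concatenate([values[c] for c in track.chroms])
    med = np.median(pooled)
    mad = np.median(np.abs(pooled - med))
    if mad == 0:
        raise DegenerateNullError(
            "MAD of the intensity distribution is zero; "
            "supply per-probe p-values directly")
    scale = 1.4826 * mad
    p = {c: stats.norm.sf((values[c] - med) / scale) for c in track.chroms}
    return ProbeSignificance(
        positions={c: track.positions(c) for c in track.chroms},
        p=p, probe_len=track.probe_len)


def significant_probes(positions: np.ndarray, p: np.ndarray,
                       cfg: PipelineConfig) -> np.ndarray:
    """Boolean mask of probes passing the neighborhood rule.

    Probe i is significant iff some adjacent probe j within
    ``neighbor_max_gap`` has ``mean(p_i, p_j) < probe_alpha`` (strict).
    """
    n = positions.size
    sig = np.zeros(n, dtype=bool)
    if n == 0:
        return sig
    if n == 1:
        return sig         # no neighbor, cannot satisfy the rule
    gap = np.diff(positions)
    pair_mean = 0.5 * (p[:-1] + p[1:])
    ok = (gap <= cfg.neighbor_max_gap) & (pair_mean < cfg.probe_alpha)
    sig[:-1] |= ok
    sig[1:] |= ok
    return sig


def call_peaks(sig: ProbeSignificance, cfg: PipelineConfig | None = None) -> list[Peak]:
    """Assemble peaks from per-probe p-values under the neighborhood model.

    Returns peaks spanning [first significant probe start, last significant
    probe start + probe length), with ``n_sig`` the number of significant
    probes in the run and score = -log10 of their mean p-value.
    """
    cfg = cfg or PipelineConfig()
    peaks: list[Peak] = []
    for chrom in sig.positions:
        pos, p = sig.positions[chrom], sig.p[chrom]
        mask = significant_probes(pos, p, cfg)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        # split runs where consecutive significant probes are > gap apart
        breaks = np.flatnonzero(np.diff(pos[idx]) > cfg.peak_probe_gap)
        for run in np.split(idx, breaks + 1):
            if run.size < cfg.min_sig_probes:
                continue
            mean_p = float(np.mean(p[run]))
            score = -math.log10(mean_p) if mean_p > 0 else math.inf
            peaks.append(Peak(
                interval=Interval(chrom, int(pos[run[0]]),
                                  int(pos[run[-1]]) + sig.probe_len,
                                  name=f"peak_{len(peaks) + 1}"),
                n_sig=int(run.size),
                score=score))
    return peaks


def peaks_to_bed_score(score: float) -> int:
    """BED score column: round(1000 * min(1, score / 10))."""
    return int(round(1000 * min(1.0, score / 10.0)))
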