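"""Synthetic genomes, annotations, probe tracks, and promoter sequences.

Everything the analysis stages consume can be generated here with recorded
ground truth: a regular multi-chromosome probe grid with Gaussian
background noise, boxcar transcription-factor peaks, broad H3K27me3-like
domains that are multiplicatively depleted in the mutant condition,
TSS-anchored Pol II tracks in two condition-dependent regimes, divergently
paired genes, and promoter sequences with planted consensus motifs.  All
generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (Domain, GeneModel, GenomeIndex, Interval, IntervalSet,
                      ProbeTrack)


class ConfigurationError(ValueError):
    """Requested simulation does not fit in the simulated genome."""


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    # planted factor peaks, keyed by factor name
    peaks: dict[str, IntervalSet] = field(default_factory=dict)
    # planted domains with the mutant depletion multiplier applied to each
    domains: list[Domain] = field(default_factory=list)
    domain_depletion: float = 1.0
    # (minus_gene_id, plus_gene_id, tss_gap) for planted divergent pairs
    dpg_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    # per-gene Pol II regime label (1 or 2)
    polII_regime: dict[str, int] = field(default_factory=dict)
    # per-promoter motif plants: seq id -> (0-based position, strand)
    motif_plants: dict[str, tuple[int, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(n_chrom: int = 2,
                        chrom_len: int = 300_000,
                        n_genes: int = 60,
                        dpg_fraction: float = 0.3,
                        seed: int = 0,
                        gene_len_range: tuple[int, int] = (2000, 5000),
                        dpg_gap_range: tuple[int, int] = (50, 1000),
                        ) -> tuple[GenomeIndex, list[GeneModel], SimTruth]:
    """Place non-overlapping genes on both strands; pair a fraction head-to-head.

    A ``dpg_fraction`` of genes is arranged as divergent pairs (minus gene
    left, plus gene right, TSS gap uniform in ``dpg_gap_range``).  Unpaired
    genes are separated by more than the 1 kb divergent-pair rule so the
    planted pairs are exactly the discoverable ones.
    """
    rng = np.random.default_rng(seed)
    n_pairs = int(round(n_genes * dpg_fraction / 2))
    n_singles = n_genes - 2 * n_pairs
    units: list[str] = ["pair"] * n_pairs + ["single"] * n_singles
    rng.shuffle(units)

    genome = GenomeIndex({f"chr{i + 1}": chrom_len for i in range(n_chrom)})
    genes: list[GeneModel] = []
    truth = SimTruth()
    gid = 0
    # round-robin units over chromosomes, packed left to right
    per_chrom: list[list[str]] = [[] for _ in range(n_chrom)]
    for i, u in enumerate(units):
        per_chrom[i % n_chrom].append(u)

    for ci, chrom_units in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(1000, 3000))
        for unit in chrom_units:
            if unit == "pair":
                len_minus = int(rng.integers(*gene_len_range))
                len_plus = int(rng.integers(*gene_len_range))
                gap = int(rng.integers(dpg_gap_range[0], dpg_gap_range[1] + 1))
                minus = _make_gene(rng, f"g{gid:04d}", chrom, "-",
                                   cursor, cursor + len_minus)
                gid += 1
                plus_start = minus.tss + gap     # TSS+ = TSS- + gap
                plus = _make_gene(rng, f"g{gid:04d}", chrom, "+",
                                  plus_start, plus_start + len_plus)
                gid += 1
                genes += [minus, plus]
                truth.dpg_pairs.append((minus.id, plus.id, gap))
                cursor = plus.txEnd + int(rng.integers(1500, 4000))
            else:
                length = int(rng.integers(*gene_len_range))
                strand = "+" if rng.random() < 0.5 else "-"
                g = _make_gene(rng, f"g{gid:04d}", chrom, strand,
                               cursor, cursor + length)
                gid += 1
                genes.append(g)
                # > 1 kb to the next unit so no accidental divergent pair
                cursor = g.txEnd + int(rng.integers(1500, 4000))
        if cursor > chrom_len:
            raise ConfigurationError(
                f"{n_genes} genes do not fit in {n_chrom} x {chrom_len} bp")
    return genome, genes, truth


def _make_gene(rng: np.random.Generator, gid: str, chrom: str, strand: str,
               start: int, end: int) -> GeneModel:
    """Gene whose exons start at txStart and end at txEnd (1 or 2 exons)."""
    length = end - start
    if length > 1600 and rng.random() < 0.6:
        e1 = int(rng.integers(300, length // 2))
        intron = int(rng.integers(100, min(500, length - e1 - 300)))
        exons = [Interval(chrom, start, start + e1),
                 Interval(chrom, start + e1 + intron, end)]
    else:
        exons = [Interval(chrom, start, end)]
    return GeneModel(gid, chrom, strand, start, end, exons)


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------

def simulate_chip_tracks(genome: GenomeIndex,
                         genes: list[GeneModel],
                         truth: SimTruth,
                         spacing: int = 33,
                         peak_snr: float = 4.0,
                         domain_depletion: float = 0.5,
                         noise_sd: float = 0.3,
                         seed: int = 0,
                         *,
                         probe_len: int = 50,
                         n_reps: int = 2,
                         n_peaks: int | None = None,
                         peak_width: int = 250,
                         domain_plateau: float = 2.0,
                         n_domains: int | None = None,
                         domain_len_range: tuple[int, int] = (8000, 20_000),
                         spike_height: float = 1.0,
                         body_height: float = 0.4,
                         regime1_scale: float = 0.5,
                         regime2_spike_scale: float = 1.5,
                         body_scale: float = 0.5,
                         ) -> dict[tuple[str, str], ProbeTrack]:
    """Simulate ChIP-chip tracks for three marks in two conditions.

    Marks: ``factor`` (boxcar peaks of height ``peak_snr * noise_sd``, in
    the control only — the mutant lacks the factor), ``h3k27`` (broad
    plateaus of height ``domain_plateau`` multiplied by
    ``domain_depletion`` in the mutant), and ``polii`` (per-gene paused
    spike at TSS-30..TSS+300 plus gene-body plateau from TSS+1000, with the
    mutant following each gene's planted regime: regime 1 scales spike and
    body down together; regime 2 raises the spike and lowers the body).

    Returns ``{(mark, condition): ProbeTrack}`` and records peaks, domains,
    and regimes in ``truth``.
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be > 0")
    if not (0 < domain_depletion <= 1):
        raise ConfigurationError("domain_depletion must be in (0, 1]")
    if peak_snr < 0:
        raise ConfigurationError("peak_snr must be >= 0")
    if any(spacing > genome[c] for c in genome.chroms):
        raise ConfigurationError("spacing exceeds a chromosome length")
    rng = np.random.default_rng(seed)
    total_bp = sum(genome.entries.values())
    if n_peaks is None:
        # ~1 peak per 12 kb, the binding-site density of the factor studied
        n_peaks = max(1, total_bp // 12_000)
    if n_domains is None:
        n_domains = max(1, total_bp // 60_000)

    grid = {c: np.arange(0, genome[c] - probe_len + 1, spacing, dtype=np.int64)
            for c in genome.chroms}

    truth.peaks["factor"] = _place_intervals(
        rng, genome, n_peaks, (peak_width, peak_width + 1), min_sep=2000,
        name_prefix="truepeak")
    truth.domains = [Domain(iv, "PcG") for iv in _place_intervals(
        rng, genome, n_domains, domain_len_range, min_sep=5000,
        name_prefix="domain")]
    truth.domain_depletion = domain_depletion
    regime_draws = rng.random(len(genes))       # drawn unconditionally: keeps
    for g, d in zip(genes, regime_draws):       # the stream seed-reproducible
        truth.polII_regime.setdefault(g.id, 1 if d < 0.5 else 2)

    # noiseless mean signal per (mark, condition)
    means: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for mark in ("factor", "h3k27", "polii"):
        for cond in ("control", "mutant"):
            means[(mark, cond)] = {c: np.zeros(grid[c].size) for c in genome.chroms}

    peak_height = peak_snr * noise_sd
    for iv in truth.peaks["factor"]:
        _add_boxcar(means[("factor", "control")][iv.chrom], grid[iv.chrom],
                    iv.start, iv.end, peak_height)
    for dom in truth.domains:
        iv = dom.interval
        _add_boxcar(means[("h3k27", "control")][iv.chrom], grid[iv.chrom],
                    iv.start, iv.end, domain_plateau)
        _add_boxcar(means[("h3k27", "mutant")][iv.chrom], grid[iv.chrom],
                    iv.start, iv.end, domain_plateau * domain_depletion)
    for g in genes:
        regime = truth.polII_regime[g.id]
        if regime == 1:
            mut_spike = spike_height * regime1_scale
            mut_body = body_height * regime1_scale
        else:
            mut_spike = spike_height * regime2_spike_scale
            mut_body = body_height * body_scale
        for cond, spike, body in (("control", spike_height, body_height),
                                  ("mutant", mut_spike, mut_body)):
            arr, pos = means[("polii", cond)][g.chrom], grid[g.chrom]
            lo, hi = g.oriented_interval(-30, 300)
            _add_boxcar(arr, pos, lo, hi + 1, spike)
            if g.length > 1000:
                lo, hi = g.oriented_interval(1000, g.length - 1)
                _add_boxcar(arr, pos, lo, hi + 1, body)

    tracks: dict[tuple[str, str], ProbeTrack] = {}
    for mark in ("factor", "h3k27", "polii"):
        for cond in ("control", "mutant"):
            data = {}
            for chrom in genome.chroms:
                mu = means[(mark, cond)][chrom]
                noise = rng.normal(0.0, noise_sd, size=(mu.size, n_reps))
                data[chrom] = (grid[chrom], mu[:, None] + noise)
            tracks[(mark, cond)] = ProbeTrack(
                probe_len, [(cond, r + 1) for r in range(n_reps)], data)
    return tracks


def _place_intervals(rng: np.random.Generator, genome: GenomeIndex, n: int,
                     len_range: tuple[int, int], min_sep: int,
                     name_prefix: str) -> IntervalSet:
    """Place n intervals uniformly, keeping them >= min_sep apart."""
    chroms = genome.chroms
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[Interval] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ConfigurationError(f"cannot place {n} intervals of "
                                     f"{len_range} bp with {min_sep} bp separation")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(*len_range))
        if genome[chrom] <= length:
            continue
        start = int(rng.integers(0, genome[chrom] - length))
        end = start + length
        if any(start - min_sep < e and s < end + min_sep
               for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        out.append(Interval(chrom, start, end, f"{name_prefix}_{len(out)}"))
    return IntervalSet(out)


def _add_boxcar(arr: np.ndarray, positions: np.ndarray,
                start: int, end: int, height: float) -> None:
    """Add ``height`` to probes whose start lies in [start, end)."""
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    arr[lo:hi] += height


# ---------------------------------------------------------------------------
# promoter sequences
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_sequences(genes: list[GeneModel],
                       motif: str = "YAACKG",
                       plant_rate: float = 0.5,
                       gc: float = 0.4,
                       seed: int = 0,
                       flank: int = 500,
                       truth: SimTruth | None = None,
                       ) -> tuple[dict[str, str], dict[str, tuple[int, str]]]:
    """Promoter windows (TSS +/- flank) of i.i.d. background with planted motifs.

    A ``plant_rate`` fraction of windows receives one exact-consensus
    instance of ``motif`` at a recorded position and strand (a minus-strand
    plant inserts the reverse complement).  Returns ``(sequences, plants)``
    where sequences map gene id to a window of length ``2 * flank + 1``.
    """
    if not (0 <= plant_rate <= 1):
        raise ConfigurationError("plant_rate must be in [0, 1]")
    window_len = 2 * flank + 1
    if len(motif) > window_len:
        raise ConfigurationError("motif longer than the promoter window")
    for code in motif.upper():
        if code not in _IUPAC:
            raise ConfigurationError(f"invalid IUPAC code {code!r} in motif")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, str] = {}
    plants: dict[str, tuple[int, str]] = {}
    for g in genes:
        window = rng.choice(4, size=window_len, p=probs)
        seq = list(bases[window])
        if rng.random() < plant_rate:
            word = "".join(_IUPAC[c][int(rng.integers(len(_IUPAC[c])))]
                           for c in motif.upper())
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(0, window_len - len(motif) + 1))
            insert = word if strand == "+" else revcomp(word)
            seq[pos:pos + len(motif)] = list(insert)
            plants[g.id] = (pos, strand)
        seqs[g.id] = "".join(seq)
    if truth is not None:
        truth.motif_plants = dict(plants)
    return seqs, plants


def write_fasta(seqs: dict[str, str], path) -> None:
    """Write sequences as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
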