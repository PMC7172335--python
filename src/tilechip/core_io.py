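"""Domain types, coordinate conventions, and format I/O.

Internal coordinates are everywhere 0-based half-open (BED-like).  GFF and
wiggle use 1-based conventions and are converted exactly once, at the
read/write boundary.  Probe identity is (chrom, start); all distance rules
downstream measure from probe starts.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not parse under the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome name -> length (bp)."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if not name:
                raise ValidationError("empty chromosome name")
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    @property
    def chroms(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def expanded(self, slack: int, genome: GenomeIndex | None = None) -> "Interval":
        """Symmetric expansion by ``slack`` bp, clipped at chromosome bounds."""
        if slack < 0:
            raise ValidationError("slack must be >= 0")
        start = max(0, self.start - slack)
        end = self.end + slack
        if genome is not None and self.chrom in genome:
            end = min(end, genome[self.chrom])
        return Interval(self.chrom, start, end, self.name, self.score, self.strand)

    def overlaps(self, other: "Interval") -> bool:
        """>= 1 bp overlap; the universal overlap predicate."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


class IntervalSet:
    """Intervals grouped by chromosome, sorted by (start, end).

    Per-chromosome start/end arrays are cached for vectorised overlap
    queries (the permutation-enrichment inner loop).
    """

    def __init__(self, intervals: Iterable[Interval] = ()):
        by_chrom: dict[str, list[Interval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        self._by_chrom = by_chrom
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return sorted(self, key=_iv_key) == sorted(other, key=_iv_key)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def on(self, chrom: str) -> list[Interval]:
        return self._by_chrom.get(chrom, [])

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome, sorted by start."""
        if chrom not in self._arrays:
            ivs = self.on(chrom)
            self._arrays[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        return self._arrays[chrom]


def _iv_key(iv: Interval):
    return (iv.chrom, iv.start, iv.end, iv.name or "", iv.score or 0.0,
            iv.strand or "")


@dataclass
class GeneModel:
    """Strand-aware gene: transcript span plus merged exons.

    TSS is txStart on + and txEnd-1 on -; TES is the opposite end.
    """

    id: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be + or -")
        if not (0 <= self.txStart < self.txEnd):
            raise ValidationError(f"gene {self.id}: invalid transcript span")
        if not self.exons:
            self.exons = [Interval(self.chrom, self.txStart, self.txEnd)]
        self.exons.sort(key=lambda e: (e.start, e.end))
        prev_end = self.txStart
        for ex in self.exons:
            if ex.start < self.txStart or ex.end > self.txEnd:
                raise ValidationError(f"gene {self.id}: exon outside transcript span")
            if ex.start < prev_end and ex is not self.exons[0]:
                raise ValidationError(f"gene {self.id}: overlapping exons")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.txStart if self.strand == "+" else self.txEnd - 1

    @property
    def tes(self) -> int:
        return self.txEnd - 1 if self.strand == "+" else self.txStart

    @property
    def length(self) -> int:
        return self.txEnd - self.txStart

    def oriented_interval(self, rel_start: int, rel_end: int) -> tuple[int, int]:
        """Map a TSS-relative closed interval to genomic [lo, hi] (closed).

        ``rel_start``/``rel_end`` are bp downstream of the TSS (negative =
        upstream), in the gene's reading direction.
        """
        if self.strand == "+":
            return self.tss + rel_start, self.tss + rel_end
        return self.tss - rel_end, self.tss - rel_start


DOMAIN_CLASSES = ("PcG", "active", "null", "HP1")


@dataclass(frozen=True)
class Domain:
    """A chromatin domain with its class label."""

    interval: Interval
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in DOMAIN_CLASSES:
            raise ValidationError(f"unknown domain class {self.cls!r}")


class ProbeTrack:
    """Per-chromosome probe positions with per-sample intensities.

    ``samples`` are (condition, replicate) pairs; the intensity matrix has
    one row per probe and one column per sample.  Positions are probe
    starts, strictly increasing within each chromosome; probe length is
    constant per track.
    """

    def __init__(self, probe_len: int,
                 samples: Sequence[tuple[str, int]],
                 data: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        if probe_len < 1:
            raise ValidationError("probe_len must be >= 1")
        self.probe_len = int(probe_len)
        self.samples = [tuple(s) for s in samples]
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, vals) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            vals = np.atleast_2d(np.asarray(vals, dtype=np.float64))
            if vals.shape[0] != pos.shape[0]:
                vals = vals.T
            if vals.shape != (pos.shape[0], len(self.samples)):
                raise ValidationError(
                    f"{chrom}: intensity matrix shape {vals.shape} does not match "
                    f"{pos.shape[0]} probes x {len(self.samples)} samples")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValidationError(f"{chrom}: probe positions not strictly increasing")
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"{chrom}: non-finite intensities")
            self._data[chrom] = (pos, vals)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def positions(self, chrom: str) -> np.ndarray:
        return self._data[chrom][0]

    def values(self, chrom: str) -> np.ndarray:
        """(n_probes, n_samples) intensity matrix."""
        return self._data[chrom][1]

    @property
    def n_probes(self) -> int:
        return sum(p.size for p, _ in self._data.values())

    def conditions(self) -> list[str]:
        out: list[str] = []
        for cond, _ in self.samples:
            if cond not in out:
                out.append(cond)
        return out

    def sample_index(self, condition: str, replicate: int) -> int:
        return self.samples.index((condition, replicate))

    def condition_values(self, chrom: str, condition: str) -> np.ndarray:
        """One value per probe for a condition: mean across its replicates."""
        cols = [i for i, (c, _) in enumerate(self.samples) if c == condition]
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return self.values(chrom)[:, cols].mean(axis=1)

    def single_sample(self, index: int = 0) -> "ProbeTrack":
        return ProbeTrack(
            self.probe_len, [self.samples[index]],
            {c: (p, v[:, [index]]) for c, (p, v) in self._data.items()})


# ---------------------------------------------------------------------------
# overlap predicate
# ---------------------------------------------------------------------------

def overlaps_with_slack(a: Interval, b: Interval, slack: int = 0) -> bool:
    """True iff ``a`` overlaps ``b`` expanded symmetrically by ``slack``.

    slack = 0 is the plain >= 1 bp overlap predicate; "within +/- N bp"
    rules use slack = N.
    """
    return a.overlaps(b.expanded(slack)) if slack else a.overlaps(b)


# ---------------------------------------------------------------------------
# BED / interval GFF
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, format: str = "BED") -> IntervalSet:
    """Read an interval file.

    BED is 0-based half-open; GFF-intervals are 1-based inclusive and
    converted on read.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF", "GFF-INTERVALS"):
        raise ValueError(f"unknown interval format {format!r}")
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    iv = _parse_bed_fields(fields)
                else:
                    iv = _parse_gff_interval_fields(fields)
            except ValidationError:
                raise ValidationError(f"{path}:{lineno}: invalid interval: {line!r}")
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return IntervalSet(intervals)


def _parse_bed_fields(fields: list[str]) -> Interval:
    if len(fields) < 3:
        raise FormatError("fewer than 3 BED columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
    strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
    return Interval(chrom, start, end, name, score, strand)


def _parse_gff_interval_fields(fields: list[str]) -> Interval:
    if len(fields) < 5:
        raise FormatError("fewer than 5 GFF columns")
    chrom = fields[0]
    start = int(fields[3]) - 1          # 1-based inclusive -> 0-based half-open
    end = int(fields[4])
    score = None
    if len(fields) > 5 and fields[5] not in (".", ""):
        score = float(fields[5])
    strand = None
    if len(fields) > 6 and fields[6] in ("+", "-"):
        strand = fields[6]
    name = None
    if len(fields) > 8:
        attrs = _parse_gff_attrs(fields[8])
        name = attrs.get("ID") or attrs.get("Name")
    return Interval(chrom, start, end, name, score, strand)


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED6 ('.' for absent name/score/strand)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, ".10g")
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                iv.name if iv.name is not None else ".",
                score,
                iv.strand if iv.strand is not None else ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _parse_gff_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene / mRNA / exon features).

    Exons are merged per gene; each gene id yields one GeneModel.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    exons: list[tuple[str, Interval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_text = fields[:9]
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gff_attrs(attr_text)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                if strand not in ("+", "-"):
                    raise ValidationError(f"{path}:{lineno}: gene {gid} without strand")
                genes[gid] = dict(chrom=chrom, strand=strand, start=start0, end=end0)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid and parent:
                    mrna_parent[mid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    continue
                exons.append((parent, Interval(chrom, start0, end0)))
    per_gene_exons: dict[str, list[Interval]] = {gid: [] for gid in genes}
    for parent, iv in exons:
        gid = mrna_parent.get(parent, parent)
        if gid in per_gene_exons:
            per_gene_exons[gid].append(iv)
    out = []
    for gid, g in genes.items():
        merged = merge_intervals(per_gene_exons[gid])
        for ex in merged:
            if ex.start < g["start"] or ex.end > g["end"]:
                raise ValidationError(f"gene {gid}: exon outside transcript span")
        out.append(GeneModel(gid, g["chrom"], g["strand"], g["start"], g["end"], merged))
    return out


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended intervals (per chromosome)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.chrom, "tilechip", "gene", str(g.txStart + 1), str(g.txEnd),
                ".", g.strand, ".", f"ID={g.id}"]) + "\n")
            for i, ex in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.chrom, "tilechip", "exon", str(ex.start + 1), str(ex.end),
                    ".", g.strand, ".", f"ID={g.id}.e{i};Parent={g.id}"]) + "\n")


# ---------------------------------------------------------------------------
# signal tracks: wiggle and probe-GFF
# ---------------------------------------------------------------------------

def read_signal(path: str | Path, format: str = "wiggle",
                probe_len: int | None = None,
                sample: tuple[str, int] = ("signal", 1)) -> ProbeTrack:
    """Read a single-sample signal track (UCSC wiggle or probe-GFF)."""
    fmt = format.lower()
    if fmt in ("wiggle", "wig"):
        return _read_wiggle(path, sample)
    if fmt in ("probe-gff", "gff"):
        return _read_probe_gff(path, probe_len, sample)
    raise ValueError(f"unknown signal format {format!r}")


def _read_wiggle(path: str | Path, sample: tuple[str, int]) -> ProbeTrack:
    data: dict[str, tuple[list[int], list[float]]] = {}
    mode = None          # ("variable", chrom) or ("fixed", chrom, next_pos, step)
    span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                if "chrom" not in kv:
                    raise FormatError(f"{path}:{lineno}: variableStep without chrom")
                mode = ("variable", kv["chrom"])
                span = int(kv.get("span", 1))
                data.setdefault(kv["chrom"], ([], []))
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                try:
                    mode = ["fixed", kv["chrom"], int(kv["start"]) - 1, int(kv["step"])]
                except KeyError as exc:
                    raise FormatError(f"{path}:{lineno}: fixedStep missing {exc}") from exc
                span = int(kv.get("span", 1))
                data.setdefault(kv["chrom"], ([], []))
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before any step declaration")
            parts = line.split()
            try:
                if mode[0] == "variable":
                    if len(parts) != 2:
                        raise FormatError("expected 'position value'")
                    pos, val = int(parts[0]) - 1, float(parts[1])   # wiggle is 1-based
                    chrom = mode[1]
                else:
                    if len(parts) != 1:
                        raise FormatError("expected a lone value")
                    val = float(parts[0])
                    chrom, pos = mode[1], mode[2]
                    mode[2] += mode[3]
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            positions, values = data[chrom]
            if positions and pos <= positions[-1]:
                raise ValidationError(
                    f"{path}:{lineno}: non-monotone position {pos + 1} on {chrom}")
            positions.append(pos)
            values.append(val)
    return ProbeTrack(span, [sample], {
        c: (np.array(p, dtype=np.int64), np.array(v)[:, None])
        for c, (p, v) in data.items()})


def _read_probe_gff(path: str | Path, probe_len: int | None,
                    sample: tuple[str, int]) -> ProbeTrack:
    data: dict[str, tuple[list[int], list[float]]] = {}
    seen_len: int | None = probe_len
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 GFF columns")
            chrom = fields[0]
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
                val = float(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: missing value token") from exc
            if seen_len is None:
                seen_len = end - start
            positions, values = data.setdefault(chrom, ([], []))
            if positions and start <= positions[-1]:
                raise ValidationError(f"{path}:{lineno}: non-monotone position on {chrom}")
            positions.append(start)
            values.append(val)
    return ProbeTrack(seen_len or 1, [sample], {
        c: (np.array(p, dtype=np.int64), np.array(v)[:, None])
        for c, (p, v) in data.items()})


def write_signal(track: ProbeTrack, path: str | Path, sample_index: int = 0) -> None:
    """Write one sample of a track as UCSC variableStep wiggle (1-based)."""
    cond, rep = track.samples[sample_index]
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{cond}_{rep}"\n')
        for chrom in track.chroms:
            pos = track.positions(chrom)
            vals = track.values(chrom)[:, sample_index]
            if pos.size == 0:
                continue
            fh.write(f"variableStep chrom={chrom} span={track.probe_len}\n")
            buf = _io.StringIO()
            pd.DataFrame({"p": pos + 1, "v": vals}).to_csv(
                buf, sep="\t", header=False, index=False, float_format="%.10g")
            fh.write(buf.getvalue())
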