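"""Sequence and interval I/O with explicit coordinate conventions.

All coordinates are 0-based, half-open internally (BED native; GTF/GFF is
converted on read).  All internal sequence uses the RNA alphabet (U); FASTA
output can be switched back to DNA.  Windows are extracted 5'->3' on the
site's strand, i.e. minus-strand sites are reverse-complemented.
"""

from __future__ import annotations

import gzip
import io
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from intervaltree import IntervalTree

RNA_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

REGION_PRIORITY = {"CDS": 0, "3UTR": 1, "5UTR": 2, "other": 3, "NA": 4}


class FastaFormatError(ValueError):
    pass


class BedFormatError(ValueError):
    pass


class LookupErrorChrom(KeyError):
    pass


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U (the internal alphabet is RNA)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (A<->U, C<->G, N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSite:
    """A single-base site; ``position`` is 0-based on ``chrom``."""

    chrom: str
    position: int
    strand: str = "+"
    label: str = "unknown"
    region: str = "NA"

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PeakInterval:
    """Half-open interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end}")

    def overlaps(self, site: GenomicSite) -> bool:
        return site.chrom == self.chrom and self.start <= site.position < self.end


@dataclass
class SequenceWindow:
    """A fixed-length window around a candidate site.

    ``sequence`` is over {A,C,G,U} (plus 'N' when truncated at a contig end
    and padding was requested); ``center_index`` is the candidate position.
    """

    sequence: str
    label: int = 0
    site: GenomicSite | None = None
    name: str | None = None
    truncated: bool = False

    @property
    def center_index(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, rna_mode: bool = True) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}``; names cut at first whitespace.

    Sequences are uppercased; with ``rna_mode`` T is converted to U.
    'N' characters are retained (callers flag/exclude downstream).
    """
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].split() else None
                if not name:
                    raise FastaFormatError(f"empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"sequence before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    norm = normalize_rna if rna_mode else str.upper
    return {k: norm(v) for k, v in records.items()}


def write_fasta(path, records: Mapping[str, str], dna_mode: bool = False, width: int = 60):
    with _open_text(path, "wt") as fh:
        for name, seq in records.items():
            seq = to_dna(seq) if dna_mode else seq
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_window(
    sequence_store: Mapping[str, str],
    site: GenomicSite,
    flank: int = 20,
    drop_truncated: bool = False,
) -> SequenceWindow | None:
    """Extract the ``2*flank+1`` window centered on ``site``.

    Minus-strand sites are reverse-complemented so the window reads 5'->3'
    on the site's strand.  Windows running off an end are padded with 'N'
    and flagged ``truncated`` (or return None when ``drop_truncated``).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if site.chrom not in sequence_store:
        raise LookupErrorChrom(f"chromosome {site.chrom!r} absent from sequence store")
    seq = sequence_store[site.chrom]
    lo, hi = site.position - flank, site.position + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    truncated = left_pad > 0 or right_pad > 0
    if truncated and drop_truncated:
        return None
    window = "N" * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + "N" * right_pad
    if site.strand == "-":
        window = reverse_complement(window)
    return SequenceWindow(sequence=window, site=site, truncated=truncated,
                          label=1 if site.label == "positive" else 0)


def read_bed(path, promote_single_base: bool = True):
    """Read BED3+ as ``PeakInterval``s; single-base records (end-start==1)
    are promoted to ``GenomicSite`` when ``promote_single_base``."""
    out = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from e
            if start >= end:
                raise BedFormatError(f"line {lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            if promote_single_base and end - start == 1:
                out.append(GenomicSite(chrom, start, strand if strand in "+-" else "+"))
            else:
                out.append(PeakInterval(chrom, start, end, strand))
    return out


def write_bed(path, records: Iterable):
    with _open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, GenomicSite):
                fh.write(
                    f"{rec.chrom}\t{rec.position}\t{rec.position + 1}\t.\t.\t{rec.strand}\n"
                )
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t.\t.\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# Transcript annotation (GTF/GFF3) and region assignment
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, position: int) -> int | None:
        """Splice-aware genomic -> transcript coordinate (5'->3' on strand);
        None for intronic/outside positions."""
        exons = sorted(self.exons)
        offset = 0
        if self.strand == "+":
            for s, e in exons:
                if s <= position < e:
                    return offset + (position - s)
                offset += e - s
        else:
            for s, e in reversed(exons):
                if s <= position < e:
                    return offset + (e - 1 - position)
                offset += e - s
        return None

    def cds_span_transcript(self) -> tuple[int, int] | None:
        """CDS [start, end) in transcript coordinates, or None (non-coding)."""
        if not self.cds:
            return None
        coords = []
        for s, e in self.cds:
            a = self.genomic_to_transcript(s)
            b = self.genomic_to_transcript(e - 1)
            if a is not None and b is not None:
                coords.extend((a, b))
        if not coords:
            return None
        return min(coords), max(coords) + 1

    def region_of(self, position: int) -> tuple[str, float]:
        """(region, fractional position within region) for a genomic position.

        Region is one of 5UTR/CDS/3UTR/other; fraction in [0, 1).  Intronic
        positions and non-coding transcripts map to 'other'.
        """
        t = self.genomic_to_transcript(position)
        if t is None:
            return "other", float("nan")
        span = self.cds_span_transcript()
        if span is None:
            return "other", float("nan")
        cs, ce = span
        if t < cs:
            return "5UTR", t / cs if cs > 0 else 0.0
        if t < ce:
            return "CDS", (t - cs) / (ce - cs)
        tail = self.length - ce
        return "3UTR", (t - ce) / tail if tail > 0 else 0.0


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    attr = attr.strip().rstrip(";")
    if "=" in attr and '"' not in attr:  # GFF3 style
        for part in attr.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
    else:  # GTF style
        for part in attr.split(";"):
            part = part.strip()
            if not part:
                continue
            bits = part.split(None, 1)
            if len(bits) == 2:
                out[bits[0]] = bits[1].strip().strip('"')
    return out


class TranscriptAnnotation:
    """Transcript models (exon + CDS) loaded from GTF/GFF3, indexed for
    point queries."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in self.transcripts.values():
            if not t.exons:
                continue
            lo = min(s for s, _ in t.exons)
            hi = max(e for _, e in t.exons)
            self._trees[t.chrom].addi(lo, hi, t.transcript_id)

    @classmethod
    def from_gtf(cls, path) -> "TranscriptAnnotation":
        tx: dict[str, Transcript] = {}
        with _open_text(path) as fh:
            for raw in fh:
                if not raw.strip() or raw.startswith("#"):
                    continue
                f = raw.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
                if feature not in ("exon", "CDS"):
                    continue
                a = _parse_attributes(attrs)
                tid = a.get("transcript_id") or a.get("Parent")
                if tid is None:
                    continue
                t = tx.setdefault(tid, Transcript(tid, chrom, strand))
                iv = (int(start) - 1, int(end))  # GTF 1-based inclusive -> half-open
                (t.exons if feature == "exon" else t.cds).append(iv)
        return cls(tx.values())

    def overlapping(self, site: GenomicSite) -> list[Transcript]:
        tree = self._trees.get(site.chrom)
        if tree is None:
            return []
        return [self.transcripts[iv.data] for iv in tree.at(site.position)]

    def locate(self, site: GenomicSite) -> tuple[str, float]:
        """Best (region, fraction) for a site.

        Candidate assignments from every overlapping transcript on the
        site's strand are ranked by region priority CDS > 3UTR > 5UTR >
        other; ties between transcripts broken by the longest transcript.
        """
        best = ("NA", float("nan"))
        best_key = (REGION_PRIORITY["NA"], 0)
        for t in self.overlapping(site):
            if t.strand != site.strand:
                continue
            region, frac = t.region_of(site.position)
            key = (REGION_PRIORITY[region], -t.length)
            if key < best_key:
                best_key = key
                best = (region, frac)
        return best


def annotate_region(site: GenomicSite, annotation: TranscriptAnnotation) -> GenomicSite:
    """Return a copy of ``site`` with ``region`` assigned (NA when no
    overlapping same-strand transcript)."""
    region, _ = annotation.locate(site)
    return replace(site, region=region)
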