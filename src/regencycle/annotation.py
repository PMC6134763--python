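"""Gene models and the genomic windows quantified by the pipeline.

A :class:`TranscriptionUnit` (TU) is a single stranded transcript model —
TSS, ordered exons, poly(A) end — used as the scaffold for all ChIP
quantification.  All coordinates are 0-based half-open genome coordinates;
exons are stored in *transcription* order (5'→3'), so for a minus-strand TU
the first exon is the genomically rightmost block.

Windows follow the study conventions:

* promoter: symmetric ``[tss - h, tss + h)`` (±250 bp for Pol II,
  ±500 bp for H3K4me3) — strand-independent by symmetry;
* gene body: 500 bp downstream of the TSS to 2 kb downstream of the
  poly(A) site, strand-aware;
* first internal exon: exon #2 in transcription order of a ≥3-exon TU,
  the anchoring feature for H3K36me3 onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TranscriptionUnit",
    "GenomicWindow",
    "read_annotation",
    "write_bed12",
    "write_gtf",
    "select_representative_tu",
    "promoter_window",
    "body_window",
    "first_internal_exon",
    "windows_to_bed6",
]


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class TranscriptionUnit:
    tu_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # genome coords, transcription order

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.tu_id}: strand must be + or -")
        if not self.exons:
            raise AnnotationError(f"{self.tu_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.tu_id}: empty exon [{s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.tu_id}: overlapping exons")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expect) != self.exons:
            raise AnnotationError(
                f"{self.tu_id}: exons not in transcription order for strand {self.strand}"
            )

    @property
    def start(self) -> int:
        """Genomic (leftmost) start of the TU span."""
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        """Genomic (rightmost) end of the TU span."""
        return max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        """5'-most transcribed base (genome coordinate of the first base)."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[0][1] - 1

    @property
    def polya_end(self) -> int:
        """3'-most transcribed base."""
        if self.strand == "+":
            return self.exons[-1][1] - 1
        return self.exons[-1][0]

    @property
    def length(self) -> int:
        """Genomic span length (TSS to poly(A), introns included)."""
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def genomic_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    anchor_label: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"window [{self.start},{self.end}) on {self.chrom} is empty"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _exons_to_transcription_order(
    blocks: list[tuple[int, int]], strand: str
) -> tuple[tuple[int, int], ...]:
    blocks = sorted(blocks)
    if strand == "-":
        blocks = blocks[::-1]
    return tuple(blocks)


def _read_bed12(path: str) -> list[TranscriptionUnit]:
    tus: list[TranscriptionUnit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != nblocks or len(starts) != nblocks:
                raise AnnotationError(f"{path}:{lineno}: block count mismatch")
            blocks = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            bad = [b for b in blocks if b[0] < start or b[1] > end]
            if bad:
                warnings.warn(f"{path}:{lineno}: exon outside TU span, record rejected")
                continue
            gene_id = name.rsplit("|", 1)[0] if "|" in name else name
            tu_id = name.rsplit("|", 1)[1] if "|" in name else name
            tus.append(
                TranscriptionUnit(
                    tu_id=tu_id, gene_id=gene_id, chrom=chrom, strand=strand,
                    exons=_exons_to_transcription_order(blocks, strand),
                )
            )
    return tus


def _parse_gtf_attrs(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _read_gtf(path: str) -> list[TranscriptionUnit]:
    # exon records grouped by transcript_id; 1-based closed → 0-based half-open
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tu -> (gene, chrom, strand)
    spans: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise AnnotationError(f"{path}:{lineno}: GTF needs 9 fields, got {len(f)}")
            chrom, _, feature, start, end, _, strand, _, attr = f
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gtf_attrs(attr)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if feature == "transcript":
                if tid is None:
                    raise AnnotationError(f"{path}:{lineno}: transcript without transcript_id")
                spans[tid] = (s, e)
                meta[tid] = (gid, chrom, strand)
                if tid not in exons:
                    exons[tid] = []
                    order.append(tid)
            elif feature == "exon":
                if tid is None:
                    raise AnnotationError(f"{path}:{lineno}: exon without transcript_id")
                if tid not in exons:
                    exons[tid] = []
                    order.append(tid)
                    meta[tid] = (gid, chrom, strand)
                exons[tid].append((s, e))
    tus = []
    for tid in order:
        blocks = exons[tid]
        if not blocks:
            continue
        gid, chrom, strand = meta[tid]
        if tid in spans:
            lo, hi = spans[tid]
            ok = [b for b in blocks if b[0] >= lo and b[1] <= hi]
            if len(ok) != len(blocks):
                warnings.warn(f"{path}: transcript {tid}: exon outside span, record rejected")
                continue
        tus.append(
            TranscriptionUnit(
                tu_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                exons=_exons_to_transcription_order(blocks, strand),
            )
        )
    return tus


def read_annotation(path: str) -> list[TranscriptionUnit]:
    """Read TUs from a GTF (``.gtf``) or BED12 (anything else) file.

    Exons are returned in transcription order regardless of file order;
    records whose exons fall outside the declared TU span are rejected
    with a warning.
    """
    if str(path).endswith((".gtf", ".gff")):
        return _read_gtf(str(path))
    return _read_bed12(str(path))


def write_bed12(tus: Iterable[TranscriptionUnit], path: str) -> None:
    """One BED12 record per TU; name field is ``gene_id|tu_id``."""
    with open(path, "w") as fh:
        for tu in tus:
            blocks = tu.genomic_exons()
            start, end = tu.start, tu.end
            sizes = ",".join(str(e - s) for s, e in blocks)
            offs = ",".join(str(s - start) for s, _ in blocks)
            fh.write(
                f"{tu.chrom}\t{start}\t{end}\t{tu.gene_id}|{tu.tu_id}\t0\t{tu.strand}"
                f"\t{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{offs}\n"
            )


def write_gtf(tus: Iterable[TranscriptionUnit], path: str) -> None:
    with open(path, "w") as fh:
        for tu in tus:
            attrs = f'gene_id "{tu.gene_id}"; transcript_id "{tu.tu_id}";'
            fh.write(
                f"{tu.chrom}\tregencycle\ttranscript\t{tu.start + 1}\t{tu.end}\t."
                f"\t{tu.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(tu.genomic_exons(), 1):
                fh.write(
                    f"{tu.chrom}\tregencycle\texon\t{s + 1}\t{e}\t.\t{tu.strand}\t."
                    f"\t{attrs} exon_number \"{i}\";\n"
                )


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def promoter_window(
    tu: TranscriptionUnit,
    half_width: int,
    chrom_length: int | None = None,
    label: str | None = None,
) -> GenomicWindow:
    """Symmetric window of ``half_width`` bp on each side of the TSS.

    Strand-independent by symmetry.  Clipped at chromosome bounds (the
    ``clipped`` flag is set when this happens).
    """
    if half_width <= 0:
        raise AnnotationError("half_width must be > 0")
    if chrom_length is not None and not (0 <= tu.tss < chrom_length):
        raise AnnotationError(f"{tu.tu_id}: TSS {tu.tss} outside chromosome")
    start = tu.tss - half_width
    end = tu.tss + half_width
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    if label is None:
        label = "promoter_polII" if half_width <= 250 else "promoter_k4"
    return GenomicWindow(tu.chrom, start, end, label, clipped)


def body_window(
    tu: TranscriptionUnit,
    tss_offset: int = 500,
    polya_extension: int = 2000,
    chrom_length: int | None = None,
) -> GenomicWindow:
    """Gene-body window: TSS+500 bp through poly(A)+2 kb, strand-aware."""
    if tu.length <= tss_offset:
        raise AnnotationError(f"{tu.tu_id}: body undefined (TU shorter than {tss_offset} bp)")
    if tu.strand == "+":
        start = tu.tss + tss_offset
        end = tu.polya_end + 1 + polya_extension
    else:
        start = tu.polya_end - polya_extension
        end = tu.tss + 1 - tss_offset
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return GenomicWindow(tu.chrom, start, end, "body", clipped)


def first_internal_exon(tu: TranscriptionUnit) -> tuple[int, int] | None:
    """Exon #2 in transcription order, or None for TUs with < 3 exons."""
    if tu.n_exons < 3:
        return None
    return tu.exons[1]


def select_representative_tu(
    tus: Sequence[TranscriptionUnit],
    promoter_density: Sequence[float],
) -> TranscriptionUnit:
    """Pick the gene's representative TU: maximum promoter Pol II density.

    Ties break to the 5'-most TSS (smallest genome coordinate on +, largest
    on -; across strands, smallest genome coordinate), then lexicographic
    ``tu_id``.
    """
    if not tus:
        raise AnnotationError("no TUs supplied")
    if len(tus) != len(promoter_density):
        raise AnnotationError("one density per TU required")

    def five_prime_rank(tu: TranscriptionUnit) -> int:
        # smaller = more 5' : genomic coordinate on +, mirrored on -
        return tu.tss if tu.strand == "+" else -tu.tss

    best = min(
        range(len(tus)),
        key=lambda i: (-promoter_density[i], five_prime_rank(tus[i]), tus[i].tu_id),
    )
    return tus[best]


def windows_to_bed6(windows: Iterable[GenomicWindow], path: str) -> None:
    """Export windows as BED6 with the anchor label in the name field."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.anchor_label}\t0\t+\n")
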