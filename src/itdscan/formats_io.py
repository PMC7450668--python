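"""Alignment-record and variant-file plumbing.

This module owns the boundary between the caller and the standard
sequencing formats: CIGAR strings, SAM/BAM alignment records (read via
pysam), the supplementary-alignment (``SA``) tag that links the pieces of
a chimeric read, and the VCF output of the final calls.

Internally every coordinate is 0-based, half-open.  The only place
1-based coordinates appear is the VCF text itself.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

# CIGAR operation kinds, per the SAM specification.
CIGAR_KINDS = frozenset("MIDSHN=XP")
#: ops that consume query bases
QUERY_OPS = frozenset("MIS=X")
#: ops that consume reference bases
REF_OPS = frozenset("MDN=X")
#: clip ops (soft and hard); hard clips anchor breakpoints but carry no sequence
CLIP_OPS = frozenset("SH")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class CigarParseError(ValueError):
    """Raised for text that does not follow the SAM CIGAR grammar."""


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: a positive length and an op code."""

    length: int
    kind: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CigarParseError(f"zero/negative-length CIGAR op: {self.length}{self.kind}")
        if self.kind not in CIGAR_KINDS:
            raise CigarParseError(f"unknown CIGAR op code: {self.kind!r}")


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a CIGAR string into a list of :class:`CigarOp`.

    ``"*"`` (no alignment) yields the empty list.  Malformed text raises
    :class:`CigarParseError` naming the offending token.
    """
    if text == "*":
        return []
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise CigarParseError(f"malformed CIGAR near {text[pos:m.start()]!r} in {text!r}")
        length, kind = int(m.group(1)), m.group(2)
        if length == 0:
            raise CigarParseError(f"zero-length CIGAR op {m.group(0)!r} in {text!r}")
        ops.append(CigarOp(length, kind))
        pos = m.end()
    if pos != len(text) or not ops:
        raise CigarParseError(f"malformed CIGAR near {text[pos:]!r} in {text!r}")
    return ops


def cigar_to_string(ops: Sequence[CigarOp]) -> str:
    """Inverse of :func:`parse_cigar`; the empty list renders as ``"*"``."""
    if not ops:
        return "*"
    return "".join(f"{op.length}{op.kind}" for op in ops)


def query_length(ops: Sequence[CigarOp]) -> int:
    """Number of query (read) bases consumed, soft clips included."""
    return sum(op.length for op in ops if op.kind in QUERY_OPS)


def reference_length(ops: Sequence[CigarOp]) -> int:
    """Number of reference bases consumed."""
    return sum(op.length for op in ops if op.kind in REF_OPS)


def leading_clip(ops: Sequence[CigarOp]) -> int:
    """Total clipped length (S or H) at the start of the alignment."""
    n = 0
    for op in ops:
        if op.kind in CLIP_OPS:
            n += op.length
        else:
            break
    return n


def trailing_clip(ops: Sequence[CigarOp]) -> int:
    n = 0
    for op in reversed(ops):
        if op.kind in CLIP_OPS:
            n += op.length
        else:
            break
    return n


class ClipMode(Enum):
    """Soft-clipping mode of an alignment.

    ``MS``: mapped prefix, clipped suffix (the alignment ends at the
    junction and the overhang is clipped on the right).  ``SM`` is the
    mirror image.  ``NONE`` covers unclipped and both-ends-clipped
    alignments.
    """

    MS = "MS"
    SM = "SM"
    NONE = "NONE"


def classify_clip_mode(cigar: Sequence[CigarOp], min_clip: int = 5) -> ClipMode:
    """Classify the clip mode of a CIGAR.

    A clip counts only when it is at least ``min_clip`` bases long; hard
    clips are treated like soft clips (they mark a breakpoint even though
    the bases are gone).
    """
    if not cigar:
        return ClipMode.NONE
    lead = leading_clip(cigar)
    tail = trailing_clip(cigar)
    left = lead >= min_clip
    right = tail >= min_clip
    if right and not left:
        return ClipMode.MS
    if left and not right:
        return ClipMode.SM
    return ClipMode.NONE


@dataclass(frozen=True)
class SAEntry:
    """One entry of the SAM ``SA:Z`` supplementary-alignment tag."""

    chrom: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    cigar: tuple[CigarOp, ...]
    mapq: int

    @property
    def ref_end(self) -> int:
        return self.pos + reference_length(self.cigar)


def parse_sa_tag(text: str) -> list[SAEntry]:
    """Parse the semicolon-delimited SA tag; unparsable entries are
    skipped with a warning rather than aborting the read."""
    entries: list[SAEntry] = []
    for chunk in text.split(";"):
        if not chunk:
            continue
        try:
            chrom, pos1, strand, cig, mapq, _nm = chunk.split(",")
            entries.append(
                SAEntry(chrom, int(pos1) - 1, strand, tuple(parse_cigar(cig)), int(mapq))
            )
        except (ValueError, CigarParseError) as exc:
            log.warning("skipping unparsable SA entry %r: %s", chunk, exc)
    return entries


@dataclass
class AlignmentRecord:
    """One read's primary alignment (plus its SA annotations).

    ``pos`` is the 0-based reference coordinate of the first aligned
    base.  ``seq`` is stored in reference-forward orientation, as in
    SAM.  The query-length invariant (CIGAR consumes exactly
    ``len(seq)`` query bases) is enforced on construction when a
    sequence is present.
    """

    query_name: str
    chrom: str
    pos: int
    strand: str
    mapq: int
    cigar: list[CigarOp]
    seq: str
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    sa_entries: list[SAEntry] = field(default_factory=list)
    tags: dict[str, str] = field(default_factory=dict)
    #: set by redefine_cigar_as_insertion when a rewrite is refused
    rewrite_refused: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0 and not self.is_unmapped:
            raise ValueError(f"negative position for {self.query_name}")
        if self.seq and self.cigar and not self.is_unmapped:
            qlen = query_length(self.cigar)
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.query_name}: CIGAR consumes {qlen} query bases "
                    f"but seq has {len(self.seq)}"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned span."""
        return self.pos + reference_length(self.cigar)

    @property
    def query_aligned_start(self) -> int:
        """Start of the aligned query span, in full-read coordinates
        (hard-clipped bases count toward the offset)."""
        return leading_clip(self.cigar)

    @property
    def query_aligned_end(self) -> int:
        return query_aligned_span(self.cigar)[1]

    def clip_mode(self, min_clip: int = 5) -> ClipMode:
        return classify_clip_mode(self.cigar, min_clip)

    def soft_clip_seq(self, side: str) -> str:
        """Clipped bases at ``side`` ('left'/'right'); empty for hard clips."""
        if side == "left":
            op = self.cigar[0] if self.cigar else None
            if op and op.kind == "S":
                return self.seq[: op.length]
        elif side == "right":
            op = self.cigar[-1] if self.cigar else None
            if op and op.kind == "S":
                return self.seq[len(self.seq) - op.length :]
        return ""

    def footprint(self) -> tuple[int, int]:
        """Reference interval touched by the read: aligned bases plus
        soft/hard-clipped overhangs projected onto the reference, plus
        the same for every SA entry.  Used for depth counting so that
        every read that can support an event also counts in its depth.
        """
        lo = self.pos - leading_clip(self.cigar)
        hi = self.ref_end + trailing_clip(self.cigar)
        for sa in self.sa_entries:
            if sa.chrom != self.chrom:
                continue
            lo = min(lo, sa.pos - leading_clip(sa.cigar))
            hi = max(hi, sa.ref_end + trailing_clip(sa.cigar))
        return max(lo, 0), hi


def query_aligned_span(ops: Sequence[CigarOp]) -> tuple[int, int]:
    """Aligned query span in full-read coordinates (clips, hard or
    soft, count toward the offsets).  Needed to measure how much of the
    read two alignments of a chimera share."""
    start = leading_clip(ops)
    aligned = sum(op.length for op in ops if op.kind in "MI=X")
    return start, start + aligned


@dataclass(frozen=True)
class ChimericPair:
    """A primary alignment together with one same-chromosome,
    same-strand SA entry of the opposite clip mode — the signature a
    soft-clipping-aware aligner leaves at a tandem-duplication junction.
    """

    primary: AlignmentRecord
    alternative: SAEntry
    primary_mode: ClipMode
    alternative_mode: ClipMode

    def __post_init__(self) -> None:
        if self.primary.chrom != self.alternative.chrom:
            raise ValueError("chimeric pair spans chromosomes")
        if self.primary.strand != self.alternative.strand:
            raise ValueError("chimeric pair spans strands")
        if ClipMode.NONE in (self.primary_mode, self.alternative_mode) or (
            self.primary_mode == self.alternative_mode
        ):
            raise ValueError("chimeric pair requires opposite clip modes")


def extract_chimeric_pairs(
    record: AlignmentRecord, min_clip: int = 5
) -> list[ChimericPair]:
    """Return one :class:`ChimericPair` per qualifying SA entry.

    Qualifying means: same chromosome, same strand, and the primary and
    the SA alignment carry opposite clip modes (one MS, one SM).
    Everything else — translocation-like or inversion-like chimeras —
    is dropped.
    """
    if record.is_secondary or record.is_duplicate or record.is_unmapped:
        raise ValueError("extract_chimeric_pairs expects a primary, mapped, non-duplicate record")
    pmode = record.clip_mode(min_clip)
    if pmode is ClipMode.NONE:
        return []
    pairs: list[ChimericPair] = []
    for sa in record.sa_entries:
        if sa.chrom != record.chrom or sa.strand != record.strand:
            continue
        amode = classify_clip_mode(sa.cigar, min_clip)
        if amode is ClipMode.NONE or amode == pmode:
            continue
        pairs.append(ChimericPair(record, sa, pmode, amode))
    return pairs


# ---------------------------------------------------------------------------
# SAM/BAM reading and writing (pysam-backed)
# ---------------------------------------------------------------------------

def _record_from_pysam(aln) -> AlignmentRecord:
    sa_text = aln.get_tag("SA") if aln.has_tag("SA") else ""
    return AlignmentRecord(
        query_name=aln.query_name,
        chrom=aln.reference_name or "*",
        pos=aln.reference_start if aln.reference_start is not None else 0,
        strand="-" if aln.is_reverse else "+",
        mapq=aln.mapping_quality,
        cigar=parse_cigar(aln.cigarstring or "*"),
        seq=aln.query_sequence or "",
        is_duplicate=aln.is_duplicate,
        is_secondary=aln.is_secondary,
        is_supplementary=aln.is_supplementary,
        is_unmapped=aln.is_unmapped,
        sa_entries=parse_sa_tag(sa_text) if sa_text else [],
    )


def read_alignments(path: str, region: str | None = None) -> Iterator[AlignmentRecord]:
    """Stream primary alignment records from a SAM/BAM file in
    coordinate order.

    Duplicate-flagged, secondary, and unmapped records are excluded;
    supplementary records are dropped as standalone records (their
    content survives as ``SA`` annotations on the primaries).  A region
    query (``chrom`` or ``chrom:start-end``, 1-based as in samtools)
    requires an indexed coordinate-sorted BAM.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    try:
        af = pysam.AlignmentFile(str(path), mode)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {path}: {exc}") from exc
    with af:
        if region is not None:
            if af.header.get("HD", {}).get("SO") != "coordinate":
                raise IOError(
                    f"{path}: region queries require a coordinate-sorted, indexed file"
                )
            try:
                it = af.fetch(region=region)
            except ValueError as exc:
                raise IOError(f"{path}: region query failed ({exc}); is the file indexed?") from exc
        else:
            it = af
        last_key: tuple[str, int] | None = None
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_duplicate or aln.is_supplementary:
                continue
            key = (aln.reference_name, aln.reference_start)
            if last_key is not None and key[0] == last_key[0] and key[1] < last_key[1]:
                raise IOError(f"{path}: records out of coordinate order near {key}")
            last_key = key
            yield _record_from_pysam(aln)


def write_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write records (already coordinate-sorted) as a SAM text file."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {c: i for i, c in enumerate(reference_lengths)}
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.query_name
            a.query_sequence = rec.seq or None
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_secondary:
                flag |= 0x100
            if rec.is_duplicate:
                flag |= 0x400
            if rec.is_supplementary:
                flag |= 0x800
            if rec.is_unmapped:
                flag |= 0x4
            a.flag = flag
            if not rec.is_unmapped:
                a.reference_id = tid[rec.chrom]
                a.reference_start = rec.pos
                a.mapping_quality = rec.mapq
                a.cigarstring = cigar_to_string(rec.cigar)
            if rec.seq:
                a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            tags = []
            if rec.sa_entries:
                sa = "".join(
                    f"{s.chrom},{s.pos + 1},{s.strand},{cigar_to_string(list(s.cigar))},{s.mapq},0;"
                    for s in rec.sa_entries
                )
                tags.append(("SA", sa))
            for k, v in rec.tags.items():
                tags.append((k, v))
            if tags:
                a.set_tags(tags)
            out.write(a)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

VCF_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type (DUP or INS)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the event in bases">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based inclusive end of the duplicated segment">',
    '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observation count (supporting reads)">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the locus">',
    '##INFO=<ID=AB,Number=1,Type=Float,Description="Allele balance / variant allele frequency, AO/DP">',
    '##ALT=<ID=DUP,Description="Tandem duplication">',
]


def write_vcf(
    calls: Sequence,
    reference: Mapping[str, str] | None,
    path: str,
    reference_name: str = "unknown",
    meta_lines: Sequence[str] = (),
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write calls as VCF 4.2.

    ``calls`` must be sorted by (chrom, pos); otherwise a ``ValueError``
    is raised.  Small events carry their inserted sequence in ALT
    (anchor base followed by the insertion); large events are symbolic
    ``<DUP>``.  POS is 1-based (``call.pos + 1``).
    """
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("write_vcf requires calls sorted by (chrom, pos)")
    lines = ["##fileformat=VCFv4.2", f"##reference={reference_name}"]
    lines.extend(meta_lines)
    if contig_lengths:
        lines.extend(f"##contig=<ID={c},length={n}>" for c, n in contig_lengths.items())
    lines.extend(VCF_INFO_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, c in enumerate(calls):
        anchor = "N"
        if reference is not None and c.chrom in reference:
            anchor = reference[c.chrom][c.pos : c.pos + 1] or "N"
        if c.svtype == "INS" and c.inserted_seq and not c.inserted_seq.startswith("<"):
            alt = anchor + c.inserted_seq
        else:
            alt = "<DUP>"
        info = (
            f"SVTYPE={c.svtype};SVLEN={c.size};END={c.end};"
            f"AO={c.AO};DP={c.DP};AB={c.VAF:.6g}"
        )
        lines.append(
            f"{c.chrom}\t{c.pos + 1}\tITD{i + 1}\t{anchor}\t{alt}\t.\t{c.filter}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
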