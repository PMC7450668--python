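"""Synthetic data: references, tandem duplications, paired-end reads,
and a deterministic aligner emulator.

Two study designs are reproduced end to end without any external data
or aligner:

* a hotspot grid — every combination of duplication length (1..201 bp)
  and start position (201 consecutive positions) in a ~2.4 kb region,
  each sequenced as a fixed 50% mixture of duplication-carrying and
  wild-type read pairs;
* a genome-wide design — 1,000 tandem duplications of 3–300 bp with
  Beta-distributed sizes placed inside coding intervals of a large
  reference, sequenced over a grid of read lengths (75/100/150/200),
  depths (20/50/100x) and allele fractions (10/20/50%).

The aligner emulator maps reads back to the reference by exact maximal
matches and emits the record shapes a soft-clipping-aware aligner
produces at a duplication junction: a clipped primary plus a
supplementary alignment with the opposite clip mode (annotated through
the SA tag), or — for reads spanning a short event entirely — a single
alignment with an internal insertion.  Reads whose overhang is too
short to anchor a second alignment come out soft-clipped only, exactly
the reads the allele-frequency step has to rescue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .formats_io import AlignmentRecord, CigarOp, SAEntry
from .reconstruct import left_normalize

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_CHROM = "sim1"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated tandem duplication, in original
    (wild-type) reference coordinates, left-normalized."""

    chrom: str
    start: int
    size: int
    vaf_true: float
    id: str

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("truth record requires size >= 1")
        if not 0 < self.vaf_true <= 1:
            raise ValueError("vaf_true must be in (0, 1]")

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-run parameters for read generation."""

    read_length: int = 100
    depth: float = 100.0
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    vaf: float = 0.5
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed twice the read length")
        if not 0 <= self.vaf <= 1:
            raise ValueError("vaf must be in [0, 1]")


@dataclass(frozen=True)
class SimRead:
    name: str
    seq: str
    mate: int  # 1 or 2
    origin: str  # "wt" or "mut"


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def make_reference(
    length: int, gc: float = 0.41, seed: int = 0
) -> tuple[str, list[tuple[int, int]]]:
    """A seeded pseudo-random reference at the requested GC content,
    with coding intervals tiling roughly 30% of it in 150–3,000 bp
    blocks.  Deterministic given (length, gc, seed)."""
    if not 0 < gc < 1:
        raise ValueError("gc must be inside (0, 1)")
    if length < 10_000:
        raise ValueError("reference length must be >= 10,000")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
    # coding blocks 150-3000 bp, gaps tuned so that blocks cover ~30%
    intervals: list[tuple[int, int]] = []
    pos = int(rng.integers(200, 2000))
    while pos < length - 400:
        block = int(rng.integers(150, 3001))
        end = min(pos + block, length)
        intervals.append((pos, end))
        pos = end + int(rng.integers(350, 7001))
    return seq, intervals


def apply_tandem_duplication(
    sequence: str, start: int, size: int, chrom: str = DEFAULT_CHROM, event_id: str = "itd"
) -> tuple[str, TruthRecord]:
    """Insert a second copy of ``sequence[start:start+size]`` right
    after the first; the result is exactly ``size`` bases longer."""
    if start < 0 or size < 1 or start + size > len(sequence):
        raise ValueError(f"duplication [{start}, {start + size}) out of range")
    end = start + size
    mutated = sequence[:end] + sequence[start:end] + sequence[end:]
    norm_start, _ = left_normalize(sequence, start, end)
    truth = TruthRecord(chrom=chrom, start=norm_start, size=size, vaf_true=1.0, id=event_id)
    return mutated, truth


def sample_itd_sizes(
    n: int,
    min_size: int = 3,
    max_size: int = 300,
    alpha: float = 2.0,
    beta: float = 5.0,
    seed: int = 0,
) -> list[int]:
    """Duplication sizes ``min + floor((max - min) * B)`` with
    ``B ~ Beta(alpha, beta)`` — right-skewed defaults concentrate mass
    at the short end of the range, as observed sizes do."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not min_size < max_size:
        raise ValueError("min_size must be < max_size")
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    b = rng.beta(alpha, beta, size=n)
    return [int(min_size + np.floor((max_size - min_size) * x)) for x in b]


def build_hotspot_grid(
    region_start: int, n_lengths: int = 201, n_starts: int = 201
) -> list[tuple[int, int]]:
    """Full Cartesian product of duplication lengths ``1..n_lengths``
    and start positions ``region_start..region_start+n_starts-1``."""
    if n_lengths < 1 or n_starts < 1:
        raise ValueError("grid dimensions must be >= 1")
    return [
        (length, start)
        for length, start in itertools.product(
            range(1, n_lengths + 1), range(region_start, region_start + n_starts)
        )
    ]


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def generate_paired_reads(
    ref_wt: str,
    ref_mut: str,
    cfg: SimConfig,
    n_pairs: int | None = None,
    name_prefix: str = "frag",
) -> list[SimRead]:
    """Paired-end reads from a two-haplotype mixture.

    Each fragment picks the mutant haplotype with probability
    ``cfg.vaf``; its length is Normal(insert_mean, insert_sd) truncated
    below at twice the read length; its start is uniform.  Read 1 is
    the forward end, read 2 the reverse-complemented other end.
    Per-base substitution errors at ``cfg.error_rate``.  Deterministic
    given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    if n_pairs is None:
        n_pairs = max(1, int(round(cfg.depth * len(ref_wt) / (2 * L))))
    reads: list[SimRead] = []
    origins = rng.random(n_pairs) < cfg.vaf
    frags = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
    starts_u = rng.random(n_pairs)
    for i in range(n_pairs):
        hap = ref_mut if origins[i] else ref_wt
        origin = "mut" if origins[i] else "wt"
        frag = int(round(frags[i]))
        frag = max(frag, 2 * L)
        frag = min(frag, len(hap))
        start = int(starts_u[i] * (len(hap) - frag + 1))
        fragment = hap[start : start + frag]
        r1 = fragment[:L]
        r2 = revcomp(fragment[-L:])
        if cfg.error_rate > 0:
            r1 = _add_errors(r1, rng, cfg.error_rate)
            r2 = _add_errors(r2, rng, cfg.error_rate)
        name = f"{name_prefix}_{i:06d}_{origin}"
        reads.append(SimRead(name=f"{name}/1", seq=r1, mate=1, origin=origin))
        reads.append(SimRead(name=f"{name}/2", seq=r2, mate=2, origin=origin))
    return reads


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for k in hits:
        choices = [b for b in "ACGT" if b != out[k]]
        out[k] = choices[rng.integers(0, 3)]
    return "".join(out)


def write_fastq(reads: Iterable[SimRead], path_r1: str, path_r2: str) -> None:
    """Write the pairs as two FASTQ files (constant base quality)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for read in reads:
            fh = f1 if read.mate == 1 else f2
            fh.write(f"@{read.name}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


# ---------------------------------------------------------------------------
# aligner emulator
# ---------------------------------------------------------------------------

ANCHOR = 20  # minimum exact match needed to place an alignment piece


class _RefIndex:
    """Exact k-mer index of a reference for anchor lookup."""

    def __init__(self, reference: Mapping[str, str], k: int = ANCHOR):
        self.k = k
        self.reference = reference
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in reference.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))


@dataclass(frozen=True)
class _Piece:
    chrom: str
    rstart: int
    qstart: int
    qend: int

    @property
    def rend(self) -> int:
        return self.rstart + (self.qend - self.qstart)


def _find_piece(seq: str, idx: _RefIndex, scan_from: int) -> _Piece | None:
    """Anchor the first placeable k-mer at or after ``scan_from`` and
    extend the exact match maximally in both directions.  Among anchor
    hits the longest extension wins; ties go to the leftmost locus."""
    k = idx.k
    for q0 in range(scan_from, len(seq) - k + 1):
        hits = idx.index.get(seq[q0 : q0 + k])
        if not hits:
            continue
        best: _Piece | None = None
        for chrom, rpos in hits:
            ref = idx.reference[chrom]
            qs, rs = q0, rpos
            while qs > 0 and rs > 0 and seq[qs - 1] == ref[rs - 1]:
                qs -= 1
                rs -= 1
            qe, re_ = q0 + k, rpos + k
            while qe < len(seq) and re_ < len(ref) and seq[qe] == ref[re_]:
                qe += 1
                re_ += 1
            piece = _Piece(chrom, rs, qs, qe)
            if best is None or (piece.qend - piece.qstart) > (best.qend - best.qstart):
                best = piece
        return best
    return None


def _piece_record(
    read_name: str,
    seq: str,
    strand: str,
    piece: _Piece,
    other: _Piece | None,
    is_supplementary: bool,
) -> AlignmentRecord:
    cigar: list[CigarOp] = []
    if piece.qstart > 0:
        cigar.append(CigarOp(piece.qstart, "S"))
    cigar.append(CigarOp(piece.qend - piece.qstart, "M"))
    if len(seq) - piece.qend > 0:
        cigar.append(CigarOp(len(seq) - piece.qend, "S"))
    sa = []
    if other is not None:
        other_cigar: list[CigarOp] = []
        if other.qstart > 0:
            other_cigar.append(CigarOp(other.qstart, "S"))
        other_cigar.append(CigarOp(other.qend - other.qstart, "M"))
        if len(seq) - other.qend > 0:
            other_cigar.append(CigarOp(len(seq) - other.qend, "S"))
        sa.append(SAEntry(other.chrom, other.rstart, strand, tuple(other_cigar), 60))
    return AlignmentRecord(
        query_name=read_name,
        chrom=piece.chrom,
        pos=piece.rstart,
        strand=strand,
        mapq=60,
        cigar=cigar,
        seq=seq,
        is_supplementary=is_supplementary,
        sa_entries=sa,
    )


def _align_oriented(seq: str, idx: _RefIndex) -> list[_Piece]:
    first = _find_piece(seq, idx, 0)
    if first is None:
        return []
    pieces = [first]
    if first.qend < len(seq) - 0:
        second = _find_piece(seq, idx, first.qend)
        if second is not None:
            pieces.append(second)
    # a junction within the first k bases leaves an unanchored prefix;
    # nothing more to anchor there (it is shorter than k by construction)
    pieces.sort(key=lambda p: p.qstart)
    return pieces


def emulate_alignment(
    reads: Iterable[SimRead | tuple[str, str]],
    reference: Mapping[str, str],
    mode: str = "chimeric",
    anchor: int = ANCHOR,
) -> list[AlignmentRecord]:
    """Deterministically align reads to the reference.

    ``mode`` controls how a read that fully spans a short duplication
    is represented: ``"chimeric"`` always splits it into primary +
    supplementary; ``"insertion"`` writes a single ``aM nI bM`` record
    whenever the geometry allows; ``"mixed"`` alternates between the
    two per read.  Reads without any exact anchor of ``anchor`` bases
    are emitted as unmapped.  Output is coordinate-sorted.
    """
    if mode not in ("chimeric", "insertion", "mixed"):
        raise ValueError(f"unknown emulation mode {mode!r}")
    idx = _RefIndex(reference, k=anchor)
    records: list[AlignmentRecord] = []
    for i, read in enumerate(reads):
        if isinstance(read, tuple):
            read = SimRead(name=read[0], seq=read[1], mate=1, origin="wt")
        fwd = _align_oriented(read.seq, idx)
        rev = _align_oriented(revcomp(read.seq), idx)

        def span(pieces: list[_Piece]) -> int:
            return sum(p.qend - p.qstart for p in pieces)

        if span(fwd) >= span(rev):
            pieces, seq, strand = fwd, read.seq, "+"
        else:
            pieces, seq, strand = rev, revcomp(read.seq), "-"
        if not pieces or span(pieces) < anchor:
            records.append(
                AlignmentRecord(
                    query_name=read.name,
                    chrom="*",
                    pos=0,
                    strand="+",
                    mapq=0,
                    cigar=[],
                    seq=seq,
                    is_unmapped=True,
                )
            )
            continue
        want_insertion = mode == "insertion" or (mode == "mixed" and i % 2 == 0)
        if len(pieces) == 1:
            records.append(_piece_record(read.name, seq, strand, pieces[0], None, False))
            continue
        p1, p2 = pieces
        ins_rec = _insertion_record(read.name, seq, strand, p1, p2) if want_insertion else None
        if ins_rec is not None:
            records.append(ins_rec)
        else:
            primary, secondary = (
                (p1, p2) if (p1.qend - p1.qstart) >= (p2.qend - p2.qstart) else (p2, p1)
            )
            records.append(_piece_record(read.name, seq, strand, primary, secondary, False))
            records.append(_piece_record(read.name, seq, strand, secondary, primary, True))
    records.sort(key=lambda r: (r.is_unmapped, r.chrom, r.pos, r.query_name))
    return records


def _insertion_record(
    read_name: str, seq: str, strand: str, p1: _Piece, p2: _Piece
) -> AlignmentRecord | None:
    """Single-record representation of a fully spanned duplication:
    ``aM nI bM`` with the insertion at the left breakpoint."""
    if p1.chrom != p2.chrom:
        return None
    s, e = p2.rstart, p1.rend
    if s >= e:
        return None
    overlap = p1.qend - p2.qstart
    size = (e - s) - max(overlap, 0)
    read_left_ref = p1.rstart - p1.qstart
    a = s - read_left_ref
    b = len(seq) - a - size
    if size < 1 or a < 1 or b < 1:
        return None
    return AlignmentRecord(
        query_name=read_name,
        chrom=p1.chrom,
        pos=s - a,
        strand=strand,
        mapq=60,
        cigar=[CigarOp(a, "M"), CigarOp(size, "I"), CigarOp(b, "M")],
        seq=seq,
    )


# ---------------------------------------------------------------------------
# study protocols
# ---------------------------------------------------------------------------

HOTSPOT_REGION_LENGTH = 2430
HOTSPOT_GRID_OFFSET = 951  # grid start within the region


@dataclass
class HotspotGridProtocol:
    """The hotspot-grid design: a fixed region, the full (length, start)
    grid, and per-config balanced mixtures generated on demand."""

    reference: str
    chrom: str
    configs: list[tuple[int, int]]
    truth: list[TruthRecord]
    n_mut_pairs: int = 1000
    n_wt_pairs: int = 1000
    seed: int = 0

    def sample_reads(
        self, length: int, start: int, cfg: SimConfig | None = None
    ) -> tuple[list[SimRead], TruthRecord]:
        """The balanced mixture for one grid configuration."""
        if cfg is None:
            cfg = SimConfig(seed=self.seed, error_rate=0.0)
        mutated, truth = apply_tandem_duplication(
            self.reference, start, length, chrom=self.chrom, event_id=f"grid_{length}_{start}"
        )
        truth = replace(truth, vaf_true=self.n_mut_pairs / (self.n_mut_pairs + self.n_wt_pairs))
        mut_reads = generate_paired_reads(
            self.reference,
            mutated,
            replace(cfg, vaf=1.0, seed=cfg.seed * 2 + 1),
            n_pairs=self.n_mut_pairs,
            name_prefix=f"mut_{length}_{start}",
        )
        wt_reads = generate_paired_reads(
            self.reference,
            mutated,
            replace(cfg, vaf=0.0, seed=cfg.seed * 2 + 2),
            n_pairs=self.n_wt_pairs,
            name_prefix=f"wt_{length}_{start}",
        )
        return mut_reads + wt_reads, truth


@dataclass
class GenomeWideProtocol:
    """The genome-wide design: one rearranged genome carrying all
    simulated duplications, read sets generated per sequencing config."""

    reference: Mapping[str, str]
    mutant: Mapping[str, str]
    coding_intervals: list[tuple[int, int]]
    truth: list[TruthRecord]
    chrom: str = DEFAULT_CHROM

    def generate_reads(self, cfg: SimConfig, n_pairs: int | None = None) -> list[SimRead]:
        return generate_paired_reads(
            self.reference[self.chrom], self.mutant[self.chrom], cfg, n_pairs=n_pairs
        )


def genome_wide_read_grid(
    read_lengths: Sequence[int] = (75, 100, 150, 200),
    depths: Sequence[float] = (20, 50, 100),
    vafs: Sequence[float] = (0.1, 0.2, 0.5),
    seed: int = 0,
    error_rate: float = 0.001,
) -> list[SimConfig]:
    """The full read-generation grid: read length x depth x VAF."""
    return [
        SimConfig(read_length=rl, depth=d, vaf=v, seed=seed, error_rate=error_rate)
        for rl, d, v in itertools.product(read_lengths, depths, vafs)
    ]


def _place_duplications(
    reference: str,
    sizes: Sequence[int],
    coding: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    chrom: str,
    max_attempts: int = 100,
) -> list[TruthRecord]:
    """Place duplications uniformly inside coding intervals, without
    overlap; positions whose left-normalized form escapes the interval
    are redrawn (breakpoints are reported left-aligned)."""
    occupied: list[tuple[int, int]] = []
    truths: list[TruthRecord] = []
    eligible = {}
    for size in sorted(set(sizes)):
        eligible[size] = [iv for iv in coding if iv[1] - iv[0] >= size]
    for i, size in enumerate(sizes):
        ivs = eligible[size]
        if not ivs:
            raise ValueError(f"no coding interval can hold a {size}-bp duplication")
        placed = False
        for _ in range(max_attempts):
            iv = ivs[rng.integers(0, len(ivs))]
            start = int(rng.integers(iv[0], iv[1] - size + 1))
            end = start + size
            norm_start, norm_end = left_normalize(reference, start, end)
            if norm_start < iv[0]:
                continue
            if any(norm_start < oe and os_ < norm_end for os_, oe in occupied):
                continue
            occupied.append((norm_start, norm_end))
            truths.append(
                TruthRecord(chrom=chrom, start=norm_start, size=size, vaf_true=1.0, id=f"itd_{i:04d}")
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place duplication of size {size} after {max_attempts} tries")
    truths.sort(key=lambda t: t.start)
    return truths


def run_protocol(name: str, **params):
    """Build one of the two study designs.

    ``hotspot_grid`` (aliases: ``flt3_grid``, ``flt3-grid``): params
    ``n_lengths``, ``n_starts``, ``n_mut_pairs``, ``n_wt_pairs``,
    ``region_length``, ``grid_offset``, ``seed``.

    ``genome_wide`` (alias ``genome-wide``): params ``length``,
    ``n_dups``, ``min_size``, ``max_size``, ``alpha``, ``beta``,
    ``seed``.
    """
    if name in ("hotspot_grid", "flt3_grid", "flt3-grid"):
        seed = params.get("seed", 0)
        n_lengths = params.get("n_lengths", 201)
        n_starts = params.get("n_starts", 201)
        region_length = params.get("region_length", HOTSPOT_REGION_LENGTH)
        offset = params.get("grid_offset", HOTSPOT_GRID_OFFSET)
        n_mut = params.get("n_mut_pairs", 1000)
        n_wt = params.get("n_wt_pairs", 1000)
        rng = np.random.default_rng(seed)
        p = [0.295, 0.205, 0.205, 0.295]
        ref = "".join(rng.choice(np.array(list("ACGT")), size=region_length, p=p))
        configs = build_hotspot_grid(offset, n_lengths=n_lengths, n_starts=n_starts)
        vaf = n_mut / (n_mut + n_wt)
        truth = [
            TruthRecord(
                chrom="hotspot",
                start=left_normalize(ref, start, start + length)[0],
                size=length,
                vaf_true=vaf,
                id=f"grid_{length}_{start}",
            )
            for length, start in configs
        ]
        return HotspotGridProtocol(
            reference=ref,
            chrom="hotspot",
            configs=configs,
            truth=truth,
            n_mut_pairs=n_mut,
            n_wt_pairs=n_wt,
            seed=seed,
        )
    if name in ("genome_wide", "genome-wide"):
        seed = params.get("seed", 0)
        length = params.get("length", 2_000_000)
        n_dups = params.get("n_dups", 1000)
        min_size = params.get("min_size", 3)
        max_size = params.get("max_size", 300)
        alpha = params.get("alpha", 2.0)
        beta = params.get("beta", 5.0)
        chrom = params.get("chrom", DEFAULT_CHROM)
        ref, coding = make_reference(length, gc=params.get("gc", 0.41), seed=seed)
        sizes = sample_itd_sizes(
            n_dups, min_size=min_size, max_size=max_size, alpha=alpha, beta=beta, seed=seed + 1
        )
        rng = np.random.default_rng(seed + 2)
        truth = _place_duplications(ref, sizes, coding, rng, chrom)
        mut = ref
        for t in sorted(truth, key=lambda t: t.start, reverse=True):
            mut = mut[: t.end] + ref[t.start : t.end] + mut[t.end :]
        return GenomeWideProtocol(
            reference={chrom: ref},
            mutant={chrom: mut},
            coding_intervals=coding,
            truth=truth,
            chrom=chrom,
        )
    raise ValueError(f"unknown protocol {name!r}")
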