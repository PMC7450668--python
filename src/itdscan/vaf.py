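"""Step 2: seed-and-realignment allele-frequency estimation.

The supporting-read count of a duplication candidate from chimeric
evidence alone undercounts: reads whose overhang past the junction was
too short for the aligner to place a second alignment end up as plain
soft-clipped (or mismatch-tailed) reads.  Those reads are rescued here:
the longest clipped segment among the candidate's supporters serves as
a seed, and every other read clipped at the same junction has its
clipped end locally aligned against the seed with the Smith–Waterman
algorithm.  However short the clip, a confident match adds the read to
the supporting count AO.

VAF = AO / DP, with DP the read depth at the anchor base immediately
left of the duplicated segment.  Measuring depth outside the segment
matters: at the junction itself the second copy contributes extra,
reference-looking coverage that would deflate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .formats_io import AlignmentRecord
from .reconstruct import ItdCandidate, left_normalize


@dataclass(frozen=True)
class SWParams:
    """Local-alignment scores: positive match, non-positive penalties.
    A gap of length g costs ``gap_open + (g - 1) * gap_extend``."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass
class ItdCall:
    """A final call ready for VCF output."""

    chrom: str
    pos: int  # 0-based start of the duplicated/insertion segment
    end: int  # 0-based exclusive end
    size: int
    svtype: str  # DUP or INS
    inserted_seq: str
    AO: int
    DP: int
    VAF: float
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if not (0 <= self.AO <= self.DP):
            raise ValueError(f"AO={self.AO} outside [0, DP={self.DP}]")
        if self.size != self.end - self.pos:
            raise ValueError("size must equal end - pos")


def smith_waterman(
    query: str, target: str, params: SWParams = SWParams()
) -> tuple[int, tuple[int, int], tuple[int, int], float]:
    """Smith–Waterman local alignment with affine gaps.

    Returns ``(score, (q0, q1), (t0, t1), identity)`` for the best
    local alignment; identity is the fraction of aligned columns with
    identical bases.  The empty alignment scores 0, so the score is
    never negative.
    """
    if not query or not target:
        raise ValueError("smith_waterman requires non-empty sequences")
    nq, nt = len(query), len(target)
    NEG = float("-inf")
    # H: best ending in a match/mismatch or fresh start; E: gap in target
    # (consuming query); F: gap in query (consuming target).
    H = [[0] * (nt + 1) for _ in range(nq + 1)]
    E = [[NEG] * (nt + 1) for _ in range(nq + 1)]
    F = [[NEG] * (nt + 1) for _ in range(nq + 1)]
    best, best_ij = 0, (0, 0)
    for i in range(1, nq + 1):
        qc = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, nt + 1):
            e = max(Hi[j - 1] + params.gap_open, Ei[j - 1] + params.gap_extend)
            f = max(Hi1[j] + params.gap_open, Fi1[j] + params.gap_extend)
            sub = params.match if qc == target[j - 1] else params.mismatch
            h = max(0, Hi1[j - 1] + sub, e, f)
            Ei[j], Fi[j] = e, f
            Hi[j] = h
            if h > best:
                best, best_ij = h, (i, j)
    if best == 0:
        return 0, (0, 0), (0, 0), 0.0
    # traceback with explicit state to respect affine gap runs
    i, j = best_ij
    state = "H"
    ident = cols = 0
    q1, t1 = i, j
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = params.match if query[i - 1] == target[j - 1] else params.mismatch
            if H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                cols += 1
                if query[i - 1] == target[j - 1]:
                    ident += 1
                i, j = i - 1, j - 1
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] + params.gap_open:
                state = "H"
            j -= 1
        else:  # F
            cols += 1
            if F[i][j] == H[i - 1][j] + params.gap_open:
                state = "H"
            i -= 1
    return best, (i, q1), (j, t1), (ident / cols if cols else 0.0)


def extract_seed(
    candidate: ItdCandidate,
    supporters: Sequence[AlignmentRecord],
    side: str | None = None,
) -> str:
    """The soft-clipped segment of the supporter with the longest clip
    at the candidate's junction (ties broken by read name).

    ``side`` restricts the choice to MS-side clips (sequence downstream
    of the junction) or SM-side clips (sequence upstream); by default
    the longest clip of either side wins.  All-hard-clipped supporters
    leave nothing to seed with and raise ``ValueError``.
    """
    best: tuple[int, str, str] | None = None
    for rec in sorted(supporters, key=lambda r: r.query_name):
        options = []
        if side in (None, "ms"):
            options.append(rec.soft_clip_seq("right"))
        if side in (None, "sm"):
            options.append(rec.soft_clip_seq("left"))
        for clip in options:
            if clip and (best is None or len(clip) > best[0]):
                best = (len(clip), rec.query_name, clip)
    if best is None:
        raise ValueError("no seed available: no supporter carries clipped sequence")
    return best[2]


def default_accept(
    score: int,
    identity: float,
    span: int,
    seg_len: int,
    seed_len: int,
    min_identity: float = 0.8,
) -> bool:
    """Default rescue acceptance: identity >= 0.8 over an aligned span
    covering >= 80% of the shorter of clip and seed.

    No absolute minimum clip length beyond 1 base: a clip at the exact
    junction coordinate is informative however short it is, and the
    locus gating already keeps unrelated clips out.
    """
    return (
        seg_len >= 1
        and identity >= min_identity
        and span >= 0.8 * min(seg_len, seed_len)
    )


def _junction_matches(
    chrom_seq: str,
    candidate: ItdCandidate,
    clip_pos: int,
    side: str,
    tolerance: int,
) -> bool:
    """Does a clip at ``clip_pos`` point at this candidate's junction?

    Exact raw-coordinate matches come first; otherwise the clip
    position is accepted when the duplication it would imply
    left-normalizes onto the candidate (junction micro-homology moves
    clip coordinates without changing the event)."""
    observed = candidate.sm_junctions if side == "sm" else candidate.ms_junctions
    if any(abs(clip_pos - p) <= tolerance for p in observed):
        return True
    n = candidate.size
    if side == "sm":
        hyp = (clip_pos, clip_pos + n)
    else:
        hyp = (clip_pos - n, clip_pos)
    if hyp[0] < 0 or hyp[1] > len(chrom_seq):
        return False
    return left_normalize(chrom_seq, *hyp) == (candidate.start, candidate.end)


def rescue_split_reads(
    candidate: ItdCandidate,
    seeds: Mapping[str, str],
    records: Iterable[AlignmentRecord],
    params: SWParams = SWParams(),
    accept=default_accept,
    reference: Mapping[str, str] | None = None,
    clip_tolerance: int = 0,
    include_mismatch_ends: bool = False,
    min_clip_len: int = 1,
) -> set[str]:
    """Rescue clipped reads at the candidate's junction.

    ``seeds`` maps side (``"ms"``/``"sm"``) to the seed sequence for
    that side of the junction; a read's clipped segment is compared
    against the same-side seed, because the two sides carry different
    sequence.  With ``include_mismatch_ends`` reads whose alignment was
    forced across the junction with >= 3 trailing mismatches are
    treated as if that tail were clipped (requires ``reference``).
    The returned set is disjoint from the existing supporters.
    """
    chrom_seq = reference[candidate.chrom] if reference else ""
    rescued: set[str] = set()
    for rec in records:
        if rec.query_name in candidate.supporting_read_names:
            continue
        if rec.chrom != candidate.chrom or rec.is_duplicate or rec.is_secondary:
            continue
        segments: list[tuple[str, str, int]] = []  # (side, segment, clip_pos)
        left = rec.soft_clip_seq("left")
        if left:
            segments.append(("sm", left, rec.pos))
        right = rec.soft_clip_seq("right")
        if right:
            segments.append(("ms", right, rec.ref_end))
        if include_mismatch_ends and reference is not None and not segments:
            segments.extend(_mismatch_tail_segments(rec, chrom_seq))
        for side, seg, clip_pos in segments:
            seed = seeds.get(side, "")
            if not seed or len(seg) < min_clip_len:
                continue
            if not chrom_seq:
                in_range = any(
                    abs(clip_pos - p) <= clip_tolerance
                    for p in (candidate.sm_junctions | candidate.ms_junctions)
                )
            else:
                in_range = _junction_matches(chrom_seq, candidate, clip_pos, side, clip_tolerance)
            if not in_range:
                continue
            score, qspan, _tspan, identity = smith_waterman(seg, seed, params)
            span = qspan[1] - qspan[0]
            if accept(score, identity, span, len(seg), len(seed)):
                rescued.add(rec.query_name)
                break
    return rescued


def _mismatch_tail_segments(
    rec: AlignmentRecord, chrom_seq: str, min_mismatches: int = 3
) -> list[tuple[str, str, int]]:
    """Ends of a fully aligned read that disagree with the reference in
    >= min_mismatches of their bases, treated as pseudo-clips."""
    if any(op.kind != "M" for op in rec.cigar):
        return []
    out = []
    ref = chrom_seq[rec.pos : rec.ref_end]
    if len(ref) != len(rec.seq):
        return []
    for side in ("sm", "ms"):
        # longest end segment in which mismatches accumulate from the tip
        best_len = 0
        mism = 0
        rng = range(len(rec.seq)) if side == "sm" else range(len(rec.seq) - 1, -1, -1)
        run = 0
        for k in rng:
            run += 1
            if rec.seq[k] != ref[k]:
                mism += 1
                if mism >= min_mismatches:
                    best_len = run
        if best_len:
            if side == "sm":
                out.append(("sm", rec.seq[:best_len], rec.pos + best_len))
            else:
                out.append(("ms", rec.seq[len(rec.seq) - best_len :], rec.ref_end - best_len))
        mism = 0
    return out


def compute_depth(chrom: str, pos: int, records: Iterable[AlignmentRecord]) -> int:
    """Reads whose footprint (aligned plus clipped bases, including SA
    pieces, projected onto the reference) covers ``pos``.  Duplicates
    and secondaries do not count.  Zero coverage is simply 0."""
    n = 0
    for rec in records:
        if rec.chrom != chrom or rec.is_duplicate or rec.is_secondary or rec.is_unmapped:
            continue
        lo, hi = rec.footprint()
        if lo <= pos < hi:
            n += 1
    return n


def compute_vaf(ao: int, dp: int) -> float:
    if dp == 0:
        raise ValueError("VAF undefined at zero depth; drop the call upstream")
    if not 0 <= ao <= dp:
        raise ValueError(f"AO={ao} outside [0, DP={dp}]")
    return ao / dp


def apply_filters(
    calls: Sequence[ItdCall],
    ao_min: int = 3,
    dp_min: int = 10,
    af_min: float = 0.01,
) -> list[ItdCall]:
    """Annotate each call with PASS or the first failing threshold.

    Filtering is annotation, not removal: failing calls stay in the
    output with their reason in the FILTER column.
    """
    out = []
    for c in calls:
        if c.AO < ao_min:
            status = "LowAO"
        elif c.DP < dp_min:
            status = "LowDP"
        elif c.VAF < af_min:
            status = "LowAF"
        else:
            status = "PASS"
        out.append(replace(c, filter=status))
    return out
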