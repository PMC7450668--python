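"""The end-to-end caller: alignment records in, duplication calls out.

Order of operations per chromosome: collect chimeric pairs, infer
candidate duplications from their geometry, left-normalize and cluster
them, classify short events as duplication vs novel insertion via the
rotation test, rescue additional clipped support by seed realignment,
count depth, compute VAF, annotate filters.  The per-chromosome step is
a pure function of its input records, so results are independent of
how chromosomes are distributed over workers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import __version__
from .formats_io import (
    AlignmentRecord,
    extract_chimeric_pairs,
    read_alignments,
    write_sam,
    write_vcf,
)
from .reconstruct import (
    ItdCandidate,
    candidate_from_insertion_read,
    classify_insertion,
    cluster_candidates,
    infer_itd_from_chimera,
    normalize_candidate,
    redefine_cigar_as_insertion,
    select_best_pair,
    tag_large_itd,
)
from .vaf import (
    ItdCall,
    SWParams,
    apply_filters,
    compute_vaf,
    extract_seed,
    rescue_split_reads,
)


@dataclass
class RunConfig:
    """All tunables of the caller, with their defaults."""

    min_clip: int = 5
    min_mapq: int = 1
    min_size: int = 3
    max_size: int = 1000
    min_support: int = 2
    cutoff_fraction: float = 0.1
    inspector: str = "asis"  # or "oracle"
    sw: SWParams = field(default_factory=SWParams)
    rescue_identity: float = 0.8
    clip_tolerance: int = 0
    rescue_mismatch_ends: bool = False
    ao_min: int = 3
    dp_min: int = 10
    af_min: float = 0.01
    use_insertion_reads: bool = True
    pass_only: bool = False
    seed: int = 0

    def to_meta_lines(self) -> list[str]:
        fields = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "sw"
        }
        sw = self.sw
        fields.update(
            sw_match=sw.match, sw_mismatch=sw.mismatch,
            sw_gap_open=sw.gap_open, sw_gap_extend=sw.gap_extend,
        )
        cfg = ",".join(f"{k}={v}" for k, v in sorted(fields.items()))
        return [f"##itdscan_version={__version__}", f"##itdscan_config={cfg}"]


def scan_records(
    records: Sequence[AlignmentRecord],
    reference: Mapping[str, str],
    config: RunConfig | None = None,
) -> list[ItdCall]:
    """Run the full caller on in-memory records (one or more chromosomes)."""
    config = config or RunConfig()
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_duplicate or rec.is_supplementary:
            continue
        by_chrom.setdefault(rec.chrom, []).append(rec)
    calls: list[ItdCall] = []
    for chrom in sorted(by_chrom):
        calls.extend(_scan_chromosome(chrom, by_chrom[chrom], reference, config))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.size))
    if config.pass_only:
        calls = [c for c in calls if c.filter == "PASS"]
    return calls


def _scan_chromosome(
    chrom: str,
    records: list[AlignmentRecord],
    reference: Mapping[str, str],
    config: RunConfig,
) -> list[ItdCall]:
    if chrom not in reference:
        raise ValueError(f"contig {chrom!r} present in alignments but not in the reference")
    chrom_seq = reference[chrom]
    candidates: list[ItdCandidate] = []
    by_name: dict[str, AlignmentRecord] = {}
    for rec in records:
        by_name[rec.query_name] = rec
        if rec.mapq < config.min_mapq:
            continue
        pairs = extract_chimeric_pairs(rec, min_clip=config.min_clip)
        best = select_best_pair(pairs)
        if best is not None:
            cand = infer_itd_from_chimera(
                best,
                min_size=config.min_size,
                max_size=config.max_size,
                min_clip=config.min_clip,
            )
            if cand is not None:
                candidates.append(normalize_candidate(cand, reference))
                continue
        if config.use_insertion_reads:
            cand = candidate_from_insertion_read(
                rec, min_size=config.min_size, max_size=config.max_size
            )
            if cand is not None:
                candidates.append(normalize_candidate(cand, reference))
    clusters = cluster_candidates(candidates, min_support=config.min_support)
    calls: list[ItdCall] = []
    for cand in clusters:
        supporters = [
            by_name[name] for name in sorted(cand.supporting_read_names) if name in by_name
        ]
        svtype, inserted = _classify_event(cand, supporters, chrom_seq, reference, config)
        seeds = {}
        for side in ("ms", "sm"):
            try:
                seeds[side] = extract_seed(cand, supporters, side=side)
            except ValueError:
                pass
        if not seeds and cand.from_insertion_read:
            # insertion-op supporters carry no clip; the inserted copy
            # itself seeds the junction on both sides
            if inserted and not inserted.startswith("<"):
                seeds = {"ms": inserted, "sm": inserted}
        rescued = set()
        if seeds:
            rescued = rescue_split_reads(
                cand,
                seeds,
                records,
                params=config.sw,
                reference=reference,
                clip_tolerance=config.clip_tolerance,
                include_mismatch_ends=config.rescue_mismatch_ends,
            )
        ao_names = cand.supporting_read_names | rescued
        ao = len(ao_names)
        # depth at the anchor base left of the segment, where the extra
        # copy's coverage cannot inflate it; supporting reads always count
        dp_pos = max(cand.start - 1, 0)
        dp = len(_covering(records, chrom, dp_pos) | ao_names)
        if dp == 0:
            continue
        calls.append(
            ItdCall(
                chrom=chrom,
                pos=cand.start,
                end=cand.end,
                size=cand.size,
                svtype=svtype,
                inserted_seq=inserted,
                AO=ao,
                DP=dp,
                VAF=compute_vaf(ao, dp),
            )
        )
    return apply_filters(calls, ao_min=config.ao_min, dp_min=config.dp_min, af_min=config.af_min)


def _covering(records: Iterable[AlignmentRecord], chrom: str, pos: int) -> set[str]:
    out = set()
    for rec in records:
        if rec.chrom != chrom or rec.is_duplicate or rec.is_secondary or rec.is_unmapped:
            continue
        lo, hi = rec.footprint()
        if lo <= pos < hi:
            out.add(rec.query_name)
    return out


def _classify_event(
    cand: ItdCandidate,
    supporters: list[AlignmentRecord],
    chrom_seq: str,
    reference: Mapping[str, str],
    config: RunConfig,
) -> tuple[str, str]:
    """(svtype, inserted sequence) for a clustered candidate.

    Large events are duplications by geometry.  Small events are run
    through the rotation test when a supporting read can be rewritten
    with a single insertion; when no read fully spans the event the
    chimeric geometry already implies tandem duplication.
    """
    if cand.event_class == "large":
        return "DUP", "<DUP>"
    duplicated = chrom_seq[cand.start : cand.end]
    for rec in supporters:
        if any(op.kind == "I" for op in rec.cigar):
            rewritten = rec
        else:
            rewritten = redefine_cigar_as_insertion(rec, cand)
            if rewritten.rewrite_refused:
                continue
        verdict = classify_insertion(
            rewritten, reference, cutoff_fraction=config.cutoff_fraction,
            inspector=config.inspector,
        )
        if verdict == "duplication":
            return "DUP", duplicated
        return "INS", _inserted_seq(rewritten)
    return "DUP", duplicated


def _inserted_seq(rec: AlignmentRecord) -> str:
    qoff = 0
    for op in rec.cigar:
        if op.kind == "I":
            return rec.seq[qoff : qoff + op.length]
        if op.kind in "MS=X":
            qoff += op.length
    return ""


def reconstructed_records(
    records: Sequence[AlignmentRecord],
    reference: Mapping[str, str],
    config: RunConfig | None = None,
) -> list[AlignmentRecord]:
    """Debug view of step 1: supporting reads with rewritten CIGARs
    (small events) or SV tags (large events), everything else as-is."""
    config = config or RunConfig()
    out: dict[str, AlignmentRecord] = {r.query_name: r for r in records if not r.is_supplementary}
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for rec in out.values():
        if not rec.is_unmapped:
            by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom, recs in by_chrom.items():
        candidates = []
        for rec in recs:
            if rec.mapq < config.min_mapq:
                continue
            best = select_best_pair(extract_chimeric_pairs(rec, min_clip=config.min_clip))
            if best is None:
                continue
            cand = infer_itd_from_chimera(
                best, min_size=config.min_size, max_size=config.max_size,
                min_clip=config.min_clip,
            )
            if cand is None:
                continue
            cand = normalize_candidate(cand, reference)
            if cand.event_class == "small":
                new = redefine_cigar_as_insertion(rec, cand)
                if not new.rewrite_refused:
                    out[rec.query_name] = new
            else:
                out[rec.query_name] = tag_large_itd(rec, cand)
    result = [r for r in out.values() if not r.is_unmapped]
    result.sort(key=lambda r: (r.chrom, r.pos, r.query_name))
    return result


def scan(
    alignments_path: str,
    reference: Mapping[str, str],
    out_vcf: str,
    region: str | None = None,
    config: RunConfig | None = None,
    reference_name: str = "reference",
    emit_reconstructed: str | None = None,
) -> list[ItdCall]:
    """File-level entry point: SAM/BAM in, VCF out."""
    config = config or RunConfig()
    records = list(read_alignments(alignments_path, region=region))
    for rec in records:
        if rec.chrom not in reference:
            raise ValueError(
                f"contig {rec.chrom!r} in {alignments_path} is absent from the reference"
            )
    calls = scan_records(records, reference, config)
    write_vcf(
        calls,
        reference,
        out_vcf,
        reference_name=reference_name,
        meta_lines=config.to_meta_lines(),
        contig_lengths={c: len(s) for c, s in reference.items()},
    )
    if emit_reconstructed:
        recon = reconstructed_records(records, reference, config)
        write_sam(recon, {c: len(s) for c, s in reference.items()}, emit_reconstructed)
    return calls
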