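"""Scoring predicted duplication calls against a simulated truth set.

Three matching criteria are supported:

* ``hotspot`` — the predicted left breakpoint falls inside a stated
  hotspot region and the predicted size equals the true size;
* ``exact_1bp`` — the predicted left breakpoint is within 1 bp of the
  true breakpoint and the size is exactly equal (the stringent,
  genome-wide criterion);
* ``overlap_20_90`` — up to 20 bp of left-breakpoint difference,
  reciprocal overlap of at least 90%, and the predicted right
  breakpoint not exceeding the true right end by more than 20 bp.

Predictions reported as insertions count the same as duplications: a
short tandem duplication is legitimately representable either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class MatchCriteria:
    mode: str  # hotspot | exact_1bp | overlap_20_90
    hotspot_region: tuple[int, int] | None = None
    left_tol: int = 20
    right_tol: int = 20
    min_overlap: float = 0.90
    reciprocal: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("hotspot", "exact_1bp", "overlap_20_90"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.left_tol < 0 or self.right_tol < 0:
            raise ValueError("tolerances must be >= 0")
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")
        if self.mode == "hotspot" and self.hotspot_region is None:
            raise ValueError("hotspot mode requires hotspot_region")


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def precision(self) -> float | None:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) > 0 else None

    @property
    def recall(self) -> float | None:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) > 0 else None

    @property
    def f1(self) -> float | None:
        denom = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / denom if denom > 0 else None


@dataclass
class MatchDetail:
    """Per-event outcome of a matching run, for size stratification."""

    counts: EvalCounts
    matched: list[tuple[object, object]] = field(default_factory=list)  # (pred, truth)
    unmatched_predictions: list[object] = field(default_factory=list)
    unmatched_truths: list[object] = field(default_factory=list)


def _pred_fields(pred) -> tuple[str, int, int]:
    """(chrom, start, size) from an ItdCall or any similar object."""
    start = getattr(pred, "pos", None)
    if start is None:
        start = pred.start
    return pred.chrom, start, pred.size


def _is_match(pred, truth, criteria: MatchCriteria) -> bool:
    chrom, start, size = _pred_fields(pred)
    if chrom != truth.chrom:
        return False
    if criteria.mode == "hotspot":
        lo, hi = criteria.hotspot_region
        return lo <= start < hi and size == truth.size
    if criteria.mode == "exact_1bp":
        return abs(start - truth.start) <= 1 and size == truth.size
    # overlap_20_90
    if abs(start - truth.start) > criteria.left_tol:
        return False
    pred_end = start + size
    truth_end = truth.start + truth.size
    if pred_end > truth_end + criteria.right_tol:
        return False
    ov = min(pred_end, truth_end) - max(start, truth.start)
    if ov <= 0:
        return False
    if ov < criteria.min_overlap * truth.size:
        return False
    if criteria.reciprocal and ov < criteria.min_overlap * size:
        return False
    return True


def match_calls(
    predicted: Sequence, truth: Sequence, criteria: MatchCriteria
) -> MatchDetail:
    """Greedy one-to-one matching, nearest left breakpoint first, with
    deterministic position tie-breaks.  Each truth record is matched at
    most once; unmatched predictions are FP, unmatched truths FN."""
    candidates = []
    for pi, pred in enumerate(predicted):
        _, pstart, _ = _pred_fields(pred)
        for ti, tr in enumerate(truth):
            if _is_match(pred, tr, criteria):
                candidates.append((abs(pstart - tr.start), tr.start, pstart, pi, ti))
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[object, object]] = []
    for _dist, _ts, _ps, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matched.append((predicted[pi], truth[ti]))
    detail = MatchDetail(
        counts=EvalCounts(
            TP=len(matched),
            FP=len(predicted) - len(used_p),
            FN=len(truth) - len(used_t),
        ),
        matched=matched,
        unmatched_predictions=[p for i, p in enumerate(predicted) if i not in used_p],
        unmatched_truths=[t for i, t in enumerate(truth) if i not in used_t],
    )
    return detail


def compute_metrics(tp: int, fp: int, fn: int) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, F1); 0/0 cases are None (undefined), not 0."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    c = EvalCounts(TP=tp, FP=fp, FN=fn)
    return c.precision, c.recall, c.f1


def stratify_by_size(
    detail: MatchDetail, bins: Sequence[tuple[int, int]]
) -> dict[tuple[int, int], EvalCounts]:
    """Per-size-bin counts (closed intervals, must be disjoint).  True
    events bin by their true size; false-positive predictions by their
    predicted size.  Events outside every bin are dropped."""
    ordered = sorted(bins)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(ordered, ordered[1:]):
        if b_lo <= a_hi:
            raise ValueError(f"overlapping bins ({a_lo},{a_hi}) and ({b_lo},{b_hi})")

    def bin_of(size: int) -> tuple[int, int] | None:
        for lo, hi in bins:
            if lo <= size <= hi:
                return (lo, hi)
        return None

    table = {b: EvalCounts() for b in bins}
    for _pred, tr in detail.matched:
        b = bin_of(tr.size)
        if b:
            table[b].TP += 1
    for tr in detail.unmatched_truths:
        b = bin_of(tr.size)
        if b:
            table[b].FN += 1
    for pred in detail.unmatched_predictions:
        b = bin_of(_pred_fields(pred)[2])
        if b:
            table[b].FP += 1
    return table
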