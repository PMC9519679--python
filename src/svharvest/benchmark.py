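"""Benchmarking of SV call sets against a simulated truth set.

Implements breakpoint-tolerance matching, sensitivity/precision/F1, boolean
caller combinations (``|``/``&``) and the two-step selection of the best
combination under a per-category precision floor.

Tolerances for a true positive:

========  =====================  ==========
class     breakpoints            length
========  =====================  ==========
INDEL     <= 2 bp each           <= 5 bp
A         <= 10 bp each          <= 20 bp
B-E       <= 50 bp each          <= 50 bp
INS, no   start <= 10 bp         --
length
TRA       both ends <= 50 bp     --
========  =====================  ==========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import CATEGORY_BOUNDS, TYPE_CATEGORIES, CallSet, SVRecord, TruthSet, log

# ---------------------------------------------------------------------------
# length categories
# ---------------------------------------------------------------------------

OUT_OF_RANGE = "OUT_OF_RANGE"


def classify_length_category(record: SVRecord) -> str:
    """Length category of a record: INDEL, A..E, "ABCDE" (translocations)
    or OUT_OF_RANGE for lengths outside [2 bp, 1 Mb].

    Records without a reported length fall back to the caller-reported
    class (``category_hint``), defaulting to A for insertions; translocations
    always form the pooled ABCDE class.
    """
    if record.sv_type == "TRA":
        return "ABCDE"
    length = record.length if record.length is not None else (
        record.span if record.sv_type != "INS" else None)
    if length is None:
        return record.category_hint or "A"
    if length < 2 or length > 1_000_000:
        log.debug("record length %s outside [2, 1e6]; excluded", length)
        return OUT_OF_RANGE
    for cat, (lo, hi) in CATEGORY_BOUNDS.items():
        if lo <= length <= hi:
            return cat
    return OUT_OF_RANGE  # unreachable given the bins tile [2, 1e6]


def record_length(record: SVRecord) -> Optional[int]:
    if record.length is not None:
        return record.length
    if record.sv_type in ("INS", "TRA"):
        return None
    return record.span


# ---------------------------------------------------------------------------
# tolerance matching
# ---------------------------------------------------------------------------

#: (breakpoint tolerance, length tolerance) per class
_TOLERANCES = {"INDEL": (2, 5), "A": (10, 20), "B": (50, 50), "C": (50, 50),
               "D": (50, 50), "E": (50, 50), "ABCDE": (50, None)}

#: start-only tolerance for insertions without a reported length
_INS_NO_LENGTH_TOL = 10


def records_match(truth: SVRecord, call: SVRecord) -> bool:
    """Whether ``call`` is a true positive for ``truth`` under the
    per-class breakpoint/length tolerances."""
    if truth.sv_type != call.sv_type or truth.chrom != call.chrom:
        return False
    if truth.sv_type == "TRA":
        assert truth.mate is not None and call.mate is not None
        if truth.mate[0] != call.mate[0]:
            return False
        return (abs(truth.start - call.start) <= 50
                and abs(truth.mate[1] - call.mate[1]) <= 50)
    t_len, c_len = record_length(truth), record_length(call)
    if truth.sv_type == "INS" and (t_len is None or c_len is None):
        return abs(truth.start - call.start) <= _INS_NO_LENGTH_TOL
    cat = classify_length_category(truth)
    if cat == OUT_OF_RANGE:
        return False
    bp_tol, len_tol = _TOLERANCES[cat]
    if abs(truth.start - call.start) > bp_tol:
        return False
    # INDELs and insertions are anchored at one breakpoint: the second end
    # is implied by the length, which has its own tolerance
    if truth.sv_type not in ("INDEL", "INS") and \
            abs(truth.end - call.end) > bp_tol:
        return False
    if len_tol is not None and t_len is not None and c_len is not None:
        if abs(t_len - c_len) > len_tol:
            return False
    return True


def match_distance(a: SVRecord, b: SVRecord) -> int:
    """Breakpoint distance used to rank candidate matches (max over the
    breakpoints that the tolerance rules compare)."""
    if a.sv_type == "TRA" and a.mate is not None and b.mate is not None:
        return max(abs(a.start - b.start), abs(a.mate[1] - b.mate[1]))
    if a.sv_type in ("INS", "INDEL"):
        return abs(a.start - b.start)
    return max(abs(a.start - b.start), abs(a.end - b.end))


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def _in_scope(records: Iterable[SVRecord], sv_type: str,
              category: Optional[str]) -> list[SVRecord]:
    out = []
    for r in records:
        if r.sv_type != sv_type:
            raise ValueError(
                f"mixed sv_type input: expected {sv_type}, got {r.sv_type}")
        if category is None or classify_length_category(r) == category:
            out.append(r)
    return out


def match_calls(
    truth: Sequence[SVRecord] | TruthSet,
    calls: Sequence[SVRecord] | CallSet,
    sv_type: str,
    category: Optional[str] = None,
) -> MatchResult:
    """One-to-one matching of calls to truth events of one SV type (and,
    optionally, one length category).

    Candidate (truth, call) pairs within tolerance are accepted greedily by
    increasing breakpoint distance, ties broken by leftmost call start.
    """
    t_records = _in_scope(
        truth.records if isinstance(truth, TruthSet) else truth, sv_type, category)
    c_records = _in_scope(
        calls.records if isinstance(calls, CallSet) else calls, sv_type, category)

    # candidate pairs via a sorted window on call starts
    c_sorted = sorted(range(len(c_records)), key=lambda j: c_records[j].start)
    c_starts = [c_records[j].start for j in c_sorted]
    candidates: list[tuple[int, int, int, int]] = []
    import bisect
    for i, t in enumerate(t_records):
        lo = bisect.bisect_left(c_starts, t.start - 60)
        hi = bisect.bisect_right(c_starts, t.start + 60)
        for jj in range(lo, hi):
            j = c_sorted[jj]
            c = c_records[j]
            if records_match(t, c):
                candidates.append((match_distance(t, c), c.start, i, j))
    candidates.sort()
    t_used = [False] * len(t_records)
    c_used = [False] * len(c_records)
    pairs: list[tuple[int, int]] = []
    for _, _, i, j in candidates:
        if not t_used[i] and not c_used[j]:
            t_used[i] = c_used[j] = True
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(c_records) - tp, fn=len(t_records) - tp,
                       pairs=pairs)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricTriple:
    """Sensitivity, precision and F1; ``None`` marks an undefined value
    (zero denominator), which is propagated as missing, never as 0."""

    sensitivity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]


def compute_metrics(m: MatchResult) -> MetricTriple:
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else None
    prec = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    if sens is None or prec is None or (sens + prec) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricTriple(sensitivity=sens, precision=prec, f1=f1)


# ---------------------------------------------------------------------------
# boolean caller combinations
# ---------------------------------------------------------------------------

class CombinationExpr:
    """Boolean expression over caller names with ``|`` (union) and ``&``
    (consensus).  ``str()`` renders e.g. ``Manta|GRIDSS|(Lumpy&NGSEP)``."""

    def __init__(self, op: str, children: Sequence["CombinationExpr"] = (),
                 caller: Optional[str] = None):
        if op not in ("leaf", "or", "and"):
            raise ValueError(f"unknown op {op!r}")
        self.op = op
        self.children = list(children)
        self.caller = caller
        if op == "leaf" and caller is None:
            raise ValueError("leaf requires a caller name")
        if op != "leaf" and not children:
            raise ValueError(f"{op} requires children")

    @classmethod
    def leaf(cls, caller: str) -> "CombinationExpr":
        return cls("leaf", caller=caller)

    @classmethod
    def or_(cls, *children: "CombinationExpr") -> "CombinationExpr":
        return children[0] if len(children) == 1 else cls("or", children)

    @classmethod
    def and_(cls, *children: "CombinationExpr") -> "CombinationExpr":
        return children[0] if len(children) == 1 else cls("and", children)

    def leaves(self) -> list[str]:
        if self.op == "leaf":
            return [self.caller]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def __str__(self) -> str:
        if self.op == "leaf":
            return self.caller  # type: ignore[return-value]
        sep = "|" if self.op == "or" else "&"
        parts = []
        for c in self.children:
            s = str(c)
            if c.op != "leaf" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CombinationExpr) and str(self) == str(other)

    def __hash__(self) -> int:
        return hash(str(self))

    @classmethod
    def parse(cls, text: str) -> "CombinationExpr":
        """Parse ``A|B|(C&D)`` style expressions."""
        pos = 0

        def skip_ws() -> None:
            nonlocal pos
            while pos < len(text) and text[pos].isspace():
                pos += 1

        def parse_atom() -> "CombinationExpr":
            nonlocal pos
            skip_ws()
            if pos < len(text) and text[pos] == "(":
                pos += 1
                node = parse_or()
                skip_ws()
                if pos >= len(text) or text[pos] != ")":
                    raise ValueError(f"unbalanced parenthesis in {text!r}")
                pos += 1
                return node
            start = pos
            while pos < len(text) and (text[pos].isalnum() or text[pos] in "_-."):
                pos += 1
            if start == pos:
                raise ValueError(f"expected caller name at {pos} in {text!r}")
            return cls.leaf(text[start:pos])

        def parse_and() -> "CombinationExpr":
            nonlocal pos
            nodes = [parse_atom()]
            while True:
                skip_ws()
                if pos < len(text) and text[pos] == "&":
                    pos += 1
                    nodes.append(parse_atom())
                else:
                    break
            return cls.and_(*nodes)

        def parse_or() -> "CombinationExpr":
            nonlocal pos
            nodes = [parse_and()]
            while True:
                skip_ws()
                if pos < len(text) and text[pos] == "|":
                    pos += 1
                    nodes.append(parse_and())
                else:
                    break
            return cls.or_(*nodes)

        node = parse_or()
        skip_ws()
        if pos != len(text):
            raise ValueError(f"trailing input in expression {text!r}")
        return node


def _dedup_add(kept: list[SVRecord], new: Iterable[SVRecord]) -> None:
    """Append records from ``new`` that do not tolerance-match a kept record
    (cross-caller duplicate removal; earlier callers win)."""
    import bisect
    kept_sorted = sorted(range(len(kept)), key=lambda i: kept[i].start)
    starts = [kept[i].start for i in kept_sorted]
    appended: list[SVRecord] = []
    for r in new:
        lo = bisect.bisect_left(starts, r.start - 60)
        hi = bisect.bisect_right(starts, r.start + 60)
        dup = any(records_match(kept[kept_sorted[k]], r) or
                  records_match(r, kept[kept_sorted[k]])
                  for k in range(lo, hi))
        if not dup:
            dup = any(records_match(k, r) or records_match(r, k)
                      for k in appended
                      if abs(k.start - r.start) <= 60)
        if not dup:
            appended.append(r)
    for r in appended:
        idx = bisect.bisect_left(starts, r.start)
        starts.insert(idx, r.start)
        kept_sorted.insert(idx, len(kept))
        kept.append(r)


def combine_callsets(
    expr: CombinationExpr,
    callsets: Mapping[str, CallSet],
    sv_type: str,
) -> list[SVRecord]:
    """Materialise the call set of a boolean caller combination.

    OR is the deduplicated union in expression order (the representative of
    a duplicate group comes from the earlier caller); AND keeps the first
    member's calls that have a tolerance match in every other member.
    """
    if expr.op == "leaf":
        try:
            cs = callsets[expr.caller]  # type: ignore[index]
        except KeyError as e:
            raise KeyError(f"unknown caller {expr.caller!r}") from e
        return list(cs.of_type(sv_type))
    child_sets = [combine_callsets(c, callsets, sv_type) for c in expr.children]
    if expr.op == "or":
        kept: list[SVRecord] = []
        for records in child_sets:
            _dedup_add(kept, records)
        return kept
    # AND: first caller's coordinates survive
    import bisect
    result = child_sets[0]
    for other in child_sets[1:]:
        other_sorted = sorted(other, key=lambda r: r.start)
        starts = [r.start for r in other_sorted]
        filtered = []
        for r in result:
            lo = bisect.bisect_left(starts, r.start - 60)
            hi = bisect.bisect_right(starts, r.start + 60)
            if any(records_match(r, other_sorted[k]) or
                   records_match(other_sorted[k], r) for k in range(lo, hi)):
                filtered.append(r)
        result = filtered
    return result


def evaluate_combination(
    expr: CombinationExpr,
    callsets: Mapping[str, CallSet],
    truth: TruthSet,
    sv_type: str,
    category: Optional[str] = None,
) -> MetricTriple:
    """Score a caller combination against truth for one type/category."""
    combined = combine_callsets(expr, callsets, sv_type)
    return compute_metrics(match_calls(truth.of_type(sv_type), combined,
                                       sv_type, category))


def _passes_floor(per_category: Mapping[str, MetricTriple],
                  floor: float) -> bool:
    # undefined precision (no calls in a category) does not fail the floor
    return all(m.precision is None or m.precision >= floor
               for m in per_category.values())


def select_best_combination(
    per_caller: Mapping[str, Mapping[str, MetricTriple]],
    callsets: Mapping[str, CallSet],
    truth: TruthSet,
    sv_type: str,
    precision_floor: float = 0.95,
) -> CombinationExpr:
    """Two-step combination selection under a per-category precision floor.

    Step 1 ORs every caller whose precision meets the floor in all length
    categories of the SV type.  Step 2 ANDs the remaining callers; the AND
    is ORed in only if its measured precision meets the floor in every
    category.  If nothing qualifies, the single caller with the highest mean
    F1 is returned with a warning.

    ``per_caller`` maps caller -> category -> MetricTriple, iterated in
    caller priority order (which fixes the OR order).
    """
    step1 = [c for c, cats in per_caller.items()
             if _passes_floor(cats, precision_floor)]
    rest = [c for c in per_caller if c not in step1]

    parts = [CombinationExpr.leaf(c) for c in step1]
    if len(rest) >= 2:
        and_expr = CombinationExpr.and_(*[CombinationExpr.leaf(c) for c in rest])
        cats = TYPE_CATEGORIES[sv_type]
        and_metrics = {cat: evaluate_combination(and_expr, callsets, truth,
                                                 sv_type, cat)
                       for cat in cats}
        if _passes_floor(and_metrics, precision_floor):
            parts.append(and_expr)
    if parts:
        return CombinationExpr.or_(*parts)

    # fallback: best single caller by mean F1 over defined categories
    def mean_f1(cats: Mapping[str, MetricTriple]) -> float:
        vals = [m.f1 for m in cats.values() if m.f1 is not None]
        return sum(vals) / len(vals) if vals else -math.inf

    best = max(per_caller, key=lambda c: mean_f1(per_caller[c]))
    log.warning("no caller or AND-combination reached precision >= %.2f "
                "in all categories; falling back to best single caller %s",
                precision_floor, best)
    return CombinationExpr.leaf(best)


def benchmark_callers(
    callsets: Mapping[str, CallSet],
    truth: TruthSet,
    sv_type: str,
) -> dict[str, dict[str, MetricTriple]]:
    """Per-caller, per-category metrics table for one SV type."""
    out: dict[str, dict[str, MetricTriple]] = {}
    for caller, cs in callsets.items():
        out[caller] = {
            cat: compute_metrics(match_calls(truth.of_type(sv_type),
                                             cs.of_type(sv_type), sv_type, cat))
            for cat in TYPE_CATEGORIES[sv_type]
        }
    return out
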