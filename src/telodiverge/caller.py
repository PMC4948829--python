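"""Divergence-point calling for cloned telomere sequences.

The procedure mirrors the clone-sequencing assay: within a set of clones of
the same telomere from one clonal population, the longest clone without
divergent sequence serves as the reference; every other clone is aligned to
it from the centromere-proximal end, and the divergence point is the first
position at which the clone stops being explainable by tolerated technical
variation (isolated point mutations, insertions/deletions of at most 6 nt).
Undiverged lengths below 125 nt are flagged as truncation events.

Alignment is an affine-gap prefix alignment: both sequences are anchored at
the proximal (left) end, the alignment ends where the score peaks, and the
distal remainders of both sequences are free.  Degenerate TG1-3 repeats are
low-complexity, so the default scoring penalizes gaps strongly relative to
mismatches and several detection rules deal specifically with the alignment
ambiguities of periodic sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import CloneSequence, TelomereSet

NEG = -1e18

#: non-diverged reasons
REASON_PERFECT = "perfect"
REASON_TOLERATED_SUBS = "tolerated_substitutions"
REASON_TOLERATED_INDEL = "tolerated_indel"
REASON_SHORTER = "shorter_matching"
#: diverged reasons
REASON_SUB_RUN = "diverged_substitution_run"
REASON_LONG_INDEL = "diverged_long_indel"
REASON_TAIL = "diverged_unalignable_tail"


@dataclass(frozen=True)
class DivergenceRules:
    """Tolerance rules separating technical variation from true divergence.

    max_indel_nt:
        longest insertion or deletion still treated as non-divergent
        (boundary inclusive: a 6-nt indel is tolerated, a 7-nt indel is not).
    max_substitution_run:
        longest run of consecutive substitutions tolerated; 1 means isolated
        point mutations only.  There is no cap on how many isolated
        substitutions a clone may carry.
    truncation_threshold_nt:
        undiverged lengths strictly below this are flagged as truncations.
    tail_window / tail_min_identity:
        a distal segment whose next ``tail_window`` alignment columns share
        less than ``tail_min_identity`` column identity with the reference is
        treated as unalignable (divergent with a non-homologous donor).
    tail_remainder_nt:
        the aligner anchors both sequences at the proximal end and stops
        where the score peaks; sequence distal of the peak stays unaligned.
        When more than ``tail_remainder_nt`` of *both* the reference and the
        clone remain unaligned, the clone's distal sequence is not the
        reference's — a diverged tail.  (If only one side remains, the clone
        is simply shorter or longer than the reference.)
    tail_rise_threshold:
        two independent stretches of degenerate TG1-3 repeats can align with
        high coincidental identity — mostly isolated 1-2 nt gaps where G-run
        lengths differ — so each lesion alone looks tolerated and the score
        may keep rising through a replaced tail.  What distinguishes such a
        tail is the *density* of lesions: each non-match event adds
        +refine_event_weight to a walk that falls -1 per column, and a
        maximal proximal-to-distal rise of the walk above this threshold is
        called a diverged tail.  Tolerated technical variation is far too
        sparse to trip this.
    refine_breakpoint / refine_event_weight / refine_nonrepeat_sub_weight:
        coincidental matches push the first violating event distal to the
        true junction; when enabled, the divergence point is refined to the
        changepoint minimizing the same walk.  On a clean all-match prefix
        the refined point coincides exactly with the start of the violating
        event.  Isolated substitutions that introduce a non-repeat base
        (A or C on the G-rich strand) are characteristic of technical noise
        rather than of replaced repeat sequence, and get the smaller
        ``refine_nonrepeat_sub_weight``.
    indel_coalesce_gap:
        in periodic repeats the aligner may split one physical indel into
        several small score-equivalent gap runs; same-side gap runs
        separated by at most this many matching columns are judged (and
        weighted) as one indel of their total length.  This both keeps a
        scattered 6-nt deletion tolerated and stops a 7-nt indel from
        evading the length rule by splitting.
    tolerate_transpositions:
        an adjacent mismatch pair that swaps two bases (ref GT read as TG)
        is the optimal alignment of an indel shift boundary within periodic
        repeats and is treated as one point lesion, not as a divergent
        substitution run.
    consensus_polish:
        correct the chosen reference toward the set consensus (majority vote
        over aligned columns) before calling, so the reference's own
        tolerated technical lesions do not appear as shared lesions in every
        clone; the assay compares clones against a consensus, not against a
        raw read.
    """

    max_indel_nt: int = 6
    allow_isolated_substitutions: bool = True
    max_substitution_run: int = 1
    truncation_threshold_nt: int = 125
    tail_window: int = 20
    tail_min_identity: float = 0.5
    tail_remainder_nt: int = 12
    tail_rise_threshold: float = 65.0
    indel_coalesce_gap: int = 8
    tolerate_transpositions: bool = True
    refine_breakpoint: bool = True
    refine_event_weight: float = 33.0
    refine_nonrepeat_sub_weight: float = 6.0
    consensus_polish: bool = True

    def __post_init__(self) -> None:
        if self.max_indel_nt < 1:
            raise ValueError("max_indel_nt must be >= 1")
        if self.truncation_threshold_nt < 1:
            raise ValueError("truncation_threshold_nt must be >= 1")
        if self.max_substitution_run < 1:
            raise ValueError("max_substitution_run must be >= 1")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring; the first gap column costs ``gap_open``.

    The mismatch penalty is deliberately NOT half the gap-open penalty: with
    mismatch -2 and gap open -4, a single 1-nt indel in a periodic repeat
    has score-equivalent representations as two adjacent mismatches plus a
    displaced gap, and the adjacent-mismatch form would spuriously violate
    the single-point-mutation tolerance rule.  -2.5 makes the gap
    representation strictly optimal.
    """

    match: float = 1.0
    mismatch: float = -2.5
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class PairwiseAlignment:
    """Left-anchored prefix alignment of a clone against the reference.

    ``columns`` is an ordered list of (ref_base | None, clone_base | None);
    None denotes a gap.  No column is gap/gap.  ``free_tail_start`` is the
    index of the first unaligned trailing column (== len(columns) when the
    alignment consumed both sequences fully).
    """

    reference_id: str
    clone_id: str
    columns: list[tuple[Optional[str], Optional[str]]]
    score: float
    free_tail_start: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.free_tail_start < 0:
            self.free_tail_start = len(self.columns)

    def ref_sequence(self) -> str:
        return "".join(r for r, _ in self.columns if r is not None)

    def clone_sequence(self) -> str:
        return "".join(c for _, c in self.columns if c is not None)


@dataclass
class DivergenceCall:
    """Per-clone verdict of the divergence caller.

    Positions are 1-based on the reference coordinate; ``undiverged_length_nt``
    is the number of reference nucleotides proximal to the divergence point
    (the black bar segment of the assay's per-telomere bar plots).
    """

    clone_id: str
    undiverged_length_nt: int
    diverged: bool
    divergence_point_1based: Optional[int]
    truncation: bool
    reason: str
    telomere_id: str = ""
    strain_id: str = ""
    genotype: str = ""
    generations: float = float("nan")
    clone_length_nt: int = 0


# ---------------------------------------------------------------------------
# alignment


def _gotoh(ref: str, clone: str, sc: AlignmentScoring):
    """Row-vectorized Gotoh DP.  Returns (M, X, Y) score matrices.

    State M ends in a match/mismatch column; X ends with a gap in the clone
    (reference base consumed); Y ends with a gap in the reference.  Left-end
    gaps are penalized (proximal anchoring); free right-end gaps are handled
    by the caller when choosing the end cell.
    """
    nr, nc = len(ref), len(clone)
    M = np.full((nr + 1, nc + 1), NEG)
    X = np.full((nr + 1, nc + 1), NEG)
    Y = np.full((nr + 1, nc + 1), NEG)
    M[0, 0] = 0.0
    if nc:
        Y[0, 1:] = sc.gap_open + sc.gap_extend * np.arange(nc)
    refA = np.frombuffer(ref.encode(), dtype=np.uint8)
    clA = np.frombuffer(clone.encode(), dtype=np.uint8)
    ext = sc.gap_extend
    jj = np.arange(nc + 1)
    for i in range(1, nr + 1):
        s = np.where(clA == refA[i - 1], sc.match, sc.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = s + prev_best[:-1]
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) + sc.gap_open, X[i - 1] + ext
        )
        # Y within-row scan: Y[i,j] = open - ext + ext*j + max_{k<j}(MX[k] - ext*k)
        MX = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(MX - ext * jj)
        Y[i, 1:] = sc.gap_open - ext + ext * jj[1:] + run[:-1]
    return M, X, Y


def _traceback(ref, clone, sc, M, X, Y, end_i, end_j, end_state, pref=("Y", "X", "M")):
    """Trace one optimal path back to (0,0).

    ``pref`` fixes the tie-break: preferring gap states over M while walking
    backwards places score-equivalent gaps at the *distal* end of periodic
    repeat blocks, keeping the proximal (undiverged) region of the alignment
    clean — within (TGG)n-like blocks a gap position is otherwise arbitrary.
    """
    cols: list[tuple[Optional[str], Optional[str]]] = []
    i, j, st = end_i, end_j, end_state
    tol = 1e-9
    while i > 0 or j > 0:
        if st == "M":
            s = sc.match if ref[i - 1] == clone[j - 1] else sc.mismatch
            cols.append((ref[i - 1], clone[j - 1]))
            target = M[i, j] - s
            i, j = i - 1, j - 1
            cand = {"M": M[i, j], "Y": Y[i, j], "X": X[i, j]}
        elif st == "X":
            cols.append((ref[i - 1], None))
            v = X[i, j]
            i -= 1
            cand = {
                "M": M[i, j] + sc.gap_open,
                "Y": Y[i, j] + sc.gap_open,
                "X": X[i, j] + sc.gap_extend,
            }
            target = v
        else:  # Y
            cols.append((None, clone[j - 1]))
            v = Y[i, j]
            j -= 1
            cand = {
                "M": M[i, j] + sc.gap_open,
                "Y": Y[i, j] + sc.gap_extend,
                "X": X[i, j] + sc.gap_open,
            }
            target = v
        for s2 in pref:
            if abs(cand[s2] - target) < tol:
                st = s2
                break
        else:  # pragma: no cover - DP consistency guard
            raise AssertionError("traceback lost the optimal path")
    cols.reverse()
    return cols


def align_sequences(
    ref: str, clone: str, scoring: AlignmentScoring | None = None
) -> tuple[list[tuple[Optional[str], Optional[str]]], float, int]:
    """Prefix alignment of ``clone`` against ``ref``.

    Both sequences are anchored at the proximal (left) end with no free
    gaps; the alignment ends wherever the score peaks, and the distal
    remainders of both sequences are free (appended as unscored end-gap
    columns).  This matches the assay: only the shared proximal region is
    meaningful, and a diverged distal tail must not be forced into a global
    alignment, where it could drag the proximal alignment out of register.

    Returns (columns, score, free_tail_start), ``free_tail_start`` being the
    index of the first unaligned trailing column.  Deterministic: on equal
    scores the earliest peak is chosen, and the traceback prefers a
    match/mismatch over a reference gap over a clone gap.
    """
    if not ref or not clone:
        raise ValueError("cannot align empty sequences")
    sc = scoring or AlignmentScoring()

    # fast path: one sequence is a prefix of the other
    if clone == ref:
        cols = [(a, a) for a in ref]
        return cols, sc.match * len(ref), len(cols)
    if ref.startswith(clone):
        cols = [(a, a) for a in clone]
        tail = len(cols)
        cols += [(a, None) for a in ref[len(clone):]]
        return cols, sc.match * len(clone), tail
    if clone.startswith(ref):
        cols = [(a, a) for a in ref]
        tail = len(cols)
        cols += [(None, a) for a in clone[len(ref):]]
        return cols, sc.match * len(ref), tail

    # strip a long shared proximal prefix (minus a safety margin) before DP
    margin = 50
    k = 0
    lim = min(len(ref), len(clone))
    while k < lim and ref[k] == clone[k]:
        k += 1
    strip = max(0, k - margin)
    r, c = ref[strip:], clone[strip:]

    M, X, Y = _gotoh(r, c, sc)
    nr, nc = len(r), len(c)
    best = np.maximum(np.maximum(M, X), Y)
    score = float(best.max())
    # earliest peak: smallest i+j, then smallest i
    tol = 1e-9
    peaks = np.argwhere(best >= score - tol)
    order = np.lexsort((peaks[:, 0], peaks.sum(axis=1)))
    ei, ej = (int(v) for v in peaks[order[0]])
    for st in ("M", "Y", "X"):
        mat = {"M": M, "X": X, "Y": Y}[st]
        if mat[ei, ej] >= score - tol:
            end_state = st
            break
    cols = _traceback(r, c, sc, M, X, Y, ei, ej, end_state)
    free_tail_start = len(cols)
    cols += [(ch, None) for ch in r[ei:]]
    cols += [(None, ch) for ch in c[ej:]]
    if strip:
        cols = [(ch, ch) for ch in ref[:strip]] + cols
        score += sc.match * strip
        free_tail_start += strip
    return cols, float(score), free_tail_start


def align_clone(
    clone: CloneSequence,
    reference: CloneSequence,
    scoring: AlignmentScoring | None = None,
) -> PairwiseAlignment:
    """Align one clone against the set's reference clone."""
    cols, score, tail = align_sequences(reference.bases, clone.bases, scoring)
    return PairwiseAlignment(
        reference_id=reference.clone_id,
        clone_id=clone.clone_id,
        columns=cols,
        score=score,
        free_tail_start=tail,
    )


# ---------------------------------------------------------------------------
# divergence calling


def _column_type(col: tuple[Optional[str], Optional[str]]) -> str:
    r, c = col
    if r is None:
        return "R"  # gap in reference (insertion in clone)
    if c is None:
        return "C"  # gap in clone (deletion / shorter clone)
    return "M" if r == c else "X"


def _events(types: Sequence[str]):
    """Maximal runs of M columns and maximal runs of non-M columns.

    Non-M runs mixing substitutions and gaps are composite events: a
    mismatch immediately adjacent to a gap is not an isolated point
    mutation, so composites always violate the tolerance rules.
    """
    out = []
    i, n = 0, len(types)
    while i < n:
        is_m = types[i] == "M"
        j = i
        while j < n and (types[j] == "M") == is_m:
            j += 1
        if is_m:
            out.append(("M", i, j))
        else:
            sub = set(types[i:j])
            kind = types[i] if len(sub) == 1 else "mixed"
            out.append((kind, i, j))
        i = j
    return out


def _refine_breakpoint(lesions, ref_consumed_at, scan_to, rules):
    """Changepoint refinement of the divergence point.

    Over columns [0, scan_to), take the prefix walk that steps -1 per column
    and +weight at the start of every non-match event (lesion); its argmin
    (earliest on ties) estimates the boundary between the almost-lesion-free
    undiverged prefix and the lesion-dense diverged tail.  ``lesions`` is a
    list of (start_column, weight) pairs.
    """
    steps = -np.ones(scan_to)
    for s, weight in lesions:
        if s < scan_to:
            steps[s] += weight
    walk = np.concatenate([[0.0], np.cumsum(steps)])
    p = int(np.argmin(walk))  # earliest index on ties
    return int(ref_consumed_at[p])


def call_divergence(
    alignment: PairwiseAlignment, rules: DivergenceRules | None = None
) -> DivergenceCall:
    """Scan an alignment proximal->distal and locate the divergence point.

    Tolerated events: substitution runs of length <= max_substitution_run
    flanked by matching (or boundary) columns; gap runs of length <=
    max_indel_nt on either side; the free distal end-gap run of the shorter
    sequence.  The first violating event (longer substitution run, longer
    gap run, a composite mismatch+gap event, or a distal segment with column
    identity below the unalignable-tail threshold) sets the divergence
    point at 1 + the number of reference bases consumed before it.
    """
    rules = rules or DivergenceRules()
    cols = alignment.columns
    types = [_column_type(c) for c in cols]
    scan_end = alignment.free_tail_start
    ref_len = sum(1 for r, _ in cols if r is not None)
    rem_ref = sum(1 for r, _ in cols[scan_end:] if r is not None)
    rem_clone = sum(1 for _, c in cols[scan_end:] if c is not None)

    match_flags = np.array([t == "M" for t in types[:scan_end]], dtype=np.int64)
    # reference bases consumed before each column index (0..scan_end)
    ref_base = np.array(
        [1 if cols[i][0] is not None else 0 for i in range(scan_end)], dtype=np.int64
    )
    ref_consumed_at = np.concatenate([[0], np.cumsum(ref_base)])
    # window identity: matches in columns [i, i+w)
    w = rules.tail_window
    cum = np.concatenate([[0], np.cumsum(match_flags)])

    sub_limit = rules.max_substitution_run if rules.allow_isolated_substitutions else 0
    events = _events(types[:scan_end])
    lesion_events = [(kind, start, end) for kind, start, end in events if kind != "M"]
    # a real diverged tail persists to the distal end of the aligned region;
    # lesion patterns followed by a long clean stretch are technical noise
    persists = bool(lesion_events) and scan_end - lesion_events[-1][2] <= 40

    def _is_transposition(start: int, end: int) -> bool:
        (r1, c1), (r2, c2) = cols[start], cols[start + 1]
        return end - start == 2 and r1 == c2 and r2 == c1

    # judge lesions: coalesce same-side gap runs split by periodic-repeat
    # ambiguity, classify substitution runs; each judged lesion carries the
    # column where it starts, its walk weight, and a verdict
    judged: list[tuple[int, float, Optional[str], str]] = []  # (start, weight, violation_reason, kind)
    i = 0
    n_lesions = len(lesion_events)
    while i < n_lesions:
        kind, start, end = lesion_events[i]
        length = end - start
        if kind == "mixed":
            judged.append((start, rules.refine_event_weight, REASON_SUB_RUN, "mixed"))
            i += 1
        elif kind == "X":
            if rules.tolerate_transpositions and _is_transposition(start, end):
                # a base swap is an indel shift boundary: tolerated noise
                # when the sequence after it is clean, a divergent lesion
                # when lesions continue into the distal end (a tail)
                verdict = REASON_SUB_RUN if persists else None
                judged.append((start, rules.refine_event_weight, verdict, "sub"))
            elif length > sub_limit:
                judged.append((start, rules.refine_event_weight, REASON_SUB_RUN, "sub"))
            else:
                _, clone_base = cols[start]
                weight = (
                    rules.refine_nonrepeat_sub_weight
                    if length == 1 and clone_base in ("A", "C")
                    else rules.refine_event_weight
                )
                judged.append((start, weight, None, "sub"))
            i += 1
        else:  # gap run, possibly split into same-side fragments
            total = length
            last_end = end
            j = i + 1
            # one physical indel only scatters within its periodic block, so
            # a coalesced group is bounded in span as well as in step
            while (
                j < n_lesions
                and lesion_events[j][0] == kind
                and lesion_events[j][1] - last_end <= rules.indel_coalesce_gap
                and lesion_events[j][2] - start <= 3 * rules.indel_coalesce_gap
            ):
                total += lesion_events[j][2] - lesion_events[j][1]
                last_end = lesion_events[j][2]
                j += 1
            verdict = REASON_LONG_INDEL if total > rules.max_indel_nt else None
            # several fragments are stronger tail evidence than one clean
            # indel, but a single group must stay below the rise threshold
            weight = min(
                rules.refine_event_weight + 13.0 * (j - i - 1),
                rules.tail_rise_threshold - 1.0,
            )
            judged.append((start, weight, verdict, "indel"))
            i = j

    weighted_lesions = [(start, weight) for start, weight, _, _ in judged]
    saw_sub = any(k == "sub" and v is None for _, _, v, k in judged)
    saw_indel = any(k == "indel" and v is None for _, _, v, k in judged)
    violation = None  # (event_start_col, reason)

    # first violating lesion under the explicit tolerance rules
    for start, _, verdict, _ in judged:
        if verdict is not None:
            violation = (start, verdict)
            break

    # low-identity window rule (unalignable tail against a foreign donor)
    for kind, start, end in events:
        if violation is not None and start >= violation[0]:
            break
        if scan_end - start >= w:
            ident = (cum[start + w] - cum[start]) / w
            if ident < rules.tail_min_identity:
                violation = (start, REASON_TAIL)
                break

    # unaligned-remainder rule: substantial sequence left on BOTH sides
    # beyond the alignment peak means the distal sequences are not each other
    if min(rem_ref, rem_clone) > rules.tail_remainder_nt:
        if violation is None or scan_end < violation[0]:
            violation = (scan_end, REASON_TAIL)

    # lesion-density (rise) rule: a coincidentally well-aligning replaced
    # tail shows as a dense run of individually tolerated lesions.  A real
    # diverged tail persists to the distal end of the aligned region, so the
    # rule only applies when lesions continue near the scan end — a dense
    # cluster followed by a long clean stretch is clustered noise, not a tail
    steps = -np.ones(scan_end)
    for s, weight in weighted_lesions:
        steps[s] += weight
    walk = np.concatenate([[0.0], np.cumsum(steps)])
    # unaligned sequence left on both sides past the peak is terminal
    # evidence of a diverged tail even when it falls short of the
    # remainder rule on its own
    bonus = 0.0
    if rem_ref > 0 and rem_clone > 0:
        bonus = float(min(rem_ref, rem_clone, rules.tail_remainder_nt))
    walk = np.concatenate([walk, [walk[-1] + bonus]])
    run_min = np.minimum.accumulate(walk)
    rises = walk - run_min
    if persists and len(rises) and rises.max() >= rules.tail_rise_threshold:
        q = min(int(np.argmax(rises >= rules.tail_rise_threshold)), scan_end)
        p = int(np.argmin(walk[: q + 1]))  # earliest tie
        if violation is None or p < violation[0]:
            violation = (p, REASON_TAIL)

    if violation is not None:
        start, reason = violation
        undiv = int(ref_consumed_at[start])
        if rules.refine_breakpoint:
            undiv = min(
                undiv,
                _refine_breakpoint(weighted_lesions, ref_consumed_at, start, rules),
            )
        undiv = min(undiv, ref_len - 1) if ref_len > 0 else 0
        call = DivergenceCall(
            clone_id=alignment.clone_id,
            undiverged_length_nt=undiv,
            diverged=True,
            divergence_point_1based=undiv + 1,
            truncation=undiv < rules.truncation_threshold_nt,
            reason=reason,
        )
    else:
        undiv = int(ref_consumed_at[scan_end])
        if saw_indel:
            reason = REASON_TOLERATED_INDEL
        elif saw_sub:
            reason = REASON_TOLERATED_SUBS
        elif undiv < ref_len:
            reason = REASON_SHORTER
        else:
            reason = REASON_PERFECT
        call = DivergenceCall(
            clone_id=alignment.clone_id,
            undiverged_length_nt=undiv,
            diverged=False,
            divergence_point_1based=None,
            truncation=undiv < rules.truncation_threshold_nt,
            reason=reason,
        )
    return call


# ---------------------------------------------------------------------------
# reference selection and set-level calling


def _sorted_candidates(ts: TelomereSet) -> list[CloneSequence]:
    return sorted(ts.clones, key=lambda c: (-len(c.bases), c.clone_id))


def _candidate_demoted(cand: CloneSequence, calls: list[DivergenceCall]) -> bool:
    """A candidate is deemed itself divergent when the majority of the other
    clones diverge against it in a way that points at the candidate's own
    junction rather than at scattered per-clone events:

    * more than half of the others diverge with a divergence point in the
      candidate's proximal half (a proximal candidate event), or
    * more than half of the others diverge and their divergence points
      cluster tightly (the shared junction of a distal candidate event;
      independent per-clone events scatter their breakpoints).
    """
    diverged_points = [
        c.divergence_point_1based for c in calls if c.diverged
    ]
    n_others = len(calls)
    if 2 * len(diverged_points) <= n_others:
        return False
    half = len(cand.bases) / 2
    n_proximal = sum(1 for p in diverged_points if p <= half)
    if 2 * n_proximal > n_others:
        return True
    pts = np.asarray(diverged_points, dtype=float)
    mad = np.median(np.abs(pts - np.median(pts)))
    return mad <= 10.0


def _consensus_polish(reference: str, alignments: list[PairwiseAlignment]) -> str:
    """Correct a reference toward the set consensus by majority vote over
    aligned columns.

    Tolerated technical lesions on the reference read show up as the same
    lesion in every clone; a majority of clones agreeing on a substitution,
    a deletion of a reference base, or an insertion after a reference
    position overrides the reference.  Columns in free distal end-gap runs
    do not vote, and diverged tails cannot reach a majority because their
    sequences are mutually independent.
    """
    n_ref = len(reference)
    sub_votes: dict[int, dict[str, int]] = {}
    del_votes = np.zeros(n_ref, dtype=int)
    ins_votes: dict[int, dict[str, int]] = {}
    coverage = np.zeros(n_ref + 1, dtype=int)
    for aln in alignments:
        ref_pos = 0
        ins_buf: list[str] = []
        for idx, (r, c) in enumerate(aln.columns):
            if idx >= aln.free_tail_start:
                break
            if r is None:
                ins_buf.append(c)
                continue
            if ins_buf:
                d = ins_votes.setdefault(ref_pos, {})
                s = "".join(ins_buf)
                d[s] = d.get(s, 0) + 1
                ins_buf = []
            coverage[ref_pos] += 1
            if c is None:
                del_votes[ref_pos] += 1
            elif c != reference[ref_pos]:
                d = sub_votes.setdefault(ref_pos, {})
                d[c] = d.get(c, 0) + 1
            ref_pos += 1

    out: list[str] = []
    for pos in range(n_ref):
        cov = coverage[pos]
        ins = ins_votes.get(pos, {})
        if ins and cov >= 3:
            s, n = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            if 2 * n > cov:
                out.append(s)
        if cov >= 3 and 2 * del_votes[pos] > cov:
            continue
        subs = sub_votes.get(pos, {})
        if subs and cov >= 3:
            base, n = max(subs.items(), key=lambda kv: (kv[1], kv[0]))
            if 2 * n > cov:
                out.append(base)
                continue
        out.append(reference[pos])
    return "".join(out)


def _calls_against(
    reference_bases: str,
    reference_id: str,
    clones: list[CloneSequence],
    rules: DivergenceRules,
    scoring: AlignmentScoring | None,
    keep_alignments: bool = False,
):
    alns = {}
    calls = {}
    for o in clones:
        cols, score, tail = align_sequences(reference_bases, o.bases, scoring)
        aln = PairwiseAlignment(
            reference_id=reference_id,
            clone_id=o.clone_id,
            columns=cols,
            score=score,
            free_tail_start=tail,
        )
        calls[o.clone_id] = call_divergence(aln, rules)
        if keep_alignments:
            alns[o.clone_id] = aln
    return calls, alns


def _reference_and_calls(
    ts: TelomereSet,
    rules: DivergenceRules,
    scoring: AlignmentScoring | None,
) -> tuple[str, str, dict[str, DivergenceCall]]:
    """Returns (reference clone id, reference/consensus sequence, calls for
    every non-reference clone keyed by clone_id)."""
    if len(ts.clones) < 2:
        raise ValueError("reference selection requires at least 2 clones")
    candidates = _sorted_candidates(ts)
    chosen = None
    for cand in candidates:
        others = [c for c in ts.clones if c.clone_id != cand.clone_id]
        calls, alns = _calls_against(
            cand.bases, cand.clone_id, others, rules, scoring,
            keep_alignments=rules.consensus_polish,
        )
        if not _candidate_demoted(cand, list(calls.values())):
            chosen = (cand, others, calls, alns)
            break
    if chosen is None:
        warnings.warn(
            f"set ({ts.telomere_id}, {ts.strain_id}): every reference candidate "
            "was demoted; falling back to the longest clone",
            stacklevel=2,
        )
        cand = candidates[0]
        others = [c for c in ts.clones if c.clone_id != cand.clone_id]
        calls, alns = _calls_against(
            cand.bases, cand.clone_id, others, rules, scoring,
            keep_alignments=rules.consensus_polish,
        )
        chosen = (cand, others, calls, alns)
    cand, others, calls, alns = chosen
    ref_seq = cand.bases
    if rules.consensus_polish:
        polished = _consensus_polish(ref_seq, list(alns.values()))
        if polished != ref_seq:
            ref_seq = polished
            calls, _ = _calls_against(ref_seq, cand.clone_id, others, rules, scoring)
    return cand.clone_id, ref_seq, calls


def select_reference(
    ts: TelomereSet,
    rules: DivergenceRules | None = None,
    scoring: AlignmentScoring | None = None,
) -> str:
    """Choose the reference clone: the longest telomere without divergent
    sequence.

    Candidates are ranked by length (ties broken lexicographically by
    clone_id); a candidate that the majority of the set diverges against in
    a candidate-specific way (see :func:`_candidate_demoted`) is demoted and
    the next-longest is tried.  If every candidate is demoted the longest
    clone is returned with a warning.  Deterministic for fixed input.
    """
    ref_id, _, _ = _reference_and_calls(ts, rules or DivergenceRules(), scoring)
    return ref_id


def call_set_detailed(
    ts: TelomereSet,
    rules: DivergenceRules | None = None,
    scoring: AlignmentScoring | None = None,
) -> tuple[str, str, list[DivergenceCall]]:
    """Like :func:`call_set` but also returns the reference clone id and the
    (consensus-polished) reference sequence the calls are measured against."""
    rules = rules or DivergenceRules()
    ref_id, ref_seq, cached = _reference_and_calls(ts, rules, scoring)
    calls = []
    for clone in ts.clones:
        if clone.clone_id == ref_id:
            if clone.bases == ref_seq:
                call = DivergenceCall(
                    clone_id=clone.clone_id,
                    undiverged_length_nt=len(clone.bases),
                    diverged=False,
                    divergence_point_1based=None,
                    truncation=len(clone.bases) < rules.truncation_threshold_nt,
                    reason=REASON_PERFECT,
                )
            else:
                # the reference read differs from the polished consensus by
                # its own tolerated lesions; call it like any other clone
                calls_ref, _ = _calls_against(ref_seq, ref_id, [clone], rules, scoring)
                call = calls_ref[clone.clone_id]
        else:
            call = cached[clone.clone_id]
        call.telomere_id = ts.telomere_id
        call.strain_id = ts.strain_id
        call.genotype = ts.genotype
        call.generations = ts.generations
        call.clone_length_nt = len(clone.bases)
        calls.append(call)
    calls.sort(key=lambda c: (-c.undiverged_length_nt, c.clone_id))
    return ref_id, ref_seq, calls


def call_set(
    ts: TelomereSet,
    rules: DivergenceRules | None = None,
    scoring: AlignmentScoring | None = None,
) -> list[DivergenceCall]:
    """Call every clone of a telomere set against the selected reference.

    The reference receives a non-diverged call over its full length.  Output
    is sorted by undiverged length, descending (the bar-plot order), with
    ties broken by clone_id.
    """
    _, _, calls = call_set_detailed(ts, rules, scoring)
    return calls


def call_truncations(
    calls: Iterable[DivergenceCall], rules: DivergenceRules | None = None
) -> int:
    """Count calls with undiverged length strictly below the truncation
    threshold (biologically meaningful for telomerase-positive sets)."""
    rules = rules or DivergenceRules()
    return sum(1 for c in calls if c.undiverged_length_nt < rules.truncation_threshold_nt)
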