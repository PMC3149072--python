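"""Tandem-repeat detection and architecture modeling.

Detects tandem-repeat (TR) domains in protein sequences under an
XSTREAM-style parameter contract: minimum copy number ``minC``, minimum
per-copy character identity ``i``, minimum aggregate consensus match
``I``, maximum consecutive gap columns ``g``, and minimum domain length
``minD``.  The repeat model is explicit: a domain is a window ``[start,
end)`` read as consecutive copies of length ``period`` (the last copy may
be partial), summarized by a column-majority consensus.  Every emitted
domain satisfies the identity thresholds against that consensus, domains
are maximal (not extendable by one residue at either end without breaking
a threshold), and overlapping candidates are resolved to the
higher-scoring one (score = copy number x aggregate identity; ties go to
the longer, then leftmost, then shortest-period domain).

Candidate generation uses a lag-correlation anchor argument: in any
qualifying ungapped window every pair of adjacent full copies must agree
on at least ``2*ceil(i*p) - p`` positions, so window starts are confined
to runs of such anchors.  Within runs, windows are evaluated exactly with
an incremental column-count update, which keeps detection polynomial even
on highly repetitive sequences.

Gap support is an extension pass: maximal ungapped domains are extended
across small insertions/deletions (at most ``g`` consecutive gap columns)
by aligning flanking copies to the consensus, mirroring the way gapped TR
architectures are usually modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .seqio import SequenceRecord

GAP = "-"


@dataclass
class TRParams:
    """Detection thresholds.

    Defaults follow the parameterization used for large-scale plant
    secretome screens: minC=2, i=0.7, I=0.8, g=3, minD=12.
    """

    min_copy_number: float = 2.0
    min_char_identity: float = 0.7
    min_consensus_match: float = 0.8
    max_consecutive_gaps: int = 3
    min_domain_length: int = 12
    allow_gaps: bool = True
    max_period: int | None = None

    def __post_init__(self) -> None:
        if self.min_copy_number < 1:
            raise ValueError("min_copy_number must be >= 1")
        if not (0 <= self.min_char_identity <= 1):
            raise ValueError("min_char_identity must be in [0, 1]")
        if not (0 <= self.min_consensus_match <= 1):
            raise ValueError("min_consensus_match must be in [0, 1]")
        if self.max_consecutive_gaps < 0:
            raise ValueError("max_consecutive_gaps must be >= 0")
        if self.min_domain_length < 1:
            raise ValueError("min_domain_length must be >= 1")


@dataclass
class TRDomain:
    """A detected tandem-repeat domain.

    ``consensus`` has length ``period`` and may contain ``-`` for gap
    columns in gapped models; ``proline_fraction`` is the fraction of
    consensus positions that are proline.  ``copies`` stores the aligned
    copy rows (with ``-`` padding) used to build the consensus.
    """

    parent_id: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    domain_sequence: str
    proline_fraction: float = field(default=0.0)
    aggregate_identity: float = field(default=1.0)
    copies: list[str] = field(default_factory=list)
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.consensus) != self.period:
            raise ValueError("consensus length must equal period")
        self.proline_fraction = self.consensus.count("P") / self.period
        self.degenerate = self.period <= 3

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        """Overlap-resolution score: copies x aggregate identity."""
        return self.copy_number * self.aggregate_identity


def _column_consensus(column: Sequence[str]) -> str:
    """Majority symbol of a column; ties break to the symbol whose first
    occurrence, reading copies top-to-bottom, is earliest."""
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for k, c in enumerate(column):
        counts[c] = counts.get(c, 0) + 1
        if c not in first:
            first[c] = k
    return max(counts, key=lambda c: (counts[c], -first[c]))


class _WindowScan:
    """Incremental exact evaluation of windows with fixed period and start.

    Appends one residue at a time; after each append reports whether the
    current window ``[start, start+n)`` qualifies.  Maintains per-column
    occupant lists, the current consensus, and per-copy match counts so an
    append costs O(copies).
    """

    def __init__(self, seq: str, start: int, period: int, params: TRParams):
        self.seq = seq
        self.start = start
        self.p = period
        self.params = params
        self.columns: list[list[str]] = [[] for _ in range(period)]
        self.consensus: list[str] = [""] * period
        self.matches: list[int] = []  # per copy
        self.copy_len: list[int] = []  # residues filled per copy
        self.n = 0

    def append(self) -> None:
        p = self.p
        k, c = divmod(self.n, p)
        ch = self.seq[self.start + self.n]
        self.n += 1
        if c == 0:
            self.matches.append(0)
            self.copy_len.append(0)
        self.copy_len[k] += 1
        col = self.columns[c]
        col.append(ch)
        new_cons = _column_consensus(col)
        old_cons = self.consensus[c]
        if new_cons != old_cons:
            self.consensus[c] = new_cons
            # re-score every copy at this column
            for j, sym in enumerate(col):
                was = 1 if (old_cons and sym == old_cons) else 0
                now = 1 if sym == new_cons else 0
                self.matches[j] += now - was
        else:
            if ch == new_cons:
                self.matches[k] += 1

    def qualifies(self) -> bool:
        n, p, prm = self.n, self.p, self.params
        if n < prm.min_domain_length:
            return False
        if n / p < prm.min_copy_number:
            return False
        total = 0
        for j, m in enumerate(self.matches):
            ln = self.copy_len[j]
            if m < math.ceil(prm.min_char_identity * ln):
                return False
            total += m
        return total >= math.ceil(prm.min_consensus_match * n)

    def snapshot(self, parent_id: str) -> TRDomain:
        p = self.p
        rows = []
        for j in range(len(self.copy_len)):
            row = self.seq[self.start + j * p:self.start + j * p
                           + self.copy_len[j]]
            rows.append(row + GAP * (p - len(row)))
        total = sum(self.matches)
        return TRDomain(
            parent_id=parent_id,
            start=self.start,
            end=self.start + self.n,
            period=p,
            copy_number=self.n / p,
            consensus="".join(self.consensus),
            domain_sequence=self.seq[self.start:self.start + self.n],
            aggregate_identity=total / self.n,
            copies=rows,
        )


def _anchor_runs(seq: str, p: int, params: TRParams) -> list[list[int]]:
    """Runs of anchor positions for period ``p``.

    An anchor ``a`` marks an adjacent-copy pair ``seq[a:a+p]`` /
    ``seq[a+p:a+2p]`` whose mutual matches reach the lower bound implied
    by the per-copy identity threshold.  Runs collect anchors in the same
    phase spaced exactly ``p`` apart; any qualifying window's full-copy
    boundaries all lie on one run.
    """
    L = len(seq)
    threshold = max(2 * math.ceil(params.min_char_identity * p) - p, 0)
    lag = [1 if seq[j] == seq[j + p] else 0 for j in range(L - p)]
    # prefix sums of lag matches
    pref = [0]
    for v in lag:
        pref.append(pref[-1] + v)
    anchors = []
    for a in range(L - 2 * p + 1):
        if pref[a + p] - pref[a] >= threshold:
            anchors.append(a)
    runs: list[list[int]] = []
    by_phase: dict[int, list[int]] = {}
    for a in anchors:
        by_phase.setdefault(a % p, []).append(a)
    for phase_anchors in by_phase.values():
        run = [phase_anchors[0]]
        for a in phase_anchors[1:]:
            if a == run[-1] + p:
                run.append(a)
            else:
                runs.append(run)
                run = [a]
        runs.append(run)
    return runs


def _qualifying_windows(seq: str, params: TRParams,
                        parent_id: str) -> dict[tuple[int, int, int], TRDomain]:
    """All qualifying ungapped windows, keyed by (period, start, end)."""
    L = len(seq)
    max_p = params.max_period or L // 2
    max_p = min(max_p, L // 2,
                int(L // params.min_copy_number))
    found: dict[tuple[int, int, int], TRDomain] = {}
    min_len = max(params.min_domain_length, 1)
    for p in range(1, max_p + 1):
        for run in _anchor_runs(seq, p, params):
            e_max = min(L, run[-1] + 3 * p - 1)
            for s in run:
                if e_max - s < min_len:
                    continue
                scan = _WindowScan(seq, s, p, params)
                for e in range(s + 1, e_max + 1):
                    scan.append()
                    if e - s >= min_len and scan.qualifies():
                        found[(p, s, e)] = scan.snapshot(parent_id)
    return found


def _maximal(found: dict[tuple[int, int, int], TRDomain]) -> list[TRDomain]:
    """Keep windows not extendable by one residue at either end."""
    out = []
    for (p, s, e), dom in found.items():
        if (p, s - 1, e) in found or (p, s, e + 1) in found:
            continue
        out.append(dom)
    return out


def _resolution_key(d: TRDomain):
    return (-d.score, -(d.end - d.start), d.start, d.period)


def _resolve_overlaps(domains: list[TRDomain]) -> list[TRDomain]:
    """Greedy selection of non-overlapping domains by score."""
    chosen: list[TRDomain] = []
    for d in sorted(domains, key=_resolution_key):
        if all(d.end <= c.start or d.start >= c.end for c in chosen):
            chosen.append(d)
    chosen.sort(key=lambda d: d.start)
    return chosen


# ---------------------------------------------------------------------------
# gapped extension

def _align_copy(segment: str, consensus: str, g: int
                ) -> tuple[int, str, int] | None:
    """Globally align ``segment`` to ``consensus`` (match=1, mismatch=0,
    gaps free up to ``g`` consecutive).

    Returns (matches, aligned-row-with-gap-columns, n_insertions) or
    ``None`` when no alignment with <= g consecutive gaps exists.  The
    aligned row is expressed over consensus columns; insertions in the
    segment are reported so callers can open new columns.
    """
    m, n = len(segment), len(consensus)
    if abs(m - n) > g:
        return None
    NEG = float("-inf")
    # DP over (i, j): segment prefix i vs consensus prefix j
    score = [[NEG] * (n + 1) for _ in range(m + 1)]
    back = [[None] * (n + 1) for _ in range(m + 1)]
    score[0][0] = 0.0
    eps = 1e-3  # small gap penalty: prefer fewer gaps among equal matches
    for i in range(m + 1):
        for j in range(n + 1):
            if score[i][j] == NEG:
                continue
            cur = score[i][j]
            if i < m and j < n:
                sc = cur + (1.0 if segment[i] == consensus[j] else 0.0)
                if sc > score[i + 1][j + 1]:
                    score[i + 1][j + 1] = sc
                    back[i + 1][j + 1] = "D"
            if i < m:
                sc = cur - eps
                if sc > score[i + 1][j]:
                    score[i + 1][j] = sc
                    back[i + 1][j] = "I"  # insertion in segment
            if j < n:
                sc = cur - eps
                if sc > score[i][j + 1]:
                    score[i][j + 1] = sc
                    back[i][j + 1] = "G"  # gap in segment
    if score[m][n] == NEG:
        return None
    # traceback
    ops = []
    i, j = m, n
    while i > 0 or j > 0:
        op = back[i][j]
        ops.append(op)
        if op == "D":
            i, j = i - 1, j - 1
        elif op == "I":
            i -= 1
        else:
            j -= 1
    ops.reverse()
    # enforce max consecutive gaps
    run = 0
    for op in ops:
        if op in ("I", "G"):
            run += 1
            if run > g:
                return None
        else:
            run = 0
    row = []
    i = 0
    matches = 0
    insertions = 0
    for op in ops:
        if op == "D":
            row.append(segment[i])
            i += 1
        elif op == "G":
            row.append(GAP)
        else:  # I: insertion relative to consensus
            row.append("+" + segment[i])  # marked, expanded by caller
            i += 1
            insertions += 1
    aligned = "".join(row)
    # count matches over consensus columns
    ci = 0
    for ch in row:
        if ch.startswith("+"):
            continue
        if ch != GAP and ch == consensus[ci]:
            matches += 1
        ci += 1
    return matches, aligned, insertions


def _expand_rows(rows: list[str]) -> tuple[list[str], int]:
    """Expand '+x' insertion markers into real columns shared by all rows.

    Returns the rectangular alignment and its column count.
    """
    # determine, per consensus column index, the max insertions before it
    parsed = []
    for row in rows:
        cells: list[tuple[list[str], str | None]] = []
        pending: list[str] = []
        i = 0
        while i < len(row):
            if row[i] == "+":
                pending.append(row[i + 1])
                i += 2
            else:
                cells.append((pending, row[i]))
                pending = []
                i += 1
        cells.append((pending, None))  # trailing insertions
        parsed.append(cells)
    ncols = max(len(c) for c in parsed) - 1
    ins_before = [0] * (ncols + 1)
    for cells in parsed:
        for idx, (pend, _) in enumerate(cells):
            if pend:
                ins_before[idx] = max(ins_before[idx], len(pend))
    out_rows = []
    for cells in parsed:
        out = []
        for idx in range(ncols + 1):
            pend, sym = (cells[idx] if idx < len(cells) else ([], None))
            out.append("".join(pend) + GAP * (ins_before[idx] - len(pend)))
            if idx < ncols:
                out.append(sym if sym is not None else GAP)
        out_rows.append("".join(out))
    width = len(out_rows[0])
    return out_rows, width


def _extend_with_gaps(seq: str, dom: TRDomain, params: TRParams,
                      parent_id: str) -> TRDomain:
    """Extend an ungapped domain across indels at its flanks."""
    g = params.max_consecutive_gaps
    if g == 0:
        return dom
    i_thr = params.min_char_identity
    cons = dom.consensus
    p = dom.period
    rows = list(dom.copies)
    start, end = dom.start, dom.end
    # a trailing partial copy can straddle an indel; trim it and let the
    # gap-aware extension re-read that stretch as aligned full copies
    if rows and GAP in rows[-1]:
        filled = p - rows[-1].count(GAP)
        end -= filled
        rows = rows[:-1]
        if not rows:
            return dom
    trimmed_end = end
    # rightward
    changed = True
    while changed:
        changed = False
        best = None
        for ln in range(max(1, p - g), min(p + g, len(seq) - end) + 1):
            res = _align_copy(seq[end:end + ln], cons, g)
            if res is None:
                continue
            matches, aligned, _ = res
            if matches >= math.ceil(i_thr * p):
                cand = (matches, -abs(ln - p), -ln, ln, aligned)
                if best is None or cand > best:
                    best = cand
        if best is not None:
            ln, aligned = best[3], best[4]
            rows.append(aligned)
            end += ln
            changed = True
    # leftward
    changed = True
    while changed:
        changed = False
        best = None
        for ln in range(max(1, p - g), min(p + g, start) + 1):
            res = _align_copy(seq[start - ln:start], cons, g)
            if res is None:
                continue
            matches, aligned, _ = res
            if matches >= math.ceil(i_thr * p):
                cand = (matches, -abs(ln - p), -ln, ln, aligned)
                if best is None or cand > best:
                    best = cand
        if best is not None:
            ln, aligned = best[3], best[4]
            rows.insert(0, aligned)
            start -= ln
            changed = True
    if start >= dom.start and end <= dom.end:
        # no net growth over the ungapped model: keep the original
        return dom
    expanded, width = _expand_rows(rows)
    consensus = "".join(
        _column_consensus([r[c] for r in expanded]) for c in range(width))
    matches = 0
    compared = 0
    per_copy_ok = True
    for r in expanded:
        cm = sum(1 for a, b in zip(r, consensus)
                 if a != GAP and b != GAP and a == b)
        cc = sum(1 for a, b in zip(r, consensus)
                 if a != GAP and b != GAP)
        if cc and cm < math.ceil(i_thr * cc):
            per_copy_ok = False
        matches += cm
        compared += cc
    if not per_copy_ok or compared == 0 or (
            matches / compared < params.min_consensus_match):
        return dom
    new = TRDomain(
        parent_id=parent_id,
        start=start,
        end=end,
        period=width,
        copy_number=(end - start) / width if width else 0.0,
        consensus=consensus,
        domain_sequence=seq[start:end],
        aggregate_identity=matches / compared,
        copies=expanded,
    )
    # adopt the gapped model only when it explains the sequence better
    # than the ungapped one (free-ish gaps must not degrade clean repeats)
    return new if new.score > dom.score else dom


# ---------------------------------------------------------------------------
# public API

def detect_repeats(seq: SequenceRecord | str,
                   params: TRParams | None = None) -> list[TRDomain]:
    """Detect tandem-repeat domains in a protein sequence.

    Returns non-overlapping maximal domains sorted by start coordinate.
    Sequences shorter than ``min_domain_length`` yield an empty list.
    Degenerate periods (1-3) are detected and flagged; downstream
    clustering excludes them.
    """
    params = params or TRParams()
    if isinstance(seq, str):
        seq = SequenceRecord(id="", sequence=seq)
    s = seq.sequence
    if len(s) < params.min_domain_length:
        return []
    windows = _qualifying_windows(s, params, seq.id)
    maximal = _maximal(windows)
    chosen = _resolve_overlaps(maximal)
    if params.allow_gaps and params.max_consecutive_gaps > 0:
        extended = [_extend_with_gaps(s, d, params, seq.id) for d in chosen]
        chosen = _resolve_overlaps(extended)
    return chosen


def model_period(domain: TRDomain, gap_free: bool = False) -> int:
    """Period of a domain, optionally remodeled without gap columns.

    With ``gap_free=True`` columns whose consensus symbol is a gap are
    discarded before measuring the period, matching gap-free periodicity
    histograms; otherwise the stored period is returned unchanged.
    """
    if not gap_free:
        return domain.period
    return sum(1 for c in domain.consensus if c != GAP)


def domains_to_table(domains: list[TRDomain]):
    """TR domains as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [{
            "parent_id": d.parent_id,
            "start": d.start,
            "end": d.end,
            "period": d.period,
            "copy_number": round(d.copy_number, 4),
            "consensus": d.consensus,
            "proline_fraction": round(d.proline_fraction, 4),
        } for d in domains],
        columns=["parent_id", "start", "end", "period", "copy_number",
                 "consensus", "proline_fraction"],
    )
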