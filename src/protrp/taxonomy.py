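"""Regex-based TR class taxonomy, periodicity classes, and proline
backbone categories.

TR classes are written in a compact pattern mini-syntax:

* a bare residue letter matches itself (``P``);
* ``[ST]`` matches any listed residue; ``[^P]`` matches any residue
  except those listed; ``.`` matches any residue;
* an atom may carry a bounded repetition ``{m,n}`` (or ``{m}``), e.g.
  ``P{3,4}`` for three to four consecutive prolines;
* ``[AP|ST]`` is a multi-motif alternation: either motif matches;
* an optional trailing ``and not [HY]`` lists residues whose presence
  anywhere in the scanned motif vetoes the match.

Matching is phase-insensitive: the inclusion pattern is searched within
the doubled consensus string (``s + s`` truncated to ``2*len(s) - 1``),
which exposes every cyclic rotation without enumerating them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seqio import AMINO_ACIDS
from .trdetect import TRDomain, model_period


class PatternSyntaxError(ValueError):
    """Mini-syntax parse error with the offending position."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (position {position})")


@dataclass(frozen=True)
class Atom:
    """One pattern element: a literal, class, wildcard, or motif
    alternation, with repetition bounds."""

    kind: str                      # literal | class | negclass | any | alt
    payload: tuple[str, ...] = ()
    min_rep: int = 1
    max_rep: int = 1

    def to_regex(self) -> str:
        if self.kind == "literal":
            core = re.escape(self.payload[0])
        elif self.kind == "any":
            core = "."
        elif self.kind == "class":
            core = "[" + "".join(self.payload) + "]"
        elif self.kind == "negclass":
            core = "[^" + "".join(self.payload) + "]"
        else:  # alt
            core = "(?:" + "|".join(self.payload) + ")"
        if (self.min_rep, self.max_rep) == (1, 1):
            return core
        if self.min_rep == self.max_rep:
            return f"{core}{{{self.min_rep}}}"
        return f"{core}{{{self.min_rep},{self.max_rep}}}"

    def to_canonical(self) -> str:
        if self.kind == "literal":
            core = self.payload[0]
        elif self.kind == "any":
            core = "."
        elif self.kind == "class":
            core = "[" + "".join(self.payload) + "]"
        elif self.kind == "negclass":
            core = "[^" + "".join(self.payload) + "]"
        else:
            core = "[" + "|".join(self.payload) + "]"
        if (self.min_rep, self.max_rep) == (1, 1):
            return core
        if self.min_rep == self.max_rep:
            return f"{core}{{{self.min_rep}}}"
        return f"{core}{{{self.min_rep},{self.max_rep}}}"


@dataclass
class RegexClassDef:
    """A named TR class: inclusion pattern plus optional exclusion
    residues ('and not [..]')."""

    name: str
    inclusion: list[Atom]
    exclusion_residues: frozenset[str] = frozenset()
    _compiled: re.Pattern = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self._compiled = re.compile(
            "".join(a.to_regex() for a in self.inclusion))

    @property
    def canonical(self) -> str:
        body = "".join(a.to_canonical() for a in self.inclusion)
        if self.exclusion_residues:
            body += " and not [" + "".join(
                sorted(self.exclusion_residues)) + "]"
        return body


_VALID_RESIDUES = set(AMINO_ACIDS)


def parse_class_def(text: str, name: str = "") -> RegexClassDef:
    """Parse one class definition in the mini-syntax.

    ``text`` may be ``"name<TAB>expression"`` or a bare expression with
    the name passed separately.
    """
    if "\t" in text:
        name, text = text.split("\t", 1)
    text = text.strip()
    exclusion: frozenset[str] = frozenset()
    lowered = text.lower()
    marker = lowered.rfind(" and not ")
    if marker != -1:
        tail = text[marker + len(" and not "):].strip()
        if not (tail.startswith("[") and tail.endswith("]")):
            raise PatternSyntaxError("exclusion must be '[..]'", marker)
        residues = tail[1:-1]
        _check_residues(residues, marker + len(" and not ") + 1)
        if not residues:
            raise PatternSyntaxError("empty exclusion list", marker)
        exclusion = frozenset(residues)
        text = text[:marker].rstrip()
    atoms = _parse_elements(text)
    if not atoms:
        raise PatternSyntaxError("empty pattern", 0)
    return RegexClassDef(name=name, inclusion=atoms,
                         exclusion_residues=exclusion)


def _check_residues(residues: str, offset: int) -> None:
    for k, c in enumerate(residues):
        if c not in _VALID_RESIDUES:
            raise PatternSyntaxError(f"invalid residue {c!r}", offset + k)


def _parse_elements(text: str) -> list[Atom]:
    atoms: list[Atom] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == ".":
            atom = Atom("any")
            i += 1
        elif c in _VALID_RESIDUES:
            atom = Atom("literal", (c,))
            i += 1
        elif c == "[":
            close = text.find("]", i)
            if close == -1:
                raise PatternSyntaxError("unbalanced '['", i)
            inner = text[i + 1:close]
            if not inner or inner == "^":
                raise PatternSyntaxError("empty alternation", i)
            if inner.startswith("^"):
                _check_residues(inner[1:], i + 2)
                atom = Atom("negclass", tuple(inner[1:]))
            elif "|" in inner:
                motifs = inner.split("|")
                if any(not m for m in motifs):
                    raise PatternSyntaxError("empty alternation branch", i)
                for m in motifs:
                    _check_residues(m, i + 1)
                atom = Atom("alt", tuple(motifs))
            else:
                _check_residues(inner, i + 1)
                atom = Atom("class", tuple(inner))
            i = close + 1
        else:
            raise PatternSyntaxError(f"unexpected character {c!r}", i)
        # optional repetition
        if i < n and text[i] == "{":
            close = text.find("}", i)
            if close == -1:
                raise PatternSyntaxError("unbalanced '{'", i)
            body = text[i + 1:close]
            parts = body.split(",")
            try:
                if len(parts) == 1:
                    lo = hi = int(parts[0])
                elif len(parts) == 2:
                    lo, hi = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternSyntaxError(
                    f"malformed repetition {{{body}}}", i) from None
            if lo < 0 or hi < lo:
                raise PatternSyntaxError(
                    f"invalid repetition bounds {{{body}}}", i)
            atom = Atom(atom.kind, atom.payload, lo, hi)
            i = close + 1
        atoms.append(atom)
    return atoms


def load_class_definitions(path: str | Path | None = None
                           ) -> list[RegexClassDef]:
    """Load class definitions from a TSV ('name<TAB>expression' per
    line, '#' comments).  Without a path, the definitions shipped with
    the package are loaded."""
    if path is None:
        source = resources.files("protrp") / "data" / "tr_classes.tsv"
        lines = source.read_text().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    defs = []
    seen = set()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        d = parse_class_def(line)
        if d.name in seen:
            raise ValueError(f"duplicate class name {d.name!r}")
        seen.add(d.name)
        defs.append(d)
    return defs


def match_class(consensus: str, definition: RegexClassDef,
                rotate: bool = True) -> bool:
    """True iff the inclusion pattern matches within some cyclic
    rotation of the consensus and no exclusion residue occurs anywhere.

    With ``rotate=False`` the pattern is searched in the given string
    only (full-domain mode).
    """
    if definition.exclusion_residues & set(consensus):
        return False
    target = consensus + consensus[:-1] if rotate else consensus
    return definition._compiled.search(target) is not None


def assign_classes(domains: Sequence[TRDomain | str],
                   defs: Sequence[RegexClassDef],
                   rotate: bool = True) -> pd.DataFrame:
    """Assignment table of (domain, class) hits.

    Every matching class is recorded per domain (classes are designed to
    be specific, so multi-hits are worth reporting); unmatched domains
    appear once with an empty class and ``matched=False``.
    """
    rows = []
    for k, d in enumerate(domains):
        if isinstance(d, TRDomain):
            did = d.parent_id or str(k)
            consensus = d.consensus
        else:
            did, consensus = str(k), str(d)
        hits = [c.name for c in defs if match_class(consensus, c, rotate)]
        if hits:
            for h in hits:
                rows.append({"domain_id": did, "index": k,
                             "consensus": consensus, "tr_class": h,
                             "matched": True})
        else:
            rows.append({"domain_id": did, "index": k,
                         "consensus": consensus, "tr_class": "",
                         "matched": False})
    return pd.DataFrame(rows, columns=["domain_id", "index", "consensus",
                                       "tr_class", "matched"])


# ---------------------------------------------------------------------------
# periodicity

PERIOD_CLASSES = ("n", "n_plus_1", "n_minus_1")


def classify_period(period: int) -> str:
    """Periodicity class relative to the nearest multiple of 3.

    Multiples of 3 are class ``n``; one above, ``n_plus_1``; one below
    (period mod 3 == 2), ``n_minus_1``.  On an extended polyproline II
    helix, whose symmetry is trilateral, class n stacks repeat side
    groups in register while n+1 / n-1 spiral them by 120 degrees per
    repeat.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    return PERIOD_CLASSES[period % 3]


def periodicity_histogram(domains: Sequence[TRDomain],
                          gap_free: bool = False
                          ) -> tuple[pd.Series, dict[str, float]]:
    """Period counts and the n / n+1 / n-1 class fractions.

    With ``gap_free=True`` periods are remodeled without gap columns
    first, the convention used for periodicity distributions.
    """
    periods = [model_period(d, gap_free=gap_free) for d in domains]
    counts = pd.Series(periods, dtype=int).value_counts().sort_index()
    counts.index.name = "period"
    fractions = {c: 0.0 for c in PERIOD_CLASSES}
    if periods:
        for p in periods:
            fractions[classify_period(p)] += 1
        for c in fractions:
            fractions[c] /= len(periods)
    return counts, fractions


# ---------------------------------------------------------------------------
# proline backbone categories

BACKBONE_CATEGORIES = (
    "SPn", "TPn", "interspersed_P1", "regular_P2", "interspersed_P2_P1",
    "regular_P2_P3", "interspersed_P2_P3_P1", "other")


def _proline_runs(consensus: str) -> list[tuple[int, str | None]]:
    """(run length, preceding residue) for each linear proline run."""
    runs = []
    i = 0
    n = len(consensus)
    while i < n:
        if consensus[i] == "P":
            j = i
            while j < n and consensus[j] == "P":
                j += 1
            runs.append((j - i, consensus[i - 1] if i > 0 else None))
            i = j
        else:
            i += 1
    return runs


def backbone_category(consensus: str,
                      flank_fraction: float = 0.8) -> str:
    """Proline backbone category of a Pro-rich consensus.

    Categories are keyed by the linear proline run-length profile and
    the residues immediately preceding runs: SPn/TPn when at least
    ``flank_fraction`` of runs of length >= 2 follow Ser (resp. Thr);
    otherwise by which run lengths occur (1, 2, 3); ``other`` for
    consensi that are not Pro-rich or fit no profile.
    """
    runs = _proline_runs(consensus)
    if not runs or consensus.count("P") / max(len(consensus), 1) < 0.2:
        return "other"
    lengths = sorted({ln for ln, _ in runs})
    long_runs = [(ln, prev) for ln, prev in runs if ln >= 2]
    if not long_runs:
        return "interspersed_P1"
    for flank, cat in (("S", "SPn"), ("T", "TPn")):
        hits = sum(1 for _, prev in long_runs if prev == flank)
        if hits / len(long_runs) >= flank_fraction:
            return cat
    if lengths == [2]:
        return "regular_P2"
    if lengths == [1, 2]:
        return "interspersed_P2_P1"
    if lengths == [2, 3]:
        return "regular_P2_P3"
    if lengths == [1, 2, 3]:
        return "interspersed_P2_P3_P1"
    return "other"
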