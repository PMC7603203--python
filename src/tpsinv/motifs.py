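"""Catalytic-motif grammars of terpene synthases.

Terpene cyclases and prenyl transferases carry short aspartate-rich
metal-binding motifs that mark their catalytic strategy: ionization-dependent
Class I enzymes carry D[D/E]xx[D/E]-type motifs, protonation-dependent
Class II enzymes carry DxDD-type motifs, and bifunctional enzymes carry both.
This module compiles the printed consensus motifs into a small grammar
(amino-acid letters, ``x`` wildcard, ``[..]`` alternative sets), scans
protein sequences for all — possibly overlapping — matches, derives the
Class I / Class II / bifunctional fold call, counts structural QW motifs,
and detects the C-terminal transmembrane helix characteristic of squalene
synthases with a Kyte-Doolittle hydropathy window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL)

FOLD_CLASSES = ("class_I", "class_II", "accessory")


class GrammarError(ValueError):
    """Malformed motif grammar; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def compile_pattern(grammar: str) -> tuple[frozenset, ...]:
    """Compile a motif grammar into a tuple of allowed-residue sets.

    Plain letters match themselves, ``x`` matches any of the 20 canonical
    residues, and ``[DE]`` matches D or E.  Raises :class:`GrammarError`
    on empty grammars, unbalanced brackets, or non-canonical letters.
    """
    if not grammar:
        raise GrammarError("empty grammar", 0)
    positions: list[frozenset] = []
    i = 0
    while i < len(grammar):
        ch = grammar[i]
        if ch == "x":
            positions.append(_CANONICAL_SET)
            i += 1
        elif ch == "[":
            j = grammar.find("]", i + 1)
            if j < 0:
                raise GrammarError("unbalanced '['", i)
            alts = grammar[i + 1 : j]
            if not alts:
                raise GrammarError("empty alternative set", i)
            bad = set(alts) - _CANONICAL_SET
            if bad:
                raise GrammarError(f"non-canonical letters {sorted(bad)}", i)
            positions.append(frozenset(alts))
            i = j + 1
        elif ch == "]":
            raise GrammarError("unbalanced ']'", i)
        elif ch in _CANONICAL_SET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise GrammarError(f"unexpected character {ch!r}", i)
    return tuple(positions)


@dataclass(frozen=True)
class MotifPattern:
    """A named motif grammar tagged with the fold class it evidences."""

    name: str
    grammar: str
    fold_class: str = "accessory"
    compiled: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.fold_class not in FOLD_CLASSES:
            raise ValueError(f"unknown fold class {self.fold_class!r}")
        compiled = compile_pattern(self.grammar)
        if len(compiled) < 2:
            raise ValueError("motif grammars must span at least 2 positions")
        object.__setattr__(self, "compiled", compiled)

    def matches(self, fragment: str) -> bool:
        """True when ``fragment`` satisfies the grammar exactly."""
        if len(fragment) != len(self.compiled):
            return False
        return all(_residue_matches(r, allowed) for r, allowed in zip(fragment, self.compiled))


@dataclass(frozen=True)
class MotifHit:
    """One match of a motif grammar; ``start`` is 1-based inclusive."""

    pattern_name: str
    start: int
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


@dataclass(frozen=True)
class FoldCall:
    """Class I / Class II / bifunctional / none call with its evidence."""

    value: str
    evidence: tuple = ()


def _residue_matches(residue: str, allowed: frozenset) -> bool:
    # Ambiguity code X certifies nothing: it satisfies only full wildcards.
    if residue == "X":
        return allowed == _CANONICAL_SET
    return residue in allowed


def scan(seq: str, patterns: Iterable[MotifPattern]) -> list[MotifHit]:
    """Find every (possibly overlapping) motif match in ``seq``.

    Returns hits sorted by (start, pattern_name), positions 1-based.
    An empty sequence yields an empty list.
    """
    hits: list[MotifHit] = []
    n = len(seq)
    for pat in patterns:
        k = len(pat.compiled)
        for s in range(n - k + 1):
            window = seq[s : s + k]
            if all(_residue_matches(r, a) for r, a in zip(window, pat.compiled)):
                hits.append(MotifHit(pat.name, s + 1, window))
    hits.sort(key=lambda h: (h.start, h.pattern_name))
    return hits


def classify_fold(hits: Iterable[MotifHit], patterns: Iterable[MotifPattern]) -> FoldCall:
    """Derive the fold call from scanned hits.

    Purely a function of the fold-class tags present among the hits:
    both Class I and Class II evidence means a bifunctional enzyme;
    accessory motifs (QW, triads) never change the call.
    """
    tag_of = {p.name: p.fold_class for p in patterns}
    hits = tuple(hits)
    tags = {tag_of.get(h.pattern_name, "accessory") for h in hits}
    has1, has2 = "class_I" in tags, "class_II" in tags
    if has1 and has2:
        value = "bifunctional"
    elif has1:
        value = "class_I"
    elif has2:
        value = "class_II"
    else:
        value = "none"
    evidence = tuple(h for h in hits if tag_of.get(h.pattern_name) in ("class_I", "class_II"))
    return FoldCall(value, evidence)


def count_qw(seq: str) -> int:
    """Number of (possibly overlapping) QW structural motifs."""
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "QW")


# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def detect_tm_helix(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    cterm_fraction: float = 0.5,
) -> Optional[tuple[int, int]]:
    """Detect a C-terminal transmembrane helix by hydropathy.

    Slides a Kyte-Doolittle window of ``window`` residues over the C-terminal
    ``cterm_fraction`` of the sequence; windows whose mean hydropathy reaches
    ``threshold`` are marked, and the longest run of consecutive residues
    covered by marked windows is returned as ``(start, length)`` with a
    1-based start.  Returns ``None`` when no window passes or the sequence
    is shorter than the window.
    """
    if window < 7:
        raise ValueError("window must be >= 7 residues")
    n = len(seq)
    if n < window:
        return None
    region_start = n - max(window, int(math.ceil(n * cterm_fraction)))
    region_start = max(region_start, 0)
    values = [KYTE_DOOLITTLE.get(r, 0.0) for r in seq]
    covered = [False] * n
    any_hit = False
    running = sum(values[region_start : region_start + window])
    for s in range(region_start, n - window + 1):
        if s > region_start:
            running += values[s + window - 1] - values[s - 1]
        if running / window >= threshold:
            any_hit = True
            for k in range(s, s + window):
                covered[k] = True
    if not any_hit:
        return None
    best_start, best_len, cur_start = 0, 0, None
    for i in range(n + 1):
        if i < n and covered[i]:
            if cur_start is None:
                cur_start = i
        elif cur_start is not None:
            if i - cur_start > best_len:
                best_start, best_len = cur_start, i - cur_start
            cur_start = None
    return best_start + 1, best_len


def default_motifs() -> list[MotifPattern]:
    """The bundled motif set (aspartate-rich variants, triads, QW, TM-free)."""
    text = resources.files("tpsinv.data").joinpath("motifs.tsv").read_text()
    return parse_motif_table(text)


def parse_motif_table(text: str) -> list[MotifPattern]:
    """Parse the plain-text motif config: name, grammar, fold_class (TSV)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"motif table line {lineno}: expected 3 tab-separated fields")
        out.append(MotifPattern(parts[0], parts[1], parts[2]))
    names = [p.name for p in out]
    if len(names) != len(set(names)):
        raise ValueError("duplicate motif names in table")
    return out


def write_motif_table(patterns: Sequence[MotifPattern]) -> str:
    return "\n".join(f"{p.name}\t{p.grammar}\t{p.fold_class}" for p in patterns) + "\n"
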