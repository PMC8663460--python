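"""Mini-terminology handling: surface-form lexicon, is-a hierarchy, closure.

The lexicon maps normalized surface terms to terminology codes (ICD-9 or
SNOMED CT); the hierarchy is an is-a DAG over codes. ``subtype_closure``
returns a code together with all transitive descendants, the semantics used
to interpret "a code with all subtypes" when querying note-derived evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

SYSTEMS = ("ICD9", "SCT")

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*")


def normalize_term(term: str) -> str:
    """Case-fold, strip punctuation at token boundaries, collapse whitespace."""
    return " ".join(m.group(0) for m in _TOKEN_RE.finditer(term.casefold()))


def term_tokens(term: str) -> tuple[str, ...]:
    return tuple(normalize_term(term).split())


@dataclass(frozen=True)
class LexiconEntry:
    term: str  # normalized surface form
    code: str
    system: str


class Lexicon:
    """Immutable collection of (surface term, code, system) entries.

    Maintains a token-tuple index for the longest-match scanner: the key is
    the normalized token sequence of the term, the value the sorted list of
    (system, code) pairs sharing that surface form.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()):
        seen: dict[tuple[str, str], str] = {}
        ordered: list[LexiconEntry] = []
        for e in entries:
            if e.system not in SYSTEMS:
                raise ValueError(f"unknown coding system {e.system!r}")
            if not e.term:
                raise ValueError("empty surface term after normalization")
            key = (e.term, e.system)
            if key in seen:
                if seen[key] != e.code:
                    raise ValueError(
                        f"conflicting codes for {key}: {seen[key]} vs {e.code}")
                continue
            seen[key] = e.code
            ordered.append(e)
        self._entries = tuple(ordered)
        index: dict[tuple[str, ...], list[tuple[str, str]]] = {}
        for e in self._entries:
            index.setdefault(term_tokens(e.term), []).append((e.system, e.code))
        for v in index.values():
            v.sort()
        self._index = index
        self._max_len = max((len(k) for k in index), default=0)

    @property
    def entries(self) -> tuple[LexiconEntry, ...]:
        return self._entries

    @property
    def max_term_tokens(self) -> int:
        return self._max_len

    def lookup(self, tokens: tuple[str, ...]) -> list[tuple[str, str]]:
        """All (system, code) pairs whose term equals the token sequence."""
        return self._index.get(tokens, [])

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        term, code, system = triple
        return any(e.term == normalize_term(term) and e.code == code
                   and e.system == system for e in self._entries)


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a ``term<TAB>code<TAB>system`` TSV; ``#`` lines and blanks skipped."""
    entries: list[LexiconEntry] = []
    seen: dict[tuple[str, str], str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}")
            term, code, system = (p.strip() for p in parts[:3])
            norm = normalize_term(term)
            if not norm:
                raise ValueError(f"{path}:{lineno}: term empty after normalization")
            if system not in SYSTEMS:
                raise ValueError(f"{path}:{lineno}: unknown system {system!r}")
            prior = seen.get((norm, system))
            if prior is not None and prior != code:
                raise ValueError(
                    f"{path}:{lineno}: duplicate term {norm!r} ({system}) "
                    f"with conflicting code {code} (was {prior})")
            seen[(norm, system)] = code
            entries.append(LexiconEntry(norm, code, system))
    return Lexicon(entries)


def add_synonyms(lex: Lexicon,
                 pairs: Iterable[tuple[str, str, str]]) -> Lexicon:
    """Return a new lexicon extended with (term, code, system) synonyms.

    Existing entries are never altered; re-adding a present pair is a no-op
    and a conflicting code for an existing (term, system) raises.
    """
    new = list(lex.entries)
    for term, code, system in pairs:
        norm = normalize_term(term)
        new.append(LexiconEntry(norm, code, system))
    return Lexicon(new)


class Hierarchy:
    """Is-a DAG over codes; cycles are rejected at construction."""

    def __init__(self, edges: Iterable[tuple[str, str]], system: str = "SCT"):
        self.system = system
        self.edges: frozenset[tuple[str, str]] = frozenset(edges)
        children: dict[str, set[str]] = {}
        for child, parent in self.edges:
            children.setdefault(parent, set()).add(child)
            children.setdefault(child, set())
        self._children = children
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {n: WHITE for n in self._children}
        for root in self._children:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, iter]] = [(root, iter(self._children[root]))]
            color[root] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GRAY:
                        raise ValueError(f"cycle detected through code {nxt}")
                    if color[nxt] == WHITE:
                        color[nxt] = GRAY
                        stack.append((nxt, iter(self._children[nxt])))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def children_of(self, code: str) -> set[str]:
        return set(self._children.get(code, set()))

    def __contains__(self, code: str) -> bool:
        return code in self._children


def load_hierarchy(path: str | Path, system: str = "SCT") -> Hierarchy:
    """Read a ``child<TAB>parent[<TAB>system]`` TSV edge list."""
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns")
            edges.append((parts[0], parts[1]))
    return Hierarchy(edges, system=system)


def subtype_closure(code: str, h: Hierarchy | None) -> set[str]:
    """The code plus all transitive is-a descendants (itself for a leaf)."""
    out = {code}
    if h is None:
        return out
    frontier = [code]
    while frontier:
        node = frontier.pop()
        for child in h.children_of(node):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


def codeset_closure(codes: Iterable[str], h: Hierarchy | None) -> set[str]:
    out: set[str] = set()
    for c in codes:
        out |= subtype_closure(c, h)
    return out
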