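"""Dictionary-based concept extraction from clinical note text.

The coder works sentence by sentence: tokenize, then scan left to right
assigning at each position the longest lexicon term that starts there
(consumed tokens are not reused). A small NegEx-style rule flags mentions
preceded within a token window by a negation trigger, so that templated
"no <condition>" sentences do not contribute evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .terminology import Hierarchy, Lexicon, normalize_term

#: Words whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset(
    "dr mr mrs ms st pt vs approx wk yr mg no e.g i.e".split())

DEFAULT_NEGATION_TRIGGERS = ("no", "denies", "without", "negative for", "not")
DEFAULT_NEGATION_WINDOW = 5

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*")


@dataclass(frozen=True)
class TokenSpan:
    text: str
    start: int  # 0-based character offset into the full text
    end: int    # half-open
    sentence_index: int = 0

    @property
    def norm(self) -> str:
        return self.text.casefold()


@dataclass(frozen=True)
class CodedMention:
    code: str
    system: str
    token_start: int  # token index range within the sentence, half-open
    token_end: int
    char_span: tuple[int, int]
    negated: bool = False


def segment_sentences(text: str) -> list[tuple[str, int]]:
    """Split on ``.!?`` and newlines with an abbreviation guard.

    Returns (sentence, start_offset) pairs; joining the sentences with the
    intervening whitespace reconstructs the input.
    """
    sentences: list[tuple[str, int]] = []
    start = 0
    i = 0
    n = len(text)

    def flush(end: int) -> None:
        nonlocal start
        chunk = text[start:end]
        stripped = chunk.strip()
        if stripped:
            lead = len(chunk) - len(chunk.lstrip())
            sentences.append((stripped, start + lead))
        start = end

    while i < n:
        ch = text[i]
        if ch == "\n":
            flush(i)
            start = i + 1
            i += 1
            continue
        if ch in ".!?":
            if ch == ".":
                m = re.search(r"(\S+)$", text[start:i])
                word = m.group(1).casefold().rstrip(".") if m else ""
                if word in ABBREVIATIONS or re.fullmatch(r"[a-z]", word or "-"):
                    i += 1
                    continue
            flush(i + 1)
            i += 1
            continue
        i += 1
    flush(n)
    return sentences


def tokenize(sentence: str, base_offset: int = 0,
             sentence_index: int = 0) -> list[TokenSpan]:
    """Maximal alphanumeric runs; hyphens and apostrophes kept internal."""
    return [
        TokenSpan(m.group(0), base_offset + m.start(), base_offset + m.end(),
                  sentence_index)
        for m in _TOKEN_RE.finditer(sentence)
    ]


def match_concepts(tokens: list[TokenSpan], lex: Lexicon) -> list[CodedMention]:
    """Greedy left-to-right longest-match assignment of lexicon codes.

    At each token position the longest entry starting there wins; among
    equal-length candidates the lexicographically smallest (system, code)
    pair is chosen. Consumed tokens are not reused.
    """
    mentions: list[CodedMention] = []
    n = len(tokens)
    i = 0
    max_len = lex.max_term_tokens
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(t.norm for t in tokens[i:i + length])
            candidates = lex.lookup(key)
            if candidates:
                system, code = candidates[0]  # sorted; smallest wins ties
                mentions.append(CodedMention(
                    code=code, system=system,
                    token_start=i, token_end=i + length,
                    char_span=(tokens[i].start, tokens[i + length - 1].end)))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def _trigger_end_positions(tokens: list[TokenSpan],
                           triggers: tuple[str, ...]) -> list[int]:
    """Token indices (of the trigger's last token) where a trigger occurs."""
    norm = [t.norm for t in tokens]
    ends: list[int] = []
    for trig in triggers:
        parts = tuple(normalize_term(trig).split())
        L = len(parts)
        for i in range(len(norm) - L + 1):
            if tuple(norm[i:i + L]) == parts:
                ends.append(i + L - 1)
    return ends


def detect_negation(mentions: list[CodedMention], tokens: list[TokenSpan],
                    triggers: tuple[str, ...] = DEFAULT_NEGATION_TRIGGERS,
                    window: int = DEFAULT_NEGATION_WINDOW) -> list[CodedMention]:
    """Flag mentions with a trigger within ``window`` tokens before them."""
    ends = _trigger_end_positions(tokens, triggers)
    out: list[CodedMention] = []
    for m in mentions:
        negated = any(0 <= m.token_start - e <= window for e in ends
                      if e < m.token_start)
        out.append(replace(m, negated=negated))
    return out


def extract_mentions(text: str, lex: Lexicon,
                     triggers: tuple[str, ...] = DEFAULT_NEGATION_TRIGGERS,
                     window: int = DEFAULT_NEGATION_WINDOW) -> list[CodedMention]:
    """Full per-note extraction: segment, tokenize, match, negate."""
    mentions: list[CodedMention] = []
    for s_idx, (sentence, offset) in enumerate(segment_sentences(text)):
        tokens = tokenize(sentence, base_offset=offset, sentence_index=s_idx)
        found = match_concepts(tokens, lex)
        mentions.extend(detect_negation(found, tokens, triggers, window))
    return mentions


def code_note(note, lex: Lexicon, h: Hierarchy | None = None,
              triggers: tuple[str, ...] = DEFAULT_NEGATION_TRIGGERS,
              window: int = DEFAULT_NEGATION_WINDOW) -> set[tuple[str, str]]:
    """Non-negated (system, code) pairs mentioned anywhere in a note.

    ``note`` is anything with a ``text`` attribute (or a plain string). The
    hierarchy is accepted for interface symmetry with downstream queries;
    closure is applied at query time, not here.
    """
    text = note if isinstance(note, str) else note.text
    return {(m.system, m.code)
            for m in extract_mentions(text, lex, triggers, window)
            if not m.negated}
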