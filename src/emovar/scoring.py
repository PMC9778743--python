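"""Per-document linguistic scores and base-rate-normalized emotion indices.

The linguistic score of emotion *m* for a document is the percentage of
its token positions matched by *m*'s lexicon (a phrase counts as one
match and consumes its tokens).  Daily indices report the mean percent
deviation of those scores from the platform base rate p_B:

    index(d, m) = (100 / |T_d|) * sum_t (p_m(t) - p_B(m)) / p_B(m)

where T_d is the set of scorable documents on date d.  Weekly indices
are arithmetic means of daily indices over consecutive 7-day blocks.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .documents import Document, document_date
from .errors import EmptySeriesError, GapError, UnscorableDocument
from .lexicon import EmotionEntry, Lexicon

__all__ = [
    "tokenize",
    "score_document",
    "score_documents",
    "daily_emotion_index",
    "weekly_emotion_index",
    "EmotionScoreVector",
    "DailyEmotionSeries",
    "WeeklyEmotionSeries",
]

# Emoticons recognized even when absent from the lexicon; the lexicon's
# own emoticon entries are added to this list at tokenization time.
BUILTIN_EMOTICONS = (
    ":)", ":(", ":-)", ":-(", ":'(", ">:(", "):", "(:", ":D", "D:",
    ":/", ":|", ";)", ";-)", "<3",
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# a token is letters/digits possibly joined by internal apostrophes
_WORD_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)

_emoticon_re_cache: dict[frozenset, re.Pattern] = {}


def _emoticon_regex(extra: frozenset[str]) -> re.Pattern:
    try:
        return _emoticon_re_cache[extra]
    except KeyError:
        pats = sorted(set(BUILTIN_EMOTICONS) | set(extra), key=len, reverse=True)
        rx = re.compile("|".join(re.escape(p) for p in pats))
        _emoticon_re_cache[extra] = rx
        return rx


def _word_tokens(segment: str) -> list[str]:
    segment = segment.replace("’", "'").lower()
    return _WORD_RE.findall(segment)


def tokenize(text: str, extra_emoticons: frozenset[str] = frozenset()) -> list[str]:
    """Deterministic token sequence for a raw short text.

    URLs and @-mentions are dropped first (a URL's ``://`` would
    otherwise be read as an emoticon); then emoticons are extracted and
    kept verbatim, in position; finally hashtags keep their word part
    and the remainder is lowercased and split on anything that is not a
    letter, digit, or internal apostrophe.
    """
    if not text:
        return []
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    rx = _emoticon_regex(extra_emoticons)
    tokens: list[str] = []
    pos = 0
    for m in rx.finditer(text):
        tokens.extend(_word_tokens(text[pos:m.start()]))
        tokens.append(m.group(0))
        pos = m.end()
    tokens.extend(_word_tokens(text[pos:]))
    return tokens


@dataclass(frozen=True)
class EmotionScoreVector:
    """Per-document linguistic scores: percent of tokens matched per emotion."""

    id: str
    token_count: int
    scores: dict[str, float]


class _EntryMatcher:
    """Compiled matcher for one emotion's entry classes."""

    __slots__ = ("words", "emoticons", "prefix_re", "phrases")

    def __init__(self, entry: EmotionEntry):
        self.words = entry.literal_words
        self.emoticons = entry.emoticons
        if entry.prefix_patterns:
            alts = sorted(entry.prefix_patterns, key=len, reverse=True)
            self.prefix_re = re.compile("|".join(re.escape(p) for p in alts))
        else:
            self.prefix_re = None
        # longest phrase first: greedy matching
        self.phrases = sorted(
            (tuple(ph.split()) for ph in entry.phrases),
            key=len, reverse=True,
        )

    def count(self, tokens: Sequence[str]) -> int:
        """Matched word events; a phrase consumes its tokens, counts once."""
        n = len(tokens)
        count = 0
        i = 0
        words, emoticons, prefix_re, phrases = (
            self.words, self.emoticons, self.prefix_re, self.phrases)
        while i < n:
            step = 1
            for ph in phrases:
                k = len(ph)
                if i + k <= n and tuple(tokens[i:i + k]) == ph:
                    count += 1
                    step = k
                    break
            else:
                t = tokens[i]
                if (t in words or t in emoticons
                        or (prefix_re is not None and prefix_re.match(t))):
                    count += 1
            i += step
        return count


class _LexiconMatcher:
    __slots__ = ("matchers", "emoticons")

    def __init__(self, lexicon: Lexicon):
        self.matchers = {m: _EntryMatcher(e) for m, e in lexicon.entries.items()}
        self.emoticons = lexicon.all_emoticons()


_matcher_cache: dict[int, tuple[Lexicon, _LexiconMatcher]] = {}


def _get_matcher(lexicon: Lexicon) -> _LexiconMatcher:
    cached = _matcher_cache.get(id(lexicon))
    if cached is not None and cached[0] is lexicon:
        return cached[1]
    matcher = _LexiconMatcher(lexicon)
    _matcher_cache[id(lexicon)] = (lexicon, matcher)
    return matcher


def score_document(doc: Document, lexicon: Lexicon) -> EmotionScoreVector:
    """Linguistic score per emotion: 100 x matched token positions / tokens.

    Raises :class:`UnscorableDocument` when the text tokenizes to zero
    tokens (the score's denominator is undefined).
    """
    matcher = _get_matcher(lexicon)
    tokens = tokenize(doc.text, matcher.emoticons)
    n = len(tokens)
    if n == 0:
        raise UnscorableDocument(f"document {doc.id!r} has no tokens")
    scores = {m: 100.0 * em.count(tokens) / n for m, em in matcher.matchers.items()}
    return EmotionScoreVector(id=doc.id, token_count=n, scores=scores)


def score_documents(
    docs: Iterable[Document], lexicon: Lexicon, tz: str = "UTC"
) -> tuple[pd.DataFrame, int]:
    """Score a collection; returns (table, n_skipped).

    The table has columns id, date, token_count and one column per
    emotion.  Zero-token documents are skipped and counted, not scored.
    """
    matcher = _get_matcher(lexicon)
    emotions = list(matcher.matchers)
    rows = []
    skipped = 0
    for doc in docs:
        tokens = tokenize(doc.text, matcher.emoticons)
        n = len(tokens)
        if n == 0:
            skipped += 1
            continue
        row = [doc.id, document_date(doc, tz=tz), n]
        row.extend(100.0 * matcher.matchers[m].count(tokens) / n for m in emotions)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["id", "date", "token_count", *emotions])
    return table, skipped


@dataclass(frozen=True)
class DailyEmotionSeries:
    """Date-indexed normalized emotion indices with per-date document counts."""

    data: pd.DataFrame  # index: date; columns: emotions + "n_documents"
    emotions: tuple[str, ...]
    n_skipped: int = 0

    def __post_init__(self):
        if (self.data["n_documents"] < 1).any():
            raise EmptySeriesError("a date with zero scored documents was included")


def daily_emotion_index(
    docs: Iterable[Document], lexicon: Lexicon, tz: str = "UTC"
) -> DailyEmotionSeries:
    """Base-rate-normalized daily emotion indices.

    For each date and emotion, the index is the mean over that date's
    scorable documents of 100 x (score - base_rate) / base_rate.
    """
    table, skipped = score_documents(docs, lexicon, tz=tz)
    return daily_index_from_scores(table, lexicon, n_skipped=skipped)


def daily_index_from_scores(
    table: pd.DataFrame, lexicon: Lexicon, n_skipped: int = 0
) -> DailyEmotionSeries:
    """Aggregate a per-document score table into daily indices."""
    emotions = list(lexicon.emotions)
    if table.empty:
        raise EmptySeriesError("no scorable documents")
    grouped = table.groupby("date")
    out = pd.DataFrame(index=sorted(grouped.groups))
    for m in emotions:
        pB = lexicon.entries[m].base_rate
        out[m] = 100.0 * (grouped[m].mean().reindex(out.index) - pB) / pB
    out["n_documents"] = grouped.size().reindex(out.index)
    out.index.name = "date"
    return DailyEmotionSeries(data=out, emotions=tuple(emotions), n_skipped=n_skipped)


@dataclass(frozen=True)
class WeeklyEmotionSeries:
    """Consecutive 7-day-block weekly means of the daily indices."""

    data: pd.DataFrame  # index: week 0..n-1; columns: emotions + "coverage"
    emotions: tuple[str, ...]
    start_date: dt.date


def weekly_emotion_index(
    daily: DailyEmotionSeries, start_date: dt.date, n_weeks: int
) -> WeeklyEmotionSeries:
    """Average daily indices over consecutive 7-day blocks.

    Week *w* spans ``start_date + 7w`` .. ``start_date + 7w + 6``; the
    weekly score is the mean of the block's available daily indices, and
    a block with no covered days raises :class:`GapError`.  Days beyond
    the last requested week are dropped.
    """
    if n_weeks < 1:
        raise EmptySeriesError("n_weeks must be >= 1")
    emotions = list(daily.emotions)
    dates = pd.Series(daily.data.index)
    offsets = (pd.to_datetime(dates) - pd.Timestamp(start_date)).dt.days
    rows = []
    for w in range(n_weeks):
        mask = (offsets >= 7 * w) & (offsets <= 7 * w + 6)
        block_dates = dates[mask.values]
        if block_dates.empty:
            raise GapError(w, "emotion daily series")
        block = daily.data.loc[list(block_dates)]
        rows.append([*(block[m].mean() for m in emotions), len(block)])
    out = pd.DataFrame(rows, columns=[*emotions, "coverage"])
    out.index.name = "week"
    return WeeklyEmotionSeries(data=out, emotions=tuple(emotions), start_date=start_date)
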