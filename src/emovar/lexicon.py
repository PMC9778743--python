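"""Emotion lexicon: word classes, prefix wildcards, phrases, emoticons.

A lexicon maps each emotion name to four entry classes plus a platform
base rate (in percent units).  A trailing ``*`` in a word entry denotes a
prefix wildcard: ``abhor*`` matches any token starting with ``abhor``.
Phrases are multi-token strings matched as one "word event".
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import LexiconError

__all__ = ["EmotionEntry", "Lexicon", "compile_lexicon", "fixture_lexicon"]


@dataclass(frozen=True)
class EmotionEntry:
    """Match sets and base rate for one emotion."""

    literal_words: frozenset[str]
    prefix_patterns: frozenset[str]
    phrases: frozenset[str]
    emoticons: frozenset[str]
    base_rate: float  # percent units, > 0

    def __post_init__(self):
        if not self.base_rate > 0:
            raise LexiconError(f"base_rate must be > 0, got {self.base_rate}")
        for name, entries in (
            ("words", self.literal_words),
            ("prefixes", self.prefix_patterns),
            ("phrases", self.phrases),
            ("emoticons", self.emoticons),
        ):
            for e in entries:
                if not e:
                    raise LexiconError(f"empty string in field '{name}'")
        for p in self.prefix_patterns:
            if any(c.isspace() for c in p):
                raise LexiconError(f"prefix pattern contains whitespace: {p!r}")
        for ph in self.phrases:
            if len(ph.split()) < 2:
                raise LexiconError(f"phrase must contain >= 2 tokens: {ph!r}")


@dataclass(frozen=True)
class Lexicon:
    """Ordered set of emotions with their match sets and base rates."""

    entries: dict[str, EmotionEntry] = field(default_factory=dict)

    def __post_init__(self):
        if not self.entries:
            raise LexiconError("emotion set is empty")
        for name in self.entries:
            if not name:
                raise LexiconError("emotion name is empty")

    @property
    def emotions(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def base_rates(self) -> dict[str, float]:
        return {m: e.base_rate for m, e in self.entries.items()}

    def all_emoticons(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.entries.values():
            out |= e.emoticons
        return frozenset(out)


_ENTRY_FIELDS = {"words", "prefixes", "phrases", "emoticons", "base_rate"}


def _build_entry(emotion: str, raw: dict) -> EmotionEntry:
    if not isinstance(raw, dict):
        raise LexiconError(f"emotion '{emotion}' must map to an object")
    unknown = set(raw) - _ENTRY_FIELDS
    if unknown:
        raise LexiconError(
            f"emotion '{emotion}': unknown field(s) {sorted(unknown)}"
        )
    if "base_rate" not in raw:
        raise LexiconError(f"emotion '{emotion}': missing base_rate")
    try:
        base_rate = float(raw["base_rate"])
    except (TypeError, ValueError):
        raise LexiconError(
            f"emotion '{emotion}': base_rate not a number: {raw['base_rate']!r}"
        ) from None
    if not base_rate > 0:
        raise LexiconError(
            f"emotion '{emotion}': base_rate must be > 0, got {base_rate}"
        )

    words: set[str] = set()
    prefixes: set[str] = set()
    for w in raw.get("words", []):
        w = str(w).strip().lower()
        if not w:
            raise LexiconError(f"emotion '{emotion}': empty word entry")
        if w.endswith("*"):
            stem = w[:-1]
            if not stem:
                raise LexiconError(f"emotion '{emotion}': bare '*' entry")
            prefixes.add(stem)
        elif " " in w:
            # multi-word entries in the word list are treated as phrases
            raw.setdefault("phrases", [])
            if w not in (str(p).lower() for p in raw["phrases"]):
                raw["phrases"] = list(raw["phrases"]) + [w]
        else:
            words.add(w)
    for p in raw.get("prefixes", []):
        p = str(p).strip().lower().rstrip("*")
        if not p:
            raise LexiconError(f"emotion '{emotion}': empty prefix entry")
        prefixes.add(p)
    phrases = set()
    for ph in raw.get("phrases", []):
        ph = " ".join(str(ph).lower().split())
        if not ph:
            raise LexiconError(f"emotion '{emotion}': empty phrase entry")
        phrases.add(ph)
    emoticons = set()
    for s in raw.get("emoticons", []):
        s = str(s).strip()
        if not s:
            raise LexiconError(f"emotion '{emotion}': empty emoticon entry")
        emoticons.add(s)

    # a literal word shadowed by a prefix of the same emotion is redundant
    words -= {w for w in words if any(w.startswith(p) for p in prefixes)}

    try:
        return EmotionEntry(
            literal_words=frozenset(words),
            prefix_patterns=frozenset(prefixes),
            phrases=frozenset(phrases),
            emoticons=frozenset(emoticons),
            base_rate=base_rate,
        )
    except LexiconError as exc:
        raise LexiconError(f"emotion '{emotion}': {exc}") from None


def compile_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from a JSON or YAML file.

    The expected shape is ``{"emotions": {"<name>": {"words": [...],
    "prefixes": [...], "phrases": [...], "emoticons": [...],
    "base_rate": <percent>}, ...}}``.  All entries are lowercased;
    duplicates within an emotion are deduplicated.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return lexicon_from_mapping(raw)


def lexicon_from_mapping(raw: dict) -> Lexicon:
    """Build a validated :class:`Lexicon` from an already-parsed mapping."""
    if not isinstance(raw, dict) or "emotions" not in raw:
        raise LexiconError("lexicon must contain an 'emotions' mapping")
    emotions = raw["emotions"]
    if not isinstance(emotions, dict) or not emotions:
        raise LexiconError("'emotions' mapping is empty")
    entries = {
        str(name): _build_entry(str(name), dict(spec))
        for name, spec in emotions.items()
    }
    return Lexicon(entries=entries)


def fixture_lexicon() -> Lexicon:
    """The lexicon shipped with the package (anger, anxiety, sadness).

    An open replacement for closed word-count dictionaries; base rates are
    the per-emotion averages observed on the synthetic reference corpus.
    """
    ref = resources.files("emovar.data").joinpath("fixture_lexicon.json")
    return lexicon_from_mapping(json.loads(ref.read_text(encoding="utf-8")))


def fixture_lexicon_path() -> Path:
    """Filesystem path of the shipped lexicon file."""
    return Path(str(resources.files("emovar.data").joinpath("fixture_lexicon.json")))
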