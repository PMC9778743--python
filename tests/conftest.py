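import datetime as dt
import random

import numpy as np
import pandas as pd
import pytest

from emovar import Document, WeeklyPanel, fixture_lexicon, tokenize
from emovar.simulate import build_truth, simulate_var_series


@pytest.fixture(scope="session")
def lexicon():
    return fixture_lexicon()


def brute_force_scores(text: str, lexicon) -> dict[str, float]:
    """Independent scorer: plain loops over every token position and every
    lexicon entry, sharing only the tokenizer with the implementation."""
    tokens = tokenize(text, lexicon.all_emoticons())
    n = len(tokens)
    out = {}
    for emotion, entry in lexicon.entries.items():
        matched = 0
        i = 0
        phrases = sorted((ph.split() for ph in entry.phrases),
                         key=len, reverse=True)
        while i < n:
            consumed = 1
            hit = False
            for ph in phrases:
                if i + len(ph) <= n and all(
                        tokens[i + k] == ph[k] for k in range(len(ph))):
                    hit = True
                    consumed = len(ph)
                    break
            if not hit:
                tok = tokens[i]
                for w in entry.literal_words:
                    if tok == w:
                        hit = True
                        break
                if not hit:
                    for pref in entry.prefix_patterns:
                        if tok.startswith(pref):
                            hit = True
                            break
                if not hit:
                    for e in entry.emoticons:
                        if tok == e:
                            hit = True
                            break
            if hit:
                matched += 1
            i += consumed
        out[emotion] = 100.0 * matched / n if n else 0.0
    return out


def random_document(rng: random.Random, lexicon, doc_id: str) -> Document:
    """A synthetic short text mixing lexicon entries of every class with
    neutral fillers, punctuation, hashtags, URLs and mentions."""
    pieces = []
    entries = list(lexicon.entries.values())
    for _ in range(rng.randint(1, 25)):
        kind = rng.random()
        entry = rng.choice(entries)
        if kind < 0.25 and entry.literal_words:
            pieces.append(rng.choice(sorted(entry.literal_words)))
        elif kind < 0.4 and entry.prefix_patterns:
            stem = rng.choice(sorted(entry.prefix_patterns))
            pieces.append(stem + rng.choice(["", "s", "ed", "ing", "xyz"]))
        elif kind < 0.5 and entry.phrases:
            pieces.append(rng.choice(sorted(entry.phrases)))
        elif kind < 0.6 and entry.emoticons:
            pieces.append(rng.choice(sorted(entry.emoticons)))
        elif kind < 0.7:
            pieces.append("#" + rng.choice(["covid19", "stayhome", "news"]))
        elif kind < 0.75:
            pieces.append(rng.choice(["http://x.co/ab", "@someone"]))
        else:
            pieces.append(rng.choice(["the", "a", "day", "lorem", "good", "123"]))
        if rng.random() < 0.3:
            pieces.append(rng.choice([",", ".", "!", "...", " - "]))
    text = " ".join(pieces)
    return Document(id=doc_id, timestamp=dt.date(2020, 3, 1), text=text)


def make_panel(y: np.ndarray, names=None, standardized=False) -> WeeklyPanel:
    """Wrap a raw (T, K) array as a weekly panel for estimator tests."""
    K = y.shape[1]
    if names is None:
        names = [f"v{i}" for i in range(K)]
    df = pd.DataFrame(y, columns=list(names))
    df.index.name = "week"
    return WeeklyPanel(data=df, start_date=dt.date(2020, 1, 21),
                       standardized=standardized)


def simulate_panel(A, sigma=None, T=200, seed=0, burn_in=50, names=None,
                   c=None) -> WeeklyPanel:
    """Simulate a stable VAR path and wrap it as a panel."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, K, _ = A.shape
    if sigma is None:
        sigma = np.eye(K)
    if names is None:
        names = tuple(f"v{i}" for i in range(K))
    truth = build_truth(
        scenario="null", T=T, seed=seed, burn_in=burn_in,
        A=A, sigma=np.asarray(sigma, dtype=float),
        c=None if c is None else np.asarray(c, dtype=float),
    )
    # build_truth derives names from the lexicon; rename for generic tests
    series = simulate_var_series(truth)
    series.columns = list(names)[:K]
    return make_panel(series.to_numpy(), names=list(names)[:K])
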