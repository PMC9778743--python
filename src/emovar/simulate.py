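"""Ground-truth synthetic study generator.

Produces the three inputs the analysis consumes — a tweet-like document
file, a lexicon, and a 0-100 behavior trends CSV — from a known latent
VAR so every pipeline stage can be verified end to end.  The latent
weekly state holds [behavior, <emotions...>]; emotion components are
percent-deviation indices that the corpus generator inverts into
per-token match probabilities

    q_m(d) = (p_B(m) / 100) * (1 + target_m(d) / 100)

so the expected daily index recovered by the scorer equals the latent
target.  Generated emotion tokens are single literal words, which makes
per-document scores exact binomial proportions with analytic moments.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .documents import Document
from .errors import EmovarError, InfeasibleTargetError, StabilityError
from .lexicon import Lexicon, fixture_lexicon, fixture_lexicon_path

__all__ = [
    "SimulationTruth",
    "StudyConfig",
    "SyntheticStudyBundle",
    "build_truth",
    "simulate_var_series",
    "weekly_to_daily_targets",
    "corpus_from_emotion_series",
    "synthesize_study",
    "SCENARIOS",
]

DEFAULT_VARIABLES = ("behavior", "anger", "anxiety", "sadness")
DEFAULT_START = dt.date(2020, 1, 21)
# innovation scale of the latent weekly indices (percent-deviation units);
# keeps 6-7 sigma excursions above the -100% feasibility floor
DEFAULT_INNOVATION_SD = 12.0


def _spectral_radius(A: np.ndarray) -> float:
    p, K, _ = A.shape
    F = np.zeros((K * p, K * p))
    for j in range(p):
        F[:K, j * K:(j + 1) * K] = A[j]
    if p > 1:
        F[K:, :K * (p - 1)] = np.eye(K * (p - 1))
    return float(np.abs(np.linalg.eigvals(F)).max())


@dataclass(frozen=True)
class SimulationTruth:
    """The generating law and corpus parameters of a synthetic study."""

    names: tuple[str, ...]
    c: np.ndarray        # (K,)
    A: np.ndarray        # (p, K, K)
    sigma: np.ndarray    # (K, K)
    T: int               # weeks
    burn_in: int
    seed: int
    docs_per_day: int
    tokens_per_doc: int
    base_rates: dict[str, float]
    start_date: dt.date = DEFAULT_START
    interpolation: str = "constant"  # daily targets from the weekly path
    behavior_affine: tuple[float, float] | None = None  # (lo, hi) of the 0-100 map

    @property
    def K(self) -> int:
        return len(self.names)

    @property
    def p(self) -> int:
        return self.A.shape[0]

    def __post_init__(self):
        if self.docs_per_day < 1 or self.tokens_per_doc < 1:
            raise EmovarError("docs_per_day and tokens_per_doc must be >= 1")
        if self.interpolation not in ("constant", "linear"):
            raise EmovarError(f"unknown interpolation {self.interpolation!r}")
        rho = _spectral_radius(self.A)
        if rho >= 1.0:
            raise StabilityError(f"truth is not stable (spectral radius {rho:.3f})")
        try:
            np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError:
            raise EmovarError("truth Sigma is not positive definite") from None

    def to_jsonable(self) -> dict:
        return {
            "names": list(self.names),
            "c": self.c.tolist(),
            "A": self.A.tolist(),
            "sigma": self.sigma.tolist(),
            "T": self.T,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "docs_per_day": self.docs_per_day,
            "tokens_per_doc": self.tokens_per_doc,
            "base_rates": self.base_rates,
            "start_date": self.start_date.isoformat(),
            "interpolation": self.interpolation,
            "behavior_affine": list(self.behavior_affine) if self.behavior_affine else None,
        }


def _scenario_null(K: int) -> tuple[np.ndarray, np.ndarray]:
    A = np.zeros((1, K, K))
    A[0] = 0.3 * np.eye(K)
    return A, DEFAULT_INNOVATION_SD ** 2 * np.eye(K)


def _scenario_anxiety_driver(K: int) -> tuple[np.ndarray, np.ndarray]:
    # behavior responds to lagged anxiety; sadness fully decoupled
    A = np.zeros((1, K, K))
    A[0] = 0.3 * np.eye(K)
    A[0, 0, 2] = 0.5
    return A, DEFAULT_INNOVATION_SD ** 2 * np.eye(K)


def _scenario_paper_like(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Qualitative structure of the study's findings: anxiety drives
    behavior strongly and positively, anger weakly and negatively with a
    3-week delay, behavior damps anxiety with a 2-3 week lag, and
    sadness is decoupled from behavior."""
    A = np.zeros((3, K, K))
    A[0] = 0.25 * np.eye(K)
    A[0, 0, 2] = 0.45    # anxiety -> behavior, lag 1
    A[1, 2, 0] = -0.15   # behavior -> anxiety, lag 2
    A[2, 2, 0] = -0.15   # behavior -> anxiety, lag 3
    A[2, 0, 1] = -0.15   # anger -> behavior, lag 3 (slight negative)
    A[2, 1, 0] = 0.05    # behavior -> anger, lag 3 (tiny)
    A[2] += 0.10 * np.eye(K)
    return A, DEFAULT_INNOVATION_SD ** 2 * np.eye(K)


SCENARIOS = {
    "null": _scenario_null,
    "anxiety-driver": _scenario_anxiety_driver,
    "paper-like": _scenario_paper_like,
}


def build_truth(
    scenario: str = "paper-like",
    T: int = 120,
    seed: int = 0,
    docs_per_day: int = 500,
    tokens_per_doc: int = 20,
    burn_in: int = 50,
    lexicon: Lexicon | None = None,
    start_date: dt.date = DEFAULT_START,
    interpolation: str = "constant",
    A: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    c: np.ndarray | None = None,
    names: tuple[str, ...] | None = None,
) -> SimulationTruth:
    """Assemble a validated :class:`SimulationTruth` from a named scenario
    preset or explicit coefficient matrices."""
    lex = lexicon if lexicon is not None else fixture_lexicon()
    if names is None:
        if A is not None and np.asarray(A).shape[-1] != 1 + len(lex.emotions):
            K_explicit = np.asarray(A).shape[-1]
            names = tuple(f"v{i}" for i in range(K_explicit))
        else:
            names = ("behavior", *lex.emotions)
    names = tuple(names)
    K = len(names)
    if A is None or sigma is None:
        if scenario not in SCENARIOS:
            raise EmovarError(
                f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
        A_s, sigma_s = SCENARIOS[scenario](K)
        A = A_s if A is None else np.asarray(A, dtype=float)
        sigma = sigma_s if sigma is None else np.asarray(sigma, dtype=float)
    else:
        A = np.asarray(A, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
    if c is None:
        c = np.zeros(K)
    return SimulationTruth(
        names=names, c=np.asarray(c, dtype=float), A=A, sigma=sigma,
        T=T, burn_in=burn_in, seed=seed,
        docs_per_day=docs_per_day, tokens_per_doc=tokens_per_doc,
        base_rates=dict(lex.base_rates), start_date=start_date,
        interpolation=interpolation,
    )


def simulate_var_series(
    truth: SimulationTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate burn_in + T steps of the latent VAR and drop the burn-in.

    y_t = c + sum_j A_j y_{t-j} + eps_t with Gaussian innovations of
    covariance Sigma; all randomness flows from the truth's seed unless
    an explicit generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    K, p, T = truth.K, truth.p, truth.T
    L = np.linalg.cholesky(truth.sigma)
    n = truth.burn_in + T
    eps = rng.standard_normal((n, K)) @ L.T
    y = np.zeros((n + p, K))
    c, A = truth.c, truth.A
    for t in range(p, n + p):
        acc = c + eps[t - p]
        for j in range(1, p + 1):
            acc = acc + A[j - 1] @ y[t - j]
        y[t] = acc
    out = pd.DataFrame(y[p + truth.burn_in:], columns=list(truth.names))
    out.index.name = "week"
    return out


def weekly_to_daily_targets(
    weekly: pd.DataFrame, start_date: dt.date, interpolation: str = "constant"
) -> pd.DataFrame:
    """Expand a weekly latent path to per-date targets.

    ``constant`` repeats the weekly value across its 7 days (weekly means
    are then preserved exactly); ``linear`` interpolates between mid-week
    anchors, which smooths the path at the cost of small edge effects on
    the recovered weekly means.
    """
    T = len(weekly)
    n_days = 7 * T
    dates = [start_date + dt.timedelta(days=i) for i in range(n_days)]
    cols = {}
    for col in weekly.columns:
        wv = weekly[col].to_numpy(dtype=float)
        if interpolation == "constant":
            daily = np.repeat(wv, 7)
        elif interpolation == "linear":
            anchors = 7.0 * np.arange(T) + 3.0  # mid-week anchor days
            days = np.arange(n_days, dtype=float)
            daily = np.interp(days, anchors, wv)
        else:
            raise EmovarError(f"unknown interpolation {interpolation!r}")
        cols[col] = daily
    out = pd.DataFrame(cols, index=pd.Index(dates, name="date"))
    return out


def _single_emotion_words(lexicon: Lexicon) -> dict[str, str]:
    """One deterministic generator word per emotion, matched by that
    emotion only (so generated scores are exact binomial proportions)."""
    from .scoring import score_document  # local import avoids a cycle

    chosen: dict[str, str] = {}
    for m, entry in lexicon.entries.items():
        for w in sorted(entry.literal_words):
            probe = Document(id="probe", timestamp=dt.date(2020, 1, 1), text=w)
            scores = score_document(probe, lexicon).scores
            if scores[m] == 100.0 and all(
                    v == 0.0 for k, v in scores.items() if k != m):
                chosen[m] = w
                break
        else:
            raise EmovarError(
                f"emotion {m!r} has no unambiguous single-word entry for generation")
    return chosen


def _filler_word(lexicon: Lexicon) -> str:
    from .scoring import score_document

    for cand in ("lorem", "ipsum", "neutralword", "fillertoken"):
        probe = Document(id="probe", timestamp=dt.date(2020, 1, 1), text=cand)
        if all(v == 0.0 for v in score_document(probe, lexicon).scores.values()):
            return cand
    raise EmovarError("could not find a neutral filler word")


def corpus_from_emotion_series(
    daily_targets: pd.DataFrame,
    lexicon: Lexicon,
    docs_per_day: int,
    tokens_per_doc: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Document]:
    """Generate documents whose expected daily indices equal the targets.

    Each token independently is emotion m's generator word with
    probability q_m = (p_B(m)/100) (1 + target_m/100) and a neutral
    filler otherwise; infeasible targets (q outside [0, 1] or
    probabilities summing above 1) raise
    :class:`InfeasibleTargetError`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    emotions = list(lexicon.emotions)
    missing = [m for m in emotions if m not in daily_targets.columns]
    if missing:
        raise EmovarError(f"daily_targets missing emotion column(s) {missing}")
    pB = np.array([lexicon.entries[m].base_rate for m in emotions]) / 100.0
    words = _single_emotion_words(lexicon)
    filler = _filler_word(lexicon)
    vocab = np.array([words[m] for m in emotions] + [filler])

    targets = daily_targets[emotions].to_numpy(dtype=float)
    q = pB[None, :] * (1.0 + targets / 100.0)
    if (q < 0).any() or (q > 1).any():
        bad = np.argwhere((q < 0) | (q > 1))[0]
        raise InfeasibleTargetError(
            f"target for {emotions[bad[1]]!r} on {daily_targets.index[bad[0]]} "
            f"implies match probability {q[bad[0], bad[1]]:.4f} outside [0, 1]")
    if (q.sum(axis=1) > 1.0).any():
        d = int(np.argmax(q.sum(axis=1) > 1.0))
        raise InfeasibleTargetError(
            f"match probabilities on {daily_targets.index[d]} sum above 1")

    docs: list[Document] = []
    for d_idx, date in enumerate(daily_targets.index):
        cum = np.cumsum(q[d_idx])
        u = rng.random((docs_per_day, tokens_per_doc))
        codes = np.searchsorted(cum, u)  # M -> filler
        tok = vocab[codes]
        date_tag = date.isoformat() if hasattr(date, "isoformat") else str(date)
        for i in range(docs_per_day):
            docs.append(Document(
                id=f"synth-{date_tag}-{i}",
                timestamp=date if isinstance(date, dt.date) else date_tag,
                text=" ".join(tok[i]),
                lang="en", country_code="US",
            ))
    return docs


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full synthetic study bundle."""

    scenario: str = "paper-like"
    T: int = 120
    docs_per_day: int = 500
    tokens_per_doc: int = 20
    seed: int = 0
    burn_in: int = 50
    start_date: dt.date = DEFAULT_START
    interpolation: str = "constant"
    out_dir: Path = Path("synthetic_study")
    force: bool = False
    A: np.ndarray | None = None
    sigma: np.ndarray | None = None


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a study configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    kwargs: dict = {}
    for key in ("scenario", "T", "docs_per_day", "tokens_per_doc", "seed",
                "burn_in", "interpolation", "force"):
        if key in raw:
            kwargs[key] = raw[key]
    if "start_date" in raw:
        kwargs["start_date"] = dt.date.fromisoformat(str(raw["start_date"]))
    if "out_dir" in raw:
        kwargs["out_dir"] = Path(raw["out_dir"])
    if "A" in raw:
        kwargs["A"] = np.asarray(raw["A"], dtype=float)
    if "sigma" in raw:
        kwargs["sigma"] = np.asarray(raw["sigma"], dtype=float)
    return StudyConfig(**kwargs)


@dataclass(frozen=True)
class SyntheticStudyBundle:
    """Paths of a generated study plus its embedded ground truth."""

    documents_path: Path
    lexicon_path: Path
    trends_path: Path
    manifest_path: Path
    truth: SimulationTruth
    checksum: str


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def behavior_to_trends(
    behavior: np.ndarray, start_date: dt.date
) -> tuple[list[str], tuple[float, float]]:
    """Affinely map a latent behavior path into integer 0-100 weekly rows."""
    lo = float(behavior.min())
    hi = float(behavior.max())
    if hi <= lo:
        raise EmovarError("latent behavior path is constant; cannot rescale")
    scaled = np.rint((behavior - lo) / (hi - lo) * 100.0).astype(int)
    lines = ["Category: synthetic preventive-behavior index", "", "Week,index"]
    for w, v in enumerate(scaled):
        d = start_date + dt.timedelta(days=7 * w)
        lines.append(f"{d.isoformat()},{int(v)}")
    return lines, (lo, hi)


def synthesize_study(config: StudyConfig) -> SyntheticStudyBundle:
    """Write a complete synthetic study: documents, lexicon, trends CSV,
    and a truth manifest.  Byte-identical for identical config and seed."""
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise EmovarError(
            f"manifest already exists at {manifest_path}; use force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    lexicon = fixture_lexicon()
    truth = build_truth(
        scenario=config.scenario, T=config.T, seed=config.seed,
        docs_per_day=config.docs_per_day, tokens_per_doc=config.tokens_per_doc,
        burn_in=config.burn_in, lexicon=lexicon, start_date=config.start_date,
        interpolation=config.interpolation, A=config.A, sigma=config.sigma,
    )
    ss = np.random.SeedSequence(config.seed)
    rng_var, rng_corpus = (np.random.default_rng(s) for s in ss.spawn(2))

    latent = simulate_var_series(truth, rng=rng_var)
    daily = weekly_to_daily_targets(
        latent[list(lexicon.emotions)], config.start_date, config.interpolation)
    docs = corpus_from_emotion_series(
        daily, lexicon, config.docs_per_day, config.tokens_per_doc, rng=rng_corpus)

    docs_path = out / "documents.jsonl"
    with docs_path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({
                "id": doc.id,
                "created_at": doc.timestamp.isoformat()
                if isinstance(doc.timestamp, dt.date) else str(doc.timestamp),
                "text": doc.text, "lang": doc.lang,
                "country_code": doc.country_code,
            }) + "\n")

    lex_path = out / "lexicon.json"
    lex_path.write_text(
        fixture_lexicon_path().read_text(encoding="utf-8"), encoding="utf-8")

    trend_lines, affine = behavior_to_trends(
        latent["behavior"].to_numpy(), config.start_date)
    trends_path = out / "trends.csv"
    trends_path.write_text("\n".join(trend_lines) + "\n", encoding="utf-8")

    truth = SimulationTruth(**{**_truth_kwargs(truth), "behavior_affine": affine})
    files = {
        "documents": docs_path, "lexicon": lex_path, "trends": trends_path,
    }
    checksum = hashlib.sha256(
        "".join(_file_sha256(p) for p in files.values()).encode()).hexdigest()
    manifest = {
        "truth": truth.to_jsonable(),
        "scenario": config.scenario,
        "files": {k: p.name for k, p in files.items()},
        "sha256": {k: _file_sha256(p) for k, p in files.items()},
        "checksum": checksum,
    }
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return SyntheticStudyBundle(
        documents_path=docs_path, lexicon_path=lex_path,
        trends_path=trends_path, manifest_path=manifest_path,
        truth=truth, checksum=checksum,
    )


def _truth_kwargs(truth: SimulationTruth) -> dict:
    return {
        "names": truth.names, "c": truth.c, "A": truth.A, "sigma": truth.sigma,
        "T": truth.T, "burn_in": truth.burn_in, "seed": truth.seed,
        "docs_per_day": truth.docs_per_day, "tokens_per_doc": truth.tokens_per_doc,
        "base_rates": truth.base_rates, "start_date": truth.start_date,
        "interpolation": truth.interpolation,
        "behavior_affine": truth.behavior_affine,
    }
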