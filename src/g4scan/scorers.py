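"""Window scorers (G4Hunter, cGcC) and the common scorer contract.

Every downstream stage (delta scoring, FDR estimation, perturbation maps)
talks to a scorer through ``predict_prob`` for probabilistic scorers, or
through :func:`window_score` / :func:`cgcc_score` for the raw-scale
baselines. Scores of the baselines are never unit-converted; threshold
schemes are scheme-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_core import normalize_rna
from .subtype_rules import PatternConfig, find_motifs, g_runs

DEFAULT_WINDOW = 60


@dataclass(frozen=True)
class ScorerThresholds:
    cgcc: float = 4.5
    g4hunter: float = 0.9
    probability: float = 0.5


@dataclass
class ScoreProfile:
    scorer_name: str
    window_size: int
    scores: np.ndarray  # aligned to window start positions (0-based)
    sequence_score: float = field(init=False)
    argmax_start: int = field(init=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValueError("profile needs at least one window")
        self.argmax_start = int(np.argmax(self.scores))
        self.sequence_score = float(self.scores[self.argmax_start])


def g4hunter_base_scores(sequence: str) -> np.ndarray:
    """Per-base scores: each base of a G run of length l scores min(l, 4),
    C runs score -min(l, 4), A/U score 0."""
    seq = normalize_rna(sequence)
    out = np.zeros(len(seq), dtype=int)
    for start, length in g_runs(seq, "G"):
        out[start : start + length] = min(length, 4)
    for start, length in g_runs(seq, "C"):
        out[start : start + length] = -min(length, 4)
    return out


def _window_starts(length: int, window: int) -> range:
    return range(max(1, length - window + 1))


def g4hunter_window_scores(sequence: str, window: int = DEFAULT_WINDOW) -> ScoreProfile:
    """G4Hunter profile: arithmetic mean of base scores per sliding window.
    A sequence shorter than the window is scored as a single window."""
    base = g4hunter_base_scores(sequence)
    w = min(window, len(base))
    csum = np.concatenate(([0.0], np.cumsum(base)))
    scores = (csum[w:] - csum[:-w]) / w
    return ScoreProfile("g4hunter", window, scores)


def window_score(scorer, sequence: str, window: int = DEFAULT_WINDOW) -> ScoreProfile:
    """Score every window of a sequence with any callable window scorer and
    max-aggregate. ``scorer`` maps a window string to a float (or is an
    object with ``predict_prob``)."""
    seq = normalize_rna(sequence)
    fn = scorer.predict_prob if hasattr(scorer, "predict_prob") else scorer
    name = getattr(scorer, "name", getattr(scorer, "__name__", "scorer"))
    w = min(window, len(seq))
    scores = [fn(seq[i : i + w]) for i in _window_starts(len(seq), w)]
    return ScoreProfile(name, window, np.array(scores))


#: per-base weight by capped run length (runs of 4+ weigh like 4);
#: configurable, the screener default is not restated here
DEFAULT_CGCC_WEIGHTS: dict[int, float] = {1: 10.0, 2: 20.0, 3: 30.0, 4: 40.0}


def _weighted_run_score(seq: str, base: str, weights: dict[int, float]) -> float:
    return sum(
        length * weights[min(length, max(weights))]
        for _, length in g_runs(seq, base)
    )


def cgcc_score(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    weights: dict[int, float] | None = None,
    pseudocount: float = 1.0,
) -> ScoreProfile:
    """cGcC profile: ratio of weighted consecutive-G score to weighted
    consecutive-C score per window, pseudocount on both sides, max-aggregated.
    Swapping all G and C maps each window score s to 1/s."""
    seq = normalize_rna(sequence)
    wtab = weights or DEFAULT_CGCC_WEIGHTS
    w = min(window, len(seq))
    scores = []
    for i in _window_starts(len(seq), w):
        win = seq[i : i + w]
        g = _weighted_run_score(win, "G", wtab)
        c = _weighted_run_score(win, "C", wtab)
        scores.append((g + pseudocount) / (c + pseudocount))
    return ScoreProfile("cgcc", window, np.array(scores))


class G4HunterScorer:
    """Binary-detection wrapper over the G4Hunter window mean."""

    name = "g4hunter"

    def __init__(self, window: int = DEFAULT_WINDOW,
                 threshold: float = ScorerThresholds.g4hunter):
        self.window = window
        self.threshold = threshold

    def profile(self, sequence: str) -> ScoreProfile:
        return g4hunter_window_scores(sequence, self.window)

    def sequence_score(self, sequence: str) -> float:
        return self.profile(sequence).sequence_score

    def detected(self, sequence: str) -> bool:
        return self.sequence_score(sequence) >= self.threshold


class CGcCScorer:
    """Binary-detection wrapper over the cGcC ratio score."""

    name = "cgcc"

    def __init__(self, window: int = DEFAULT_WINDOW,
                 threshold: float = ScorerThresholds.cgcc,
                 weights: dict[int, float] | None = None):
        self.window = window
        self.threshold = threshold
        self.weights = weights

    def profile(self, sequence: str) -> ScoreProfile:
        return cgcc_score(sequence, self.window, self.weights)

    def sequence_score(self, sequence: str) -> float:
        return self.profile(sequence).sequence_score

    def detected(self, sequence: str) -> bool:
        return self.sequence_score(sequence) >= self.threshold


class RegexOracleScorer:
    """Probabilistic oracle: 1.0 iff the canonical rG4 pattern is present.

    Used as the exactness reference for delta scoring, FDR estimation and
    perturbation bookkeeping.
    """

    name = "oracle"

    def __init__(self, config: PatternConfig | None = None):
        self.config = config or PatternConfig()

    def predict_prob(self, sequence: str) -> float:
        return 1.0 if find_motifs(sequence, 3, 4, self.config.canonical_loop) else 0.0

    def predict_prob_many(self, sequences) -> np.ndarray:
        return np.array([self.predict_prob(s) for s in sequences])


class ConstantScorer:
    """Degenerate scorer returning a fixed probability (testing aid)."""

    name = "constant"

    def __init__(self, value: float):
        self.value = float(value)

    def predict_prob(self, sequence: str) -> float:
        return self.value

    def predict_prob_many(self, sequences) -> np.ndarray:
        return np.full(len(list(sequences)), self.value)


def predict_prob_many(scorer, sequences) -> np.ndarray:
    """Batch probability scoring through whichever interface is available."""
    if hasattr(scorer, "predict_prob_many"):
        return np.asarray(scorer.predict_prob_many(sequences), dtype=float)
    return np.array([scorer.predict_prob(s) for s in sequences], dtype=float)
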