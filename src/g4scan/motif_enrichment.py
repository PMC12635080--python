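"""PWM scanning of rG4 flanks and the log2 fold-enrichment statistic.

Flanking sequences of canonical rG4 motifs are split into a forming group
(prediction score > 0.7) and a non-forming group (score < 0.3); sequences
in between are excluded. Each position probability matrix is scanned with
log-odds scores against a uniform background, calling a hit when any offset
exceeds the exact-null p < 1e-4 score threshold (computed by dynamic
programming over matrix columns). Enrichment per motif is

    log2((fraction of forming units with motif + eps) /
         (fraction of non-forming units with motif + eps)),  eps = 1e-6,

with a one-sided Fisher exact test on the 2x2 hit table and BH adjustment
across motifs; reported motifs need >= 5 total hits, q < 0.05 and
log2 fold enrichment > 1. Hits are counted as unique flank units (the two
flanks of one motif form one unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .subtype_rules import PatternConfig, find_motifs

BASES = "ACGU"


@dataclass
class PWM:
    """Position probability matrix over {A, C, G, U}."""

    motif_id: str
    matrix: np.ndarray  # (length, 4), columns ordered A C G U

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: float = 0.25, pseudocount: float = 1e-3) -> np.ndarray:
        p = (self.matrix + pseudocount) / (1.0 + 4 * pseudocount)
        return np.log2(p / background)

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.matrix.argmax(axis=1))


def read_meme_pwms(path: str | Path) -> list[PWM]:
    """Read position probability matrices from MEME minimal format
    (T columns are treated as U)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        cols = []
        alphabet = {b: b for b in m.alphabet}
        for base in BASES:
            key = base if base in alphabet else ("T" if base == "U" else base)
            cols.append(np.asarray(m.pwm[key]))
        mat = np.stack(cols, axis=1)
        out.append(PWM(m.name or m.base_id, mat / mat.sum(axis=1, keepdims=True)))
    return out


#: integer discretization step for log-odds scores; the null DP and the
#: scanner share this grid so threshold comparisons are exact
SCORE_RESOLUTION = 1e-3


def null_score_threshold(pwm: PWM, pvalue: float = 1e-4,
                         resolution: float = SCORE_RESOLUTION) -> float:
    """Smallest log-odds score s with P(S >= s) <= pvalue under the uniform
    i.i.d. null, via discretized DP convolution over matrix columns."""
    lo = np.round(pwm.log_odds() / resolution).astype(int)
    dist = np.array([1.0])
    start = 0  # integer score represented by dist[0]
    for row in lo:
        col = np.zeros(row.max() - row.min() + 1)
        for v in row:
            col[v - row.min()] += 0.25
        dist = np.convolve(dist, col)
        start += row.min()
    scores = (start + np.arange(len(dist))) * resolution
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= pvalue)[0]
    if len(ok) == 0:
        # short matrices cannot reach the requested p (best case 4^-length);
        # fall back to requiring the best achievable score
        return float(scores[dist > 0][-1])
    return float(scores[ok[0]])


def scan_sequence(sequence: str, pwm: PWM, threshold: float,
                  resolution: float = SCORE_RESOLUTION) -> list[int]:
    """0-based offsets where the log-odds score passes the threshold.

    Scores are discretized on the same grid as the null distribution so the
    comparison with a :func:`null_score_threshold` value is exact.
    """
    L, W = len(sequence), len(pwm)
    if L < W:
        return []
    lo = np.round(pwm.log_odds() / resolution).astype(int)
    # a hit always needs a strictly positive log-odds score: a matrix equal
    # to the background (all zero scores) can never produce hits
    thr = max(int(round(threshold / resolution)), 1)
    idx = np.array([BASES.index(b) for b in sequence])
    cols = np.arange(W)
    hits = []
    for off in range(L - W + 1):
        if lo[cols, idx[off : off + W]].sum() >= thr:
            hits.append(off)
    return hits


@dataclass(frozen=True)
class FlankUnit:
    """The two flanks of one canonical motif, one counting unit."""

    unit_id: str
    left: str
    right: str

    def has_hit(self, pwm: PWM, threshold: float) -> bool:
        return bool(scan_sequence(self.left, pwm, threshold)
                    or scan_sequence(self.right, pwm, threshold))


def split_forming_flanks(
    sequences: list[tuple[str, str]],
    scores: list[float],
    form_thr: float = 0.7,
    nonform_thr: float = 0.3,
    pattern_config: PatternConfig | None = None,
) -> tuple[list[FlankUnit], list[FlankUnit]]:
    """Split (id, sequence) pairs into forming / non-forming flank units.

    Each sequence must contain a canonical motif (leftmost is used); the
    motif itself is excluded from the flanks. Sequences scoring inside
    [nonform_thr, form_thr] are excluded; ones without a motif are skipped
    with a warning.
    """
    cfg = pattern_config or PatternConfig()
    forming, nonforming, skipped = [], [], []
    for (sid, seq), score in zip(sequences, scores):
        spans = find_motifs(seq, 3, 4, cfg.canonical_loop)
        if not spans:
            skipped.append(sid)
            continue
        ms, me = spans[0]
        unit = FlankUnit(sid, seq[: ms - 1], seq[me:])
        if score > form_thr:
            forming.append(unit)
        elif score < nonform_thr:
            nonforming.append(unit)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} sequences without a canonical "
                      f"motif: {skipped[:10]}", stacklevel=2)
    return forming, nonforming


def pwm_scan(flanks: list[FlankUnit], pwm: PWM,
             pvalue: float = 1e-4) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Per-unit hit indicator plus hit offsets (left flank then right,
    right offsets shifted by the left length)."""
    thr = null_score_threshold(pwm, pvalue)
    indicator = np.zeros(len(flanks), dtype=bool)
    hit_lists: dict[str, list[int]] = {}
    for i, unit in enumerate(flanks):
        hits = scan_sequence(unit.left, pwm, thr)
        hits += [len(unit.left) + off for off in scan_sequence(unit.right, pwm, thr)]
        if hits:
            indicator[i] = True
            hit_lists[unit.unit_id] = hits
    return indicator, hit_lists


def log2_fold_enrichment(frac_forming: float, frac_nonforming: float,
                         epsilon: float = 1e-6) -> float:
    return float(np.log2((frac_forming + epsilon) / (frac_nonforming + epsilon)))


def enrich(
    pwms: list[PWM],
    forming: list[FlankUnit],
    nonforming: list[FlankUnit],
    epsilon: float = 1e-6,
    min_hits: int = 5,
    alpha: float = 0.05,
    min_log2_fc: float = 1.0,
    pvalue: float = 1e-4,
) -> pd.DataFrame:
    """Per-motif enrichment table with the pass/fail filter flags.

    Returns all motifs with columns n_forming_with_hit, n_forming_total,
    n_nonforming_with_hit, n_nonforming_total, log2_fc, p (one-sided
    Fisher), q (BH) and passes_filter (>= min_hits total hits, q < alpha,
    log2_fc > min_log2_fc).
    """
    if not forming or not nonforming:
        raise ValueError("both groups must be non-empty")
    rows = []
    for pwm in pwms:
        hit_f, _ = pwm_scan(forming, pwm, pvalue)
        hit_n, _ = pwm_scan(nonforming, pwm, pvalue)
        a, na = int(hit_f.sum()), len(forming)
        b, nb = int(hit_n.sum()), len(nonforming)
        table = [[a, na - a], [b, nb - b]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({
            "motif_id": pwm.motif_id,
            "n_forming_with_hit": a, "n_forming_total": na,
            "n_nonforming_with_hit": b, "n_nonforming_total": nb,
            "log2_fc": log2_fold_enrichment(a / na, b / nb, epsilon),
            "p": float(p),
        })
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["passes_filter"] = (
        (df["n_forming_with_hit"] + df["n_nonforming_with_hit"] >= min_hits)
        & (df["q"] < alpha)
        & (df["log2_fc"] > min_log2_fc)
    )
    return df
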