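"""Training-set construction for binary and multiclass fine-tuning.

Positives are experimentally-detected (or simulated) rG4 sequences extended
with transcript flanks to at most 70 nt. Negatives are matches of the
relaxed putative-G4 pattern G2+(N1-30 G2+)x3 found in rG4-free background
transcripts, centered in windows whose lengths are drawn from the empirical
positive-length distribution, with at most 1200 negatives sampled per 10-nt
match-length bin over 10-60 nt.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from ..sequence_core import Transcript, extract_flanked_window
from ..subtype_rules import PatternConfig, classify_subtype
from .model import LabeledExample

RELAXED_G4_PATTERN = re.compile(r"G{2,}(?:[ACGU]{1,30}?G{2,}){3}")

POSITIVE_LABEL, NEGATIVE_LABEL = "rG4", "non-rG4"


def _extend_positive(item, target_length: int) -> str:
    if isinstance(item, str):
        return item
    transcript, span = item
    return extract_flanked_window(transcript, span, target_length).sequence


def _dedup(seqs: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for s in seqs:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def build_binary_dataset(
    positives,
    background_transcripts: list[Transcript],
    seed: int = 0,
    target_length: int = 70,
    bin_cap: int = 1200,
    bin_range: tuple[int, int] = (10, 60),
    bin_width: int = 10,
) -> list[LabeledExample]:
    """Interleaved positive/negative examples per the fine-tuning recipe.

    ``positives`` are sequences or (transcript, motif_span) pairs; they are
    deduplicated after flank extension. Background transcripts must contain
    no experimentally-positive region. If the background cannot supply as
    many negatives as positives, the builder proceeds with a warning that
    reports the shortfall.
    """
    rng = np.random.default_rng(seed)
    pos_seqs = _dedup([_extend_positive(p, target_length) for p in positives])
    if not pos_seqs:
        raise ValueError("no positive sequences")
    pos_lengths = np.array([len(s) for s in pos_seqs])

    lo, hi = bin_range
    bins: dict[int, list[tuple[Transcript, int, int]]] = {}
    for tx in background_transcripts:
        for m in RELAXED_G4_PATTERN.finditer(tx.sequence):
            length = m.end() - m.start()
            if not lo <= length <= hi:
                continue
            b = min((length - lo) // bin_width, (hi - lo) // bin_width - 1)
            bins.setdefault(b, []).append((tx, m.start(), m.end()))

    candidates: list[tuple[Transcript, int, int]] = []
    for b in sorted(bins):
        matches = bins[b]
        if len(matches) > bin_cap:
            take = rng.choice(len(matches), size=bin_cap, replace=False)
            matches = [matches[i] for i in sorted(take)]
        candidates.extend(matches)

    n_needed = len(pos_seqs)
    if len(candidates) > n_needed:
        take = rng.choice(len(candidates), size=n_needed, replace=False)
        candidates = [candidates[i] for i in sorted(take)]
    elif len(candidates) < n_needed:
        warnings.warn(
            f"background exhausted: {len(candidates)} negatives for "
            f"{n_needed} positives (shortfall {n_needed - len(candidates)})",
            stacklevel=2,
        )

    neg_seqs = []
    for tx, s0, e0 in candidates:
        # window length matched to the positive-length distribution,
        # never shorter than the match itself
        target = int(rng.choice(pos_lengths))
        target = max(target, e0 - s0)
        neg_seqs.append(
            extract_flanked_window(tx, (s0 + 1, e0), target).sequence
        )
    neg_seqs = _dedup(neg_seqs)

    out: list[LabeledExample] = []
    for i in range(max(len(pos_seqs), len(neg_seqs))):
        if i < len(pos_seqs):
            out.append(LabeledExample(pos_seqs[i], POSITIVE_LABEL,
                                      "experimental-positive"))
        if i < len(neg_seqs):
            out.append(LabeledExample(neg_seqs[i], NEGATIVE_LABEL,
                                      "regex-negative"))
    return out


def build_multiclass_dataset(
    positives,
    config: PatternConfig | None = None,
    target_length: int = 70,
) -> list[LabeledExample]:
    """Label deduplicated positives with their hierarchical subtype class."""
    pos_seqs = _dedup([_extend_positive(p, target_length) for p in positives])
    return [
        LabeledExample(s, classify_subtype(s, config).subtype.value,
                       "experimental-positive")
        for s in pos_seqs
    ]
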