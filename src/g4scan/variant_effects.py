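"""Delta scoring of variants, categorical calls, and the FDR estimator.

The delta score of a variant is the mutant-minus-wild-type change in the
predicted rG4 formation probability, computed on identically-placed windows
containing the variant. Two published threshold schemes coexist and are
named explicitly in every record:

* GNOMAD scheme — breaking iff wild-type > 0.7 and mutant < 0.3;
  non-breaking iff wild-type > 0.7 and |delta| <= 0.02.
* PMBB scheme — breaking iff wild-type > 0.5 and delta <= -0.2; forming iff
  wild-type < 0.5 and delta >= +0.2.

Records matching neither band are retained with category OTHER for
auditability rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .sequence_core import (SequenceVariant, Transcript, apply_variant,
                            extract_flanked_window)


class Category(str, Enum):
    BREAKING = "BREAKING"
    NON_BREAKING = "NON_BREAKING"
    FORMING = "FORMING"
    OTHER = "OTHER"


class Scheme(str, Enum):
    GNOMAD = "GNOMAD"
    PMBB = "PMBB"


@dataclass(frozen=True)
class WindowPolicy:
    """Variant-centric window placement for transcriptome scanning."""

    window: int = 70  # nt, centered on the variant, clipped at ends
    stride: int = 10  # used only by whole-transcript sliding mode


@dataclass(frozen=True)
class DeltaRecord:
    variant: SequenceVariant
    transcript_id: str
    wt_score: float
    mut_score: float
    delta: float
    category: Category
    scheme: Scheme


def categorize(wt: float, mut: float, scheme: Scheme) -> Category:
    """Categorical call for one (wild-type, mutant) score pair."""
    if not (0.0 <= wt <= 1.0 and 0.0 <= mut <= 1.0):
        raise ValueError("scores must lie in [0, 1]")
    delta = mut - wt
    if scheme == Scheme.GNOMAD:
        if wt > 0.7 and mut < 0.3:
            return Category.BREAKING
        if wt > 0.7 and abs(delta) <= 0.02:
            return Category.NON_BREAKING
        return Category.OTHER
    if wt > 0.5 and delta <= -0.2:
        return Category.BREAKING
    if wt < 0.5 and delta >= 0.2:
        return Category.FORMING
    return Category.OTHER


def delta_score(
    scorer,
    transcript: Transcript,
    variant: SequenceVariant,
    scheme: Scheme = Scheme.GNOMAD,
    window_policy: WindowPolicy | None = None,
) -> DeltaRecord:
    """Score wild-type and mutant on the same variant-centered window."""
    policy = window_policy or WindowPolicy()
    mutated = apply_variant(transcript, variant)  # also validates ref
    win = extract_flanked_window(
        transcript, (variant.position, variant.position), policy.window)
    wt_seq = win.sequence
    mut_seq = mutated[win.start - 1 : win.end]
    wt = float(scorer.predict_prob(wt_seq))
    mut = float(scorer.predict_prob(mut_seq))
    return DeltaRecord(
        variant=variant,
        transcript_id=transcript.id,
        wt_score=wt,
        mut_score=mut,
        delta=mut - wt,
        category=categorize(wt, mut, scheme),
        scheme=scheme,
    )


def recategorize(record: DeltaRecord, scheme: Scheme) -> DeltaRecord:
    return replace(record, scheme=scheme,
                   category=categorize(record.wt_score, record.mut_score, scheme))


def reduce_min_delta(records: list[DeltaRecord], key=None) -> list[DeltaRecord]:
    """One record per variant: the most disruptive (minimum-delta) instance,
    ties broken by lexicographic transcript id.

    ``key`` maps a record to its variant identity; the default treats
    records sharing (position, ref, alt) as one variant seen on several
    transcripts.
    """
    if not records:
        raise ValueError("no records to reduce")
    if key is None:
        key = lambda r: (r.variant.position, r.variant.ref, r.variant.alt)
    groups: dict[tuple, list[DeltaRecord]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)
    return [
        min(rs, key=lambda r: (r.delta, r.transcript_id))
        for rs in groups.values()
    ]


def sliding_windows(transcript: Transcript, window: int = 70, stride: int = 10):
    """Whole-transcript window sequences for background scanning."""
    seq = transcript.sequence
    if len(seq) <= window:
        return [seq]
    starts = list(range(0, len(seq) - window + 1, stride))
    if starts[-1] != len(seq) - window:
        starts.append(len(seq) - window)
    return [seq[s : s + window] for s in starts]


def estimate_fdr(
    scorer,
    negative_transcripts: list[Transcript],
    threshold: float = 0.7,
    window_policy: WindowPolicy | None = None,
) -> float:
    """Fraction of windows on an rG4-free background scoring > threshold.

    Every window on the negative background is a prediction; those above
    the probability threshold are false positives, and the FDR is their
    fraction among all windows scored.
    """
    policy = window_policy or WindowPolicy()
    n_hi = n_all = 0
    for tx in negative_transcripts:
        windows = sliding_windows(tx, policy.window, policy.stride)
        from .scorers import predict_prob_many

        scores = predict_prob_many(scorer, windows)
        n_hi += int((scores > threshold).sum())
        n_all += len(windows)
    if n_all == 0:
        raise ValueError("no windows scored")
    return n_hi / n_all
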