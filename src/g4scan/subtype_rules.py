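"""Hierarchical rule engine for rG4 subtype classification.

Eight stability-ranked classes are assigned from sequence alone: canonical
(four G>=3 runs, 1-7 nt loops), long loop (one loop 8-12 nt), bulges (one
G-run interrupted by a single-nucleotide bulge), two-quartet (four G>=2
runs, loops 1-9), then the G-rich categories (potential G-quadruplex /
G-triplex with relaxed loops and G content >= 40%, plain G >= 40%) and
unknown. When several patterns match, the most stable (lowest-rank) class
wins.

Matching operates on maximal G runs, never splitting a run to fabricate a
loop, and reports leftmost non-overlapping spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .sequence_core import normalize_rna


class Subtype(str, Enum):
    CANONICAL = "CANONICAL"
    LONGLOOP = "LONGLOOP"
    BULGES = "BULGES"
    TWO_QUARTET = "TWO_QUARTET"
    POTENTIAL_GQ_40 = "POTENTIAL_GQ_40"
    POTENTIAL_G_TRIPLEX_40 = "POTENTIAL_G_TRIPLEX_40"
    G_RICH_40 = "G_RICH_40"
    UNKNOWN = "UNKNOWN"


#: 1 = most stable; drives hierarchical precedence
SUBTYPE_RANK: dict[Subtype, int] = {
    Subtype.CANONICAL: 1,
    Subtype.LONGLOOP: 2,
    Subtype.BULGES: 3,
    Subtype.TWO_QUARTET: 4,
    Subtype.POTENTIAL_GQ_40: 5,
    Subtype.POTENTIAL_G_TRIPLEX_40: 6,
    Subtype.G_RICH_40: 7,
    Subtype.UNKNOWN: 8,
}


@dataclass(frozen=True)
class PatternConfig:
    """Loop-length bounds and G-content threshold for every class."""

    canonical_loop: tuple[int, int] = (1, 7)
    longloop_loop: tuple[int, int] = (8, 12)  # exactly one loop in this range
    bulge_size: int = 1  # single-nucleotide bulge, one bulged run
    two_quartet_loop: tuple[int, int] = (1, 9)
    g_content: float = 0.40  # computed over the full input sequence
    relaxed_loop: tuple[int, int] = (1, 30)

    def __post_init__(self):
        for lo, hi in (self.canonical_loop, self.longloop_loop,
                       self.two_quartet_loop, self.relaxed_loop):
            if not 0 < lo <= hi:
                raise ValueError("loop bounds must be positive and ordered")
        if self.canonical_loop[1] >= self.longloop_loop[1]:
            raise ValueError("canonical upper loop bound must be < longloop's")


@dataclass(frozen=True)
class SubtypeCall:
    subtype: Subtype
    rank: int
    motif_span: tuple[int, int] | None  # 1-based closed; None for G_RICH_40/UNKNOWN
    matched_pattern: str


def g_runs(sequence: str, base: str = "G") -> list[tuple[int, int]]:
    """Maximal runs of ``base`` as (start0, length), 0-based."""
    runs, i, n = [], 0, len(sequence)
    while i < n:
        if sequence[i] == base:
            j = i
            while j < n and sequence[j] == base:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _scan_runs(
    runs: list[tuple[int, int]],
    min_run: int,
    n_runs: int,
    loop_ok,
) -> list[tuple[int, int]]:
    """Leftmost non-overlapping windows of ``n_runs`` consecutive qualifying
    runs whose loop-length vector satisfies ``loop_ok``. Spans are 0-based
    closed (start of first run, end of last run)."""
    qual = [(s, l) for s, l in runs if l >= min_run]
    spans, j = [], 0
    while j + n_runs <= len(qual):
        window = qual[j : j + n_runs]
        loops = [b[0] - (a[0] + a[1]) for a, b in zip(window, window[1:])]
        if loop_ok(loops):
            spans.append((window[0][0], window[-1][0] + window[-1][1] - 1))
            j += n_runs
        else:
            j += 1
    return spans


def find_motifs(
    sequence: str,
    min_run: int = 3,
    n_runs: int = 4,
    loop_bounds: tuple[int, int] = (1, 7),
) -> list[tuple[int, int]]:
    """Leftmost non-overlapping matches of the (G{min_run,}N{lo,hi})xN
    pattern, as 1-based closed spans. Default is the canonical rG4 pattern
    G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+."""
    seq = normalize_rna(sequence)
    lo, hi = loop_bounds
    spans = _scan_runs(
        g_runs(seq), min_run, n_runs,
        lambda loops: all(lo <= L <= hi for L in loops),
    )
    return [(s + 1, e + 1) for s, e in spans]


def _find_longloop(seq: str, cfg: PatternConfig) -> tuple[int, int] | None:
    clo, chi = cfg.canonical_loop
    llo, lhi = cfg.longloop_loop
    spans = _scan_runs(
        g_runs(seq), 3, 4,
        lambda loops: sum(llo <= L <= lhi for L in loops) == 1
        and all(clo <= L <= chi or llo <= L <= lhi for L in loops),
    )
    return spans[0] if spans else None


def _find_bulged(seq: str, cfg: PatternConfig) -> tuple[int, int] | None:
    """Four G units with exactly one bulged run: G{1,2}.X.G{1,2}, total G >= 3
    in that unit; other units are plain G>=3 runs; loops 1-7 between units."""
    runs = g_runs(seq)
    clo, chi = cfg.canonical_loop
    n = len(runs)
    # unit = (start, end, bulged?) built from one run or a bulged pair
    for i in range(n):
        for bulge_slot in range(4):
            units, ri, ok = [], i, True
            for slot in range(4):
                if ri >= n:
                    ok = False
                    break
                s, l = runs[ri]
                if slot == bulge_slot:
                    if (
                        ri + 1 < n
                        and 1 <= l <= 2
                        and 1 <= runs[ri + 1][1] <= 2
                        and runs[ri + 1][0] - (s + l) == cfg.bulge_size
                        and l + runs[ri + 1][1] >= 3
                    ):
                        units.append((s, runs[ri + 1][0] + runs[ri + 1][1] - 1))
                        ri += 2
                    else:
                        ok = False
                        break
                else:
                    if l >= 3:
                        units.append((s, s + l - 1))
                        ri += 1
                    else:
                        ok = False
                        break
            if ok:
                loops = [b[0] - a[1] - 1 for a, b in zip(units, units[1:])]
                if all(clo <= L <= chi for L in loops):
                    return (units[0][0], units[-1][1])
    return None


def _g_fraction(seq: str) -> float:
    return seq.count("G") / len(seq) if seq else 0.0


def classify_subtype(sequence: str, config: PatternConfig | None = None) -> SubtypeCall:
    """Assign the most stable matching class; exactly one class is returned.

    G content is computed over the full input sequence.
    """
    cfg = config or PatternConfig()
    seq = normalize_rna(sequence)
    if len(seq) < 8:
        raise ValueError(f"sequence length {len(seq)} < 8")

    def call(subtype: Subtype, span0, pattern: str) -> SubtypeCall:
        span = (span0[0] + 1, span0[1] + 1) if span0 is not None else None
        return SubtypeCall(subtype, SUBTYPE_RANK[subtype], span, pattern)

    clo, chi = cfg.canonical_loop
    canonical = find_motifs(seq, 3, 4, cfg.canonical_loop)
    if canonical:
        s, e = canonical[0]
        return call(Subtype.CANONICAL, (s - 1, e - 1), f"G3+N{clo}-{chi}x4")

    span = _find_longloop(seq, cfg)
    if span is not None:
        llo, lhi = cfg.longloop_loop
        return call(Subtype.LONGLOOP, span, f"G3+ one loop {llo}-{lhi}")

    span = _find_bulged(seq, cfg)
    if span is not None:
        return call(Subtype.BULGES, span, f"one {cfg.bulge_size}-nt bulged G-run")

    tlo, thi = cfg.two_quartet_loop
    spans = _scan_runs(g_runs(seq), 2, 4,
                       lambda loops: all(tlo <= L <= thi for L in loops))
    if spans:
        return call(Subtype.TWO_QUARTET, spans[0], f"G2+N{tlo}-{thi}x4")

    g_ok = _g_fraction(seq) >= cfg.g_content
    rlo, rhi = cfg.relaxed_loop
    if g_ok:
        spans = _scan_runs(g_runs(seq), 2, 4,
                           lambda loops: all(rlo <= L <= rhi for L in loops))
        if spans:
            return call(Subtype.POTENTIAL_GQ_40, spans[0],
                        f"G2+N{rlo}-{rhi}x4, G>=40%")
        spans = _scan_runs(g_runs(seq), 2, 3,
                           lambda loops: all(rlo <= L <= rhi for L in loops))
        if spans:
            return call(Subtype.POTENTIAL_G_TRIPLEX_40, spans[0],
                        f"G2+N{rlo}-{rhi}x3, G>=40%")
        return call(Subtype.G_RICH_40, None, "G>=40%")
    return call(Subtype.UNKNOWN, None, "no rule matched")
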