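"""Seeded generators for transcriptomes, variant tables and PWM plants.

Every generator is a pure function of (parameters, seed) and returns its
ground truth alongside the data, emulating the input structure of the real
analyses: transcriptomes with planted rG4 subtypes standing in for
rG4-seq-derived positives, variant tables with a selection structure
standing in for population catalogs, and planted RBP motif sites standing
in for motif-database scans. Backgrounds are i.i.d. by default (a 1st-order
Markov option exists for harder language-model tasks).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motif_enrichment import BASES, PWM
from .sequence_core import Transcript, extract_flanked_window
from .subtype_rules import (PatternConfig, Subtype, classify_subtype,
                            find_motifs, g_runs)

LOOP_BASES = "AUC"  # loop alphabet that never merges adjacent G-runs


@dataclass(frozen=True)
class PlantedMotif:
    transcript_id: str
    start: int  # 1-based closed
    end: int
    subtype: str


@dataclass
class SimTruth:
    motifs: list[PlantedMotif] = field(default_factory=list)
    pwm_sites: list[tuple[str, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("transcript_id\tstart\tend\tsubtype\n")
        for m in self.motifs:
            buf.write(f"{m.transcript_id}\t{m.start}\t{m.end}\t{m.subtype}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "SimTruth":
        truth = cls()
        for line in text.strip().splitlines()[1:]:
            tid, s, e, sub = line.split("\t")
            truth.motifs.append(PlantedMotif(tid, int(s), int(e), sub))
        return truth


# --------------------------------------------------------------- grammars
def _loops(rng, n, lo, hi):
    return ["".join(rng.choice(list(LOOP_BASES), size=rng.integers(lo, hi + 1)))
            for _ in range(n)]


def motif_from_grammar(subtype: Subtype, rng: np.random.Generator,
                       config: PatternConfig | None = None) -> str:
    """Sample one motif sequence from the subtype's pattern grammar."""
    cfg = config or PatternConfig()
    clo, chi = cfg.canonical_loop
    if subtype == Subtype.CANONICAL:
        runs = ["G" * rng.integers(3, 5) for _ in range(4)]
        loops = _loops(rng, 3, clo, chi)
    elif subtype == Subtype.LONGLOOP:
        runs = ["G" * 3 for _ in range(4)]
        loops = _loops(rng, 3, clo, chi)
        llo, lhi = cfg.longloop_loop
        loops[rng.integers(3)] = "".join(
            rng.choice(list(LOOP_BASES), size=rng.integers(llo, lhi + 1)))
    elif subtype == Subtype.BULGES:
        runs = ["G" * 3 for _ in range(4)]
        halves = rng.choice([(1, 2), (2, 1), (2, 2)])
        bulged = "G" * halves[0] + str(rng.choice(list(LOOP_BASES))) + "G" * halves[1]
        runs[rng.integers(4)] = bulged
        loops = _loops(rng, 3, clo, chi)
    elif subtype == Subtype.TWO_QUARTET:
        runs = ["GG" for _ in range(4)]
        loops = _loops(rng, 3, *cfg.two_quartet_loop)
    elif subtype == Subtype.POTENTIAL_GQ_40:
        # four G2 runs, one loop beyond the two-quartet bound but short
        # enough to keep G-content above the threshold
        runs = ["GG" for _ in range(4)]
        loops = _loops(rng, 3, 1, 2)
        loops[rng.integers(3)] = "".join(
            rng.choice(list(LOOP_BASES),
                       size=rng.integers(cfg.two_quartet_loop[1] + 1, 12)))
    elif subtype == Subtype.POTENTIAL_G_TRIPLEX_40:
        runs = ["GGG" for _ in range(3)]
        loops = _loops(rng, 2, 1, 3)
    elif subtype == Subtype.G_RICH_40:
        # alternating single G's: G-rich but no G2 run
        n = rng.integers(5, 9)
        return "".join("G" + str(rng.choice(list(LOOP_BASES))) for _ in range(n))
    else:
        raise ValueError(f"no grammar for {subtype}")
    out = [runs[0]]
    for loop, run in zip(loops, runs[1:]):
        out.append(loop)
        out.append(run)
    return "".join(out)


def subtype_exemplars(subtype: Subtype, n: int, seed: int = 0,
                      config: PatternConfig | None = None) -> list[str]:
    """Standalone sequences whose hierarchical class is exactly ``subtype``
    (verified against the rule engine, re-rolled on collision)."""
    cfg = config or PatternConfig()
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        if subtype == Subtype.UNKNOWN:
            seq = "".join(rng.choice(list("AUC"), size=rng.integers(10, 30)))
        else:
            seq = motif_from_grammar(subtype, rng, cfg)
        if classify_subtype(seq, cfg).subtype == subtype:
            out.append(seq)
    return out


# ----------------------------------------------------------- transcriptome
def _background(rng, length: int, gc: float, markov: bool = False) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    bases = np.array(list("ACGU"))
    if not markov:
        return rng.choice(bases, size=length, p=probs)
    # simple 1st-order chain biased toward repeating the previous base
    seq = [rng.choice(bases, p=probs)]
    for _ in range(length - 1):
        p = probs * 0.7
        p[np.where(bases == seq[-1])[0][0]] += 0.3
        seq.append(rng.choice(bases, p=p / p.sum()))
    return np.array(seq)


def _strip_canonical(seq_arr: np.ndarray, rng, protect: tuple[int, int] | None,
                     config: PatternConfig) -> None:
    """Mutate out accidental canonical motifs (outside the protected span)
    by replacing one interior G of an involved run with A/U."""
    for _ in range(200):
        spans = find_motifs("".join(seq_arr), 3, 4, config.canonical_loop)
        spans = [s for s in spans
                 if protect is None or s[1] < protect[0] or s[0] > protect[1]]
        if not spans:
            return
        s, e = spans[0]
        sub = "".join(seq_arr[s - 1 : e])
        runs = [r for r in g_runs(sub) if r[1] >= 3]
        run = runs[rng.integers(len(runs))]
        pos = s - 1 + run[0] + 1 + rng.integers(max(run[1] - 2, 1))
        if protect and protect[0] - 1 <= pos <= protect[1] - 1:
            continue
        seq_arr[pos] = rng.choice(list("AU"))
    raise RuntimeError("failed to remove accidental canonical motifs")


DEFAULT_SUBTYPE_MIX = {
    Subtype.CANONICAL: 0.40,
    Subtype.LONGLOOP: 0.15,
    Subtype.BULGES: 0.15,
    Subtype.TWO_QUARTET: 0.15,
    None: 0.15,  # motif-free background transcript
}


def simulate_transcriptome(
    n: int = 50,
    length: int | tuple[int, int] = (400, 1200),
    gc: float = 0.5,
    subtype_mix: dict | None = None,
    seed: int = 0,
    config: PatternConfig | None = None,
    markov: bool = False,
) -> tuple[list[Transcript], SimTruth]:
    """Transcripts with planted rG4 motifs at recorded positions.

    ``subtype_mix`` maps subtypes (or None for motif-free) to probabilities
    summing to 1. Planted motifs are drawn from their pattern grammar;
    accidental canonical motifs in the background are mutated out, and a
    plant whose extracted 70-nt window does not classify as intended is
    re-rolled, so planted canonical motifs classify CANONICAL for 100% of
    plants. Motif-free transcripts carry no canonical motif at all.
    """
    cfg = config or PatternConfig()
    mix = subtype_mix or DEFAULT_SUBTYPE_MIX
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("subtype_mix must sum to 1")
    if not 0 < gc < 1:
        raise ValueError("infeasible GC content")
    rng = np.random.default_rng(seed)
    keys = list(mix)
    probs = np.array([mix[k] for k in keys])
    transcripts, truth = [], SimTruth(params={
        "n": n, "length": str(length), "gc": gc, "seed": seed})
    window_checked = {Subtype.CANONICAL, Subtype.LONGLOOP, Subtype.BULGES,
                      Subtype.TWO_QUARTET}
    for i in range(n):
        tid = f"TX{i:05d}"
        target = keys[rng.choice(len(keys), p=probs)]
        L = (rng.integers(length[0], length[1] + 1)
             if isinstance(length, tuple) else length)
        for _attempt in range(60):
            arr = _background(rng, L, gc, markov)
            if target is None:
                _strip_canonical(arr, rng, None, cfg)
                transcripts.append(Transcript(tid, "".join(arr)))
                break
            motif = motif_from_grammar(target, rng, cfg)
            if len(motif) + 2 > L:
                raise ValueError("transcript too short for motif")
            start0 = int(rng.integers(1, L - len(motif)))
            arr[start0 : start0 + len(motif)] = list(motif)
            span = (start0 + 1, start0 + len(motif))
            _strip_canonical(arr, rng, span, cfg)
            seq = "".join(arr)
            if target in window_checked:
                window = extract_flanked_window(seq, span, 70).sequence
                ok = classify_subtype(window, cfg).subtype == target
            else:
                ok = classify_subtype(motif, cfg).subtype == target
            if ok:
                transcripts.append(Transcript(tid, seq))
                truth.motifs.append(PlantedMotif(tid, span[0], span[1],
                                                 target.value))
                break
        else:
            raise RuntimeError(f"could not plant {target} in {tid}")
    return transcripts, truth


def write_fasta(transcripts: list[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.id}\n")
            for i in range(0, len(tx.sequence), 70):
                fh.write(tx.sequence[i : i + 70] + "\n")


# ----------------------------------------------------------------- variants
@dataclass(frozen=True)
class VariantRegime:
    """MAF/annotation distributions for breaking vs neutral variants."""

    breaking_beta: tuple[float, float] = (0.3, 30.0)
    neutral_beta: tuple[float, float] = (0.5, 30.0)
    an_max: int = 152_312
    an_min_frac: float = 0.75
    cadd_breaking_shift: float = 2.0  # mean raw-CADD lift for breaking truth
    constraint_sd: float = 1.0


NULL_REGIME = VariantRegime(breaking_beta=(0.5, 30.0), neutral_beta=(0.5, 30.0),
                            cadd_breaking_shift=0.0)


def simulate_variants(
    transcripts: list[Transcript],
    truth: SimTruth,
    regime: VariantRegime | None = None,
    per_motif: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant table with truth labels over the planted motifs.

    Breaking variants substitute an interior G of a motif G-run (which
    destroys that run); neutral variants substitute an A/U at least 10 nt
    away from the motif. MAFs are Beta-distributed per regime, allele
    numbers uniform in [an_min_frac, 1] x an_max, constraint Z standard
    normal, raw CADD normal with the regime's shift for breaking truth.
    """
    if not truth.motifs:
        raise ValueError("no planted motifs in truth")
    regime = regime or VariantRegime()
    rng = np.random.default_rng(seed)
    by_id = {tx.id: tx for tx in transcripts}
    rows = []
    for m in truth.motifs:
        tx = by_id[m.transcript_id]
        seq = tx.sequence
        motif_seq = seq[m.start - 1 : m.end]
        interior = [
            m.start + r0 + 1 + k
            for r0, rl in g_runs(motif_seq)
            if rl >= 2
            for k in range(max(rl - 2, 1))
        ]
        flank_pos = [
            p for p in range(1, len(seq) + 1)
            if (p < m.start - 10 or p > m.end + 10) and seq[p - 1] in "AU"
        ]
        for j in range(per_motif):
            for label, positions in (("breaking", interior), ("neutral", flank_pos)):
                if not positions:
                    continue
                pos = int(positions[rng.integers(len(positions))])
                ref = seq[pos - 1]
                alt = str(rng.choice([b for b in "ACGU" if b != ref
                                      and (label != "neutral" or b in "AU")]))
                a, b = (regime.breaking_beta if label == "breaking"
                        else regime.neutral_beta)
                maf = float(rng.beta(a, b))
                rows.append({
                    "variant_id": f"{m.transcript_id}:{pos}{ref}>{alt}",
                    "transcript_id": m.transcript_id,
                    "position": pos, "ref": ref, "alt": alt,
                    "maf": maf,
                    "an": int(rng.integers(int(regime.an_min_frac * regime.an_max),
                                           regime.an_max + 1)),
                    "constraint_z": float(rng.normal(0, regime.constraint_sd)),
                    "cadd_raw": float(rng.normal(
                        regime.cadd_breaking_shift if label == "breaking" else 0.0,
                        1.0)),
                    "region": str(rng.choice(["FIVE_UTR", "THREE_UTR"])),
                    "subtype": m.subtype,
                    "rg4_length": m.end - m.start + 1,
                    "truth_label": label,
                })
    return pd.DataFrame(rows)


# -------------------------------------------------------------- PWM plants
def plant_pwm_sites(
    sequences: list[str],
    pwm: PWM,
    rate: float,
    seed: int = 0,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Write PWM-sampled sites into sequences at a per-sequence rate.

    Each selected sequence receives one site sampled per-column from the
    PWM at a uniformly random feasible position; returns the modified
    sequences and (sequence index, 0-based site offset) truth records.
    Sequences shorter than the motif are never selected.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    W = len(pwm)
    out, sites = [], []
    for i, seq in enumerate(sequences):
        if len(seq) >= W and rng.random() < rate:
            site = "".join(rng.choice(list(BASES), p=row)
                           for row in pwm.matrix)
            off = int(rng.integers(0, len(seq) - W + 1))
            seq = seq[:off] + site + seq[off + W:]
            sites.append((i, off))
        out.append(seq)
    return out, sites


def random_flanks(n: int, length: int = 60, gc: float = 0.5,
                  seed: int = 0) -> list[str]:
    """Plain i.i.d. flank-like sequences (no planted structure)."""
    rng = np.random.default_rng(seed)
    return ["".join(_background(rng, length, gc)) for _ in range(n)]


def simulate_clinvar_table(
    n_benign: int = 400,
    n_pathogenic: int = 100,
    pathogenic_delta_shift: float = -0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Benign/pathogenic variant table with a pathogenic shift toward
    rG4-disrupting delta scores (deltas clipped to [-1, 0])."""
    rng = np.random.default_rng(seed)
    benign = np.clip(rng.normal(-0.05, 0.15, n_benign), -1, 0)
    path = np.clip(rng.normal(-0.05 + pathogenic_delta_shift, 0.3,
                              n_pathogenic), -1, 0)
    return pd.DataFrame({
        "variant_id": [f"V{i}" for i in range(n_benign + n_pathogenic)],
        "delta": np.concatenate([benign, path]),
        "clinsig": ["BENIGN"] * n_benign + ["PATHOGENIC"] * n_pathogenic,
    })
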