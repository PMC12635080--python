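"""Transcript data model, k-mer tokenization, variant application and windows.

All coordinates are 1-based closed intervals in transcript space. Sequences
are RNA over {A, C, G, U}; T is accepted on input and normalized to U, any
other character rejects the record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
REGION_LABELS = ("FIVE_UTR", "CDS", "THREE_UTR")

#: content-token cap per chunk; [CLS]/[SEP] are carried as flags on top of
#: this so a chunk fits a 512-token encoder input
MAX_CONTENT_TOKENS = 510


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, U, T}."""


class ReferenceMismatchError(ValueError):
    """Variant reference allele disagrees with the transcript base."""


def normalize_rna(sequence: str) -> str:
    """Uppercase, T->U; raise :class:`AlphabetError` on anything else."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)} in sequence")
    return seq


@dataclass(frozen=True)
class Region:
    start: int  # 1-based inclusive
    end: int  # inclusive
    label: str

    def __post_init__(self):
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad region interval [{self.start}, {self.end}]")


@dataclass
class Transcript:
    id: str
    sequence: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        for r in self.regions:
            if r.end > len(self.sequence):
                raise ValueError(
                    f"region [{r.start}, {r.end}] out of bounds for "
                    f"{self.id} (length {len(self.sequence)})"
                )
        # per-label intervals must not overlap
        by_label: dict[str, list[Region]] = {}
        for r in self.regions:
            by_label.setdefault(r.label, []).append(r)
        for label, rs in by_label.items():
            rs = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping {label} regions in {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceVariant:
    """A single-nucleotide substitution in transcript coordinates."""

    transcript_id: str
    position: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "ref", normalize_rna(self.ref))
        object.__setattr__(self, "alt", normalize_rna(self.alt))
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")


@dataclass
class TokenSequence:
    """One encoder chunk of overlapping k-mer tokens."""

    tokens: list[str]
    chunk_index: int
    has_cls: bool = True
    has_sep: bool = True


def tokenize_kmers(
    sequence: str, k: int = 6, max_tokens: int = MAX_CONTENT_TOKENS
) -> list[TokenSequence]:
    """Tokenize into overlapping k-mers, split into <=max_tokens chunks.

    Adjacent tokens within a chunk overlap in k-1 bases; chunks partition the
    token list (no token is shared between chunks), so the total content
    token count is len(sequence) - k + 1.
    """
    seq = normalize_rna(sequence)
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    tokens = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return [
        TokenSequence(tokens=tokens[i : i + max_tokens], chunk_index=ci)
        for ci, i in enumerate(range(0, len(tokens), max_tokens))
    ]


def detokenize(chunk: TokenSequence) -> str:
    """Reconstruct the subsequence covered by one chunk."""
    toks = chunk.tokens
    return toks[0] + "".join(t[-1] for t in toks[1:])


def apply_variant(transcript: Transcript | str, variant: SequenceVariant) -> str:
    """Return the transcript sequence with the variant substituted."""
    seq = transcript.sequence if isinstance(transcript, Transcript) else transcript
    pos = variant.position
    if not 1 <= pos <= len(seq):
        raise ValueError(f"variant position {pos} outside transcript")
    if seq[pos - 1] != variant.ref:
        raise ReferenceMismatchError(
            f"ref allele {variant.ref} != transcript base {seq[pos - 1]} "
            f"at position {pos}"
        )
    return seq[: pos - 1] + variant.alt + seq[pos:]


@dataclass(frozen=True)
class Window:
    sequence: str
    start: int  # 1-based, inclusive, transcript coordinates
    end: int
    motif_truncated: bool = False  # motif longer than the target length


def extract_flanked_window(
    transcript: Transcript | str,
    motif_span: tuple[int, int],
    target_length: int = 70,
) -> Window:
    """Window of ``target_length`` containing the motif with even flanks.

    The left flank receives the extra base when the total flank is odd.
    Windows are truncated at transcript ends without padding; the unused
    budget is given to the other side. A motif longer than ``target_length``
    yields a window equal to the motif with ``motif_truncated`` set.
    """
    seq = transcript.sequence if isinstance(transcript, Transcript) else transcript
    ms, me = motif_span
    if not 1 <= ms <= me <= len(seq):
        raise ValueError(f"motif span {motif_span} outside transcript")
    motif_len = me - ms + 1
    if motif_len >= target_length:
        return Window(seq[ms - 1 : me], ms, me, motif_truncated=motif_len > target_length)
    budget = target_length - motif_len
    left = budget - budget // 2  # left gets the extra base when odd
    right = budget // 2
    # redistribute what the transcript ends cannot provide
    avail_left, avail_right = ms - 1, len(seq) - me
    if avail_left < left:
        right += left - avail_left
        left = avail_left
    if avail_right < right:
        left = min(avail_left, left + (right - avail_right))
        right = avail_right
    return Window(seq[ms - 1 - left : me + right], ms - left, me + right)


def variant_window(
    transcript: Transcript | str, position: int, window: int = 70
) -> tuple[int, int]:
    """1-based span of a ``window``-nt window centered on ``position``."""
    seq = transcript.sequence if isinstance(transcript, Transcript) else transcript
    w = extract_flanked_window(seq, (position, position), window)
    return w.start, w.end


def load_transcripts(
    fasta_path: str | Path, regions_path: str | Path | None = None
) -> list[Transcript]:
    """Load transcripts from FASTA plus optional region annotations.

    Records with invalid characters are skipped; their ids are reported in a
    single warning. Region rows (TSV: transcript_id, start, end, label, or
    GFF3) must reference loaded transcripts.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(str(fasta_path))
    regions = read_regions(regions_path) if regions_path else {}
    transcripts, rejected = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            transcripts.append(
                Transcript(rec.id, str(rec.seq), regions.pop(rec.id, []))
            )
        except AlphabetError:
            rejected.append(rec.id)
    if regions:
        raise ValueError(
            f"regions reference unknown transcripts: {sorted(regions)}"
        )
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} records with invalid characters: "
            f"{rejected}", stacklevel=2
        )
    return transcripts


def read_regions(path: str | Path) -> dict[str, list[Region]]:
    """Read region annotations from 4-column TSV or GFF3."""
    path = Path(path)
    out: dict[str, list[Region]] = {}
    label_map = {"five_prime_utr": "FIVE_UTR", "cds": "CDS",
                 "three_prime_utr": "THREE_UTR"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 9:  # GFF3
                tid, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
                label = label_map.get(ftype.lower(), ftype.upper())
            elif len(parts) == 4:
                tid, start, end, label = parts
            else:
                raise ValueError(f"malformed region line: {line!r}")
            out.setdefault(tid, []).append(Region(int(start), int(end), label))
    return out


def read_variants(path: str | Path) -> list[SequenceVariant]:
    """Read variants from TSV (transcript_id, pos, ref, alt; header optional)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("transcript_id", "transcript"):
                continue
            tid, pos, ref, alt = parts[:4]
            out.append(SequenceVariant(tid, int(pos), ref, alt))
    return out


def read_vcf_variants(
    vcf_path: str | Path, mapping_path: str | Path
) -> list[SequenceVariant]:
    """Read a genomic VCF with a precomputed genome-to-transcript mapping.

    The mapping TSV has columns chrom, pos, transcript_id, transcript_pos;
    splice-aware projection is out of scope, the table is required input.
    """
    mapping: dict[tuple[str, int], list[tuple[str, int]]] = {}
    with open(mapping_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            chrom, pos, tid, tpos = line.split("\t")[:4]
            mapping.setdefault((chrom, int(pos)), []).append((tid, int(tpos)))
    out = []
    with open(vcf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, _, ref, alts = line.split("\t")[:5]
            for tid, tpos in mapping.get((chrom, int(pos)), []):
                for alt in alts.split(","):
                    if len(ref) == 1 and len(alt) == 1 and ref != alt:
                        out.append(SequenceVariant(tid, tpos, ref, alt))
    return out
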