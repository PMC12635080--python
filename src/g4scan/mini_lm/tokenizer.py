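"""Overlapping k-mer vocabulary shared by pre-training and fine-tuning."""

from __future__ import annotations

from itertools import product

import numpy as np

from ..sequence_core import MAX_CONTENT_TOKENS, tokenize_kmers

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)


class KmerVocab:
    """All 4^k RNA k-mers plus the five special tokens."""

    def __init__(self, k: int = 6):
        self.k = k
        kmers = ["".join(p) for p in product("ACGU", repeat=k)]
        self.tokens = list(SPECIAL_TOKENS) + kmers
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.pad_id = self.index[PAD]
        self.unk_id = self.index[UNK]
        self.cls_id = self.index[CLS]
        self.sep_id = self.index[SEP]
        self.mask_id = self.index[MASK]
        self.n_special = len(SPECIAL_TOKENS)

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, sequence: str, max_tokens: int = MAX_CONTENT_TOKENS) -> list[np.ndarray]:
        """Token-id chunks for one sequence, each wrapped in [CLS] ... [SEP]."""
        chunks = tokenize_kmers(sequence, self.k, max_tokens)
        out = []
        for chunk in chunks:
            ids = [self.cls_id]
            ids += [self.index.get(t, self.unk_id) for t in chunk.tokens]
            ids.append(self.sep_id)
            out.append(np.array(ids, dtype=np.int64))
        return out

    def pad_batch(self, id_lists: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Stack variable-length id arrays into (ids, mask) with PAD filling."""
        T = max(len(x) for x in id_lists)
        ids = np.full((len(id_lists), T), self.pad_id, dtype=np.int64)
        mask = np.zeros((len(id_lists), T))
        for i, x in enumerate(id_lists):
            ids[i, : len(x)] = x
            mask[i, : len(x)] = 1.0
        return ids, mask
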