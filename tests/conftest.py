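"""Shared fixtures: synthetic corpora and a fine-tuned miniature model.

The expensive session fixtures build the study-condition dataset (2000
canonical positives plus length-matched relaxed-regex negatives), pre-train
the masked LM briefly and fine-tune the binary classifier once; several
test modules reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from g4scan.mini_lm import (G4merClassifier, ModelConfig, POSITIVE_LABEL,
                            build_binary_dataset, pretrain_mlm)
from g4scan.scorers import RegexOracleScorer
from g4scan.subtype_rules import Subtype
from g4scan.synthetic_data import simulate_transcriptome


@pytest.fixture(scope="session")
def oracle():
    return RegexOracleScorer()


@pytest.fixture(scope="session")
def small_transcriptome():
    """30 transcripts with mixed planted subtypes plus their truth."""
    return simulate_transcriptome(n=30, seed=101)


@pytest.fixture(scope="session")
def negative_transcripts():
    """Motif-free background transcripts (no canonical rG4 anywhere)."""
    txs, _ = simulate_transcriptome(n=40, subtype_mix={None: 1.0}, seed=102,
                                    length=(300, 600))
    return txs


@pytest.fixture(scope="session")
def binary_dataset():
    """The fine-tuning set at study scale: 2000 unique canonical positives
    extended with flanks, interleaved with relaxed-regex negatives."""
    txs_pos, truth = simulate_transcriptome(
        n=2000, subtype_mix={Subtype.CANONICAL: 1.0}, seed=201,
        length=(200, 400))
    txs_bg, _ = simulate_transcriptome(
        n=900, subtype_mix={None: 1.0}, seed=202, length=(600, 1000))
    by_id = {t.id: t for t in txs_pos}
    positives = [(by_id[m.transcript_id], (m.start, m.end))
                 for m in truth.motifs]
    dataset = build_binary_dataset(positives, txs_bg, seed=203)
    return dataset, txs_pos, truth, txs_bg


@pytest.fixture(scope="session")
def trained_binary_model(binary_dataset):
    """Briefly pre-trained, fine-tuned binary classifier plus its held-out
    split (stratified 70/30)."""
    from sklearn.model_selection import train_test_split

    dataset, _, _, _ = binary_dataset
    seqs = [ex.sequence for ex in dataset]
    labels = [ex.label for ex in dataset]
    x_tr, x_te, y_tr, y_te = train_test_split(
        seqs, labels, test_size=0.3, random_state=11, stratify=labels)
    # masked-LM pre-training on (unlabeled) training-split domain sequences
    cfg = ModelConfig(seed=7, pretrain_steps=150)
    lm, _ = pretrain_mlm(x_tr[:500], cfg)
    clf = G4merClassifier(pretrained=lm, seed=13).fit(x_tr, y_tr)
    y_te_bin = np.array([y == POSITIVE_LABEL for y in y_te])
    return {"clf": clf, "x_test": x_te, "y_test": y_te_bin,
            "x_train": x_tr, "lm": lm}
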