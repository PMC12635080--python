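"""Fine-tuned sequence classifier with a scikit-learn style surface."""

from __future__ import annotations

import copy

import numpy as np

from .model import LabeledExample, MiniBert, ModelConfig
from .nn import Adam


class G4merClassifier:
    """Sequence classifier fine-tuned from a (pre-trained) miniature encoder.

    Parameters
    ----------
    config : ModelConfig, optional
        Architecture and training hyperparameters. Binary tasks default to
        2 fine-tuning epochs, multiclass to 5 (``epochs`` overrides both).
    pretrained : MiniBert, optional
        Masked-LM pre-trained encoder to start from; copied, never mutated.
        When omitted, fine-tuning starts from random initialization.
    epochs : int, optional
    seed : int

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of class labels, sorted
    model_ : the fine-tuned :class:`MiniBert`
    n_features_in_ : always 1 (a sequence string)
    """

    def __init__(self, config: ModelConfig | None = None,
                 pretrained: MiniBert | None = None,
                 epochs: int | None = None, seed: int = 0):
        self.config = config
        self.pretrained = pretrained
        self.epochs = epochs
        self.seed = seed

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "pretrained": self.pretrained,
                "epochs": self.epochs, "seed": self.seed}

    def set_params(self, **params) -> "G4merClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- training ---------------------------------------------------------
    def fit(self, sequences, labels=None) -> "G4merClassifier":
        if labels is None and sequences and isinstance(sequences[0], LabeledExample):
            labels = [ex.label for ex in sequences]
            sequences = [ex.sequence for ex in sequences]
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        if len(self.classes_) < 2:
            raise ValueError("dataset must contain at least two classes")
        y = np.searchsorted(self.classes_, labels)

        if self.pretrained is not None:
            model = MiniBert(self.pretrained.config, self.pretrained.vocab)
            model.params = copy.deepcopy(self.pretrained.params)
        else:
            model = MiniBert(self.config or ModelConfig(seed=self.seed))
        cfg = model.config
        model.add_classifier_head(len(self.classes_), seed=self.seed)

        n_epochs = self.epochs
        if n_epochs is None:
            n_epochs = (cfg.finetune_epochs_binary if len(self.classes_) == 2
                        else cfg.finetune_epochs_multiclass)

        rng = np.random.default_rng(self.seed)
        chunks = [model.vocab.encode(s)[0] for s in sequences]
        opt = Adam(model.params, cfg.finetune_lr)
        n = len(chunks)
        for _ in range(n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.finetune_batch):
                take = order[start : start + cfg.finetune_batch]
                ids, mask = model.vocab.pad_batch([chunks[i] for i in take])
                _, grads = model.cls_loss_and_grads(ids, mask, y[take])
                opt.step(grads)
        self.model_ = model
        self.n_features_in_ = 1
        return self

    # -- prediction -------------------------------------------------------
    def predict_proba(self, sequences) -> np.ndarray:
        """Class-probability matrix (n_sequences, n_classes).

        Sequences longer than one encoder chunk are scored per chunk; each
        class column takes its maximum over chunks and rows are renormalized.
        """
        self._check_fitted()
        model = self.model_
        out = np.empty((len(sequences), len(self.classes_)))
        batch, owners = [], []
        for i, s in enumerate(sequences):
            for chunk in model.vocab.encode(s):
                batch.append(chunk)
                owners.append(i)
        probs_rows = np.zeros_like(out)
        bs = 64
        for start in range(0, len(batch), bs):
            ids, mask = model.vocab.pad_batch(batch[start : start + bs])
            p = model.predict_proba_ids(ids, mask)
            for j, owner in enumerate(owners[start : start + bs]):
                probs_rows[owner] = np.maximum(probs_rows[owner], p[j])
        out = probs_rows / probs_rows.sum(axis=1, keepdims=True)
        return out

    def predict(self, sequences) -> np.ndarray:
        return self.classes_[self.predict_proba(sequences).argmax(axis=1)]

    def predict_prob(self, sequence: str) -> float:
        """Probability of the positive (last, sorted) class for one sequence."""
        return float(self.predict_proba([sequence])[0, -1])

    def predict_prob_many(self, sequences) -> np.ndarray:
        return self.predict_proba(sequences)[:, -1]

    @property
    def name(self) -> str:
        return "g4mer-mini"

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")

    # -- attribution interface (binary models) ----------------------------
    def input_embeddings(self, sequence: str) -> np.ndarray:
        self._check_fitted()
        return self.model_.input_embeddings(sequence)

    def predict_from_embeddings(self, emb: np.ndarray) -> float:
        self._check_fitted()
        return self.model_.predict_from_embeddings(emb, target_class=len(self.classes_) - 1)

    def gradient_from_embeddings(self, emb: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self.model_.gradient_from_embeddings(emb, target_class=len(self.classes_) - 1)

    def representation(self, sequence: str) -> np.ndarray:
        self._check_fitted()
        return self.model_.representation(sequence)
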