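"""Miniature BERT-style encoder over overlapping 6-mer tokens.

A bidirectional transformer encoder with learned token and position
embeddings, post-layer-norm residual blocks and GELU feed-forward layers,
written directly in numpy. It supports masked-language-model pre-training,
classification fine-tuning from the [CLS] state, and exact gradients with
respect to the input token embeddings for attribution analysis.

Desk-scale defaults (2 layers, 2 heads, hidden 64) exercise the mechanism;
the full-scale settings (6 layers, 6 heads, effective batch 250,
200k steps) are expressible through :class:`ModelConfig` but never required.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..sequence_core import MAX_CONTENT_TOKENS
from .nn import (Adam, dense_backward, dense_forward, gelu_backward,
                 gelu_forward, layer_norm_backward, layer_norm_forward,
                 softmax)
from .tokenizer import KmerVocab


@dataclass
class ModelConfig:
    layers: int = 2
    heads: int = 2
    hidden: int = 64
    ffn: int | None = None  # defaults to 4 x hidden
    k: int = 6
    max_len: int = MAX_CONTENT_TOKENS + 2
    pretrain_lr: float = 4e-4
    pretrain_batch: int = 32  # full scale: effective 250
    pretrain_steps: int = 1000  # full scale: 200_000
    finetune_lr: float = 2e-4
    finetune_batch: int = 32
    finetune_epochs_binary: int = 2
    finetune_epochs_multiclass: int = 5
    mask_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.ffn is None:
            self.ffn = 4 * self.hidden
        if min(self.layers, self.heads, self.hidden, self.ffn) <= 0:
            raise ValueError("model dimensions must be positive")
        if self.hidden % self.heads:
            raise ValueError("heads must divide hidden size")


class MiniBert:
    """Encoder plus optional MLM and classification heads."""

    def __init__(self, config: ModelConfig | None = None,
                 vocab: KmerVocab | None = None):
        self.config = config or ModelConfig()
        self.vocab = vocab or KmerVocab(self.config.k)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(self.config.seed))
        self.n_classes: int | None = None

    # ------------------------------------------------------------------ init
    def _init_params(self, rng: np.random.Generator, scale: float = 0.02):
        c, p = self.config, self.params
        V, d, f = len(self.vocab), c.hidden, c.ffn

        def normal(*shape):
            return rng.normal(0.0, scale, size=shape)

        p["tok_emb"] = normal(V, d)
        p["pos_emb"] = normal(c.max_len, d)
        p["ln_e_g"], p["ln_e_b"] = np.ones(d), np.zeros(d)
        for i in range(c.layers):
            for w in ("q", "k", "v", "o"):
                p[f"l{i}_W{w}"], p[f"l{i}_b{w}"] = normal(d, d), np.zeros(d)
            p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"] = np.ones(d), np.zeros(d)
            p[f"l{i}_W1"], p[f"l{i}_b1"] = normal(d, f), np.zeros(f)
            p[f"l{i}_W2"], p[f"l{i}_b2"] = normal(f, d), np.zeros(d)
            p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"] = np.ones(d), np.zeros(d)
        p["mlm_W"], p["mlm_b"] = normal(d, V), np.zeros(V)

    def add_classifier_head(self, n_classes: int, seed: int | None = None):
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        self.params["cls_W"] = rng.normal(0.0, 0.02, (self.config.hidden, n_classes))
        self.params["cls_b"] = np.zeros(n_classes)
        self.n_classes = n_classes

    # --------------------------------------------------------------- forward
    def _encode(self, tok_e: np.ndarray, mask: np.ndarray):
        """Run the encoder from token embeddings (B, T, d); returns the final
        hidden states and the caches needed for the backward pass."""
        c, p = self.config, self.params
        B, T, d = tok_e.shape
        h = c.heads
        dh = d // h
        emb = tok_e + p["pos_emb"][:T]
        x, ln_e_cache = layer_norm_forward(emb, p["ln_e_g"], p["ln_e_b"])
        bias = (1.0 - mask)[:, None, None, :] * -1e9
        caches = []
        for i in range(c.layers):
            pre = f"l{i}_"

            def split(z):
                return z.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

            q, cq = dense_forward(x, p[pre + "Wq"], p[pre + "bq"])
            k, ck = dense_forward(x, p[pre + "Wk"], p[pre + "bk"])
            v, cv = dense_forward(x, p[pre + "Wv"], p[pre + "bv"])
            qs, ks, vs = split(q), split(k), split(v)
            scores = qs @ ks.transpose(0, 1, 3, 2) / np.sqrt(dh) + bias
            probs = softmax(scores)
            ctx = probs @ vs
            merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, d)
            a, co = dense_forward(merged, p[pre + "Wo"], p[pre + "bo"])
            r1 = x + a
            x1, c_ln1 = layer_norm_forward(r1, p[pre + "ln1_g"], p[pre + "ln1_b"])
            f1, c1 = dense_forward(x1, p[pre + "W1"], p[pre + "b1"])
            g, gt = gelu_forward(f1)
            f2, c2 = dense_forward(g, p[pre + "W2"], p[pre + "b2"])
            r2 = x1 + f2
            x2, c_ln2 = layer_norm_forward(r2, p[pre + "ln2_g"], p[pre + "ln2_b"])
            caches.append((cq, ck, cv, qs, ks, vs, probs, co, c_ln1, c1,
                           (f1, gt), c2, c_ln2, x))
            x = x2
        return x, (ln_e_cache, caches, (B, T, d, h, dh))

    def _encode_backward(self, dx: np.ndarray, cache, grads: dict) -> np.ndarray:
        """Backprop through the encoder; returns gradient w.r.t. the input
        token embeddings and accumulates parameter gradients in ``grads``."""
        c, p = self.config, self.params
        ln_e_cache, caches, (B, T, d, h, dh) = cache
        for i in reversed(range(c.layers)):
            pre = f"l{i}_"
            (cq, ck, cv, qs, ks, vs, probs, co, c_ln1, c1, (f1, gt), c2,
             c_ln2, x_in) = caches[i]
            dr2, dg2, db2 = layer_norm_backward(dx, c_ln2)
            grads[pre + "ln2_g"] = grads.get(pre + "ln2_g", 0) + dg2
            grads[pre + "ln2_b"] = grads.get(pre + "ln2_b", 0) + db2
            dx1 = dr2.copy()
            dgelu_out, dW2, db_2 = dense_backward(dr2, p[pre + "W2"], c2)
            grads[pre + "W2"] = grads.get(pre + "W2", 0) + dW2
            grads[pre + "b2"] = grads.get(pre + "b2", 0) + db_2
            df1 = dgelu_out * gelu_backward(f1, gt)
            dx1b, dW1, db_1 = dense_backward(df1, p[pre + "W1"], c1)
            grads[pre + "W1"] = grads.get(pre + "W1", 0) + dW1
            grads[pre + "b1"] = grads.get(pre + "b1", 0) + db_1
            dx1 += dx1b
            dr1, dg1, db1 = layer_norm_backward(dx1, c_ln1)
            grads[pre + "ln1_g"] = grads.get(pre + "ln1_g", 0) + dg1
            grads[pre + "ln1_b"] = grads.get(pre + "ln1_b", 0) + db1
            dxl = dr1.copy()
            dmerged, dWo, dbo = dense_backward(dr1, p[pre + "Wo"], co)
            grads[pre + "Wo"] = grads.get(pre + "Wo", 0) + dWo
            grads[pre + "bo"] = grads.get(pre + "bo", 0) + dbo
            dctx = dmerged.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
            dprobs = dctx @ vs.transpose(0, 1, 3, 2)
            dvs = probs.transpose(0, 1, 3, 2) @ dctx
            dscores = probs * (dprobs - (dprobs * probs).sum(axis=-1, keepdims=True))
            dscores /= np.sqrt(dh)
            dqs = dscores @ ks
            dks = dscores.transpose(0, 1, 3, 2) @ qs

            def merge(z):
                return z.transpose(0, 2, 1, 3).reshape(B, T, d)

            for name, dz, cc in (("q", dqs, cq), ("k", dks, ck), ("v", dvs, cv)):
                dxi, dW, db = dense_backward(merge(dz), p[pre + "W" + name], cc)
                grads[pre + "W" + name] = grads.get(pre + "W" + name, 0) + dW
                grads[pre + "b" + name] = grads.get(pre + "b" + name, 0) + db
                dxl += dxi
            dx = dxl
        demb, dge, dbe = layer_norm_backward(dx, ln_e_cache)
        grads["ln_e_g"] = grads.get("ln_e_g", 0) + dge
        grads["ln_e_b"] = grads.get("ln_e_b", 0) + dbe
        grads["pos_emb"] = grads.get("pos_emb", 0) + np.pad(
            demb.sum(axis=0),
            ((0, self.params["pos_emb"].shape[0] - demb.shape[1]), (0, 0)),
        )
        return demb

    def _embed(self, ids: np.ndarray) -> np.ndarray:
        return self.params["tok_emb"][ids]

    def hidden_states(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        h, _ = self._encode(self._embed(ids), mask)
        return h

    def representation(self, sequence: str) -> np.ndarray:
        """Mean of final hidden states over real tokens (baseline selection)."""
        ids, mask = self.vocab.pad_batch([self.vocab.encode(sequence)[0]])
        h = self.hidden_states(ids, mask)
        return h[0].mean(axis=0)

    # ------------------------------------------------------------------- MLM
    def mlm_logits(self, ids: np.ndarray, mask: np.ndarray):
        h, cache = self._encode(self._embed(ids), mask)
        logits = h @ self.params["mlm_W"] + self.params["mlm_b"]
        return logits, (h, cache)

    def mlm_loss_and_grads(self, ids, mask, targets, target_mask):
        """Mean cross-entropy over positions flagged in ``target_mask``.

        Vocabulary logits are materialized only at the masked positions,
        which keeps the output projection proportional to the mask count
        rather than the full batch length.
        """
        h, cache = self._encode(self._embed(ids), mask)
        sel = target_mask > 0
        h_sel = h[sel]  # (M, d)
        t_sel = targets[sel]
        logits = h_sel @ self.params["mlm_W"] + self.params["mlm_b"]
        probs = softmax(logits)
        M = max(len(t_sel), 1)
        loss = -np.log(probs[np.arange(len(t_sel)), t_sel] + 1e-12).mean() \
            if len(t_sel) else 0.0
        dlogits = probs.copy()
        dlogits[np.arange(len(t_sel)), t_sel] -= 1.0
        dlogits /= M
        grads: dict[str, np.ndarray] = {}
        grads["mlm_W"] = h_sel.T @ dlogits
        grads["mlm_b"] = dlogits.sum(axis=0)
        dh = np.zeros_like(h)
        dh[sel] = dlogits @ self.params["mlm_W"].T
        demb = self._encode_backward(dh, cache, grads)
        grads["tok_emb"] = np.zeros_like(self.params["tok_emb"])
        np.add.at(grads["tok_emb"], ids, demb)
        return loss, grads

    # ---------------------------------------------------------- classifier
    def cls_logits(self, ids: np.ndarray, mask: np.ndarray):
        h, cache = self._encode(self._embed(ids), mask)
        logits = h[:, 0, :] @ self.params["cls_W"] + self.params["cls_b"]
        return logits, (h, cache)

    def cls_loss_and_grads(self, ids, mask, labels):
        logits, (h, cache) = self.cls_logits(ids, mask)
        probs = softmax(logits)
        B = len(labels)
        loss = -np.log(probs[np.arange(B), labels] + 1e-12).mean()
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        grads["cls_W"] = h[:, 0, :].T @ dlogits
        grads["cls_b"] = dlogits.sum(axis=0)
        dh = np.zeros_like(h)
        dh[:, 0, :] = dlogits @ self.params["cls_W"].T
        demb = self._encode_backward(dh, cache, grads)
        grads["tok_emb"] = np.zeros_like(self.params["tok_emb"])
        np.add.at(grads["tok_emb"], ids, demb)
        return loss, grads

    def predict_proba_ids(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.cls_logits(ids, mask)
        return softmax(logits)

    # ------------------------------------------------- attribution interface
    def input_embeddings(self, sequence: str) -> np.ndarray:
        """Token-embedding matrix (T, d) for one sequence (first chunk),
        including the [CLS]/[SEP] rows."""
        ids = self.vocab.encode(sequence)[0]
        return self._embed(ids[None, :])[0]

    def predict_from_embeddings(self, emb: np.ndarray, target_class: int = 1) -> float:
        mask = np.ones((1, emb.shape[0]))
        h, _ = self._encode(emb[None, :, :], mask)
        logits = h[:, 0, :] @ self.params["cls_W"] + self.params["cls_b"]
        return float(softmax(logits)[0, target_class])

    def gradient_from_embeddings(self, emb: np.ndarray, target_class: int = 1) -> np.ndarray:
        """d P(target_class) / d token-embedding input, shape (T, d)."""
        mask = np.ones((1, emb.shape[0]))
        h, cache = self._encode(emb[None, :, :], mask)
        logits = h[:, 0, :] @ self.params["cls_W"] + self.params["cls_b"]
        probs = softmax(logits)[0]
        # dp_t/dlogit_j = p_t (delta_tj - p_j)
        dlogits = (-probs[target_class] * probs)[None, :]
        dlogits[0, target_class] += probs[target_class]
        dh = np.zeros_like(h)
        dh[:, 0, :] = dlogits @ self.params["cls_W"].T
        grads: dict[str, np.ndarray] = {}
        return self._encode_backward(dh, cache, grads)[0]

    # ----------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Single portable archive: weights (.npz) plus config JSON."""
        path = Path(path)
        meta = {"config": asdict(self.config), "n_classes": self.n_classes}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "MiniBert":
        data = np.load(Path(path) if str(path).endswith(".npz") else f"{path}")
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(ModelConfig(**meta["config"]))
        model.params = {k: data[k] for k in data.files if k != "__meta__"}
        model.n_classes = meta["n_classes"]
        return model


@dataclass
class LabeledExample:
    """One training unit for fine-tuning."""

    sequence: str
    label: str
    source: str = "synthetic"  # experimental-positive | regex-negative | synthetic


def pretrain_mlm(
    corpus: list[str],
    config: ModelConfig | None = None,
    heldout_fraction: float = 0.1,
) -> tuple[MiniBert, dict]:
    """Masked-language-model pre-training on a sequence corpus.

    15% of content tokens are selected per chunk (80% -> [MASK], 10% random
    k-mer, 10% unchanged); the loss is mean cross-entropy at the selected
    positions. Returns the model and a small report containing the held-out
    masked-token loss and accuracy, which for any non-degenerate corpus ends
    below the uniform-vocabulary baseline log(V).
    """
    if not corpus:
        raise ValueError("empty corpus")
    cfg = config or ModelConfig()
    model = MiniBert(cfg)
    rng = np.random.default_rng(cfg.seed)
    chunks = [c for seq in corpus for c in model.vocab.encode(seq)]
    rng.shuffle(chunks)
    n_held = max(1, int(round(heldout_fraction * len(chunks)))) if len(chunks) > 1 else 0
    held, train = chunks[:n_held], chunks[n_held:] or chunks
    opt = Adam(model.params, cfg.pretrain_lr)
    final_loss = None
    for _ in range(cfg.pretrain_steps):
        take = rng.choice(len(train), size=min(cfg.pretrain_batch, len(train)),
                          replace=False)
        ids, mask = model.vocab.pad_batch([train[i] for i in take])
        masked_ids, targets, target_mask = _apply_mlm_masking(
            ids, mask, model.vocab, cfg.mask_fraction, rng)
        loss, grads = model.mlm_loss_and_grads(masked_ids, mask, targets, target_mask)
        opt.step(grads)
        final_loss = loss
    report = {"final_train_loss": final_loss,
              "uniform_baseline": float(np.log(len(model.vocab)))}
    report.update(heldout_mlm_metrics(model, held or train,
                                      seed=cfg.seed + 1,
                                      mask_fraction=cfg.mask_fraction))
    return model, report


def _apply_mlm_masking(ids, mask, vocab: KmerVocab, fraction: float,
                       rng: np.random.Generator):
    """Standard BERT masking; special tokens and padding are never selected."""
    maskable = mask.astype(bool) & (ids >= vocab.n_special)
    select = (rng.random(ids.shape) < fraction) & maskable
    # guarantee at least one target per batch
    if not select.any():
        cand = np.argwhere(maskable)
        if len(cand):
            i, j = cand[rng.integers(len(cand))]
            select[i, j] = True
    targets = ids.copy()
    masked = ids.copy()
    action = rng.random(ids.shape)
    masked[select & (action < 0.8)] = vocab.mask_id
    randomize = select & (action >= 0.8) & (action < 0.9)
    masked[randomize] = rng.integers(vocab.n_special, len(vocab),
                                     size=int(randomize.sum()))
    return masked, targets, select.astype(float)


def heldout_mlm_metrics(model: MiniBert, chunks, seed: int = 0,
                        mask_fraction: float = 0.15) -> dict:
    """Masked-token cross-entropy and accuracy on held-out chunks."""
    rng = np.random.default_rng(seed)
    ids, mask = model.vocab.pad_batch(chunks)
    masked_ids, targets, tmask = _apply_mlm_masking(
        ids, mask, model.vocab, mask_fraction, rng)
    h = model.hidden_states(masked_ids, mask)
    sel = tmask > 0
    logits = h[sel] @ model.params["mlm_W"] + model.params["mlm_b"]
    probs = softmax(logits)
    t_sel = targets[sel]
    logp = np.log(probs[np.arange(len(t_sel)), t_sel] + 1e-12)
    acc = (probs.argmax(axis=-1) == t_sel).mean()
    return {"heldout_loss": float(-logp.mean()),
            "heldout_accuracy": float(acc),
            "n_heldout_masked": int(len(t_sel))}
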