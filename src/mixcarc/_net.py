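"""NumPy implementation of the hybrid SMILES-CNN + descriptor-FFNN network.

Two branches feed one head. The structural branch embeds each SMILES token
index into a dense vector (size 100 by default), so a batch of K length-L
encodings becomes a K x L x 100 array, runs a 1-D convolution over the
sequence and global-max-pools over positions. The descriptor branch is a
plain multilayer perceptron over the (standardized) mixture descriptor
vector. The pooled CNN output is concatenated with the FFNN's last hidden
layer, passed through one merged dense layer, and the head is a single
sigmoid unit (binary), K softmax units (multiclass) or one linear unit
(regression). Either branch may be absent, giving the descriptor-only FFNN
("NN") and the SMILES-only CNN ablations.

Training is minibatch Adam with manual backpropagation and inverted dropout;
everything is plain NumPy, so a fixed seed under single-threaded execution
gives bitwise-reproducible fits.
"""

from __future__ import annotations

import numpy as np

from .errors import DivergenceError


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class HybridCore:
    """Weights, forward pass, backprop and the Adam loop for one network."""

    def __init__(
        self,
        *,
        task: str,
        n_outputs: int,
        smiles_length: int,
        n_descriptors: int,
        vocab_size: int = 94,
        embedding_dim: int = 100,
        conv_filters: int = 64,
        conv_kernel: int = 5,
        hidden_sizes: tuple[int, ...] = (512, 128),
        merge_units: int = 128,
        dropout: float = 0.2,
        learning_rate: float = 1e-3,
        epochs: int = 50,
        batch_size: int = 64,
        seed: int = 0,
    ):
        if task not in ("binary", "multiclass", "regression"):
            raise ValueError(f"unknown task {task!r}")
        if smiles_length == 0 and n_descriptors == 0:
            raise ValueError("at least one branch (SMILES or descriptors) is required")
        if smiles_length and smiles_length < conv_kernel:
            raise ValueError("smiles_length must be >= conv_kernel")
        self.task = task
        self.n_outputs = n_outputs
        self.L = smiles_length
        self.p = n_descriptors
        self.V = vocab_size
        self.d = embedding_dim
        self.F = conv_filters
        self.k = conv_kernel
        self.hidden_sizes = tuple(hidden_sizes)
        self.m = merge_units
        self.dropout = dropout
        self.lr = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self._init_params(np.random.default_rng(seed))

    # -- parameters --------------------------------------------------------

    def _init_params(self, rng):
        P = {}
        merged_in = 0
        if self.L:
            P["emb"] = rng.normal(0.0, 0.05, size=(self.V + 1, self.d))
            fan_in = self.k * self.d
            P["conv_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, self.F))
            P["conv_b"] = np.zeros(self.F)
            merged_in += self.F
        if self.p:
            prev = self.p
            for i, h in enumerate(self.hidden_sizes):
                P[f"ffnn_w{i}"] = rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, h))
                P[f"ffnn_b{i}"] = np.zeros(h)
                prev = h
            merged_in += prev if self.hidden_sizes else self.p
        P["merge_w"] = rng.normal(0.0, np.sqrt(2.0 / merged_in), size=(merged_in, self.m))
        P["merge_b"] = np.zeros(self.m)
        P["head_w"] = rng.normal(0.0, np.sqrt(1.0 / self.m), size=(self.m, self.n_outputs))
        P["head_b"] = np.zeros(self.n_outputs)
        self.params = P
        self._adam_m = {k: np.zeros_like(v) for k, v in P.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in P.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _forward(self, tokens, X, drop_rng=None):
        """Returns (raw head output, cache). ``drop_rng`` enables dropout."""
        P = self.params
        cache = {"tokens": tokens, "X": X}
        parts = []
        if self.L:
            E = P["emb"][tokens]  # (B, L, d)
            B = E.shape[0]
            T = self.L - self.k + 1
            col = np.empty((B, T, self.k * self.d))
            for j in range(self.k):
                col[:, :, j * self.d:(j + 1) * self.d] = E[:, j:j + T, :]
            Z = col.reshape(B * T, -1) @ P["conv_w"]
            Z = Z.reshape(B, T, self.F) + P["conv_b"]
            H = _relu(Z)
            arg = H.argmax(axis=1)  # (B, F)
            pool = np.take_along_axis(H, arg[:, None, :], axis=1)[:, 0, :]
            cache.update(col=col, Z=Z, arg=arg, T=T)
            parts.append(pool)
        if self.p:
            A = X
            acts = []
            masks = []
            for i in range(len(self.hidden_sizes)):
                A = _relu(A @ P[f"ffnn_w{i}"] + P[f"ffnn_b{i}"])
                if drop_rng is not None and self.dropout > 0:
                    mask = (drop_rng.random(A.shape) >= self.dropout) / (1.0 - self.dropout)
                    A = A * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(A)
            cache.update(ffnn_acts=acts, ffnn_masks=masks)
            parts.append(A)
        z = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        M_pre = z @ P["merge_w"] + P["merge_b"]
        M = _relu(M_pre)
        if drop_rng is not None and self.dropout > 0:
            mmask = (drop_rng.random(M.shape) >= self.dropout) / (1.0 - self.dropout)
            M = M * mmask
        else:
            mmask = None
        out = M @ P["head_w"] + P["head_b"]
        cache.update(z=z, M_pre=M_pre, M=M, mmask=mmask)
        return out, cache

    # -- loss and gradients -------------------------------------------------

    def _loss_and_dout(self, out, y):
        B = out.shape[0]
        if self.task == "binary":
            z = out[:, 0]
            # stable BCE on logits: softplus(z) - y*z
            loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
            dout = ((_sigmoid(z) - y) / B)[:, None]
        elif self.task == "multiclass":
            zmax = out.max(axis=1, keepdims=True)
            logsum = zmax[:, 0] + np.log(np.exp(out - zmax).sum(axis=1))
            loss = float(np.mean(logsum - out[np.arange(B), y]))
            probs = _softmax(out)
            probs[np.arange(B), y] -= 1.0
            dout = probs / B
        else:
            resid = out[:, 0] - y
            loss = float(np.mean(resid ** 2))
            dout = (2.0 * resid / B)[:, None]
        return loss, dout

    def _backward(self, dout, cache):
        P = self.params
        G = {}
        M = cache["M"]
        G["head_w"] = M.T @ dout
        G["head_b"] = dout.sum(axis=0)
        dM = dout @ P["head_w"].T
        if cache["mmask"] is not None:
            dM = dM * cache["mmask"]
        dM_pre = dM * (cache["M_pre"] > 0)
        G["merge_w"] = cache["z"].T @ dM_pre
        G["merge_b"] = dM_pre.sum(axis=0)
        dz = dM_pre @ P["merge_w"].T

        offset = 0
        if self.L:
            dpool = dz[:, :self.F]
            offset = self.F
            B, T = dpool.shape[0], cache["T"]
            dH = np.zeros((B, T, self.F))
            np.put_along_axis(dH, cache["arg"][:, None, :], dpool[:, None, :], axis=1)
            dZ = dH * (cache["Z"] > 0)
            col = cache["col"]
            G["conv_w"] = col.reshape(B * T, -1).T @ dZ.reshape(B * T, self.F)
            G["conv_b"] = dZ.sum(axis=(0, 1))
            dcol = dZ.reshape(B * T, self.F) @ P["conv_w"].T
            dcol = dcol.reshape(B, T, self.k * self.d)
            dE = np.zeros((B, self.L, self.d))
            for j in range(self.k):
                dE[:, j:j + T, :] += dcol[:, :, j * self.d:(j + 1) * self.d]
            dW_emb = np.zeros_like(P["emb"])
            np.add.at(dW_emb, cache["tokens"].reshape(-1), dE.reshape(-1, self.d))
            G["emb"] = dW_emb
        if self.p:
            dA = dz[:, offset:]
            acts = cache["ffnn_acts"]
            masks = cache["ffnn_masks"]
            for i in reversed(range(len(self.hidden_sizes))):
                if masks[i] is not None:
                    dA = dA * masks[i]
                # post-dropout activation sign equals the relu gate wherever the
                # dropout mask is nonzero; where it is zero dA is already zero
                dA = dA * (acts[i] > 0)
                inp = cache["X"] if i == 0 else acts[i - 1]
                G[f"ffnn_w{i}"] = inp.T @ dA
                G[f"ffnn_b{i}"] = dA.sum(axis=0)
                dA = dA @ P[f"ffnn_w{i}"].T
        return G

    def _adam_step(self, grads):
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, g in grads.items():
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # -- training loop -------------------------------------------------------

    def fit(self, tokens, X, y) -> list[float]:
        """Run the Adam loop; returns the per-epoch mean loss curve."""
        n = len(y)
        rng = np.random.default_rng(self.seed + 1)
        drop_rng = np.random.default_rng(self.seed + 2)
        loss_curve = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                bt = tokens[idx] if self.L else None
                bx = X[idx] if self.p else None
                out, cache = self._forward(bt, bx, drop_rng=drop_rng)
                loss, dout = self._loss_and_dout(out, y[idx])
                grads = self._backward(dout, cache)
                self._adam_step(grads)
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise DivergenceError(epoch)
            loss_curve.append(epoch_loss)
        return loss_curve

    def predict_raw(self, tokens, X, batch_size: int = 1024) -> np.ndarray:
        """Head outputs (logits or values) with dropout disabled."""
        n = tokens.shape[0] if self.L else X.shape[0]
        outs = []
        for start in range(0, n, batch_size):
            bt = tokens[start:start + batch_size] if self.L else None
            bx = X[start:start + batch_size] if self.p else None
            out, _ = self._forward(bt, bx, drop_rng=None)
            outs.append(out)
        return np.vstack(outs) if outs else np.zeros((0, self.n_outputs))
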