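"""Compact NumPy convolutional network for genomic prediction.

Small 1-D CNN over the SNP axis: repeated [conv -> ReLU -> max-pool]
blocks, a dense ReLU layer with dropout, and a linear output. The phased
variant treats the two gametes as a preserved "phase" axis: the same
convolutional stack runs on each phase slice (shared weights) and the
phase axis is collapsed by mean pooling just before the dense head, so a
network fed two identical phase slices computes exactly what the unphased
network computes on the equivalent input.

Sized for marker subsets (tens to a few hundred SNPs) and training sets of
a few hundred trees; trained with Adam on mean-squared error.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CnnRegressor"]


def _conv1d_forward(x, W, b):
    """x: (N, L, Cin); W: (kw, Cin, Cout); valid convolution."""
    N, L, Cin = x.shape
    kw, _, Cout = W.shape
    Lo = L - kw + 1
    # im2col: (N, Lo, kw*Cin)
    cols = np.lib.stride_tricks.sliding_window_view(x, kw, axis=1)  # (N, Lo, Cin, kw)
    cols = cols.transpose(0, 1, 3, 2).reshape(N, Lo, kw * Cin)
    out = cols @ W.reshape(kw * Cin, Cout) + b
    return out, cols


def _maxpool_forward(x, size=2):
    N, L, C = x.shape
    Lo = L // size
    if Lo == 0:
        return x, None, False
    xt = x[:, : Lo * size].reshape(N, Lo, size, C)
    idx = xt.argmax(axis=2)
    out = xt.max(axis=2)
    return out, (idx, x.shape), True


class CnnRegressor:
    """1-D CNN regressor with an optional preserved phase axis.

    Parameters mirror the tunable search space: number of conv blocks,
    filters, kernel width, dense width, dropout rate, learning rate and
    batch size; epochs are a fixed budget.
    """

    def __init__(self, n_blocks=1, filters=8, kernel_width=3, dense_units=16,
                 dropout=0.1, learning_rate=1e-3, batch_size=32, epochs=40,
                 phased=False, seed=0):
        self.n_blocks = int(n_blocks)
        self.filters = int(filters)
        self.kernel_width = int(kernel_width)
        self.dense_units = int(dense_units)
        self.dropout = float(dropout)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.epochs = int(epochs)
        self.phased = bool(phased)
        self.seed = int(seed)
        self.params_ = None

    # ---- parameter handling -------------------------------------------------
    def _init_params(self, n_snps):
        rng = np.random.default_rng(self.seed)
        params = []
        cin, L = 1, n_snps
        for _ in range(self.n_blocks):
            kw = min(self.kernel_width, L)
            W = rng.normal(0, np.sqrt(2.0 / (kw * cin)), size=(kw, cin, self.filters))
            params.append([W, np.zeros(self.filters)])
            L = L - kw + 1
            if L // 2 > 0:
                L //= 2
            cin = self.filters
        flat = L * cin
        Wd = rng.normal(0, np.sqrt(2.0 / flat), size=(flat, self.dense_units))
        params.append([Wd, np.zeros(self.dense_units)])
        Wo = rng.normal(0, np.sqrt(1.0 / self.dense_units), size=(self.dense_units, 1))
        params.append([Wo, np.zeros(1)])
        self.params_ = params
        return rng

    # ---- forward / backward -------------------------------------------------
    def _forward(self, x, rng=None):
        """x: (N, L, 1) unphased or (N, L, 2) phased; returns (pred, cache)."""
        N = x.shape[0]
        if self.phased:
            # fold the phase axis into the batch, shared weights per slice
            P = x.shape[2]
            h = x.transpose(0, 2, 1).reshape(N * P, -1, 1)
        else:
            P = 1
            h = x
        cache = {"convs": [], "P": P, "N": N}
        for li in range(self.n_blocks):
            W, b = self.params_[li]
            z, cols = _conv1d_forward(h, W, b)
            a = np.maximum(z, 0.0)
            p, pool_cache, pooled = _maxpool_forward(a)
            cache["convs"].append((cols, z, a.shape, pool_cache, pooled))
            h = p
        flat = h.reshape(h.shape[0], -1)
        if self.phased:
            flat = flat.reshape(N, P, -1).mean(axis=1)  # collapse phase axis
        cache["flat_in_shape"] = h.shape
        cache["flat"] = flat
        Wd, bd = self.params_[self.n_blocks]
        zd = flat @ Wd + bd
        ad = np.maximum(zd, 0.0)
        if rng is not None and self.dropout > 0:
            mask = (rng.random(ad.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(ad)
        ad_d = ad * mask
        Wo, bo = self.params_[self.n_blocks + 1]
        pred = (ad_d @ Wo + bo).ravel()
        cache.update(zd=zd, ad_d=ad_d, mask=mask)
        return pred, cache

    def _backward(self, x, err, cache):
        grads = [None] * len(self.params_)
        N = cache["N"]
        P = cache["P"]
        g = err[:, None] / len(err)  # d MSE/2 d pred
        Wo, _ = self.params_[self.n_blocks + 1]
        grads[self.n_blocks + 1] = [cache["ad_d"].T @ g, g.sum(axis=0)]
        g = (g @ Wo.T) * cache["mask"] * (cache["zd"] > 0)
        Wd, _ = self.params_[self.n_blocks]
        grads[self.n_blocks] = [cache["flat"].T @ g, g.sum(axis=0)]
        g = g @ Wd.T
        if self.phased:
            g = np.repeat(g[:, None, :] / P, P, axis=1).reshape(N * P, -1)
        g = g.reshape(cache["flat_in_shape"])
        for li in range(self.n_blocks - 1, -1, -1):
            cols, z, a_shape, pool_cache, pooled = cache["convs"][li]
            if pooled:
                idx, full_shape = pool_cache
                Nb, Lo, C = g.shape
                up = np.zeros((Nb, Lo, 2, C))
                ii, jj, cc = np.ogrid[:Nb, :Lo, :C]
                up[ii, jj, idx, cc] = g
                ga = np.zeros(a_shape)
                ga[:, : Lo * 2] = up.reshape(Nb, Lo * 2, C)
            else:
                ga = g
            gz = ga * (z > 0)
            W, _ = self.params_[li]
            kwCin = W.shape[0] * W.shape[1]
            gW = (cols.reshape(-1, kwCin).T @ gz.reshape(-1, W.shape[2])).reshape(W.shape)
            gb = gz.sum(axis=(0, 1))
            grads[li] = [gW, gb]
            if li > 0:
                gcols = gz @ W.reshape(kwCin, -1).T  # (Nb, Lo, kw*Cin)
                kw, Cin = W.shape[0], W.shape[1]
                Nb, Lo, _ = gz.shape
                Lprev = Lo + kw - 1
                gx = np.zeros((Nb, Lprev, Cin))
                gcols = gcols.reshape(Nb, Lo, kw, Cin)
                for t in range(kw):
                    gx[:, t : t + Lo] += gcols[:, :, t]
                g = gx
        return grads

    # ---- training -----------------------------------------------------------
    def fit(self, X, y):
        """X: (N, L) codes for the unphased net or (N, L, 2) 0/1 phase."""
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if self.phased:
            if X.ndim != 3 or X.shape[2] != 2:
                raise ValueError("phased network expects (N, L, 2) input")
            x = X
        else:
            if X.ndim != 2:
                raise ValueError("unphased network expects (N, L) input")
            x = X[:, :, None]
        rng = self._init_params(X.shape[1])
        mom = [[np.zeros_like(W), np.zeros_like(b)] for W, b in self.params_]
        vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in self.params_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(y)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                if len(idx) < 2:
                    continue
                pred, cache = self._forward(x[idx], rng=rng)
                grads = self._backward(x[idx], pred - y[idx], cache)
                t += 1
                for li, gpair in enumerate(grads):
                    for k in range(2):
                        gk = gpair[k]
                        mom[li][k] = b1 * mom[li][k] + (1 - b1) * gk
                        vel[li][k] = b2 * vel[li][k] + (1 - b2) * gk**2
                        mhat = mom[li][k] / (1 - b1**t)
                        vhat = vel[li][k] / (1 - b2**t)
                        self.params_[li][k] -= (
                            self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                        )
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        x = X if self.phased else X[:, :, None]
        pred, _ = self._forward(x, rng=None)
        return pred
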