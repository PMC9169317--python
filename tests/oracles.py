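"""Independent brute-force oracles used by the test-suite.

Everything here is written as literal per-element loops over the defining
formulas, deliberately sharing no code with the library implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


# --------------------------------------------------------------------------
# Squeeze-and-excitation
# --------------------------------------------------------------------------

def se_oracle(x, w1, b1, w2, b2):
    """Per-channel loop: mean -> FC -> ReLU -> FC -> sigmoid -> scale."""
    c, h, w = x.shape
    means = [float(np.mean(x[ch])) for ch in range(c)]
    hidden = []
    for j in range(w1.shape[1]):
        v = b1[j] + sum(means[i] * w1[i, j] for i in range(c))
        hidden.append(max(v, 0.0))
    out = np.zeros_like(x)
    for ch in range(c):
        v = b2[ch] + sum(hidden[j] * w2[j, ch] for j in range(len(hidden)))
        out[ch] = x[ch] * _sigmoid(v)
    return out


# --------------------------------------------------------------------------
# Non-local block (positional attention)
# --------------------------------------------------------------------------

def _conv1x1_vectors(x, weight, bias):
    """Apply a 1x1 conv (weight (O,C,1,1)) to every position; returns
    a list of O-vectors indexed by flattened position."""
    c, h, w = x.shape
    o = weight.shape[0]
    vecs = []
    for i in range(h * w):
        xi = np.array([x[ch, i // w, i % w] for ch in range(c)])
        v = np.zeros(o)
        for oc in range(o):
            v[oc] = float(np.dot(weight[oc, :, 0, 0], xi))
            if bias is not None:
                v[oc] += bias[oc]
        vecs.append(v)
    return vecs


def nl_oracle(x, wt, bt, wp, bp, wg, bg, wz, bz, similarity):
    """Double loop over all position pairs evaluating the non-local sum."""
    c, h, w = x.shape
    n = h * w
    theta = _conv1x1_vectors(x, wt, bt)
    phi = _conv1x1_vectors(x, wp, bp)
    g = _conv1x1_vectors(x, wg, bg)
    cbar = wt.shape[0]
    y = [np.zeros(cbar) for _ in range(n)]
    for i in range(n):
        f = np.array([float(np.dot(theta[i], phi[j])) for j in range(n)])
        if similarity == "embedded_gaussian":
            e = np.exp(f - f.max())
            weights = e / e.sum()
        else:
            weights = f / n
        for j in range(n):
            y[i] = y[i] + weights[j] * g[j]
    out = np.zeros_like(x)
    for i in range(n):
        zi = np.zeros(c)
        for oc in range(c):
            zi[oc] = float(np.dot(wz[oc, :, 0, 0], y[i]))
            if bz is not None:
                zi[oc] += bz[oc]
        for oc in range(c):
            out[oc, i // w, i % w] = zi[oc] + x[oc, i // w, i % w]
    return out


def nl_attention_oracle(x, wt, bt, wp, bp, similarity):
    """Direct exp/normalise loop for the (HW)x(HW) attention matrix."""
    c, h, w = x.shape
    n = h * w
    theta = _conv1x1_vectors(x, wt, bt)
    phi = _conv1x1_vectors(x, wp, bp)
    attn = np.zeros((n, n))
    for i in range(n):
        logits = np.array([float(np.dot(theta[i], phi[j])) for j in range(n)])
        if similarity == "embedded_gaussian":
            e = np.exp(logits - logits.max())
            attn[i] = e / e.sum()
        else:
            attn[i] = logits / n
    return attn


# --------------------------------------------------------------------------
# Deformed non-local block (channel attention)
# --------------------------------------------------------------------------

def dnl_oracle(x, wt, bt, wp, bp, wg, bg, w_pool, b_pool, w_red, b_red,
               w_exp, b_exp, w_out, b_out, se_w1, se_b1, se_w2, se_b2,
               gate="sigmoid"):
    """Step-by-step scalar-loop evaluation of the channel-attention chain."""
    c, h, w = x.shape
    n = h * w
    cbar = wt.shape[0]
    xf = x.reshape(c, n)

    def conv_rows(weight, bias):
        out_ch = weight.shape[0]
        rows = np.zeros((out_ch, n))
        for oc in range(out_ch):
            for k in range(n):
                rows[oc, k] = float(np.dot(weight[oc, :, 0, 0], xf[:, k]))
                if bias is not None:
                    rows[oc, k] += bias[oc]
        return rows

    t = conv_rows(wt, bt)
    p = conv_rows(wp, bp)
    gmat = conv_rows(wg, bg)
    # channel-channel similarity, softmax per query row
    attn = np.zeros((cbar, cbar))
    for a in range(cbar):
        logits = np.array([float(np.dot(t[a], p[b])) for b in range(cbar)])
        e = np.exp(logits - logits.max())
        attn[a] = e / e.sum()
    y1 = np.zeros((cbar, n))
    for a in range(cbar):
        for k in range(n):
            y1[a, k] = sum(attn[a, b] * gmat[b, k] for b in range(cbar))
    pooled = conv_rows(w_pool, b_pool)[0]          # (HW,)
    y2 = np.array([float(np.dot(pooled, y1[b])) for b in range(cbar)])
    y3 = np.maximum(y2 @ w_red + b_red, 0.0)
    y4 = y3 @ w_exp + b_exp
    if gate == "sigmoid":
        y4 = np.array([_sigmoid(v) for v in y4])
    ox = conv_rows(w_out, b_out)
    y = np.zeros_like(x)
    for ch in range(c):
        for k in range(n):
            y[ch, k // w, k % w] = y4[ch] * ox[ch, k]
    y = se_oracle(y, se_w1, se_b1, se_w2, se_b2)
    return y + x


def dnl_oracle_from_block(x, block):
    """Convenience: pull weights out of a DNLBlock and run `dnl_oracle`."""
    def wb(conv):
        return conv.weight.data, (None if conv.bias is None else conv.bias.data)

    return dnl_oracle(
        x, *wb(block.theta), *wb(block.phi), *wb(block.g), *wb(block.pool),
        block.reduce.weight.data, block.reduce.bias.data,
        block.expand.weight.data, block.expand.bias.data,
        *wb(block.out_conv),
        block.se_tail.fc1.weight.data, block.se_tail.fc1.bias.data,
        block.se_tail.fc2.weight.data, block.se_tail.fc2.bias.data,
        gate=block.gate)


def nl_oracle_from_block(x, block):
    def wb(conv):
        return conv.weight.data, (None if conv.bias is None else conv.bias.data)

    return nl_oracle(x, *wb(block.theta), *wb(block.phi), *wb(block.g),
                     *wb(block.wz), similarity=block.similarity)


# --------------------------------------------------------------------------
# Channel attention vector (GAP -> L2 normalise -> linear -> gate)
# --------------------------------------------------------------------------

def av_oracle(x, weight, bias, gate="sigmoid"):
    c = x.shape[0]
    means = np.array([float(np.mean(x[ch])) for ch in range(c)])
    norm = math.sqrt(sum(v * v for v in means))
    normed = means / norm if norm > 0 else means
    av = normed @ weight + (bias if bias is not None else 0.0)
    if gate == "sigmoid":
        av = np.array([_sigmoid(v) for v in av])
    return av


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def confusion_oracle(pred, mask):
    tp = fp = tn = fn = 0
    for p, m in zip(np.ravel(pred), np.ravel(mask)):
        if p == 1 and m == 1:
            tp += 1
        elif p == 1 and m == 0:
            fp += 1
        elif p == 0 and m == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def dice_oracle(pred, mask):
    num = den = 0.0
    for p, q in zip(np.ravel(pred).astype(float), np.ravel(mask).astype(float)):
        num += p * q
        den += p * p + q * q
    return 2.0 * num / den if den else 1.0


def miou_oracle(pred, mask, k=2):
    ious = []
    pr, mr = np.ravel(pred), np.ravel(mask)
    for c in range(k):
        inter = union = 0
        for p, m in zip(pr, mr):
            if p == c and m == c:
                inter += 1
            if p == c or m == c:
                union += 1
        if union:
            ious.append(inter / union)
    return sum(ious) / len(ious) if ious else float("nan")


def auc_pairwise_oracle(scores, labels):
    """Mann–Whitney statistic by exhaustive positive/negative comparison."""
    s = np.ravel(scores)
    y = np.ravel(labels)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins) / (pos.shape[0] * neg.shape[1])
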