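"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid numpy vectorisation and the package's own code
paths: plain loops and textbook formulas only.
"""

import numpy as np


def naive_statistical(series):
    """Loop-based reference for the 8-statistic battery."""
    x = list(map(float, series))
    n = len(x)
    mean = sum(x) / n
    mx, mn = max(x), min(x)
    if mx == mn:
        return [mean, 0.0, mx, mn, 0.0, 0.0, 0.0, 0]
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = var ** 0.5
    tbar = (n - 1) / 2
    denom = sum((i - tbar) ** 2 for i in range(n))
    slope = sum((i - tbar) * (v - mean) for i, v in enumerate(x)) / denom
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    skw = m3 / m2 ** 1.5
    signs = [1 if v > mean else -1 for v in x if v != mean]
    zc = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    return [mean, sd, mx, mn, mx - mn, slope, skw, zc]


def naive_kernel(series, k):
    """Triple-loop dilated convolution with (max, ppv) pooling."""
    x = [0.0] * k.padding + list(map(float, series)) + [0.0] * k.padding
    outs = []
    n_out = len(x) - (k.length - 1) * k.dilation
    for i in range(n_out):
        s = k.bias
        for j in range(k.length):
            s += k.weights[j] * x[i + j * k.dilation]
        outs.append(s)
    return max(outs), sum(1 for v in outs if v > 0) / len(outs)


def naive_metrics(y_true, y_pred, n_classes=3):
    """Confusion-tally oracle for accuracy and macro precision/recall/F1."""
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    acc = np.trace(conf) / conf.sum()
    precs, recs, f1s = [], [], []
    for c in range(n_classes):
        tp = conf[c, c]
        prec = tp / conf[:, c].sum() if conf[:, c].sum() else 0.0
        rec = tp / conf[c, :].sum() if conf[c, :].sum() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return (100 * acc, 100 * float(np.mean(precs)), 100 * float(np.mean(recs)),
            100 * float(np.mean(f1s)))


def naive_kw_statistic(groups):
    """Rank-based Kruskal-Wallis H with tie correction, from scratch."""
    pooled = np.concatenate(groups)
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty_like(pooled)
    sorted_vals = pooled[order]
    r = np.arange(1, len(pooled) + 1, dtype=float)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i:j + 1] = r[i:j + 1].mean()
        i = j + 1
    ranks[order] = r
    N = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        n = len(g)
        rbar = ranks[start:start + n].mean()
        h += n * (rbar - (N + 1) / 2) ** 2
        start += n
    h *= 12 / (N * (N + 1))
    _, t = np.unique(pooled, return_counts=True)
    corr = 1 - (t**3 - t).sum() / (N**3 - N)
    return h / corr
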