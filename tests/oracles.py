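"""Independent brute-force reference implementations used by the tests.

These are deliberately written as plain double loops over definitions,
sharing no code with the package.
"""

import math

import numpy as np


def apen_oracle(x, m, r):
    """Approximate entropy: O(N^2) double loop, Chebyshev, self-matches,
    strict < r."""
    x = [float(v) for v in x]
    n = len(x)

    def phi(mm):
        cnt = n - mm + 1
        vecs = [x[i:i + mm] for i in range(cnt)]
        total = 0.0
        for i in range(cnt):
            c = 0
            for j in range(cnt):
                if max(abs(a - b) for a, b in zip(vecs[i], vecs[j])) < r:
                    c += 1
            total += math.log(c / cnt)
        return total / cnt

    return phi(m) - phi(m + 1)


def higuchi_oracle(x, k_max):
    """Higuchi FD: explicit loops over k and start offset, then a hand-rolled
    least-squares slope of log length vs log k."""
    x = [float(v) for v in x]
    n = len(x)
    log_k, log_len = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                continue
            dist = 0.0
            for i in range(1, n_i + 1):
                dist += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            lengths.append(dist * (n - 1) / (n_i * k * k))
        if lengths:
            mean_len = sum(lengths) / len(lengths)
            if mean_len > 0:
                log_k.append(math.log(k))
                log_len.append(math.log(mean_len))
    if len(log_k) < 2:
        return 1.0
    mx = sum(log_k) / len(log_k)
    my = sum(log_len) / len(log_len)
    sxx = sum((v - mx) ** 2 for v in log_k)
    sxy = sum((a - mx) * (b - my) for a, b in zip(log_k, log_len))
    return -sxy / sxx


def nsi_oracle(x, n_segments):
    """Instability index with numpy's array_split segmentation, looped."""
    segments = np.array_split(np.asarray(x, dtype=float), n_segments)
    means = [float(sum(seg) / len(seg)) for seg in segments]
    mu = sum(means) / len(means)
    return math.sqrt(sum((v - mu) ** 2 for v in means) / len(means))


def mi_matrix_oracle(X, n_bins):
    """Histogram MI matrix via explicit bin counting double loops."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape

    def bins(col):
        lo, hi = col.min(), col.max()
        span = hi - lo if hi > lo else 1.0
        idx = []
        for v in col:
            b = int((v - lo) / span * n_bins)
            idx.append(min(max(b, 0), n_bins - 1))
        return idx

    def entropy(counts):
        total = sum(counts)
        h = 0.0
        for c in counts:
            if c > 0:
                p = c / total
                h -= p * math.log(p)
        return h

    binned = [bins(X[:, j]) for j in range(n)]
    marg_h = []
    for j in range(n):
        counts = [0] * n_bins
        for b in binned[j]:
            counts[b] += 1
        marg_h.append(entropy(counts))
    out = np.zeros((n, n))
    for j in range(n):
        out[j, j] = marg_h[j]
        for k in range(j + 1, n):
            joint = {}
            for a, b in zip(binned[j], binned[k]):
                joint[(a, b)] = joint.get((a, b), 0) + 1
            h_joint = entropy(list(joint.values()))
            mi = max(marg_h[j] + marg_h[k] - h_joint, 0.0)
            out[j, k] = out[k, j] = mi
    return out
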