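"""Independent brute-force oracles used by the tests.

Every function here deliberately re-derives a quantity by the most direct
method available (enumeration, scalar loops, the textbook formula) so that
the vectorized implementations in the package are checked against a second,
structurally different computation.
"""

import itertools
import math

import numpy as np


def bh_stepup_bruteforce(p):
    """Benjamini-Hochberg by the literal step-up definition:
    q_i = min over j with rank >= rank(i) of p_(j) * n / rank(j), capped."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        val = p[i] * n / (pos + 1)
        if pos < n - 1:
            val = min(val, q[order[pos + 1]])
        q[i] = min(val, 1.0)
    return np.array(q)


def enumerate_word_pvalues(bins, background):
    """Exact p-values of every L-mer by full enumeration of 4^L words.

    ``bins`` is the L x 4 integer score matrix (may contain -inf); the
    p-value of a word is the total background probability of words with an
    equal or larger integer score. Returns (words, scores, pvalues).
    """
    L = bins.shape[0]
    words = list(itertools.product(range(4), repeat=L))
    scores = []
    probs = []
    for w in words:
        s = sum(bins[i, b] for i, b in enumerate(w))
        pr = math.prod(background[b] for b in w)
        scores.append(s)
        probs.append(pr)
    scores = np.array(scores)
    probs = np.array(probs)
    pvals = np.array(
        [
            probs[np.isfinite(scores) & (scores >= s)].sum()
            if np.isfinite(s)
            else 1.0
            for s in scores
        ]
    )
    return words, scores, pvals


def tanimoto_scalar(x, y):
    dot = sum(a * b for a, b in zip(x, y))
    rad = sum(a * a for a in x) + sum(b * b for b in y) - abs(dot)
    if rad <= 0:
        return 0.0
    return dot / math.sqrt(rad)


def normalize_scalar(m):
    """(z_row + z_col)/sqrt(2) by explicit loops, population SD."""
    m = [list(row) for row in m]
    nr, nc = len(m), len(m[0])
    out = [[0.0] * nc for _ in range(nr)]
    rmean = [sum(row) / nc for row in m]
    rsd = [math.sqrt(sum((v - rmean[i]) ** 2 for v in m[i]) / nc) for i in range(nr)]
    cmean = [sum(m[i][j] for i in range(nr)) / nr for j in range(nc)]
    csd = [
        math.sqrt(sum((m[i][j] - cmean[j]) ** 2 for i in range(nr)) / nr)
        for j in range(nc)
    ]
    for i in range(nr):
        for j in range(nc):
            zr = (m[i][j] - rmean[i]) / rsd[i] if rsd[i] > 0 else 0.0
            zc = (m[i][j] - cmean[j]) / csd[j] if csd[j] > 0 else 0.0
            out[i][j] = (zr + zc) / math.sqrt(2)
    return out


def panda_one_step_scalar(w0, p0, c0, alpha):
    """One message-passing iteration evaluated step by step with scalar
    loops: normalize the three inputs, compute responsibility and
    availability via the Tanimoto kernel, and blend into W."""
    W = normalize_scalar(w0)
    P = normalize_scalar(p0)
    C = normalize_scalar(c0)
    nt = len(W)
    ng = len(W[0])
    R = [
        [
            tanimoto_scalar(P[i], [W[k][j] for k in range(nt)])
            for j in range(ng)
        ]
        for i in range(nt)
    ]
    A = [
        [
            tanimoto_scalar(W[i], [C[k][j] for k in range(ng)])
            for j in range(ng)
        ]
        for i in range(nt)
    ]
    return [
        [
            (1 - alpha) * W[i][j] + alpha * 0.5 * (R[i][j] + A[i][j])
            for j in range(ng)
        ]
        for i in range(nt)
    ]
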