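"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a direct, loop-based transcription of the
defining formula, sharing no code with the package implementations it
checks.
"""

import math

import numpy as np


def brute_nt_xent(z, tau):
    """NT-Xent by explicit double loops over all ordered similarity terms.

    Rows 2k and 2k+1 are positive pairs; cosine similarity; each anchor's
    denominator sums over every other row.
    """
    z = np.asarray(z, dtype=float)
    two_n = z.shape[0]
    sim = np.empty((two_n, two_n))
    for i in range(two_n):
        for j in range(two_n):
            sim[i, j] = float(z[i] @ z[j]) / (
                np.linalg.norm(z[i]) * np.linalg.norm(z[j])
            )
    total = 0.0
    for i in range(two_n):
        j = i + 1 if i % 2 == 0 else i - 1
        denom = sum(math.exp(sim[i, k] / tau) for k in range(two_n) if k != i)
        total += -math.log(math.exp(sim[i, j] / tau) / denom)
    return total / two_n


def brute_ari(truth, pred):
    """Adjusted Rand index from the pair-counting contingency formula."""
    truth = list(truth)
    pred = list(pred)
    n = len(truth)
    t_labels = sorted(set(truth))
    p_labels = sorted(set(pred))
    table = [[0] * len(p_labels) for _ in t_labels]
    for t, p in zip(truth, pred):
        table[t_labels.index(t)][p_labels.index(p)] += 1

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = sum(comb2(c) for row in table for c in row)
    sum_i = sum(comb2(sum(row)) for row in table)
    sum_j = sum(comb2(sum(col)) for col in zip(*table))
    expected = sum_i * sum_j / comb2(n)
    max_index = (sum_i + sum_j) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def brute_nmi(truth, pred):
    """NMI via explicit entropy sums, arithmetic-mean normalisation."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = truth.size

    def entropy(labels):
        h = 0.0
        for value in set(labels.tolist()):
            p = (labels == value).sum() / n
            h -= p * math.log(p)
        return h

    mi = 0.0
    for t in set(truth.tolist()):
        for p in set(pred.tolist()):
            joint = ((truth == t) & (pred == p)).sum() / n
            if joint > 0:
                pt = (truth == t).sum() / n
                pp = (pred == p).sum() / n
                mi += joint * math.log(joint / (pt * pp))
    ht, hp = entropy(truth), entropy(pred)
    if ht == 0 or hp == 0:
        return 0.0
    return mi / ((ht + hp) / 2)


def brute_silhouette(z, labels):
    """Mean of (b - a)/max(a, b) with explicit pairwise Euclidean loops."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    n = z.shape[0]
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(z[i] - z[j]) for j in same])
        b = min(
            np.mean(
                [np.linalg.norm(z[i] - z[j]) for j in range(n) if labels[j] == other]
            )
            for other in set(labels.tolist())
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def brute_calinski(z, labels):
    """[B/(K-1)] / [W/(n-K)] with explicit centroid sums."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    n = z.shape[0]
    clusters = sorted(set(labels.tolist()))
    k = len(clusters)
    overall = z.mean(axis=0)
    b = w = 0.0
    for c in clusters:
        members = z[labels == c]
        centroid = members.mean(axis=0)
        b += members.shape[0] * float(((centroid - overall) ** 2).sum())
        w += float(((members - centroid) ** 2).sum())
    return (b / (k - 1)) / (w / (n - k))
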