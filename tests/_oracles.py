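"""Independent brute-force reference implementations used by the tests.

Each oracle restates the defining computation in the most literal way
possible (explicit loops, no shared code with the package) so that the
vectorised implementations can be checked against it.
"""

from __future__ import annotations

import math

import numpy as np


def auc_pair_counting(pos, neg) -> float:
    """AUC by exhaustive pair enumeration, ties counting one half."""
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition.

    q_(i) = min over j >= i of (m * p_(j) / j), mapped back to input order.
    """
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running_min = math.inf
    for rank in range(m - 1, -1, -1):
        val = m * p[order[rank]] / (rank + 1)
        running_min = min(running_min, val, 1.0)
        q_sorted[rank] = running_min
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return np.array(q)


def normfinder_oracle(y: np.ndarray, group_labels) -> np.ndarray:
    """Grouped stability values by direct (looped) variance-component algebra.

    Implements, step by step: candidate-set sample centering; per gene/group
    sample means m and variances s2 of the centered data; unbiased intragroup
    variances (for >= 3 genes); intergroup biases d (group mean minus the
    gene's across-group mean); the moment estimate of the between-gene bias
    variance gamma2; and the per-gene stability
    mean_g(|d| * g2/(g2+v) + sqrt(v)) with v = sigma2/n_g.
    """
    n_genes, n_samples = y.shape
    labels = []
    for lab in group_labels:
        if lab not in labels:
            labels.append(lab)
    n_groups = len(labels)

    z = np.zeros_like(y, dtype=float)
    for j in range(n_samples):
        col_mean = sum(y[i, j] for i in range(n_genes)) / n_genes
        for i in range(n_genes):
            z[i, j] = y[i, j] - col_mean

    m = np.zeros((n_genes, n_groups))
    s2 = np.zeros((n_genes, n_groups))
    k = np.zeros(n_groups)
    for g, lab in enumerate(labels):
        idx = [j for j in range(n_samples) if group_labels[j] == lab]
        k[g] = len(idx)
        for i in range(n_genes):
            vals = [z[i, j] for j in idx]
            mu = sum(vals) / len(vals)
            m[i, g] = mu
            s2[i, g] = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)

    sigma2 = np.zeros((n_genes, n_groups))
    for g in range(n_groups):
        if n_genes >= 3:
            total = sum(s2[i, g] for i in range(n_genes)) * n_genes / (n_genes - 1)
            for i in range(n_genes):
                est = (s2[i, g] - total / n_genes**2) * n_genes / (n_genes - 2)
                sigma2[i, g] = max(est, 0.0)
        else:
            for i in range(n_genes):
                sigma2[i, g] = s2[i, g]

    d = np.zeros((n_genes, n_groups))
    for i in range(n_genes):
        row_mean = sum(m[i, g] for g in range(n_groups)) / n_groups
        for g in range(n_groups):
            d[i, g] = m[i, g] - row_mean

    var_d = np.zeros((n_genes, n_groups))
    for i in range(n_genes):
        for g in range(n_groups):
            var_d[i, g] = sigma2[i, g] / k[g]

    d2_sum = sum(d[i, g] ** 2 for i in range(n_genes) for g in range(n_groups))
    gamma2 = d2_sum / ((n_genes - 1) * max(n_groups - 1, 1)) - var_d.mean()
    gamma2 = max(gamma2, 0.0)

    rho = np.zeros(n_genes)
    for i in range(n_genes):
        acc = 0.0
        for g in range(n_groups):
            v = var_d[i, g]
            shrink = gamma2 / (gamma2 + v) if gamma2 > 0 else 0.0
            acc += abs(d[i, g]) * shrink + math.sqrt(v)
        rho[i] = acc / n_groups
    return rho


def curate_cell_oracle(cts, qualities, ct_limit=25.0, quality_min=0.65):
    """Final Ct of one sample x assay cell by literal rule application."""
    passing = []
    for ct, q in zip(cts, qualities):
        if ct is None or (isinstance(ct, float) and math.isnan(ct)):
            continue
        if ct > ct_limit:
            continue
        if q is None or (isinstance(q, float) and math.isnan(q)) or q < quality_min:
            continue
        passing.append(ct)
    if not passing:
        return float("nan")
    passing.sort()
    n = len(passing)
    if n % 2:
        return passing[n // 2]
    return 0.5 * (passing[n // 2 - 1] + passing[n // 2])


def pearson_formula(x, y) -> float:
    """Pearson r by the textbook sum formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
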