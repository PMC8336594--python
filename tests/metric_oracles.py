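"""Brute-force clustering-metric oracles built straight from the
contingency table: pair counting for the adjusted Rand index, entropies
and mutual information for the normalized/adjusted scores, and the
exact hypergeometric expectation of mutual information.  Deliberately
independent of the package (and of scikit-learn): plain loops and
``math`` only.
"""

import math
from collections import Counter


def contingency(p, t):
    xs = sorted(set(p))
    ys = sorted(set(t))
    n = Counter(zip(p, t))
    return xs, ys, {(i, j): n[(i, j)] for i in xs for j in ys}


def ari_oracle(p, t) -> float:
    xs, ys, n = contingency(p, t)
    N = len(p)
    sum_ij = sum(math.comb(n[(i, j)], 2) for i in xs for j in ys)
    a = {i: sum(n[(i, j)] for j in ys) for i in xs}
    b = {j: sum(n[(i, j)] for i in xs) for j in ys}
    sum_a = sum(math.comb(v, 2) for v in a.values())
    sum_b = sum(math.comb(v, 2) for v in b.values())
    expected = sum_a * sum_b / math.comb(N, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def _entropy(counts, N) -> float:
    return -sum(c / N * math.log(c / N) for c in counts if c > 0)


def _mutual_info(p, t) -> float:
    xs, ys, n = contingency(p, t)
    N = len(p)
    a = {i: sum(n[(i, j)] for j in ys) for i in xs}
    b = {j: sum(n[(i, j)] for i in xs) for j in ys}
    mi = 0.0
    for i in xs:
        for j in ys:
            nij = n[(i, j)]
            if nij > 0:
                mi += nij / N * math.log(N * nij / (a[i] * b[j]))
    return mi


def nmi_oracle(p, t) -> float:
    N = len(p)
    hp = _entropy(Counter(p).values(), N)
    ht = _entropy(Counter(t).values(), N)
    mi = _mutual_info(p, t)
    if hp == 0 and ht == 0:
        return 1.0
    if hp == 0 or ht == 0:
        return 0.0
    return mi / math.sqrt(hp * ht)


def expected_mi_oracle(p, t) -> float:
    """Exact E[MI] under the permutation (hypergeometric) null model."""
    N = len(p)
    a = sorted(Counter(p).values())
    b = sorted(Counter(t).values())
    lg = math.lgamma
    emi = 0.0
    for ai in a:
        for bj in b:
            for nij in range(max(1, ai + bj - N), min(ai, bj) + 1):
                log_term = (
                    lg(ai + 1) + lg(bj + 1) + lg(N - ai + 1) + lg(N - bj + 1)
                    - lg(N + 1) - lg(nij + 1) - lg(ai - nij + 1)
                    - lg(bj - nij + 1) - lg(N - ai - bj + nij + 1)
                )
                emi += (nij / N) * math.log(N * nij / (ai * bj)) * math.exp(log_term)
    return emi


def ami_oracle(p, t) -> float:
    N = len(p)
    hp = _entropy(Counter(p).values(), N)
    ht = _entropy(Counter(t).values(), N)
    mi = _mutual_info(p, t)
    emi = expected_mi_oracle(p, t)
    denom = (hp + ht) / 2 - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def homogeneity_oracle(p, t) -> float:
    """1 - H(T|P)/H(T), with 1 by convention when H(T)=0."""
    N = len(p)
    ht = _entropy(Counter(t).values(), N)
    if ht == 0:
        return 1.0
    xs, ys, n = contingency(p, t)
    a = {i: sum(n[(i, j)] for j in ys) for i in xs}
    h_t_given_p = 0.0
    for i in xs:
        for j in ys:
            nij = n[(i, j)]
            if nij > 0:
                h_t_given_p -= nij / N * math.log(nij / a[i])
    return 1.0 - h_t_given_p / ht
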