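"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths (and libraries) they check:
Fisher's exact p-value by exact integer hypergeometric enumeration, and the
AUC by explicit pairwise comparison.
"""

from math import comb


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for the 2x2 table [[a, b], [c, d]] by enumerating
    all tables with the same margins and summing those no more probable than
    the observed one.  Probabilities are compared as exact integers
    (C(r1,k)*C(r2,c1-k)), so ties are handled without floating-point
    ambiguity."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    observed = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    tail = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        weight = comb(r1, k) * comb(r2, c1 - k)
        if weight <= observed:
            tail += weight
    return tail / total


def auc_pairwise(case_scores, control_scores) -> float:
    """AUC by brute force: fraction of (case, control) pairs where the case
    scores strictly lower (ties count 1/2); lower score = more diseased."""
    wins = 0.0
    for x in case_scores:
        for y in control_scores:
            if x < y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(case_scores) * len(control_scores))
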