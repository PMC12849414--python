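"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and, where feasible, the libraries)
they are checked against: exact integer hypergeometric enumeration for
Fisher's test, lgamma-based direct tail summation for the binomial test, the
hand step-up recursion for Benjamini-Hochberg, and a direct per-sample
enumeration for carrier-group assignment.
"""

import math
from fractions import Fraction

from carrierscreen.types import MISSING, Consequence, Loftee, Moi


def fisher_two_sided_oracle(k1, n1, k2, n2):
    """Exact two-sided Fisher p as a Fraction, by full hypergeometric enumeration.

    Probability-mass convention: sum P(table) over all tables with the same
    margins whose point probability does not exceed the observed one (integer
    weight comparison, so no floating-point ties).
    """
    col = k1 + k2  # carriers column total
    obs = math.comb(n1, k1) * math.comb(n2, k2)
    total = 0
    for x in range(max(0, col - n2), min(col, n1) + 1):
        w = math.comb(n1, x) * math.comb(n2, col - x)
        if w <= obs:
            total += w
    return Fraction(total, math.comb(n1 + n2, col))


def binomial_upper_tail_oracle(k, n, p):
    """P(K >= k) for K ~ Binom(n, p) by direct term-by-term summation."""
    if k <= 0:
        return 1.0
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    lp, lq = math.log(p), math.log1p(-p)
    lgn = math.lgamma(n + 1)
    s = 0.0
    for j in range(n, k - 1, -1):  # small terms first
        s += math.exp(lgn - math.lgamma(j + 1) - math.lgamma(n - j + 1) + j * lp + (n - j) * lq)
    return min(s, 1.0)


def bh_stepup_oracle(p_values):
    """BH adjusted p-values by the textbook step-up recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def group_assignment_oracle(matrix, variants, panel, cadd_min, scope):
    """Per-sample group labels by direct enumeration of every variant x gene MOI
    combination, independent of the classify module's filtering/join machinery."""
    genes = {
        g.gene: g.moi for g in panel if (g.nhs_panel if scope == "nhs" else g.extended_panel)
    }
    vindex = {v: j for j, v in enumerate(matrix.variant_ids)}
    groups = {}
    for i, sid in enumerate(matrix.sample_ids):
        any_carriage = False
        any_consistent = False
        for v in variants:
            if v.gene not in genes:
                continue
            if v.consequence is Consequence.INTRONIC:
                continue
            if v.cadd_phred < cadd_min:
                continue
            if v.loftee is Loftee.LC:
                continue
            if v.variant_id not in vindex:
                continue
            d = int(matrix.dosage[i, vindex[v.variant_id]])
            if d == MISSING or d == 0:
                continue
            any_carriage = True
            if genes[v.gene] is Moi.DOMINANT or d == 2:
                any_consistent = True
        groups[sid] = 3 if any_consistent else (2 if any_carriage else 1)
    return groups
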