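"""Estimators and exact tests for carrier-rate and oligogenic analyses.

The co-occurrence test for a gene pair works on capped gene loads of
MOI-consistent (group 3) carriers: the expected probability that one
individual carries qualifying variants in both genes is the product of the
two marginal carrier proportions, and the observed double-carrier count is
compared against it with an exact binomial test. Enrichment (upper tail) is
the default sidedness — the hypothesis of interest is excess co-occurrence —
with a two-sided option.

Cohort carrier-rate comparisons use Fisher's exact test (two-sided,
probability-mass convention). Confidence intervals are the Wald formula
p ± 1.96·sqrt(p(1−p)/n), clamped to [0, 1], matching the error bars used for
carriage-rate plots; multiple testing is addressed with Benjamini–Hochberg
FDR within one family of tests per run.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CarrierProfile, ValidationError

Z_95 = 1.96  # normal quantile behind the 95% Wald interval


@dataclass(frozen=True)
class ProportionEstimate:
    k: int
    n: int
    p: float
    ci_low: float
    ci_high: float


def proportion_ci(k: int, n: int) -> ProportionEstimate:
    """Wald 95% CI for a proportion: p ± 1.96·sqrt(p(1−p)/n), clamped to [0,1].

    Degenerate at p ∈ {0, 1}, where the half-width collapses to zero — a
    known property of the Wald interval, kept to match standard error-bar
    conventions for carriage-rate plots.
    """
    if n < 1:
        raise ValidationError(f"proportion undefined for n = {n}")
    if not 0 <= k <= n:
        raise ValidationError(f"k must lie in [0, n]; got k={k}, n={n}")
    p = k / n
    half = Z_95 * math.sqrt(p * (1.0 - p) / n)
    return ProportionEstimate(k=k, n=n, p=p, ci_low=max(0.0, p - half), ci_high=min(1.0, p + half))


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 → 3, −2.5 → −3), unlike banker's rounding."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def format_percent(k: int, n: int, decimals: int = 1) -> float:
    """k/n as a percentage rounded half-away-from-zero to ``decimals``."""
    return round_half_away(100.0 * k / n, decimals)


def fisher_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for carrier counts k1/n1 vs k2/n2.

    The 2×2 table is [[k1, n1−k1], [k2, n2−k2]]; two-sidedness follows the
    probability-mass convention (sum hypergeometric outcomes whose point
    probability does not exceed the observed table's).
    """
    for name, val in (("k1", k1), ("n1", n1), ("k2", k2), ("n2", n2)):
        if val < 0:
            raise ValidationError(f"{name} must be non-negative, got {val}")
    if n1 < 1 or n2 < 1:
        raise ValidationError("both cohort sizes must be >= 1")
    if k1 > n1 or k2 > n2:
        raise ValidationError("carrier count exceeds cohort size")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return min(p, 1.0)


@dataclass(frozen=True)
class CohortComparison:
    """One carrier-rate comparison between two cohorts."""

    label: str
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    fisher_p: float
    fdr_q: Optional[float] = None


def compare_cohorts(
    counts: Sequence[Tuple[str, int, int, int, int]], fdr: bool = True
) -> List[CohortComparison]:
    """Fisher-compare a family of (label, k1, n1, k2, n2) carrier counts.

    All comparisons in one call form one BH-FDR family; pass ``fdr=False``
    for standalone unadjusted tests.
    """
    raw = [fisher_exact(k1, n1, k2, n2) for _, k1, n1, k2, n2 in counts]
    qs: Sequence[Optional[float]] = bh_fdr(raw) if (fdr and raw) else [None] * len(raw)
    return [
        CohortComparison(
            label=label, k1=k1, n1=n1, k2=k2, n2=n2,
            p1=k1 / n1, p2=k2 / n2, fisher_p=p, fdr_q=q,
        )
        for (label, k1, n1, k2, n2), p, q in zip(counts, raw, qs)
    ]


def multi_gene_proportion(profiles: Sequence[CarrierProfile]) -> ProportionEstimate:
    """Proportion of group-3 carriers with capped load in ≥ 2 distinct genes.

    Because load is capped at 1 per gene, several variants in one gene never
    count as multi-gene carriage.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("empty profile list")
    if any(p.group != 3 for p in profiles):
        raise ValidationError("multi_gene_proportion expects group-3 profiles only")
    k = sum(1 for p in profiles if len(p.loaded_genes) >= 2)
    return proportion_ci(k, len(profiles))


def pair_expected_probability(marginal_a: float, marginal_b: float) -> float:
    """Chance probability of carrying variants in both genes of a pair.

    Product of the marginal carrier proportions, i.e. independence of the two
    genes' carriage; by construction never exceeds either marginal.
    """
    for name, m in (("marginal_a", marginal_a), ("marginal_b", marginal_b)):
        if not 0.0 <= m <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {m}")
    return marginal_a * marginal_b


def binomial_exact_test(
    k_obs: int, n: int, p0: float, alternative: str = "greater"
) -> float:
    """Exact binomial p-value for k_obs successes in n trials at null rate p0.

    Default is the upper tail P(K ≥ k_obs | n, p0) — the enrichment
    alternative used for gene-pair co-occurrence; ``alternative='two-sided'``
    gives the minimum-likelihood two-sided test.
    """
    if not 0 <= k_obs <= n:
        raise ValidationError(f"k_obs must lie in [0, n]; got k_obs={k_obs}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValidationError(f"p0 must lie in [0, 1], got {p0}")
    if alternative == "greater":
        p = float(sps.binom.sf(k_obs - 1, n, p0))
    elif alternative == "two-sided":
        p = float(sps.binomtest(k_obs, n, p0, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    if p <= 0.0:  # keep p in (0, 1] despite floating underflow
        p = 5e-324
    return min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def gene_pair_edges(profiles: Sequence[CarrierProfile]) -> Counter:
    """Multiset of gene-pair edges among multi-gene group-3 carriers.

    Each profile with capped load in genes G (|G| ≥ 2) contributes every
    unordered pair of G once; an edge's multiplicity is the number of
    contributing carriers. Pairs are canonically ordered lexicographically.
    """
    edges: Counter = Counter()
    for p in profiles:
        genes = sorted(p.loaded_genes)
        for a, b in itertools.combinations(genes, 2):
            edges[(a, b)] += 1
    return edges


@dataclass(frozen=True)
class PairTestResult:
    gene_a: str
    gene_b: str
    k_obs: int
    n: int
    p_obs: float
    p_expected: float
    p_value: float
    fdr_q: Optional[float] = None


def load_matrix(profiles: Sequence[CarrierProfile], genes: Sequence[str]) -> np.ndarray:
    """Profiles × genes boolean capped-load matrix."""
    return np.array(
        [[g in p.loaded_genes for g in genes] for p in profiles], dtype=bool
    )


def pair_test_grid(loads: np.ndarray, alternative: str = "greater") -> pd.DataFrame:
    """Vectorised co-occurrence tests for every gene pair of a load matrix.

    ``loads`` is samples × genes boolean. Marginals are empirical carrier
    proportions; expected joint probability is their product; the p-value is
    the exact binomial tail. Returns one row per unordered pair (i < j by
    column index).
    """
    n, m = loads.shape
    if n == 0:
        raise ValidationError("empty load matrix")
    li = loads.astype(np.int32)
    joint = li.T @ li
    marg = loads.mean(axis=0)
    ii, jj = np.triu_indices(m, k=1)
    k_obs = joint[ii, jj]
    p0 = marg[ii] * marg[jj]
    if alternative == "greater":
        pvals = sps.binom.sf(k_obs - 1, n, p0)
    elif alternative == "two-sided":
        pvals = np.array(
            [binomial_exact_test(int(k), n, float(p), "two-sided") for k, p in zip(k_obs, p0)]
        )
    else:
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    pvals = np.clip(pvals, 5e-324, 1.0)
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "k_obs": k_obs,
            "n": n,
            "p_obs": k_obs / n,
            "p_expected": p0,
            "p_value": pvals,
        }
    )


def pair_cooccurrence_tests(
    profiles: Sequence[CarrierProfile],
    genes: Optional[Sequence[str]] = None,
    alternative: str = "greater",
    fdr: bool = False,
    observed_only: bool = False,
) -> List[PairTestResult]:
    """Co-occurrence enrichment test for gene pairs among group-3 carriers.

    For each pair, the expected double-carrier probability under independence
    is the product of the two marginal carrier proportions over the same
    profiles, and the observed double-carrier count is tested with the exact
    binomial. ``genes`` defaults to every gene with at least one carrier;
    ``observed_only`` restricts the output to pairs with ≥ 1 double carrier
    (the network's edges). BH-FDR, when requested, adjusts across the emitted
    pair family; unadjusted p-values are always reported.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("empty profile list")
    if genes is None:
        genes = sorted({g for p in profiles for g in p.loaded_genes})
    genes = list(genes)
    if len(genes) < 2:
        return []
    loads = load_matrix(profiles, genes)
    grid = pair_test_grid(loads, alternative=alternative)
    if observed_only:
        grid = grid[grid["k_obs"] >= 1]
    qs = bh_fdr(grid["p_value"].tolist()) if (fdr and len(grid)) else [None] * len(grid)
    results = []
    for (_, row), q in zip(grid.iterrows(), qs):
        a, b = sorted((genes[int(row["i"])], genes[int(row["j"])]))
        results.append(
            PairTestResult(
                gene_a=a,
                gene_b=b,
                k_obs=int(row["k_obs"]),
                n=int(row["n"]),
                p_obs=float(row["p_obs"]),
                p_expected=float(row["p_expected"]),
                p_value=float(row["p_value"]),
                fdr_q=q,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.gene_a, r.gene_b))
    return results
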