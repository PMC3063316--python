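"""Tissue-specificity statistics: Fisher's exact test on tissue-vs-pool
2×2 tables, per-tissue Benjamini-Hochberg FDR control, and the
chromatogram editing-level estimator.

For one site and one tissue T the table is::

            edited   unedited
    T          a        b
    pool       c        d

where the pool row sums every other tissue.  Under the null hypothesis that
editing is independent of tissue, ``a`` follows the hypergeometric
distribution fixed by the table margins; the two-sided p-value sums the
probabilities of all tables (same margins) whose probability mass does not
exceed the observed table's, with a relative tolerance of 1e-7 on the
mass-equality comparison; the one-sided ("greater") p-value sums the
enrichment tail, i.e. tables with edited count in T at least ``a``.

Within each tissue, the per-site p-values are corrected by the
Benjamini-Hochberg step-up procedure at level ``q`` (default 0.05): with the
m p-values in ascending order p(1) <= ... <= p(m), k is the largest rank
with p(k) <= (k/m)·q and the hypotheses of ranks 1..k are rejected.  The
reported "FDR corrected" value is the BH adjusted p-value
``min over j >= i of min(1, m·p(j)/j)``; rejection is equivalent to
adjusted p <= q.

A tissue-specific *call* additionally requires the editing fraction in T to
exceed the pool's: "specific to T" asserts elevated editing in T.  Without
this direction requirement a site strongly edited in one tissue would also
flag every well-covered other tissue as significantly *depleted* against
the inflated pool, which is not tissue-specific editing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import EditingSite, ValidationError

logger = logging.getLogger("tsedit")

#: relative slack when comparing hypergeometric masses for the two-sided tail
MASS_EQUALITY_RTOL = 1e-7

SIDEDNESS_OPTIONS = ("two_sided", "greater")


class SiteTissueCounts(NamedTuple):
    """The 2×2 table: (a, b) in tissue T, (c, d) pooled over other tissues."""

    a: int  # edited in T
    b: int  # unedited in T
    c: int  # edited in pool
    d: int  # unedited in pool


@dataclass(frozen=True)
class FDRRun:
    """One tissue's Benjamini-Hochberg run, in input order where per-test."""

    m: int
    q: float
    ranked_p: tuple[float, ...]
    k: int
    adjusted_p: tuple[float, ...]
    rejected: tuple[bool, ...]


@dataclass(frozen=True)
class SpecificityCall:
    """One rejected (site, tissue) pair: a tissue-specific editing call."""

    site: EditingSite
    tissue: str
    raw_p: float
    adjusted_p: float
    counts: SiteTissueCounts


@lru_cache(maxsize=None)
def _fisher_p(a: int, b: int, c: int, d: int, sidedness: str) -> float:
    n_t = a + b
    k_edited = a + c
    total = a + b + c + d
    lo = max(0, n_t - (total - k_edited))
    hi = min(n_t, k_edited)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, total, k_edited, n_t)
    if sidedness == "greater":
        p = float(pmf[support >= a].sum())
    else:
        p_obs = float(pmf[support == a][0])
        p = float(pmf[pmf <= p_obs * (1.0 + MASS_EQUALITY_RTOL)].sum())
    # the p-value is strictly positive (the observed table is in its own
    # tail); guard against pmf underflow for extreme tables and snap
    # accumulated rounding when every table is included
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return 1.0 if 1.0 - p < 1e-12 else p


def fisher_exact_p(
    t: SiteTissueCounts | tuple[int, int, int, int], sidedness: str = "two_sided"
) -> float:
    """Fisher's exact p-value for one tissue-vs-pool 2×2 table.

    ``sidedness`` is ``"two_sided"`` (default; sums all tables as or more
    extreme in probability mass) or ``"greater"`` (enrichment tail: edited
    count in T at least the observed ``a``).
    """
    a, b, c, d = t
    if min(a, b, c, d) < 0:
        raise ValidationError(f"negative count in table {(a, b, c, d)}")
    if a + b + c + d < 1:
        raise ValidationError("empty 2x2 table")
    if sidedness not in SIDEDNESS_OPTIONS:
        raise ValidationError(f"sidedness must be one of {SIDEDNESS_OPTIONS}")
    return _fisher_p(int(a), int(b), int(c), int(d), sidedness)


def bh_procedure(pvalues: Sequence[float], q: float = 0.05) -> FDRRun:
    """Benjamini-Hochberg step-up FDR control over one tissue's p-values.

    Returns the rank cutoff ``k``, the adjusted p-values and the rejection
    flags, the latter two in the input order.  Ties in the ranking are
    broken by input order; the min-over-suffix construction makes the
    adjusted values (and hence the decisions) invariant to that choice.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError(f"q must be in (0, 1), got {q}")
    m = p.size
    if m == 0:
        return FDRRun(0, q, (), 0, (), ())
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    passing = ranked <= (ranks / m) * q
    k = int(ranks[passing][-1]) if passing.any() else 0
    adj_ranked = np.minimum.accumulate((m * ranked / ranks)[::-1])[::-1]
    adj_ranked = np.minimum(adj_ranked, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_ranked
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return FDRRun(
        m=m,
        q=q,
        ranked_p=tuple(ranked),
        k=k,
        adjusted_p=tuple(adjusted),
        rejected=tuple(bool(r) for r in rejected),
    )


def detect(
    tables: pd.DataFrame,
    q: float = 0.05,
    sidedness: str = "two_sided",
    min_edited_in_tissue: int = 1,
) -> list[SpecificityCall]:
    """Detect tissue-specific editing sites from per-(site, tissue) counts.

    ``tables`` is the DataFrame produced by :func:`tsedit.tissues.tabulate`
    (columns ``chrom, strand, position, gene, tissue, edited, unedited``).
    For each tissue T, every site observed in T with at least
    ``min_edited_in_tissue`` edited sequences is tested against the pool of
    all other tissues; BH correction is applied within T (m = number of
    tests in T).  Calls are the rejected pairs whose editing fraction in T
    exceeds the pool's, with their adjusted p.
    """
    if tables.empty:
        return []
    tissues = tables["tissue"].unique()
    if len(tissues) < 2:
        logger.warning(
            "detect: only %d tissue in the tabulation; the pool of other "
            "tissues is empty, no tests performed",
            len(tissues),
        )
        return []
    site_cols = ["chrom", "strand", "position"]
    totals = tables.groupby(site_cols)[["edited", "unedited"]].sum()
    calls: list[SpecificityCall] = []
    for tissue, group in tables.groupby("tissue", sort=True):
        testable = group[group["edited"] >= min_edited_in_tissue]
        if testable.empty:
            continue
        keys = list(zip(testable["chrom"], testable["strand"], testable["position"]))
        tot = totals.loc[keys]
        a = testable["edited"].to_numpy()
        b = testable["unedited"].to_numpy()
        c = tot["edited"].to_numpy() - a
        d = tot["unedited"].to_numpy() - b
        pvals = [
            fisher_exact_p((int(ai), int(bi), int(ci), int(di)), sidedness)
            for ai, bi, ci, di in zip(a, b, c, d)
        ]
        run = bh_procedure(pvals, q)
        logger.info("detect: tissue %s, m=%d tests, k=%d rejected", tissue, run.m, run.k)
        for i, row in enumerate(testable.itertuples(index=False)):
            if not run.rejected[i]:
                continue
            pool_total = c[i] + d[i]
            frac_t = a[i] / (a[i] + b[i])
            frac_pool = c[i] / pool_total if pool_total else 0.0
            if frac_t <= frac_pool:
                continue  # depleted vs pool: not tissue-specific editing
            gene = row.gene if isinstance(row.gene, str) and row.gene else None
            site = EditingSite(row.chrom, row.strand, int(row.position), gene)
            calls.append(
                SpecificityCall(
                    site=site,
                    tissue=str(tissue),
                    raw_p=float(pvals[i]),
                    adjusted_p=float(run.adjusted_p[i]),
                    counts=SiteTissueCounts(int(a[i]), int(b[i]), int(c[i]), int(d[i])),
                )
            )
    return calls


def editing_level_percent(g_count: int, total: int) -> float:
    """Editing level as a percentage, rounded half-up to one decimal.

    Estimates the edited fraction from chromatogram peak heights (or any
    G/A counts) as 100·G/(G+A); e.g. 151 of 855 gives 17.7.
    """
    if total <= 0:
        raise ValidationError(f"total must be positive, got {total}")
    if not 0 <= g_count <= total:
        raise ValidationError(f"g_count must lie in [0, {total}], got {g_count}")
    pct = Decimal(100) * Decimal(g_count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
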