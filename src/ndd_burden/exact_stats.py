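"""Exact combinatorial statistics for the burden and yield analyses.

Fisher's exact test on 2x2 case/control carrier tables (right-tailed for the
gene-burden scan, two-sided for diagnostic-yield comparisons) and
Benjamini-Hochberg step-up FDR adjustment.

The test works on the central hypergeometric distribution conditional on the
table margins.  Point masses are evaluated in log space so that tables with
a very large control margin (the study design pairs ~100 cases with 1246
controls) do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = ["ContingencyTable2x2", "fisher_exact", "bh_adjust"]

#: relative slack on the "point probability <= observed" comparison that
#: defines the two-sided tail; guards against ties broken by rounding.
TWO_SIDED_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control carrier table.

    a: case carriers, b: case non-carriers,
    c: control carriers, d: control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"table entry {name}={v!r} must be a non-negative integer")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """Simultaneous row and column swap (d,c,b,a)."""
        return ContingencyTable2x2(self.d, self.c, self.b, self.a)


def _support_logpmf(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support of the case-carrier count ``a`` and its log point masses.

    Conditional on the margins, ``a`` is Hypergeometric(N, K, n_cases) with
    N the table total and K the carrier margin a+c.
    """
    n = table.n_total
    k = table.a + table.c
    r = table.n_cases
    lo = max(0, k - table.n_controls)
    hi = min(k, r)
    support = np.arange(lo, hi + 1)
    return support, hypergeom.logpmf(support, n, k, r)


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[int],
    tail: Literal["right", "two_sided"] = "right",
) -> float:
    """Exact p-value for a 2x2 table.

    ``right`` gives P(X >= a) under the margin-conditional hypergeometric —
    the burden scan's one-sided test for carrier excess in cases.
    ``two_sided`` sums the probabilities of all tables with the same margins
    whose point probability does not exceed the observed one (the standard
    probability-mass definition, not tail doubling and not mid-p).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    support, logpmf = _support_logpmf(table)
    if support.size == 1:  # margins admit a single table
        return 1.0
    log_obs = logpmf[support.searchsorted(table.a)]
    if tail == "right":
        sel = support >= table.a
    elif tail == "two_sided":
        sel = logpmf <= log_obs + np.log1p(TWO_SIDED_REL_TOL)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if sel.all():
        return 1.0
    p = float(np.exp(logsumexp(logpmf[sel])))
    return min(p, 1.0)


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j>=i} m * p_(j) / j, clipped to 1.  Declaring genes with
    q <= alpha significant reproduces the step-up rejection set at level
    alpha; the burden scan uses alpha = 0.005.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
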