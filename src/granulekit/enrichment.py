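"""Gene-set overlap enrichment: Fisher's exact test, log2 effect size,
Benjamini-Hochberg FDR.

For two gene sets A and B inside an explicit universe U, the 2x2 table
(in-A/not-A x in-B/not-B) is tested with the two-sided Fisher exact
test (sum of hypergeometric table probabilities not exceeding the
observed table's). The effect size is ``log2(observed / expected)``
with ``expected = |A||B|/|U|``; a small continuity guard epsilon is
applied only when the observed or expected overlap is zero, and the
result records whether it was used. The universe is always a mandatory
argument — it is never inferred from the sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "fisher_from_counts",
    "bh_adjust",
    "enrichment_matrix",
]


@dataclass
class EnrichmentResult:
    """One Fisher-test cell: counts, effect size, p, FDR."""

    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    expected_overlap: float
    log2_enrichment: float
    p_value: float
    fdr: float = float("nan")
    epsilon: float = 0.5
    epsilon_applied: bool = False

    @property
    def direction(self) -> str:
        return "enriched" if self.n_overlap >= self.expected_overlap else "depleted"


def fisher_from_counts(
    n_universe: int, n_a: int, n_b: int, n_overlap: int, epsilon: float = 0.5
) -> EnrichmentResult:
    """Fisher enrichment from the four counts directly.

    ``epsilon`` guards ``log2(observed/expected)`` only when the
    observed or expected overlap is zero.
    """
    if n_universe < 1:
        raise ValueError("universe must be non-empty")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes must lie within the universe")
    if not (max(0, n_a + n_b - n_universe) <= n_overlap <= min(n_a, n_b)):
        raise ValueError("overlap incompatible with the margins")

    table = [
        [n_overlap, n_a - n_overlap],
        [n_b - n_overlap, n_universe - n_a - n_b + n_overlap],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    expected = n_a * n_b / n_universe
    if n_overlap > 0 and expected > 0:
        log2_enr = float(np.log2(n_overlap / expected))
        eps_applied = False
    else:
        log2_enr = float(np.log2((n_overlap + epsilon) / (expected + epsilon)))
        eps_applied = True
    return EnrichmentResult(
        n_universe=n_universe,
        n_set_a=n_a,
        n_set_b=n_b,
        n_overlap=n_overlap,
        expected_overlap=expected,
        log2_enrichment=log2_enr,
        p_value=float(min(p, 1.0)),
        epsilon=epsilon,
        epsilon_applied=eps_applied,
    )


def fisher_enrichment(
    set_a: set, set_b: set, universe: set, epsilon: float = 0.5
) -> EnrichmentResult:
    """Fisher overlap enrichment of two gene sets within a universe."""
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        extra = (set_a | set_b) - universe
        raise ValueError(
            f"sets must be subsets of the universe; {len(extra)} foreign ids, "
            f"e.g. {sorted(extra)[:3]}"
        )
    return fisher_from_counts(
        len(universe), len(set_a), len(set_b), len(set_a & set_b), epsilon=epsilon
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_matrix(
    row_sets: dict[str, set],
    column_sets: dict[str, set],
    universe: set,
    epsilon: float = 0.5,
    significance: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Fisher enrichment with matrix-wide BH correction.

    Returns a long-format table (one row per cell) with overlap,
    expected overlap, log2 enrichment, raw p, FDR across the whole
    matrix, direction and a ``significant`` flag (raw p below the
    stated threshold, matching the figure convention of bolding cells
    at p < 0.05).
    """
    rows = []
    results = []
    for rname, rset in row_sets.items():
        for cname, cset in column_sets.items():
            res = fisher_enrichment(rset, cset, universe, epsilon=epsilon)
            results.append(res)
            rows.append({"row_set": rname, "col_set": cname})
    fdrs = bh_adjust([r.p_value for r in results])
    out = []
    for meta, res, fdr in zip(rows, results, fdrs):
        res.fdr = float(fdr)
        out.append(
            {
                **meta,
                "n_universe": res.n_universe,
                "n_row": res.n_set_a,
                "n_col": res.n_set_b,
                "overlap": res.n_overlap,
                "expected": res.expected_overlap,
                "log2_enrichment": res.log2_enrichment,
                "p_value": res.p_value,
                "fdr": res.fdr,
                "direction": res.direction,
                "significant": res.p_value < significance,
            }
        )
    return pd.DataFrame(out)
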