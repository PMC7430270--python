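"""Differential expression, the cascading DEG-selection rules, and P_de.

The over-representation probability P_de of a pathway asks how surprising
its count of differentially expressed genes is under a hypergeometric
draw: with m measured genes of which n are DEGs, a pathway covering t
measured genes containing r DEGs scores P(X >= r). The gene universe is
the set of measured genes, since unmeasured genes can be neither drawn nor
differentially expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGTable",
    "OraInput",
    "differential_test",
    "select_degs",
    "compute_deg_table",
    "pde_hypergeometric",
    "ora_input_for_pathway",
]

#: Lower clamp for P_de, keeping the Fisher-style combination finite.
PDE_EPS = 1e-300

FDR_RULE = "fdr_rule"
P_AND_FC_RULE = "p_and_fc_rule"
TOP_PERCENT_RULE = "top_percent_rule"


@dataclass(frozen=True)
class DEGTable:
    """Per-gene differential-expression statistics plus the selected DEGs.

    ``stats`` is indexed by gene ID with columns ``p_value``, ``p_adj``
    (Benjamini-Hochberg) and ``log_fc`` (mean disease minus mean normal);
    ``degs`` is the selected gene set and ``rule`` the cascade rule that
    produced it.
    """

    stats: pd.DataFrame
    degs: frozenset
    rule: str

    def __post_init__(self):
        if not set(self.degs) <= set(self.stats.index):
            raise ValueError("DEG set contains genes absent from the statistics table")


@dataclass(frozen=True)
class OraInput:
    """Counts entering the hypergeometric over-representation test."""

    m: int  # measured genes
    n: int  # DEGs among the m
    t: int  # pathway genes among the m
    r: int  # DEGs among the t

    def __post_init__(self):
        if self.m < 0:
            raise ValueError(f"m={self.m} must be nonnegative")
        if not 0 <= self.n <= self.m:
            raise ValueError(f"n={self.n} outside [0, m={self.m}]")
        if not 0 <= self.t <= self.m:
            raise ValueError(f"t={self.t} outside [0, m={self.m}]")
        if not 0 <= self.r <= min(self.n, self.t):
            raise ValueError(
                f"r={self.r} outside [0, min(n={self.n}, t={self.t})]"
            )


def differential_test(data) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test of disease vs normal.

    Returns a DataFrame indexed by gene ID with columns ``p_value``,
    ``p_adj`` (Benjamini-Hochberg across all genes), ``log_fc`` (mean
    disease minus mean normal) and ``zero_variance``. A gene constant in
    both conditions is not testable and gets p_value 1.0 with the
    ``zero_variance`` flag set, rather than an exception.
    """
    d = data.disease_values
    n = data.normal_values
    log_fc = d.mean(axis=1) - n.mean(axis=1)
    zero_both = (d.var(axis=1) == 0) & (n.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(d, n, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    p[zero_both] = 1.0
    p[~np.isfinite(p)] = 1.0
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "p_value": p,
            "p_adj": p_adj,
            "log_fc": log_fc,
            "zero_variance": zero_both,
        },
        index=pd.Index(data.genes, name="gene_id"),
    )


def select_degs(
    stats_table: pd.DataFrame,
    min_count: int = 200,
    fdr_thresh: float = 0.05,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.5,
    top_frac: float = 0.01,
) -> tuple:
    """Apply the cascading DEG-selection rules.

    1. If more than ``min_count`` genes have ``p_adj < fdr_thresh``, select
       them (``fdr_rule``).
    2. Otherwise, if more than ``min_count`` genes have
       ``p_value < p_thresh`` and ``|log_fc| > lfc_thresh``, select them
       (``p_and_fc_rule``).
    3. Otherwise select the top ``ceil(top_frac * m)`` genes by smallest
       p-value (``top_percent_rule``), ties broken by larger ``|log_fc|``,
       then by gene ID.

    Returns ``(frozenset of gene IDs, rule name)``.
    """
    if stats_table.empty:
        raise ValueError("cannot select DEGs from an empty table")
    fdr_set = stats_table.index[stats_table["p_adj"] < fdr_thresh]
    if len(fdr_set) > min_count:
        return frozenset(fdr_set), FDR_RULE
    pfc_mask = (stats_table["p_value"] < p_thresh) & (
        stats_table["log_fc"].abs() > lfc_thresh
    )
    if int(pfc_mask.sum()) > min_count:
        return frozenset(stats_table.index[pfc_mask]), P_AND_FC_RULE
    k = math.ceil(top_frac * len(stats_table))
    # deterministic ordering: p asc, |lfc| desc, gene ID asc
    idx = sorted(
        stats_table.index,
        key=lambda g: (
            stats_table.at[g, "p_value"],
            -abs(stats_table.at[g, "log_fc"]),
            str(g),
        ),
    )
    return frozenset(idx[:k]), TOP_PERCENT_RULE


def compute_deg_table(data, precomputed: pd.DataFrame = None, **select_kwargs) -> DEGTable:
    """Run (or accept) the differential test and apply the selection cascade."""
    stats_table = differential_test(data) if precomputed is None else precomputed
    degs, rule = select_degs(stats_table, **select_kwargs)
    return DEGTable(stats=stats_table, degs=degs, rule=rule)


def pde_hypergeometric(x: OraInput, mode: str = "upper_tail") -> float:
    """Over-representation probability of a pathway's DEG count.

    ``mode="upper_tail"`` (default) returns P(X >= r) for X hypergeometric
    (population ``m``, ``n`` successes, ``t`` draws) — the standard ORA
    statistic. ``mode="literal_eq5"`` returns ``1 - P(X = r)``, one minus
    the point mass. The result is clamped into (1e-300, 1].
    """
    if mode == "upper_tail":
        p = float(stats.hypergeom.sf(x.r - 1, x.m, x.n, x.t))
    elif mode == "literal_eq5":
        p = 1.0 - float(stats.hypergeom.pmf(x.r, x.m, x.n, x.t))
    else:
        raise ValueError(f"unknown P_de mode {mode!r}")
    return min(max(p, PDE_EPS), 1.0)


def ora_input_for_pathway(graph, universe, degs) -> OraInput:
    """Build the hypergeometric counts for one pathway.

    ``universe`` is the set of measured genes; only pathway nodes inside it
    count toward ``t``.
    """
    universe = set(universe)
    degs = set(degs) & universe
    measured_nodes = set(graph.nodes) & universe
    return OraInput(
        m=len(universe),
        n=len(degs),
        t=len(measured_nodes),
        r=len(measured_nodes & degs),
    )
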