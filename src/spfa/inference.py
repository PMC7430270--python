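"""Permutation null for P_sd, p-value combination, FDR, and diagnostics.

P_sd asks how often a pathway's total accumulated signal variation would
be reached by chance if its gene labels carried no meaning: the topology
is held fixed while node labels are replaced by a uniform draw without
replacement from all measured genes (each relabeled node bringing that
gene's real expression rows), and ASV is recomputed per draw. Only gene
identities are permuted — sample labels never are.

P_sd and the over-representation P_de use disjoint aspects of the data
(pair correlations vs DEG counts), so they are combined as two independent
uniform p-values via the Fisher closed form P = c - c*ln(c), c = P_de*P_sd,
and Benjamini-Hochberg adjusted across pathways.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pathways import PathwayGraph, effector_set, find_effectors
from .signal import CorrelationCache, _as_cache

__all__ = [
    "PermutationResult",
    "psd_permutation",
    "combine_p",
    "fdr_adjust_and_rank",
    "independence_diagnostic",
    "evaluation_metrics",
    "pathway_rng",
]

#: Permutation rows evaluated per vectorized block (memory bound).
_PERM_BLOCK = 256

FLAG_ORA_ONLY = "ora_only"


@dataclass(frozen=True)
class PermutationResult:
    pathway_id: str
    n_perm: int
    count_ge: int
    p_sd: float
    seed: int
    asv_observed: float

    def __post_init__(self):
        if not 0 <= self.count_ge <= self.n_perm:
            raise ValueError("count_ge outside [0, n_perm]")
        if not 0.0 < self.p_sd <= 1.0:
            raise ValueError("P_sd outside (0, 1]")


def pathway_rng(seed: int, pathway_id: str) -> np.random.Generator:
    """Deterministic per-pathway generator.

    The child seed mixes the run seed with a CRC32 of the pathway ID, so
    results are independent of pathway processing order (serial or
    parallel runs agree).
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(pathway_id.encode())])
    )


def _pair_index_arrays(graph: PathwayGraph, cache: CorrelationCache):
    """Node ordering plus (source-position, effector-position, distance) arrays."""
    nodes = sorted(graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    es = effector_set(graph)
    s_pos, e_pos, dist = [], [], []
    for g, e, d in es.links():
        s_pos.append(pos[g])
        e_pos.append(pos[e])
        dist.append(d)
    return nodes, np.array(s_pos), np.array(e_pos), np.array(dist, dtype=float)


def observed_asv(graph: PathwayGraph, cache: CorrelationCache) -> float:
    """Pathway ASV via the vectorized pair machinery (equals pathway_asv)."""
    nodes, s_pos, e_pos, dist = _pair_index_arrays(graph, cache)
    if len(dist) == 0:
        return 0.0
    idx = np.array([cache.index_of(n) for n in nodes])
    return float(cache.pair_variations(idx[s_pos], idx[e_pos], dist).sum())


def psd_permutation(
    data,
    graph: PathwayGraph,
    n_perm: int = 2000,
    seed: int = 0,
    estimator: str = "smoothed",
) -> PermutationResult:
    """Gene-ID permutation probability of the pathway's observed ASV.

    For each of ``n_perm`` draws the pathway's node labels are replaced by
    a uniform sample without replacement from the measured-gene universe
    and the ASV recomputed; ``count_ge`` counts draws at least as large as
    the observed ASV.

    The default estimator is the smoothed ``(1 + count_ge)/(1 + n_perm)``,
    which is a valid permutation p-value and never returns 0 (a raw 0
    would make the downstream combination ln(0)-undefined).
    ``estimator="literal"`` divides the raw count by ``n_perm``, floored
    at ``1/n_perm``.
    """
    if not find_effectors(graph):
        raise ValueError(
            f"pathway {graph.pathway_id!r} has no effectors; P_sd is undefined"
        )
    cache = _as_cache(data)
    nodes, s_pos, e_pos, dist = _pair_index_arrays(graph, cache)
    q = len(nodes)
    n_genes = cache.n_genes
    if n_genes < q:
        raise ValueError(
            f"pathway {graph.pathway_id!r} has {q} nodes but only "
            f"{n_genes} genes are measured; cannot relabel without replacement"
        )
    obs = observed_asv(graph, cache)

    rng = pathway_rng(seed, graph.pathway_id)
    count_ge = 0
    done = 0
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        # ranks of iid uniforms give a uniform ordered sample w/o replacement
        keys = rng.random((block, n_genes))
        labels = np.argsort(keys, axis=1, kind="stable")[:, :q]
        e = cache.pair_variations(labels[:, s_pos], labels[:, e_pos], dist)
        asv_per = e.sum(axis=1)
        count_ge += int((asv_per >= obs).sum())
        done += block

    if estimator == "smoothed":
        p_sd = (1 + count_ge) / (1 + n_perm)
    elif estimator == "literal":
        p_sd = max(count_ge, 1) / n_perm
    else:
        raise ValueError(f"unknown P_sd estimator {estimator!r}")
    return PermutationResult(
        pathway_id=graph.pathway_id,
        n_perm=n_perm,
        count_ge=count_ge,
        p_sd=float(p_sd),
        seed=int(seed),
        asv_observed=obs,
    )


def combine_p(p_de: float, p_sd: float) -> tuple:
    """Fisher-style combination of two independent p-values.

    Returns ``(c, P)`` with ``c = p_de * p_sd`` and ``P = c - c*ln(c)``;
    P is the probability that the product of two independent U(0,1)
    variables falls below c. P = 1 exactly when c = 1, and P is strictly
    increasing in c on (0, 1].
    """
    for name, v in (("P_de", p_de), ("P_sd", p_sd)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name}={v} outside (0, 1]")
    c = p_de * p_sd
    return c, float(c - c * np.log(c))


def fdr_adjust_and_rank(scores: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg over combined P, then rank pathways.

    ``scores`` must carry ``pathway_id`` and ``P`` columns. Ranks are by
    ascending ``P_adj``, ties broken by raw ``P`` then ``pathway_id``;
    ``significant`` flags ``P_adj <= alpha``. Input row order is
    irrelevant to the result.
    """
    if scores.empty:
        raise ValueError("no pathway scores to adjust")
    out = scores.copy()
    out["P_adj"] = multipletests(out["P"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(
        ["P_adj", "P", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = out["P_adj"] <= alpha
    return out


def independence_diagnostic(p_de_values, p_sd_values) -> float:
    """Squared Pearson correlation between the P_de and P_sd vectors.

    Near-zero R-squared across pathways supports treating the two
    probabilities as independent in the combination. A constant vector has
    no defined correlation; R-squared is reported as 0.0 in that case.
    """
    x = np.asarray(p_de_values, dtype=float)
    y = np.asarray(p_sd_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("P_de and P_sd vectors differ in length")
    if x.size < 3:
        raise ValueError(f"need >= 3 paired values, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def evaluation_metrics(result_tables, target_ids, alpha: float = 0.05) -> dict:
    """Benchmark summary over several result tables with known targets.

    For each (table, target pathway) pair collects the target's rank and
    combined P; returns their medians plus the mean, over tables, of the
    fraction of pathways significant at ``alpha``.
    """
    if len(result_tables) != len(target_ids):
        raise ValueError("one target_id is required per result table")
    ranks, pvals, sig_ratios = [], [], []
    for table, tid in zip(result_tables, target_ids):
        row = table.loc[table["pathway_id"] == tid]
        if row.empty:
            raise KeyError(f"target pathway {tid!r} absent from result table")
        ranks.append(float(row["rank"].iloc[0]))
        pvals.append(float(row["P"].iloc[0]))
        sig_ratios.append(float((table["P_adj"] <= alpha).mean()))
    return {
        "median_rank": float(np.median(ranks)),
        "median_p": float(np.median(pvals)),
        "significant_ratio": float(np.mean(sig_ratios)),
    }
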