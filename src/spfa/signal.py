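"""Signal-variation scores: pairwise e_se, per-effector ASV, pathway ASV.

The signal variation carried from an upstream gene g_s to an effector g_e
is the absolute difference of their within-condition Pearson correlations,

    e_se = |cor_disease(g_s, g_e) - cor_normal(g_s, g_e)| / d_se,

penalized by the network distance d_se (shortest directed-path length):
signal relayed through intermediaries is attenuated. Summing e over all
upstream genes of an effector gives its accumulated signal variation
ASV(g_i); summing over all effectors gives the pathway ASV. Scoring uses
topology only — edge signs and interaction types are ignored.

A gene that is unmeasured, or constant within a condition, transmits no
detectable signal change: its pairs contribute e = 0 and are flagged
degenerate rather than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pathways import PathwayGraph, find_effectors, upstream_distances

__all__ = [
    "CorrelationCache",
    "UpstreamLink",
    "EffectorProfile",
    "PathwayASV",
    "pair_signal_variation",
    "effector_asv",
    "pathway_asv",
]


class CorrelationCache:
    """Standardized per-condition expression rows for fast pair correlations.

    Each gene row is centered within condition and scaled to unit Euclidean
    norm, so the Pearson correlation of two measured, non-constant genes is
    a plain dot product. Rows constant within a condition are zeroed and
    marked invalid (their correlation is undefined). Built once per run and
    shared across pathways and permutations.
    """

    def __init__(self, data):
        self.data = data
        self.gene_index = data.gene_index
        self.n_genes = data.n_genes
        self.z = {}
        self.valid = {}
        for cond in ("normal", "disease"):
            x = data.values_for(cond)
            centered = x - x.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(centered, axis=1)
            ok = norms > 0
            z = np.zeros_like(centered)
            z[ok] = centered[ok] / norms[ok, None]
            self.z[cond] = z
            self.valid[cond] = ok

    def corr(self, gi: int, gj: int, cond: str):
        """Pearson correlation by row index, or None when undefined."""
        if gi < 0 or gj < 0:
            return None
        if not (self.valid[cond][gi] and self.valid[cond][gj]):
            return None
        return float(self.z[cond][gi] @ self.z[cond][gj])

    def index_of(self, gene: str) -> int:
        """Row index of ``gene``, or -1 if unmeasured."""
        return self.gene_index.get(gene, -1)

    def pair_variations(self, si, ei, d) -> np.ndarray:
        """Vectorized e for index arrays of source/effector gene rows.

        ``si``/``ei`` hold row indices (-1 = unmeasured) and broadcast to
        any shape; ``d`` holds the matching network distances. Pairs with
        an unmeasured or within-condition-constant member score 0.
        """
        si = np.asarray(si)
        ei = np.asarray(ei)
        d = np.asarray(d, dtype=float)
        measured = (si >= 0) & (ei >= 0)
        s_safe = np.where(measured, si, 0)
        e_safe = np.where(measured, ei, 0)
        ok = measured.copy()
        cors = {}
        for cond in ("normal", "disease"):
            z = self.z[cond]
            cors[cond] = np.einsum("...k,...k->...", z[s_safe], z[e_safe])
            ok &= self.valid[cond][s_safe] & self.valid[cond][e_safe]
        return np.where(ok, np.abs(cors["disease"] - cors["normal"]) / d, 0.0)


@dataclass(frozen=True)
class UpstreamLink:
    """One (upstream gene, effector) pair with its signal variation."""

    g_s: str
    g_e: str
    d_se: int
    cor_disease: object  # float or None when undefined
    cor_normal: object
    e_se: float
    degenerate: bool = False

    def __post_init__(self):
        if self.d_se < 1:
            raise ValueError(f"network distance d_se={self.d_se} must be >= 1")


@dataclass(frozen=True)
class EffectorProfile:
    """Accumulated signal variation of one effector over its s upstream genes."""

    g_i: str
    s: int
    asv: float
    links: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class PathwayASV:
    """Pathway-level total ASV over its k effector profiles."""

    pathway_id: str
    k: int
    asv: float
    profiles: tuple = field(default_factory=tuple)

    @property
    def no_effectors(self) -> bool:
        return self.k == 0


def _as_cache(data_or_cache) -> CorrelationCache:
    if isinstance(data_or_cache, CorrelationCache):
        return data_or_cache
    return CorrelationCache(data_or_cache)


def pair_signal_variation(data, g_s: str, g_e: str, d_se: int) -> UpstreamLink:
    """Signal variation e_se for one (upstream gene, effector) pair.

    Pearson correlations are computed separately within disease and within
    normal samples; if either gene is unmeasured or constant within a
    condition the link is degenerate with e_se = 0.
    """
    if d_se < 1:
        raise ValueError(f"network distance d_se={d_se} must be >= 1")
    cache = _as_cache(data)
    gi, gj = cache.index_of(g_s), cache.index_of(g_e)
    cor_d = cache.corr(gi, gj, "disease")
    cor_n = cache.corr(gi, gj, "normal")
    if cor_d is None or cor_n is None:
        return UpstreamLink(g_s, g_e, d_se, cor_d, cor_n, 0.0, degenerate=True)
    return UpstreamLink(g_s, g_e, d_se, cor_d, cor_n, abs(cor_d - cor_n) / d_se)


def effector_asv(data, graph: PathwayGraph, effector: str) -> EffectorProfile:
    """Accumulated signal variation of one effector: sum of its link e values."""
    cache = _as_cache(data)
    links = tuple(
        pair_signal_variation(cache, g, effector, d)
        for g, d in sorted(upstream_distances(graph, effector).items())
    )
    return EffectorProfile(
        g_i=effector,
        s=len(links),
        asv=float(sum(l.e_se for l in links)),
        links=links,
    )


def pathway_asv(data, graph: PathwayGraph) -> PathwayASV:
    """Total accumulated signal variation of a pathway over its effectors.

    A pathway without effectors scores ASV = 0 and is flagged via
    :attr:`PathwayASV.no_effectors` (it is excluded from permutation
    testing downstream).
    """
    cache = _as_cache(data)
    profiles = tuple(
        effector_asv(cache, graph, e) for e in find_effectors(graph)
    )
    return PathwayASV(
        pathway_id=graph.pathway_id,
        k=len(profiles),
        asv=float(sum(p.asv for p in profiles)),
        profiles=profiles,
    )
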