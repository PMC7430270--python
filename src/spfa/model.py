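"""The SPFA model object and its fitted results.

Usage mirrors the estimator/results split common in statistical packages::

    model = SPFA(dataset, pathways)
    res = model.fit(n_perm=2000, seed=7)
    print(res.summary())
    res.write("out/")

The model couples two independent lines of evidence per pathway: an
over-representation probability P_de (hypergeometric on DEG counts) and a
signal-variation probability P_sd (gene-ID permutation null on the
distance-penalized correlation differences received by effector genes),
combined as P = c - c*ln(c) with c = P_de * P_sd and BH-adjusted across
pathways. Pathways without effectors cannot be permutation-tested; they
are reported with P = P_de and flagged ``ora_only`` rather than dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    ExpressionDataset,
    load_expression,
    load_deg_table,
    write_deg_table,
    write_effector_report,
    write_results,
    RESULT_COLUMNS,
    EFFECTOR_COLUMNS,
)
from .dge import DEGTable, compute_deg_table, ora_input_for_pathway, pde_hypergeometric
from .inference import (
    FLAG_ORA_ONLY,
    combine_p,
    fdr_adjust_and_rank,
    independence_diagnostic,
    psd_permutation,
)
from .pathways import read_registry
from .signal import CorrelationCache, pathway_asv

logger = logging.getLogger(__name__)

__all__ = ["SPFA", "SPFAResults"]


class SPFA:
    """Signaling-pathway functional attributes analysis.

    Parameters
    ----------
    data : ExpressionDataset
        Gene x sample matrix with normal/disease labels.
    pathways : list of PathwayGraph
        Directed pathways to score.
    deg_stats : DataFrame, optional
        Precomputed per-gene table (p_value, p_adj, log_fc) replacing the
        built-in Welch test; the selection cascade still applies.
    ora_mode : {"upper_tail", "literal_eq5"}
        Form of the hypergeometric P_de.
    estimator : {"smoothed", "literal"}
        P_sd estimator (see :func:`spfa.inference.psd_permutation`).
    deg_params : dict, optional
        Overrides for the DEG cascade thresholds
        (min_count, fdr_thresh, p_thresh, lfc_thresh, top_frac).
    """

    def __init__(
        self,
        data: ExpressionDataset,
        pathways: list,
        deg_stats: pd.DataFrame = None,
        ora_mode: str = "upper_tail",
        estimator: str = "smoothed",
        deg_params: dict = None,
    ):
        if not pathways:
            raise ValueError("SPFA requires at least one pathway")
        ids = [p.pathway_id for p in pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway IDs")
        self.data = data
        self.pathways = list(pathways)
        self.deg_stats = deg_stats
        self.ora_mode = ora_mode
        self.estimator = estimator
        self.deg_params = dict(deg_params or {})

    @classmethod
    def from_files(
        cls,
        pathways_registry,
        expression_path,
        phenotype_path,
        deg_path=None,
        **kwargs,
    ) -> "SPFA":
        """Build a model from a pathway registry TSV plus matrix/phenotype files."""
        pathways = read_registry(pathways_registry)
        data = load_expression(expression_path, phenotype_path)
        deg_stats = load_deg_table(deg_path) if deg_path else None
        return cls(data, pathways, deg_stats=deg_stats, **kwargs)

    def fit(self, n_perm: int = 2000, seed: int = 0, alpha: float = 0.05) -> "SPFAResults":
        """Score every pathway and return a :class:`SPFAResults`.

        Step one maps DEGs onto pathways for P_de; step two finds effector
        genes, accumulates distance-penalized correlation differences into
        ASV, and permutation-tests it for P_sd. Both are combined, BH
        adjusted, and ranked. Fully deterministic given ``seed``.
        """
        deg = compute_deg_table(self.data, precomputed=self.deg_stats, **self.deg_params)
        universe = set(self.data.genes)
        cache = CorrelationCache(self.data)

        rows = []
        asv_by_pathway = {}
        for graph in self.pathways:
            ora = ora_input_for_pathway(graph, universe, deg.degs)
            p_de = pde_hypergeometric(ora, mode=self.ora_mode)
            pasv = pathway_asv(cache, graph)
            asv_by_pathway[graph.pathway_id] = pasv
            if pasv.no_effectors:
                p_sd, c, combined, flag = np.nan, np.nan, p_de, FLAG_ORA_ONLY
            else:
                perm = psd_permutation(
                    cache, graph, n_perm=n_perm, seed=seed, estimator=self.estimator
                )
                p_sd = perm.p_sd
                c, combined = combine_p(p_de, p_sd)
                flag = ""
            logger.info(
                "pathway %s: k=%d ASV=%.4g P_de=%.3g P_sd=%s P=%.3g",
                graph.pathway_id, pasv.k, pasv.asv, p_de, p_sd, combined,
            )
            rows.append(
                {
                    "pathway_id": graph.pathway_id,
                    "name": graph.name,
                    "t": ora.t,
                    "r": ora.r,
                    "k": pasv.k,
                    "ASV": pasv.asv,
                    "P_de": p_de,
                    "P_sd": p_sd,
                    "c": c,
                    "P": combined,
                    "flag": flag,
                }
            )

        table = fdr_adjust_and_rank(pd.DataFrame(rows), alpha=alpha)
        table = table[RESULT_COLUMNS + ["significant", "flag"]]
        return SPFAResults(
            model=self,
            table=table,
            deg=deg,
            asv_by_pathway=asv_by_pathway,
            n_perm=n_perm,
            seed=seed,
            alpha=alpha,
        )


@dataclass
class SPFAResults:
    """Fitted SPFA results: the ranked pathway table plus diagnostics."""

    model: SPFA
    table: pd.DataFrame
    deg: DEGTable
    asv_by_pathway: dict
    n_perm: int
    seed: int
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        """Rows with BH-adjusted combined P at or below alpha."""
        return self.table.loc[self.table["significant"]]

    @property
    def effector_report(self) -> pd.DataFrame:
        """Per-effector table (pathway_id, effector_gene, s, ASV_gi)."""
        rows = [
            (pid, prof.g_i, prof.s, prof.asv)
            for pid, pasv in sorted(self.asv_by_pathway.items())
            for prof in pasv.profiles
        ]
        return pd.DataFrame(rows, columns=EFFECTOR_COLUMNS)

    def top_links(self, n: int = 5) -> pd.DataFrame:
        """Strongest upstream links per effector (the functional-attribute view).

        The per-link e values locate which upstream genes, and hence which
        part of the pathway, drive an effector's signal variation.
        """
        rows = []
        for pid, pasv in sorted(self.asv_by_pathway.items()):
            for prof in pasv.profiles:
                links = sorted(
                    prof.links, key=lambda l: (-l.e_se, l.d_se, l.g_s)
                )[: n if n else None]
                rows.extend(
                    (pid, prof.g_i, l.g_s, l.d_se, l.e_se) for l in links
                )
        return pd.DataFrame(
            rows, columns=["pathway_id", "effector_gene", "g_s", "d_se", "e_se"]
        )

    def independence_r2(self) -> float:
        """Squared correlation between P_de and P_sd across tested pathways.

        ``ora_only`` pathways have no P_sd and are excluded.
        """
        sub = self.table.loc[self.table["flag"] != FLAG_ORA_ONLY]
        return independence_diagnostic(sub["P_de"].to_numpy(), sub["P_sd"].to_numpy())

    def manifest(self) -> dict:
        cfg = {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha": self.alpha,
            "ora_mode": self.model.ora_mode,
            "estimator": self.model.estimator,
            "deg_params": self.model.deg_params,
            "deg_rule": self.deg.rule,
            "n_degs": len(self.deg.degs),
            "n_pathways": len(self.model.pathways),
            "n_genes": self.model.data.n_genes,
            "n_samples": len(self.model.data.samples),
        }
        cfg["config_hash"] = hashlib.md5(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
        cfg["spfa_version"] = __version__
        return cfg

    def write(self, outdir, top_links: int = 0) -> dict:
        """Write results.tsv, effector_report.tsv, degs.tsv and manifest.json.

        Returns the paths written. Output bytes depend only on the inputs
        and seed.
        """
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "results": os.path.join(outdir, "results.tsv"),
            "effector_report": os.path.join(outdir, "effector_report.tsv"),
            "degs": os.path.join(outdir, "degs.tsv"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        write_results(self.table, paths["results"])
        write_effector_report(
            self.effector_report,
            paths["effector_report"],
            top_links=self.top_links(top_links) if top_links else None,
        )
        write_deg_table(self.deg.stats, self.deg.degs, paths["degs"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top-ranked pathways."""
        m = self.manifest()
        lines = [
            "SPFA results",
            "=" * 64,
            f"pathways analyzed: {m['n_pathways']}   genes: {m['n_genes']}   "
            f"samples: {m['n_samples']}",
            f"DEG rule: {self.deg.rule}   DEGs: {len(self.deg.degs)}",
            f"permutations: {self.n_perm}   seed: {self.seed}   "
            f"estimator: {self.model.estimator}   P_de mode: {self.model.ora_mode}",
            f"significant pathways (P_adj <= {self.alpha}): "
            f"{int(self.table['significant'].sum())} / {len(self.table)}",
            "-" * 64,
        ]
        show = self.table.head(top)
        header = f"{'rank':>4}  {'pathway_id':<14} {'ASV':>9} {'P_de':>9} {'P_sd':>9} {'P':>10} {'P_adj':>10}"
        lines.append(header)
        for _, row in show.iterrows():
            psd = "NA" if pd.isna(row["P_sd"]) else f"{row['P_sd']:.3g}"
            lines.append(
                f"{int(row['rank']):>4}  {row['pathway_id']:<14} {row['ASV']:>9.4g} "
                f"{row['P_de']:>9.3g} {psd:>9} {row['P']:>10.3g} {row['P_adj']:>10.3g}"
            )
        return "\n".join(lines)
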