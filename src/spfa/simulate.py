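"""Synthetic pathways and two-condition expression data with known truth.

The generator emulates exactly the structure the scoring assumes: directed
acyclic pathway graphs with a guaranteed effector (sink) layer, a gene
universe in which one *target* pathway carries condition-specific
co-expression — every upstream→effector gene pair has Pearson correlation
about ``rho_normal`` in normal samples and ``rho_disease`` in disease
samples — and mean-shifted (differentially expressed) genes both inside
and outside the target pathway.

The co-expression is induced by a single per-pathway latent factor per
condition: gene g is ``x_g = s_g*sqrt(|rho|)*z + sqrt(1-|rho|)*eps_g``
with sign ``s_g`` flipped on effector genes when rho is negative. Because
effectors are never upstream of other effectors, every scored pair then
has correlation exactly rho, at any network distance.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .pathways import PathwayGraph, find_effectors

__all__ = [
    "SimulationConfig",
    "generate_pathways",
    "generate_expression",
    "recovery_experiment",
    "write_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe one perturbed (target) pathway among 20 pathways of
    8-15 nodes drawn over a 2,000-gene universe, 20 samples per condition,
    a co-expression flip from +0.8 to -0.8 on target upstream→effector
    pairs, half of the target genes mean-shifted by 2 within-group SDs,
    and 1% of background genes shifted likewise.
    """

    n_pathways: int = 20
    nodes_min: int = 8
    nodes_max: int = 15
    edge_density: float = 0.3
    universe_size: int = 2000
    samples_per_condition: int = 20
    target_pathway: int = 0
    rho_normal: float = 0.8
    rho_disease: float = -0.8
    deg_frac_target: float = 0.5
    deg_frac_background: float = 0.01
    mean_shift: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        if not 2 <= self.nodes_min <= self.nodes_max:
            raise ValueError("need 2 <= nodes_min <= nodes_max")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must be in (0, 1]")
        if self.universe_size < self.nodes_max:
            raise ValueError("universe_size must cover the largest pathway")
        if self.samples_per_condition < 2:
            raise ValueError("samples_per_condition must be >= 2")
        if not 0 <= self.target_pathway < self.n_pathways:
            raise ValueError("target_pathway index out of range")
        for name in ("rho_normal", "rho_disease"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        for name in ("deg_frac_target", "deg_frac_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        return self

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A globally null configuration: equal co-expression in both
        conditions and no mean shifts anywhere."""
        base = dict(
            rho_normal=0.5,
            rho_disease=0.5,
            deg_frac_target=0.0,
            deg_frac_background=0.0,
        )
        base.update(overrides)
        return cls(**base)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_pathways(config: SimulationConfig) -> list:
    """Random DAG pathways over the gene universe, each with >= 1 effector.

    Nodes are topologically ordered; a designated sink layer (about a
    fifth of the nodes, at least one) receives edges but emits none, and
    every non-sink node is forced to have at least one outgoing edge —
    so the sinks are exactly the effectors. The target pathway's genes are
    reserved for it; background pathways draw from the rest of the
    universe and may overlap each other. Reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    universe = [_gene_name(i) for i in range(config.universe_size)]

    sizes = rng.integers(config.nodes_min, config.nodes_max + 1, size=config.n_pathways)
    target_genes = list(
        rng.choice(config.universe_size, size=int(sizes[config.target_pathway]), replace=False)
    )
    background_pool = np.array(
        [i for i in range(config.universe_size) if i not in set(target_genes)]
    )

    pathways = []
    for p in range(config.n_pathways):
        n = int(sizes[p])
        if p == config.target_pathway:
            gene_ids = [universe[i] for i in target_genes]
        else:
            gene_ids = [universe[i] for i in rng.choice(background_pool, size=n, replace=False)]
        n_sinks = max(1, n // 5)
        edges = set()
        for i in range(n - n_sinks):          # non-sink nodes
            targets = np.flatnonzero(rng.random(n - i - 1) < config.edge_density) + i + 1
            if targets.size == 0:
                targets = np.array([int(rng.integers(i + 1, n))])
            for j in targets:
                edges.add((gene_ids[i], gene_ids[int(j)]))
        for j in range(n - n_sinks, n):       # sinks must receive a signal
            if not any(t == gene_ids[j] for _, t in edges):
                i = int(rng.integers(0, n - n_sinks))
                edges.add((gene_ids[i], gene_ids[j]))
        graph = PathwayGraph(
            pathway_id=f"SIM{p:03d}",
            name=f"simulated pathway {p}",
            nodes=frozenset(gene_ids),
            edges=frozenset(edges),
        )
        if not find_effectors(graph):
            raise RuntimeError(f"generated pathway SIM{p:03d} lacks an effector")
        pathways.append(graph)
    return pathways


def _factor_block(rng, genes, effectors, rho, n_samples, noise_sd):
    """Expression block for correlated pathway genes in one condition."""
    b = abs(rho)
    z = rng.normal(size=n_samples)
    signs = np.array([-1.0 if (rho < 0 and g in effectors) else 1.0 for g in genes])
    eps = rng.normal(size=(len(genes), n_samples))
    x = signs[:, None] * math.sqrt(b) * z[None, :] + math.sqrt(1.0 - b) * eps
    return noise_sd * x


def generate_expression(config: SimulationConfig, pathways: list) -> tuple:
    """Expression matrix plus ground truth for the generated pathways.

    Background genes are i.i.d. Gaussian in both conditions; target-pathway
    genes share the per-condition latent factor described in the module
    docstring; the configured fractions of target and background genes are
    mean-shifted in disease. Returns ``(ExpressionDataset, truth dict)``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    m = config.universe_size
    ns = config.samples_per_condition
    genes = [_gene_name(i) for i in range(m)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    x_normal = rng.normal(scale=config.noise_sd, size=(m, ns))
    x_disease = rng.normal(scale=config.noise_sd, size=(m, ns))

    target = pathways[config.target_pathway]
    target_genes = sorted(target.nodes)
    effectors = set(find_effectors(target))
    t_idx = np.array([gene_pos[g] for g in target_genes])
    x_normal[t_idx] = _factor_block(
        rng, target_genes, effectors, config.rho_normal, ns, config.noise_sd
    )
    x_disease[t_idx] = _factor_block(
        rng, target_genes, effectors, config.rho_disease, ns, config.noise_sd
    )

    n_shift_t = math.ceil(config.deg_frac_target * len(target_genes))
    shifted_target = sorted(
        rng.choice(np.array(target_genes), size=n_shift_t, replace=False)
    ) if n_shift_t else []
    background = [g for g in genes if g not in target.nodes]
    n_shift_b = math.ceil(config.deg_frac_background * len(background))
    shifted_background = sorted(
        rng.choice(np.array(background), size=n_shift_b, replace=False)
    ) if n_shift_b else []
    shift = config.mean_shift * config.noise_sd
    for g in list(shifted_target) + list(shifted_background):
        x_disease[gene_pos[g]] += shift

    samples = [f"N{i:03d}" for i in range(ns)] + [f"D{i:03d}" for i in range(ns)]
    condition = {s: ("normal" if s.startswith("N") else "disease") for s in samples}
    data = ExpressionDataset(
        genes=genes,
        samples=samples,
        values=np.hstack([x_normal, x_disease]),
        condition=condition,
    )
    truth = {
        "target_pathway_id": target.pathway_id,
        "target_genes": target_genes,
        "target_effectors": sorted(effectors),
        "shifted_target_genes": [str(g) for g in shifted_target],
        "shifted_background_genes": [str(g) for g in shifted_background],
        "rho_normal": config.rho_normal,
        "rho_disease": config.rho_disease,
        "config": asdict(config),
    }
    return data, truth


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Run the full pipeline on fresh simulations and score target recovery.

    Each replicate regenerates pathways and data under ``config`` with a
    distinct derived seed, fits the model, and records the target
    pathway's rank and adjusted P. Reports the fraction of replicates
    where the target ranks first and where it is significant at ``alpha``.
    """
    from .model import SPFA  # deferred: model imports this module's peers

    config.validate()
    ranks, p_adjs, sig_ratios = [], [], []
    for rep in range(n_replicates):
        child = np.random.SeedSequence([config.seed, 3, rep]).generate_state(1)[0]
        rep_config = SimulationConfig(**{**asdict(config), "seed": int(child % 2**31)})
        pathways = generate_pathways(rep_config)
        data, truth = generate_expression(rep_config, pathways)
        res = SPFA(data, pathways).fit(n_perm=n_perm, seed=rep_config.seed, alpha=alpha)
        row = res.table.loc[res.table["pathway_id"] == truth["target_pathway_id"]].iloc[0]
        ranks.append(int(row["rank"]))
        p_adjs.append(float(row["P_adj"]))
        sig_ratios.append(float((res.table["P_adj"] <= alpha).mean()))
    ranks = np.array(ranks)
    p_adjs = np.array(p_adjs)
    return {
        "n_replicates": n_replicates,
        "ranks": ranks.tolist(),
        "p_adj": p_adjs.tolist(),
        "rank1_fraction": float((ranks == 1).mean()) if n_replicates else float("nan"),
        "significant_fraction": float((p_adjs <= alpha).mean()) if n_replicates else float("nan"),
        "rank1_and_significant_fraction": (
            float(((ranks == 1) & (p_adjs <= alpha)).mean()) if n_replicates else float("nan")
        ),
        "median_rank": float(np.median(ranks)) if n_replicates else float("nan"),
        "significant_ratio": float(np.mean(sig_ratios)) if n_replicates else float("nan"),
    }


def write_fixture(config: SimulationConfig, outdir) -> dict:
    """Write a complete simulated input set for the command-line pipeline.

    Produces a pathway registry with per-pathway edge lists, the
    expression TSV, the phenotype TSV, and a ground-truth JSON; returns
    the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    pathways = generate_pathways(config)
    data, truth = generate_expression(config, pathways)

    edgedir = os.path.join(outdir, "pathways")
    os.makedirs(edgedir, exist_ok=True)
    reg_rows = []
    for g in pathways:
        rel = os.path.join("pathways", f"{g.pathway_id}.tsv")
        with open(os.path.join(outdir, rel), "w") as fh:
            fh.write("source\ttarget\ttype\n")
            for s, t in sorted(g.edges):
                fh.write(f"{s}\t{t}\t{g.edge_types.get((s, t), '')}\n")
        reg_rows.append((g.pathway_id, g.name, rel))
    registry = os.path.join(outdir, "registry.tsv")
    with open(registry, "w") as fh:
        fh.write("pathway_id\tname\tedgelist_path\n")
        for row in reg_rows:
            fh.write("\t".join(row) + "\n")

    expr = os.path.join(outdir, "expression.tsv")
    pd.DataFrame(data.values, index=data.genes, columns=data.samples).to_csv(
        expr, sep="\t", index_label="gene_id", float_format="%.6g"
    )
    pheno = os.path.join(outdir, "phenotype.tsv")
    with open(pheno, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s in data.samples:
            fh.write(f"{s}\t{data.condition[s]}\n")
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "registry": registry,
        "expression": expr,
        "phenotype": pheno,
        "truth": truth_path,
    }
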