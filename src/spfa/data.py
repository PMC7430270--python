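"""Expression matrices, phenotype labels, and result-table I/O.

Expression values are used as supplied — the package performs no
normalization. Fold changes are plain mean differences, so the matrix is
assumed to be on a log scale; Pearson correlations are not invariant under
monotone transforms, so callers should be deliberate about the scale.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "load_expression",
    "write_results",
    "read_results",
    "write_effector_report",
    "load_deg_table",
    "RESULT_COLUMNS",
    "EFFECTOR_COLUMNS",
]

CONDITIONS = ("normal", "disease")

#: Fixed column order of the pathway result table.
RESULT_COLUMNS = [
    "pathway_id", "name", "t", "r", "k", "ASV",
    "P_de", "P_sd", "c", "P", "P_adj", "rank",
]
#: Extra columns appended after the fixed block.
RESULT_EXTRA_COLUMNS = ["significant", "flag"]

EFFECTOR_COLUMNS = ["pathway_id", "effector_gene", "s", "ASV_gi"]

_INT_COLUMNS = {"t", "r", "k", "s", "rank"}


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with two-condition labels.

    Parameters
    ----------
    genes : list of str
        Unique gene IDs, one per matrix row.
    samples : list of str
        Unique sample IDs, one per matrix column.
    values : ndarray, shape (n_genes, n_samples)
        Expression values; must be finite.
    condition : dict
        Maps every sample ID to ``"normal"`` or ``"disease"``. Each
        condition needs >= 2 samples (Pearson correlation needs two
        points); fewer than 3 triggers a warning.
    """

    genes: list
    samples: list
    values: np.ndarray
    condition: dict

    def __post_init__(self):
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene IDs in expression dataset")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in expression dataset")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        for s in self.samples:
            if s not in self.condition:
                raise ValueError(f"sample {s!r} has no condition label")
            lab = self.condition[s]
            if lab not in CONDITIONS:
                raise ValueError(
                    f"sample {s!r} has unknown condition {lab!r}; "
                    f"expected one of {CONDITIONS}"
                )
        for cond in CONDITIONS:
            n = sum(1 for s in self.samples if self.condition[s] == cond)
            if n < 2:
                raise ValueError(
                    f"condition {cond!r} has {n} samples; at least 2 are required"
                )
            if n < 3:
                warnings.warn(
                    f"condition {cond!r} has only {n} samples; "
                    "correlations will be extremely noisy",
                    stacklevel=2,
                )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        labels = np.array([self.condition[s] for s in self.samples])
        self._normal_cols = np.flatnonzero(labels == "normal")
        self._disease_cols = np.flatnonzero(labels == "disease")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_index(self) -> dict:
        return self._gene_index

    def values_for(self, cond: str) -> np.ndarray:
        cols = self._normal_cols if cond == "normal" else self._disease_cols
        return self.values[:, cols]

    @property
    def normal_values(self) -> np.ndarray:
        return self.values_for("normal")

    @property
    def disease_values(self) -> np.ndarray:
        return self.values_for("disease")


def _read_matrix(path) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric expression value {bad.iloc[0]!r} for gene "
                f"{bad.index[0]!r}, sample {col!r}"
            )
    if df.isna().any().any():
        g = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing expression value for gene {g!r}")
    return df


def _read_phenotype(path) -> dict:
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError(f"phenotype file {path!s} must have two columns")
    # header row is optional: detect it by an invalid label in row 0
    if raw.iloc[0, 1] not in CONDITIONS:
        raw = raw.iloc[1:]
    return dict(zip(raw.iloc[:, 0], raw.iloc[:, 1]))


def load_expression(matrix_path, phenotype_path) -> ExpressionDataset:
    """Load and validate an expression matrix plus phenotype labels.

    The matrix is TSV (or CSV by ``.csv`` extension) with gene IDs in the
    first column and sample IDs in the header. The phenotype file is a
    two-column TSV ``sample_id<TAB>condition`` (header optional) with
    condition in {normal, disease}. Duplicate gene rows are collapsed by
    keeping the row with the largest variance.
    """
    df = _read_matrix(matrix_path)
    condition = _read_phenotype(phenotype_path)
    for s in df.columns:
        if s not in condition:
            raise ValueError(
                f"sample {s!r} in the expression matrix is missing from the "
                f"phenotype file"
            )
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene IDs by maximum variance: %s",
            len(dups), ", ".join(dups[:10]),
        )
        variances = df.var(axis=1).to_numpy()
        order = np.lexsort((-variances, df.index.to_numpy()))
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
    condition = {s: condition[s] for s in df.columns}
    return ExpressionDataset(
        genes=list(df.index), samples=list(df.columns),
        values=df.to_numpy(dtype=float), condition=condition,
    )


def _format_cell(col: str, v) -> str:
    if isinstance(v, float) and (v != v):  # NaN
        return "NA"
    if v is None:
        return "NA"
    if col in _INT_COLUMNS:
        return str(int(v))
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return "%.6g" % v
    return str(v)


def _write_table(table: pd.DataFrame, columns: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for _, row in table.iterrows():
            fh.write("\t".join(_format_cell(c, row[c]) for c in columns) + "\n")


def write_results(table: pd.DataFrame, path) -> None:
    """Write the pathway result table as a TSV sorted by rank.

    Columns follow :data:`RESULT_COLUMNS` (plus ``significant``/``flag``
    when present); floats are printed at 6 significant digits, undefined
    values as ``NA``. Output is byte-stable for identical inputs.
    """
    cols = list(RESULT_COLUMNS)
    for c in RESULT_EXTRA_COLUMNS:
        if c in table.columns:
            cols.append(c)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table is missing columns {missing}")
    out = table.sort_values("rank")
    _write_table(out, cols, path)


def read_results(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_effector_report(report: pd.DataFrame, path, top_links: pd.DataFrame = None) -> None:
    """Write the per-effector report TSV (pathway_id, effector_gene, s, ASV_gi).

    If ``top_links`` is given (columns pathway_id, effector_gene, g_s,
    d_se, e_se), it is written next to ``path`` with suffix ``_links``.
    """
    _write_table(report, EFFECTOR_COLUMNS, path)
    if top_links is not None:
        base, ext = os.path.splitext(os.fspath(path))
        _write_table(
            top_links,
            ["pathway_id", "effector_gene", "g_s", "d_se", "e_se"],
            base + "_links" + (ext or ".tsv"),
        )


def write_deg_table(stats: pd.DataFrame, degs, path) -> None:
    out = stats.copy()
    out.insert(0, "gene_id", out.index.astype(str))
    out["is_deg"] = out["gene_id"].isin(set(degs))
    _write_table(out, ["gene_id", "p_value", "p_adj", "log_fc", "is_deg"], path)


def load_deg_table(path) -> pd.DataFrame:
    """Load a precomputed per-gene DEG table.

    TSV with columns gene_id, p_value, p_adj, log_fc (an ``is_deg`` column,
    if present, is ignored — selection is re-derived from the statistics).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "p_value", "p_adj", "log_fc"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"DEG table {path!s}: expected columns {sorted(required)}, "
            f"got {list(df.columns)!r}"
        )
    df = df.set_index("gene_id")
    return df[["p_value", "p_adj", "log_fc"]]
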