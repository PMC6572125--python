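"""Differential phosphopeptide signature and hierarchical clustering.

The signature is defined by a two-sample Student's t-test (pooled variance,
two-sided) per peptide between the non-type columns and the luminal/basal
columns of the quant matrix, at raw p <= alpha (default 0.05).  BH-adjusted
q-values are reported alongside but deliberately not used for the signature
definition.  Clustering z-scores each row, uses 1 - Pearson correlation as
the distance and average linkage, for both rows and columns.

A generic hypergeometric over-representation test is included as plumbing
for annotation enrichment; it makes no attempt to model any proprietary
pathway knowledge base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import SampleDesign
from .quant import QuantMatrix


def differential_test(
    qm: QuantMatrix,
    design: SampleDesign,
    group_a: tuple[str, ...] = ("non_type",),
    group_b: tuple[str, ...] = ("luminal", "basal"),
    alpha: float = 0.05,
    replicate_mean: bool = False,
) -> pd.DataFrame:
    """Per-peptide pooled-variance t-test between two sample groups.

    Columns enter as sample x replicate by default (``replicate_mean=False``);
    with ``replicate_mean`` on, technical replicates are averaged first so
    each sample contributes one column.  Returns a DataFrame with columns
    peptide_id, mean_a, mean_b, t, p, q, in_signature.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha={alpha} outside (0,1)")
    data = qm.sample_means() if replicate_mean else qm.data
    samples_a = design.samples_in_groups(group_a)
    samples_b = design.samples_in_groups(group_b)
    if replicate_mean:
        cols_a = [s for s in data.columns if s in samples_a]
        cols_b = [s for s in data.columns if s in samples_b]
    else:
        cols_a = qm.columns_for_samples(samples_a)
        cols_b = qm.columns_for_samples(samples_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"each group needs >= 2 columns (got {len(cols_a)} vs {len(cols_b)})"
        )
    a = data[cols_a].to_numpy(dtype=float)
    b = data[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        t_stat, p = np.asarray(t_stat, float), np.asarray(p, float)

    # zero pooled variance: make the outcome deterministic rather than
    # relying on scipy's nan/inf behavior
    degenerate = (a.var(axis=1, ddof=0) == 0) & (b.var(axis=1, ddof=0) == 0)
    if degenerate.any():
        eq = np.isclose(mean_a, mean_b)
        n_bad = int((degenerate & ~eq).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} peptides have zero pooled variance with unequal "
                "means; their p is set to 0",
                stacklevel=2,
            )
        sign = np.sign(mean_a - mean_b)
        p = np.where(degenerate, np.where(eq, 1.0, 0.0), p)
        with np.errstate(invalid="ignore"):
            t_stat = np.where(
                degenerate, np.where(eq, 0.0, sign * np.inf), t_stat
            )

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "peptide_id": data.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t_stat,
            "p": p,
            "q": q,
            "in_signature": p <= alpha,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Row/column dendrograms over the z-scored matrix that was clustered."""

    z_matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    @property
    def row_order(self) -> list[str]:
        return [self.z_matrix.index[i] for i in hierarchy.leaves_list(self.row_linkage)]

    @property
    def col_order(self) -> list[str]:
        return [self.z_matrix.columns[i] for i in hierarchy.leaves_list(self.col_linkage)]

    def cut_columns(self, k: int) -> dict[str, int]:
        """Column label -> cluster id when the column tree is cut into k."""
        labels = hierarchy.fcluster(self.col_linkage, t=k, criterion="maxclust")
        return {c: int(l) for c, l in zip(self.z_matrix.columns, labels)}

    def newick(self, axis: str = "columns") -> str:
        if axis == "columns":
            z, labels = self.col_linkage, list(self.z_matrix.columns)
        elif axis == "rows":
            z, labels = self.row_linkage, list(self.z_matrix.index)
        else:
            raise ValueError("axis must be 'rows' or 'columns'")
        return linkage_to_newick(z, [str(x) for x in labels])


def cluster(
    matrix: pd.DataFrame,
    rows: list[str] | None = None,
    columns: list | None = None,
) -> ClusterResult:
    """Hierarchical clustering with row z-scoring, correlation distance and
    average linkage.

    ``rows`` restricts to a selection (supervised mode: pass the signature
    peptide ids).  Zero-variance rows cannot be z-scored and are excluded
    with a warning.
    """
    m = matrix
    if rows is not None:
        m = m.loc[rows]
    if columns is not None:
        m = m[columns]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 rows and >= 2 columns")
    vals = m.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance rows before z-scoring",
            stacklevel=2,
        )
        m = m.loc[keep]
        vals = vals[keep]
        sd = sd[keep]
    if m.shape[0] < 2:
        raise ValidationError("fewer than 2 rows with nonzero variance")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    zdf = pd.DataFrame(z, index=m.index, columns=m.columns)
    row_link = hierarchy.linkage(z, method="average", metric="correlation")
    col_link = hierarchy.linkage(z.T, method="average", metric="correlation")
    return ClusterResult(zdf, row_link, col_link)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string; branch lengths are
    differences of merge heights."""
    tree = hierarchy.to_tree(z)

    def build(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.get_left(), node.dist)
        right = build(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# over-representation (generic stand-in for proprietary pathway analysis)
# ---------------------------------------------------------------------------


def overrepresentation_test(
    signature: set[str],
    annotation_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    For each annotation set of size n within a universe of size M, with a
    signature of size N and overlap k, p = P(X >= k) for X hypergeometric.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not signature <= universe:
        raise ValidationError("signature must be a subset of the universe")
    M, N = len(universe), len(signature)
    rows = []
    for name, genes in annotation_sets.items():
        inset = genes & universe
        k = len(inset & signature)
        n = len(inset)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((name, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df.sort_values(["p", "set"]).reset_index(drop=True)
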