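"""Per-sample EMT scoring from the ECDF difference of mesenchymal- versus
epithelial-set expression.

For one sample, the empirical cumulative distribution functions of the
epithelial-set and mesenchymal-set expression values are compared via the
two one-sided two-sample Kolmogorov-Smirnov statistics:

    D_epi_over_mes = max_x [ECDF_Epi(x) - ECDF_Mes(x)]
    D_mes_over_epi = max_x [ECDF_Mes(x) - ECDF_Epi(x)]
    score          = D_epi_over_mes - D_mes_over_epi

The score lies in [-1, +1]; a positive score means the mesenchymal-set
values sit above the epithelial-set values (a "mesenchymal-like" sample),
a negative score "epithelial-like".  Because the score depends on the
values only through within-sample ranks it is invariant under any strictly
increasing per-sample transform.  The two-sample KS p-value is reported
alongside but never gates the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSetPair


@dataclass
class EMTScoreResult:
    sample: str
    d_epi_over_mes: float
    d_mes_over_epi: float
    score: float
    label: str
    p_2ks: float
    n_epithelial: int
    n_mesenchymal: int


def _usable(genes: list[str], expr: ExpressionMatrix, set_name: str) -> list[str]:
    import warnings

    present = [g for g in genes if g in expr.values.index]
    dropped = len(genes) - len(present)
    if dropped:
        warnings.warn(
            f"{dropped} {set_name} genes absent from the expression matrix",
            stacklevel=3,
        )
    if len(present) < 2:
        raise ValidationError(
            f"fewer than 2 usable genes in the {set_name} set"
        )
    return present


def _ecdf_at(values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Right-continuous ECDF of ``values`` evaluated at ``points``."""
    return np.searchsorted(np.sort(values), points, side="right") / values.size


def emt_score(
    expr: ExpressionMatrix, sets: GeneSetPair, sample: str
) -> EMTScoreResult:
    """EMT score of one sample (see module docstring for the definition)."""
    if sample not in expr.values.columns:
        raise ValidationError(f"sample {sample!r} not in expression matrix")
    epi_genes = _usable(sets.epithelial, expr, "epithelial")
    mes_genes = _usable(sets.mesenchymal, expr, "mesenchymal")
    col = expr.values[sample]
    epi = col.loc[epi_genes].to_numpy(dtype=float)
    mes = col.loc[mes_genes].to_numpy(dtype=float)
    pooled = np.unique(np.concatenate([epi, mes]))
    diff = _ecdf_at(epi, pooled) - _ecdf_at(mes, pooled)
    d_epi_over_mes = float(max(diff.max(), 0.0))
    d_mes_over_epi = float(max((-diff).max(), 0.0))
    score = d_epi_over_mes - d_mes_over_epi
    if score > 0:
        label = "mesenchymal-like"
    elif score < 0:
        label = "epithelial-like"
    else:
        label = "neutral"
    import warnings

    with warnings.catch_warnings():
        # ties force scipy onto the asymptotic path; that is fine here
        warnings.filterwarnings("ignore", message="ks_2samp")
        p = float(stats.ks_2samp(epi, mes, alternative="two-sided").pvalue)
    return EMTScoreResult(
        sample=sample,
        d_epi_over_mes=d_epi_over_mes,
        d_mes_over_epi=d_mes_over_epi,
        score=score,
        label=label,
        p_2ks=p,
        n_epithelial=len(epi_genes),
        n_mesenchymal=len(mes_genes),
    )


def emt_score_all(expr: ExpressionMatrix, sets: GeneSetPair) -> list[EMTScoreResult]:
    """Score every sample; ordering is deterministic (score desc, then name)."""
    results = [emt_score(expr, sets, s) for s in expr.samples]
    return sorted(results, key=lambda r: (-r.score, r.sample))


def emt_table(results: list[EMTScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sample, r.d_epi_over_mes, r.d_mes_over_epi, r.score, r.label,
             r.p_2ks, r.n_epithelial, r.n_mesenchymal)
            for r in results
        ],
        columns=["sample", "D_epi_over_mes", "D_mes_over_epi", "score",
                 "label", "p_2KS", "n_epithelial", "n_mesenchymal"],
    )
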