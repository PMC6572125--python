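"""Kinase-substrate enrichment analysis (kinase activity inference).

Each kinase's activity is inferred from the log2 fold-changes of its
annotated substrate sites:

    z = (mean_substrates - mean_all) * sqrt(m) / sd_all

where ``mean_substrates`` is the mean fold-change over the kinase's m
matched sites, and ``mean_all`` / ``sd_all`` are the mean and population
standard deviation over *all* site fold-changes in the input.  z is
converted to a two-sided normal p, BH-adjusted across kinases, and a
kinase is flagged reportable when p < 0.05 and m >= 5 (the conventional
plotting cutoffs of this analysis).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError
from .io import KinaseSubstrateMap, PhosphoPeptideRecord, SampleDesign
from .quant import QuantMatrix, SiteKey


def site_fold_changes(
    qm: QuantMatrix,
    records: Sequence[PhosphoPeptideRecord],
    design: SampleDesign,
    group_a: tuple[str, ...] = ("non_type",),
    group_b: tuple[str, ...] = ("luminal", "basal"),
) -> dict[SiteKey, float]:
    """Per-site log2 fold-change for a group contrast.

    A peptide's fold-change (mean over group-A columns minus mean over
    group-B columns) is propagated to every site it covers; sites covered
    by several peptides take the mean.
    """
    cols_a = qm.columns_for_samples(design.samples_in_groups(group_a))
    cols_b = qm.columns_for_samples(design.samples_in_groups(group_b))
    if not cols_a or not cols_b:
        raise ValidationError("a contrast group matched no quant-matrix columns")
    fc = qm.data[cols_a].mean(axis=1) - qm.data[cols_b].mean(axis=1)
    by_id = {r.peptide_id: r for r in records}
    acc: dict[SiteKey, list[float]] = {}
    for pid, value in fc.items():
        rec = by_id.get(str(pid))
        if rec is None:
            continue
        for key in rec.site_keys():
            acc.setdefault(key, []).append(float(value))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def ksea(
    site_fcs: Mapping[SiteKey, float],
    ksmap: KinaseSubstrateMap,
    p_cutoff: float = 0.05,
    m_cutoff: int = 5,
) -> pd.DataFrame:
    """Kinase z-scores from substrate-site fold-changes.

    Returns a DataFrame sorted by z (descending) with columns kinase, m,
    mean_substrate_fc, z, p, q, direction, reportable.  Requires at least
    two sites overall; raises on zero spread of the fold-changes.
    """
    if len(site_fcs) < 2:
        raise ValidationError("need >= 2 site fold-changes")
    all_fc = np.fromiter(site_fcs.values(), dtype=float)
    mean_p = float(all_fc.mean())
    delta = float(all_fc.std(ddof=0))
    if delta == 0.0:
        raise DegenerateInputError("all site fold-changes identical (sd = 0)")

    rows = []
    for kin in ksmap.kinases:
        matched = [
            site_fcs[SiteKey(a, p, r)]
            for a, p, r in ksmap.sites_of(kin)
            if SiteKey(a, p, r) in site_fcs
        ]
        m = len(matched)
        if m < 1:
            continue
        mean_s = float(np.mean(matched))
        z = (mean_s - mean_p) * np.sqrt(m) / delta
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append((kin, m, mean_s, float(z), p))
    if not rows:
        raise ValidationError("no kinase has any matched substrate site")
    df = pd.DataFrame(rows, columns=["kinase", "m", "mean_substrate_fc", "z", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(df["z"] > 0, "activated", "suppressed")
    df["reportable"] = (df["p"] < p_cutoff) & (df["m"] >= m_cutoff)
    return df.sort_values("z", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def tally_kinase_families(
    identified: set[str], classification: Mapping[str, str]
) -> dict[str, int]:
    """Count identified kinases per family (CMGC, STE, AGC, CAMK, TK, TKL,
    CK1, atypical, ...); kinases absent from the table count as
    ``unclassified``."""
    counts: Counter[str] = Counter()
    for kin in identified:
        counts[classification.get(kin, "unclassified")] += 1
    return dict(counts)


def plot_ksea_bars(results: pd.DataFrame, path: str) -> None:
    """Horizontal bar chart of reportable kinase z-scores (activated red,
    suppressed blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = results[results["reportable"]].sort_values("z")
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(rep))))
    colors = ["red" if z > 0 else "steelblue" for z in rep["z"]]
    ax.barh(rep["kinase"], rep["z"], color=colors)
    ax.set_xlabel("KSEA z-score")
    ax.axvline(0, color="black", lw=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
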