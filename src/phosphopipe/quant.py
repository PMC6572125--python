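"""Reporter-intensity quantitation: control-relative log2 ratios, the
localization / completeness filters, dysregulation calls and site tallies.

Filtering semantics:

* the localization filter keeps a peptide only if **every** site probability
  is **strictly** greater than the threshold (default 0.75);
* peptides not quantified (> 0 intensity) in every channel of every
  replicate are dropped before any ratio is formed;
* ratios are taken within replicate against the control channel of the same
  replicate, then replicate-averaged for the +/- 2-fold dysregulation calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import PhosphoPeptideRecord, SampleDesign

HYPER = "hyper"
HYPO = "hypo"
UNCHANGED = "unchanged"


class SiteKey(NamedTuple):
    """A phosphosite: protein accession, 1-based position, residue."""

    accession: str
    position: int
    residue: str


@dataclass
class QuantMatrix:
    """Peptides x (sample, replicate) log2 ratios versus the control sample.

    ``data`` is indexed by peptide id with a (sample, replicate) column
    MultiIndex; the control sample itself never appears as a column.
    ``provenance`` lists the filters applied upstream, with parameters.
    """

    data: pd.DataFrame
    provenance: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite log2 ratio in quant matrix")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.data.index)

    def columns_for_samples(self, samples: Iterable[str]) -> list[tuple[str, int]]:
        wanted = set(samples)
        return [c for c in self.data.columns if c[0] in wanted]

    def sample_means(self) -> pd.DataFrame:
        """Replicate-averaged log2 ratio per sample."""
        return self.data.T.groupby(level=0).mean().T


def filter_localization(
    records: Sequence[PhosphoPeptideRecord], threshold: float = 0.75
) -> list[PhosphoPeptideRecord]:
    """Keep records whose every site probability is strictly > ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"localization threshold {threshold} outside [0,1]")
    return [
        r for r in records if all(p > threshold for p in r.localization_probs)
    ]


def filter_quantified_complete(
    records: Sequence[PhosphoPeptideRecord],
) -> list[PhosphoPeptideRecord]:
    """Keep records quantified (> 0) in all design channels of all replicates."""
    return [r for r in records if r.quantified_complete]


def compute_ratios(
    records: Sequence[PhosphoPeptideRecord],
    design: SampleDesign,
    normalize: bool = False,
    provenance: Sequence[str] = (),
) -> QuantMatrix:
    """log2(intensity_sample / intensity_control), within replicate.

    Non-complete records are dropped (and recorded in provenance).  With
    ``normalize`` on, each column is median-centered to 0 afterwards.
    """
    complete = filter_quantified_complete(records)
    control = design.control_sample
    cols = [
        (s, rep)
        for s in design.samples
        if s != control
        for rep in design.replicates
    ]
    chan = {(e.sample, e.replicate): e.channel for e in design.entries}
    keys = [
        ((chan[(s, rep)], rep), (chan[(control, rep)], rep)) for s, rep in cols
    ]
    values = np.empty((len(complete), len(cols)))
    for i, rec in enumerate(complete):
        ints = rec.intensities
        for j, (num_key, den_key) in enumerate(keys):
            values[i, j] = math.log2(ints[num_key] / ints[den_key])
    df = pd.DataFrame(
        values,
        index=pd.Index([r.peptide_id for r in complete], name="peptide_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"]),
    )
    prov = list(provenance) + ["quantified_complete"]
    if normalize:
        df = df - df.median(axis=0)
        prov.append("median_center_columns")
    return QuantMatrix(df, prov)


@dataclass
class DysregulationCall:
    """Per-sample hyper/hypo/unchanged call for one peptide, from the
    replicate-averaged log2 ratio thresholded at +/- 1 (2-fold)."""

    peptide_id: str
    calls: dict[str, str]

    def is_dysregulated(self) -> bool:
        return any(c != UNCHANGED for c in self.calls.values())


def call_dysregulation(
    qm: QuantMatrix, log2_threshold: float = 1.0
) -> list[DysregulationCall]:
    if qm.data.empty:
        raise ValidationError("empty quant matrix")
    if log2_threshold <= 0:
        raise ValidationError("fold-change threshold must be positive")
    means = qm.sample_means()
    out = []
    for pid, row in means.iterrows():
        calls = {}
        for sample, m in row.items():
            if m >= log2_threshold:
                calls[sample] = HYPER
            elif m <= -log2_threshold:
                calls[sample] = HYPO
            else:
                calls[sample] = UNCHANGED
        out.append(DysregulationCall(str(pid), calls))
    return out


def calls_table(calls: Sequence[DysregulationCall]) -> pd.DataFrame:
    samples = list(calls[0].calls) if calls else []
    return pd.DataFrame(
        [[c.peptide_id, *[c.calls[s] for s in samples]] for c in calls],
        columns=["peptide_id", *samples],
    )


@dataclass
class SiteTally:
    """Unique-phosphosite counts by residue class."""

    by_residue: dict[str, int]
    n_unique_sites: int
    n_unique_peptides: int
    n_proteins: int


def tally_sites(
    records: Sequence[PhosphoPeptideRecord],
    proteome: Mapping[str, str] | None = None,
) -> SiteTally:
    """Count unique (accession, position, residue) sites, split by S/T/Y.

    When a proteome is supplied, every site's residue is cross-checked
    against the protein sequence; mismatches raise a validation error that
    lists the offending keys.
    """
    sites: set[SiteKey] = set()
    for rec in records:
        sites.update(rec.site_keys())
    if proteome is not None:
        bad = [
            k
            for k in sorted(sites)
            if k.accession not in proteome
            or k.position > len(proteome[k.accession])
            or proteome[k.accession][k.position - 1] != k.residue
        ]
        if bad:
            raise ValidationError(f"site/proteome residue mismatch: {bad[:10]}")
    by_res = {"S": 0, "T": 0, "Y": 0}
    for k in sites:
        by_res[k.residue] += 1
    return SiteTally(
        by_residue=by_res,
        n_unique_sites=len(sites),
        n_unique_peptides=len({r.peptide_id for r in records}),
        n_proteins=len({r.accession for r in records}),
    )
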