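"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a 10-plex TMT phosphoproteomics experiment: one
non-neoplastic control plus six tumor cell lines (two luminal, one basal,
three non-type) in two technical replicates.  Planted structure — group-wise
log2 shifts on a fraction of peptides, active kinases whose substrate sites
share a shift, a sequence motif around a fraction of planted sites, and
epithelial/mesenchymal expression polarity — is recorded in a
:class:`SyntheticTruth` so every downstream stage can be checked against
ground truth.

Model: the control channel intensity of a peptide is log-normal; every
other channel is control x 2^(effect + N(0, noise_sd)), so the log2 ratio
of a null peptide is pure N(0, noise_sd) and of a planted peptide is
effect + N(0, noise_sd).  Defaults (2 replicates, noise SD 0.25 on the log2
scale, 10% planted differential peptides with |effect| = 1, 3 active
kinases x 10 substrates with shift +1) are desk-scale yet statistically
resolvable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    AMINO_ACIDS,
    DesignEntry,
    ExpressionMatrix,
    GeneSetPair,
    KinaseSubstrateEntry,
    KinaseSubstrateMap,
    PhosphoPeptideRecord,
    SampleDesign,
)

#: Channel assignment of the emulated study: control on 126, luminal on
#: 130N/130C, basal on 129C, non-type on 131/128C/128N, two replicates.
STUDY_CHANNELS = [
    ("126", "TERT-NHUC", "control"),
    ("130N", "SW780", "luminal"),
    ("130C", "RT112", "luminal"),
    ("129C", "VMCUB-1", "basal"),
    ("131", "T24", "non_type"),
    ("128C", "J82", "non_type"),
    ("128N", "UMUC3", "non_type"),
]


def study_design(n_replicates: int = 2) -> SampleDesign:
    """The emulated 10-plex design: 7 used channels, 2 technical replicates."""
    entries = [
        DesignEntry(ch, sample, group, rep)
        for rep in range(1, n_replicates + 1)
        for ch, sample, group in STUDY_CHANNELS
    ]
    return SampleDesign(entries)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment, serializable to JSON."""

    seed: int
    differential: dict[str, dict[str, float]]  # peptide id -> {group: log2 effect}
    active_kinases: dict[str, float]  # kinase -> substrate log2 shift
    motif: tuple[int, str, float]  # (offset, residue, foreground fraction)
    noise_sd: float
    emt_polarity: dict[str, str] = field(default_factory=dict)
    motif_peptides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise SD must be positive")
        frac = self.motif[2]
        if not (0.0 < frac <= 1.0):
            raise ValidationError("motif foreground fraction must be in (0,1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "differential": self.differential,
            "active_kinases": self.active_kinases,
            "motif": {
                "offset": self.motif[0],
                "residue": self.motif[1],
                "foreground_fraction": self.motif[2],
            },
            "noise_sd": self.noise_sd,
            "emt_polarity": self.emt_polarity,
            "motif_peptides": self.motif_peptides,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            differential=d["differential"],
            active_kinases=d["active_kinases"],
            motif=(
                d["motif"]["offset"],
                d["motif"]["residue"],
                d["motif"]["foreground_fraction"],
            ),
            noise_sd=d["noise_sd"],
            emt_polarity=d["emt_polarity"],
            motif_peptides=d.get("motif_peptides", []),
        )


@dataclass
class SyntheticExperiment:
    """Bundle returned by :func:`simulate_phospho_experiment`."""

    records: list[PhosphoPeptideRecord]
    truth: SyntheticTruth
    kinase_substrates: KinaseSubstrateMap
    proteome: dict[str, str]


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
) -> dict[str, str]:
    """Uniform-random amino-acid sequences, deterministic for a fixed seed."""
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValidationError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    out = {}
    for i in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        out[f"SYN{i + 1:05d}"] = "".join(rng.choice(aas, size=n))
    return out


def _sty_sites(proteome: Mapping[str, str]) -> list[tuple[str, int, str]]:
    sites = []
    for acc in proteome:
        seq = proteome[acc]
        for i, aa in enumerate(seq):
            if aa in "STY":
                sites.append((acc, i + 1, aa))
    return sites


def simulate_phospho_experiment(
    design: SampleDesign,
    proteome: Mapping[str, str],
    n_peptides: int = 1000,
    *,
    frac_differential: float = 0.10,
    effect_size: float = 1.0,
    effect_group: str = "non_type",
    n_active_kinases: int = 3,
    substrates_per_kinase: int = 10,
    kinase_shift: float = 1.0,
    n_null_kinases: int = 20,
    motif_offset: int = 1,
    motif_residue: str = "P",
    motif_fraction: float = 0.4,
    frac_low_localization: float = 0.10,
    frac_incomplete: float = 0.02,
    noise_sd: float = 0.25,
    base_log2_mean: float = 20.0,
    base_log2_sd: float = 1.5,
    seed: int = 0,
) -> SyntheticExperiment:
    """Simulate a full TMT phosphopeptide quantitation with planted truth.

    Planted differential peptides get a +/-``effect_size`` log2 shift in the
    ``effect_group`` samples; planted kinases get ``substrates_per_kinase``
    dedicated substrate peptides that all shift by ``+kinase_shift``; a
    ``motif_fraction`` of the positively planted differential peptides carry
    ``motif_residue`` at ``motif_offset`` from the phosphosite (written into
    the simulated proteome); ``frac_low_localization`` of peptides draw a
    localization probability below 0.75, and ``frac_incomplete`` lose one
    random channel to exercise the completeness filter.
    """
    for name, frac in (("frac_differential", frac_differential),
                       ("motif_fraction", motif_fraction),
                       ("frac_low_localization", frac_low_localization),
                       ("frac_incomplete", frac_incomplete)):
        if not (0.0 <= frac <= 1.0):
            raise ValidationError(f"{name}={frac} outside [0,1]")
    if motif_offset == 0 or abs(motif_offset) > 7:
        raise ValidationError("motif offset must be in [-7,+7], nonzero")
    if effect_group not in {design.group_of(s) for s in design.samples}:
        raise ValidationError(f"design has no samples in group {effect_group!r}")

    rng = np.random.default_rng(seed)
    proteome = dict(proteome)

    all_sites = _sty_sites(proteome)
    if len(all_sites) < n_peptides:
        raise ValidationError(
            f"proteome hosts only {len(all_sites)} S/T/Y sites, "
            f"need {n_peptides}"
        )
    chosen_idx = rng.choice(len(all_sites), size=n_peptides, replace=False)
    sites = [all_sites[i] for i in chosen_idx]
    site_positions = {(acc, pos) for acc, pos, _ in sites}

    n_diff = int(round(frac_differential * n_peptides))
    n_kin_subs = (n_active_kinases + n_null_kinases) * substrates_per_kinase
    if n_diff + n_kin_subs > n_peptides:
        raise ValidationError(
            "n_peptides too small for the requested planted structure"
        )

    order = rng.permutation(n_peptides)
    diff_idx = order[:n_diff]
    kin_idx = order[n_diff:n_diff + n_kin_subs]

    pids = [f"pep{i + 1:06d}" for i in range(n_peptides)]
    effects = np.zeros(n_peptides)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    effects[diff_idx] = signs * effect_size

    differential = {
        pids[i]: {effect_group: float(effects[i])} for i in np.sort(diff_idx)
    }

    # dedicated substrate peptides per kinase; planted kinases' substrates
    # all shift by +kinase_shift in the effect group, null kinases' do not
    ks_entries = []
    active_kinases = {}
    for k in range(n_active_kinases + n_null_kinases):
        planted = k < n_active_kinases
        name = f"KIN{'A' if planted else 'N'}{k + 1:03d}"
        block = kin_idx[k * substrates_per_kinase:(k + 1) * substrates_per_kinase]
        for i in block:
            acc, pos, res = sites[i]
            ks_entries.append(
                KinaseSubstrateEntry(name, acc, pos, res, "synthetic")
            )
            if planted:
                effects[i] = kinase_shift
        if planted:
            active_kinases[name] = float(kinase_shift)

    # plant the motif on positively shifted differential peptides by editing
    # the simulated proteome next to the phosphosite (never on another
    # chosen site, which would break its residue identity)
    motif_pids: list[str] = []
    pos_diff = [i for i in np.sort(diff_idx) if effects[i] > 0]
    n_motif = int(round(motif_fraction * len(pos_diff)))
    for i in pos_diff:
        if len(motif_pids) >= n_motif:
            break
        acc, pos, _res = sites[i]
        tgt = pos + motif_offset  # 1-based
        seq = proteome[acc]
        if not (1 <= tgt <= len(seq)) or (acc, tgt) in site_positions:
            continue
        proteome[acc] = seq[:tgt - 1] + motif_residue + seq[tgt:]
        motif_pids.append(pids[i])

    # intensities: control log-normal per replicate; every other channel is
    # control x 2^(effect + noise)
    group_of = {s: design.group_of(s) for s in design.samples}
    control = design.control_sample
    reps = design.replicates
    non_control = [s for s in design.samples if s != control]

    control_log2 = rng.normal(base_log2_mean, base_log2_sd,
                              size=(n_peptides, len(reps)))
    intensity = {}  # (sample, rep) -> array over peptides
    for r_i, rep in enumerate(reps):
        intensity[(control, rep)] = 2.0 ** control_log2[:, r_i]
    for s in non_control:
        eff = effects if group_of[s] == effect_group else np.zeros(n_peptides)
        for r_i, rep in enumerate(reps):
            noise = rng.normal(0.0, noise_sd, size=n_peptides)
            intensity[(s, rep)] = 2.0 ** (control_log2[:, r_i] + eff + noise)

    # drop one random channel for a fraction of peptides
    n_inc = int(round(frac_incomplete * n_peptides))
    incomplete_idx = rng.choice(n_peptides, size=n_inc, replace=False)
    pairs = [(s, rep) for s in design.samples for rep in reps]
    drop_choice = rng.integers(0, len(pairs), size=n_inc)

    zeroed: dict[int, tuple[str, int]] = {
        int(i): pairs[int(c)] for i, c in zip(incomplete_idx, drop_choice)
    }

    # localization probabilities
    low_mask = rng.random(n_peptides) < frac_low_localization
    probs = np.where(
        low_mask,
        rng.uniform(0.40, 0.745, size=n_peptides),
        rng.uniform(0.80, 1.00, size=n_peptides),
    )

    records = []
    for i in range(n_peptides):
        acc, pos, res = sites[i]
        seq = proteome[acc]
        start = max(0, pos - 8)
        pep_seq = seq[start:pos + 7]
        rec_int = {}
        for s in design.samples:
            for rep in reps:
                ch = design.channel_of(s, rep)
                v = float(intensity[(s, rep)][i])
                if zeroed.get(i) == (s, rep):
                    v = 0.0
                rec_int[(ch, rep)] = v
        rec = PhosphoPeptideRecord(
            peptide_id=pids[i],
            sequence=pep_seq,
            accession=acc,
            positions=[pos],
            residues=[res],
            localization_probs=[float(probs[i])],
            intensities=rec_int,
        )
        rec.quantified_complete = i not in zeroed
        records.append(rec)

    truth = SyntheticTruth(
        seed=seed,
        differential=differential,
        active_kinases=active_kinases,
        motif=(motif_offset, motif_residue, motif_fraction),
        noise_sd=noise_sd,
        motif_peptides=motif_pids,
    )
    return SyntheticExperiment(
        records=records,
        truth=truth,
        kinase_substrates=KinaseSubstrateMap(ks_entries),
        proteome=proteome,
    )


def default_gene_set_pair(n_per_set: int = 15) -> GeneSetPair:
    """Synthetic epithelial/mesenchymal marker sets (EPI0001.., MES0001..)."""
    return GeneSetPair(
        epithelial=[f"EPI{i + 1:04d}" for i in range(n_per_set)],
        mesenchymal=[f"MES{i + 1:04d}" for i in range(n_per_set)],
    )


def simulate_expression(
    samples: Sequence[str],
    gene_set_pair: GeneSetPair,
    polarity: Mapping[str, str],
    n_background_genes: int = 200,
    shift: float = 1.5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Gene x sample matrix with planted epithelial/mesenchymal polarity.

    In a mesenchymal-polarity sample the mesenchymal-set genes are drawn
    from N(+shift/2, 1) and the epithelial-set from N(-shift/2, 1) (and vice
    versa for epithelial polarity); neutral samples and background genes
    draw from N(0, 1).
    """
    valid = {"epithelial", "mesenchymal", "neutral"}
    for s in samples:
        if s not in polarity:
            raise ValidationError(f"no polarity given for sample {s!r}")
    for s, p in polarity.items():
        if s not in samples:
            raise ValidationError(f"polarity names unknown sample {s!r}")
        if p not in valid:
            raise ValidationError(f"polarity {p!r} not in {sorted(valid)}")
    rng = np.random.default_rng(seed)
    genes = (
        list(gene_set_pair.epithelial)
        + list(gene_set_pair.mesenchymal)
        + [f"BG{i + 1:05d}" for i in range(n_background_genes)]
    )
    n_epi = len(gene_set_pair.epithelial)
    n_mes = len(gene_set_pair.mesenchymal)
    values = rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    half = shift / 2.0
    for j, s in enumerate(samples):
        if polarity[s] == "mesenchymal":
            values[n_epi:n_epi + n_mes, j] += half
            values[:n_epi, j] -= half
        elif polarity[s] == "epithelial":
            values[:n_epi, j] += half
            values[n_epi:n_epi + n_mes, j] -= half
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                     columns=list(samples))
    )


#: EMT polarity of the emulated study: non-type lines mesenchymal-like,
#: luminal/basal epithelial-like, control neutral.
STUDY_POLARITY = {
    "TERT-NHUC": "neutral",
    "SW780": "epithelial",
    "RT112": "epithelial",
    "VMCUB-1": "epithelial",
    "T24": "mesenchymal",
    "J82": "mesenchymal",
    "UMUC3": "mesenchymal",
}
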