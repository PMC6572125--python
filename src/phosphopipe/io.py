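"""Readers and writers for every file the pipeline touches.

All downstream modules operate on the typed containers defined here:

* :class:`SampleDesign` — TMT channel -> sample/group/replicate mapping,
* :class:`PhosphoPeptideRecord` — one quantified phosphopeptide,
* :class:`GeneSetPair` / :class:`ExpressionMatrix` — EMT-scoring inputs,
* :class:`KinaseSubstrateMap` — kinase -> substrate-site annotation.

File dialects are plain TSV with headers (one row per peptide; site lists
joined with ";" inside a cell), standard FASTA (accession = first token of
the header) and standard GMT.  All protein coordinates are 1-based.
A reporter intensity of 0 means "not quantified in that channel", never a
measured zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

VALID_GROUPS = ("control", "luminal", "basal", "non_type")
PHOSPHO_RESIDUES = ("S", "T", "Y")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignEntry:
    channel: str
    sample: str
    group: str
    replicate: int


@dataclass
class SampleDesign:
    """Channel assignment of a multiplexed (TMT-style) experiment.

    Exactly one sample must carry ``group == "control"``; every sample must
    be labeled in the same set of replicates, and at least one non-control
    sample must exist so group comparisons are possible.
    """

    entries: list[DesignEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("design has no entries")
        seen: set[tuple[str, int]] = set()
        per_sample_reps: dict[str, set[int]] = {}
        groups: dict[str, str] = {}
        for e in self.entries:
            if e.group not in VALID_GROUPS:
                raise ValidationError(
                    f"unknown group {e.group!r} (expected one of {VALID_GROUPS})"
                )
            if e.replicate < 1:
                raise ValidationError(f"replicate must be >= 1, got {e.replicate}")
            key = (e.channel, e.replicate)
            if key in seen:
                raise ValidationError(f"duplicate channel x replicate pair {key}")
            seen.add(key)
            per_sample_reps.setdefault(e.sample, set()).add(e.replicate)
            prev = groups.setdefault(e.sample, e.group)
            if prev != e.group:
                raise ValidationError(
                    f"sample {e.sample!r} assigned to two groups ({prev}, {e.group})"
                )
        controls = [s for s, g in groups.items() if g == "control"]
        if len(controls) != 1:
            raise ValidationError(
                f"exactly one control sample required, found {len(controls)}"
            )
        rep_sets = {frozenset(r) for r in per_sample_reps.values()}
        if len(rep_sets) != 1:
            raise ValidationError("every sample must appear in the same replicates")
        if len(groups) < 2:
            raise ValidationError("design needs at least one non-control sample")

    # -- convenience accessors ------------------------------------------------

    @property
    def control_sample(self) -> str:
        return next(e.sample for e in self.entries if e.group == "control")

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.sample not in out:
                out.append(e.sample)
        return out

    @property
    def replicates(self) -> list[int]:
        return sorted({e.replicate for e in self.entries})

    def group_of(self, sample: str) -> str:
        for e in self.entries:
            if e.sample == sample:
                return e.group
        raise KeyError(sample)

    def samples_in_groups(self, groups: Iterable[str]) -> list[str]:
        wanted = set(groups)
        return [s for s in self.samples if self.group_of(s) in wanted]

    def channel_of(self, sample: str, replicate: int) -> str:
        for e in self.entries:
            if e.sample == sample and e.replicate == replicate:
                return e.channel
        raise KeyError((sample, replicate))

    def intensity_columns(self) -> list[str]:
        """Quant-table column names, one per channel x replicate."""
        return [f"{e.channel}_r{e.replicate}" for e in self.entries]

    def channel_replicate_pairs(self) -> list[tuple[str, int]]:
        return [(e.channel, e.replicate) for e in self.entries]


def read_design(path: str | Path) -> SampleDesign:
    df = _read_tsv(path, required=("channel", "sample", "group", "replicate"))
    entries = []
    for row in df.itertuples(index=False):
        try:
            rep = int(row.replicate)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-integer replicate {row.replicate!r}") from exc
        entries.append(
            DesignEntry(str(row.channel), str(row.sample), str(row.group), rep)
        )
    return SampleDesign(entries)


def write_design(design: SampleDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.channel, e.sample, e.group, e.replicate) for e in design.entries],
        columns=["channel", "sample", "group", "replicate"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phosphopeptide quantitation table
# ---------------------------------------------------------------------------


@dataclass
class PhosphoPeptideRecord:
    """One quantified phosphopeptide with its site assignment and reporter
    intensities.

    ``positions`` are 1-based coordinates in the protein, strictly
    increasing; ``residues`` and ``localization_probs`` are parallel to
    them.  ``quantified_complete`` is true iff every design channel in every
    replicate has intensity > 0.
    """

    peptide_id: str
    sequence: str
    accession: str
    positions: list[int]
    residues: list[str]
    localization_probs: list[float]
    intensities: dict[tuple[str, int], float]
    quantified_complete: bool = field(default=False)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n == 0:
            raise ValidationError(f"{self.peptide_id}: no phosphosites")
        if len(self.residues) != n or len(self.localization_probs) != n:
            raise ValidationError(
                f"{self.peptide_id}: site lists are not parallel "
                f"({n} positions, {len(self.residues)} residues, "
                f"{len(self.localization_probs)} probabilities)"
            )
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValidationError(
                f"{self.peptide_id}: positions not strictly increasing"
            )
        for r in self.residues:
            if r not in PHOSPHO_RESIDUES:
                raise ValidationError(f"{self.peptide_id}: residue {r!r} not in S/T/Y")
        for p in self.localization_probs:
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ValidationError(
                    f"{self.peptide_id}: localization probability {p} outside [0,1]"
                )
        for key, v in self.intensities.items():
            if v < 0 or math.isnan(v):
                raise ValidationError(
                    f"{self.peptide_id}: negative intensity {v} in channel {key}"
                )

    def site_keys(self) -> list["SiteKey"]:
        from .quant import SiteKey  # local import: quant depends on io

        return [
            SiteKey(self.accession, p, r)
            for p, r in zip(self.positions, self.residues)
        ]


def _compute_complete(
    intensities: Mapping[tuple[str, int], float], design: SampleDesign
) -> bool:
    return all(
        intensities.get(pair, 0.0) > 0.0 for pair in design.channel_replicate_pairs()
    )


def read_quant_table(
    path: str | Path, design: SampleDesign
) -> list[PhosphoPeptideRecord]:
    base_cols = ("peptide_id", "sequence", "accession", "positions", "residues",
                 "loc_probs")
    df = _read_tsv(path, required=base_cols)
    intensity_cols = design.intensity_columns()
    missing = [c for c in intensity_cols if c not in df.columns]
    if missing:
        raise FormatError(
            f"quant table lacks intensity columns for the design: {missing}"
        )
    pairs = design.channel_replicate_pairs()
    records = []
    for d in df.to_dict(orient="records"):
        try:
            positions = [int(x) for x in str(d["positions"]).split(";")]
            residues = str(d["residues"]).split(";")
            probs = [float(x) for x in str(d["loc_probs"]).split(";")]
        except ValueError as exc:
            raise FormatError(
                f"unparseable site lists for peptide {d['peptide_id']!r}: {exc}"
            ) from exc
        intensities = {}
        for pair, col in zip(pairs, intensity_cols):
            try:
                intensities[pair] = float(d[col])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"unparseable intensity {d[col]!r} in column {col}"
                ) from exc
        rec = PhosphoPeptideRecord(
            peptide_id=str(d["peptide_id"]),
            sequence=str(d["sequence"]).upper(),
            accession=str(d["accession"]),
            positions=positions,
            residues=residues,
            localization_probs=probs,
            intensities=intensities,
        )
        rec.quantified_complete = _compute_complete(rec.intensities, design)
        records.append(rec)
    ids = [r.peptide_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate peptide ids in quant table")
    return records


def write_quant_table(
    records: Sequence[PhosphoPeptideRecord], design: SampleDesign, path: str | Path
) -> None:
    pairs = design.channel_replicate_pairs()
    cols = design.intensity_columns()
    rows = []
    for r in records:
        row = {
            "peptide_id": r.peptide_id,
            "sequence": r.sequence,
            "accession": r.accession,
            "positions": ";".join(str(p) for p in r.positions),
            "residues": ";".join(r.residues),
            "loc_probs": ";".join(_fmt(p) for p in r.localization_probs),
        }
        for pair, col in zip(pairs, cols):
            row[col] = _fmt(r.intensities.get(pair, 0.0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets and expression
# ---------------------------------------------------------------------------


@dataclass
class GeneSetPair:
    """Epithelial and mesenchymal marker gene sets used for EMT scoring."""

    epithelial: list[str]
    mesenchymal: list[str]
    name: str = "EMT"

    def __post_init__(self) -> None:
        for label, genes in (("epithelial", self.epithelial),
                             ("mesenchymal", self.mesenchymal)):
            if not genes:
                raise ValidationError(f"{label} gene set is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate symbols in {label} gene set")
        overlap = set(self.epithelial) & set(self.mesenchymal)
        if overlap:
            raise ValidationError(
                f"epithelial and mesenchymal sets overlap: {sorted(overlap)}"
            )


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into (name, description, genes) triples."""
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"empty GMT file: {path}")
    sets = []
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {i} has fewer than 3 fields")
        genes = [g for g in parts[2:] if g]
        sets.append((parts[0], parts[1], genes))
    return sets


def write_gmt(sets: Sequence[tuple[str, str, Sequence[str]]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def gene_set_pair_from_gmt(
    path: str | Path,
    epithelial_name: str = "EPITHELIAL",
    mesenchymal_name: str = "MESENCHYMAL",
) -> GeneSetPair:
    by_name = {name: genes for name, _, genes in read_gmt(path)}
    for wanted in (epithelial_name, mesenchymal_name):
        if wanted not in by_name:
            raise FormatError(f"GMT file lacks the {wanted!r} gene set")
    return GeneSetPair(
        epithelial=list(by_name[epithelial_name]),
        mesenchymal=list(by_name[mesenchymal_name]),
    )


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (any within-sample monotone scale)."""

    values: pd.DataFrame  # index = gene symbols, columns = sample names

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            raise ValidationError("duplicate gene symbols in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite values in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = _read_tsv(path, required=("gene",))
    return ExpressionMatrix(df.set_index("gene").astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Kinase-substrate annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinaseSubstrateEntry:
    kinase: str
    substrate_accession: str
    position: int
    residue: str
    source: str = "curated"


@dataclass
class KinaseSubstrateMap:
    """Kinase -> substrate-site table (PhosphoSitePlus/NetworKIN style)."""

    entries: list[KinaseSubstrateEntry]

    def __post_init__(self) -> None:
        triples = set()
        for e in self.entries:
            if e.residue not in PHOSPHO_RESIDUES:
                raise ValidationError(f"substrate residue {e.residue!r} not in S/T/Y")
            if e.position < 1:
                raise ValidationError("substrate position must be 1-based positive")
            t = (e.kinase, e.substrate_accession, e.position)
            if t in triples:
                raise ValidationError(f"duplicate kinase-substrate triple {t}")
            triples.add(t)

    @property
    def kinases(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.kinase not in out:
                out.append(e.kinase)
        return out

    def sites_of(self, kinase: str) -> list[tuple[str, int, str]]:
        return [
            (e.substrate_accession, e.position, e.residue)
            for e in self.entries
            if e.kinase == kinase
        ]


def read_kinase_substrate_table(path: str | Path) -> KinaseSubstrateMap:
    df = _read_tsv(path, required=("kinase", "sub_acc", "position", "residue",
                                   "source"))
    entries = [
        KinaseSubstrateEntry(
            str(r.kinase), str(r.sub_acc), int(r.position), str(r.residue),
            str(r.source),
        )
        for r in df.itertuples(index=False)
    ]
    return KinaseSubstrateMap(entries)


def write_kinase_substrate_table(ksmap: KinaseSubstrateMap,
                                 path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.kinase, e.substrate_accession, e.position, e.residue, e.source)
            for e in ksmap.entries
        ],
        columns=["kinase", "sub_acc", "position", "residue", "source"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Proteome FASTA -> {accession: sequence}.

    The accession is the first whitespace-delimited token of the header,
    matching common proteome FASTA dialects.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"empty or non-FASTA file: {path}")
    out: dict[str, str] = {}
    for rec in records:
        acc = rec.id
        if acc in out:
            raise ValidationError(f"duplicate FASTA accession {acc!r}")
        out[acc] = str(rec.seq).upper()
    return out


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _fmt(x: float) -> str:
    """Serialize a float to 6 significant digits (deterministic outputs)."""
    return format(float(x), ".6g")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV with 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
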