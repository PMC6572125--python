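"""End-to-end orchestration: configuration, simulation, and the full
quant -> differential -> EMT -> KSEA -> motifs run.

All stage parameters live in a single :class:`PipelineConfig` (loadable
from YAML); all randomness flows from its one seed.  Output tables are TSV
with floats serialized to 6 significant digits, so a rerun on unchanged
inputs is byte-identical.  Stage progress is logged to standard error with
stage prefixes.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import differential as diff_mod
from . import emt as emt_mod
from . import motifs as motif_mod
from .ksea import ksea as ksea_test
from .ksea import site_fold_changes
from . import quant as quant_mod
from . import synth
from .errors import PhosphopipeError, ValidationError
from . import io as pio

logger = logging.getLogger("phosphopipe")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class Thresholds:
    localization: float = 0.75
    fold_change: float = 2.0  # linear; calls use log2(fold_change)
    alpha: float = 0.05
    ksea_p: float = 0.05
    ksea_m: int = 5
    motif_p: float = 1e-3
    motif_min_occurrence_ser: int = 20
    motif_min_occurrence_thr: int = 10

    def validate(self) -> None:
        if not (0.0 <= self.localization <= 1.0):
            raise ValidationError(
                f"config: localization threshold {self.localization} outside [0,1]"
            )
        if self.fold_change <= 1.0:
            raise ValidationError("config: fold_change must exceed 1")
        for name in ("alpha", "ksea_p", "motif_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"config: {name}={v} outside (0,1)")
        for name in ("ksea_m", "motif_min_occurrence_ser",
                     "motif_min_occurrence_thr"):
            if getattr(self, name) < 1:
                raise ValidationError(f"config: {name} must be >= 1")


@dataclass
class SimulateParams:
    n_proteins: int = 600
    protein_length: tuple[int, int] = (200, 400)
    n_peptides: int = 10000
    frac_differential: float = 0.10
    effect_size: float = 1.0
    noise_sd: float = 0.25
    n_active_kinases: int = 3
    substrates_per_kinase: int = 10
    n_null_kinases: int = 20
    kinase_shift: float = 1.0
    motif_offset: int = 1
    motif_residue: str = "P"
    motif_fraction: float = 0.4
    frac_low_localization: float = 0.10
    frac_incomplete: float = 0.02
    expression_shift: float = 1.5
    n_background_genes: int = 200


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags of one pipeline run."""

    design: str | None = None
    quant_table: str | None = None
    proteome: str | None = None
    kinase_substrates: str | None = None
    gene_sets: str | None = None
    expression: str | None = None
    outdir: str = "results"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: SimulateParams = field(default_factory=SimulateParams)
    normalize: bool = False
    replicate_mean: bool = False
    seed: int = 0

    def validate(self) -> None:
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        paths = raw.get("paths", {})
        thr = Thresholds(**raw.get("thresholds", {}))
        sim_raw = dict(raw.get("simulate", {}))
        if "protein_length" in sim_raw:
            sim_raw["protein_length"] = tuple(sim_raw["protein_length"])
        sim = SimulateParams(**sim_raw)
        flags = raw.get("flags", {})
        cfg = cls(
            design=paths.get("design"),
            quant_table=paths.get("quant_table"),
            proteome=paths.get("proteome"),
            kinase_substrates=paths.get("kinase_substrates"),
            gene_sets=paths.get("gene_sets"),
            expression=paths.get("expression"),
            outdir=paths.get("outdir", "results"),
            thresholds=thr,
            simulate=sim,
            normalize=bool(flags.get("normalize", False)),
            replicate_mean=bool(flags.get("replicate_mean", False)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def default_paths_under(self, root: str | Path) -> None:
        """Fill unset input paths with conventional names under ``root``."""
        root = Path(root)
        defaults = {
            "design": "design.tsv",
            "quant_table": "quant.tsv",
            "proteome": "proteome.fasta",
            "kinase_substrates": "kinase_substrates.tsv",
            "gene_sets": "gene_sets.gmt",
            "expression": "expression.tsv",
        }
        for attr, name in defaults.items():
            if getattr(self, attr) is None:
                setattr(self, attr, str(root / name))


def _stage(name: str):
    return logging.getLogger(f"phosphopipe.{name}")


def _require(config: PipelineConfig, stage: str, attr: str) -> Path:
    value = getattr(config, attr)
    if value is None or not Path(value).exists():
        raise ValidationError(f"{stage}: {attr.replace('_', ' ')} required")
    return Path(value)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, datadir: str | Path) -> synth.SyntheticTruth:
    """Write a complete synthetic dataset (design, quant table, proteome,
    kinase-substrate table, gene sets, expression matrix, truth JSON)."""
    config.validate()
    log = _stage("simulate")
    datadir = Path(datadir)
    datadir.mkdir(parents=True, exist_ok=True)
    sp = config.simulate
    design = synth.study_design()
    proteome = synth.simulate_proteome(
        sp.n_proteins, sp.protein_length, seed=config.seed
    )
    expt = synth.simulate_phospho_experiment(
        design,
        proteome,
        sp.n_peptides,
        frac_differential=sp.frac_differential,
        effect_size=sp.effect_size,
        noise_sd=sp.noise_sd,
        n_active_kinases=sp.n_active_kinases,
        substrates_per_kinase=sp.substrates_per_kinase,
        n_null_kinases=sp.n_null_kinases,
        kinase_shift=sp.kinase_shift,
        motif_offset=sp.motif_offset,
        motif_residue=sp.motif_residue,
        motif_fraction=sp.motif_fraction,
        frac_low_localization=sp.frac_low_localization,
        frac_incomplete=sp.frac_incomplete,
        seed=config.seed + 1,
    )
    sets = synth.default_gene_set_pair()
    expr = synth.simulate_expression(
        design.samples,
        sets,
        synth.STUDY_POLARITY,
        n_background_genes=sp.n_background_genes,
        shift=sp.expression_shift,
        seed=config.seed + 2,
    )
    expt.truth.emt_polarity = dict(synth.STUDY_POLARITY)

    config.default_paths_under(datadir)
    pio.write_design(design, config.design)
    pio.write_quant_table(expt.records, design, config.quant_table)
    pio.write_fasta(expt.proteome, config.proteome)
    pio.write_kinase_substrate_table(expt.kinase_substrates,
                                     config.kinase_substrates)
    pio.write_gmt(
        [("EPITHELIAL", "synthetic", sets.epithelial),
         ("MESENCHYMAL", "synthetic", sets.mesenchymal)],
        config.gene_sets,
    )
    pio.write_expression_matrix(expr, config.expression)
    expt.truth.to_json(datadir / "truth.json")
    manifest = {
        "seed": config.seed,
        "n_peptides": sp.n_peptides,
        "n_proteins": sp.n_proteins,
        "files": sorted(p.name for p in datadir.iterdir()),
    }
    log.info("wrote synthetic dataset: %s", json.dumps(manifest, sort_keys=True))
    return expt.truth


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute quant -> differential -> emt -> ksea -> motifs and write the
    result bundle plus a summary JSON into ``config.outdir``.

    Returns the summary dictionary.  Any stage validation error surfaces as
    a :class:`PhosphopipeError` with a stage-tagged message.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"parameters": _params_dict(config), "counts": {}}
    counts = summary["counts"]

    # ---- quant ------------------------------------------------------------
    log = _stage("quant")
    design = pio.read_design(_require(config, "quant", "design"))
    records = pio.read_quant_table(_require(config, "quant", "quant_table"),
                                   design)
    counts["peptides_input"] = len(records)
    kept = quant_mod.filter_localization(records, config.thresholds.localization)
    counts["peptides_after_localization"] = len(kept)
    complete = quant_mod.filter_quantified_complete(kept)
    counts["peptides_after_complete"] = len(complete)
    qm = quant_mod.compute_ratios(
        complete, design, normalize=config.normalize,
        provenance=[f"localization>{config.thresholds.localization}"],
    )
    log2_cut = math.log2(config.thresholds.fold_change)
    calls = quant_mod.call_dysregulation(qm, log2_cut)
    counts["peptides_dysregulated_any"] = sum(
        c.is_dysregulated() for c in calls
    )
    proteome = None
    if config.proteome is not None and Path(config.proteome).exists():
        proteome = pio.read_fasta(config.proteome)
    tally = quant_mod.tally_sites(complete, proteome)
    counts["unique_sites"] = tally.n_unique_sites
    counts["sites_by_residue"] = tally.by_residue
    _write_quant_matrix(qm, outdir / "quant_matrix.tsv")
    pio.write_table(quant_mod.calls_table(calls),
                    outdir / "dysregulation_calls.tsv")
    (outdir / "site_tallies.json").write_text(
        json.dumps(asdict(tally), indent=2, sort_keys=True)
    )
    log.info("%d/%d peptides survive filters", len(complete), len(records))

    # ---- differential -----------------------------------------------------
    log = _stage("differential")
    dres = diff_mod.differential_test(
        qm, design, alpha=config.thresholds.alpha,
        replicate_mean=config.replicate_mean,
    )
    signature = dres.loc[dres["in_signature"], "peptide_id"].tolist()
    counts["signature_peptides"] = len(signature)
    by_id = {r.peptide_id: r for r in complete}
    counts["signature_proteins"] = len(
        {by_id[p].accession for p in signature}
    )
    pio.write_table(dres, outdir / "differential.tsv")
    pio.write_table(
        pd.DataFrame(
            {"peptide_id": signature,
             "accession": [by_id[p].accession for p in signature]}
        ),
        outdir / "signature_peptides.tsv",
    )
    if len(signature) >= 2:
        cres = diff_mod.cluster(qm.data, rows=signature)
        cols = ["%s_r%d" % c for c in cres.z_matrix.columns]
        cres.z_matrix.columns = cols
        (outdir / "cluster_columns.nwk").write_text(cres.newick("columns") + "\n")
        (outdir / "cluster_rows.nwk").write_text(cres.newick("rows") + "\n")
    log.info("signature: %d peptides", len(signature))

    # ---- emt --------------------------------------------------------------
    log = _stage("emt")
    sets = pio.gene_set_pair_from_gmt(_require(config, "emt", "gene_sets"))
    expr = pio.read_expression_matrix(_require(config, "emt", "expression"))
    emt_results = emt_mod.emt_score_all(expr, sets)
    pio.write_table(emt_mod.emt_table(emt_results), outdir / "emt_scores.tsv")
    counts["emt_mesenchymal_like"] = sum(r.score > 0 for r in emt_results)
    log.info("scored %d samples", len(emt_results))

    # ---- ksea -------------------------------------------------------------
    log = _stage("ksea")
    ksmap = pio.read_kinase_substrate_table(
        _require(config, "ksea", "kinase_substrates")
    )
    site_fcs = site_fold_changes(qm, complete, design)
    kres = ksea_test(
        site_fcs, ksmap,
        p_cutoff=config.thresholds.ksea_p, m_cutoff=config.thresholds.ksea_m,
    )
    counts["kinases_tested"] = len(kres)
    counts["kinases_reportable"] = int(kres["reportable"].sum())
    pio.write_table(kres, outdir / "ksea.tsv")
    log.info("%d kinases reportable", counts["kinases_reportable"])

    # ---- motifs -----------------------------------------------------------
    log = _stage("motifs")
    if proteome is None:
        raise ValidationError("motifs: proteome required")
    sig_sites = [
        k for p in signature for k in by_id[p].site_keys()
    ]
    motif_report: dict[str, Any] = {}
    for central, min_occ in (
        ("s", config.thresholds.motif_min_occurrence_ser),
        ("t", config.thresholds.motif_min_occurrence_thr),
    ):
        fg = motif_mod.extract_windows(sig_sites, proteome, central)
        bg = motif_mod.background_windows(proteome, central)
        found = motif_mod.find_motifs(
            fg, bg, p_threshold=config.thresholds.motif_p,
            min_occurrence=min_occ, central=central,
        ) if fg else []
        motif_report[central] = [_motif_dict(m) for m in found]
        rows = [
            (m.pattern, m.support, m.fold_enrichment,
             json.dumps([s.p for s in m.steps]))
            for m in found
        ]
        pio.write_table(
            pd.DataFrame(rows, columns=["pattern", "support",
                                        "fold_enrichment", "step_p"]),
            outdir / f"motifs_{'ser' if central == 's' else 'thr'}.tsv",
        )
        counts[f"motifs_{central}"] = len(found)
    (outdir / "motifs.json").write_text(
        json.dumps(motif_report, indent=2, sort_keys=True)
    )
    log.info("motifs: %d serine, %d threonine",
             counts["motifs_s"], counts["motifs_t"])

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return summary


def _motif_dict(m: motif_mod.MotifResult) -> dict[str, Any]:
    return {
        "pattern": m.pattern,
        "support": m.support,
        "fold_enrichment": round(m.fold_enrichment, 6),
        "steps": [
            {"offset": s.offset, "residue": s.residue, "k": s.k, "n": s.n,
             "p_bg": round(s.p_bg, 6), "p": float(f"{s.p:.6g}")}
            for s in m.steps
        ],
    }


def _params_dict(config: PipelineConfig) -> dict[str, Any]:
    return {
        "thresholds": asdict(config.thresholds),
        "normalize": config.normalize,
        "replicate_mean": config.replicate_mean,
        "seed": config.seed,
    }


def _write_quant_matrix(qm: quant_mod.QuantMatrix, path: Path) -> None:
    df = qm.data.copy()
    df.columns = ["%s_r%d" % c for c in df.columns]
    pio.write_table(df.reset_index(), path)
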