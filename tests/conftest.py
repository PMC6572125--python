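"""Shared fixtures: the 10-plex two-replicate study design and small
hand-built phosphopeptide records."""

import pytest

from phosphopipe import PhosphoPeptideRecord, SampleDesign, study_design
from phosphopipe.io import DesignEntry


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    """7 samples (1 control, 2 luminal, 1 basal, 3 non-type), 2 replicates."""
    return study_design()


@pytest.fixture
def tiny_design() -> SampleDesign:
    """Control + two non-control samples, 2 replicates — small enough for
    hand-computable ratios."""
    entries = [
        DesignEntry("c1", "CTRL", "control", r) for r in (1, 2)
    ] + [
        DesignEntry("c2", "LUM", "luminal", r) for r in (1, 2)
    ] + [
        DesignEntry("c3", "NT", "non_type", r) for r in (1, 2)
    ]
    return SampleDesign(entries)


def make_record(design: SampleDesign, pid: str, intensities=None, *,
                accession="P1", positions=(4,), residues=("S",),
                probs=(0.9,), sequence="MKTSAPLE") -> PhosphoPeptideRecord:
    """Record with intensity 100 everywhere unless overridden via a
    {(channel, replicate): value} mapping."""
    ints = {pair: 100.0 for pair in design.channel_replicate_pairs()}
    if intensities:
        ints.update(intensities)
    rec = PhosphoPeptideRecord(
        peptide_id=pid,
        sequence=sequence,
        accession=accession,
        positions=list(positions),
        residues=list(residues),
        localization_probs=list(probs),
        intensities=ints,
    )
    rec.quantified_complete = all(
        ints.get(p, 0.0) > 0 for p in design.channel_replicate_pairs()
    )
    return rec


@pytest.fixture
def record_factory():
    return make_record
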