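"""Iterative phosphorylation-motif discovery (motif-x style).

A sequence window is the +/-7-residue context of a phosphosite (a 15-mer
with the central residue in lowercase s/t/y and ``_`` padding where the
protein terminus truncates the window).  Motifs are grown greedily: at each
step the binomial upper tail P(X >= k) is computed for every
(offset, residue) pair — k foreground matches out of n foreground windows,
against the pair's current background frequency — and the most significant
pair is fixed if its p is below the significance threshold (default 1e-3)
and its foreground count meets the minimum occurrence (default 20 for
serine-centered runs, 10 for threonine).  Both sets are then reduced to the
matching windows and the step repeats.  When no pair qualifies the motif is
emitted, its matches are removed from the original foreground, and the
search restarts for further motifs.

The padding character never enters an enrichment test, and an
(offset, residue) pair absent from the background cannot be tested and is
skipped.  Ties in p are broken by larger foreground count, then smaller
|offset|, then residue alphabetical order, so output is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io import AMINO_ACIDS
from .quant import SiteKey

WINDOW_FLANK = 7
WINDOW_LEN = 2 * WINDOW_FLANK + 1
PAD = "_"


def extract_windows(
    site_keys: Sequence[SiteKey],
    proteome: Mapping[str, str],
    center_class: str | None = None,
) -> list[str]:
    """Extract the 15-mer window around each site, ``_``-padded at termini.

    ``center_class`` (``"s"``/``"t"``/``"y"``) restricts output to sites of
    that residue class.  The site residue must match the proteome sequence.
    """
    missing = sorted({k.accession for k in site_keys if k.accession not in proteome})
    if missing:
        raise ValidationError(f"accessions absent from proteome: {missing[:10]}")
    windows = []
    for k in site_keys:
        seq = proteome[k.accession]
        if not (1 <= k.position <= len(seq)):
            raise ValidationError(f"position {k.position} outside {k.accession}")
        if seq[k.position - 1] != k.residue:
            raise ValidationError(
                f"residue mismatch at {k.accession}:{k.position} "
                f"(expected {k.residue}, proteome has {seq[k.position - 1]})"
            )
        if center_class is not None and k.residue.lower() != center_class:
            continue
        windows.append(_window_at(seq, k.position))
    return windows


def _window_at(seq: str, position: int) -> str:
    i = position - 1
    left = seq[max(0, i - WINDOW_FLANK):i]
    right = seq[i + 1:i + 1 + WINDOW_FLANK]
    return (
        PAD * (WINDOW_FLANK - len(left))
        + left
        + seq[i].lower()
        + right
        + PAD * (WINDOW_FLANK - len(right))
    )


def background_windows(proteome: Mapping[str, str], central: str) -> list[str]:
    """Windows around every occurrence of the central residue class in the
    proteome — the enrichment background."""
    central_upper = central.upper()
    out = []
    for acc in proteome:
        seq = proteome[acc]
        for i, aa in enumerate(seq):
            if aa == central_upper:
                out.append(_window_at(seq, i + 1))
    return out


def binomial_enrichment(k: int, n: int, p_bg: float) -> float:
    """Exact binomial upper tail P(X >= k) for k successes in n trials."""
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p_bg < 1.0):
        raise ValidationError(f"background frequency must be in (0,1), got {p_bg}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p_bg))


@dataclass(frozen=True)
class MotifStep:
    offset: int  # in [-7, +7], never 0
    residue: str
    k: int  # foreground matches at fixing time
    n: int  # foreground size at fixing time
    p_bg: float  # background frequency at fixing time
    p: float  # binomial upper tail


@dataclass
class MotifResult:
    """A fixed-position motif, e.g. ``xxxxxxxsPxxxxxx``.

    ``support`` counts the windows of the *original* foreground matching the
    full pattern; ``fold_enrichment`` is the ratio of the foreground match
    fraction to the background match fraction, both over the original sets.
    """

    pattern: str
    steps: list[MotifStep]
    support: int
    fold_enrichment: float

    def matches(self, window: str) -> bool:
        return _matches(self.pattern, window)


def _matches(pattern: str, window: str) -> bool:
    return all(p == "x" or p == w for p, w in zip(pattern, window))


def _pattern_from(central: str, fixed: dict[int, str]) -> str:
    chars = ["x"] * WINDOW_LEN
    chars[WINDOW_FLANK] = central.lower()
    for off, res in fixed.items():
        chars[WINDOW_FLANK + off] = res
    return "".join(chars)


def _to_array(windows: Sequence[str]) -> np.ndarray:
    """Windows as a (n, 15) uint8 character matrix for fast counting."""
    if not windows:
        return np.empty((0, WINDOW_LEN), dtype=np.uint8)
    return np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(
        len(windows), WINDOW_LEN
    )


def _pattern_mask(arr: np.ndarray, pattern: str) -> np.ndarray:
    mask = np.ones(arr.shape[0], dtype=bool)
    for i, ch in enumerate(pattern):
        if ch != "x" and i != WINDOW_FLANK:
            mask &= arr[:, i] == ord(ch)
    return mask


def find_motifs(
    foreground: Sequence[str],
    background: Sequence[str],
    p_threshold: float = 1e-3,
    min_occurrence: int = 20,
    central: str = "s",
) -> list[MotifResult]:
    """Greedy iterative motif discovery over 15-mer windows (see module
    docstring for the algorithm)."""
    if central not in ("s", "t", "y"):
        raise ValidationError("central residue class must be 's', 't' or 'y'")
    if not (0.0 < p_threshold < 1.0):
        raise ValidationError("p threshold must be in (0,1)")
    if min_occurrence < 1:
        raise ValidationError("minimum occurrence must be >= 1")
    for name, ws in (("foreground", foreground), ("background", background)):
        for w in ws:
            if len(w) != WINDOW_LEN or w[WINDOW_FLANK] != central:
                raise ValidationError(
                    f"{name} window {w!r} is not a {WINDOW_LEN}-mer centered "
                    f"on {central!r}"
                )
    if not foreground:
        return []
    if not background:
        raise ValidationError("empty background")
    if len(background) < len(foreground):
        warnings.warn(
            "background smaller than foreground; enrichment estimates will "
            "be unstable",
            stacklevel=2,
        )

    original_fg = _to_array(foreground)
    original_bg = _to_array(background)
    remaining_fg = original_fg.copy()
    motifs: list[MotifResult] = []

    while True:
        fg = remaining_fg
        bg = original_bg
        fixed: dict[int, str] = {}
        steps: list[MotifStep] = []
        while fg.shape[0]:
            best = None  # (p, -k, |offset|, residue) for lexicographic ties
            n_fg, n_bg = fg.shape[0], bg.shape[0]
            for offset in range(-WINDOW_FLANK, WINDOW_FLANK + 1):
                if offset == 0 or offset in fixed:
                    continue
                i = WINDOW_FLANK + offset
                counts_fg = np.bincount(fg[:, i], minlength=128)
                counts_bg = np.bincount(bg[:, i], minlength=128)
                for residue in AMINO_ACIDS:
                    k = int(counts_fg[ord(residue)])
                    if k < min_occurrence:
                        continue
                    kb = int(counts_bg[ord(residue)])
                    if kb == 0 or kb == n_bg:
                        continue  # untestable frequency (0 or 1); skipped
                    p_bg = kb / n_bg
                    p = binomial_enrichment(k, n_fg, p_bg)
                    if p >= p_threshold:
                        continue
                    cand = (p, -k, abs(offset), residue, offset, p_bg, k)
                    if best is None or cand < best:
                        best = cand
            if best is None:
                break
            p, _negk, _aoff, residue, offset, p_bg, k = best
            steps.append(MotifStep(offset, residue, k, n_fg, p_bg, p))
            fixed[offset] = residue
            i = WINDOW_FLANK + offset
            fg = fg[fg[:, i] == ord(residue)]
            bg = bg[bg[:, i] == ord(residue)]
        if not steps:
            break
        pattern = _pattern_from(central, fixed)
        fg_mask = _pattern_mask(original_fg, pattern)
        support = int(fg_mask.sum())
        bg_matches = int(_pattern_mask(original_bg, pattern).sum())
        if support < min_occurrence or bg_matches == 0:
            break
        fe = (support / original_fg.shape[0]) / (bg_matches / original_bg.shape[0])
        motifs.append(MotifResult(pattern, steps, support, fe))
        remaining_fg = remaining_fg[~_pattern_mask(remaining_fg, pattern)]
        if remaining_fg.shape[0] == 0:
            break
    return motifs


def serine_run(
    foreground: Sequence[str],
    background: Sequence[str],
    p_threshold: float = 1e-3,
    min_occurrence: int = 20,
) -> list[MotifResult]:
    """Motif search over serine-centered windows (minimum occurrence 20)."""
    return find_motifs(foreground, background, p_threshold, min_occurrence, "s")


def threonine_run(
    foreground: Sequence[str],
    background: Sequence[str],
    p_threshold: float = 1e-3,
    min_occurrence: int = 10,
) -> list[MotifResult]:
    """Motif search over threonine-centered windows (minimum occurrence 10)."""
    return find_motifs(foreground, background, p_threshold, min_occurrence, "t")
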