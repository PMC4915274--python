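"""Synthetic proteome generation with planted disordered segments.

The generator emulates a UniProt reference-proteome FASTA file at desk
scale: mixed Swiss-Prot/TrEMBL entries, protein-existence qualifiers 1-5, a
controllable fraction of sequences carrying ambiguous residue codes, and
planted low-hydropathy / charge-enriched segments that the built-in
charge-hydropathy predictor scores as disordered.  A truth table records the
coordinates of every planted segment so detection can be benchmarked.

Background residues are drawn from average Swiss-Prot amino-acid
frequencies, which puts typical windows near the folded side of the
charge-hydropathy boundary; planted segments draw a configurable fraction of
their residues from the charged set {D,E,K,R} and fill the remainder with
polar, disorder-promoting residues, which pushes their windows well across
the boundary regardless of how the positive and negative charges cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sequence_io import ProteinRecord, write_fasta

__all__ = ["PlantedSegmentRule", "SyntheticProteomeSpec", "generate_synthetic_proteome"]

# Average Swiss-Prot residue frequencies (percent), used for background draws.
_BACKGROUND_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}

_CHARGED = "DEKR"
_AMBIGUOUS = "BJOUXZ"

# Normalized Kyte-Doolittle hydropathy of the polar fill candidates.
_FILL_HYDROPATHY = {"Q": 0.1111, "N": 0.1111, "P": 0.3222, "S": 0.4111,
                    "T": 0.4222, "G": 0.4556}


@dataclass(frozen=True)
class PlantedSegmentRule:
    """Composition rule for one planted disordered segment.

    Attributes
    ----------
    length : int
        Segment length in residues.
    charge_enrichment : float
        Fraction of segment residues drawn uniformly from {D,E,K,R}.
    hydropathy_depletion : float
        Upper bound on the normalized Kyte-Doolittle hydropathy of the
        non-charged fill residues; the fill alphabet is the subset of
        {Q,N,P,S,T,G} at or below this bound.
    probability : float
        Per-protein probability that this rule plants a segment.
    """

    length: int
    charge_enrichment: float = 0.65
    hydropathy_depletion: float = 0.46
    probability: float = 0.6

    def fill_alphabet(self) -> list[str]:
        return [aa for aa, h in _FILL_HYDROPATHY.items() if h <= self.hydropathy_depletion]


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Parameters of one synthetic proteome draw.

    Defaults emulate a small reference-proteome slice: 50 proteins of
    60-400 residues, a 10% ineligible fraction (comparable to the share of
    partially defined sequences in a real reference proteome), PE levels
    dominated by experimental evidence, and one planted disordered segment
    rule applied to roughly half the eligible proteins.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (60, 400)
    fraction_ineligible: float = 0.1
    pe_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.22, 4: 0.13, 5: 0.05})
    planted_disorder: tuple[PlantedSegmentRule, ...] = (PlantedSegmentRule(length=30),)
    fraction_trembl: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ConfigurationError("n_proteins must be non-negative")
        if not 0.0 <= self.fraction_ineligible <= 1.0:
            raise ConfigurationError("fraction_ineligible must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid length_range {self.length_range}")
        weights = list(self.pe_distribution.values())
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigurationError("PE weights must be non-negative and not all zero")
        if not set(self.pe_distribution) <= {1, 2, 3, 4, 5}:
            raise ConfigurationError("PE qualifiers must be in 1-5")
        for rule in self.planted_disorder:
            if rule.length > lo:
                raise ConfigurationError(
                    f"planted segment of length {rule.length} cannot fit the "
                    f"shortest protein (length_range minimum {lo})")
            if not rule.fill_alphabet():
                raise ConfigurationError(
                    f"hydropathy_depletion {rule.hydropathy_depletion} admits no fill residues")


def _draw_background(rng: np.random.Generator, n: int) -> np.ndarray:
    letters = np.array(list(_BACKGROUND_FREQ))
    p = np.array(list(_BACKGROUND_FREQ.values()))
    return rng.choice(letters, size=n, p=p / p.sum())


def _draw_segment(rng: np.random.Generator, rule: PlantedSegmentRule) -> str:
    fill = rule.fill_alphabet()
    charged = rng.random(rule.length) < rule.charge_enrichment
    out = [rng.choice(list(_CHARGED)) if c else rng.choice(fill) for c in charged]
    return "".join(out)


def _place_segments(rng: np.random.Generator, length: int,
                    rules: tuple[PlantedSegmentRule, ...]) -> list[tuple[int, int, PlantedSegmentRule]]:
    """Choose non-overlapping 0-based [start, end) slots for the applicable rules."""
    taken: list[tuple[int, int]] = []
    placed = []
    for rule in rules:
        if rng.random() >= rule.probability:
            continue
        for _ in range(25):  # rejection sampling against overlap
            start = int(rng.integers(0, length - rule.length + 1))
            end = start + rule.length
            if all(end <= s or start >= e for s, e in taken):
                taken.append((start, end))
                placed.append((start, end, rule))
                break
    return placed


def generate_synthetic_proteome(spec: SyntheticProteomeSpec) -> tuple[str, pd.DataFrame]:
    """Generate a synthetic proteome FASTA and its planted-segment truth table.

    Returns
    -------
    fasta_text : str
        UniProt-dialect FASTA; deterministic for a given spec and seed.
        Exactly ``round(n_proteins * fraction_ineligible)`` sequences contain
        at least one ambiguous residue code from {B,J,O,U,X,Z}.
    truth : pandas.DataFrame
        One row per planted segment with columns ``accession``, ``start``,
        ``end`` (1-based inclusive), ``length`` and ``charge_enrichment``.
        Segments are planted only in eligible sequences, since ineligible
        proteins never reach the predictors.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    n_bad = int(round(n * spec.fraction_ineligible))
    bad_idx = set(rng.choice(n, size=n_bad, replace=False).tolist()) if n_bad else set()

    pe_levels = np.array(list(spec.pe_distribution))
    pe_w = np.array(list(spec.pe_distribution.values()), dtype=float)
    pe_w /= pe_w.sum()

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for i in range(n):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _draw_background(rng, length)
        accession = f"SYN{i + 1:05d}"
        if i not in bad_idx:
            for start, end, rule in _place_segments(rng, length, spec.planted_disorder):
                seq[start:end] = list(_draw_segment(rng, rule))
                truth_rows.append({"accession": accession, "start": start + 1,
                                   "end": end, "length": rule.length,
                                   "charge_enrichment": rule.charge_enrichment})
        else:
            n_amb = int(rng.integers(1, 4))
            pos = rng.choice(length, size=min(n_amb, length), replace=False)
            for p in pos:
                seq[p] = rng.choice(list(_AMBIGUOUS))
        source_db = "trembl" if rng.random() < spec.fraction_trembl else "swissprot"
        pe = int(rng.choice(pe_levels, p=pe_w))
        records.append(ProteinRecord(
            accession=accession, source_db=source_db,
            name=f"{accession}_SYNTH", pe_qualifier=pe, sequence="".join(seq)))

    truth = pd.DataFrame(truth_rows,
                         columns=["accession", "start", "end", "length", "charge_enrichment"])
    return write_fasta(records), truth
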