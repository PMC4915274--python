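"""Per-residue disorder score tracks.

Four score tracks are attached to every protein, following the common
four-method annotation layout: IUPred long mode (I) plus the three DisEMBL
neural-network outputs Coils (C), Hotloops (H) and REM465 (R).  This module
provides parsers for the two tools' text outputs and a built-in
charge-hydropathy predictor so the full pipeline can run without external
binaries.

The built-in predictor is a windowed FoldIndex-style classifier on the
Uversky charge-hydropathy plane.  It is physics-motivated and clearly
labelled: it is not equivalent to IUPred or DisEMBL, and the provenance of
every track is recorded in the track itself and in pipeline outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .errors import AlignmentError, PredictorParseError, SequenceError

__all__ = [
    "PredictorTrack",
    "ThresholdConfig",
    "DEFAULT_THRESHOLDS",
    "KD_HYDROPATHY",
    "METHOD_IDS",
    "parse_iupred_long",
    "parse_disembl_scores",
    "predict_charge_hydropathy",
    "builtin_track_set",
]

#: Canonical method order used for agreement IDs and table columns.
METHOD_IDS = ("I", "C", "H", "R")

#: Published default decision thresholds: IUPred 0.5; DisEMBL "random
#: expectation" defaults Coils 0.43, Hotloops 0.086, REM465 0.5.
DEFAULT_THRESHOLDS = {"I": 0.5, "C": 0.43, "H": 0.086, "R": 0.5}

#: Kyte-Doolittle hydropathy scale.
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Per-residue charge: Asp/Glu negative, Lys/Arg positive, His neutral.
RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

#: Default built-in windows for the four track slots; distinct smoothing
#: scales stand in for the method diversity of a real multi-predictor run.
DEFAULT_BUILTIN_WINDOWS = {"I": 21, "C": 9, "H": 5, "R": 41}


@dataclass(frozen=True)
class PredictorTrack:
    """Per-residue disorder scores for one method over one protein."""

    method_id: str
    scores: np.ndarray
    threshold: float
    source: str = "external"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1:
            raise PredictorParseError("scores must be one-dimensional")
        if scores.size and not np.all(np.isfinite(scores)):
            raise PredictorParseError(f"non-finite score in {self.method_id} track")
        if not np.isfinite(self.threshold):
            raise PredictorParseError("threshold must be finite")

    @property
    def protein_length(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-method threshold overrides and the tie convention.

    ``tie_disordered=True`` means a score exactly at threshold is called
    disordered (score >= threshold); set ``False`` for a strict comparison.
    """

    overrides: dict[str, float] = field(default_factory=dict)
    tie_disordered: bool = True

    def threshold_for(self, track: PredictorTrack) -> float:
        t = self.overrides.get(track.method_id, track.threshold)
        if not np.isfinite(t):
            raise PredictorParseError(f"threshold for {track.method_id} must be finite")
        return float(t)


def parse_iupred_long(text: str | TextIO, expected_length: int,
                      threshold: float | None = None) -> PredictorTrack:
    """Parse IUPred long-mode output into an I track.

    The format is ``#``-prefixed comment lines followed by whitespace-
    separated ``position residue score`` lines with 1-based ascending
    positions.  A position gap, out-of-order position, or residue-count
    mismatch against *expected_length* is rejected so that a truncated
    track can never be silently paired with a full-length sequence.
    """
    if not isinstance(text, str):
        text = text.read()
    scores: list[float] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise PredictorParseError(
                f"IUPred line {lineno}: expected 'position residue score', got {line!r}")
        try:
            pos, score = int(parts[0]), float(parts[2])
        except ValueError as exc:
            raise PredictorParseError(f"IUPred line {lineno}: {exc}") from exc
        if pos != len(scores) + 1:
            raise PredictorParseError(
                f"IUPred line {lineno}: position {pos} out of order "
                f"(expected {len(scores) + 1})")
        scores.append(score)
    if len(scores) != expected_length:
        raise AlignmentError(
            f"IUPred track has {len(scores)} residues, sequence has {expected_length}")
    return PredictorTrack("I", np.array(scores),
                          DEFAULT_THRESHOLDS["I"] if threshold is None else threshold,
                          source="iupred")


def parse_disembl_scores(text: str | TextIO, expected_length: int,
                         thresholds: dict[str, float] | None = None
                         ) -> tuple[PredictorTrack, PredictorTrack, PredictorTrack]:
    """Parse DisEMBL per-residue scores output into (C, H, R) tracks.

    Each record carries the residue letter and three scores in the tool's
    COILS, REM465, HOTLOOPS column order; the returned tuple is in the
    canonical C, H, R method order.  Comment lines starting with ``#`` are
    tolerated.
    """
    if not isinstance(text, str):
        text = text.read()
    thresholds = thresholds or {}
    coils: list[float] = []
    rem465: list[float] = []
    hotloops: list[float] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PredictorParseError(
                f"DisEMBL line {lineno}: expected 'residue coils rem465 hotloops', "
                f"got {line!r}")
        try:
            c, r, h = (float(parts[1]), float(parts[2]), float(parts[3]))
        except ValueError as exc:
            raise PredictorParseError(f"DisEMBL line {lineno}: {exc}") from exc
        coils.append(c)
        rem465.append(r)
        hotloops.append(h)
    if len(coils) != expected_length:
        raise AlignmentError(
            f"DisEMBL track has {len(coils)} residues, sequence has {expected_length}")

    def _mk(method_id: str, vals: list[float]) -> PredictorTrack:
        return PredictorTrack(method_id, np.array(vals),
                              thresholds.get(method_id, DEFAULT_THRESHOLDS[method_id]),
                              source="disembl")

    return _mk("C", coils), _mk("H", hotloops), _mk("R", rem465)


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over the window centered at each position, clipped at the termini."""
    n = values.size
    half = window // 2
    cums = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cums[hi] - cums[lo]) / (hi - lo)


def predict_charge_hydropathy(sequence: str, window: int = 21,
                              boundary: tuple[float, float] = (2.785, 1.151),
                              method_id: str = "I") -> PredictorTrack:
    """Built-in windowed charge-hydropathy disorder predictor.

    For each residue, over the *window* centered on it (clipped at the
    termini), the mean normalized Kyte-Doolittle hydropathy <H> (per residue
    ``(KD + 4.5) / 9``) and the mean net charge per residue <q> (D,E -> -1;
    K,R -> +1; else 0) are computed, and the FoldIndex-style margin

        FI = slope * <H> - |<q>| - intercept

    measures the distance from the Uversky charge-hydropathy boundary
    (default slope 2.785, intercept 1.151).  The disorder score is
    ``0.5 - FI`` clipped to [0, 1] with decision threshold 0.5, so FI < 0
    is called disordered.

    Raises
    ------
    SequenceError
        If the sequence contains anything but the 20 standard residues.
    """
    if window < 1 or window % 2 == 0:
        raise SequenceError(f"window must be a positive odd integer, got {window}")
    bad = set(sequence) - set(KD_HYDROPATHY)
    if bad:
        raise SequenceError(
            f"sequence contains ineligible residues {sorted(bad)}; screen first")
    h = np.array([(KD_HYDROPATHY[a] + 4.5) / 9.0 for a in sequence])
    q = np.array([RESIDUE_CHARGE.get(a, 0.0) for a in sequence])
    slope, intercept = boundary
    fold_index = slope * _windowed_mean(h, window) - np.abs(_windowed_mean(q, window)) - intercept
    scores = np.clip(0.5 - fold_index, 0.0, 1.0)
    return PredictorTrack(method_id, scores, 0.5, source="builtin")


def builtin_track_set(sequence: str,
                      windows: dict[str, int] | None = None,
                      boundary: tuple[float, float] = (2.785, 1.151)
                      ) -> dict[str, PredictorTrack]:
    """Fill all four track slots with built-in predictions at distinct windows."""
    windows = windows or DEFAULT_BUILTIN_WINDOWS
    return {m: predict_charge_hydropathy(sequence, windows[m], boundary, method_id=m)
            for m in METHOD_IDS}
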