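"""Binary disorder calls and multi-predictor residue statistics.

Each residue gets a disorder classification count (DCC: the number of the
four methods calling it disordered, 0-4) and an agreement ID: ``"O"`` when
all four methods agree the residue is ordered, ``"NA"`` when only a single
method calls it disordered (no agreement), and otherwise the letters of the
agreeing methods concatenated in the canonical I, C, H, R order (``"ICHR"``
when all four agree on disorder).  Consensus calls use the strict all-four
rule: a residue is consensus-disordered iff DCC = 4 and consensus-ordered
iff DCC = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import AlignmentError, DisorderDBError
from .predictors import METHOD_IDS, PredictorTrack, ThresholdConfig
from .sequence_io import ProteinRecord

__all__ = [
    "ResidueAnnotation",
    "ConsensusCall",
    "binarize_track",
    "agreement_id",
    "annotate_residues",
    "annotation_frame",
    "consensus_calls",
    "percent_disorder",
]


class ConsensusCall(str, Enum):
    DISORDERED = "disordered"
    ORDERED = "ordered"
    NO_CONSENSUS = "no_consensus"


@dataclass(frozen=True)
class ResidueAnnotation:
    """One row of the residue-level disorder table."""

    position: int           # 1-based
    residue: str
    score_I: float
    score_C: float
    score_H: float
    score_R: float
    call_I: bool
    call_C: bool
    call_H: bool
    call_R: bool
    dcc: int
    agreement_id: str


def binarize_track(track: PredictorTrack,
                   config: ThresholdConfig | None = None) -> np.ndarray:
    """Convert a score track to boolean disorder calls.

    With the default tie convention a score equal to the threshold counts as
    disordered.
    """
    config = config or ThresholdConfig()
    t = config.threshold_for(track)
    if config.tie_disordered:
        return track.scores >= t
    return track.scores > t


def agreement_id(calls: tuple[bool, bool, bool, bool]) -> str:
    """Agreement ID for one residue's four calls, in canonical I,C,H,R order."""
    dcc = sum(calls)
    if dcc == 0:
        return "O"
    if dcc == 1:
        return "NA"
    return "".join(m for m, c in zip(METHOD_IDS, calls) if c)


def _check_lengths(n: int, tracks: dict) -> None:
    for m, arr in tracks.items():
        if len(arr) != n:
            raise AlignmentError(
                f"track {m} has {len(arr)} values for a protein of length {n}")


def annotation_frame(protein: ProteinRecord,
                     calls: dict[str, np.ndarray],
                     scores: dict[str, np.ndarray]) -> pd.DataFrame:
    """Vectorized residue annotation table for one protein.

    Columns: position, residue, score_I/C/H/R, call_I/C/H/R, dcc,
    agreement_id.  Raises :class:`AlignmentError` when any call or score
    list does not match the protein length.
    """
    n = protein.length
    _check_lengths(n, calls)
    _check_lengths(n, scores)
    call_mat = np.column_stack([np.asarray(calls[m], dtype=bool) for m in METHOD_IDS])
    dcc = call_mat.sum(axis=1)

    # Map each of the 16 call patterns to its agreement ID once.
    pattern = call_mat @ (1 << np.arange(4))
    lut = np.array([agreement_id(tuple(bool(k & (1 << b)) for b in range(4)))
                    for k in range(16)])
    frame = pd.DataFrame({
        "position": np.arange(1, n + 1),
        "residue": list(protein.sequence),
    })
    for m in METHOD_IDS:
        frame[f"score_{m}"] = np.asarray(scores[m], dtype=float)
    for m, col in zip(METHOD_IDS, call_mat.T):
        frame[f"call_{m}"] = col
    frame["dcc"] = dcc
    frame["agreement_id"] = lut[pattern]
    return frame


def annotate_residues(protein: ProteinRecord,
                      calls: dict[str, np.ndarray],
                      scores: dict[str, np.ndarray]) -> list[ResidueAnnotation]:
    """Residue annotations as typed objects (see :func:`annotation_frame`)."""
    frame = annotation_frame(protein, calls, scores)
    return [ResidueAnnotation(
        position=int(r.position), residue=r.residue,
        score_I=r.score_I, score_C=r.score_C, score_H=r.score_H, score_R=r.score_R,
        call_I=bool(r.call_I), call_C=bool(r.call_C),
        call_H=bool(r.call_H), call_R=bool(r.call_R),
        dcc=int(r.dcc), agreement_id=r.agreement_id)
        for r in frame.itertuples(index=False)]


def consensus_calls(dcc: np.ndarray) -> list[ConsensusCall]:
    """All-four consensus per residue: disordered iff DCC=4, ordered iff DCC=0."""
    out = []
    for d in np.asarray(dcc):
        if d == 4:
            out.append(ConsensusCall.DISORDERED)
        elif d == 0:
            out.append(ConsensusCall.ORDERED)
        else:
            out.append(ConsensusCall.NO_CONSENSUS)
    return out


def percent_disorder(calls: np.ndarray) -> float:
    """Disorder content: percentage of residues called disordered."""
    calls = np.asarray(calls, dtype=bool)
    if calls.size == 0:
        raise DisorderDBError("percent disorder is undefined for an empty call list")
    return 100.0 * float(calls.sum()) / calls.size
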