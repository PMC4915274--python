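"""Continuous-disorder (CD) regions and derived metrics.

A CD region is a maximal run of consecutively disordered residues of length
at least two -- the theoretical minimum for "continuous" disorder, so an
isolated disordered residue never forms a region.  Per method (and for the
all-four consensus track) the region list, the longest region length (CD_L)
and its percentage of the protein length (LCPL = 100 * CD_L / length) are
recorded.  A protein with no CD under any method is omitted from CD outputs
entirely; when only some methods find CD, the doubting methods carry an
explicit N/A sentinel rather than an absent row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MIN_CD_LENGTH", "CDRegion", "MethodCD", "CDSummary",
           "extract_cd_regions", "summarize_cd"]

#: Theoretical minimum length of a continuous-disorder region.
MIN_CD_LENGTH = 2


@dataclass(frozen=True)
class CDRegion:
    """Maximal run of disordered residues; 1-based inclusive coordinates."""

    method_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MethodCD:
    """CD information for one method over one protein.

    ``cd_l`` and ``lcpl`` are ``None`` (the N/A sentinel) when the method
    finds no region.
    """

    method_id: str
    regions: tuple[CDRegion, ...]
    cd_l: int | None
    lcpl: float | None

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class CDSummary:
    """Per-method CD summaries for one protein; ``consensus`` key included."""

    protein_length: int
    methods: dict[str, MethodCD]

    @property
    def has_cd(self) -> bool:
        """True when at least one method finds a CD region."""
        return any(m.regions for m in self.methods.values())


def extract_cd_regions(calls: np.ndarray, method_id: str) -> list[CDRegion]:
    """All maximal runs of consecutive disordered calls with length >= 2.

    Regions are returned sorted by start and are pairwise disjoint and
    non-adjacent (adjacency would contradict maximality).
    """
    calls = np.asarray(calls, dtype=bool)
    if calls.size == 0:
        return []
    padded = np.concatenate(([False], calls, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)    # 0-based run starts
    ends = np.flatnonzero(edges == -1)     # 0-based exclusive ends
    return [CDRegion(method_id, int(s) + 1, int(e))
            for s, e in zip(starts, ends) if e - s >= MIN_CD_LENGTH]


def summarize_cd(region_lists: dict[str, list[CDRegion]],
                 protein_length: int) -> CDSummary:
    """Per-method CD_L and LCPL over extracted region lists.

    ``lcpl`` lies in (0, 100] and reaches 100 only when the whole protein is
    a single CD region.  Methods without regions carry ``None`` sentinels;
    whether the protein appears in CD outputs at all is decided by
    :attr:`CDSummary.has_cd`.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    methods: dict[str, MethodCD] = {}
    for method_id, regions in region_lists.items():
        if regions:
            cd_l = max(r.length for r in regions)
            lcpl = 100.0 * cd_l / protein_length
        else:
            cd_l = None
            lcpl = None
        methods[method_id] = MethodCD(method_id, tuple(regions), cd_l, lcpl)
    return CDSummary(protein_length=protein_length, methods=methods)
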