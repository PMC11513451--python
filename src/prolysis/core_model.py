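"""Substrate/peptide coordinate model.

Maps identified peptides onto the substrate sequence, derives cleavage
sites in Schechter–Berger P1/P1' nomenclature, and groups peptides into
gapless coverage fragments.

Conventions
-----------
* All residue coordinates are 1-based and inclusive.
* A cleavage site is identified by its P1 residue index: the residue
  immediately N-terminal to the scissile bond.  The bond cut at P1 = i
  lies between residues i and i+1, so 1 <= P1 < substrate length.
* Except at the protein termini, every proteolytic product is the result
  of two cuts: the product's N-terminal residue is the P1' of one cut and
  its C-terminal residue is the P1 of the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger("prolysis")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class SubstrateProtein:
    """A substrate sequence with a recombinant -> native numbering map.

    ``numbering_offset`` converts recombinant coordinates (those of the
    sequence actually digested and searched) to native coordinates used in
    the literature, e.g. a protease construct spanning native residues
    158-480 has offset +157.
    """

    id: str
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("substrate sequence must be non-empty")
        if not self.sequence.isupper():
            raise ValueError("substrate sequence must be uppercase")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues in substrate: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_native(self, position: int) -> int:
        """Map a recombinant residue position to native numbering."""
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside substrate 1..{self.length}"
            )
        return position + self.numbering_offset


@dataclass
class PeptideMeasurement:
    """One identified peptide with its replicate x time intensity block.

    ``intensities`` has shape (n_replicates, n_timepoints); ``np.nan``
    marks a missing (non-detected) cell.  ``control_intensities`` carries
    the protease-free control block with the same layout, or ``None`` when
    no controls were measured.
    """

    peptide_id: str
    peptide_sequence: str
    start: int
    end: int
    score: float
    intensities: np.ndarray
    control_intensities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be replicate x time (2-D)")
        if np.nanmin(self.intensities, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative where present")
        if self.control_intensities is not None:
            self.control_intensities = np.asarray(
                self.control_intensities, dtype=float
            )
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval ({self.start}, {self.end})")
        if len(self.peptide_sequence) != self.end - self.start + 1:
            raise ValueError("interval length does not match peptide sequence")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True, order=True)
class CleavageSite:
    """A scissile bond identified by its P1 residue position."""

    p1: int

    @property
    def p1_prime(self) -> int:
        return self.p1 + 1


@dataclass
class Fragment:
    """A maximal substrate region covered by gaplessly aligned peptides."""

    start: int
    end: int
    member_peptides: list[str] = field(default_factory=list)


@dataclass
class FragmentMap:
    """Merged gapless coverage intervals at one time point."""

    time_point: float
    fragments: list[Fragment]
    n_peptides: int
    n_cleavage_sites: int


def map_peptide(peptide_sequence: str, substrate: SubstrateProtein) -> list[tuple[int, int]]:
    """Return every exact occurrence of ``peptide_sequence`` as 1-based
    inclusive (start, end) intervals on the substrate.  Empty if none."""
    if not peptide_sequence:
        raise ValueError("peptide sequence must be non-empty")
    hits: list[tuple[int, int]] = []
    pos = substrate.sequence.find(peptide_sequence)
    while pos != -1:
        hits.append((pos + 1, pos + len(peptide_sequence)))
        pos = substrate.sequence.find(peptide_sequence, pos + 1)
    return hits


def cleavage_sites_from_peptide(
    start: int, end: int, substrate_length: int
) -> set[CleavageSite]:
    """Cleavage sites evidenced by a product spanning start..end.

    An internal product is the result of two cuts: P1 = start - 1
    (the product's first residue is that cut's P1') and P1 = end.  A
    product touching the protein N- or C-terminus evidences only one cut;
    the intact chain evidences none.
    """
    if not (1 <= start <= end <= substrate_length):
        raise ValueError(
            f"interval ({start}, {end}) out of bounds for length {substrate_length}"
        )
    sites: set[CleavageSite] = set()
    if start > 1:
        sites.add(CleavageSite(start - 1))
    if end < substrate_length:
        sites.add(CleavageSite(end))
    return sites


def group_fragments(
    intervals: Sequence[tuple[int, int]],
    *,
    time_point: float = 0.0,
    substrate_length: Optional[int] = None,
    peptide_ids: Optional[Sequence[str]] = None,
) -> FragmentMap:
    """Merge peptide intervals into fragments (connected components under
    "overlap or abut"): intervals separated by a gap of zero residues
    belong to one fragment.

    Also counts distinct cleavage sites over all member peptides when
    ``substrate_length`` is given (terminal peptides contribute one site,
    internal peptides two).
    """
    if peptide_ids is None:
        peptide_ids = [f"pep{i}" for i in range(len(intervals))]
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    fragments: list[Fragment] = []
    for idx in order:
        s, e = intervals[idx]
        if not 1 <= s <= e:
            raise ValueError(f"invalid interval ({s}, {e})")
        if fragments and s <= fragments[-1].end + 1:
            frag = fragments[-1]
            frag.end = max(frag.end, e)
            frag.member_peptides.append(peptide_ids[idx])
        else:
            fragments.append(Fragment(s, e, [peptide_ids[idx]]))
    n_sites = 0
    if substrate_length is not None:
        sites: set[CleavageSite] = set()
        for s, e in intervals:
            sites |= cleavage_sites_from_peptide(s, e, substrate_length)
        n_sites = len(sites)
    return FragmentMap(
        time_point=time_point,
        fragments=fragments,
        n_peptides=len(set(peptide_ids)),
        n_cleavage_sites=n_sites,
    )


def to_native_numbering(position: int, substrate: SubstrateProtein) -> int:
    """Convert a recombinant residue position to native numbering."""
    return substrate.to_native(position)


def assign_coordinates(
    peptide_sequence: str,
    substrate: SubstrateProtein,
    *,
    ambiguity: str = "discard",
) -> Optional[tuple[int, int]]:
    """Resolve a peptide's substrate coordinates.

    ``ambiguity`` controls multi-hit peptides: ``"discard"`` (default)
    drops the peptide with a warning — a wrong coordinate would poison
    every downstream statistic — while ``"first"`` keeps the first
    occurrence.
    """
    hits = map_peptide(peptide_sequence, substrate)
    if not hits:
        return None
    if len(hits) > 1:
        if ambiguity == "first":
            return hits[0]
        logger.warning(
            "peptide %s maps to %d positions on %s; discarded",
            peptide_sequence, len(hits), substrate.id,
        )
        return None
    return hits[0]


def coverage_mask(
    intervals: Iterable[tuple[int, int]], substrate_length: int
) -> np.ndarray:
    """Boolean per-residue coverage mask (index 0 == residue 1)."""
    mask = np.zeros(substrate_length, dtype=bool)
    for s, e in intervals:
        mask[s - 1 : e] = True
    return mask
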