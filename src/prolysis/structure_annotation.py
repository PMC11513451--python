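"""Per-residue structural and evolutionary context tracks.

Reads a crystal structure (PDB) to provide secondary structure (from the
file's HELIX/SHEET records, i.e. "as detected in the crystal structure"),
per-residue mean B-factors, and Shrake-Rupley solvent accessibility; and
a multiple sequence alignment to provide Clustal-style conservation
symbols.  The tracks are joined with cut-frequency profiles into one
per-residue table suitable for figure-style rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from Bio.SeqUtils import seq1

from .core_model import SubstrateProtein
from .cut_frequency import SiteProfile, profiles_to_frame

logger = logging.getLogger("prolysis")

__all__ = [
    "ResidueRecord",
    "parse_structure",
    "map_to_substrate",
    "secondary_structure",
    "solvent_accessibility",
    "msa_conservation",
    "annotate_profiles",
    "MAX_ASA_TIEN",
]

#: Theoretical maximum ASA per residue (Tien et al. 2013), Å².
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "V": 174.0, "W": 285.0, "Y": 263.0,
}

#: Expected heavy-atom counts of complete residues (for partial flagging).
_HEAVY_ATOMS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7,
    "L": 8, "I": 8, "N": 8, "D": 8, "M": 8, "Q": 9, "E": 9,
    "K": 9, "H": 10, "R": 11, "F": 11, "Y": 12, "W": 14,
}

# Clustal conservation groups
_STRONG_GROUPS = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]
_WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
    "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
]


@dataclass
class ResidueRecord:
    """One structure residue: author numbering, B-factor, completeness."""

    author_position: int
    resname: str
    amino_acid: str
    mean_b_factor: float
    n_heavy_atoms: int
    partial: bool
    substrate_position: Optional[int] = None


def parse_structure(path: str, chain_id: str) -> list[ResidueRecord]:
    """Read one chain of a PDB file into per-residue records.

    Altloc duplicates resolve to the highest-occupancy conformer;
    hydrogens and heteroatoms (waters, ligands) are ignored.  Raises
    ``KeyError`` naming the available chains when the chain is absent.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("structure", path)
    model = next(structure.get_models())
    chains = [c.id for c in model]
    if chain_id not in chains:
        raise KeyError(
            f"chain {chain_id!r} not in structure; available chains: {chains}"
        )
    records: list[ResidueRecord] = []
    for residue in model[chain_id]:
        het, seqnum, _ = residue.id
        if het.strip():
            continue
        bs, n_heavy = [], 0
        for atom in residue:  # disordered atoms yield highest occupancy
            if atom.element == "H":
                continue
            n_heavy += 1
            bs.append(atom.get_bfactor())
        aa = seq1(residue.get_resname())
        expected = _HEAVY_ATOMS.get(aa, n_heavy)
        records.append(
            ResidueRecord(
                author_position=seqnum,
                resname=residue.get_resname(),
                amino_acid=aa,
                mean_b_factor=float(np.mean(bs)) if bs else float("nan"),
                n_heavy_atoms=n_heavy,
                partial=n_heavy < expected,
            )
        )
    return records


def map_to_substrate(
    records: Sequence[ResidueRecord], substrate: SubstrateProtein
) -> list[ResidueRecord]:
    """Assign substrate coordinates to structure residues.

    The chain's one-letter sequence must match the substrate exactly or
    as a contiguous substring (a constant offset); anything else is
    rejected with a diff report.  Records gain ``substrate_position``.
    """
    chain_seq = "".join(r.amino_acid for r in records)
    idx = substrate.sequence.find(chain_seq)
    if idx >= 0:
        for j, r in enumerate(records):
            r.substrate_position = idx + 1 + j
        return list(records)
    idx = chain_seq.find(substrate.sequence)
    if idx >= 0:
        out = []
        for j, r in enumerate(records):
            pos = j - idx + 1
            if 1 <= pos <= substrate.length:
                r.substrate_position = pos
                out.append(r)
        return out
    n = min(len(chain_seq), substrate.length)
    diffs = [
        f"pos {i + 1}: structure {chain_seq[i]} vs substrate {substrate.sequence[i]}"
        for i in range(n)
        if chain_seq[i] != substrate.sequence[i]
    ][:10]
    raise ValueError(
        "structure sequence does not match substrate (no offset found); "
        f"first mismatches: {diffs}"
    )


def secondary_structure(path: str, chain_id: str) -> dict[int, str]:
    """Secondary-structure class per author residue number.

    Read from the HELIX/SHEET records of the file; residues in neither
    are 'loop'.  Overlaps resolve with helix precedence.
    """
    st = gemmi.read_structure(path)
    classes: dict[int, str] = {}
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name != chain_id:
                continue
            lo = strand.start.res_id.seqid.num
            hi = strand.end.res_id.seqid.num
            if lo is None or hi is None:
                logger.warning("unparseable SHEET record in %s; skipped", path)
                continue
            for p in range(lo, hi + 1):
                classes[p] = "strand"
    for helix in st.helices:
        if helix.start.chain_name != chain_id:
            continue
        lo = helix.start.res_id.seqid.num
        hi = helix.end.res_id.seqid.num
        if lo is None or hi is None:
            logger.warning("unparseable HELIX record in %s; skipped", path)
            continue
        for p in range(lo, hi + 1):
            classes[p] = "helix"
    if not classes:
        logger.warning("no HELIX/SHEET records in %s; all residues 'loop'", path)
    return classes


def solvent_accessibility(
    path: str,
    chain_id: str,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    surface_threshold: float = 0.2,
) -> pd.DataFrame:
    """Shrake-Rupley solvent accessibility per residue of one chain.

    ASA is the numerical accessible surface area (Å²) of the isolated
    chain; RSA = ASA / theoretical max ASA (Tien 2013 scale), clipped to
    [0, 1] (a free residue can exceed the in-chain theoretical maximum).
    ``surface`` is RSA >= ``surface_threshold``.  Residues with missing
    atoms are flagged partial; their ASA covers the present atoms only.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("structure", path)
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise KeyError(f"chain {chain_id!r} not in structure")
    chain = model[chain_id]
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_sphere_points)
    sr.compute(chain, level="R")
    rows = []
    for residue in chain:
        if residue.id[0].strip():
            continue
        aa = seq1(residue.get_resname())
        asa = float(residue.sasa)
        max_asa = MAX_ASA_TIEN.get(aa)
        rsa = min(asa / max_asa, 1.0) if max_asa else float("nan")
        n_heavy = sum(1 for a in residue if a.element != "H")
        rows.append(
            {
                "author_position": residue.id[1],
                "amino_acid": aa,
                "asa": asa,
                "rsa": rsa,
                "surface": bool(rsa >= surface_threshold) if max_asa else False,
                "partial": n_heavy < _HEAVY_ATOMS.get(aa, n_heavy),
            }
        )
    return pd.DataFrame(rows)


def _column_symbol(column: str) -> str:
    """Clustal consensus symbol for one alignment column."""
    if "-" in column or "." in column:
        return " "
    residues = set(column.upper())
    if len(residues) == 1:
        return "*"
    for grp in _STRONG_GROUPS:
        if residues <= set(grp):
            return ":"
    for grp in _WEAK_GROUPS:
        if residues <= set(grp):
            return "."
    return " "


def msa_conservation(
    alignment, reference_id: str
) -> dict[int, str]:
    """Per-residue conservation symbols from a multiple sequence alignment.

    ``alignment`` is a ``Bio.Align.MultipleSeqAlignment`` (or a path to a
    FASTA/Clustal file).  Columns are mapped to ungapped positions of the
    reference row; symbols follow Clustal conventions: '*' identical,
    ':' strong conservation group, '.' weak group, ' ' otherwise.
    """
    if isinstance(alignment, str):
        fmt = "clustal" if alignment.endswith((".aln", ".clustal")) else "fasta"
        alignment = AlignIO.read(alignment, fmt)
    ref = None
    for rec in alignment:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    if ref is None:
        raise KeyError(
            f"reference {reference_id!r} not in alignment: "
            f"{[r.id for r in alignment]}"
        )
    symbols: dict[int, str] = {}
    ref_pos = 0
    for col_idx, ref_char in enumerate(ref):
        if ref_char in "-.":
            continue
        ref_pos += 1
        column = "".join(str(rec.seq)[col_idx] for rec in alignment)
        symbols[ref_pos] = _column_symbol(column)
    return symbols


def annotate_profiles(
    profiles: Sequence[SiteProfile],
    substrate: SubstrateProtein,
    *,
    residue_records: Optional[Sequence[ResidueRecord]] = None,
    secondary: Optional[dict[int, str]] = None,
    accessibility: Optional[pd.DataFrame] = None,
    conservation: Optional[dict[int, str]] = None,
) -> pd.DataFrame:
    """One row per substrate residue joining every available track.

    Columns: position, residue, secondary structure, mean B-factor, RSA,
    surface flag, conservation symbol, and one cut-frequency column per
    time point (frequency of the bond whose P1 is that residue).
    """
    positions = np.arange(1, substrate.length + 1)
    df = pd.DataFrame(
        {
            "position": positions,
            "residue": list(substrate.sequence),
        }
    )
    by_author: dict[int, ResidueRecord] = {}
    sub_to_author: dict[int, int] = {}
    if residue_records is not None:
        for r in residue_records:
            if r.substrate_position is not None:
                sub_to_author[r.substrate_position] = r.author_position
                by_author[r.author_position] = r
    df["mean_b_factor"] = [
        by_author[sub_to_author[p]].mean_b_factor if p in sub_to_author else np.nan
        for p in positions
    ]
    if secondary is not None:
        df["secondary_structure"] = [
            secondary.get(sub_to_author.get(p, p), "loop")
            if (sub_to_author or residue_records is None)
            else "unknown"
            for p in positions
        ]
        if residue_records is not None:
            df.loc[~df["position"].isin(sub_to_author), "secondary_structure"] = (
                "unknown"
            )
    if accessibility is not None:
        acc = accessibility.set_index("author_position")
        rsa, surf = [], []
        for p in positions:
            ap = sub_to_author.get(p, p)
            if ap in acc.index:
                rsa.append(float(acc.loc[ap, "rsa"]))
                surf.append(bool(acc.loc[ap, "surface"]))
            else:
                rsa.append(np.nan)
                surf.append(False)
        df["rsa"] = rsa
        df["surface"] = surf
    if conservation is not None:
        df["conservation"] = [conservation.get(p, " ") for p in positions]
    freq = profiles_to_frame(list(profiles))
    if not freq.empty:
        df = df.merge(
            freq.reset_index(), left_on="position", right_on="p1", how="left"
        ).drop(columns=["p1"])
        for col in freq.columns:
            df[col] = df[col].fillna(0.0)
    return df
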