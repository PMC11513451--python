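"""Shared fixtures: tiny substrates and programmatically written PDB files."""

from __future__ import annotations

import numpy as np
import pytest

from prolysis import SubstrateProtein


def pdb_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    occupancy: float = 1.0,
    b_factor: float = 20.0,
    element: str = "C",
    altloc: str = " ",
) -> str:
    x, y, z = xyz
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{b_factor:6.2f}"
        f"          {element:>2s}"
    )


def helix_record(serial, res1, seq1, res2, seq2, chain="A"):
    return (
        f"HELIX  {serial:3d} {serial:3d} {res1:>3s} {chain} {seq1:4d} "
        f"{res2:>3s} {chain} {seq2:4d}  1"
    )


def sheet_record(res1, seq1, res2, seq2, chain="A"):
    return (
        f"SHEET  {1:3d} {'A':>3s}{1:2d} {res1:>3s} {chain}{seq1:4d}  "
        f"{res2:>3s} {chain}{seq2:4d}{0:3d}"
    )


_BACKBONE = [  # name, element, local offset (rough peptide geometry)
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.4, 0.0)),
    ("O", "O", (1.4, 2.4, 0.3)),
]


def write_backbone_pdb(
    path,
    residues: list[tuple[str, int]],
    chain: str = "A",
    spacing: float = 3.8,
    header_records: list[str] | None = None,
    b_factors: dict[int, float] | None = None,
) -> str:
    """Write a minimal all-backbone PDB chain along the x axis."""
    lines = list(header_records or [])
    serial = 1
    for i, (resname, resseq) in enumerate(residues):
        b = (b_factors or {}).get(resseq, 20.0)
        for name, element, (dx, dy, dz) in _BACKBONE:
            lines.append(
                pdb_atom(
                    serial, name, resname, chain, resseq,
                    (i * spacing + dx, dy, dz), b_factor=b, element=element,
                )
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def tiny_substrate() -> SubstrateProtein:
    return SubstrateProtein(id="tiny", sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")


@pytest.fixture
def glycine_pdb(tmp_path):
    return write_backbone_pdb(tmp_path / "gly.pdb", [("GLY", 1)])


@pytest.fixture
def toy_pdb(tmp_path):
    """Three residues with HELIX/SHEET records and distinct B-factors."""
    header = [
        helix_record(1, "ALA", 1, "ALA", 2),
        sheet_record("GLY", 3, "GLY", 3),
    ]
    return write_backbone_pdb(
        tmp_path / "toy.pdb",
        [("ALA", 1), ("ALA", 2), ("GLY", 3)],
        header_records=header,
        b_factors={1: 10.0, 2: 20.0, 3: 30.0},
    )


@pytest.fixture
def cluster_pdb(tmp_path):
    """A compact pseudo-random 10-residue glycine cluster (~40 atoms)."""
    rng = np.random.default_rng(12)
    lines = []
    serial = 1
    for resseq in range(1, 11):
        center = rng.uniform(-6, 6, size=3)
        for name, element, off in _BACKBONE:
            xyz = center + np.array(off)
            lines.append(
                pdb_atom(
                    serial, name, "GLY", "A", resseq, tuple(xyz), element=element
                )
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "cluster.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)
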