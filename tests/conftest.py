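"""Shared fixtures and small construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nlsgeom.structure import AtomRecord, ComplexStructure, Residue
from nlsgeom.synthetic import make_toy_complex


def format_atom_line(serial, name, resname, chain, resseq, x, y, z,
                     altloc="", occ=1.0, bfac=0.0, element=None, het=False):
    """Render one fixed-width PDB ATOM/HETATM record."""
    record = "HETATM" if het else "ATOM  "
    element = element or name[0]
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record}{serial:5d} {name_field}{altloc or ' ':1s}{resname:>3s} "
            f"{chain:1s}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{bfac:6.2f}          {element:>2s}")


def chain_from_seq(seq, chain="A", start=1, spacing=3.8,
                   structure_id="synthetic_chain"):
    """CA-only chain along a gentle 3D curve (never collinear)."""
    from nlsgeom.structure import ONE_TO_THREE

    residues = []
    for i, letter in enumerate(seq):
        ca = np.array([spacing * i, 2.0 * np.sin(0.6 * i),
                       1.5 * np.cos(0.6 * i)])
        residues.append(Residue(chain, start + i, "",
                                ONE_TO_THREE.get(letter, "GLY"),
                                {"CA": AtomRecord("CA", "C", ca)}))
    return ComplexStructure(structure_id, residues, {chain: "receptor"})


@pytest.fixture
def toy():
    return make_toy_complex()


@pytest.fixture
def rng():
    return np.random.default_rng(20140307)
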