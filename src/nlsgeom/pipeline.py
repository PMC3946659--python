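"""End-to-end conservation analysis over a set of complex structures.

Orchestrates: receptor correspondence by sequence alignment, ensemble
superposition onto a chosen reference entry, geometric anchor detection
and position assignment per entry, and dispersion statistics for the
monitored atoms (peptide anchor positions and pocket tryptophans).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import (CorrespondenceMap, DispersionStats,
                           EnsembleSuperposition, build_correspondence,
                           dispersion, dispersion_receptor,
                           identity_correspondence, pairwise_max_rmsd,
                           superpose_ensemble)
from .errors import NlsGeomError, OccupancyError
from .positions import (MOUSE_POCKETS, PocketDefinition, PositionAssignment,
                        assign_positions, find_anchor_residue)
from .structure import ComplexStructure, read_structure

__all__ = ["ConservationReport", "run_site_conservation", "load_entries",
           "DEFAULT_MONITORED"]

#: monitored (position label, atom) pairs per site; pocket Trp Cζ3 atoms are
#: monitored through the correspondence map in addition
DEFAULT_MONITORED = {
    "minor": (("P1'", "CA"), ("P1'", "CE"), ("P2'", "CA"), ("P2'", "CZ")),
    "major": (("P1", "CA"), ("P2", "CA"), ("P3", "CA"),
              ("P4", "CA"), ("P5", "CA")),
}


@dataclass
class ConservationReport:
    site: str
    reference_id: str
    superposition: EnsembleSuperposition
    correspondence: CorrespondenceMap
    assignments: dict[str, PositionAssignment]
    stats: list[DispersionStats]
    max_pairwise_rmsd: float
    skipped_entries: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"position": s.label, "atom": s.atom_name,
                 "n": s.n_entries, "mean_A": round(s.mean, 3),
                 "sd_A": round(s.sd, 3)} for s in self.stats]
        return pd.DataFrame(rows)


def load_entries(paths: Mapping[str, str | Path],
                 chain_roles: Mapping[str, Mapping[str, str]] | None = None
                 ) -> dict[str, ComplexStructure]:
    """Read one structure per entry id; optional per-entry chain roles."""
    out = {}
    for entry_id, path in paths.items():
        roles = chain_roles.get(entry_id) if chain_roles else None
        st = read_structure(path, roles)
        st.id = entry_id
        out[entry_id] = st
    return out


def _entry_pocket(entry: ComplexStructure, entry_id: str,
                  reference: ComplexStructure,
                  correspondence: CorrespondenceMap,
                  pocket: PocketDefinition,
                  ref_chain: str) -> tuple[PocketDefinition, str]:
    """Translate a pocket defined in reference numbering into the entry's."""
    seqs = []
    entry_chain = None
    for seq in pocket.pocket_trps:
        ref_res = reference.find_residue(ref_chain, seq)
        if ref_res is None:
            raise NlsGeomError(
                f"reference lacks pocket residue {ref_chain}:{seq}")
        key = correspondence.resolve(entry_id, ref_res.key)
        if key is None:
            raise OccupancyError(
                f"{entry_id}: pocket residue {seq} not aligned")
        entry_chain = key[0]
        seqs.append(key[1])
    return (PocketDefinition(pocket.site, tuple(seqs),
                             numbering_species=entry_id), entry_chain)


def run_site_conservation(entries: Mapping[str, ComplexStructure],
                          reference_id: str,
                          site: str = "minor",
                          pocket: PocketDefinition | None = None,
                          monitored=None,
                          fit_atoms=("CA",),
                          use_alignment: bool = True) -> ConservationReport:
    """Superpose all entries on the reference and measure per-position
    dispersion at the requested site.

    ``pocket`` gives the two anchor-pocket tryptophans in the *reference*
    receptor numbering (defaults to the mouse numbering); it is translated
    into each entry through the correspondence map.  Entries where the site
    is unoccupied are skipped for the peptide statistics (reported in
    ``skipped_entries``) but still contribute to the superposition and to
    the receptor-atom statistics.
    """
    reference = entries[reference_id]
    if pocket is None:
        pocket = MOUSE_POCKETS[site]
    if monitored is None:
        monitored = DEFAULT_MONITORED[site]
    correspondence = (build_correspondence(entries, reference)
                      if use_alignment
                      else identity_correspondence(entries, reference))
    sup = superpose_ensemble(entries, reference, correspondence, fit_atoms)
    ref_chain = reference.chains_with_role("receptor")[0]

    assignments: dict[str, PositionAssignment] = {}
    skipped: dict[str, str] = {}
    for entry_id, entry in sup.superposed.items():
        try:
            entry_pocket, entry_chain = _entry_pocket(
                entry, entry_id, reference, correspondence, pocket, ref_chain)
            anchor = find_anchor_residue(entry, entry_pocket,
                                         receptor_chain=entry_chain)
            assignments[entry_id] = assign_positions(entry, anchor, site)
        except NlsGeomError as exc:
            skipped[entry_id] = str(exc)

    stats: list[DispersionStats] = []
    contributing = {i: s for i, s in sup.superposed.items()
                    if i in assignments}
    for label, atom in monitored:
        stats.append(dispersion(contributing, assignments, label, atom))
    for seq in pocket.pocket_trps + pocket.extra_trps:
        ref_res = reference.find_residue(ref_chain, seq)
        stats.append(dispersion_receptor(sup.superposed, correspondence,
                                         ref_res.key, "CZ3",
                                         label=f"W{seq}"))
    worst = pairwise_max_rmsd(entries, reference, correspondence, fit_atoms)
    return ConservationReport(site, reference_id, sup, correspondence,
                              assignments, stats, worst, skipped)
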