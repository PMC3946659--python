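"""Model-vs-reference comparison by local-shell superposition.

A modeled complex is compared against an X-ray reference by first fitting
the model onto the reference using the Cα atoms of receptor residues whose
heavy atoms lie within 5 Å of the reference peptide (the binding-site
"shell"), then reporting grouped peptide RMSDs: at the minor site the
P1'–P2' backbone and sidechains, the P4' backbone and sidechain, and the
P7'–P8' backbone; at the major site the P2–P6 backbone and the P2 and P5
sidechains.  Sidechain atom sets are heavy atoms excluding N, CA, C, O
(CB included); no per-residue re-fit is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .positions import PositionAssignment
from .structure import ComplexStructure, ResidueKey
from .superpose import residues_within, rmsd, superpose_on_subset

__all__ = ["RmsdReport", "evaluate_model", "SHELL_CUTOFF"]

SHELL_CUTOFF = 5.0  # Å, receptor shell around the reference peptide

#: report groups per site: name -> (labels, "ca" | "sidechain")
GROUPS = {
    "minor": (
        ("P1'-P2' CA", ("P1'", "P2'"), "ca"),
        ("P1'-P2' sidechain", ("P1'", "P2'"), "sidechain"),
        ("P4' CA", ("P4'",), "ca"),
        ("P4' sidechain", ("P4'",), "sidechain"),
        ("P7'-P8' CA", ("P7'", "P8'"), "ca"),
    ),
    "major": (
        ("P2-P6 CA", ("P2", "P3", "P4", "P5", "P6"), "ca"),
        ("P2 sidechain", ("P2",), "sidechain"),
        ("P5 sidechain", ("P5",), "sidechain"),
    ),
}


@dataclass
class RmsdReport:
    site: str
    groups: dict[str, float | None]
    flags: dict[str, list[str]] = field(default_factory=dict)
    shell: list[ResidueKey] = field(default_factory=list)
    shell_rmsd: float = 0.0


def _group_pairs(model: ComplexStructure, reference: ComplexStructure,
                 assignment: PositionAssignment, labels, kind,
                 flags: list[str]):
    model_pts, ref_pts = [], []
    for label in labels:
        key = assignment.mapping.get(label)
        if key is None:
            flags.append(f"{label}: not assigned")
            continue
        rres = reference.get_residue(key)
        mres = model.get_residue(key)
        if rres is None or mres is None:
            flags.append(f"{label}: residue missing")
            continue
        if kind == "ca":
            names = ["CA"]
        else:
            names = sorted({a.name for a in rres.sidechain_atoms()}
                           & {a.name for a in mres.sidechain_atoms()})
            only = ({a.name for a in rres.sidechain_atoms()}
                    ^ {a.name for a in mres.sidechain_atoms()})
            if only:
                flags.append(f"{label}: unpaired sidechain atoms {sorted(only)}")
        for name in names:
            ra = rres.atoms.get(name)
            ma = mres.atoms.get(name)
            if ra is None or ma is None:
                flags.append(f"{label}:{name} missing")
                continue
            ref_pts.append(ra.coords)
            model_pts.append(ma.coords)
    return np.array(model_pts), np.array(ref_pts)


def evaluate_model(model: ComplexStructure,
                   reference: ComplexStructure,
                   site: str,
                   assignment: PositionAssignment) -> RmsdReport:
    """Shell-superpose ``model`` onto ``reference`` and report grouped
    peptide RMSDs.  The shell is computed on the reference, so every model
    evaluated against it shares the same fit set."""
    peptide_chains = set(reference.chains_with_role("peptide"))
    if not peptide_chains:
        peptide_chains = {assignment.peptide_chain}
    shell = residues_within(reference, peptide_chains, SHELL_CUTOFF)
    fit_keys = []
    for key in shell:
        res = reference.residue(key)
        if "CA" in res.atoms:
            fit_keys.append((key[0], key[1], key[2], "CA"))
    if len(fit_keys) < 3:
        raise GeometryError(
            f"shell has only {len(fit_keys)} Cα atoms; need >= 3")
    fitted, shell_rmsd, _ = superpose_on_subset(model, reference, fit_keys)

    groups: dict[str, float | None] = {}
    flags: dict[str, list[str]] = {}
    for name, labels, kind in GROUPS[site]:
        group_flags: list[str] = []
        m_pts, r_pts = _group_pairs(fitted, reference, assignment,
                                    labels, kind, group_flags)
        groups[name] = rmsd(m_pts, r_pts) if len(m_pts) else None
        if group_flags:
            flags[name] = group_flags
    return RmsdReport(site, groups, flags, shell, shell_rmsd)
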