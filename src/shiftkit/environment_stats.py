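"""Chemical-environment classification and per-environment error reports.

Prediction error is not uniform across chemistry: sp²- and sp³-carbons,
halogen-bound carbons, ring atoms and heteroatom-bound hydrogens all show
distinct error distributions.  This module classifies each nucleus from
the bond graph (hybridization from bond orders, neighbor elements, ring
membership) and aggregates MAE/RMSE/MAXAE per group.

Attachment groups deliberately overlap: an atom bonded to k distinct
neighbor-element types contributes its error to each of those k groups,
so attachment-group counts sum to more than the number of atoms.
Hybridization groups partition the carbons exactly once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem

from shiftkit.errors import MoleculeError, ScalingError
from shiftkit.shifts_scaling import ErrorReport, error_metrics

GROUP_BY_NEIGHBOR = "neighbor_element"
GROUP_BY_HYBRIDIZATION = "hybridization"
GROUP_BY_RING = "ring"


@dataclass
class AtomEnvironment:
    """Bond-graph environment of one atom (1-based index)."""

    atom_index: int
    element: str
    hybridization: Optional[str]  # sp | sp2 | sp3 | other; carbon only
    neighbors: tuple[str, ...]  # neighbor element multiset, sorted
    in_ring: bool


def _carbon_hybridization(atom: Chem.Atom) -> str:
    bonds = atom.GetBonds()
    n_triple = sum(1 for b in bonds if b.GetBondType() == Chem.BondType.TRIPLE)
    n_double = sum(1 for b in bonds if b.GetBondType() == Chem.BondType.DOUBLE)
    aromatic = any(b.GetIsAromatic() for b in bonds)
    if n_triple >= 1 or n_double >= 2:  # triple or cumulated double bonds
        return "sp"
    if n_double == 1 or aromatic:
        return "sp2"
    if bonds:
        return "sp3"
    return "other"


def perceive_environments(mol: Chem.Mol) -> list[AtomEnvironment]:
    """Classify every atom of a connectivity-annotated RDKit molecule.

    Hybridization is derived from bond orders (aromatic counts as sp²),
    ring membership from cycle detection, neighbors from the bond graph.
    """
    if mol is None or mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
        raise MoleculeError("molecule lacks connectivity; bonds are required")
    Chem.GetSSSR(mol)
    ring_info = mol.GetRingInfo()
    envs: list[AtomEnvironment] = []
    for atom in mol.GetAtoms():
        el = atom.GetSymbol()
        envs.append(
            AtomEnvironment(
                atom_index=atom.GetIdx() + 1,
                element=el,
                hybridization=_carbon_hybridization(atom) if el == "C" else None,
                neighbors=tuple(
                    sorted(n.GetSymbol() for n in atom.GetNeighbors())
                ),
                in_ring=ring_info.IsAtomInRingOfSize(atom.GetIdx(), 3)
                or atom.IsInRing(),
            )
        )
    return envs


def _group_keys(env: AtomEnvironment, group_by: str) -> list[str]:
    if group_by == GROUP_BY_NEIGHBOR:
        # One overlapping group per distinct neighbor-element type; for
        # hydrogen this is its single heavy-atom attachment (H-C, H-N, H-O).
        return [f"{env.element}-{nbr}" for nbr in sorted(set(env.neighbors))]
    if group_by == GROUP_BY_HYBRIDIZATION:
        return [env.hybridization] if env.element == "C" else []
    if group_by == GROUP_BY_RING:
        return ["ring" if env.in_ring else "acyclic"]
    raise ScalingError(f"unknown grouping {group_by!r}")


def grouped_errors(
    environments: Sequence[AtomEnvironment],
    pairs: Mapping[int, tuple[float, float]],
    group_by: str = GROUP_BY_NEIGHBOR,
) -> list[ErrorReport]:
    """Aggregate (exp, calc) pairs into per-environment error reports.

    ``pairs`` maps atom index -> (experimental, calculated) shift; the
    indexing must match ``environments``.  Returns one report per group,
    sorted by group name.
    """
    env_by_index = {e.atom_index: e for e in environments}
    buckets: dict[str, list[tuple[float, float]]] = {}
    for idx, (exp, calc) in pairs.items():
        env = env_by_index.get(idx)
        if env is None:
            raise ScalingError(f"no environment for atom index {idx}")
        for key in _group_keys(env, group_by):
            buckets.setdefault(key, []).append((exp, calc))
    if not buckets:
        raise ScalingError(f"empty grouping for {group_by!r}")
    reports = []
    for key in sorted(buckets):
        exp_list, calc_list = zip(*buckets[key])
        reports.append(error_metrics(exp_list, calc_list, group=key))
    return reports


def reports_to_frame(reports: Sequence[ErrorReport]) -> pd.DataFrame:
    """Tabulate grouped error reports (columns: group, n, MAE, RMSE, MAXAE)."""
    return pd.DataFrame(
        {
            "group": [r.group for r in reports],
            "n": [r.n for r in reports],
            "MAE": [r.mae for r in reports],
            "RMSE": [r.rmse for r in reports],
            "MAXAE": [r.maxae for r in reports],
        }
    )


def export_grouped_errors(
    reports: Sequence[ErrorReport], path: str | Path, sep: str = ","
) -> None:
    reports_to_frame(reports).to_csv(path, sep=sep, index=False)
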