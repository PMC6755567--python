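"""Boltzmann weighting of conformer ensembles and ensemble-averaged shifts.

Solution NMR observes a population-weighted average over the conformers a
flexible molecule visits.  Given relative free energies G_i (kcal/mol) at
temperature T, the fractional population of conformer i is

    w_i = exp(−(G_i − G_min)/RT) / Σ_j exp(−(G_j − G_min)/RT)

with R = 1.987204e−3 kcal·mol⁻¹·K⁻¹.  Shifting all energies by the
minimum before exponentiating makes the weights invariant to the energy
zero and numerically safe for spreads of hundreds of kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from shiftkit.dft_interface import hartree_to_kcalmol
from shiftkit.errors import EnsembleError
from shiftkit.shifts_scaling import ShiftTable

#: Gas constant in kcal/(mol·K).
R_KCALMOL_K = 1.987204e-3

#: Room temperature default (K).
DEFAULT_TEMPERATURE = 298.15


def boltzmann_weights(
    free_energies: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[float]:
    """Fractional populations from relative free energies (kcal/mol)."""
    if temperature <= 0:
        raise EnsembleError(f"temperature must be positive, got {temperature}")
    g = np.asarray(free_energies, dtype=float)
    if g.size == 0:
        raise EnsembleError("at least one conformer is required")
    if not np.all(np.isfinite(g)):
        raise EnsembleError("free energies must be finite")
    ex = np.exp(-(g - g.min()) / (R_KCALMOL_K * temperature))
    return list(ex / ex.sum())


@dataclass
class ConformerEnsemble:
    """Shared-topology conformers with free energies and shift tables.

    ``conformers`` holds ``(label, free_energy_kcalmol, ShiftTable)``
    triples; all conformers must share the same atom indexing and element
    sequence.  Weights are computed on construction.
    """

    conformers: list[tuple[str, float, ShiftTable]]
    temperature: float = DEFAULT_TEMPERATURE
    weights: list[float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise EnsembleError("ensemble needs at least one conformer")
        first = self.conformers[0][2]
        for label, _, table in self.conformers[1:]:
            if table.nuclei != first.nuclei:
                raise EnsembleError(
                    f"conformer {label!r} does not share the ensemble topology"
                )
        labels = [c[0] for c in self.conformers]
        if len(set(labels)) != len(labels):
            raise EnsembleError("conformer labels must be unique")
        self.weights = boltzmann_weights(
            [c[1] for c in self.conformers], self.temperature
        )

    @classmethod
    def from_conformers(
        cls,
        conformers: Sequence[tuple[str, float, ShiftTable]],
        temperature: float = DEFAULT_TEMPERATURE,
        energy_unit: str = "kcal/mol",
    ) -> "ConformerEnsemble":
        """Build an ensemble, converting Hartree energies if requested."""
        if energy_unit == "kcal/mol":
            conv = list(conformers)
        elif energy_unit == "hartree":
            conv = [
                (label, hartree_to_kcalmol(g), table)
                for label, g, table in conformers
            ]
        else:
            raise EnsembleError(
                f"unknown energy unit {energy_unit!r}; use 'kcal/mol' or 'hartree'"
            )
        return cls(conformers=conv, temperature=temperature)


def ensemble_shift(ensemble: ConformerEnsemble) -> ShiftTable:
    """Population-weighted average shift per atom: δ̄ = Σ_i w_i δ_i."""
    first = ensemble.conformers[0][2]
    indices = sorted(first.shifts)
    for label, _, table in ensemble.conformers:
        if sorted(table.shifts) != indices:
            raise EnsembleError(f"conformer {label!r} has misaligned atoms")
    averaged = {
        idx: float(
            sum(
                w * table.shifts[idx]
                for w, (_, _, table) in zip(ensemble.weights, ensemble.conformers)
            )
        )
        for idx in indices
    }
    return ShiftTable(
        shifts=averaged,
        nuclei={i: first.nuclei[i] for i in indices},
        provenance=f"boltzmann(T={ensemble.temperature} K, "
        f"n={len(ensemble.conformers)})",
    )


def group_population(
    ensemble: ConformerEnsemble, labels: Mapping[str, str]
) -> dict[str, float]:
    """Sum conformer weights into named groups (e.g. axial/equatorial)."""
    populations: dict[str, float] = {}
    for (label, _, _), w in zip(ensemble.conformers, ensemble.weights):
        if label not in labels:
            raise EnsembleError(f"conformer {label!r} has no group label")
        group = labels[label]
        populations[group] = populations.get(group, 0.0) + w
    return populations
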