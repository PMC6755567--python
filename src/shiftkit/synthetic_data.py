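"""Synthetic fixtures: shift datasets, mock engine output, conformer sets.

Everything the pipeline consumes can be generated here with known ground
truth, so every parser and fitting path is testable without a
quantum-chemistry installation.  All generators are pure functions of
their arguments including the seed.

Default study conditions mirror benchmark-scale DFT shift data: ¹H
shifts sampled on [0, 17] ppm with 0.3 ppm Gaussian noise, ¹³C on
[0, 220] ppm with 4 ppm noise, and calc/exp slopes within a couple of
percent of unity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from shiftkit.conformers import DEFAULT_TEMPERATURE, ConformerEnsemble
from shiftkit.shifts_scaling import ShiftTable


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth linear relation calc = slope·δ_exp + intercept + noise."""

    slope: float = 1.02
    intercept: float = 0.05
    noise_sd: float = 0.3
    shift_range: tuple[float, float] = (0.0, 17.0)
    nucleus: str = "H"
    seed: int = 20

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("true slope must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


#: Study-condition defaults per nucleus: near-unity slopes and noise
#: levels matching typical benchmark MAE magnitudes (~0.3 ppm ¹H, ~4 ppm ¹³C).
DEFAULT_TRUTHS = {
    "H": SyntheticTruth(slope=1.02, intercept=0.05, noise_sd=0.3,
                        shift_range=(0.0, 17.0), nucleus="H"),
    "C": SyntheticTruth(slope=1.02, intercept=2.0, noise_sd=4.0,
                        shift_range=(0.0, 220.0), nucleus="C"),
}


def gen_shift_dataset(n: int, truth: SyntheticTruth) -> pd.DataFrame:
    """Paired (calc, δ_exp) table with a known linear relation plus noise.

    Experimental shifts are uniform on the nucleus range; the computed
    column is ``slope·δ_exp + intercept + N(0, sd)``.  For shielding-like
    data pass a negative slope and a large intercept.
    """
    if n < 2:
        raise ValueError("need n >= 2 paired values")
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.shift_range
    exp = rng.uniform(lo, hi, size=n)
    noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0
    calc = truth.slope * exp + truth.intercept + noise
    return pd.DataFrame(
        {"nucleus": truth.nucleus, "delta_exp": exp, "calc": calc}
    )


def gen_mock_engine_output(
    shieldings: Mapping[int, float],
    elements: Optional[Mapping[int, str]] = None,
    energy: float = -115.0,
    thermal_correction_kcalmol: Optional[float] = None,
    terminated: bool = True,
) -> str:
    """Engine output text in the pinned dialect for given shieldings.

    ``parse_engine_output`` inverts this exactly: the same atom->ppm map
    comes back, the final energy line is read, a thermochemistry line
    yields a free energy, and omitting the termination marker flips the
    converged flag.
    """
    if not shieldings:
        raise ValueError("shieldings map must be non-empty")
    lines = [" Mock quantum-chemistry engine output (synthetic)", ""]
    lines.append(f"         Total DFT energy =     {energy:.9f}")
    lines.append("")
    lines.append("      Chemical Shielding Tensors (GIAO), mock dialect")
    for idx in sorted(shieldings):
        el = elements.get(idx, "C") if elements else "C"
        lines.append(f"   {idx}   {el}   isotropic =   {shieldings[idx]:.4f}")
    lines.append("")
    if thermal_correction_kcalmol is not None:
        lines.append(
            " Thermal correction to Free Energy  =   "
            f"{thermal_correction_kcalmol:.3f} kcal/mol"
        )
        lines.append("")
    if terminated:
        lines.append(" Total times  cpu:        0.1s     wall:        0.1s")
    return "\n".join(lines) + "\n"


def gen_conformer_ensemble(
    n_per_group: int = 40,
    gap: float = 1.99,
    shift_offsets: tuple[Mapping[int, float], Mapping[int, float]] = (
        {1: 19.5, 2: 0.85},
        {1: 23.0, 2: 0.90},
    ),
    nuclei: Optional[Mapping[int, str]] = None,
    energy_noise_sd: float = 0.0,
    shift_noise_sd: float = 0.0,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 20,
) -> tuple[ConformerEnsemble, dict[str, str]]:
    """Two-group conformer ensemble with a stated free-energy gap.

    Emulates an axial/equatorial chair pair: two groups of
    ``n_per_group`` conformers whose group-mean free energies differ by
    exactly ``gap`` kcal/mol (within-group jitter is re-centered so the
    gap is exact), each conformer carrying a shift table equal to its
    group's offset plus jitter.  Returns the ensemble and a
    conformer->group label map.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    nuclei = dict(nuclei) if nuclei else {i: "C" for i in shift_offsets[0]}
    conformers: list[tuple[str, float, ShiftTable]] = []
    labels: dict[str, str] = {}
    for group, (name, base_g) in enumerate(
        (("minor", gap), ("major", 0.0))
    ):
        e_jitter = rng.normal(0.0, energy_noise_sd, size=n_per_group)
        e_jitter -= e_jitter.mean()  # keep the group-mean gap exact
        for k in range(n_per_group):
            offsets = shift_offsets[group]
            shifts = {
                i: float(
                    offsets[i]
                    + (rng.normal(0.0, shift_noise_sd) if shift_noise_sd > 0 else 0.0)
                )
                for i in offsets
            }
            label = f"{name}_{k + 1}"
            labels[label] = name
            conformers.append(
                (
                    label,
                    float(base_g + e_jitter[k]),
                    ShiftTable(shifts=shifts, nuclei=dict(nuclei)),
                )
            )
    return ConformerEnsemble(conformers=conformers, temperature=temperature), labels
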