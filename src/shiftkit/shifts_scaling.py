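"""Chemical shifts from shieldings, error statistics, empirical scaling.

A computed isotropic shielding σ_i becomes a chemical shift through a
reference compound measured at the same level of theory:

    δ_i = σ_ref − σ_i + δ_ref

Systematic method error is removed by ordinary least squares of the
computed quantity (shift or shielding) on the experimental shift,

    calc ≈ slope · δ_exp + intercept,

inverted as scaled = (calc − intercept)/slope.  The shift-based and the
shielding-based regressions share this one orientation, so the corrected
mean absolute error (CMAE) uses the same (slope, intercept) meaning in
both modes; in the shielding mode the slope is typically near −1.

¹H and ¹³C are always fit separately by callers; nothing here mixes
nuclei.  Atoms lacking experimental values are excluded from pairings by
the caller (see :mod:`shiftkit.pipeline`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from shiftkit.errors import ScalingError
from shiftkit.dft_interface import ShieldingResult
from shiftkit.molecule_io import MoleculeRecord

SHIFT_BASED = "shift_based"
SHIELDING_BASED = "shielding_based"


@dataclass
class ReferenceStandard:
    """Per-nucleus reference shieldings and experimental shifts (ppm)."""

    name: str
    sigma_ref: dict[str, float]
    delta_ref: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.sigma_ref) - set(self.delta_ref)
        if missing:
            raise ScalingError(
                f"reference {self.name}: δ_ref missing for nuclei {sorted(missing)}"
            )


@dataclass
class ShiftTable:
    """Per-atom chemical shifts (ppm), 1-based indices, with provenance."""

    shifts: dict[int, float]
    nuclei: dict[int, str]
    provenance: str = "unscaled"

    def __post_init__(self) -> None:
        if set(self.shifts) - set(self.nuclei):
            raise ScalingError("shift table has shifts for unlabeled atoms")
        for i, v in self.shifts.items():
            if not np.isfinite(v):
                raise ScalingError(f"non-finite shift on atom {i}")


@dataclass
class ScalingModel:
    """Linear model calc = slope·δ_exp + intercept with fit diagnostics."""

    slope: float
    intercept: float
    mode: str = SHIFT_BASED
    n: int = 0
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ScalingError("scaling model slope must be nonzero")


@dataclass
class ErrorReport:
    """MAE/CMAE/RMSE/MAXAE (ppm) over a pairing of exp vs calc shifts."""

    mae: float
    rmse: float
    maxae: float
    n: int
    cmae: Optional[float] = None
    group: str = "all"


@dataclass
class CvReport:
    """Monte Carlo cross-validation of the scaling regression."""

    slopes: list[float]
    intercepts: list[float]
    test_maes: list[float]
    split_fraction: float
    repetitions: int
    seed: int
    slope_mean: float = field(init=False)
    slope_sd: float = field(init=False)
    intercept_mean: float = field(init=False)
    intercept_sd: float = field(init=False)
    test_mae_mean: float = field(init=False)
    test_mae_sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ScalingError("repetitions must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ScalingError("split fraction must lie in (0, 1)")
        self.slope_mean = float(np.mean(self.slopes))
        self.slope_sd = float(np.std(self.slopes, ddof=1)) if len(self.slopes) > 1 else 0.0
        self.intercept_mean = float(np.mean(self.intercepts))
        self.intercept_sd = (
            float(np.std(self.intercepts, ddof=1)) if len(self.intercepts) > 1 else 0.0
        )
        self.test_mae_mean = float(np.mean(self.test_maes))
        self.test_mae_sd = (
            float(np.std(self.test_maes, ddof=1)) if len(self.test_maes) > 1 else 0.0
        )


def reference_from_shieldings(
    record: MoleculeRecord,
    result: ShieldingResult,
    ref_exp_shifts: Mapping[str, float],
    nuclei: Optional[Sequence[str]] = None,
) -> ReferenceStandard:
    """Build a reference standard from a reference molecule's shieldings.

    σ_ref per nucleus is the arithmetic mean over all atoms of that
    element in the reference molecule (equivalent nuclei averaged);
    δ_ref comes from ``ref_exp_shifts`` — zero for TMS by convention.
    Any molecule may serve as reference as long as it carries every
    requested nucleus.
    """
    wanted = list(nuclei) if nuclei is not None else sorted(ref_exp_shifts)
    sigma_ref: dict[str, float] = {}
    delta_ref: dict[str, float] = {}
    elements = record.elements
    for el in wanted:
        values = [
            s for idx, s in result.shieldings.items() if elements[idx - 1] == el
        ]
        if not values:
            raise ScalingError(
                f"reference molecule {record.name} has no shielded {el} atoms"
            )
        if el not in ref_exp_shifts:
            raise ScalingError(f"no experimental reference shift for nucleus {el}")
        sigma_ref[el] = float(np.mean(values))
        delta_ref[el] = float(ref_exp_shifts[el])
    return ReferenceStandard(name=record.name, sigma_ref=sigma_ref, delta_ref=delta_ref)


def shieldings_to_shifts(
    record: MoleculeRecord,
    result: ShieldingResult,
    ref: ReferenceStandard,
) -> ShiftTable:
    """Convert shieldings to chemical shifts: δ_i = σ_ref − σ_i + δ_ref."""
    shifts: dict[int, float] = {}
    nuclei: dict[int, str] = {}
    elements = record.elements
    for idx, sigma in result.shieldings.items():
        el = elements[idx - 1]
        if el not in ref.sigma_ref:
            raise ScalingError(
                f"no reference entry for nucleus {el} (atom {idx} of {record.name})"
            )
        shifts[idx] = ref.sigma_ref[el] - sigma + ref.delta_ref[el]
        nuclei[idx] = el
    return ShiftTable(shifts=shifts, nuclei=nuclei, provenance="unscaled")


def error_metrics(
    exp: Sequence[float],
    calc: Sequence[float],
    model: Optional[ScalingModel] = None,
    group: str = "all",
) -> ErrorReport:
    """Quantify errors of calculated vs experimental shifts.

    MAE = mean|δ_exp − δ_calc|; RMSE = sqrt(mean(δ_exp − δ_calc)²);
    MAXAE = max|δ_exp − δ_calc|; CMAE (when a model is given) applies the
    inverted linear correction first:
    CMAE = mean|δ_exp − (δ_calc − intercept)/slope|.
    """
    exp_arr = np.asarray(exp, dtype=float)
    calc_arr = np.asarray(calc, dtype=float)
    if exp_arr.shape != calc_arr.shape:
        raise ScalingError(
            f"length mismatch: {exp_arr.shape[0]} exp vs {calc_arr.shape[0]} calc"
        )
    if exp_arr.size == 0:
        raise ScalingError("empty pairing: no experimental/calculated pairs")
    resid = exp_arr - calc_arr
    report = ErrorReport(
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        maxae=float(np.max(np.abs(resid))),
        n=int(exp_arr.size),
        group=group,
    )
    if model is not None:
        corrected = (calc_arr - model.intercept) / model.slope
        report.cmae = float(np.mean(np.abs(exp_arr - corrected)))
    return report


def fit_scaling(
    calc_values: Sequence[float],
    exp_shifts: Sequence[float],
    mode: str = SHIFT_BASED,
) -> ScalingModel:
    """OLS of the computed quantity on experimental shifts.

    ``calc_values`` are chemical shifts in ``shift_based`` mode or raw
    shieldings in ``shielding_based`` mode (where the slope comes out
    near −1 because shielding decreases as shift increases).
    """
    if mode not in (SHIFT_BASED, SHIELDING_BASED):
        raise ScalingError(f"unknown scaling mode {mode!r}")
    calc_arr = np.asarray(calc_values, dtype=float)
    exp_arr = np.asarray(exp_shifts, dtype=float)
    if calc_arr.shape != exp_arr.shape:
        raise ScalingError("calc and exp lists must pair one-to-one")
    if calc_arr.size < 2:
        raise ScalingError("need at least two points to fit a scaling model")
    if np.ptp(exp_arr) == 0:
        raise ScalingError("degenerate regression: experimental shifts constant")
    fit = stats.linregress(exp_arr, calc_arr)
    if fit.slope == 0:
        raise ScalingError("degenerate regression: zero slope")
    return ScalingModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        mode=mode,
        n=int(calc_arr.size),
        r2=float(fit.rvalue**2),
    )


def apply_scaling(
    values: Sequence[float], model: ScalingModel
) -> list[float]:
    """Invert the linear model: scaled = (value − intercept)/slope."""
    arr = np.asarray(values, dtype=float)
    return list((arr - model.intercept) / model.slope)


def apply_scaling_table(table: ShiftTable, model: ScalingModel) -> ShiftTable:
    """Scale every entry of a shift table, tagging provenance."""
    indices = sorted(table.shifts)
    scaled = apply_scaling([table.shifts[i] for i in indices], model)
    return ShiftTable(
        shifts=dict(zip(indices, scaled)),
        nuclei={i: table.nuclei[i] for i in indices},
        provenance=f"scaled({model.mode}, slope={model.slope:.6g}, "
        f"intercept={model.intercept:.6g})",
    )


def save_model(model: ScalingModel, path) -> None:
    """Persist a scaling model as a small key=value text file."""
    from pathlib import Path

    Path(path).write_text(
        f"slope={model.slope!r}\nintercept={model.intercept!r}\n"
        f"mode={model.mode}\nn={model.n}\nr2={model.r2!r}\n"
    )


def load_model(path) -> ScalingModel:
    """Read a scaling model written by :func:`save_model`."""
    from pathlib import Path

    kv = dict(
        line.split("=", 1)
        for line in Path(path).read_text().splitlines()
        if "=" in line
    )
    try:
        return ScalingModel(
            slope=float(kv["slope"]),
            intercept=float(kv["intercept"]),
            mode=kv.get("mode", SHIFT_BASED),
            n=int(kv.get("n", 0)),
            r2=float(kv.get("r2", "nan")),
        )
    except (KeyError, ValueError) as exc:
        raise ScalingError(f"malformed model file {path}: {exc}") from exc


def monte_carlo_cv(
    calc: Sequence[float],
    exp: Sequence[float],
    mode: str = SHIFT_BASED,
    split_fraction: float = 0.8,
    repetitions: int = 1000,
    seed: int = 20,
) -> CvReport:
    """Monte Carlo cross-validation of the scaling regression.

    Each repetition draws a random train/test split, fits the scaling on
    the training fold, and scores the mean absolute error of the scaled
    test fold.  Fully reproducible for a fixed seed.
    """
    calc_arr = np.asarray(calc, dtype=float)
    exp_arr = np.asarray(exp, dtype=float)
    if calc_arr.shape != exp_arr.shape:
        raise ScalingError("calc and exp lists must pair one-to-one")
    n = calc_arr.size
    n_train = int(round(split_fraction * n))
    if not 0 < split_fraction < 1:
        raise ScalingError("split fraction must lie in (0, 1)")
    if n_train < 2 or n - n_train < 1:
        raise ScalingError(
            f"infeasible split: {n_train} train / {n - n_train} test from n={n}"
        )
    rng = np.random.default_rng(seed)
    slopes, intercepts, maes = [], [], []
    for _ in range(repetitions):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        model = fit_scaling(calc_arr[train], exp_arr[train], mode=mode)
        scaled = np.asarray(apply_scaling(calc_arr[test], model))
        slopes.append(model.slope)
        intercepts.append(model.intercept)
        maes.append(float(np.mean(np.abs(exp_arr[test] - scaled))))
    return CvReport(
        slopes=slopes,
        intercepts=intercepts,
        test_maes=maes,
        split_fraction=split_fraction,
        repetitions=repetitions,
        seed=seed,
    )
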