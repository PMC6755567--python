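"""End-to-end orchestration: prep decks, run backend, collect, score.

The workflow expands a molecule list against a method matrix, renders one
input deck per (molecule, method) pair into
``<outdir>/<molecule>__<functional>_<basis>/``, executes each deck
through the configured runner, parses shieldings, converts them to
chemical shifts against the reference compound (TMS by default, whose
experimental shifts are zero by convention), and writes an augmented
Molfile per pair.  Scoring pools experimental/computed pairs per nucleus
and method, fits the empirical scaling, and reports MAE/CMAE/RMSE/MAXAE.

Per-pair failures are recorded in the run index without aborting the
batch; only a batch where every pair failed raises.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from shiftkit import molecule_io
from shiftkit.conformers import (
    DEFAULT_TEMPERATURE,
    ConformerEnsemble,
    ensemble_shift,
    group_population,
)
from shiftkit.dft_interface import (
    ExternalRunner,
    MethodSpec,
    MockRunner,
    Runner,
    parse_engine_output,
    parse_method_list,
    render_input_deck,
    run_backend,
)
from shiftkit.environment_stats import (
    export_grouped_errors,
    grouped_errors,
    perceive_environments,
)
from shiftkit.errors import ShiftkitError
from shiftkit.molecule_io import MoleculeRecord, parse_molecule_list
from shiftkit.shifts_scaling import (
    SHIELDING_BASED,
    SHIFT_BASED,
    ErrorReport,
    ScalingModel,
    ShiftTable,
    apply_scaling,
    error_metrics,
    fit_scaling,
    monte_carlo_cv,
    reference_from_shieldings,
    save_model,
    shieldings_to_shifts,
)

logger = logging.getLogger("shiftkit")

#: Tetramethylsilane, the conventional ¹H/¹³C zero-point reference.
TMS_INCHI = "InChI=1S/C4H12Si/c1-5(2,3)4/h1-4H3"


class PipelineError(ShiftkitError):
    """Batch-level failure (nothing to run, or every pair failed)."""


def _sanitize(token: str) -> str:
    return re.sub(r"[^A-Za-z0-9._+-]", "-", token)


def pair_dirname(molecule_name: str, spec: MethodSpec) -> str:
    return f"{molecule_name}__{_sanitize(spec.functional)}_{_sanitize(spec.basis)}"


@dataclass
class RunManifest:
    """Everything one pipeline run needs, resolvable at launch."""

    molecules: Path
    methods: Path
    outdir: Path
    template: Optional[Path] = None
    reference_inchi: str = TMS_INCHI
    reference_shifts: dict[str, float] = field(default_factory=dict)
    exp_dir: Optional[Path] = None
    runner_mode: str = "mock"
    engine_cmd: Optional[str] = None
    seed: int = 20
    temperature: float = DEFAULT_TEMPERATURE

    def make_runner(self) -> Runner:
        if self.runner_mode == "mock":
            return MockRunner()
        if self.runner_mode == "external":
            if not self.engine_cmd:
                raise PipelineError("external runner requires an engine command")
            return ExternalRunner(self.engine_cmd)
        raise PipelineError(f"unknown runner mode {self.runner_mode!r}")

    def reference_record(self) -> MoleculeRecord:
        return molecule_io.embed_3d(self.reference_inchi, seed=self.seed)

    def reference_delta(self, nuclei) -> dict[str, float]:
        # TMS convention: unspecified nuclei reference to 0 ppm.
        return {el: self.reference_shifts.get(el, 0.0) for el in nuclei}


def _load_inputs(
    manifest: RunManifest,
) -> tuple[list[MoleculeRecord], list[MethodSpec], Optional[str]]:
    records = parse_molecule_list(manifest.molecules)
    specs = parse_method_list(manifest.methods)
    if not records:
        raise PipelineError(f"no molecules in {manifest.molecules}")
    if not specs:
        raise PipelineError(f"no methods in {manifest.methods}")
    template = (
        Path(manifest.template).read_text() if manifest.template else None
    )
    if manifest.exp_dir:
        for rec in records:
            mol_path = Path(manifest.exp_dir) / f"{rec.name}.mol"
            if mol_path.exists():
                rec.exp_shifts = molecule_io.read_experimental_shifts(
                    mol_path.read_text()
                )
    return records, specs, template


def cmd_prep(manifest: RunManifest) -> pd.DataFrame:
    """Render every (molecule, method) deck; return/write the deck index."""
    records, specs, template = _load_inputs(manifest)
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for spec in specs:
            pair_dir = outdir / pair_dirname(rec.name, spec)
            pair_dir.mkdir(parents=True, exist_ok=True)
            deck = render_input_deck(rec, spec, template)
            deck_path = pair_dir / "input.nw"
            deck_path.write_text(deck)
            rows.append(
                {
                    "molecule": rec.name,
                    "functional": spec.functional,
                    "basis": spec.basis,
                    "deck": str(deck_path.relative_to(outdir)),
                }
            )
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "deck_index.csv", index=False)
    logger.info("prepared %d decks under %s", len(rows), outdir)
    return index


def _reference_standard(manifest, spec, runner, template):
    ref_record = manifest.reference_record()
    ref_spec = MethodSpec(
        functional=spec.functional,
        basis=spec.basis,
        solvent=spec.solvent,
        tasks=("shielding",),
        nuclei=spec.nuclei,
        template_overrides=spec.template_overrides,
    )
    deck = render_input_deck(ref_record, ref_spec, template)
    out = run_backend(deck, runner, identity=f"reference/{spec.label}")
    shielding, _ = parse_engine_output(out, ref_spec, n_atoms=ref_record.n_atoms)
    nuclei = sorted(spec.nuclei & set(ref_record.elements))
    return ref_record, reference_from_shieldings(
        ref_record, shielding, manifest.reference_delta(nuclei), nuclei=nuclei
    )


def cmd_run_collect(manifest: RunManifest) -> pd.DataFrame:
    """Run all decks, parse shieldings, write shifts into Molfiles.

    Returns the result index (one row per pair, status ``ok`` or
    ``failed`` with a reason); raises :class:`PipelineError` only when
    every pair failed.
    """
    records, specs, template = _load_inputs(manifest)
    runner = manifest.make_runner()
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    references: dict[str, tuple] = {}
    rows = []
    n_ok = 0
    for spec in specs:
        try:
            references[spec.label] = _reference_standard(
                manifest, spec, runner, template
            )
        except ShiftkitError as exc:
            references[spec.label] = exc
    for rec in records:
        for spec in specs:
            pair_dir = outdir / pair_dirname(rec.name, spec)
            pair_dir.mkdir(parents=True, exist_ok=True)
            row = {
                "molecule": rec.name,
                "functional": spec.functional,
                "basis": spec.basis,
                "status": "ok",
                "reason": "",
                "molfile": "",
            }
            try:
                ref = references[spec.label]
                if isinstance(ref, Exception):
                    raise ref
                _, standard = ref
                deck = render_input_deck(rec, spec, template)
                (pair_dir / "input.nw").write_text(deck)
                out = run_backend(
                    deck, runner, identity=f"{rec.name}/{spec.label}"
                )
                (pair_dir / "output.out").write_text(out)
                shielding, energy = parse_engine_output(
                    out, spec, n_atoms=rec.n_atoms
                )
                table = shieldings_to_shifts(rec, shielding, standard)
                molfile = molecule_io.write_molfile_with_properties(
                    rec, shieldings=shielding.shieldings, shifts=table.shifts
                )
                mol_path = pair_dir / f"{rec.name}.mol"
                mol_path.write_text(molfile)
                row["molfile"] = str(mol_path.relative_to(outdir))
                n_ok += 1
            except ShiftkitError as exc:
                row["status"] = "failed"
                row["reason"] = str(exc)
                logger.warning("pair %s/%s failed: %s", rec.name, spec.label, exc)
            rows.append(row)
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "result_index.csv", index=False)
    if n_ok == 0:
        raise PipelineError("all (molecule, method) pairs failed")
    logger.info("collected %d/%d pairs", n_ok, len(rows))
    return index


@dataclass
class ScoreReport:
    """Scoring output for one (method, nucleus) pool."""

    method: str
    nucleus: str
    unscaled: ErrorReport
    models: dict[str, ScalingModel]
    scaled: dict[str, ErrorReport]
    cv: dict[str, object] = field(default_factory=dict)
    grouped: list[ErrorReport] = field(default_factory=list)


def _collect_pairs(outdir: Path):
    """Pool (exp, calc shift, shielding) pairs per (method, nucleus)."""
    index_path = outdir / "result_index.csv"
    if not index_path.exists():
        raise PipelineError(f"no result index under {outdir}; run collect first")
    index = pd.read_csv(index_path, keep_default_na=False)
    pools: dict[tuple[str, str], dict[str, list]] = {}
    mols: dict[tuple[str, str], list] = {}
    for _, row in index.iterrows():
        if row["status"] != "ok" or not row["molfile"]:
            continue
        text = (outdir / row["molfile"]).read_text()
        record = molecule_io.read_molfile(text)
        fields = molecule_io.read_molfile_fields(text)
        shifts = fields.get(molecule_io.FIELD_SHIFTS, {})
        sigmas = fields.get(molecule_io.FIELD_SHIELDINGS, {})
        exp = fields.get(molecule_io.FIELD_EXPERIMENTAL, {})
        method = f"{row['functional']}_{row['basis']}"
        for idx, exp_val in exp.items():
            if idx not in shifts:
                continue
            el = record.elements[idx - 1]
            pool = pools.setdefault(
                (method, el),
                {"exp": [], "calc": [], "sigma": [], "atoms": []},
            )
            pool["exp"].append(exp_val)
            pool["calc"].append(shifts[idx])
            pool["sigma"].append(sigmas.get(idx))
            pool["atoms"].append((record, idx))
        mols.setdefault((method, "all"), []).append(record)
    return pools


def cmd_score(
    manifest: RunManifest,
    modes: tuple[str, ...] = (SHIFT_BASED,),
    provided_model: Optional[ScalingModel] = None,
    cv: bool = False,
    cv_repetitions: int = 1000,
    cv_split: float = 0.8,
    group_errors: bool = False,
) -> list[ScoreReport]:
    """Score collected results against experimental shifts per nucleus.

    With ``provided_model`` no fit is performed: the supplied slope and
    intercept scale the computed shifts directly.  Otherwise one model
    per requested mode is fitted on the pooled pairs.
    """
    outdir = Path(manifest.outdir)
    pools = _collect_pairs(outdir)
    if not all(len(p["exp"]) >= 2 for p in pools.values()) or not pools:
        raise PipelineError(
            "no experimental chemical shifts available (need >= 2 per nucleus); "
            "nothing to score"
        )
    scores_dir = outdir / "scores"
    scores_dir.mkdir(exist_ok=True)
    reports: list[ScoreReport] = []
    for (method, nucleus), pool in sorted(pools.items()):
        exp, calc, sigma = pool["exp"], pool["calc"], pool["sigma"]
        unscaled = error_metrics(exp, calc)
        models: dict[str, ScalingModel] = {}
        scaled: dict[str, ErrorReport] = {}
        cv_reports: dict[str, object] = {}
        if provided_model is not None:
            models["provided"] = provided_model
            scaled["provided"] = error_metrics(exp, calc, model=provided_model)
        else:
            for mode in modes:
                values = calc if mode == SHIFT_BASED else sigma
                if mode == SHIELDING_BASED and any(v is None for v in sigma):
                    continue
                model = fit_scaling(values, exp, mode=mode)
                models[mode] = model
                scaled_vals = apply_scaling(values, model)
                rep = error_metrics(exp, scaled_vals)
                rep.cmae = rep.mae  # scaling already applied
                scaled[mode] = rep
                save_model(
                    model, scores_dir / f"{method}_{nucleus}_{mode}.model"
                )
                if cv:
                    cv_reports[mode] = monte_carlo_cv(
                        values,
                        exp,
                        mode=mode,
                        split_fraction=cv_split,
                        repetitions=cv_repetitions,
                        seed=manifest.seed,
                    )
        grouped: list[ErrorReport] = []
        if group_errors:
            env_pairs = {}
            envs = []
            offset = 0
            for (record, idx), e, c in zip(pool["atoms"], exp, calc):
                mol_envs = perceive_environments(record.mol)
                for env in mol_envs:
                    if env.atom_index == idx:
                        env = type(env)(
                            atom_index=offset + idx,
                            element=env.element,
                            hybridization=env.hybridization,
                            neighbors=env.neighbors,
                            in_ring=env.in_ring,
                        )
                        envs.append(env)
                        env_pairs[offset + idx] = (e, c)
                offset += record.n_atoms
            grouped = grouped_errors(envs, env_pairs)
            export_grouped_errors(
                grouped, scores_dir / f"{method}_{nucleus}_grouped.csv"
            )
        report = ScoreReport(
            method=method,
            nucleus=nucleus,
            unscaled=unscaled,
            models=models,
            scaled=scaled,
            cv=cv_reports,
            grouped=grouped,
        )
        reports.append(report)
        _export_score(report, scores_dir)
    return reports


def _export_score(report: ScoreReport, scores_dir: Path) -> None:
    rows = [
        {
            "method": report.method,
            "nucleus": report.nucleus,
            "kind": "unscaled",
            "n": report.unscaled.n,
            "MAE": report.unscaled.mae,
            "CMAE": "",
            "RMSE": report.unscaled.rmse,
            "MAXAE": report.unscaled.maxae,
        }
    ]
    for mode, rep in report.scaled.items():
        rows.append(
            {
                "method": report.method,
                "nucleus": report.nucleus,
                "kind": mode,
                "n": rep.n,
                "MAE": rep.mae,
                "CMAE": rep.cmae,
                "RMSE": rep.rmse,
                "MAXAE": rep.maxae,
            }
        )
    pd.DataFrame(rows).to_csv(
        scores_dir / f"{report.method}_{report.nucleus}_report.csv", index=False
    )


def load_ensemble_manifest(
    path: str | Path,
    temperature: float = DEFAULT_TEMPERATURE,
    energy_unit: str = "kcal/mol",
) -> tuple[ConformerEnsemble, dict[str, str]]:
    """Read an ensemble manifest: label, group, free_energy, shifts_path.

    Each referenced shift-table file is a CSV/TSV with columns
    ``atom_index``, ``nucleus``, ``shift``; paths resolve relative to the
    manifest.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    required = {"label", "group", "free_energy", "shifts_path"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"ensemble manifest missing columns {sorted(missing)}")
    conformers = []
    labels = {}
    for _, row in df.iterrows():
        shifts_path = Path(row["shifts_path"])
        if not shifts_path.is_absolute():
            shifts_path = path.parent / shifts_path
        tdf = pd.read_csv(shifts_path)
        table = ShiftTable(
            shifts={int(r.atom_index): float(r.shift) for r in tdf.itertuples()},
            nuclei={int(r.atom_index): str(r.nucleus) for r in tdf.itertuples()},
        )
        conformers.append((str(row["label"]), float(row["free_energy"]), table))
        labels[str(row["label"])] = str(row["group"])
    ensemble = ConformerEnsemble.from_conformers(
        conformers, temperature=temperature, energy_unit=energy_unit
    )
    return ensemble, labels


def cmd_conformers(
    manifest_path: str | Path,
    outdir: str | Path,
    temperature: float = DEFAULT_TEMPERATURE,
    energy_unit: str = "kcal/mol",
) -> tuple[ShiftTable, dict[str, float]]:
    """Weight an ensemble manifest and write averaged shifts/populations."""
    ensemble, labels = load_ensemble_manifest(
        manifest_path, temperature=temperature, energy_unit=energy_unit
    )
    averaged = ensemble_shift(ensemble)
    populations = group_population(ensemble, labels)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "atom_index": sorted(averaged.shifts),
            "nucleus": [averaged.nuclei[i] for i in sorted(averaged.shifts)],
            "shift": [averaged.shifts[i] for i in sorted(averaged.shifts)],
        }
    ).to_csv(outdir / "ensemble_shifts.csv", index=False)
    pd.DataFrame(
        sorted(populations.items()), columns=["group", "population"]
    ).to_csv(outdir / "group_populations.csv", index=False)
    return averaged, populations
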