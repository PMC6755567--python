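"""Quantum-chemistry engine interface: decks, output parsing, runners.

The package never computes shieldings itself.  It renders NWChem-dialect
input decks from a :class:`MethodSpec` and a molecule record, hands the
deck to a runner — either an external executable or the deterministic
:class:`MockRunner` — and parses the textual output back into per-atom
isotropic shieldings and energies.

The pinned output dialect is: a header line containing ``Chemical
Shielding``, one per-atom line containing ``isotropic`` with the 1-based
atom index, a final ``Total DFT energy`` line, optional thermochemistry
lines, and a timing line as normal-termination marker.  The mock backend
emits exactly this dialect, so generator and parser are exact inverses.
"""

from __future__ import annotations

import hashlib
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

import pandas as pd

from shiftkit.errors import (
    BackendError,
    DeckError,
    EngineUnavailableError,
    ParseError,
)
from shiftkit.molecule_io import MoleculeRecord

#: CODATA conversion: 1 Hartree in kcal/mol.
HARTREE_TO_KCALMOL = 627.509474

#: Built-in COSMO dielectric constants; overridable per MethodSpec via
#: template_overrides["dielectric"].
SOLVENT_DIELECTRICS = {
    "chloroform": 4.81,
    "water": 78.4,
    "dmso": 46.7,
    "methanol": 32.6,
}

VALID_TASKS = ("optimize", "frequency", "shielding")

# Exchange-correlation directives for the stock functional ladder
# (0/20/35/50 % Hartree-Fock exchange); unknown names pass through
# verbatim and the engine owns their validity.
_XC_DIRECTIVES = {
    "BLYP": "xc becke88 lyp",
    "B3LYP": "xc b3lyp",
    "B35LYP": "xc hfexch 0.35 becke88 0.65 lyp 1.00",
    "BHLYP": "xc beckehandh",
}

DEFAULT_TEMPLATE = """echo
start {name}

title "{name} {functional}/{basis}"

charge {charge}

geometry units angstroms noautosym
{geometry}
end

basis
 * library {basis}
end

dft
 {xc}
end

{cosmo}{tasks}"""

REQUIRED_PLACEHOLDERS = ("geometry", "basis", "xc", "tasks")


@dataclass(frozen=True)
class MethodSpec:
    """One level of theory: functional x basis x solvent x tasks."""

    functional: str
    basis: str
    solvent: Optional[str] = None
    tasks: tuple[str, ...] = ("shielding",)
    nuclei: frozenset[str] = frozenset({"H", "C"})
    template_overrides: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("MethodSpec requires at least one task")
        unknown = [t for t in self.tasks if t not in VALID_TASKS]
        if unknown:
            raise ValueError(f"unknown tasks {unknown}; valid: {VALID_TASKS}")
        if "shielding" in self.tasks and not self.nuclei:
            raise ValueError("shielding task requires a non-empty nuclei set")

    @property
    def label(self) -> str:
        return f"{self.functional}_{self.basis}"

    def overrides(self) -> dict[str, str]:
        return dict(self.template_overrides)


@dataclass
class ShieldingResult:
    """Per-atom isotropic shieldings (ppm), 1-based atom indices."""

    shieldings: dict[int, float]
    method: Optional[MethodSpec] = None
    converged: bool = True


@dataclass
class EnergyResult:
    """Electronic energy (Hartree) and optional free energy (kcal/mol)."""

    electronic_hartree: Optional[float] = None
    free_energy_kcalmol: Optional[float] = None


def hartree_to_kcalmol(e: float) -> float:
    """Convert an energy from Hartree to kcal/mol."""
    return e * HARTREE_TO_KCALMOL


def parse_method_list(path: str | Path) -> list[MethodSpec]:
    """Read a method matrix (XLSX/CSV/TSV) into MethodSpec rows.

    Required columns: ``functional``, ``basis``, ``tasks``.  Optional:
    ``solvent``, ``nuclei`` (whitespace/comma-separated element symbols).
    Functional and basis names are passed through verbatim; the engine
    owns their validity.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"method list not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path, dtype=str)
    elif suffix == ".tsv":
        df = pd.read_csv(path, dtype=str, sep="\t")
    else:
        df = pd.read_csv(path, dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"functional", "basis", "tasks"} - set(df.columns)
    if missing:
        raise ParseError(f"method list missing columns: {sorted(missing)}")
    specs = []
    for i, row in df.iterrows():
        tasks_cell = row.get("tasks")
        if not isinstance(tasks_cell, str) or not tasks_cell.strip():
            raise ParseError(f"row {i + 1}: empty task cell")
        tasks = tuple(re.split(r"[,\s]+", tasks_cell.strip().lower()))
        solvent = row.get("solvent")
        if not isinstance(solvent, str) or not solvent.strip():
            solvent = None
        else:
            solvent = solvent.strip().lower()
        nuclei_cell = row.get("nuclei")
        if isinstance(nuclei_cell, str) and nuclei_cell.strip():
            nuclei = frozenset(re.split(r"[,\s]+", nuclei_cell.strip()))
        else:
            nuclei = frozenset({"H", "C"})
        try:
            specs.append(
                MethodSpec(
                    functional=str(row["functional"]).strip(),
                    basis=str(row["basis"]).strip(),
                    solvent=solvent,
                    tasks=tasks,
                    nuclei=nuclei,
                )
            )
        except ValueError as exc:
            raise ParseError(f"row {i + 1}: {exc}") from exc
    return specs


def _xc_directive(functional: str) -> str:
    return _XC_DIRECTIVES.get(functional.upper(), f"xc {functional}")


def _cosmo_block(spec: MethodSpec) -> str:
    if spec.solvent is None:
        return ""
    override = spec.overrides().get("dielectric")
    if override is not None:
        dielec = float(override)
    else:
        try:
            dielec = SOLVENT_DIELECTRICS[spec.solvent.lower()]
        except KeyError:
            raise DeckError(
                f"no dielectric constant for solvent {spec.solvent!r}; supply "
                "one via template_overrides['dielectric']"
            ) from None
    return f"cosmo\n dielec {dielec}\nend\n\n"


def _task_block(record: MoleculeRecord, spec: MethodSpec) -> str:
    lines: list[str] = []
    for task in spec.tasks:
        if task == "optimize":
            lines.append("task dft optimize")
        elif task == "frequency":
            lines.append("task dft frequency")
        elif task == "shielding":
            indices = [
                str(i)
                for i, el in enumerate(record.elements, start=1)
                if el in spec.nuclei
            ]
            if not indices:
                raise DeckError(
                    f"no atoms of requested nuclei {sorted(spec.nuclei)} in "
                    f"{record.name}"
                )
            lines.append(
                "property\n shielding "
                + str(len(indices))
                + " "
                + " ".join(indices)
                + "\nend\ntask dft property"
            )
    return "\n".join(lines) + "\n"


def render_input_deck(
    record: MoleculeRecord,
    spec: MethodSpec,
    template: Optional[str] = None,
) -> str:
    """Render an NWChem-dialect input deck; byte-identical on repetition.

    The template uses named placeholders ``{name}``, ``{charge}``,
    ``{geometry}``, ``{basis}``, ``{functional}``, ``{xc}``, ``{cosmo}``,
    ``{tasks}``; ``template_overrides`` on the spec win over computed
    values.
    """
    if record.n_atoms == 0:
        raise DeckError(f"{record.name}: no atoms to render")
    template = template if template is not None else DEFAULT_TEMPLATE
    for ph in REQUIRED_PLACEHOLDERS:
        if "{" + ph + "}" not in template:
            raise DeckError(f"template missing required placeholder {{{ph}}}")
    geometry = "\n".join(
        f" {el} {x:.6f} {y:.6f} {z:.6f}" for el, x, y, z in record.atoms
    )
    values = {
        "name": record.name,
        "charge": str(record.charge),
        "geometry": geometry,
        "basis": spec.basis,
        "functional": spec.functional,
        "xc": _xc_directive(spec.functional),
        "cosmo": _cosmo_block(spec),
        "tasks": _task_block(record, spec),
    }
    values.update(
        {k: v for k, v in spec.overrides().items() if k != "dielectric"}
    )
    try:
        return template.format(**values)
    except KeyError as exc:
        raise DeckError(f"template placeholder with no value: {exc}") from exc


# ---------------------------------------------------------------------------
# Output parsing

_SHIELDING_HEADER_RE = re.compile(r"Chemical Shielding")
_ISOTROPIC_RE = re.compile(
    r"^\s*(\d+)\s+[A-Za-z]{1,2}\s+isotropic\s*=\s*(-?\d+(?:\.\d+)?)"
)
_ENERGY_RE = re.compile(r"Total DFT energy\s*=\s*(-?\d+(?:\.\d+)?)")
_THERMO_RE = re.compile(
    r"Thermal correction to Free Energy\s*=\s*(-?\d+(?:\.\d+)?)\s*kcal/mol"
)
_TERMINATION_RE = re.compile(r"Total times\s+cpu")


def parse_engine_output(
    text: str,
    method: Optional[MethodSpec] = None,
    n_atoms: Optional[int] = None,
) -> tuple[ShieldingResult, EnergyResult]:
    """Parse engine output text into shieldings and energies.

    Shielding lines are matched inside the ``Chemical Shielding`` section;
    an output without that section yields empty shieldings while energies
    are still extracted.  A missing normal-termination marker sets
    ``converged=False`` rather than raising.
    """
    shieldings: dict[int, float] = {}
    in_section = False
    for line in text.splitlines():
        if _SHIELDING_HEADER_RE.search(line):
            in_section = True
            continue
        if in_section:
            m = _ISOTROPIC_RE.match(line)
            if m:
                idx = int(m.group(1))
                if n_atoms is not None and idx > n_atoms:
                    raise ParseError(
                        f"shielding atom index {idx} exceeds geometry size {n_atoms}"
                    )
                shieldings[idx] = float(m.group(2))
            elif line.strip() and "isotropic" in line:
                raise ParseError(f"unparseable shielding line: {line!r}")
    energies = _ENERGY_RE.findall(text)
    electronic = float(energies[-1]) if energies else None
    free_energy = None
    thermo = _THERMO_RE.findall(text)
    if thermo and electronic is not None:
        # G = E_elec + (thermal correction to G) as printed by the engine.
        free_energy = hartree_to_kcalmol(electronic) + float(thermo[-1])
    converged = bool(_TERMINATION_RE.search(text))
    return (
        ShieldingResult(shieldings=shieldings, method=method, converged=converged),
        EnergyResult(electronic_hartree=electronic, free_energy_kcalmol=free_energy),
    )


# ---------------------------------------------------------------------------
# Runners


class Runner(Protocol):
    """Execution contract: a runner maps a deck to raw output text."""

    def run(self, deck: str) -> str: ...


# Baseline isotropic shieldings (ppm) and deterministic spread per element
# for the mock engine; values sit in the physically familiar range so that
# downstream referencing produces shift-like numbers.
_MOCK_BASE = {
    "H": 31.5,
    "C": 185.0,
    "N": 245.0,
    "O": 320.0,
    "F": 460.0,
    "Si": 368.0,
    "P": 350.0,
    "S": 700.0,
    "Cl": 950.0,
}
_MOCK_SPREAD = {"H": 4.0, "C": 60.0}

_GEOM_LINE_RE = re.compile(
    r"^\s*([A-Z][a-z]?)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)
_SHIELD_DIRECTIVE_RE = re.compile(r"^\s*shielding\s+\d+((?:\s+\d+)+)\s*$")


def _deck_geometry(deck: str) -> list[tuple[str, float, float, float]]:
    atoms = []
    in_geom = False
    for line in deck.splitlines():
        stripped = line.strip().lower()
        if stripped.startswith("geometry"):
            in_geom = True
            continue
        if in_geom and stripped == "end":
            break
        if in_geom:
            m = _GEOM_LINE_RE.match(line)
            if m:
                atoms.append(
                    (m.group(1), float(m.group(2)), float(m.group(3)), float(m.group(4)))
                )
    return atoms


class MockRunner:
    """Deterministic stand-in engine for tests and offline runs.

    Shieldings are a pure function of each atom's element and printed
    coordinates (a hash-derived perturbation around an element baseline),
    so identical decks always yield identical output and distinct
    geometries yield distinct, reproducible values.
    """

    def run(self, deck: str) -> str:
        atoms = _deck_geometry(deck)
        if not atoms:
            raise BackendError("mock engine: deck has no geometry block")
        requested: Optional[list[int]] = None
        for line in deck.splitlines():
            m = _SHIELD_DIRECTIVE_RE.match(line)
            if m:
                requested = [int(t) for t in m.group(1).split()]
        lines = [" Mock quantum-chemistry engine output (synthetic)", ""]
        energy = 0.0
        for i, (el, x, y, z) in enumerate(atoms, start=1):
            energy -= self._element_energy(el) + 1e-4 * self._unit_hash(
                f"E|{el}|{i}|{x:.6f}|{y:.6f}|{z:.6f}"
            )
        lines.append(f"         Total DFT energy =     {energy:.9f}")
        lines.append("")
        if requested is not None:
            lines.append("      Chemical Shielding Tensors (GIAO), mock dialect")
            for idx in requested:
                el, x, y, z = atoms[idx - 1]
                sigma = self.shielding_for(el, x, y, z)
                lines.append(f"   {idx}   {el}   isotropic =   {sigma:.4f}")
            lines.append("")
        if "task dft frequency" in deck:
            corr = 10.0 + 2.0 * self._unit_hash(f"G|{len(atoms)}|{energy:.6f}")
            lines.append(
                f" Thermal correction to Free Energy  =   {corr:.3f} kcal/mol"
            )
            lines.append("")
        lines.append(" Total times  cpu:        0.1s     wall:        0.1s")
        return "\n".join(lines) + "\n"

    @staticmethod
    def _unit_hash(key: str) -> float:
        digest = hashlib.sha256(key.encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2**64

    @classmethod
    def shielding_for(cls, el: str, x: float, y: float, z: float) -> float:
        base = _MOCK_BASE.get(el, 300.0)
        spread = _MOCK_SPREAD.get(el, 20.0)
        u = cls._unit_hash(f"S|{el}|{x:.6f}|{y:.6f}|{z:.6f}")
        return round(base + spread * (2.0 * u - 1.0), 4)

    @staticmethod
    def _element_energy(el: str) -> float:
        return {"H": 0.5, "C": 37.8, "N": 54.4, "O": 74.9, "Si": 288.9}.get(el, 40.0)


@dataclass
class ExternalRunner:
    """Adapter around a local engine executable (e.g. ``nwchem``)."""

    command: str
    timeout: Optional[float] = None

    def run(self, deck: str) -> str:
        import tempfile

        exe = self.command.split()[0]
        if shutil.which(exe) is None:
            raise EngineUnavailableError(
                f"engine executable not found on PATH: {exe!r}"
            )
        with tempfile.TemporaryDirectory() as tmp:
            deck_path = Path(tmp) / "input.nw"
            deck_path.write_text(deck)
            proc = subprocess.run(
                self.command.split() + [str(deck_path)],
                capture_output=True,
                text=True,
                timeout=self.timeout,
                cwd=tmp,
            )
            return proc.stdout + proc.stderr


def run_backend(deck: str, runner: Runner, identity: str = "") -> str:
    """Execute a deck through a runner; failures carry the deck identity."""
    try:
        return runner.run(deck)
    except BackendError as exc:
        raise BackendError(f"{identity or 'deck'}: {exc}") from exc
    except Exception as exc:
        raise BackendError(f"{identity or 'deck'}: runner failed: {exc}") from exc
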