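"""Molecule input/output: InChI, XYZ, and MDL Molfile with per-atom data.

A :class:`MoleculeRecord` is the canonical in-memory molecule: an ordered
atom list whose order is frozen at creation and preserved through every
derived file (input deck, engine output, Molfile).  Atom indices are
1-based throughout the package, matching Molfile and NWChem conventions.

Per-atom results (isotropic shieldings, chemical shifts, scaled shifts,
experimental shifts) travel as named SDF data fields appended to a V2000
Molfile, one whitespace-separated value per atom in record order, with
``NA`` marking atoms that carry no value.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDetermineBonds

from shiftkit.errors import MoleculeError

RDLogger.DisableLog("rdApp.*")

#: Default seed for distance-geometry embedding; fixed so that a rough 3D
#: structure is reproducible run to run.  Overridable per call.
DEFAULT_EMBED_SEED = 20

#: Fixed print precision: coordinates (Å) and ppm values.
COORD_DECIMALS = 6
PPM_DECIMALS = 4

# SDF data-field names carrying per-atom values.
FIELD_SHIELDINGS = "ISOTROPIC_SHIELDINGS"
FIELD_SHIFTS = "CHEMICAL_SHIFTS"
FIELD_SCALED = "SCALED_SHIFTS"
FIELD_EXPERIMENTAL = "EXPERIMENTAL_SHIFTS"

_PERIODIC_TABLE = Chem.GetPeriodicTable()


def _validate_element(symbol: str) -> str:
    try:
        if _PERIODIC_TABLE.GetAtomicNumber(symbol) <= 0:
            raise ValueError
    except Exception:
        raise MoleculeError(f"unknown element symbol: {symbol!r}") from None
    return symbol


@dataclass
class MoleculeRecord:
    """One molecule: name, ordered atoms, optional experimental shifts.

    Parameters
    ----------
    name:
        InChIKey for InChI-derived molecules, file basename for XYZ input.
    atoms:
        Ordered ``(element, x, y, z)`` tuples in Å.  The order is frozen:
        every derived file and per-atom array uses this order.
    inchi:
        Source InChI when the molecule came from an identifier.
    exp_shifts:
        Sparse 1-based map ``atom_index -> experimental shift (ppm)``.
    charge:
        Net molecular charge.
    mol:
        Optional RDKit molecule carrying bonds (same atom order); used for
        Molfile export and environment perception.
    """

    name: str
    atoms: list[tuple[str, float, float, float]]
    inchi: Optional[str] = None
    exp_shifts: dict[int, float] = field(default_factory=dict)
    charge: int = 0
    mol: Optional[Chem.Mol] = None

    def __post_init__(self) -> None:
        for el, x, y, z in self.atoms:
            _validate_element(el)
            if not all(math.isfinite(c) for c in (x, y, z)):
                raise MoleculeError(f"non-finite coordinate on atom {el}")
        for idx in self.exp_shifts:
            if not 1 <= idx <= len(self.atoms):
                raise MoleculeError(
                    f"experimental shift index {idx} outside 1..{len(self.atoms)}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a[0] for a in self.atoms]


def inchi_to_inchikey(inchi: str) -> str:
    """Hash an InChI into its fixed-length 27-character InChIKey."""
    if not isinstance(inchi, str) or not inchi.startswith("InChI="):
        raise MoleculeError(f"not an InChI string: {inchi!r}")
    if Chem.MolFromInchi(inchi) is None:
        raise MoleculeError(f"unparseable InChI: {inchi!r}")
    key = Chem.InchiToInchiKey(inchi)
    if not key:
        raise MoleculeError(f"InChIKey generation failed for {inchi!r}")
    return key


def embed_3d(inchi: str, seed: int = DEFAULT_EMBED_SEED) -> MoleculeRecord:
    """Generate a rough 3D structure for an InChI by classical force field.

    Explicit hydrogens are added, coordinates come from distance-geometry
    embedding refined with MMFF94, and the result is deterministic for a
    fixed ``seed``.  The record is named by the molecule's InChIKey.
    """
    mol = Chem.MolFromInchi(inchi)
    if mol is None:
        raise MoleculeError(f"unparseable InChI: {inchi!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise MoleculeError(f"3D embedding failed for {inchi!r}")
    try:
        AllChem.MMFFOptimizeMolecule(mol)
    except Exception:
        pass  # keep the raw embedding if the force field lacks parameters
    conf = mol.GetConformer()
    atoms = [
        (
            atom.GetSymbol(),
            conf.GetAtomPosition(i).x,
            conf.GetAtomPosition(i).y,
            conf.GetAtomPosition(i).z,
        )
        for i, atom in enumerate(mol.GetAtoms())
    ]
    return MoleculeRecord(
        name=inchi_to_inchikey(inchi),
        atoms=atoms,
        inchi=inchi,
        charge=Chem.GetFormalCharge(mol),
        mol=mol,
    )


def read_xyz(path: str | Path) -> MoleculeRecord:
    """Read a free-format XYZ file (count line, comment, element x y z)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise MoleculeError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise MoleculeError(f"bad XYZ count line in {path}") from None
    atoms: list[tuple[str, float, float, float]] = []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise MoleculeError(f"bad XYZ atom line in {path}: {ln!r}")
        atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    if len(atoms) != n:
        raise MoleculeError(f"XYZ file {path} declares {n} atoms, found {len(atoms)}")
    record = MoleculeRecord(name=path.stem, atoms=atoms)
    record.mol = _mol_from_record(record)
    return record


def write_xyz(record: MoleculeRecord, path: str | Path) -> None:
    """Write a record as XYZ with fixed coordinate precision."""
    lines = [str(record.n_atoms), record.name]
    for el, x, y, z in record.atoms:
        lines.append(
            f"{el} {x:.{COORD_DECIMALS}f} {y:.{COORD_DECIMALS}f} {z:.{COORD_DECIMALS}f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _mol_from_record(record: MoleculeRecord) -> Optional[Chem.Mol]:
    """Build an RDKit molecule (with perceived bonds) preserving atom order."""
    rw = Chem.RWMol()
    for el, *_ in record.atoms:
        rw.AddAtom(Chem.Atom(el))
    conf = Chem.Conformer(record.n_atoms)
    for i, (_, x, y, z) in enumerate(record.atoms):
        conf.SetAtomPosition(i, (x, y, z))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineConnectivity(mol)
    except Exception:
        return mol  # geometry too odd for bond perception; atoms-only
    return mol


def parse_molecule_list(path: str | Path) -> list[MoleculeRecord]:
    """Read a molecule list (XLSX/CSV/TSV, one column) into records.

    Each row is either an InChI string (embedded to 3D, named by InChIKey)
    or a path to an XYZ file (read verbatim, named by basename; relative
    paths resolve against the list file's directory).
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeError(f"molecule list not found: {path}")
    rows = _read_single_column(path)
    records: list[MoleculeRecord] = []
    for i, cell in enumerate(rows, start=1):
        cell = cell.strip()
        if not cell:
            continue
        if cell.startswith("InChI="):
            try:
                records.append(embed_3d(cell))
            except MoleculeError as exc:
                raise MoleculeError(f"row {i} of {path.name}: {exc}") from exc
        else:
            xyz = Path(cell)
            if not xyz.is_absolute():
                xyz = path.parent / xyz
            if not xyz.exists():
                raise MoleculeError(
                    f"row {i} of {path.name}: neither an InChI nor an existing "
                    f"XYZ file: {cell!r}"
                )
            records.append(read_xyz(xyz))
    return records


def _read_single_column(path: Path) -> list[str]:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path, header=None, dtype=str)
        if df.empty:
            return []
        return [v for v in df.iloc[:, 0].tolist() if isinstance(v, str)]
    if suffix not in {".tsv", ".csv", ".txt", ""}:
        raise MoleculeError(f"unsupported list format: {path.suffix!r}")
    # Text lists are one entry per line.  InChI strings legitimately
    # contain commas, so rows are only ever split on tabs.
    rows = []
    for line in path.read_text().splitlines():
        cell = line.split("\t")[0].strip()
        if cell:
            rows.append(cell)
    return rows


def _format_atom_values(
    values: Optional[Mapping[int, float]], n_atoms: int
) -> str:
    tokens = []
    for i in range(1, n_atoms + 1):
        if values is not None and i in values:
            tokens.append(f"{values[i]:.{PPM_DECIMALS}f}")
        else:
            tokens.append("NA")
    return " ".join(tokens)


def write_molfile_with_properties(
    record: MoleculeRecord,
    shieldings: Optional[Mapping[int, float]] = None,
    shifts: Optional[Mapping[int, float]] = None,
    scaled: Optional[Mapping[int, float]] = None,
) -> str:
    """Render an SDF block: V2000 Molfile plus per-atom data fields.

    Every supplied map is keyed by 1-based atom index in record order and
    must not reference atoms outside the record.  Experimental shifts on
    the record are always written so they round-trip through
    :func:`read_experimental_shifts`.
    """
    for label, mapping in (
        (FIELD_SHIELDINGS, shieldings),
        (FIELD_SHIFTS, shifts),
        (FIELD_SCALED, scaled),
        (FIELD_EXPERIMENTAL, record.exp_shifts),
    ):
        if mapping:
            bad = [i for i in mapping if not 1 <= i <= record.n_atoms]
            if bad:
                raise MoleculeError(
                    f"{label}: atom indices {bad} outside 1..{record.n_atoms}"
                )
    mol = record.mol if record.mol is not None else _mol_from_record(record)
    if mol is None or mol.GetNumAtoms() != record.n_atoms:
        raise MoleculeError("record has no consistent RDKit molecule")
    mol = Chem.Mol(mol)
    mol.SetProp("_Name", record.name)
    block = Chem.MolToMolBlock(mol, kekulize=True)
    fields = []
    for label, mapping in (
        (FIELD_SHIELDINGS, shieldings),
        (FIELD_SHIFTS, shifts),
        (FIELD_SCALED, scaled),
        (FIELD_EXPERIMENTAL, record.exp_shifts or None),
    ):
        if mapping is not None:
            fields.append(
                f">  <{label}>\n{_format_atom_values(mapping, record.n_atoms)}\n"
            )
    return block + "\n" + "\n".join(fields) + "\n$$$$\n"


_FIELD_RE = re.compile(r">\s+<([A-Z_]+)>\s*\n([^\n]*)\n")


def read_molfile_fields(molfile_text: str) -> dict[str, dict[int, float]]:
    """Parse all per-atom data fields from an SDF block written by us."""
    out: dict[str, dict[int, float]] = {}
    for name, payload in _FIELD_RE.findall(molfile_text):
        values: dict[int, float] = {}
        for i, tok in enumerate(payload.split(), start=1):
            if tok == "NA":
                continue
            try:
                values[i] = float(tok)
            except ValueError:
                raise MoleculeError(
                    f"malformed value {tok!r} in field {name}"
                ) from None
        out[name] = values
    return out


def read_experimental_shifts(molfile_text: str) -> dict[int, float]:
    """Extract the sparse experimental-shift map from a Molfile block.

    Atoms without a value are absent from the map, never zero-filled; a
    file lacking the field yields an empty map.
    """
    return read_molfile_fields(molfile_text).get(FIELD_EXPERIMENTAL, {})


def read_molfile(molfile_text: str) -> MoleculeRecord:
    """Read an SDF block back into a record (atom order preserved)."""
    mol = Chem.MolFromMolBlock(molfile_text, removeHs=False, sanitize=False)
    if mol is None:
        raise MoleculeError("unparseable Molfile block")
    conf = mol.GetConformer()
    atoms = [
        (
            atom.GetSymbol(),
            conf.GetAtomPosition(i).x,
            conf.GetAtomPosition(i).y,
            conf.GetAtomPosition(i).z,
        )
        for i, atom in enumerate(mol.GetAtoms())
    ]
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else "molecule"
    return MoleculeRecord(
        name=name,
        atoms=atoms,
        exp_shifts=read_experimental_shifts(molfile_text),
        mol=mol,
    )
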