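"""Structure I/O: PQR/PDB reading, atom/residue typing, dataset manifests.

A *complex* here is a protein assembly split into a ligand chain set and a
receptor chain set (e.g. ``"AB:C"`` puts chains A and B on the ligand side
and chain C on the receptor side).  Structures arrive as PQR files — the
PDB-like dialect in which the occupancy and B-factor columns are replaced by
per-atom partial charge (e) and radius (Å) — or as plain PDB files, in which
case charges may be filled in from the typing table's default-charge map.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel for atoms whose atom/residue class could not be assigned
UNTYPED: int = -1

N_ATOM_TYPES: int = 18
N_RESIDUE_TYPES: int = 20

STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}


class PQRParseError(ValueError):
    """Raised when a structure record cannot be parsed; names the line."""


@dataclass
class Atom:
    """One atom record with optional charge/radius and assigned types."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    charge: float | None = None
    radius: float | None = None
    atom_type: int = UNTYPED
    residue_type: int = UNTYPED

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        n = self.name.lstrip("0123456789")
        return n.startswith("H") or n.startswith("D")


@dataclass
class Complex:
    """A structure with a ligand/receptor chain partition and a class label."""

    id: str
    atoms: list[Atom]
    ligand_chains: frozenset[str] = frozenset()
    receptor_chains: frozenset[str] = frozenset()
    label: str | None = None

    def __post_init__(self) -> None:
        if self.ligand_chains & self.receptor_chains:
            raise ValueError(f"{self.id}: ligand and receptor chain sets overlap")

    @property
    def partitioned(self) -> bool:
        return bool(self.ligand_chains) and bool(self.receptor_chains)

    def side(self, which: str) -> list[Atom]:
        chains = self.ligand_chains if which == "ligand" else self.receptor_chains
        return [a for a in self.atoms if a.chain_id in chains]

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in atoms])


@dataclass
class TypingTable:
    """Maps (residue, atom name) to one of 18 atom classes, residues to one
    of 20 classes, and carries the symmetric 18x18 atomic contact potential
    (ACP) matrix used by the desolvation energy model.

    The packaged default (``typing_table_synthetic.json``) is a synthetic
    stand-in: an 18-class grouping by element/polarity with an ACP built from
    per-class solvation propensities.  Published ACP tables can be dropped in
    via :meth:`from_json` without code changes.
    """

    atom_map: dict[tuple[str, str], int]
    residue_map: dict[str, int]
    acp: np.ndarray
    default_charge: dict[tuple[str, str], float] = field(default_factory=dict)
    atom_type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.acp = np.asarray(self.acp, dtype=float)
        if self.acp.shape != (N_ATOM_TYPES, N_ATOM_TYPES):
            raise ValueError("ACP matrix must be 18x18")
        if not np.allclose(self.acp, self.acp.T):
            raise ValueError("ACP matrix must be symmetric")
        if any(not (0 <= t < N_ATOM_TYPES) for t in self.atom_map.values()):
            raise ValueError("atom_map values must lie in [0, 18)")
        missing = set(STANDARD_RESIDUES) - set(self.residue_map)
        if missing:
            raise ValueError(f"residue_map misses standard residues: {sorted(missing)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "TypingTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: dict) -> "TypingTable":
        residues = raw.get("residue_names", list(STANDARD_RESIDUES))
        atom_map = {}
        for key, t in raw["atom_map"].items():
            res, name = key.split()
            atom_map[(res, name)] = int(t)
        charge = {}
        for key, q in raw.get("default_charge", {}).items():
            res, name = key.split()
            charge[(res, name)] = float(q)
        return cls(
            atom_map=atom_map,
            residue_map={r: i for i, r in enumerate(residues)},
            acp=np.asarray(raw["acp"], dtype=float),
            default_charge=charge,
            atom_type_names=list(raw.get("atom_type_names", [])),
        )

    @classmethod
    def default(cls) -> "TypingTable":
        ref = resources.files("ppitype.data") / "typing_table_synthetic.json"
        return cls._from_dict(json.loads(ref.read_text()))

    def residue_type_names(self) -> list[str]:
        inv = sorted(self.residue_map, key=self.residue_map.get)
        return inv


_DEFAULT_TABLE: TypingTable | None = None


def default_table() -> TypingTable:
    """Cached packaged typing table."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = TypingTable.default()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# PQR / PDB reading and writing
# ---------------------------------------------------------------------------

def _parse_pqr_fields(fields: list[str], lineno: int) -> Atom:
    # PQR whitespace dialect: ATOM serial name resname [chain] resseq x y z q r
    # chain id is optional (pdb2pqr --chain includes it)
    try:
        serial = int(fields[1])
        name = fields[2]
        resname = fields[3]
        if fields[4].isalpha():
            chain = fields[4]
            rest = fields[5:]
        else:
            chain = ""
            rest = fields[4:]
        resseq = int("".join(c for c in rest[0] if c.isdigit() or c == "-"))
        x, y, z, q, r = (float(v) for v in rest[1:6])
    except (IndexError, ValueError) as exc:
        raise PQRParseError(f"line {lineno}: malformed PQR record ({exc})") from exc
    return Atom(serial, name, resname, chain, resseq, np.array([x, y, z]),
                charge=q, radius=r)


def read_pqr(path: str | Path, *, keep_hetero: bool = False,
             keep_waters: bool = False) -> Complex:
    """Read a PQR file into a :class:`Complex` (partition unset).

    HETATM records and waters are skipped unless the corresponding flag is
    set.  Raises :class:`PQRParseError` (naming the offending line) on a
    malformed record and ``ValueError`` on a file with no atoms.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            rec = fields[0] if fields else ""
            if rec not in ("ATOM", "HETATM"):
                continue
            atom = _parse_pqr_fields(fields, lineno)
            if rec == "HETATM" and not keep_hetero:
                continue
            if atom.residue_name in _WATER_NAMES and not keep_waters:
                continue
            atoms.append(atom)
    if not atoms:
        raise ValueError(f"{path}: no atom records")
    return Complex(id=path.stem, atoms=atoms)


def write_pqr(cplx: Complex, path: str | Path) -> None:
    """Write ATOM records in the whitespace PQR dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for a in cplx.atoms:
            q = 0.0 if a.charge is None else a.charge
            r = 0.0 if a.radius is None else a.radius
            chain = a.chain_id or ""
            fh.write(
                f"ATOM {a.serial:6d} {a.name:<4s} {a.residue_name:<4s} "
                f"{chain:<1s} {a.residue_seq:5d} "
                f"{a.coords[0]:10.3f} {a.coords[1]:10.3f} {a.coords[2]:10.3f} "
                f"{q:8.4f} {r:7.4f}\n"
            )
        fh.write("END\n")


def read_pdb(path: str | Path, *, keep_hetero: bool = False) -> Complex:
    """Read a plain fixed-column PDB file (no charges/radii) via Biopython."""
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            het = residue.id[0].strip()
            if het and not keep_hetero:
                continue
            if residue.resname in _WATER_NAMES:
                continue
            for at in residue:
                if at.get_altloc() not in (" ", "A"):
                    continue
                atoms.append(Atom(
                    serial=at.serial_number, name=at.get_name(),
                    residue_name=residue.resname, chain_id=chain.id,
                    residue_seq=residue.id[1], coords=np.array(at.coord, float),
                ))
    if not atoms:
        raise ValueError(f"{path}: no atom records")
    return Complex(id=path.stem, atoms=atoms)


def read_structure(path: str | Path, **kw) -> Complex:
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return read_pdb(path, **kw)
    return read_pqr(path, **kw)


# ---------------------------------------------------------------------------
# Typing
# ---------------------------------------------------------------------------

def assign_types(cplx: Complex, table: TypingTable | None = None) -> Complex:
    """Assign atom and residue class indices in place (idempotent).

    Atoms of nonstandard residues, hydrogens, and atoms absent from the
    table stay :data:`UNTYPED`; they are excluded from feature accumulation
    downstream.  Missing charges are filled from the table's default-charge
    map when available (zero otherwise) so plain PDB inputs remain usable
    with the electrostatic model.
    """
    table = table or default_table()
    n_untyped = 0
    for atom in cplx.atoms:
        rt = table.residue_map.get(atom.residue_name, UNTYPED)
        at = table.atom_map.get((atom.residue_name, atom.name), UNTYPED)
        atom.residue_type = rt
        atom.atom_type = at if rt != UNTYPED else UNTYPED
        if atom.atom_type == UNTYPED:
            n_untyped += 1
        if atom.charge is None:
            atom.charge = table.default_charge.get(
                (atom.residue_name, atom.name), 0.0)
    if n_untyped:
        logger.info("%s: %d atoms left untyped", cplx.id, n_untyped)
    return cplx


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def parse_partition(text: str) -> tuple[frozenset[str], frozenset[str]]:
    """Parse ``"AB:C"`` into (ligand chains {A,B}, receptor chains {C})."""
    parts = text.strip().split(":")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(f"unparseable chain partition: {text!r}")
    lig, rec = frozenset(parts[0]), frozenset(parts[1])
    if lig & rec:
        raise ValueError(f"partition sides share chains: {text!r}")
    return lig, rec


def load_manifest(path: str | Path, table: TypingTable | None = None,
                  *, assign: bool = True) -> list[Complex]:
    """Load a dataset manifest (CSV with columns file, partition, label).

    Structure paths are resolved relative to the manifest's directory.  Rows
    whose structure file is missing are skipped with a warning; an
    unparseable partition string raises.  Returns typed, partitioned,
    labelled complexes in manifest row order.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, skipinitialspace=True)
    required = {"file", "partition", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    if df.empty:
        warnings.warn(f"{path}: empty manifest")
        return []
    out: list[Complex] = []
    for row in df.itertuples(index=False):
        spath = Path(str(row.file))
        if not spath.is_absolute():
            spath = path.parent / spath
        if not spath.exists():
            warnings.warn(f"{path}: missing structure file {spath}, row skipped")
            continue
        lig, rec = parse_partition(str(row.partition))
        cplx = read_structure(spath)
        cplx.ligand_chains, cplx.receptor_chains = lig, rec
        cplx.label = str(row.label)
        cplx.id = f"{spath.stem} {row.partition}"
        if assign:
            assign_types(cplx, table)
        out.append(cplx)
    return out
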