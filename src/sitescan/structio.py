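"""Structure, pose and sequence I/O.

Uniform coordinate model over the three text formats the pipeline touches:

* PDB (single- or multi-model; a multi-model file doubles as a trajectory),
* PDBQT in the docking-output dialect (multi-MODEL with
  ``REMARK VINA RESULT`` score lines),
* FASTA.

PDB and PDBQT share one fixed-width record grammar, so both are handled by
a single tokenizer.  The writer emits fixed-width records that are
bit-identical across runs; ``write_pdb(read_pdb(f))`` preserves atom count,
ordering and coordinates to the format's three-decimal precision.

Hydrogens are read but flagged ``is_heavy=False`` and excluded from all
distance/contact computations downstream.  Alternate locations keep the
highest-occupancy copy (ties resolved to the first seen).  Residue
numbering is taken verbatim from the file — no re-indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

__all__ = [
    "Atom",
    "Structure",
    "Pose",
    "PoseSet",
    "read_pdb",
    "write_pdb",
    "read_pdbqt_poses",
    "write_pdbqt_poses",
    "read_fasta",
    "write_fasta",
]

# Two-letter element symbols that can appear left-justified in the PDB atom
# name column.  "CA"/"CD" etc. are deliberately absent: inside protein ATOM
# records those are carbons.
_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "FE", "ZN", "MG", "MN", "NA", "NI", "CU", "CO", "SE", "CD",
}


@dataclass
class Atom:
    """One atom record with author numbering preserved."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    xyz: np.ndarray
    element: str = ""
    icode: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    record: str = "ATOM"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValidationError(f"atom {self.serial}: xyz must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            self.element = infer_element(self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, resid, icode) — insertion codes are part of identity."""
        return (self.chain, self.resid, self.icode)


def infer_element(name: str) -> str:
    """Derive the element from a PDB atom-name field.

    Works on either the raw 4-character column or a stripped name.  Digits
    and primes are ignored; a leading two-letter symbol is honoured only for
    the unambiguous (hetero/metal) set, so ``CA`` stays carbon.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2]
    return stripped[0]


class Structure:
    """An ordered stack of frames (models), each a list of :class:`Atom`.

    For multi-model files intended as trajectories every frame must share
    atom count and ordering; this is enforced at read time.
    """

    def __init__(self, models: Sequence[Sequence[Atom]], id: str = "") -> None:
        if not models or not models[0]:
            raise ValidationError("Structure requires at least one non-empty model")
        self.models: list[list[Atom]] = [list(m) for m in models]
        self.id = id

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0])

    def __len__(self) -> int:
        return self.n_models

    def coords(self, model_index: int = 0) -> np.ndarray:
        """(n_atoms, 3) array of one frame."""
        return np.array([a.xyz for a in self.models[model_index]], dtype=float)

    def atoms(self, model_index: int = 0) -> list[Atom]:
        return self.models[model_index]

    def heavy_atoms(self, model_index: int = 0) -> list[Atom]:
        return [a for a in self.models[model_index] if a.is_heavy]

    def select(self, predicate, model_index: int = 0) -> list[int]:
        """Indices of atoms in a frame satisfying ``predicate(atom)``."""
        return [i for i, a in enumerate(self.models[model_index]) if predicate(a)]

    def residues(self, model_index: int = 0) -> list[tuple[str, int, str, str]]:
        """Ordered unique (chain, resid, icode, resname) of one frame."""
        seen: dict[tuple[str, int, str], str] = {}
        for a in self.models[model_index]:
            seen.setdefault(a.residue_key, a.resname)
        return [(c, r, i, n) for (c, r, i), n in seen.items()]

    def copy(self) -> "Structure":
        return Structure(
            [[replace(a, xyz=a.xyz.copy()) for a in m] for m in self.models],
            id=self.id,
        )


@dataclass
class Pose:
    """One docked conformation: heavy-atom coordinates plus score."""

    model_index: int
    coords: np.ndarray
    affinity: float
    rank: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.rank < 1:
            raise ValidationError(f"pose rank must be >= 1, got {self.rank}")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("pose coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"pose rank {self.rank}: non-finite coordinates")


@dataclass
class PoseSet:
    """All docked poses of one ligand against one receptor conformation."""

    ligand_id: str
    category: str
    poses: list[Pose]
    receptor_conformation_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in ("substrate", "non-substrate", "unknown"):
            raise ValidationError(
                f"category must be substrate/non-substrate/unknown, got {self.category!r}"
            )
        ranks = [p.rank for p in self.poses]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"pose ranks must be consecutive from 1, got {ranks}"
            )
        affinities = [p.affinity for p in self.poses]
        if any(b < a - 1e-9 for a, b in zip(affinities, affinities[1:])):
            warnings.warn(
                f"{self.ligand_id}: affinities not non-decreasing with rank",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# fixed-width record grammar (shared by PDB and PDBQT)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, *, pdbqt: bool = False) -> Atom:
    try:
        serial = int(line[6:11])
        name_raw = line[12:16]
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed atom record: {line.rstrip()!r}") from exc
    occ_field = line[54:60].strip()
    bfac_field = line[60:66].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    bfactor = float(bfac_field) if bfac_field else 0.0
    # PDBQT replaces the element column with an AutoDock atom type; fall back
    # to name-based inference there.
    element = "" if pdbqt else line[76:78].strip()
    if not element:
        element = infer_element(name_raw)
    return Atom(
        serial=serial,
        name=name_raw.strip(),
        resname=resname,
        chain=chain,
        resid=resid,
        icode=icode,
        altloc=altloc,
        xyz=np.array([x, y, z]),
        element=element,
        occupancy=occupancy,
        bfactor=bfactor,
        record=line[:6].strip(),
    )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy alternate location per atom (ties → first)."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain, a.resid, a.icode, a.name)
        j = best.get(key)
        if j is None or atoms[j].occupancy < a.occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [atoms[i] for i in keep]


def _iter_model_blocks(lines: Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    """Yield (model_number, lines) per MODEL block; whole file if none."""
    current: list[str] | None = None
    number = 0
    saw_model = False
    prelude: list[str] = []
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            try:
                number = int(line.split()[1])
            except (IndexError, ValueError):
                number += 1
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                yield number, current
            current = None
        elif current is not None:
            current.append(line)
        else:
            prelude.append(line)
    if current is not None:  # MODEL without ENDMDL: tolerate
        yield number, current
    if not saw_model:
        yield 1, prelude


def read_pdb(path: str | Path, model_policy: str = "all") -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    ``model_policy='first'`` keeps only the first frame.  Under
    ``model_policy='all'`` every model must have the same atom count and
    ordering; the first offending model is named in the error.
    """
    if model_policy not in ("all", "first"):
        raise ValidationError(f"model_policy must be 'all' or 'first', got {model_policy!r}")
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc

    models: list[list[Atom]] = []
    model_numbers: list[int] = []
    for number, block in _iter_model_blocks(lines):
        atoms = [
            _parse_atom_line(ln)
            for ln in block
            if ln[:6].strip() in ("ATOM", "HETATM")
        ]
        if not atoms:
            continue
        models.append(_resolve_altlocs(atoms))
        model_numbers.append(number)
        if model_policy == "first":
            break
    if not models:
        raise FormatError(f"{path}: no ATOM/HETATM records")

    if model_policy == "all" and len(models) > 1:
        ref_sig = [(a.chain, a.resid, a.icode, a.name) for a in models[0]]
        for k, model in enumerate(models[1:], start=1):
            sig = [(a.chain, a.resid, a.icode, a.name) for a in model]
            if sig != ref_sig:
                raise FormatError(
                    f"{path}: model {model_numbers[k]} has inconsistent atoms "
                    f"(count {len(model)} vs {len(models[0])} in model "
                    f"{model_numbers[0]})"
                )
    return Structure(models, id=path.stem)


def _format_atom_name(name: str, element: str) -> str:
    """PDB name column: 1-letter elements start at column 14."""
    if len(name) >= 4 or len(element) == 2:
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)


def _atom_line(a: Atom, serial: int) -> str:
    return (
        f"{a.record:<6s}{serial:>5d} {_format_atom_name(a.name, a.element)}"
        f"{a.altloc or ' '}{a.resname:>3s} {a.chain or ' '}{a.resid:>4d}"
        f"{a.icode or ' '}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-width PDB records, MODEL/ENDMDL when multi-frame."""
    path = Path(path)
    out: list[str] = []
    multi = structure.n_models > 1
    for m, model in enumerate(structure.models, start=1):
        if multi:
            out.append(f"MODEL     {m:>4d}")
        for i, a in enumerate(model, start=1):
            out.append(_atom_line(a, i))
        if multi:
            out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PDBQT docking output
# ---------------------------------------------------------------------------

_VINA_TAG = "REMARK VINA RESULT:"


def read_pdbqt_poses(
    path: str | Path,
    ligand_id: str,
    category: str = "unknown",
    receptor_conformation_id: str = "",
) -> PoseSet:
    """Parse a docking-output multi-MODEL PDBQT file into a :class:`PoseSet`.

    One pose per MODEL; the affinity is the first numeric field of the
    ``REMARK VINA RESULT`` line; only heavy atoms are retained.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not any(ln[:6].strip() == "MODEL" for ln in lines):
        raise FormatError(f"{path}: no MODEL records — not a docking output file")

    poses: list[Pose] = []
    for number, block in _iter_model_blocks(lines):
        affinity = None
        for ln in block:
            if ln.startswith(_VINA_TAG):
                fields = ln[len(_VINA_TAG):].split()
                try:
                    affinity = float(fields[0])
                except (IndexError, ValueError) as exc:
                    raise FormatError(
                        f"{path}: MODEL {number}: malformed result line {ln!r}"
                    ) from exc
                break
        if affinity is None:
            raise FormatError(f"{path}: MODEL {number} has no {_VINA_TAG!r} line")
        atoms = [
            _parse_atom_line(ln, pdbqt=True)
            for ln in block
            if ln[:6].strip() in ("ATOM", "HETATM")
        ]
        heavy = np.array([a.xyz for a in atoms if a.is_heavy], dtype=float)
        if heavy.size == 0:
            raise FormatError(f"{path}: MODEL {number} contains no heavy atoms")
        poses.append(
            Pose(model_index=number, coords=heavy, affinity=affinity, rank=len(poses) + 1)
        )
    return PoseSet(
        ligand_id=ligand_id,
        category=category,
        poses=poses,
        receptor_conformation_id=receptor_conformation_id,
    )


def write_pdbqt_poses(
    path: str | Path,
    coords_per_pose: Sequence[np.ndarray],
    affinities: Sequence[float],
    atom_name: str = "C",
    resname: str = "LIG",
) -> None:
    """Write a minimal Vina-style multi-MODEL PDBQT file (used by synth)."""
    if len(coords_per_pose) != len(affinities):
        raise ValidationError("coords_per_pose and affinities length mismatch")
    out: list[str] = []
    for m, (coords, aff) in enumerate(zip(coords_per_pose, affinities), start=1):
        coords = np.asarray(coords, dtype=float)
        out.append(f"MODEL {m}")
        out.append(f"{_VINA_TAG}    {aff:8.3f}      0.000      0.000")
        for i, xyz in enumerate(coords, start=1):
            a = Atom(
                serial=i, name=atom_name, resname=resname, chain="",
                resid=1, xyz=xyz, element=infer_element(atom_name),
                record="HETATM",
            )
            out.append(_atom_line(a, i))
        out.append("ENDMDL")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, upper-cased sequence), file order preserved."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).strip().upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")
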