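"""Cα-level structure and catalytic-annotation I/O.

A protein is reduced to the ordered list of its α-carbon positions, one
record per residue, with chains concatenated in file order into a single
0-based linear index space. Catalytic-site annotations are plain-text
tables (``structure_id, chain_id, res_seq[, icode]``) in the style of
Catalytic Site Atlas exports, and are mapped onto the linear indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "Residue",
    "CAStructure",
    "AnnotationSet",
    "EmptyStructureError",
    "AnnotationFormatError",
    "read_pdb_calpha",
    "write_pdb_calpha",
    "read_annotations",
    "write_annotations",
    "map_annotations",
]


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no ATOM-record CA atoms."""


class AnnotationFormatError(ValueError):
    """Raised when an annotation table is malformed."""


@dataclass(frozen=True)
class Residue:
    """One Cα record: author identifiers plus equilibrium coordinates (Å)."""

    chain_id: str
    res_seq: int
    icode: str  # "" when absent
    coords: tuple[float, float, float]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class CAStructure:
    """Ordered Cα trace of one structure.

    Residue order preserves file order; the position in ``residues`` is the
    global linear index used by every downstream indicator.
    """

    structure_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.structure_id}: duplicate residue identifiers")
        if not np.all(np.isfinite(self.coords())):
            raise ValueError(f"{self.structure_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """(N, 3) array of Cα positions in Å."""
        return np.asarray([r.coords for r in self.residues], dtype=float).reshape(-1, 3)

    def chain_ids(self) -> np.ndarray:
        """Per-residue chain label, aligned with the linear index."""
        return np.asarray([r.chain_id for r in self.residues])

    def index_of(self, chain_id: str, res_seq: int, icode: str = "") -> int:
        """Linear index of a residue identifier; KeyError if absent."""
        key = (chain_id, res_seq, icode)
        for i, r in enumerate(self.residues):
            if r.key == key:
                return i
        raise KeyError(key)


@dataclass
class AnnotationSet:
    """Catalytic residues of one structure as (chain_id, res_seq, icode) triples."""

    structure_id: str
    sites: set[tuple[str, int, str]] = field(default_factory=set)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def read_pdb_calpha(
    path: str | Path,
    model_policy: str = "first",
    altloc_policy: str = "occupancy",
) -> CAStructure:
    """Read the Cα trace of a PDB file.

    Only ATOM records with atom name CA contribute; HETATM records (waters,
    ligands, and modified residues deposited as heteroatoms) are ignored.
    Alternate locations are resolved by ``altloc_policy``:

    - ``"occupancy"`` (default): keep the conformer with the highest
      occupancy, first encountered winning ties;
    - ``"first"``: keep the first conformer in file order.

    ``model_policy="first"`` keeps only the first MODEL of multi-model files
    (NMR ensembles are out of scope).
    """
    path = Path(path)
    if model_policy != "first":
        raise ValueError(f"unsupported model_policy: {model_policy!r}")
    if altloc_policy not in ("occupancy", "first"):
        raise ValueError(f"unsupported altloc_policy: {altloc_policy!r}")

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - empty file raises in parser
        raise EmptyStructureError(f"{path}: no models")

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetfield, res_seq, icode = res.id
            if hetfield.strip():
                continue  # HETATM record
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                # child_dict preserves insertion (= file) order
                atoms = list(atom.child_dict.values())
                if altloc_policy == "occupancy":
                    occ = [a.get_occupancy() or 0.0 for a in atoms]
                    atom = atoms[int(np.argmax(occ))]  # argmax: first max wins ties
                else:
                    atom = atoms[0]
            # PDB coordinates carry exactly 3 decimals; rounding undoes the
            # float32 storage of the parser losslessly
            x, y, z = (round(float(v), 3) for v in atom.get_coord())
            residues.append(
                Residue(chain.id, int(res_seq), icode.strip(), (x, y, z))
            )
    if not residues:
        raise EmptyStructureError(f"{path}: no ATOM-record CA atoms found")
    return CAStructure(structure_id=path.stem, residues=residues)


_ATOM_FMT = (
    "ATOM  {serial:5d}  CA {altloc}{resname:>3s} {chain:1s}{res_seq:4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {element:>2s}"
)


def write_pdb_calpha(s: CAStructure, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write a Cα-only PDB file (wwPDB v3.3 ATOM records, one per residue).

    Coordinates are printed at 8.3 fixed precision, so structures whose
    coordinates are pre-rounded to 3 decimals round-trip exactly.
    """
    lines = [f"REMARK 999 {h}" for h in header]
    serial = 0
    prev_chain = None
    for r in s.residues:
        if prev_chain is not None and r.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = r.chain_id
        serial += 1
        x, y, z = r.coords
        lines.append(
            _ATOM_FMT.format(
                serial=serial, altloc=" ", resname="GLY", chain=r.chain_id,
                res_seq=r.res_seq, icode=r.icode or " ", x=x, y=y, z=z,
                occ=1.0, bf=0.0, element="C",
            )
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationSet]:
    """Read a catalytic-site table (TSV or CSV, sniffed).

    Mandatory columns ``structure_id, chain_id, res_seq``; optional
    ``icode``. Duplicate rows are deduplicated. Returns one
    :class:`AnnotationSet` per distinct ``structure_id`` in row order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise AnnotationFormatError(f"{path}: empty annotation file (no header)")
    df.columns = [c.strip() for c in df.columns]
    for col in ("structure_id", "chain_id", "res_seq"):
        if col not in df.columns:
            raise AnnotationFormatError(f"{path}: missing mandatory column {col!r}")
    if "icode" not in df.columns:
        df["icode"] = ""
    df["icode"] = df["icode"].fillna("").astype(str).str.strip()

    sets: dict[str, AnnotationSet] = {}
    order: list[str] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.structure_id).strip()
        try:
            res_seq = int(str(row.res_seq).strip())
        except ValueError:
            raise AnnotationFormatError(
                f"{path}, line {lineno}: non-integer res_seq {row.res_seq!r}"
            )
        if sid not in sets:
            sets[sid] = AnnotationSet(structure_id=sid)
            order.append(sid)
        sets[sid].sites.add((str(row.chain_id).strip(), res_seq, row.icode))
    return [sets[sid] for sid in order]


def write_annotations(annotations: Iterable[AnnotationSet], path: str | Path) -> None:
    """Write annotation sets back to a TSV with the canonical header."""
    rows = []
    for ann in annotations:
        for chain_id, res_seq, icode in sorted(ann.sites):
            rows.append((ann.structure_id, chain_id, res_seq, icode))
    df = pd.DataFrame(rows, columns=["structure_id", "chain_id", "res_seq", "icode"])
    df.to_csv(path, sep="\t", index=False)


def map_annotations(s: CAStructure, a: AnnotationSet) -> set[int]:
    """Map annotated residues onto linear indices of ``s``.

    Annotations whose (chain, res_seq, icode) is absent from the structure
    are reported through :mod:`warnings` rather than silently dropped.
    """
    if a.structure_id != s.structure_id:
        raise ValueError(
            f"annotation set {a.structure_id!r} does not match structure {s.structure_id!r}"
        )
    lookup = {r.key: i for i, r in enumerate(s.residues)}
    mapped: set[int] = set()
    unmapped: list[tuple[str, int, str]] = []
    for site in sorted(a.sites):
        if site in lookup:
            mapped.add(lookup[site])
        else:
            unmapped.append(site)
    if unmapped:
        warnings.warn(
            f"{s.structure_id}: {len(unmapped)} annotation(s) not present in "
            f"structure: {unmapped}",
            stacklevel=2,
        )
    return mapped
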