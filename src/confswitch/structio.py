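"""Uniform atomic data model and structure/sequence I/O.

The pipeline works on a flat chain → residue → atom hierarchy with author
residue numbering (1-based) and coordinates in Å.  For predicted models the
B-factor column carries the per-residue pLDDT confidence (0–100).  PDB and
mmCIF parsing is delegated to :mod:`gemmi`; PDB is the only write dialect.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .constants import ONE_TO_THREE, STANDARD_AA3, THREE_TO_ONE
from .errors import CapacityError, StructureFormatError

log = logging.getLogger(__name__)


@dataclass
class Atom:
    name: str
    coord: np.ndarray  # shape (3,), Å
    bfactor: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureFormatError(
                f"atom {self.name}: coordinates must be a finite 3-vector"
            )
        if not self.element:
            self.element = next(
                (c for c in self.name if c.isalpha()), "C"
            ).upper()


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    name: str  # 3-letter code
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def is_complete(self) -> bool:
        return {"N", "CA", "C"} <= self.atoms.keys()

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].coord

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.coord for a in self.atoms.values() if a.element != "H"]
        )

    def add(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise StructureFormatError(
                f"duplicate atom {atom.name} in {self.chain_id}/{self.res_seq}"
            )
        self.atoms[atom.name] = atom


@dataclass
class Structure:
    """An ordered single-model atomic structure (standard residues only)."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str | None = None) -> list[Residue]:
        chains = self.chains()
        if not chain_id:
            if len(chains) != 1:
                raise LookupError(
                    f"{self.id}: chain id required (chains present: {chains})"
                )
            chain_id = chains[0]
            log.debug("%s: defaulting to single chain %r", self.id, chain_id)
        if chain_id not in chains:
            raise LookupError(f"{self.id}: no chain {chain_id!r}")
        return [r for r in self.residues if r.chain_id == chain_id]

    def residue(self, res_seq: int, chain_id: str | None = None) -> Residue:
        for r in self.chain(chain_id):
            if r.res_seq == res_seq:
                return r
        raise LookupError(f"{self.id}: no residue {res_seq}")

    def ca_coords(
        self,
        chain_id: str | None = None,
        res_seqs: Iterable[int] | None = None,
    ) -> tuple[list[int], np.ndarray]:
        """Cα coordinates (and their res_seq labels) in residue order."""
        wanted = None if res_seqs is None else set(res_seqs)
        nums, coords = [], []
        for r in self.chain(chain_id):
            if "CA" not in r.atoms:
                continue
            if wanted is not None and r.res_seq not in wanted:
                continue
            nums.append(r.res_seq)
            coords.append(r.coord("CA"))
        return nums, np.array(coords).reshape(len(nums), 3)

    def atom_table(self) -> list[tuple]:
        return [
            (r.chain_id, r.res_seq, r.name, a.name, *np.round(a.coord, 3),
             round(a.bfactor, 2))
            for r in self.residues
            for a in r.atoms.values()
        ]

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply a rigid transform x -> R x + t in place."""
        for r in self.residues:
            for a in r.atoms.values():
                a.coord = rotation @ a.coord + translation


@dataclass
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise StructureFormatError(f"{self.id}: empty sequence")
        bad = set(self.seq) - set(ONE_TO_THREE)
        if bad:
            raise StructureFormatError(
                f"{self.id}: non-standard letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _gemmi_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt == "mmcif":
        return gemmi.CoorFormat.Mmcif
    return gemmi.CoorFormat.Detect


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB/mmCIF file into the uniform atom model.

    Only the first model is kept; non-standard residues (ligands, waters,
    HETATM chemistry) are dropped with a warning; alternate locations are
    resolved to the highest-occupancy conformer (ties: first listed);
    insertion-coded chains are renumbered sequentially with a logged map.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read structure file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_gemmi_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    if len(st) > 1:
        log.warning("%s: %d models; using the first", path.name, len(st))

    out = Structure(id=path.stem)
    dropped: set[str] = set()
    for chain in st[0]:
        chain_res: list[Residue] = []
        has_icode = False
        for res in chain:
            if res.name not in STANDARD_AA3:
                dropped.add(res.name)
                continue
            if (res.seqid.icode or " ").strip():
                has_icode = True
            # resolve altlocs: group by atom name, keep max occupancy
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            residue = Residue(chain.name, res.seqid.num, res.name)
            for atom in best.values():
                residue.add(
                    Atom(
                        atom.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        bfactor=atom.b_iso,
                        element=atom.element.name or "",
                    )
                )
            if not residue.is_complete:
                log.warning(
                    "%s: residue %s/%s incomplete backbone",
                    path.name, chain.name, res.seqid.num,
                )
            chain_res.append(residue)
        if has_icode:
            mapping = {}
            for new, r in enumerate(chain_res, start=1):
                mapping[r.res_seq] = new
                r.res_seq = new
            log.warning(
                "%s: chain %s has insertion codes; renumbered 1..%d (map: %s)",
                path.name, chain.name, len(chain_res), mapping,
            )
        out.residues.extend(chain_res)
    if dropped:
        log.warning("%s: dropped non-standard residues %s", path.name,
                    sorted(dropped))
    if not out.residues:
        raise StructureFormatError(f"{path}: zero standard amino-acid residues")
    return out


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a Structure as PDB (coords at 3 decimals, B-factor at 2)."""
    if format != "pdb":
        raise StructureFormatError(f"unsupported write format: {format}")
    for cid in s.chains():
        nres = len(s.chain(cid))
        if nres > 9999:
            raise CapacityError(
                f"chain {cid}: {nres} residues exceed PDB capacity (9999)"
            )
    lines = []
    serial = 0
    last_chain = None
    for r in s.residues:
        if last_chain is not None and r.chain_id != last_chain:
            lines.append("TER")
        last_chain = r.chain_id
        for a in r.atoms.values():
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {r.name:>3s} "
                f"{r.chain_id[:1]:1s}{r.res_seq:4d}    "
                f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{1.00:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
            )
    lines += ["TER", "END", ""]
    Path(path).write_text("\n".join(lines))


def extract_sequence(s: Structure, chain: str | None = None) -> SequenceRecord:
    """One-letter sequence of a chain in res_seq order (no gap placeholders)."""
    residues = s.chain(chain)
    seq = "".join(r.one_letter for r in residues)
    cid = residues[0].chain_id if residues else (chain or "")
    return SequenceRecord(id=f"{s.id}_{cid}", seq=seq)


def numbering_map(s: Structure, chain: str | None = None) -> list[int]:
    """res_seq of each position of :func:`extract_sequence`, in order."""
    return [r.res_seq for r in s.chain(chain)]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    from Bio import SeqIO

    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise StructureFormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.seq), 60):
                fh.write(rec.seq[k:k + 60] + "\n")
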