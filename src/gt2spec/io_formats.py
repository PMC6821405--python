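"""Readers and writers for the formats the pipeline touches.

Aligned FASTA, multi-model PDB (one MODEL per trajectory frame), Newick
trees and tab-separated reports with ``#``-prefixed metadata lines.

The PDB dialect is deliberately strict: fixed-column parsing, and records
with alternate-location indicators or insertion codes are rejected with a
clear error.  The trajectories handled here are machine generated, so
bit-exactness is preferred over permissiveness.  Coordinates are stored in
Angstrom exactly as written; no unit conversion happens anywhere in the
pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AtomRecord",
    "TrajectoryFile",
    "read_fasta",
    "write_fasta",
    "read_pdb_models",
    "write_pdb_models",
    "write_newick",
    "write_tsv",
    "read_tsv",
]

# Residue alphabet: the 20 amino acids, X for unknown, '-' for gaps.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X", "-"}


@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly aligned) protein sequence.

    ``id`` is the token before the first whitespace of the FASTA header;
    the remainder of the header is kept as ``description``.
    """

    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased and ``.`` is normalised to ``-``.  Duplicate
    ids are a hard error.  With ``aligned=True`` all records must share one
    length.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace(".", "-")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged alignment in {path}: lengths {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a PDB model; positions in Angstrom."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    position: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        stripped = re.sub(r"\d", "", self.atom_name)
        if stripped and self.element and stripped[0].upper() != self.element[0].upper():
            raise ValueError(
                f"atom {self.serial}: element {self.element!r} inconsistent "
                f"with atom name {self.atom_name!r}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the atom independent of coordinates."""
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class TrajectoryFile:
    """Ordered coordinate frames sharing one atom topology."""

    models: list[list[AtomRecord]]
    frame_times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("trajectory must contain at least one model")
        ref = [(a.key, a.residue_name) for a in self.models[0]]
        for i, model in enumerate(self.models[1:], start=1):
            if [(a.key, a.residue_name) for a in model] != ref:
                raise ValueError(
                    f"frame {i}: atom count/ordering differs from frame 0 "
                    f"({len(model)} vs {len(self.models[0])} atoms)"
                )
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != len(self.models):
                raise ValueError("frame_times length must match model count")
            if np.any(np.diff(t) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0])

    def coordinates(self) -> np.ndarray:
        """(frames, atoms, 3) coordinate array."""
        return np.array([[a.position for a in m] for m in self.models])


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    altloc = line[16:17]
    if altloc not in (" ", ""):
        raise ValueError(f"line {lineno}: alternate locations are not supported ({altloc!r})")
    icode = line[26:27]
    if icode not in (" ", ""):
        raise ValueError(f"line {lineno}: insertion codes are not supported ({icode!r})")
    element = line[76:78].strip()
    atom_name = line[12:16].strip()
    if not element:
        element = re.sub(r"\d", "", atom_name)[:1]
    return AtomRecord(
        serial=int(line[6:11]),
        atom_name=atom_name,
        residue_name=line[17:20].strip(),
        chain_id=line[21:22],
        residue_number=int(line[22:26]),
        element=element,
        position=np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        ),
    )


def read_pdb_models(path: str | Path) -> TrajectoryFile:
    """Parse a multi-model PDB text file at fixed column positions.

    A MODEL-less single structure counts as one frame.  Frames with
    differing atom counts or ordering raise an error naming the frame.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    has_models = any(line[:6] == "MODEL " for line in lines)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None if has_models else []
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current is not None and has_models:
                raise ValueError(f"line {lineno}: nested MODEL record")
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise ValueError(f"line {lineno}: ENDMDL without MODEL")
            models.append(current)
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                raise ValueError(f"line {lineno}: atom outside MODEL block")
            current.append(_parse_atom_line(line, lineno))
    if not has_models:
        models = [current] if current else []
    elif current is not None:
        raise ValueError(f"unterminated MODEL block in {path}")
    if not models or not models[0]:
        raise ValueError(f"no atoms found in {path}")
    try:
        return TrajectoryFile(models=models)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_pdb_models(traj: TrajectoryFile, path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL blocks with fixed-column records."""
    path = Path(path)
    with path.open("w") as fh:
        for i, model in enumerate(traj.models, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            for atom in model:
                name = atom.atom_name
                # conventional PDB name justification
                field_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.position
                fh.write(
                    f"ATOM  {atom.serial:5d} {field_name:<4s} "
                    f"{atom.residue_name:<3s} {atom.chain_id}{atom.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


_NEWICK_RESERVED = re.compile(r"[\s()\[\]:;,']")


def _escape_label(label: str) -> str:
    if _NEWICK_RESERVED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(value: float) -> str:
    text = f"{value:.6f}".rstrip("0")
    if text.endswith("."):
        text += "0"
    return text


def write_newick(tree) -> str:
    """Serialise an ultrametric tree (see :mod:`gt2spec.phylo`) to Newick.

    Branch lengths are parent height minus child height, written at fixed
    decimal precision; labels containing reserved characters are quoted.
    """

    def render(node, parent_height: float | None) -> str:
        if node.children:
            inner = ",".join(render(c, node.height) for c in node.children)
            text = f"({inner})"
        else:
            text = _escape_label(node.name)
        if parent_height is not None:
            if node.height > parent_height + 1e-9:
                raise ValueError("malformed tree: child higher than parent")
            text += f":{_format_length(parent_height - node.height)}"
        return text

    root = getattr(tree, "root", tree)
    return render(root, None) + ";"


def write_tsv(path: str | Path, table, metadata: Mapping[str, object] | None = None) -> None:
    """Write a pandas DataFrame as TSV with ``#`` metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path):
    """Read a TSV report, skipping ``#`` metadata lines."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
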