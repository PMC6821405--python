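"""Idealized heavy-atom beta-glucan chain construction.

Chains of beta-D-glucopyranose are assembled residue by residue from a
single rigid 4C1 chair template, connected through (1,4) or (1,3)
glycosidic linkages whose phi/psi torsions default to named low-energy
conformers: a two-fold-screw (cellulose 2_1-like) geometry for (1,4)
bonds and a single-helix (curdlan-like, ~60 degree rotation per residue)
geometry for (1,3) bonds.  Mixing the two linkage codes yields
mixed-linkage glucan (MLG) chains.  The triple-helix solution form of
curdlan is intentionally not buildable: the builder emulates chains as
translocated through a synthase trans-membrane channel, where that
conformation does not fit.

Conventions
-----------
* Glc residues are numbered from the non-reducing acceptor end, the
  acceptor being residue 0.
* The glycosidic bridge between residue ``i`` and ``i+1`` runs
  C1(i) - O - Cx(i+1) with x = 4 or 3 by linkage; the bridge oxygen keeps
  its chemical atom name (O4 or O3) inside residue ``i+1``.
* Every residue carries atoms C1..C6 and O2..O6; only the reducing-end
  residue keeps an anomeric O1, giving ``12n - (n-1)`` heavy atoms for an
  ``n``-residue chain.
* The finished chain is rigidly placed with its axis along +y and the
  acceptor at minimal y, matching the channel frame used by the
  trajectory metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import kabsch, nerf_place, rotation_between, signed_angle_xz, wrap_angle
from .io_formats import AtomRecord, TrajectoryFile

__all__ = [
    "GLUCOSE_TEMPLATE",
    "LinkageGeometry",
    "DEFAULT_GEOMETRIES",
    "GlucanChain",
    "build_glucan",
    "inter_residue_distances",
    "residue_rotation",
    "consecutive_rotations",
    "exocyclic_side",
]

# Idealized beta-D-glucopyranose 4C1 chair, heavy atoms only, Angstrom.
# Fixed constants of the builder (standard pyranose bond lengths/angles,
# all non-ring substituents equatorial, ring centred at the origin).
GLUCOSE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "C1": (-0.3082, -1.1209, 0.8127),
    "C2": (-0.7560, 0.2931, 1.2141),
    "C3": (-0.9285, 1.1440, -0.0397),
    "C4": (0.3445, 1.1108, -0.8891),
    "C5": (0.7489, -0.3441, -1.1649),
    "C6": (2.0839, -0.4180, -1.9136),
    "O1": (-0.0748, -1.8572, 2.0057),
    "O2": (-1.9955, 0.2637, 1.9372),
    "O3": (-1.2205, 2.5050, 0.3141),
    "O4": (0.1125, 1.8207, -2.1063),
    "O5": (0.8993, -1.0829, 0.0668),
    "O6": (2.4426, -1.7876, -2.1147),
}

_ATOM_ORDER = ["C1", "C2", "C3", "C4", "C5", "C6", "O1", "O2", "O3", "O4", "O5", "O6"]

_T = {name: np.array(xyz) for name, xyz in GLUCOSE_TEMPLATE.items()}


def _template_distance(a: str, b: str) -> float:
    return float(np.linalg.norm(_T[a] - _T[b]))


def _template_angle(a: str, b: str, c: str) -> float:
    u = _T[a] - _T[b]
    v = _T[c] - _T[b]
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass(frozen=True)
class LinkageGeometry:
    """Glycosidic bond geometry for one linkage type.

    ``phi`` is the O5-C1-Ox-Cx torsion and ``psi`` the C1-Ox-Cx-C(x-1)
    torsion (degrees, wrapped to (-180, 180]); ``bond_length`` is the
    C1-O bridge bond and ``bond_angle`` the C1-O-Cx valence angle.
    """

    phi: float
    psi: float
    bond_length: float = 1.41
    bond_angle: float = 116.0

    def __post_init__(self) -> None:
        for name in ("phi", "psi"):
            value = getattr(self, name)
            if not -180.0 < value <= 180.0:
                raise ValueError(f"{name} must lie in (-180, 180], got {value}")
        if not 1.2 <= self.bond_length <= 1.6:
            raise ValueError(f"bond_length outside 1.2-1.6 A: {self.bond_length}")


# Default glycosidic conformers.  (1,4): two-fold-screw cellulose-like
# geometry (~180 degree rotation between neighbours); (1,3): single-helix
# curdlan-like geometry (~60 degree rotation).  Values sit inside the
# published low-energy basins for the respective disaccharide maps; the
# chain-level rotations and spacings emerge from the geometry.
DEFAULT_GEOMETRIES: dict[int, LinkageGeometry] = {
    4: LinkageGeometry(phi=-110.0, psi=110.0),
    3: LinkageGeometry(phi=-80.0, psi=130.0),
}


@dataclass
class GlucanChain:
    """Heavy-atom coordinates of an idealized beta-glucan.

    ``residues[i]`` maps atom names to 3-vectors (Angstrom);
    ``linkage_of[i]`` is the linkage code (4 or 3) of the bond between
    residues ``i`` and ``i+1``.
    """

    residues: list[dict[str, np.ndarray]]
    linkage_of: list[int]

    def __post_init__(self) -> None:
        if len(self.linkage_of) != len(self.residues) - 1:
            raise ValueError("need exactly one linkage per inter-residue bond")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def heavy_atom_count(self) -> int:
        return sum(len(r) for r in self.residues)

    def residue_center(self, i: int) -> np.ndarray:
        """Geometric centre (unit masses) of residue ``i``'s heavy atoms."""
        return np.mean(list(self.residues[i].values()), axis=0)

    def atom_records(self, chain_id: str = "G", start_serial: int = 1) -> list[AtomRecord]:
        """PDB-style records; residue name BGC, numbered from 1."""
        records = []
        serial = start_serial
        for i, res in enumerate(self.residues):
            for name in _ATOM_ORDER:
                if name not in res:
                    continue
                records.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=name,
                        residue_name="BGC",
                        chain_id=chain_id,
                        residue_number=i + 1,
                        element=name[0],
                        position=res[name].copy(),
                    )
                )
                serial += 1
        return records

    def to_trajectory_file(self) -> TrajectoryFile:
        return TrajectoryFile(models=[self.atom_records()])


def _normalise_pattern(n: int, pattern: Sequence[int] | None) -> list[int]:
    if pattern is None:
        pattern = [4] * (n - 1)
    pattern = [int(p) for p in pattern]
    if len(pattern) != n - 1:
        raise ValueError(f"pattern must list {n - 1} linkages, got {len(pattern)}")
    bad = sorted({p for p in pattern if p not in (3, 4)})
    if bad:
        raise ValueError(f"unknown linkage code(s) {bad}; use 4 for (1,4) or 3 for (1,3)")
    return pattern


def build_glucan(
    n: int,
    pattern: Sequence[int] | None = None,
    geometry: Mapping[int, LinkageGeometry] | None = None,
) -> GlucanChain:
    """Construct an ``n``-residue beta-glucan with the given linkages.

    ``pattern`` lists the linkage code (4 or 3) of each of the ``n - 1``
    bonds from the acceptor end; it defaults to all-(1,4).  ``geometry``
    optionally overrides the default phi/psi conformer per linkage type.
    Coordinates are deterministic functions of the inputs.
    """
    if n < 1:
        raise ValueError("chain needs at least one residue")
    pattern = _normalise_pattern(n, pattern)
    geos = dict(DEFAULT_GEOMETRIES)
    if geometry:
        geos.update(geometry)

    # Working copies keep O1 on every residue; the O1 of residue i points
    # along the direction in which the bridge oxygen to residue i+1 is
    # placed (beta-equatorial at C1), and is dropped afterwards except at
    # the reducing end.
    working: list[dict[str, np.ndarray]] = [{k: v.copy() for k, v in _T.items()}]
    for i, lk in enumerate(pattern):
        geo = geos[lk]
        prev = working[i]
        cx, cprev, ox = f"C{lk}", f"C{lk - 1}", f"O{lk}"
        u = prev["O1"] - prev["C1"]
        u /= np.linalg.norm(u)
        bridge = prev["C1"] + geo.bond_length * u
        cx_pos = nerf_place(
            prev["O5"], prev["C1"], bridge,
            _template_distance(ox, cx), geo.bond_angle, geo.phi,
        )
        cprev_pos = nerf_place(
            prev["C1"], bridge, cx_pos,
            _template_distance(cx, cprev), _template_angle(ox, cx, cprev), geo.psi,
        )
        R, t = kabsch(
            np.array([_T[ox], _T[cx], _T[cprev]]),
            np.array([bridge, cx_pos, cprev_pos]),
        )
        working.append({k: R @ v + t for k, v in _T.items()})

    residues: list[dict[str, np.ndarray]] = []
    for i, res in enumerate(working):
        atoms = dict(res)
        if i < n - 1:
            del atoms["O1"]  # C1 bonds the next residue's bridge oxygen
        # for i > 0 the bridge oxygen IS this residue's O4/O3: the Kabsch
        # step mapped that template atom exactly onto the bridge position
        residues.append(atoms)

    chain = GlucanChain(residues=residues, linkage_of=pattern)
    return _orient_chain(chain)


def _orient_chain(chain: GlucanChain) -> GlucanChain:
    """Rigidly place the chain axis along +y, acceptor at minimal y."""
    if chain.n_residues == 1:
        center = chain.residue_center(0)
        for res in chain.residues:
            for k in res:
                res[k] = res[k] - center
        return chain
    centers = np.array([chain.residue_center(i) for i in range(chain.n_residues)])
    axis = centers[-1] - centers[0]
    R = rotation_between(axis, np.array([0.0, 1.0, 0.0]))
    origin = centers[0]
    for res in chain.residues:
        for k in res:
            res[k] = R @ (res[k] - origin)
    return chain


def inter_residue_distances(chain: GlucanChain) -> np.ndarray:
    """Distances between geometric centres of consecutive residues (A).

    A single-residue chain yields an empty array.
    """
    centers = [chain.residue_center(i) for i in range(chain.n_residues)]
    return np.array(
        [np.linalg.norm(centers[i + 1] - centers[i]) for i in range(chain.n_residues - 1)]
    )


def residue_rotation(
    residue: Mapping[str, np.ndarray],
    reference: np.ndarray | Mapping[str, np.ndarray],
) -> float | None:
    """Signed rotation (degrees, about +y) of a residue's C2->C5 vector.

    ``reference`` is either a fixed 3-vector or another residue, in which
    case that residue's C2->C5 vector is used.  Angles compare the
    xz-plane projections; a degenerate (near-axial) projection yields
    ``None``.
    """
    u = np.asarray(residue["C5"] - residue["C2"], float)
    if isinstance(reference, Mapping):
        ref = np.asarray(reference["C5"] - reference["C2"], float)
    else:
        ref = np.asarray(reference, float)
    return signed_angle_xz(u, ref)


def consecutive_rotations(chain: GlucanChain) -> list[float | None]:
    """Wrapped rotation of each residue relative to its predecessor."""
    out: list[float | None] = []
    for i in range(chain.n_residues - 1):
        angle = residue_rotation(chain.residues[i + 1], chain.residues[i])
        out.append(None if angle is None else wrap_angle(angle))
    return out


def exocyclic_side(chain: GlucanChain, axis: np.ndarray | None = None) -> list[int]:
    """Which side of the polymerisation axis each exocyclic group points.

    The C5->C6 vector of each residue is projected onto the plane normal
    to the chain axis (+y by default) and compared with residue 0's
    direction; the result is +1 or -1 per residue, residue 0 being +1 by
    convention.
    """
    axis = np.array([0.0, 1.0, 0.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    projected = []
    for res in chain.residues:
        v = np.asarray(res["C6"] - res["C5"], float)
        projected.append(v - np.dot(v, axis) * axis)
    ref = projected[0]
    signs = []
    for v in projected:
        dot = float(np.dot(v, ref))
        signs.append(1 if dot >= 0 else -1)
    return signs
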