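"""Synthetic inputs with planted ground truth.

Two generators emulate the study's data so that every pipeline stage is
testable without downloads:

* :func:`gen_clade_msa` builds a clade-structured multiple sequence
  alignment in which each column's conservation category (FULL / STRONG /
  DIFFERENTIAL / NONE) is planted by construction.  Planted columns are
  composed with exact residue counts, so their identities strictly
  respect the category definitions; background columns draw residues
  uniformly from the 20 amino acids -- the distribution most hostile to
  spurious conservation.
* :func:`gen_interaction_traj` builds a toy channel-frame coordinate
  trajectory (anchor C-alphas, a Trp and a Phe side chain, glucose
  residues, one donor--acceptor pair) with planted per-frame H-bond and
  stacking states, planted Glc orientations, and Gaussian coordinate
  jitter.  On/off geometries have explicit margins so the planted state
  is unambiguous at small jitter; generation fails loudly when the
  requested jitter could blur them.

Randomness comes exclusively from ``numpy.random.default_rng`` (PCG64)
seeded by the caller, so identical parameters and seed reproduce outputs
bit for bit on any platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .conservation import Category, CladeAlignment, ConservationThresholds
from .glucan_builder import GLUCOSE_TEMPLATE
from .geometry import rotation_about_y, rotation_between, signed_angle_xz
from .io_formats import AtomRecord, SequenceRecord
from .traj_metrics import Trajectory

__all__ = [
    "MsaParams",
    "MsaTruth",
    "gen_clade_msa",
    "TrajParams",
    "TrajTruth",
    "gen_interaction_traj",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_JITTER_SIGMA = 0.1  # A; keeps on/off interaction margins unambiguous


# --------------------------------------------------------------------------
# clade MSA generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaParams:
    """Shape and identity levels of the planted alignment.

    Identity levels are realised with exact residue counts
    (``ceil(level * n_seqs)`` consensus copies per clade), so planted
    categories hold by construction rather than in expectation.
    ``identity_jitter`` uniformly lowers each planted column's level by
    up to its value while clamping inside the category-valid range.
    """

    n_clades: int = 3
    seqs_per_clade: int = 20
    n_columns: int = 100
    n_full: int = 10
    n_strong: int = 10
    n_differential: int = 10
    strong_identity: float = 0.80
    differential_identity: float = 0.92
    identity_jitter: float = 0.0
    gap_rate: float = 0.02
    thresholds: ConservationThresholds = field(default_factory=ConservationThresholds)

    def __post_init__(self) -> None:
        if self.n_clades < 2 or self.seqs_per_clade < 2:
            raise ValueError("need at least 2 clades with at least 2 sequences each")
        planted = self.n_full + self.n_strong + self.n_differential
        if planted > self.n_columns:
            raise ValueError("planted columns exceed alignment length")
        n = self.seqs_per_clade
        th = self.thresholds
        if math.ceil(self.differential_identity * n) / n <= th.differential:
            raise ValueError(
                "differential_identity too low to realise per-clade identity "
                f"> {th.differential} with {n} sequences"
            )
        if not th.strong < math.ceil(self.strong_identity * n) / n <= th.full:
            raise ValueError(
                f"strong_identity must realise pooled identity in ({th.strong}, {th.full}]"
            )
        if self.n_differential and self.n_clades > 20:
            raise ValueError("cannot plant distinct consensus residues for >20 clades")
        if not 0 <= self.gap_rate < 0.5:
            raise ValueError("gap_rate must lie in [0, 0.5)")


@dataclass
class MsaTruth:
    """Planted per-column category and per-clade intended consensus."""

    categories: dict[int, Category]
    consensus: dict[int, dict[str, str]]
    params: MsaParams
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "params": {
                k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                for k, v in asdict(self.params).items()
            },
            "categories": {str(c): cat.value for c, cat in self.categories.items()},
            "consensus": {str(c): cons for c, cons in self.consensus.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _clade_names(n: int) -> list[str]:
    base = ["BcsA", "CrdS", "BgsA"]
    return base[:n] + [f"clade{i}" for i in range(4, n + 1)]


def _min_count(level: float, jitter: float, n: int, floor: float, rng) -> int:
    """Consensus copies for a (possibly jittered) identity level.

    The realised count never drops to or below ``floor * n``.
    """
    level = level - rng.uniform(0.0, jitter) if jitter else level
    count = math.ceil(level * n)
    min_valid = math.floor(floor * n) + 1
    return max(count, min_valid)


def gen_clade_msa(
    params: MsaParams = MsaParams(), seed: int = 0
) -> tuple[CladeAlignment, MsaTruth]:
    """Generate a clade alignment with planted conservation categories.

    Deterministic given ``(params, seed)``.  Gaps are inserted at
    ``gap_rate`` in background (NONE) columns only, never in the
    reference sequence (the first sequence of the first clade), which is
    therefore gap-free.
    """
    rng = np.random.default_rng(seed)
    clades = _clade_names(params.n_clades)
    n = params.seqs_per_clade
    ids = [f"{clade}_{i:03d}" for clade in clades for i in range(n)]
    clade_of = {f"{clade}_{i:03d}": clade for clade in clades for i in range(n)}
    reference_id = ids[0]

    n_cols = params.n_columns
    order = rng.permutation(n_cols)
    planted_cols = {
        Category.FULL: list(order[: params.n_full]),
        Category.STRONG: list(order[params.n_full: params.n_full + params.n_strong]),
        Category.DIFFERENTIAL: list(
            order[
                params.n_full
                + params.n_strong: params.n_full + params.n_strong + params.n_differential
            ]
        ),
    }
    aa = np.array(list(AMINO_ACIDS))
    columns = np.empty((n_cols, len(ids)), dtype="U1")
    categories: dict[int, Category] = {c: Category.NONE for c in range(n_cols)}
    consensus: dict[int, dict[str, str]] = {}
    th = params.thresholds

    def fill_clade(col: int, clade_idx: int, residue: str, count: int, exclude: set[str]) -> None:
        pool = np.array(sorted(set(AMINO_ACIDS) - exclude))
        chars = np.array([residue] * count + list(rng.choice(pool, size=n - count)))
        rng.shuffle(chars)
        columns[col, clade_idx * n: (clade_idx + 1) * n] = chars

    for col in range(n_cols):
        columns[col] = rng.choice(aa, size=len(ids))

    for col in planted_cols[Category.FULL]:
        residue = str(rng.choice(aa))
        columns[col, :] = residue
        categories[col] = Category.FULL
        consensus[col] = {clade: residue for clade in clades}

    for col in planted_cols[Category.STRONG]:
        residue = str(rng.choice(aa))
        count = _min_count(
            params.strong_identity, params.identity_jitter, n, th.strong, rng
        )
        for ci in range(len(clades)):
            fill_clade(col, ci, residue, count, exclude={residue})
        categories[col] = Category.STRONG
        consensus[col] = {clade: residue for clade in clades}

    for col in planted_cols[Category.DIFFERENTIAL]:
        residues = [str(r) for r in rng.choice(aa, size=len(clades), replace=False)]
        count = _min_count(
            params.differential_identity, params.identity_jitter, n, th.differential, rng
        )
        for ci in range(len(clades)):
            fill_clade(col, ci, residues[ci], count, exclude=set(residues))
        categories[col] = Category.DIFFERENTIAL
        consensus[col] = dict(zip(clades, residues))

    if params.gap_rate > 0:
        planted = {c for cols in planted_cols.values() for c in cols}
        for col in range(n_cols):
            if col in planted:
                continue
            mask = rng.random(len(ids)) < params.gap_rate
            mask[0] = False  # reference stays gap-free
            columns[col, mask] = "-"

    records = [
        SequenceRecord(id=sid, description="", residues="".join(columns[:, j]))
        for j, sid in enumerate(ids)
    ]
    aln = CladeAlignment(records=records, clade_of=clade_of, reference_id=reference_id)
    truth = MsaTruth(categories=categories, consensus=consensus, params=params, seed=seed)
    return aln, truth


# --------------------------------------------------------------------------
# toy interaction trajectory generator
# --------------------------------------------------------------------------

# Planar indole (Trp side chain) heavy atoms, approximate ring geometry,
# local (x, z) coordinates in Angstrom; the ring lies in the xz plane.
_INDOLE_XZ = {
    "CG": (0.00, 0.00),
    "CD1": (0.83, 1.10),
    "NE1": (2.18, 0.70),
    "CE2": (2.25, -0.66),
    "CD2": (0.92, -1.11),
    "CE3": (0.37, -2.39),
    "CZ3": (1.19, -3.50),
    "CH2": (2.55, -3.38),
    "CZ2": (3.12, -2.13),
}

# Phe ring (six-membered) plus CB, local (x, z), ring in the xz plane.
_PHE_XZ = {
    "CG": (1.39, 0.00),
    "CD1": (0.695, 1.204),
    "CE1": (-0.695, 1.204),
    "CZ": (-1.39, 0.00),
    "CE2": (-0.695, -1.204),
    "CD2": (0.695, -1.204),
    "CB": (2.89, 0.00),
}

_HBOND_ON_DISTANCE = 2.9  # A, donor-acceptor in the bonded state
_HBOND_OFF_DISTANCE = 6.0
_STACK_ON_OFFSET = 3.5  # A above the Phe ring plane, parallel stacking
_STACK_OFF_OFFSET = 9.0


@dataclass(frozen=True)
class TrajParams:
    """Planted probabilities and geometry of the toy trajectory."""

    n_frames: int = 1000
    p_hbond: float = 0.6
    p_stack: float = 0.3
    orientations: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0)
    sigma: float = 0.05  # A, isotropic Gaussian jitter per axis
    frame_dt: float = 0.1  # ns between frames

    def __post_init__(self) -> None:
        for name in ("p_hbond", "p_stack"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.sigma > MAX_JITTER_SIGMA:
            raise ValueError(
                f"sigma={self.sigma} exceeds {MAX_JITTER_SIGMA} A and could blur "
                "the planted on/off geometric margins"
            )
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not self.orientations:
            raise ValueError("need at least one planted orientation")


@dataclass
class TrajTruth:
    """Ground truth of every random draw in the generated trajectory."""

    params: TrajParams
    seed: int
    hbond_states: np.ndarray  # (frames,) bool
    stack_states: np.ndarray  # (frames,) bool
    orientations: tuple[float, ...]  # degrees, per Glc residue of chain G
    donor: tuple[str, int, str] = ("A", 20, "OG")
    acceptor: tuple[str, int, str] = ("W", 21, "O")
    trp: tuple[str, int] = ("A", 10)
    phe: tuple[str, int] = ("A", 30)
    stack_glc: tuple[str, int] = ("S", 1)
    orientation_chain: str = "G"

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "params": asdict(self.params),
            "p_hbond": self.params.p_hbond,
            "p_stack": self.params.p_stack,
            "hbond_states": self.hbond_states.astype(int).tolist(),
            "stack_states": self.stack_states.astype(int).tolist(),
            "orientations": list(self.orientations),
            "donor": list(self.donor),
            "acceptor": list(self.acceptor),
            "trp": list(self.trp),
            "phe": list(self.phe),
            "stack_glc": list(self.stack_glc),
            "orientation_chain": self.orientation_chain,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _glucose_atoms(rotation: np.ndarray, center: np.ndarray) -> dict[str, np.ndarray]:
    return {
        name: rotation @ np.array(xyz) + center
        for name, xyz in GLUCOSE_TEMPLATE.items()
        if name != "O1"
    }


def _base_topology_and_frame(
    orientations: Sequence[float],
) -> tuple[list[AtomRecord], np.ndarray]:
    """The unjittered 'on-state' geometry and its atom records."""
    atoms: list[tuple[str, str, str, int, str, np.ndarray]] = []

    def add(chain, resname, name, resnum, element, pos) -> None:
        atoms.append((chain, resname, name, resnum, element, np.asarray(pos, float)))

    # channel anchors: bottom CA at the origin, top CA 30 A up the axis;
    # ALA1's CB is the first off-axis atom and fixes the roll convention
    add("A", "ALA", "CA", 1, "C", (0.0, 0.0, 0.0))
    add("A", "ALA", "CB", 1, "C", (1.53, 0.4, 0.0))
    add("A", "ALA", "CA", 2, "C", (0.0, 30.0, 0.0))

    # signature Trp: indole parallel to the xz plane at y=5, with the
    # CG->CZ3 reference vector rotated to lie along +x
    cz3 = np.array([_INDOLE_XZ["CZ3"][0], 0.0, _INDOLE_XZ["CZ3"][1]])
    R_trp = rotation_between(cz3, np.array([1.0, 0.0, 0.0]))
    trp_origin = np.array([3.0, 5.0, 1.0])
    add("A", "TRP", "CA", 10, "C", trp_origin + np.array([-1.0, 1.8, 1.2]))
    add("A", "TRP", "CB", 10, "C", trp_origin + np.array([-0.8, 0.9, 0.6]))
    for name, (x, z) in _INDOLE_XZ.items():
        pos = R_trp @ np.array([x, 0.0, z]) + trp_origin
        add("A", "TRP", name, 10, "N" if name.startswith("N") else "C", pos)

    # H-bond pair: Ser donor with its hydroxyl hydrogen pointing +x,
    # acceptor water oxygen placed collinearly (angle D-H-A = 180)
    og = np.array([-20.0, 5.0, 0.0])
    add("A", "SER", "CB", 20, "C", og + np.array([-1.4, -0.2, 0.3]))
    add("A", "SER", "OG", 20, "O", og)
    add("A", "SER", "HG", 20, "H", og + np.array([0.96, 0.0, 0.0]))
    add("W", "HOH", "O", 21, "O", og + np.array([_HBOND_ON_DISTANCE, 0.0, 0.0]))

    # stacking pair: Phe ring in the xz plane at y=10, glucose parallel
    # above it ('on' offset; the 'off' state translates it up the normal)
    phe_origin = np.array([20.0, 10.0, 0.0])
    add("A", "PHE", "CA", 30, "C", phe_origin + np.array([4.0, 0.8, 0.5]))
    for name, (x, z) in _PHE_XZ.items():
        add("A", "PHE", name, 30, "C", phe_origin + np.array([x, 0.0, z]))
    ring = [a for a in GLUCOSE_TEMPLATE if a in ("C1", "C2", "C3", "C4", "C5", "O5")]
    ring_coords = np.array([GLUCOSE_TEMPLATE[a] for a in ring])
    normal = np.linalg.svd(ring_coords - ring_coords.mean(axis=0))[2][2]
    R_flat = rotation_between(normal, np.array([0.0, 1.0, 0.0]))
    for name, pos in _glucose_atoms(R_flat, phe_origin + np.array([0.0, _STACK_ON_OFFSET, 0.0])).items():
        add("S", "BGC", name, 1, name[0], pos)

    # orientation chain: one glucose per planted angle, stacked along +y;
    # angles are relative to the Trp CG->CZ3 reference (+x after R_trp)
    c25 = np.array(GLUCOSE_TEMPLATE["C5"]) - np.array(GLUCOSE_TEMPLATE["C2"])
    base_angle = signed_angle_xz(c25, np.array([1.0, 0.0, 0.0]))
    R_zero = rotation_about_y(-base_angle)
    for j, theta in enumerate(orientations, start=1):
        R = rotation_about_y(theta) @ R_zero
        center = np.array([0.0, 8.0 + 4.0 * j, 0.0])
        for name, pos in _glucose_atoms(R, center).items():
            add("G", "BGC", name, j, name[0], pos)

    records = [
        AtomRecord(
            serial=i + 1,
            atom_name=name,
            residue_name=resname,
            chain_id=chain,
            residue_number=resnum,
            element=element,
            position=pos,
        )
        for i, (chain, resname, name, resnum, element, pos) in enumerate(atoms)
    ]
    frame = np.array([a.position for a in records])
    return records, frame


def gen_interaction_traj(
    params: TrajParams = TrajParams(), seed: int = 0
) -> tuple[Trajectory, TrajTruth]:
    """Generate a toy channel-frame trajectory with known interactions.

    Per frame, the H-bond acceptor and the stacking glucose are switched
    to their 'on' geometry with the planted probabilities, then isotropic
    Gaussian jitter of ``sigma`` A is added to every atom.  The per-frame
    states are recorded in the returned :class:`TrajTruth`.
    """
    rng = np.random.default_rng(seed)
    topology, base = _base_topology_and_frame(params.orientations)
    index = {(a.chain_id, a.residue_number, a.atom_name): i for i, a in enumerate(topology)}
    i_acceptor = index[("W", 21, "O")]
    stack_idx = [i for i, a in enumerate(topology) if a.chain_id == "S"]

    hbond_states = rng.random(params.n_frames) < params.p_hbond
    stack_states = rng.random(params.n_frames) < params.p_stack
    jitter = rng.normal(0.0, params.sigma, size=(params.n_frames, len(topology), 3))

    coords = np.repeat(base[None], params.n_frames, axis=0)
    off_shift = np.array([_HBOND_OFF_DISTANCE - _HBOND_ON_DISTANCE, 0.0, 0.0])
    coords[~hbond_states, i_acceptor] += off_shift
    stack_shift = np.array([0.0, _STACK_OFF_OFFSET - _STACK_ON_OFFSET, 0.0])
    coords[np.ix_(~stack_states, stack_idx)] += stack_shift
    coords += jitter

    times = [params.frame_dt * f for f in range(params.n_frames)]
    traj = Trajectory(topology=topology, coords=coords, frame_times=times)
    truth = TrajTruth(
        params=params,
        seed=seed,
        hbond_states=hbond_states,
        stack_states=stack_states,
        orientations=params.orientations,
    )
    return traj, truth
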