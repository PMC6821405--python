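"""Interaction statistics on multi-model coordinate trajectories.

These are the analyses used to characterise how a glucan synthase holds
its product in the trans-membrane (TM) channel: per-frame H-bond
detection and occupancy, aromatic--Glc stacking occupancy, the
orientation (rotation about the channel axis) and axial position of each
Glc residue relative to the conserved signature Trp, and RMSD/RMSF on
named residue selections.

All channel-frame metrics assume the trajectory has been aligned with
:func:`align_to_channel_axis`, which places the TM channel axis along +y
(bottom anchor at the origin) for every frame.

Occupancy semantics: an interaction's occupancy is the percentage of
analysed window frames in which its geometric criterion holds; windows
are given in frames (or in ns when frame times are available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import kabsch, rotation_between, signed_angle_xz
from .io_formats import AtomRecord, TrajectoryFile

__all__ = [
    "Trajectory",
    "Selection",
    "InteractionRecord",
    "DOMAIN_RESIDUE_RANGES",
    "preset_selection",
    "align_to_channel_axis",
    "detect_hbond",
    "hbond_occupancy",
    "stacking_contacts",
    "stacking_occupancy",
    "glc_orientation",
    "glc_position",
    "rmsd_series",
    "rmsf_per_residue",
]

AROMATIC_RESIDUES = {"PHE", "TYR", "TRP"}
GLC_RESIDUES = {"BGC", "GLC"}
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

AtomSpec = tuple[str, int, str]  # (chain, residue number, atom name)
ResidueSpec = tuple[str, int]  # (chain, residue number)


@dataclass
class Trajectory:
    """Frames x named atoms with residue topology; coordinates in Angstrom."""

    topology: list[AtomRecord]
    coords: np.ndarray  # (frames, atoms, 3)
    frame_times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.topology):
            raise ValueError("coords must be (frames, atoms, 3) matching topology")

    @classmethod
    def from_file(cls, tf: TrajectoryFile) -> "Trajectory":
        return cls(
            topology=list(tf.models[0]),
            coords=tf.coordinates(),
            frame_times=tf.frame_times,
        )

    def to_file(self) -> TrajectoryFile:
        models = []
        for frame in self.coords:
            models.append(
                [
                    AtomRecord(
                        serial=a.serial,
                        atom_name=a.atom_name,
                        residue_name=a.residue_name,
                        chain_id=a.chain_id,
                        residue_number=a.residue_number,
                        element=a.element,
                        position=pos.copy(),
                    )
                    for a, pos in zip(self.topology, frame)
                ]
            )
        return TrajectoryFile(models=models, frame_times=self.frame_times)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, spec: AtomSpec) -> int:
        chain, resnum, name = spec
        for i, a in enumerate(self.topology):
            if a.chain_id == chain and a.residue_number == resnum and a.atom_name == name:
                return i
        raise KeyError(f"atom {chain}:{resnum}:{name} not found")

    def residue_indices(self, spec: ResidueSpec, heavy_only: bool = True) -> np.ndarray:
        chain, resnum = spec
        idx = [
            i
            for i, a in enumerate(self.topology)
            if a.chain_id == chain
            and a.residue_number == resnum
            and (not heavy_only or a.element.upper() != "H")
        ]
        if not idx:
            raise KeyError(f"residue {chain}:{resnum} not found")
        return np.array(idx)

    def residue_name(self, spec: ResidueSpec) -> str:
        return self.topology[self.residue_indices(spec, heavy_only=False)[0]].residue_name

    def residues(self) -> list[ResidueSpec]:
        """Unique (chain, residue number) pairs in topology order."""
        seen: list[ResidueSpec] = []
        for a in self.topology:
            key = (a.chain_id, a.residue_number)
            if not seen or seen[-1] != key:
                if key not in seen:
                    seen.append(key)
        return seen


def resolve_window(
    traj: Trajectory,
    window: tuple[float, float] | None,
    ns: bool = False,
) -> np.ndarray:
    """Frame indices of an analysis window ``[a, b)`` (frames or ns)."""
    if window is None:
        idx = np.arange(traj.n_frames)
    elif ns:
        if traj.frame_times is None:
            raise ValueError("ns windows require frame_times")
        t = np.asarray(traj.frame_times)
        idx = np.nonzero((t >= window[0]) & (t < window[1]))[0]
    else:
        a, b = int(window[0]), int(window[1])
        idx = np.arange(max(a, 0), min(b, traj.n_frames))
    if idx.size == 0:
        raise ValueError(f"empty analysis window {window}")
    return idx


@dataclass(frozen=True)
class Selection:
    """Named predicate over atoms: residue ranges, atom/residue names."""

    name: str = "selection"
    chain_id: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: tuple[str, ...] = ()
    residue_names: tuple[str, ...] = ()

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_ranges and not any(
            lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.atom_names and atom.atom_name not in self.atom_names:
            return False
        if self.residue_names and atom.residue_name not in self.residue_names:
            return False
        return True

    def resolve(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(topology) if self.matches(a)], dtype=int)
        if idx.size == 0:
            raise ValueError(f"selection {self.name!r} resolves to no atoms")
        return idx


# Residue ranges of the structural domains used for RMSD selections in the
# two study proteins (reference numbering of each protein).
DOMAIN_RESIDUE_RANGES: dict[str, dict[str, tuple[tuple[int, int], ...]]] = {
    "RsBcsA": {
        "catalytic": ((141, 402),),
        "tm_domain": ((1, 125), (403, 497), (518, 582)),
        "tm_channel": ((75, 125), (403, 497), (547, 582)),
        "gating_loop": ((498, 517),),
    },
    "AtumCrdS": {
        "catalytic": ((118, 365),),
        "tm_domain": ((3, 92), (366, 458), (483, 537)),
        "tm_channel": ((50, 92), (366, 458), (510, 530)),
        "gating_loop": ((459, 482),),
    },
}


def preset_selection(protein: str, domain: str, chain_id: str | None = None) -> Selection:
    """Selection preset for a named domain of a study protein."""
    try:
        ranges = DOMAIN_RESIDUE_RANGES[protein][domain]
    except KeyError as exc:
        raise KeyError(f"no preset for protein={protein!r}, domain={domain!r}") from exc
    return Selection(name=f"{protein}:{domain}", chain_id=chain_id, residue_ranges=ranges)


@dataclass
class InteractionRecord:
    """Occupancy of one pairwise interaction over an analysis window."""

    kind: str  # "hbond" | "stacking"
    partner_a: str
    partner_b: str
    occupancy: float  # percent of window frames
    series: np.ndarray = field(repr=False)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=bool)
        expected = 100.0 * float(np.mean(self.series))
        if abs(expected - self.occupancy) > 1e-9:
            raise ValueError("occupancy must equal 100 x mean of the series")


def align_to_channel_axis(
    traj: Trajectory,
    bottom: AtomSpec,
    top: AtomSpec,
    roll_reference: AtomSpec | None = None,
) -> Trajectory:
    """Rigidly place each frame in the TM-channel frame.

    The bottom anchor (channel entrance at the active site) is moved to
    the origin and the bottom-to-top direction onto +y.  The remaining
    roll about +y is fixed deterministically: a reference atom (by
    default the first atom off the axis in frame 0) is brought into the
    +x half of the xz plane.  All downstream xz/y metrics assume this
    frame.
    """
    i_bot = traj.atom_index(bottom)
    i_top = traj.atom_index(top)
    y = np.array([0.0, 1.0, 0.0])
    n_frames = traj.n_frames
    out = np.empty_like(traj.coords)
    for f in range(n_frames):
        frame = traj.coords[f]
        axis = frame[i_top] - frame[i_bot]
        if np.linalg.norm(axis) < 1e-8:
            raise ValueError(f"frame {f}: coincident channel anchors")
        R = rotation_between(axis, y)
        out[f] = (frame - frame[i_bot]) @ R.T

    if roll_reference is not None:
        i_ref = traj.atom_index(roll_reference)
    else:
        radial = np.hypot(out[0, :, 0], out[0, :, 2])
        candidates = np.nonzero(radial > 1e-6)[0]
        if candidates.size == 0:
            raise ValueError("cannot fix roll: all atoms lie on the channel axis")
        i_ref = int(candidates[0])
    for f in range(n_frames):
        x, z = out[f, i_ref, 0], out[f, i_ref, 2]
        r = np.hypot(x, z)
        if r < 1e-10:
            continue  # reference atom on axis this frame; leave roll as-is
        c, s = x / r, z / r
        # rotate about +y so the reference atom lands at (+r, y, 0)
        roll = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        out[f] = out[f] @ roll.T
    return Trajectory(topology=traj.topology, coords=out, frame_times=traj.frame_times)


@dataclass(frozen=True)
class HBondResult:
    bonded: bool
    distance: float
    angle: float | None  # donor-H-acceptor angle, degrees
    used_angle: bool


def _bonded_hydrogens(
    topology: Sequence[AtomRecord], frame: np.ndarray, donor: int, max_bond: float = 1.2
) -> list[int]:
    d_pos = frame[donor]
    return [
        i
        for i, a in enumerate(topology)
        if a.element.upper() == "H" and np.linalg.norm(frame[i] - d_pos) < max_bond
    ]


def detect_hbond(
    topology: Sequence[AtomRecord],
    frame: np.ndarray,
    donor: int,
    acceptor: int,
    dist_cut: float = 3.4,
    angle_cut: float = 60.0,
    require_hydrogen: bool = True,
    hydrogens: list[int] | None = None,
) -> HBondResult:
    """Geometric H-bond test for one frame.

    True iff the donor--acceptor heavy-atom distance is within
    ``dist_cut`` and the donor-H-acceptor angle of the best (most linear)
    bonded hydrogen deviates from linearity by at most ``angle_cut``
    degrees.  Bonded hydrogens are inferred from the frame geometry
    (covalent distance < 1.2 A) unless ``hydrogens`` supplies them;
    bonding is a topology property, so occupancy calculations infer it
    once rather than per frame.  When the topology carries no hydrogens
    the angle test is skipped (distance-only fallback) and flagged in
    the result.
    """
    dist = float(np.linalg.norm(frame[acceptor] - frame[donor]))
    if hydrogens is None:
        hydrogens = _bonded_hydrogens(topology, frame, donor) if require_hydrogen else []
    if not hydrogens:
        if require_hydrogen:
            warnings.warn(
                f"donor {topology[donor].atom_name} has no bonded hydrogen; "
                "using distance-only H-bond criterion",
                stacklevel=2,
            )
        return HBondResult(bonded=dist <= dist_cut, distance=dist, angle=None, used_angle=False)
    best = None
    for h in hydrogens:
        u = frame[donor] - frame[h]
        v = frame[acceptor] - frame[h]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
        if best is None or angle > best:
            best = angle
    bonded = dist <= dist_cut and (180.0 - best) <= angle_cut
    return HBondResult(bonded=bonded, distance=dist, angle=best, used_angle=True)


def _residue_label(traj: Trajectory, spec: ResidueSpec) -> str:
    chain, resnum = spec
    return f"{chain}:{traj.residue_name(spec)}{resnum}"


def hbond_occupancy(
    traj: Trajectory,
    donor: AtomSpec,
    acceptor: AtomSpec,
    window: tuple[float, float] | None = None,
    dist_cut: float = 3.4,
    angle_cut: float = 60.0,
    ns: bool = False,
) -> InteractionRecord:
    """Percentage of window frames in which the pair is H-bonded."""
    i_d = traj.atom_index(donor)
    i_a = traj.atom_index(acceptor)
    frames = resolve_window(traj, window, ns=ns)
    hydrogens = _bonded_hydrogens(traj.topology, traj.coords[frames[0]], i_d)
    used_angle = bool(hydrogens)
    series = np.zeros(frames.size, dtype=bool)
    for k, f in enumerate(frames):
        result = detect_hbond(
            traj.topology, traj.coords[f], i_d, i_a, dist_cut, angle_cut,
            require_hydrogen=used_angle, hydrogens=hydrogens,
        )
        series[k] = result.bonded
    if not used_angle:
        warnings.warn(
            f"H-bond {donor}->{acceptor}: no donor hydrogen found; "
            "occupancy uses the distance-only fallback",
            stacklevel=2,
        )
    return InteractionRecord(
        kind="hbond",
        partner_a=f"{donor[0]}:{donor[2]}{donor[1]}",
        partner_b=f"{acceptor[0]}:{acceptor[2]}{acceptor[1]}",
        occupancy=100.0 * float(np.mean(series)),
        series=series,
        flags={"distance_only": not used_angle},
    )


def stacking_contacts(
    traj: Trajectory,
    frame: int,
    residue_a: ResidueSpec,
    residue_b: ResidueSpec,
    cutoff: float = 5.5,
) -> int:
    """Count of heavy-atom pairs closer than ``cutoff`` (strict ``<``).

    One residue must be aromatic (Phe, Tyr or Trp); all heavy atoms,
    backbone included, participate.  The count is symmetric in the order
    of the two residues.
    """
    names = {traj.residue_name(residue_a), traj.residue_name(residue_b)}
    if not names & AROMATIC_RESIDUES:
        raise ValueError(
            f"stacking requires an aromatic residue (Phe/Tyr/Trp); got {sorted(names)}"
        )
    idx_a = traj.residue_indices(residue_a)
    idx_b = traj.residue_indices(residue_b)
    coords = traj.coords[frame]
    dists = cdist(coords[idx_a], coords[idx_b])
    return int(np.sum(dists < cutoff))


def stacking_occupancy(
    traj: Trajectory,
    aromatic: ResidueSpec,
    glc: ResidueSpec,
    threshold: int = 25,
    cutoff: float = 5.5,
    window: tuple[float, float] | None = None,
    ns: bool = False,
) -> InteractionRecord:
    """Percentage of window frames with more than ``threshold`` contacts.

    A frame counts as stacked only with strictly more than ``threshold``
    heavy-atom pairs within ``cutoff``.
    """
    frames = resolve_window(traj, window, ns=ns)
    series = np.array(
        [
            stacking_contacts(traj, f, aromatic, glc, cutoff=cutoff) > threshold
            for f in frames
        ]
    )
    return InteractionRecord(
        kind="stacking",
        partner_a=_residue_label(traj, aromatic),
        partner_b=_residue_label(traj, glc),
        occupancy=100.0 * float(np.mean(series)),
        series=series,
    )


def glc_orientation(
    traj: Trajectory,
    frame: int,
    glc: ResidueSpec,
    trp: ResidueSpec,
) -> float | None:
    """Rotation of a Glc residue relative to the signature Trp (degrees).

    Signed angle about +y between the xz-projections of the Glc C2->C5
    vector and the Trp CG->CZ3 vector; assumes a channel-aligned frame.
    Near-axial (degenerate) projections yield ``None``.
    """
    coords = traj.coords[frame]
    chain_g, res_g = glc
    chain_t, res_t = trp
    u = coords[traj.atom_index((chain_g, res_g, "C5"))] - coords[
        traj.atom_index((chain_g, res_g, "C2"))
    ]
    ref = coords[traj.atom_index((chain_t, res_t, "CZ3"))] - coords[
        traj.atom_index((chain_t, res_t, "CG"))
    ]
    return signed_angle_xz(u, ref)


def glc_position(
    traj: Trajectory,
    frame: int,
    glc: ResidueSpec,
    trp: ResidueSpec,
    use_masses: bool = False,
) -> float:
    """Signed distance along the channel axis (y) between the Glc centre
    of mass and the Trp C-alpha.

    The centre of mass uses unit masses (geometric centre) by default;
    for an all-heavy-atom Glc the difference from true masses is well
    under 0.1 A.
    """
    coords = traj.coords[frame]
    idx = traj.residue_indices(glc)
    if use_masses:
        m = np.array([ATOMIC_MASSES[traj.topology[i].element.upper()] for i in idx])
        com_y = float(np.average(coords[idx, 1], weights=m))
    else:
        com_y = float(np.mean(coords[idx, 1]))
    ca_y = float(coords[traj.atom_index((trp[0], trp[1], "CA")), 1])
    return com_y - ca_y


def rmsd_series(
    traj: Trajectory,
    selection: Selection | np.ndarray,
    reference_frame: int = 0,
    fit: bool = True,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-frame RMSD of a selection against a reference frame (A).

    With ``fit=True`` each frame's selection is first superposed onto the
    reference selection by the optimal rigid transform.
    """
    idx = selection.resolve(traj.topology) if isinstance(selection, Selection) else np.asarray(selection)
    if fit and idx.size < 3:
        raise ValueError("least-squares fitting needs at least 3 atoms")
    frames = resolve_window(traj, window)
    ref = traj.coords[reference_frame][idx]
    out = np.empty(frames.size)
    for k, f in enumerate(frames):
        mobile = traj.coords[f][idx]
        if fit:
            R, t = kabsch(mobile, ref)
            mobile = mobile @ R.T + t
        out[k] = float(np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1))))
    return out


def _representative_atom(traj: Trajectory, spec: ResidueSpec) -> int | None:
    """CA for amino acids, C1 for Glc residues."""
    name = "C1" if traj.residue_name(spec) in GLC_RESIDUES else "CA"
    try:
        return traj.atom_index((spec[0], spec[1], name))
    except KeyError:
        return None


def rmsf_per_residue(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    fit: bool = True,
) -> dict[ResidueSpec, float | None]:
    """Root-mean-square fluctuation of each residue's representative atom.

    Representative atoms are the C-alpha of amino acid residues and the
    C1 of Glc residues.  Window frames are superposed onto the
    window-mean structure before the fluctuations are measured; the fit
    uses the protein backbone (the C-alpha subset) when at least three
    C-alphas exist, so mobile glucan residues cannot drag the frame of
    reference, and falls back to all representative atoms otherwise.
    Residues lacking their representative atom are reported as ``None``
    with a warning.
    """
    residues = traj.residues()
    rep = {spec: _representative_atom(traj, spec) for spec in residues}
    missing = [spec for spec, i in rep.items() if i is None]
    for spec in missing:
        warnings.warn(f"residue {spec[0]}:{spec[1]} lacks its representative atom", stacklevel=2)
    idx = np.array([i for i in rep.values() if i is not None])
    frames = resolve_window(traj, window)
    X = traj.coords[frames][:, idx, :].copy()
    if fit:
        if idx.size < 3:
            raise ValueError("RMSF fitting needs at least 3 representative atoms")
        ca_rows = np.array(
            [k for k, i in enumerate(idx) if traj.topology[i].atom_name == "CA"]
        )
        fit_rows = ca_rows if ca_rows.size >= 3 else np.arange(idx.size)
        # two-pass fit to the window-mean structure
        mean = X[0]
        for _ in range(2):
            fitted = np.empty_like(X)
            for k in range(X.shape[0]):
                R, t = kabsch(X[k][fit_rows], mean[fit_rows])
                fitted[k] = X[k] @ R.T + t
            mean = fitted.mean(axis=0)
        X = fitted
    mean = X.mean(axis=0)
    sq = np.mean(np.sum((X - mean[None]) ** 2, axis=2), axis=0)
    rmsf = np.sqrt(sq)
    out: dict[ResidueSpec, float | None] = {}
    k = 0
    for spec in residues:
        if rep[spec] is None:
            out[spec] = None
        else:
            out[spec] = float(rmsf[k])
            k += 1
    return out
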