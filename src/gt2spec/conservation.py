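"""Clade-aware conservation classification of alignment columns.

Each column of a master alignment of glucan-synthase sub-families (e.g.
BcsA / CrdS / BgsA) is placed in one of four categories:

``FULL``
    identity above the *full* threshold (default >99%) across the pooled
    alignment -- catalytic-core style residues.
``DIFFERENTIAL``
    every clade individually conserved above the *differential* threshold
    (default >90%) with a different consensus residue in at least one
    clade; or, as a special case, all but one clade conserved while the
    remaining clade never samples the conserved residue type of the
    passing clades above a small noise floor.  These columns are the
    candidate specificity determinants.
``STRONG``
    pooled identity above the *strong* threshold (default >75%).
``NONE``
    everything else.

All threshold comparisons are strict (``>``).  Precedence is
FULL > DIFFERENTIAL > STRONG > NONE, so a >99% pooled column can never be
reported as differential and the category sets are disjoint.

Identity denominators only count non-gap characters; ``X`` participates
in frequencies as a 21st symbol but can never be a consensus residue, so
unknown characters cannot create spurious conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SequenceRecord

__all__ = [
    "Category",
    "ConservationThresholds",
    "CladeAlignment",
    "ColumnFrequencies",
    "CladeColumnStats",
    "ColumnProfile",
    "column_frequencies",
    "consensus_residue",
    "classify_column",
    "map_to_reference",
    "conservation_profile",
    "profile_table",
    "category_counts",
    "logo_matrix",
]

ALL = "ALL"
_N_RESIDUE_TYPES = 20  # alphabet size used for logo information content


class Category(str, Enum):
    FULL = "FULL"
    STRONG = "STRONG"
    DIFFERENTIAL = "DIFFERENTIAL"
    NONE = "NONE"


@dataclass(frozen=True)
class ConservationThresholds:
    """Identity fractions used by :func:`classify_column` (strict ``>``)."""

    full: float = 0.99
    strong: float = 0.75
    differential: float = 0.90
    noise_floor: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.strong < self.differential < self.full <= 1:
            raise ValueError("thresholds must satisfy 0 < strong < differential < full <= 1")
        if not 0 <= self.noise_floor < self.strong:
            raise ValueError("noise_floor must lie in [0, strong)")


@dataclass
class CladeAlignment:
    """A master alignment plus clade labels and a reference sequence.

    The ungapped numbering of ``reference_id`` anchors every report.
    """

    records: list[SequenceRecord]
    clade_of: dict[str, str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain records")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"records must share one aligned length, got {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        missing = [i for i in ids if i not in self.clade_of]
        if missing:
            raise ValueError(f"records without clade assignment: {missing[:5]}")
        if self.reference_id not in set(ids):
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")
        if len(self.clades) < 2:
            raise ValueError("alignment must contain at least two clades")
        ref = self.record(self.reference_id)
        if ref.ungapped_length == 0:
            raise ValueError("reference sequence is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def clades(self) -> list[str]:
        return sorted({self.clade_of[r.id] for r in self.records})

    def record(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def column(self, column: int, clade: str = ALL) -> list[str]:
        """Characters of one column, optionally restricted to a clade."""
        if not 0 <= column < self.n_columns:
            raise IndexError(f"column {column} outside alignment of {self.n_columns}")
        if clade != ALL and clade not in self.clades:
            raise KeyError(f"unknown clade {clade!r}")
        return [
            rec.residues[column]
            for rec in self.records
            if clade == ALL or self.clade_of[rec.id] == clade
        ]


@dataclass(frozen=True)
class ColumnFrequencies:
    """Non-gap residue frequencies of one column plus gap coverage."""

    freqs: dict[str, float]
    coverage: float


def column_frequencies(aln: CladeAlignment, column: int, clade: str = ALL) -> ColumnFrequencies:
    """Residue frequencies over non-gap characters of one column.

    Frequencies sum to 1 whenever any non-gap character is present; an
    all-gap column yields an empty map with coverage 0.  ``X`` counts as
    its own symbol.
    """
    chars = aln.column(column, clade)
    non_gap = [c for c in chars if c != "-"]
    coverage = len(non_gap) / len(chars) if chars else 0.0
    if not non_gap:
        return ColumnFrequencies(freqs={}, coverage=0.0)
    counts: dict[str, int] = {}
    for c in non_gap:
        counts[c] = counts.get(c, 0) + 1
    total = len(non_gap)
    return ColumnFrequencies(
        freqs={r: n / total for r, n in sorted(counts.items())},
        coverage=coverage,
    )


def consensus_residue(freqs: Mapping[str, float]) -> tuple[str | None, float, bool]:
    """Consensus residue, its identity, and whether the top was tied.

    ``X`` is ineligible as a consensus residue.  Ties are broken
    alphabetically and flagged.
    """
    eligible = {r: f for r, f in freqs.items() if r != "X"}
    if not eligible:
        return None, 0.0, False
    top = max(eligible.values())
    winners = sorted(r for r, f in eligible.items() if f == top)
    return winners[0], top, len(winners) > 1


def _pooled_identity(pooled_freqs: Mapping[str, float]) -> float:
    _, identity, _ = consensus_residue(pooled_freqs)
    return identity


def classify_column(
    per_clade_freqs: Mapping[str, Mapping[str, float]],
    pooled_freqs: Mapping[str, float],
    thresholds: ConservationThresholds = ConservationThresholds(),
    mode: str = "pooled",
) -> Category:
    """Assign one column to FULL / DIFFERENTIAL / STRONG / NONE.

    ``mode="pooled"`` (default) evaluates FULL and STRONG on the pooled
    all-clade frequencies; ``mode="per_clade"`` instead requires every
    clade to exceed the threshold individually with the same consensus.
    DIFFERENTIAL is always evaluated per clade.
    """
    if mode not in ("pooled", "per_clade"):
        raise ValueError("mode must be 'pooled' or 'per_clade'")
    covered = {c: f for c, f in per_clade_freqs.items() if f}
    if len(covered) < 2:
        raise ValueError("classification needs at least two clades with coverage")

    cons = {c: consensus_residue(f) for c, f in covered.items()}
    identities = {c: ident for c, (_, ident, _) in cons.items()}
    residues = {c: res for c, (res, _, _) in cons.items()}

    def shared_above(threshold: float) -> bool:
        if mode == "pooled":
            return _pooled_identity(pooled_freqs) > threshold
        same = len({r for r in residues.values()}) == 1
        return same and all(ident > threshold for ident in identities.values())

    if shared_above(thresholds.full):
        return Category.FULL

    passing = [c for c in covered if identities[c] > thresholds.differential]
    failing = [c for c in covered if c not in passing]
    if not failing:
        if len(set(residues.values())) > 1:
            return Category.DIFFERENTIAL
    elif len(failing) == 1:
        fail = failing[0]
        passing_consensus = {residues[c] for c in passing}
        sampled = {
            r for r, f in covered[fail].items() if f > thresholds.noise_floor
        }
        if not sampled & passing_consensus:
            return Category.DIFFERENTIAL

    if shared_above(thresholds.strong):
        return Category.STRONG
    return Category.NONE


def map_to_reference(aln: CladeAlignment) -> dict[int, int | None]:
    """Map alignment columns to ungapped reference positions (1-based).

    Columns where the reference is gapped map to ``None``.
    """
    ref = aln.record(aln.reference_id)
    mapping: dict[int, int | None] = {}
    pos = 0
    for col, ch in enumerate(ref.residues):
        if ch == "-":
            mapping[col] = None
        else:
            pos += 1
            mapping[col] = pos
    return mapping


@dataclass(frozen=True)
class CladeColumnStats:
    consensus: str | None
    identity: float
    coverage: float
    tie: bool


@dataclass(frozen=True)
class ColumnProfile:
    """Classification record for one alignment column."""

    column: int
    per_clade: dict[str, CladeColumnStats]
    pooled_identity: float
    pooled_consensus: str | None
    category: Category
    ref_position: int | None


def conservation_profile(
    aln: CladeAlignment,
    thresholds: ConservationThresholds = ConservationThresholds(),
    mode: str = "pooled",
) -> list[ColumnProfile]:
    """Classify every column of the alignment.

    Columns covered in fewer than two clades cannot be classified and are
    reported as ``NONE`` with their coverage; the per-column coverage
    values let the user judge such regions (e.g. truncated alignments).
    """
    ref_map = map_to_reference(aln)
    profiles = []
    for col in range(aln.n_columns):
        per_clade_cf = {c: column_frequencies(aln, col, c) for c in aln.clades}
        pooled = column_frequencies(aln, col, ALL)
        pooled_res, pooled_ident, _ = consensus_residue(pooled.freqs)
        covered = sum(1 for cf in per_clade_cf.values() if cf.freqs)
        if covered < 2:
            category = Category.NONE
        else:
            category = classify_column(
                {c: cf.freqs for c, cf in per_clade_cf.items()},
                pooled.freqs,
                thresholds,
                mode=mode,
            )
        stats = {}
        for c, cf in per_clade_cf.items():
            res, ident, tie = consensus_residue(cf.freqs)
            stats[c] = CladeColumnStats(
                consensus=res, identity=ident, coverage=cf.coverage, tie=tie
            )
        profiles.append(
            ColumnProfile(
                column=col,
                per_clade=stats,
                pooled_identity=pooled_ident,
                pooled_consensus=pooled_res,
                category=category,
                ref_position=ref_map[col],
            )
        )
    return profiles


def profile_table(profiles: Sequence[ColumnProfile], clades: Iterable[str]) -> pd.DataFrame:
    """Flatten profiles to the report layout: column, ref position,
    category, then per-clade consensus / identity / coverage."""
    clades = list(clades)
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "column": p.column,
            "ref_position": p.ref_position,
            "category": p.category.value,
            "pooled_consensus": p.pooled_consensus,
            "pooled_identity": round(p.pooled_identity, 4),
        }
        for c in clades:
            s = p.per_clade[c]
            row[f"{c}_consensus"] = (s.consensus or "") + ("*" if s.tie else "")
            row[f"{c}_identity"] = round(s.identity, 4)
            row[f"{c}_coverage"] = round(s.coverage, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def category_counts(profiles: Sequence[ColumnProfile]) -> dict[str, int]:
    counts = {cat.value: 0 for cat in Category}
    for p in profiles:
        counts[p.category.value] += 1
    return counts


def logo_matrix(aln: CladeAlignment, clade: str) -> list[dict[str, float]]:
    """Per-column sequence-logo heights in bits for one clade.

    Column information content is ``log2(20) - H`` where ``H`` is the
    Shannon entropy of the non-gap frequencies; each residue's height is
    its frequency times the column information.  All-gap columns yield an
    empty (zero) row.
    """
    if clade != ALL and clade not in aln.clades:
        raise KeyError(f"unknown clade {clade!r}")
    matrix = []
    for col in range(aln.n_columns):
        cf = column_frequencies(aln, col, clade)
        if not cf.freqs:
            matrix.append({})
            continue
        entropy = -sum(f * math.log2(f) for f in cf.freqs.values() if f > 0)
        info = max(math.log2(_N_RESIDUE_TYPES) - entropy, 0.0)
        matrix.append({r: f * info for r, f in cf.freqs.items()})
    return matrix
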