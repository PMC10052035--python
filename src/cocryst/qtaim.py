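"""Interaction energies from bond-critical-point descriptors.

Within the quantum theory of atoms in molecules, each non-covalent
contact in a crystal carries a (3,-1) bond critical point.  Closed-shell
contacts (positive Laplacian) with electron density rho_b above
0.003 a.u. are retained, and the interaction energy is estimated from the
local kinetic energy density G_b at the critical point by the linear
correlation

    E_int (kJ/mol) = 1147 * G_b (a.u.)

which holds across conventional and non-conventional hydrogen bonds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "EINT_PER_GB",
    "RHO_B_MIN",
    "CriticalPoint",
    "InteractionEnergyRecord",
    "filter_critical_points",
    "interaction_energy",
    "rank_interactions",
]

#: Slope of the E_int vs G_b correlation, kJ/mol per a.u.
EINT_PER_GB = 1147.0
#: Electron-density retention cutoff at the (3,-1) point, a.u. (strict >).
RHO_B_MIN = 0.003

_CP_TYPE_RE = re.compile(r"^\(\s*3\s*,\s*([+-]?\d+)\s*\)$")

BondClass = Literal["conventional-H-bond", "non-conventional", "other"]


@dataclass(frozen=True)
class CriticalPoint:
    """One critical point of the crystal electron density."""

    cp_id: str
    cp_type: str  # signature, e.g. "(3,-1)"
    rho_b: float  # a.u.
    laplacian: float  # a.u.
    g_b: float  # a.u.
    atom_pair: tuple[str, str] = ("", "")
    distance: float | None = None  # Angstrom

    def __post_init__(self) -> None:
        if not _CP_TYPE_RE.match(self.cp_type.replace(" ", "") or ""):
            raise ValueError(
                f"critical point {self.cp_id!r}: malformed cp_type {self.cp_type!r}"
            )
        if self.rho_b < 0:
            raise ValueError(f"critical point {self.cp_id!r}: rho_b < 0")
        if self.g_b < 0:
            raise ValueError(f"critical point {self.cp_id!r}: g_b < 0")

    @property
    def is_bond_cp(self) -> bool:
        m = _CP_TYPE_RE.match(self.cp_type.replace(" ", ""))
        return m is not None and int(m.group(1)) == -1


@dataclass(frozen=True)
class InteractionEnergyRecord:
    cp_id: str
    e_int: float  # kJ/mol
    bond_class: BondClass = "other"


def filter_critical_points(
    points: Sequence[CriticalPoint],
    max_distance: float | None = None,
) -> list[CriticalPoint]:
    """Retain bond critical points of genuine closed-shell contacts.

    Keeps exactly the (3,-1) points with positive Laplacian and
    rho_b strictly above 0.003 a.u., preserving input order.
    `max_distance` optionally drops records whose stored contact distance
    exceeds it (records without a distance are kept).
    """
    out = []
    for p in points:
        if not p.is_bond_cp:
            continue
        if p.laplacian <= 0 or p.rho_b <= RHO_B_MIN:
            continue
        if (
            max_distance is not None
            and p.distance is not None
            and p.distance > max_distance
        ):
            continue
        out.append(p)
    return out


def interaction_energy(g_b: float) -> float:
    """E_int = 1147 * G_b, kJ/mol (G_b in a.u.)."""
    if g_b < 0:
        raise ValueError(f"g_b must be non-negative, got {g_b}")
    return EINT_PER_GB * g_b


def rank_interactions(
    records: Sequence[InteractionEnergyRecord], top_k: int | None = None
) -> list[InteractionEnergyRecord]:
    """Stable sort by interaction energy descending; ties break by cp_id."""
    ranked = sorted(records, key=lambda r: (-r.e_int, r.cp_id))
    return ranked if top_k is None else ranked[:top_k]


def energies_from_points(
    points: Sequence[CriticalPoint],
    bond_classes: dict[str, BondClass] | None = None,
) -> list[InteractionEnergyRecord]:
    """Filter points and attach E_int; bond classes come from input labels."""
    bond_classes = bond_classes or {}
    return [
        InteractionEnergyRecord(
            cp_id=p.cp_id,
            e_int=interaction_energy(p.g_b),
            bond_class=bond_classes.get(p.cp_id, "other"),
        )
        for p in filter_critical_points(points)
    ]
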