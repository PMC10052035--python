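"""Molecular electrostatic potential (MEP) based cocrystal screening.

Hydrogen-bond donor and acceptor strengths are read off the extrema of a
molecule's electrostatic potential surface: surface maxima (near acidic
protons) map to dimensionless donor parameters ``alpha``, surface minima
(near lone pairs) to acceptor parameters ``beta``.  Sites are then paired
hierarchically — best donor with best acceptor, second-best with
second-best, and so on — and each pair contributes ``-alpha * beta`` to the
pairing energy ``E`` of the solid.

For a hypothetical 1:1 cocrystal of an API with a coformer, the screening
score is

    dE = E_cc - E_1 - E_2

where ``E_1`` and ``E_2`` are the pairing energies of the two pure solids
and ``E_cc`` that of the combined system.  ``dE < 0`` means the mixed solid
pairs its hydrogen-bond sites more favourably than the pure solids do
separately, i.e. cocrystallization is likely.

Two pairing variants for ``E_cc`` are implemented:

* method ``"A"`` — cross pairing only: API donors with coformer acceptors
  plus coformer donors with API acceptors;
* method ``"B"`` — the donor and acceptor lists of both molecules are
  merged, re-ranked, and paired hierarchically, so homomeric contacts may
  survive in the hypothetical cocrystal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "DEFAULT_DONOR_COEFFS",
    "DEFAULT_ACCEPTOR_COEFFS",
    "InteractionSite",
    "MoleculeSites",
    "PairingResult",
    "ScreeningScore",
    "site_param_from_esp",
    "pairing_energy",
    "cocrystal_pairing",
    "delta_e",
    "rank_coformers",
]

#: Quadratic coefficients (c2, c1) of the ESP -> site-parameter map,
#: alpha = c2*V**2 + c1*V for donors and beta = c2*V**2 - c1*V for
#: acceptors, with V the surface extremum in kJ/mol (Hunter-type
#: calibration against hydrogen-bond scales).
DEFAULT_DONOR_COEFFS: tuple[float, float] = (1.62e-5, 9.62e-3)
DEFAULT_ACCEPTOR_COEFFS: tuple[float, float] = (1.46e-4, 9.30e-3)

KCAL_TO_KJ = 4.184

SiteKind = Literal["donor", "acceptor"]
PairingMethod = Literal["A", "B"]


def site_param_from_esp(
    esp_value: float,
    kind: SiteKind,
    coefficients: tuple[float, float] | None = None,
) -> float:
    """Convert an ESP surface extremum (kJ/mol) to a site parameter.

    Donors (ESP maxima, ``esp_value >= 0``) yield ``alpha``; acceptors
    (ESP minima, ``esp_value <= 0``) yield ``beta``.  Both are
    non-negative under the default calibration.

    Parameters
    ----------
    esp_value : float
        Electrostatic potential at the surface extremum, kJ/mol.
    kind : {"donor", "acceptor"}
    coefficients : (c2, c1), optional
        Quadratic map coefficients; defaults depend on `kind`.
    """
    if kind == "donor":
        if esp_value < 0:
            raise ValueError(
                f"donor site requires esp_value >= 0, got {esp_value}"
            )
        c2, c1 = coefficients if coefficients is not None else DEFAULT_DONOR_COEFFS
        return c2 * esp_value**2 + c1 * esp_value
    if kind == "acceptor":
        if esp_value > 0:
            raise ValueError(
                f"acceptor site requires esp_value <= 0, got {esp_value}"
            )
        c2, c1 = coefficients if coefficients is not None else DEFAULT_ACCEPTOR_COEFFS
        return c2 * esp_value**2 - c1 * esp_value
    raise ValueError(f"unknown site kind: {kind!r}")


@dataclass(frozen=True)
class InteractionSite:
    """One hydrogen-bond donor or acceptor site of a molecule."""

    site_id: str
    kind: SiteKind
    esp_value: float  # kJ/mol; >= 0 for donors, <= 0 for acceptors
    param: float  # alpha (donor) or beta (acceptor), dimensionless

    @classmethod
    def from_esp(
        cls,
        site_id: str,
        kind: SiteKind,
        esp_value: float,
        coefficients: tuple[float, float] | None = None,
    ) -> "InteractionSite":
        return cls(site_id, kind, esp_value,
                   site_param_from_esp(esp_value, kind, coefficients))


@dataclass
class MoleculeSites:
    """Ranked donor and acceptor site lists of one molecule.

    Lists are kept sorted by `param` descending; a site id may not appear
    in both lists.
    """

    molecule_id: str
    donors: list[InteractionSite] = field(default_factory=list)
    acceptors: list[InteractionSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.donors:
            if s.kind != "donor":
                raise ValueError(f"site {s.site_id} in donor list has kind {s.kind}")
        for s in self.acceptors:
            if s.kind != "acceptor":
                raise ValueError(
                    f"site {s.site_id} in acceptor list has kind {s.kind}"
                )
        dup = {s.site_id for s in self.donors} & {s.site_id for s in self.acceptors}
        if dup:
            raise ValueError(f"sites in both donor and acceptor lists: {sorted(dup)}")
        self.donors.sort(key=lambda s: -s.param)
        self.acceptors.sort(key=lambda s: -s.param)


@dataclass(frozen=True)
class PairingResult:
    """Hierarchical site-pairing outcome for one (real or hypothetical) solid."""

    energy: float
    pairs: tuple[tuple[str, str, float], ...]  # (donor id, acceptor id, -a*b)
    unpaired: tuple[str, ...]


@dataclass(frozen=True)
class ScreeningScore:
    api_id: str
    coformer_id: str
    method: PairingMethod
    e_api: float
    e_coformer: float
    e_cocrystal: float
    delta_e: float
    verdict: Literal["favorable", "unfavorable"]


def _paired(
    donors: Sequence[InteractionSite], acceptors: Sequence[InteractionSite]
) -> PairingResult:
    d = sorted(donors, key=lambda s: -s.param)
    a = sorted(acceptors, key=lambda s: -s.param)
    k = min(len(d), len(a))
    pairs = tuple(
        (d[i].site_id, a[i].site_id, -d[i].param * a[i].param) for i in range(k)
    )
    unpaired = tuple(s.site_id for s in d[k:]) + tuple(s.site_id for s in a[k:])
    return PairingResult(energy=sum(p[2] for p in pairs), pairs=pairs,
                         unpaired=unpaired)


def pairing_energy(
    donors: Iterable[InteractionSite | float],
    acceptors: Iterable[InteractionSite | float],
) -> PairingResult:
    """Hierarchical pairing energy E = -sum(alpha_i * beta_i).

    Both lists are sorted descending and paired rank for rank over
    ``min(n_donors, n_acceptors)`` pairs; excess sites stay unpaired with
    zero contribution.  Bare floats are accepted as anonymous parameters.

    By the rearrangement inequality this rank-for-rank matching minimises
    E over all one-to-one assignments (it maximises the paired sum of
    products), i.e. it is the most stabilising pairing.
    """
    def as_sites(vals, kind):
        out = []
        for i, v in enumerate(vals):
            if isinstance(v, InteractionSite):
                out.append(v)
            else:
                out.append(InteractionSite(f"{kind}{i}", kind, 0.0, float(v)))
        return out

    return _paired(as_sites(donors, "donor"), as_sites(acceptors, "acceptor"))


def homomeric_energy(mol: MoleculeSites) -> PairingResult:
    """Pairing energy of the pure solid of one molecule (E_1 or E_2)."""
    return _paired(mol.donors, mol.acceptors)


def cocrystal_pairing(
    api: MoleculeSites, cf: MoleculeSites, method: PairingMethod
) -> PairingResult:
    """Pairing energy E_cc of a hypothetical 1:1 cocrystal.

    Method "A" pairs across the components only (API donors with coformer
    acceptors and vice versa); method "B" merges and re-ranks all donor
    and all acceptor sites before hierarchical pairing.
    """
    if method == "A":
        r1 = _paired(api.donors, cf.acceptors)
        r2 = _paired(cf.donors, api.acceptors)
        return PairingResult(
            energy=r1.energy + r2.energy,
            pairs=r1.pairs + r2.pairs,
            unpaired=r1.unpaired + r2.unpaired,
        )
    if method == "B":
        return _paired(api.donors + cf.donors, api.acceptors + cf.acceptors)
    raise ValueError(f"unknown pairing method: {method!r} (expected 'A' or 'B')")


def delta_e(
    api: MoleculeSites, cf: MoleculeSites, method: PairingMethod
) -> ScreeningScore:
    """Screening score dE = E_cc - E_1 - E_2 for a 1:1 cocrystal.

    Negative dE (the mixed pairing is more stabilising than the pure
    solids) is classified favorable; dE = 0 is unfavorable under the
    strict inequality.
    """
    e1 = homomeric_energy(api).energy
    e2 = homomeric_energy(cf).energy
    ecc = cocrystal_pairing(api, cf, method).energy
    de = ecc - e1 - e2
    return ScreeningScore(
        api_id=api.molecule_id,
        coformer_id=cf.molecule_id,
        method=method,
        e_api=e1,
        e_coformer=e2,
        e_cocrystal=ecc,
        delta_e=de,
        verdict="favorable" if de < 0 else "unfavorable",
    )


def rank_coformers(
    api: MoleculeSites,
    coformers: Sequence[MoleculeSites],
    method: PairingMethod,
) -> list[ScreeningScore]:
    """Rank coformers by dE ascending (most favorable first).

    Ties are broken by coformer id, lexicographically.
    """
    if not coformers:
        raise ValueError("at least one coformer is required")
    scores = [delta_e(api, cf, method) for cf in coformers]
    scores.sort(key=lambda s: (s.delta_e, s.coformer_id))
    return scores
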