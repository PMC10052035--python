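"""Cocrystal formation thermodynamics from solubility data.

For the reaction  x·A(s) + y·B(s) -> A_x B_y (s)  the formation constant
follows from saturated-solution activities of the pure components
(a_p) and the component activities in equilibrium with the cocrystal
(a_cc), activities approximated by molar concentrations:

    ln K_f = x ln(a_p,A / a_cc,A) + y ln(a_p,B / a_cc,B)
    dG_form = -R T ln K_f
    d(ln K_f)/d(1/T) = -dH_form / R        (van't Hoff)
    dS_form = (dH_form - dG_form) / T

Aqueous stability of a 1:1 cocrystal relative to the drug is quantified
at the eutectic point (drug and cocrystal solids both in equilibrium with
solution) by the eutectic constant K_eu = [coformer]_eu / [drug]_eu and
the cocrystal solubility S_cc = sqrt([drug]_eu * [coformer]_eu); the
cocrystal is thermodynamically stable when K_eu <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "SolubilityRecord",
    "CocrystalSystem",
    "FormationThermodynamics",
    "EutecticRecord",
    "formation_constant",
    "gibbs_formation",
    "ln_kf_from_gibbs",
    "vant_hoff_fit",
    "entropy_term",
    "sector_classify",
    "eutectic_constant",
    "cocrystal_solubility",
    "stability_class",
    "formation_thermodynamics",
]

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class SolubilityRecord:
    """One saturated-solution solubility measurement."""

    compound_id: str
    solvent: str
    temperature: float  # K
    solubility: float  # mol/L
    replicate_sd: float | None = None  # mol/L

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.solubility <= 0:
            raise ValueError(f"solubility must be positive, got {self.solubility}")


@dataclass
class CocrystalSystem:
    """Matched-temperature solubility data for one binary cocrystal system.

    ``pure`` maps temperature (K) to the pure-component saturation
    concentrations (a_p,A, a_p,B); ``cocrystal`` maps the same
    temperatures to the component concentrations in equilibrium with the
    cocrystal (a_cc,A, a_cc,B).  All concentrations mol/L.
    """

    api_id: str
    coformer_id: str
    stoichiometry: tuple[int, int]
    pure: dict[float, tuple[float, float]]
    cocrystal: dict[float, tuple[float, float]]

    def __post_init__(self) -> None:
        x, y = self.stoichiometry
        if x < 1 or y < 1:
            raise ValueError(f"stoichiometric coefficients must be >= 1, got {x}:{y}")
        missing = set(self.cocrystal) - set(self.pure)
        if missing:
            raise ValueError(
                f"cocrystal temperatures without pure-component data: {sorted(missing)}"
            )

    def ln_kf_series(self) -> list[tuple[float, float]]:
        """(T, ln K_f) pairs at every matched temperature, T ascending."""
        out = []
        for T in sorted(self.cocrystal):
            a_pA, a_pB = self.pure[T]
            a_ccA, a_ccB = self.cocrystal[T]
            out.append(
                (T, formation_constant(a_pA, a_pB, a_ccA, a_ccB, *self.stoichiometry))
            )
        return out


@dataclass(frozen=True)
class FormationThermodynamics:
    """Formation functions of one cocrystal at a reference temperature.

    Energies in kJ/mol; uncertainties are one standard error (``nan``
    when not estimable).
    """

    ln_kf: float
    ln_kf_se: float
    gibbs: float
    gibbs_se: float
    enthalpy: float
    enthalpy_se: float
    entropy_term: float  # T * dS_form, kJ/mol
    entropy_term_se: float
    reference_temperature: float  # K


@dataclass(frozen=True)
class EutecticRecord:
    """Eutectic-point stability metrics of a 1:1 cocrystal."""

    cbz_eu: float  # drug eutectic concentration, mol/L
    cf_eu: float  # coformer eutectic concentration, mol/L
    k_eu: float
    k_eu_se: float
    s_cc: float  # mol/L
    s_cc_se: float
    cf_intrinsic: float | None = None  # S_0 of the coformer, mol/L
    stable: bool = False


def formation_constant(
    a_pA: float,
    a_pB: float,
    a_ccA: float,
    a_ccB: float,
    x: int = 1,
    y: int = 1,
) -> float:
    """ln K_f from pure-component and cocrystal-equilibrium concentrations.

    K_f = (a_p,A^x * a_p,B^y) / K_sp with K_sp = a_cc,A^x * a_cc,B^y.
    """
    for name, v in (("a_pA", a_pA), ("a_pB", a_pB),
                    ("a_ccA", a_ccA), ("a_ccB", a_ccB)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return x * math.log(a_pA / a_ccA) + y * math.log(a_pB / a_ccB)


def solubility_product(a_ccA: float, a_ccB: float, x: int = 1, y: int = 1) -> float:
    """Cocrystal solubility product K_sp = a_cc,A^x * a_cc,B^y."""
    if a_ccA <= 0 or a_ccB <= 0:
        raise ValueError("concentrations must be positive")
    return a_ccA**x * a_ccB**y


def gibbs_formation(ln_kf: float, temperature: float) -> float:
    """dG_form = -R T ln K_f, in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -R_GAS * temperature * ln_kf / 1000.0


def ln_kf_from_gibbs(gibbs: float, temperature: float) -> float:
    """Invert dG_form = -R T ln K_f (gibbs in kJ/mol)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -gibbs * 1000.0 / (R_GAS * temperature)


def vant_hoff_fit(series: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Formation enthalpy from a (T, ln K_f) series by van't Hoff analysis.

    Ordinary least squares of ln K_f against 1/T; dH_form = -R * slope,
    assumed constant over the temperature range.  Returns (dH_form,
    standard error), both kJ/mol; the SE is ``nan`` for a two-point
    series.
    """
    if len(series) < 2:
        raise ValueError("van't Hoff fit needs at least two temperatures")
    T = np.asarray([t for t, _ in series], dtype=float)
    lnk = np.asarray([k for _, k in series], dtype=float)
    if np.unique(T).size < 2:
        raise ValueError("all temperatures identical: singular design")
    fit = stats.linregress(1.0 / T, lnk)
    dh = -R_GAS * fit.slope / 1000.0
    dh_se = R_GAS * fit.stderr / 1000.0 if len(series) > 2 else math.nan
    return dh, dh_se


def entropy_term(enthalpy: float, gibbs: float, temperature: float) -> tuple[float, float]:
    """(T*dS_form in kJ/mol, dS_form in J/mol/K) from dH and dG."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    tds = enthalpy - gibbs
    return tds, tds * 1000.0 / temperature


# Octant letters on the (dH, TdS) plane, counterclockwise from the
# positive dH axis.  A (entropy-driven, TdS > 0 dominant with dH < 0) and
# D (enthalpy-driven, both negative with |dH| > |TdS|) are fixed by the
# driving-force analysis; the remaining letters fill the other octants
# counterclockwise after A and are purely conventional.
_OCTANT_LETTERS = ("G", "H", "A", "B", "D", "C", "E", "F")

Category = Literal[
    "enthalpy-driven", "entropy-driven", "cooperative", "formation-unfavorable"
]


def sector_classify(enthalpy: float, entropy_term_kj: float) -> tuple[str, Category]:
    """Place a system on the enthalpy–entropy diagram.

    The (dH, TdS) plane is split into eight sectors by the axes and the
    quadrant bisectors.  Returns ``(sector letter, driving-force
    category)``; dG = dH - TdS decides favourability, and the dominant
    term (larger magnitude) names the driving force.  Boundary ties
    |dH| = |TdS| are assigned to the enthalpy-dominant sector.
    """
    dh, tds = float(enthalpy), float(entropy_term_kj)
    if not (math.isfinite(dh) and math.isfinite(tds)):
        raise ValueError("enthalpy and entropy term must be finite")
    dg = dh - tds

    if dh == 0.0 and tds == 0.0:
        return "origin", "formation-unfavorable"

    angle = math.degrees(math.atan2(tds, dh)) % 360.0
    octant = int(angle // 45.0) % 8
    # ties on a bisector go to the enthalpy-dominant (lower-angle) side in
    # quadrant III so that (-c, -c) is sector D
    if abs(dh) == abs(tds) and dh < 0 and tds < 0:
        octant = 4
    sector = _OCTANT_LETTERS[octant]

    if dg >= 0:
        category: Category = "formation-unfavorable"
    elif tds > 0 and abs(tds) > abs(dh):
        category = "entropy-driven"
    elif dh < 0 and tds < 0:
        category = "enthalpy-driven"
    else:  # dh < 0 and 0 < tds <= |dh|: both terms favour formation
        category = "cooperative"
    return sector, category


def eutectic_constant(
    cf_eu: float,
    cbz_eu: float,
    cf_eu_sd: float = 0.0,
    cbz_eu_sd: float = 0.0,
) -> tuple[float, float]:
    """K_eu = [coformer]_eu / [drug]_eu with quadrature-propagated SE."""
    if cf_eu <= 0 or cbz_eu <= 0:
        raise ValueError("eutectic concentrations must be positive")
    k = cf_eu / cbz_eu
    rel = math.hypot(cf_eu_sd / cf_eu, cbz_eu_sd / cbz_eu)
    return k, k * rel


def cocrystal_solubility(
    cbz_eu: float,
    cf_eu: float,
    cbz_eu_sd: float = 0.0,
    cf_eu_sd: float = 0.0,
    stoichiometry: tuple[int, int] = (1, 1),
) -> tuple[float, float]:
    """S_cc = sqrt([drug]_eu * [coformer]_eu) for a 1:1 cocrystal, mol/L."""
    if stoichiometry != (1, 1):
        raise ValueError(
            f"only 1:1 stoichiometry is supported, got {stoichiometry[0]}:{stoichiometry[1]}"
        )
    if cbz_eu <= 0 or cf_eu <= 0:
        raise ValueError("eutectic concentrations must be positive")
    s = math.sqrt(cbz_eu * cf_eu)
    rel = 0.5 * math.hypot(cbz_eu_sd / cbz_eu, cf_eu_sd / cf_eu)
    return s, s * rel


def stability_class(k_eu: float) -> Literal["stable", "unstable"]:
    """1:1 cocrystal is stable relative to the drug iff K_eu <= 1."""
    if k_eu <= 0:
        raise ValueError(f"k_eu must be positive, got {k_eu}")
    return "stable" if k_eu <= 1.0 else "unstable"


def eutectic_record(
    cbz_eu: float,
    cf_eu: float,
    cbz_eu_sd: float = 0.0,
    cf_eu_sd: float = 0.0,
    cf_intrinsic: float | None = None,
) -> EutecticRecord:
    """Assemble K_eu, S_cc and the stability verdict for one system."""
    k, k_se = eutectic_constant(cf_eu, cbz_eu, cf_eu_sd, cbz_eu_sd)
    s, s_se = cocrystal_solubility(cbz_eu, cf_eu, cbz_eu_sd, cf_eu_sd)
    return EutecticRecord(
        cbz_eu=cbz_eu, cf_eu=cf_eu, k_eu=k, k_eu_se=k_se,
        s_cc=s, s_cc_se=s_se, cf_intrinsic=cf_intrinsic,
        stable=stability_class(k) == "stable",
    )


def formation_thermodynamics(
    system: CocrystalSystem, reference_temperature: float = 298.15
) -> FormationThermodynamics:
    """End-to-end formation functions from matched-temperature solubilities.

    ln K_f at the reference temperature comes from the van't Hoff line
    (intercept + slope / T_ref), dH from its slope, dG = -R T ln K_f and
    T dS = dH - dG.  Uncertainties are OLS standard errors propagated
    through the linear relations.
    """
    series = system.ln_kf_series()
    if len(series) < 2:
        raise ValueError("need at least two temperatures")
    T = np.asarray([t for t, _ in series])
    lnk = np.asarray([k for _, k in series])
    fit = stats.linregress(1.0 / T, lnk)
    x_ref = 1.0 / reference_temperature
    ln_kf = fit.intercept + fit.slope * x_ref
    n = len(series)
    if n > 2:
        # SE of the fitted mean response at x_ref
        x = 1.0 / T
        resid = lnk - (fit.intercept + fit.slope * x)
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        ln_kf_se = math.sqrt(s2 * (1.0 / n + (x_ref - x.mean()) ** 2 / sxx))
        dh_se = R_GAS * fit.stderr / 1000.0
    else:
        ln_kf_se = math.nan
        dh_se = math.nan
    gibbs = gibbs_formation(ln_kf, reference_temperature)
    gibbs_se = R_GAS * reference_temperature * ln_kf_se / 1000.0
    dh = -R_GAS * fit.slope / 1000.0
    tds, _ = entropy_term(dh, gibbs, reference_temperature)
    tds_se = math.hypot(dh_se, gibbs_se)
    return FormationThermodynamics(
        ln_kf=ln_kf, ln_kf_se=ln_kf_se,
        gibbs=gibbs, gibbs_se=gibbs_se,
        enthalpy=dh, enthalpy_se=dh_se,
        entropy_term=tds, entropy_term_se=tds_se,
        reference_temperature=reference_temperature,
    )
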