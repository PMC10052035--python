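"""Seeded synthetic datasets with the statistical structure the analysis assumes.

Each generator is a pure function of its arguments (seed included), so a
repeated call reproduces its output exactly.  The generators emulate:

* temperature-resolved solubility series consistent with a van't Hoff
  ln K_f(T) = -dH/(R T) + dS/R line, with multiplicative lognormal
  measurement noise (solubilities are positive and errors roughly
  proportional to the value);
* two-population screening score sets (positive and negative
  cocrystallization outcomes) as unit-variance Gaussians separated by a
  standardized mean difference d, for which the true ROC area is
  Phi(d / sqrt(2));
* molecule site tables with ESP extrema drawn uniformly in
  sign-consistent ranges;
* bond-critical-point lists with a prescribed number of records passing
  the closed-shell retention filter.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .evaluate import LabeledScore
from .mep import InteractionSite, MoleculeSites
from .qtaim import RHO_B_MIN, CriticalPoint
from .thermo import R_GAS, CocrystalSystem

__all__ = [
    "simulate_solubility_dataset",
    "simulate_screening_scores",
    "simulate_sites",
    "simulate_critical_points",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative noise with coefficient of variation `cv`."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_solubility_dataset(
    delta_h: float = -9.5,
    delta_s: float = -8.05,
    temperatures: Sequence[float] = (293.15, 298.15, 303.15, 308.15, 313.15),
    noise_cv: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    api_id: str = "API",
    coformer_id: str = "CF",
    stoichiometry: tuple[int, int] = (1, 1),
) -> CocrystalSystem:
    """Matched-temperature solubility data for a 1:1 binary system.

    The noiseless data back-compute to ln K_f(T) = -dH/(R T) + dS/R
    exactly (`delta_h` in kJ/mol, `delta_s` in J/mol/K).  Pure-component
    baselines are smooth increasing exponentials of T; only the
    pure-to-cocrystal concentration ratios enter ln K_f, so their
    absolute form is immaterial.  Per replicate, every concentration is
    multiplied by independent lognormal noise with coefficient of
    variation `noise_cv`; stored concentrations are replicate means.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if len(temperatures) < 2:
        raise ValueError("need at least two temperatures")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    x, y = stoichiometry
    T = np.asarray(temperatures, dtype=float)
    ln_kf = -delta_h * 1000.0 / (R_GAS * T) + delta_s / R_GAS

    # arbitrary smooth increasing solubility baselines, mol/L
    a_pA = 0.10 * np.exp(0.03 * (T - 298.15))
    a_pB = 0.25 * np.exp(0.025 * (T - 298.15))
    # split ln K_f evenly between the two component ratios
    a_ccA = a_pA * np.exp(-ln_kf / (2.0 * x))
    a_ccB = a_pB * np.exp(-ln_kf / (2.0 * y))

    def noisy(base: np.ndarray) -> np.ndarray:
        reps = base[:, None] * _lognormal_factors(rng, noise_cv, (T.size, replicates))
        return reps.mean(axis=1)

    obs = {name: noisy(v) for name, v in
           (("pA", a_pA), ("pB", a_pB), ("ccA", a_ccA), ("ccB", a_ccB))}
    temps = [float(t) for t in T]
    return CocrystalSystem(
        api_id=api_id,
        coformer_id=coformer_id,
        stoichiometry=stoichiometry,
        pure={t: (float(obs["pA"][i]), float(obs["pB"][i]))
              for i, t in enumerate(temps)},
        cocrystal={t: (float(obs["ccA"][i]), float(obs["ccB"][i]))
                   for i, t in enumerate(temps)},
    )


def simulate_screening_scores(
    n_pos: int = 55,
    n_neg: int = 32,
    separation: float = 1.19,
    seed: int = 0,
) -> list[LabeledScore]:
    """Labelled scores: positives ~ N(d, 1), negatives ~ N(0, 1).

    Defaults mirror a screening benchmark of 55 experimentally positive
    and 32 negative coformer pairings; ``separation`` is the standardized
    mean difference d, so the population AUC is Phi(d / sqrt(2)).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one member")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    pos = rng.normal(separation, 1.0, n_pos)
    neg = rng.normal(0.0, 1.0, n_neg)
    out = [
        LabeledScore(f"pos{i:04d}", True, float(s)) for i, s in enumerate(pos)
    ] + [
        LabeledScore(f"neg{i:04d}", False, float(s)) for i, s in enumerate(neg)
    ]
    return out


def simulate_sites(
    n_donors: int,
    n_acceptors: int,
    donor_esp_range: tuple[float, float] = (50.0, 220.0),
    acceptor_esp_range: tuple[float, float] = (-220.0, -50.0),
    seed: int = 0,
    molecule_id: str = "MOL",
) -> MoleculeSites:
    """A molecule with uniform-random ESP extrema in kJ/mol."""
    if donor_esp_range[0] < 0:
        raise ValueError("donor ESP range must be non-negative")
    if acceptor_esp_range[1] > 0:
        raise ValueError("acceptor ESP range must be non-positive")
    rng = np.random.default_rng(seed)
    donors = [
        InteractionSite.from_esp(f"{molecule_id}_d{i}", "donor",
                                 float(rng.uniform(*donor_esp_range)))
        for i in range(n_donors)
    ]
    acceptors = [
        InteractionSite.from_esp(f"{molecule_id}_a{i}", "acceptor",
                                 float(rng.uniform(*acceptor_esp_range)))
        for i in range(n_acceptors)
    ]
    return MoleculeSites(molecule_id, donors, acceptors)


def simulate_critical_points(
    n: int,
    fraction_passing: float = 0.5,
    seed: int = 0,
) -> list[CriticalPoint]:
    """Critical points of which exactly round(n * fraction_passing) pass
    the (3,-1)/positive-Laplacian/rho_b retention filter."""
    if not 0.0 <= fraction_passing <= 1.0:
        raise ValueError("fraction_passing must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = int(np.rint(n * fraction_passing))
    points: list[CriticalPoint] = []
    for i in range(n):
        g_b = float(rng.uniform(0.002, 0.04))
        if i < n_pass:
            cp_type, lap = "(3,-1)", float(rng.uniform(0.01, 0.12))
            rho = float(rng.uniform(RHO_B_MIN * 1.5, 0.05))
        else:
            # violate exactly one retention condition at random
            mode = rng.integers(3)
            cp_type = "(3,+1)" if mode == 0 else "(3,-1)"
            lap = -float(rng.uniform(0.01, 0.12)) if mode == 1 else float(
                rng.uniform(0.01, 0.12))
            rho = float(rng.uniform(0.0005, RHO_B_MIN)) if mode == 2 else float(
                rng.uniform(RHO_B_MIN * 1.5, 0.05))
        points.append(
            CriticalPoint(
                cp_id=f"cp{i:03d}",
                cp_type=cp_type,
                rho_b=rho,
                laplacian=lap,
                g_b=g_b,
                atom_pair=(f"A{i}", f"B{i}"),
                distance=float(rng.uniform(1.6, 4.9)),
            )
        )
    order = rng.permutation(n)
    return [points[i] for i in order]
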