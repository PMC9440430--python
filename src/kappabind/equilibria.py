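"""Equilibrium solvers for NF-κB dimer binding to one- and two-site DNA.

All concentrations are in nM. The solvers work in the ligand-depletion
regime: bound protein is not assumed negligible relative to total protein,
so free protein is obtained from mass balance rather than approximated by
the total. For a single site this is the familiar quadratic isotherm; for
two discrete sites the species ladder (00, 10, 01, 11) is weighted by
statistical factors and the free-protein concentration is found by
root-finding on total-protein conservation.

The two-site model is parameterized by per-site dissociation constants
``kd_site1``/``kd_site2`` and a dimensionless cooperativity factor ``omega``
multiplying the doubly-bound state (ω = 1: independent sites; ω > 1:
positive cooperativity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingParams",
    "MixtureState",
    "single_site_complex",
    "hyperbolic_fraction",
    "two_site_species",
    "two_site_occupancies",
    "free_protein_two_site",
]

#: relative tolerance demanded of the mass-balance conservation checks
CONSERVATION_RTOL = 1e-9


@dataclass(frozen=True)
class BindingParams:
    """Thermodynamic and readout parameters of a binding model.

    Parameters
    ----------
    kd_site1, kd_site2 : float
        Per-site dissociation constants in nM. For a single-site model only
        ``kd_site1`` is used; ``kd_site2`` may be ``math.inf`` to disable
        the second site.
    omega : float
        Cooperativity factor weighting the doubly-occupied state. 1 means
        the two sites are independent.
    amplitude : float
        Maximum anisotropy change of a titration curve (per-curve nuisance
        parameter in fits).
    baseline : float
        Anisotropy of the free labeled DNA.
    """

    kd_site1: float
    kd_site2: float = math.inf
    omega: float = 1.0
    amplitude: float = 0.1
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.kd_site1 > 0:
            raise ValueError(f"kd_site1 must be > 0, got {self.kd_site1}")
        if not self.kd_site2 > 0:
            raise ValueError(f"kd_site2 must be > 0, got {self.kd_site2}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class MixtureState:
    """Equilibrium composition of a protein/two-site-DNA mixture (nM).

    ``species`` maps occupancy patterns '00', '10', '01', '11' (site 1,
    site 2) to DNA concentrations. Conservation of DNA and protein holds to
    ``CONSERVATION_RTOL``.
    """

    p_total: float
    d_total: float
    free_protein: float
    species: dict = field(default_factory=dict)

    def site_occupancies(self) -> tuple[float, float]:
        """Fractional occupancy (θ₁, θ₂) of each site."""
        if self.d_total == 0:
            return 0.0, 0.0
        th1 = (self.species["10"] + self.species["11"]) / self.d_total
        th2 = (self.species["01"] + self.species["11"]) / self.d_total
        return th1, th2

    def validate(self) -> None:
        if any(c < -1e-12 for c in self.species.values()):
            raise ValueError("negative species concentration")
        d_sum = sum(self.species.values())
        scale = max(self.d_total, 1.0)
        if abs(d_sum - self.d_total) > CONSERVATION_RTOL * scale:
            raise ValueError("DNA mass balance violated")
        bound = (
            self.species["10"] + self.species["01"] + 2.0 * self.species["11"]
        )
        scale = max(self.p_total, 1.0)
        if abs(self.free_protein + bound - self.p_total) > CONSERVATION_RTOL * scale:
            raise ValueError("protein mass balance violated")


def single_site_complex(p_total: float, d_total: float, kd: float) -> float:
    """Concentration of the 1:1 protein·DNA complex with ligand depletion.

    Solves the quadratic mass balance
    ``C² − (P₀ + D₀ + Kd)·C + P₀·D₀ = 0`` and returns the physically valid
    (smaller) root, which always lies in ``[0, min(P₀, D₀)]``.
    """
    if p_total < 0 or d_total < 0:
        raise ValueError("concentrations must be nonnegative")
    if not kd > 0:
        raise ValueError("kd must be > 0")
    s = p_total + d_total + kd
    disc = s * s - 4.0 * p_total * d_total
    # smaller root written in its cancellation-free form 2ac/(−b + √disc)
    c = 2.0 * p_total * d_total / (s + math.sqrt(max(disc, 0.0)))
    return min(max(c, 0.0), min(p_total, d_total))


def hyperbolic_fraction(p_free: float, kd: float) -> float:
    """Bound fraction x/(x + Kd): the no-depletion (Langmuir) isotherm.

    Valid when total protein ≫ total DNA so that free ≈ total protein;
    used for weak nonspecific binding where Kd ≫ [DNA].
    """
    if p_free < 0:
        raise ValueError("concentration must be nonnegative")
    if not kd > 0:
        raise ValueError("kd must be > 0")
    return p_free / (p_free + kd)


def _two_site_weights(params: BindingParams) -> tuple[float, float, float]:
    w1 = 1.0 / params.kd_site1
    w2 = 1.0 / params.kd_site2
    w12 = params.omega * w1 * w2
    return w1, w2, w12


def free_protein_two_site(
    p_total: np.ndarray | float,
    d_total: float,
    params: BindingParams,
    n_iter: int = 90,
) -> np.ndarray:
    """Vectorized free-protein solve for the two-site ladder.

    Bisection on total-protein conservation, which is strictly monotone in
    the free-protein concentration, so the bracket [0, p_total] always
    contains exactly one root. 90 halvings reach machine precision.
    """
    p = np.atleast_1d(np.asarray(p_total, dtype=float))
    if np.any(p < 0) or d_total < 0:
        raise ValueError("concentrations must be nonnegative")
    w1, w2, w12 = _two_site_weights(params)

    def excess(pf: np.ndarray) -> np.ndarray:
        z = 1.0 + pf * (w1 + w2) + pf * pf * w12
        bound = d_total * pf * (w1 + w2 + 2.0 * pf * w12) / z
        return pf + bound - p

    lo = np.zeros_like(p)
    hi = p.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        high_side = excess(mid) > 0
        hi = np.where(high_side, mid, hi)
        lo = np.where(high_side, lo, mid)
    return 0.5 * (lo + hi)


def two_site_species(
    p_total: float, d_total: float, params: BindingParams
) -> MixtureState:
    """Equilibrium species of a protein dimer binding two discrete DNA sites.

    The four occupancy species carry statistical weights
    ``[D10] = [D00]·P/Kd1``, ``[D01] = [D00]·P/Kd2`` and
    ``[D11] = [D00]·P²·ω/(Kd1·Kd2)`` at free protein P, which is found by
    bracketed root-finding on total-protein conservation.
    """
    if p_total < 0 or d_total < 0:
        raise ValueError("concentrations must be nonnegative")
    w1, w2, w12 = _two_site_weights(params)

    if p_total == 0 or d_total == 0:
        pf = p_total
    else:

        def excess(pf: float) -> float:
            z = 1.0 + pf * (w1 + w2) + pf * pf * w12
            bound = d_total * pf * (w1 + w2 + 2.0 * pf * w12) / z
            return pf + bound - p_total

        try:
            pf = brentq(
                excess,
                0.0,
                p_total,
                xtol=1e-300,
                rtol=4 * np.finfo(float).eps,
                maxiter=600,
            )
        except (ValueError, RuntimeError) as err:  # pragma: no cover
            raise ArithmeticError(
                f"free-protein solve failed for p={p_total}, d={d_total}, "
                f"params={params}: {err}"
            ) from err

    z = 1.0 + pf * (w1 + w2) + pf * pf * w12
    d00 = d_total / z
    species = {
        "00": d00,
        "10": d00 * pf * w1,
        "01": d00 * pf * w2,
        "11": d00 * pf * pf * w12,
    }
    # polish the free-protein value once so conservation holds to 1e-9 even
    # when bound protein nearly exhausts the pool
    bound = species["10"] + species["01"] + 2.0 * species["11"]
    pf = max(p_total - bound, 0.0)
    state = MixtureState(
        p_total=p_total, d_total=d_total, free_protein=pf, species=species
    )
    state.validate()
    return state


def two_site_occupancies(
    p_total: np.ndarray | float, d_total: float, params: BindingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Site occupancies (θ₁, θ₂) over an array of total-protein values.

    Vectorized companion of :func:`two_site_species` for titration-curve
    prediction inside fits and simulations.
    """
    pf = free_protein_two_site(p_total, d_total, params)
    w1, w2, w12 = _two_site_weights(params)
    z = 1.0 + pf * (w1 + w2) + pf * pf * w12
    th1 = (pf * w1 + pf * pf * w12) / z
    th2 = (pf * w2 + pf * pf * w12) / z
    return th1, th2
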