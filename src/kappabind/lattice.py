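"""Finite one-dimensional lattice model of dimers binding footprinted DNA.

A DNA molecule of L base pairs is a 1-D lattice on which each bound protein
dimer occludes a fixed footprint (10 bp by default). Discrete κB sites have
their own dissociation constants and are bound "specifically" only when a
dimer sits exactly in register with the site interval; every other start
position with the full footprint on the DNA is a candidate nonspecific
placement with a common weaker Kd. Bound dimers exclude each other
(hard-core overlap exclusion); there is no lateral cooperativity.

This is a McGhee–von-Hippel-type model on a finite lattice with embedded
specific sites. The grand-canonical weight of a configuration with dimers
at sites {j} is Π_j P_free/Kd_j, so the single-molecule partition function
is a polynomial Z(P) = Σ_n a_n Pⁿ whose coefficients a_n are computed
exactly by dynamic programming (transfer-matrix recursion along the
lattice); an exhaustive enumeration path is kept for cross-validation on
short lattices. Free protein is obtained from mass balance over all DNA
molecules, including competition between several DNA species for a shared
protein pool.

Coordinates are 1-based inclusive base-pair intervals throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DNAConstruct",
    "SpeciesDistribution",
    "Placement",
    "max_occupancy",
    "longest_nonspecific_stretch",
    "enumerate_configurations",
    "occupancy_polynomial",
    "species_distribution",
    "competition_distribution",
]

#: largest lattice accepted by the exhaustive-enumeration path
ENUMERATION_GUARD_BP = 200


@dataclass(frozen=True)
class DNAConstruct:
    """Geometry and affinities of one DNA species.

    ``specific_sites`` are 1-based inclusive (start, end) bp intervals, each
    exactly one footprint wide and mutually non-overlapping.
    ``kd_specific`` gives one Kd per site (a scalar is broadcast);
    ``kd_nonspecific`` may be ``math.inf`` to forbid nonspecific binding.
    """

    name: str
    length: int
    specific_sites: tuple = ()
    footprint: int = 10
    kd_specific: tuple = ()
    kd_nonspecific: float = math.inf

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1 bp")
        if self.length < 0:
            raise ValueError("length must be nonnegative")
        sites = tuple(tuple(s) for s in self.specific_sites)
        object.__setattr__(self, "specific_sites", sites)
        kds = self.kd_specific
        if np.isscalar(kds):
            kds = (float(kds),) * len(sites)
        kds = tuple(float(k) for k in kds)
        if len(kds) != len(sites):
            raise ValueError("need one kd_specific per specific site")
        object.__setattr__(self, "kd_specific", kds)
        prev_end = 0
        for (start, end), kd in zip(sites, kds):
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"site ({start},{end}) outside 1..{self.length}")
            if end - start + 1 != self.footprint:
                raise ValueError(
                    f"site ({start},{end}) is not one footprint "
                    f"({self.footprint} bp) wide"
                )
            if start <= prev_end:
                raise ValueError("specific sites overlap or are unsorted")
            if not kd > 0:
                raise ValueError("kd_specific must be > 0")
            prev_end = end
        if not self.kd_nonspecific > 0:
            raise ValueError("kd_nonspecific must be > 0")

    def site_index_at(self, start: int) -> int | None:
        """Index of the specific site exactly registered at ``start``."""
        for i, (s, _e) in enumerate(self.specific_sites):
            if s == start:
                return i
        return None


@dataclass(frozen=True)
class Placement:
    """One bound dimer: start bp, specific/nonspecific, and its Kd."""

    start: int
    specific: bool
    kd: float


@dataclass(frozen=True)
class SpeciesDistribution:
    """Per-DNA-molecule occupancy distribution at equilibrium.

    ``probabilities[n]`` is the fraction of DNA molecules carrying exactly
    n dimers, n = 0..n_max; ``free_protein`` is in nM.
    """

    probabilities: np.ndarray
    free_protein: float
    mean_occupancy: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < -1e-12):
            raise ValueError("negative occupancy probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy probabilities do not sum to 1")

    def binned(self, n_cap: int = 4) -> dict:
        """Collapse occupancies ≥ n_cap into an 'n_cap+' bin (EMSA smear)."""
        out = {str(n): float(self.probabilities[n]) for n in range(min(n_cap, len(self.probabilities)))}
        tail = float(self.probabilities[n_cap:].sum()) if len(self.probabilities) > n_cap else 0.0
        out[f"{n_cap}+"] = tail
        return out


def max_occupancy(length: int, footprint: int = 10) -> int:
    """Largest number of non-overlapping footprints fitting on ``length`` bp."""
    if footprint < 1:
        raise ValueError("footprint must be >= 1 bp")
    if length < 0:
        raise ValueError("length must be nonnegative")
    return length // footprint


def longest_nonspecific_stretch(construct: DNAConstruct) -> int:
    """Length of the longest contiguous run of bp outside all specific sites."""
    best = 0
    pos = 1
    for start, end in construct.specific_sites:
        best = max(best, start - pos)
        pos = end + 1
    best = max(best, construct.length - pos + 1)
    return best


def _placement_weight(construct: DNAConstruct, start: int) -> tuple[bool, float]:
    """(is_specific, 1/Kd) of a dimer starting at ``start``; weight 0 if none."""
    idx = construct.site_index_at(start)
    if idx is not None:
        return True, 1.0 / construct.kd_specific[idx]
    if math.isinf(construct.kd_nonspecific):
        return False, 0.0
    return False, 1.0 / construct.kd_nonspecific


def enumerate_configurations(
    construct: DNAConstruct,
) -> Iterator[tuple[Placement, ...]]:
    """Yield every set of non-overlapping dimer placements, exhaustively.

    Intended as the brute-force cross-check of the transfer-matrix
    recursion; guarded to short lattices.
    """
    if construct.length > ENUMERATION_GUARD_BP:
        raise ValueError(
            f"lattice of {construct.length} bp exceeds the enumeration guard "
            f"({ENUMERATION_GUARD_BP} bp); use the transfer-matrix path "
            "(occupancy_polynomial / species_distribution)"
        )
    fp = construct.footprint

    def recurse(pos: int, acc: tuple) -> Iterator[tuple[Placement, ...]]:
        if pos > construct.length - fp + 1:
            yield acc
            return
        # position pos left empty
        yield from recurse(pos + 1, acc)
        specific, w = _placement_weight(construct, pos)
        if w > 0.0:
            pl = Placement(start=pos, specific=specific, kd=1.0 / w)
            yield from recurse(pos + fp, acc + (pl,))

    yield from recurse(1, ())


def configuration_weight(config: Sequence[Placement], p_free: float) -> float:
    """Statistical weight Π P_free/Kd of one configuration."""
    w = 1.0
    for pl in config:
        w *= p_free / pl.kd
    return w


def occupancy_polynomial(construct: DNAConstruct) -> np.ndarray:
    """Coefficients a_n of the partition polynomial Z(P) = Σ a_n Pⁿ.

    Computed by a right-to-left transfer-matrix recursion: the suffix
    partition vector at bp i either leaves i empty or places a dimer whose
    footprint starts there. Exact (no truncation); a_0 = 1 always.
    """
    L, fp = construct.length, construct.footprint
    n_max = max_occupancy(L, fp)
    # f[i] = coefficient vector for the suffix starting at bp i (1-based)
    empty = np.zeros(n_max + 1)
    empty[0] = 1.0
    f = [empty.copy() for _ in range(L + 2 + fp)]
    for i in range(L - fp + 1, 0, -1):
        coeffs = f[i + 1].copy()
        _spec, w = _placement_weight(construct, i)
        if w > 0.0:
            nxt = f[i + fp] if i + fp <= L + 1 else empty
            coeffs[1:] += w * nxt[:-1]
        f[i] = coeffs
    return f[1]


def _mean_occupancy(coeffs: np.ndarray, p_free: float) -> float:
    n = np.arange(len(coeffs))
    terms = coeffs * p_free**n
    return float((n * terms).sum() / terms.sum())


def _distribution_at(coeffs: np.ndarray, p_free: float) -> SpeciesDistribution:
    n = np.arange(len(coeffs))
    terms = coeffs * p_free**n
    probs = terms / terms.sum()
    return SpeciesDistribution(
        probabilities=probs,
        free_protein=p_free,
        mean_occupancy=float((n * probs).sum()),
    )


def _solve_free_protein(
    coeff_sets: Sequence[tuple[np.ndarray, float]], p_total: float
) -> float:
    """Root of P + Σ_k d_k·⟨n⟩_k(P) = p_total on [0, p_total]."""
    if p_total == 0:
        return 0.0

    def excess(pf: float) -> float:
        bound = sum(d * _mean_occupancy(c, pf) for c, d in coeff_sets)
        return pf + bound - p_total

    try:
        return brentq(
            excess,
            0.0,
            p_total,
            xtol=1e-300,
            rtol=4 * np.finfo(float).eps,
            maxiter=600,
        )
    except (ValueError, RuntimeError) as err:  # pragma: no cover
        raise ArithmeticError(
            f"free-protein solve failed at p_total={p_total}: {err}"
        ) from err


def species_distribution(
    construct: DNAConstruct, p_total: float, d_total: float
) -> SpeciesDistribution:
    """Equilibrium occupancy distribution of one DNA species.

    Solves mass balance P + D·⟨n⟩(P) = P_total for the free-protein
    concentration, then reads the per-molecule distribution off the
    partition polynomial.
    """
    if p_total < 0 or d_total < 0:
        raise ValueError("concentrations must be nonnegative")
    coeffs = occupancy_polynomial(construct)
    pf = _solve_free_protein([(coeffs, d_total)], p_total)
    return _distribution_at(coeffs, pf)


def competition_distribution(
    constructs: Sequence[tuple[DNAConstruct, float]], p_total: float
) -> list[SpeciesDistribution]:
    """Simultaneous equilibrium of several DNA species sharing one protein pool.

    ``constructs`` is a list of (construct, d_total nM) pairs. A single
    global free-protein root satisfies the pooled mass balance; each
    species' distribution is evaluated at that root.
    """
    if not constructs:
        raise ValueError("need at least one construct")
    if p_total < 0 or any(d < 0 for _c, d in constructs):
        raise ValueError("concentrations must be nonnegative")
    coeff_sets = [(occupancy_polynomial(c), d) for c, d in constructs]
    pf = _solve_free_protein(coeff_sets, p_total)
    return [_distribution_at(c, pf) for c, _d in coeff_sets]
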