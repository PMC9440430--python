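"""Small-angle X-ray scattering utilities for compactness analysis.

Covers the minimal SAXS arithmetic behind disorder/compactness arguments:
reading 3-column (q, I, σ) profiles, the Guinier approximation
ln I(q) ≈ ln I₀ − q²Rg²/3 fit over a low-q window truncated at
q·Rg ≤ 1.3, the Kratky transform q²I(q), and the excluded-volume polymer
scaling law Rg = R₀·N^ν (R₀ = 1.927 Å, ν = 0.598, the denatured-protein
calibration) used to benchmark how expanded a disordered chain of N
residues would be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SAXSProfile",
    "GuinierResult",
    "read_profile",
    "write_profile",
    "guinier_fit",
    "kratky",
    "polymer_rg",
]

DEFAULT_Q_RG_LIMIT = 1.3
POLYMER_R0_A = 1.927
POLYMER_NU = 0.598


@dataclass(frozen=True)
class SAXSProfile:
    """A buffer-subtracted scattering profile: q (Å⁻¹), I (a.u.), σ(I)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)
        if not (len(q) == len(i) == len(s)):
            raise ValueError("q, intensity, sigma must have equal length")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing and positive")

    @property
    def negative_intensity_mask(self) -> np.ndarray:
        """Flag (do not drop) points with nonpositive intensity."""
        return self.intensity <= 0

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class GuinierResult:
    """Guinier fit: radius of gyration, forward scattering, range, quality."""

    rg: float
    rg_stderr: float
    i0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if not self.rg > 0:
            raise ValueError("rg must be positive")


def read_profile(path) -> SAXSProfile:
    """Read a 3-column text profile (whitespace or comma separated).

    Header/comment lines (non-numeric, or starting with '#') are skipped;
    a malformed data row raises with its line number.
    """
    qs, ints, sigs = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if not qs:  # header line before any data
                    continue
                raise ValueError(f"{path}: malformed row at line {lineno}: {raw!r}")
            if len(vals) < 3:
                if not qs:
                    continue
                raise ValueError(
                    f"{path}: expected 3 columns at line {lineno}, got {len(vals)}"
                )
            qs.append(vals[0])
            ints.append(vals[1])
            sigs.append(vals[2])
    if not qs:
        raise ValueError(f"{path}: no data rows")
    return SAXSProfile(np.array(qs), np.array(ints), np.array(sigs))


def write_profile(path, profile: SAXSProfile, header: str = "q I sigma") -> None:
    """Write a profile in the 3-column text format read by read_profile."""
    data = np.column_stack([profile.q, profile.intensity, profile.sigma])
    np.savetxt(path, data, header=header, fmt="%.8e")


def guinier_fit(
    profile: SAXSProfile,
    q_rg_limit: float = DEFAULT_Q_RG_LIMIT,
    min_points: int = 5,
) -> GuinierResult:
    """Weighted Guinier fit of the low-q region.

    Fits ln I against q² with σ-propagated weights, starting from the full
    profile and iteratively truncating the upper end until
    q_max·Rg ≤ ``q_rg_limit`` (self-consistent Guinier window). Points with
    nonpositive intensity are excluded from the fit.
    """
    ok = profile.intensity > 0
    q = profile.q[ok]
    i = profile.intensity[ok]
    s = profile.sigma[ok]
    if len(q) < min_points:
        raise ValueError("not enough positive-intensity points for a Guinier fit")

    n_use = len(q)
    for _ in range(len(q)):
        qq = q[:n_use] ** 2
        ln_i = np.log(i[:n_use])
        # σ(ln I) = σ(I)/I; fall back to unweighted when σ is absent/zero
        w_sig = np.where(s[:n_use] > 0, s[:n_use] / i[:n_use], np.nan)
        weights = 1.0 / w_sig**2 if np.all(np.isfinite(w_sig)) else np.ones_like(qq)

        wsum = weights.sum()
        xm = (weights * qq).sum() / wsum
        ym = (weights * ln_i).sum() / wsum
        sxx = (weights * (qq - xm) ** 2).sum()
        sxy = (weights * (qq - xm) * (ln_i - ym)).sum()
        slope = sxy / sxx
        intercept = ym - slope * xm
        if slope >= 0:
            n_use -= 1
            if n_use < min_points:
                raise ValueError("no convergent Guinier range (non-decaying profile)")
            continue
        rg = math.sqrt(-3.0 * slope)
        if q[n_use - 1] * rg <= q_rg_limit:
            break
        n_use -= 1
        if n_use < min_points:
            raise ValueError(
                f"no Guinier range with q·Rg <= {q_rg_limit} and "
                f">= {min_points} points"
            )
    else:  # pragma: no cover
        raise ValueError("Guinier range search did not terminate")

    resid = ln_i - (intercept + slope * qq)
    ss_res = float((weights * resid**2).sum())
    ss_tot = float((weights * (ln_i - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(n_use - 2, 1)
    slope_var = (ss_res / dof) / sxx
    rg_se = math.sqrt(slope_var) * 3.0 / (2.0 * rg)  # |d Rg/d slope| = 3/(2 Rg)
    return GuinierResult(
        rg=rg,
        rg_stderr=rg_se,
        i0=math.exp(intercept),
        q_min=float(q[0]),
        q_max=float(q[n_use - 1]),
        n_points=n_use,
        r_squared=r2,
    )


def kratky(profile: SAXSProfile) -> tuple[np.ndarray, np.ndarray]:
    """Kratky transform (q, q²·I): flat for 1/q² decay, peaked for globules."""
    return profile.q, profile.q**2 * profile.intensity


def polymer_rg(
    n_residues: int, r0: float = POLYMER_R0_A, nu: float = POLYMER_NU
) -> float:
    """Expected Rg (Å) of an excluded-volume polymer of N residues, R₀·N^ν."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return r0 * n_residues**nu
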