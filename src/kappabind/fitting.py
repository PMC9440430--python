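"""Least-squares estimation of binding parameters from anisotropy titrations.

Single curves are fit to the ligand-depletion quadratic isotherm (specific
hairpins, Kd comparable to the 5 nM DNA) or the hyperbolic isotherm (weak
nonspecific binding, Kd ≫ [DNA]). Tandem two-site constructs are fit
globally across forward- and reverse-labeled replicate sets: the
dissociation constants are shared over all curves while amplitude and
baseline remain per-curve nuisance parameters (labeling efficiency varies
between DNA preparations).

Numerical strategy: Kd (and ω) are optimized on a natural-log scale, which
enforces positivity and lets the multi-start search span decades; for any
trial Kd the per-curve amplitude/baseline enter the model linearly and are
profiled out exactly by linear least squares (variable projection), so the
nonlinear problem has only 1–3 parameters. Standard errors come from the
Gauss-Newton covariance of the full parameter vector at the optimum.

Replicates are fit independently and aggregated as mean ± SEM; competing
models (equal Kd, distinct Kd, cooperative) are compared with the
small-sample-corrected Akaike criterion; group differences in Kd use a
two-tailed Welch t-test with a permutation cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .anisotropy import LabelConfig, site_weights
from .equilibria import BindingParams, single_site_complex, two_site_occupancies
from .lattice import DNAConstruct

__all__ = [
    "TitrationCurve",
    "FitResult",
    "fit_single_site",
    "fit_global_two_site",
    "select_model",
    "aggregate_replicates",
    "mean_sem",
    "compare_groups",
]

#: minimum fitted amplitude (anisotropy units) for Kd to count as identifiable
MIN_IDENTIFIABLE_AMPLITUDE = 1e-4
#: number of log-spaced Kd starting values for the multi-start search
N_MULTISTARTS = 5
#: cost tolerance passed to the trust-region optimizer
COST_TOL = 1e-10
#: plausibility bounds keeping the search off degenerate ridges
LOG_KD_BOUNDS = (math.log(1e-4), math.log(1e6))  # 0.1 pM – 1 mM
LOG_OMEGA_BOUNDS = (math.log(1e-3), math.log(1e3))

GLOBAL_MODELS = ("equal_kd", "distinct_kd", "cooperative")


@dataclass(frozen=True)
class TitrationCurve:
    """One replicate's anisotropy titration.

    ``concentrations`` is the varied total protein-dimer concentration (nM)
    and ``d_total`` the fixed labeled-DNA concentration (nM).
    """

    construct: str
    label: LabelConfig
    replicate: int
    concentrations: np.ndarray
    anisotropy: np.ndarray
    d_total: float = 5.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.anisotropy, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "anisotropy", y)
        if conc.shape != y.shape or conc.ndim != 1:
            raise ValueError("concentration and anisotropy vectors must match")
        if len(conc) < 5:
            raise ValueError("need at least 5 titration points")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.d_total < 0:
            raise ValueError("d_total must be nonnegative")


@dataclass
class FitResult:
    """Outcome of one least-squares fit."""

    model: str
    params: BindingParams
    curve_amplitudes: list = field(default_factory=list)
    curve_baselines: list = field(default_factory=list)
    rss: float = math.nan
    converged: bool = False
    stderr: dict = field(default_factory=dict)
    n_obs: int = 0
    n_params: int = 0
    aicc: float = math.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.rss) and self.rss < 0:
            raise ValueError("RSS must be nonnegative")


# ---------------------------------------------------------------------------
# isotherm shapes (bound fraction as a function of total protein)
# ---------------------------------------------------------------------------


def _quadratic_fraction(conc: np.ndarray, d_total: float, kd: float) -> np.ndarray:
    return np.array(
        [single_site_complex(x, d_total, kd) / d_total for x in conc]
    )


def _hyperbolic_fraction(conc: np.ndarray, _d: float, kd: float) -> np.ndarray:
    return conc / (conc + kd)


_ISOTHERMS: dict[str, Callable] = {
    "quadratic": _quadratic_fraction,
    "hyperbolic": _hyperbolic_fraction,
}


def _profile_linear(y: np.ndarray, frac: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Best baseline/amplitude for fixed bound-fraction shape.

    Returns (baseline, amplitude, residuals); amplitude is clamped to be
    nonnegative (a binding event cannot lower the fraction-weighted signal
    in this parameterization).
    """
    design = np.column_stack([np.ones_like(frac), frac])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    base, amp = coef
    if amp < 0.0:
        amp = 0.0
        base = float(np.mean(y))
    resid = y - (base + amp * frac)
    return float(base), float(amp), resid


def _kd_starts(conc: np.ndarray, n: int = N_MULTISTARTS) -> np.ndarray:
    pos = conc[conc > 0]
    lo = max(pos.min() * 0.2, 1e-3)
    hi = pos.max() * 5.0
    return np.logspace(math.log10(lo), math.log10(hi), n)


def _covariance_stderr(
    resid_full: Callable[[np.ndarray], np.ndarray], x_opt: np.ndarray, rss: float, n: int
) -> np.ndarray:
    """Gauss-Newton standard errors from a numeric jacobian at the optimum."""
    p = len(x_opt)
    if n <= p:
        return np.full(p, np.nan)
    jac = np.empty((n, p))
    r0 = resid_full(x_opt)
    for j in range(p):
        h = 1e-6 * max(abs(x_opt[j]), 1.0)
        xp = x_opt.copy()
        xp[j] += h
        jac[:, j] = (resid_full(xp) - r0) / h
    try:
        cov = rss / (n - p) * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    # floor at a 1e-10 per-point residual: below that a fit is numerically
    # perfect and model comparison must fall to the parameter-count tie-break
    rss = max(rss, n * 1e-20)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# single-curve fits
# ---------------------------------------------------------------------------


def fit_single_site(curve: TitrationCurve, isotherm: str = "quadratic") -> FitResult:
    """Fit one titration to a single-site isotherm.

    ``isotherm='quadratic'`` accounts for ligand depletion (use when Kd is
    comparable to d_total); ``'hyperbolic'`` is y = A·x/(x + Kd). A
    non-identifiable fit (flat curve, vanishing amplitude) is returned with
    ``converged=False`` rather than raising.
    """
    if isotherm not in _ISOTHERMS:
        raise ValueError(f"unknown isotherm {isotherm!r}")
    frac_of = _ISOTHERMS[isotherm]
    conc, y = curve.concentrations, curve.anisotropy

    def resid(theta: np.ndarray) -> np.ndarray:
        frac = frac_of(conc, curve.d_total, math.exp(theta[0]))
        return _profile_linear(y, frac)[2]

    best = None
    for kd0 in _kd_starts(conc):
        sol = least_squares(
            resid, x0=[math.log(kd0)], method="lm", ftol=COST_TOL, xtol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol

    kd = math.exp(best.x[0])
    frac = frac_of(conc, curve.d_total, kd)
    base, amp, r = _profile_linear(y, frac)
    rss = float(r @ r)

    def resid_full(x: np.ndarray) -> np.ndarray:
        f = frac_of(conc, curve.d_total, math.exp(x[0]))
        return y - (x[2] + x[1] * f)

    se = _covariance_stderr(resid_full, np.array([math.log(kd), amp, base]), rss, len(y))
    identifiable = amp > MIN_IDENTIFIABLE_AMPLITUDE and np.all(np.isfinite(se))
    n_params = 3
    return FitResult(
        model=isotherm,
        params=BindingParams(kd_site1=kd, amplitude=amp, baseline=base),
        curve_amplitudes=[amp],
        curve_baselines=[base],
        rss=rss,
        converged=bool(best.success and identifiable),
        stderr={
            "kd_site1": kd * se[0],
            "amplitude": se[1],
            "baseline": se[2],
        },
        n_obs=len(y),
        n_params=n_params,
        aicc=_aicc(rss, len(y), n_params + 1),
    )


# ---------------------------------------------------------------------------
# global two-site fits
# ---------------------------------------------------------------------------


def _theta_to_params(theta: np.ndarray, model: str) -> BindingParams:
    if model == "equal_kd":
        kd = math.exp(theta[0])
        return BindingParams(kd_site1=kd, kd_site2=kd, omega=1.0)
    if model == "distinct_kd":
        return BindingParams(
            kd_site1=math.exp(theta[0]), kd_site2=math.exp(theta[1]), omega=1.0
        )
    if model == "cooperative":
        kd = math.exp(theta[0])
        return BindingParams(kd_site1=kd, kd_site2=kd, omega=math.exp(theta[1]))
    raise ValueError(f"unknown model {model!r}")


def _global_starts(model: str, conc: np.ndarray) -> list[np.ndarray]:
    starts = []
    for kd0 in _kd_starts(conc):
        lk = math.log(kd0)
        if model == "equal_kd":
            starts.append(np.array([lk]))
        elif model == "distinct_kd":
            starts.append(np.array([lk, lk + math.log(3.0)]))
        else:
            starts.append(np.array([lk, 0.0]))
    return starts


def fit_global_two_site(
    curves: Sequence[TitrationCurve],
    construct: DNAConstruct,
    model: str = "equal_kd",
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Globally fit forward- and reverse-labeled titrations of one construct.

    The label of each curve selects which site its anisotropy change
    reports (binary proximity weights from the construct geometry); Kd
    parameters are shared across all curves, amplitude and baseline are
    per-curve. ``model`` is one of 'equal_kd' (one shared Kd), 'distinct_kd'
    (independent Kd per site) or 'cooperative' (shared Kd plus a free
    cooperativity factor ω).

    For the non-equal models one extra start is seeded from the best
    equal-Kd solution, so the nested-model inequality
    RSS(distinct) ≤ RSS(equal) holds by construction.
    """
    if model not in GLOBAL_MODELS:
        raise ValueError(f"model must be one of {GLOBAL_MODELS}")
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("global fit needs at least two curves")
    strands = {c.label.labeled_strand for c in curves}
    if not {"forward", "reverse"} <= strands:
        raise ValueError(
            "global two-site fit needs both forward- and reverse-labeled curves"
        )
    if len(construct.specific_sites) != 2:
        raise ValueError("construct must carry exactly two specific sites")

    weight_sets = [site_weights(construct, c.label) for c in curves]
    if any(w.sum() == 0 for w in weight_sets):
        raise ValueError("a curve's label senses no site; check label geometry")

    def curve_fractions(params: BindingParams) -> list[np.ndarray]:
        out = []
        for c, w in zip(curves, weight_sets):
            th1, th2 = two_site_occupancies(c.concentrations, c.d_total, params)
            out.append((w[0] * th1 + w[1] * th2) / w.sum())
        return out

    def resid(theta: np.ndarray) -> np.ndarray:
        params = _theta_to_params(theta, model)
        parts = [
            _profile_linear(c.anisotropy, f)[2]
            for c, f in zip(curves, curve_fractions(params))
        ]
        return np.concatenate(parts)

    all_conc = np.concatenate([c.concentrations for c in curves])
    starts = _global_starts(model, all_conc) + [np.asarray(s, float) for s in extra_starts]
    if model != "equal_kd":
        eq = fit_global_two_site(curves, construct, model="equal_kd")
        lk = math.log(eq.params.kd_site1)
        starts.append(np.array([lk, lk]) if model == "distinct_kd" else np.array([lk, 0.0]))

    if model == "equal_kd":
        lo, hi = [LOG_KD_BOUNDS[0]], [LOG_KD_BOUNDS[1]]
    elif model == "distinct_kd":
        lo = [LOG_KD_BOUNDS[0]] * 2
        hi = [LOG_KD_BOUNDS[1]] * 2
    else:
        lo = [LOG_KD_BOUNDS[0], LOG_OMEGA_BOUNDS[0]]
        hi = [LOG_KD_BOUNDS[1], LOG_OMEGA_BOUNDS[1]]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, np.array(lo) + 1e-9, np.array(hi) - 1e-9)
        sol = least_squares(
            resid, x0=x0, bounds=(lo, hi), method="trf",
            ftol=COST_TOL, xtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    params = _theta_to_params(best.x, model)
    amps, bases, rss = [], [], 0.0
    for c, f in zip(curves, curve_fractions(params)):
        base, amp, r = _profile_linear(c.anisotropy, f)
        amps.append(amp)
        bases.append(base)
        rss += float(r @ r)

    n_nl = len(best.x)
    n_obs = sum(len(c.anisotropy) for c in curves)

    def resid_full(x: np.ndarray) -> np.ndarray:
        p = _theta_to_params(x[:n_nl], model)
        parts = []
        for i, (c, f) in enumerate(zip(curves, curve_fractions(p))):
            a = x[n_nl + 2 * i]
            b = x[n_nl + 2 * i + 1]
            parts.append(c.anisotropy - (b + a * f))
        return np.concatenate(parts)

    x_full = np.concatenate([best.x, np.ravel(np.column_stack([amps, bases]))])
    se = _covariance_stderr(resid_full, x_full, rss, n_obs)
    stderr = {"kd_site1": params.kd_site1 * se[0]}
    if model == "distinct_kd":
        stderr["kd_site2"] = params.kd_site2 * se[1]
    elif model == "cooperative":
        stderr["omega"] = params.omega * se[1]
    else:
        stderr["kd_site2"] = stderr["kd_site1"]

    n_params = n_nl + 2 * len(curves)
    mean_amp = float(np.mean(amps))
    identifiable = mean_amp > MIN_IDENTIFIABLE_AMPLITUDE
    params = BindingParams(
        kd_site1=params.kd_site1,
        kd_site2=params.kd_site2,
        omega=params.omega,
        amplitude=mean_amp,
        baseline=float(np.mean(bases)),
    )
    return FitResult(
        model=model,
        params=params,
        curve_amplitudes=amps,
        curve_baselines=bases,
        rss=rss,
        converged=bool(best.success and identifiable),
        stderr=stderr,
        n_obs=n_obs,
        n_params=n_params,
        aicc=_aicc(rss, n_obs, n_params + 1),
    )


def select_model(
    curves: Sequence[TitrationCurve],
    construct: DNAConstruct,
    candidates: Sequence[str] = GLOBAL_MODELS,
) -> tuple[str, dict[str, FitResult]]:
    """Pick the binding model favored by the corrected Akaike criterion.

    Ties (ΔAICc < 1e-6) are broken toward the model with fewer parameters.
    Returns (chosen model name, fits per candidate).
    """
    fits = {m: fit_global_two_site(curves, construct, model=m) for m in candidates}
    ranked = sorted(
        fits.items(), key=lambda kv: (round(kv[1].aicc, 6), kv[1].n_params)
    )
    return ranked[0][0], fits


# ---------------------------------------------------------------------------
# replicate aggregation & group comparison
# ---------------------------------------------------------------------------


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD / √n)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(len(v)))


def aggregate_replicates(fits: Sequence[FitResult]) -> dict[str, tuple[float, float]]:
    """Mean ± SEM of each binding parameter over independently fit replicates."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 replicate fits to aggregate")
    out = {}
    for name in ("kd_site1", "kd_site2", "omega", "amplitude", "baseline"):
        vals = [getattr(f.params, name) for f in fits]
        if np.all(np.isfinite(vals)):
            out[name] = mean_sem(vals)
    return out


def compare_groups(
    kds_a: Sequence[float],
    kds_b: Sequence[float],
    method: str = "welch",
    n_permutations: int = 20000,
    seed: int | None = None,
) -> float:
    """Two-tailed p-value for a difference in Kd between two groups.

    'welch' is the unequal-variance t-test on the per-replicate Kd values;
    'permutation' is an exact/Monte-Carlo label-permutation test on the
    difference of means, provided as a distribution-free cross-check.
    Groups with zero variance and equal means return p = 1.
    """
    a = np.asarray(kds_a, dtype=float)
    b = np.asarray(kds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if method == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if method == "permutation":
        res = stats.permutation_test(
            (a, b),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_permutations,
            rng=seed,
        )
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
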