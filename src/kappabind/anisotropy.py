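"""Fluorescence-anisotropy readout: intensities → r, occupancy → signal.

Anisotropy reports the rotational mobility of the fluorescein label on the
DNA; a dimer bound at a κB site adjacent to the label immobilizes it and
raises r. The readout is site-selective: the change in anisotropy drops off
sharply once the fluorophore is more than ~3 bp from the nearest edge of
the bound site, so a 5′ label on the forward strand reports site 1 of a
tandem construct and a 5′ label on the reverse strand reports site 2. This
module implements that proximity rule as a binary weight and maps site
occupancies to predicted anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import BindingParams, MixtureState
from .lattice import DNAConstruct

__all__ = [
    "LabelConfig",
    "anisotropy_from_intensities",
    "site_weights",
    "predicted_signal",
    "normalize_curve",
    "denormalize_curve",
]

DEFAULT_G_FACTOR = 0.67
DEFAULT_PROXIMITY_CUTOFF_BP = 3


@dataclass(frozen=True)
class LabelConfig:
    """Position of the fluorophore on a labeled DNA construct.

    ``fluorophore_position`` is the 1-based bp coordinate of the 5′ label
    mapped onto construct coordinates: bp 1 for a forward-strand or hairpin
    label, bp ``length`` for a reverse-strand label. ``proximity_cutoff``
    is the largest label→site-edge distance (bp) that still transmits a
    binding event into the anisotropy signal.
    """

    labeled_strand: str = "forward"
    fluorophore_position: int = 1
    proximity_cutoff: float = DEFAULT_PROXIMITY_CUTOFF_BP

    def __post_init__(self) -> None:
        if self.labeled_strand not in ("forward", "reverse", "hairpin"):
            raise ValueError(f"unknown strand {self.labeled_strand!r}")
        if self.proximity_cutoff < 0:
            raise ValueError("proximity_cutoff must be >= 0")
        if self.fluorophore_position < 1:
            raise ValueError("fluorophore_position is a 1-based bp coordinate")

    @classmethod
    def for_construct(
        cls,
        construct: DNAConstruct,
        strand: str,
        proximity_cutoff: float = DEFAULT_PROXIMITY_CUTOFF_BP,
    ) -> "LabelConfig":
        """5′-end label on the given strand of ``construct``."""
        pos = 1 if strand in ("forward", "hairpin") else construct.length
        return cls(
            labeled_strand=strand,
            fluorophore_position=pos,
            proximity_cutoff=proximity_cutoff,
        )


def anisotropy_from_intensities(
    i_parallel: float,
    i_perpendicular: float,
    g_factor: float = DEFAULT_G_FACTOR,
    printed_denominator: bool = False,
) -> float:
    """Steady-state anisotropy from polarized intensities.

    r = (I_VV − G·I_VH) / (I_VV + 2·G·I_VH), with the instrument G-factor
    correcting the detection efficiency of the two polarization channels.
    ``printed_denominator=True`` switches to a compatibility variant with a
    minus sign in the denominator, which is not bounded in (−0.5, 1] and is
    provided only for reproducing legacy calculations.
    """
    if i_parallel < 0 or i_perpendicular < 0:
        raise ValueError("intensities must be nonnegative")
    if i_parallel == 0 and i_perpendicular == 0:
        raise ValueError("total intensity is zero")
    if not g_factor > 0:
        raise ValueError("g_factor must be > 0")
    num = i_parallel - g_factor * i_perpendicular
    if printed_denominator:
        den = i_parallel - 2.0 * g_factor * i_perpendicular
    else:
        den = i_parallel + 2.0 * g_factor * i_perpendicular
    if den == 0:
        raise ValueError("zero denominator in anisotropy formula")
    return num / den


def site_weights(construct: DNAConstruct, label: LabelConfig) -> np.ndarray:
    """Binary readout weight of each specific site for the given label.

    A site contributes to the anisotropy change (weight 1) when its nearest
    edge lies within ``proximity_cutoff`` bp of the fluorophore position,
    and not at all (weight 0) otherwise.
    """
    pos = label.fluorophore_position
    if construct.length and pos > construct.length:
        raise ValueError(
            f"fluorophore at bp {pos} outside construct of {construct.length} bp"
        )
    weights = np.zeros(len(construct.specific_sites))
    for i, (start, end) in enumerate(construct.specific_sites):
        if start <= pos <= end:
            dist = 0
        else:
            dist = min(abs(start - pos), abs(end - pos))
        if dist <= label.proximity_cutoff:
            weights[i] = 1.0
    return weights


def predicted_signal(
    occupancies,
    weights,
    params: BindingParams,
) -> np.ndarray | float:
    """Anisotropy predicted from per-site occupancies.

    r = baseline + amplitude · (Σ_s w_s·θ_s) / (Σ_s w_s), so the signal
    saturates at baseline + amplitude when every label-proximal site is
    occupied and sites the label cannot sense contribute nothing. With all
    weights zero the signal is the baseline.
    """
    if isinstance(occupancies, MixtureState):
        occupancies = occupancies.site_occupancies()
    th = np.asarray(occupancies, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any((th < -1e-9) | (th > 1 + 1e-9)):
        raise ValueError("occupancies must lie in [0, 1]")
    w_sum = w.sum()
    if w_sum == 0:
        frac = np.zeros(th.shape[:-1]) if th.ndim > 1 else 0.0
    else:
        frac = (th * w).sum(axis=-1) / w_sum
    out = params.baseline + params.amplitude * frac
    return out if np.ndim(out) else float(out)


def normalize_curve(anisotropy, baseline: float, amplitude: float) -> np.ndarray:
    """Rescale raw anisotropy to bound fraction, (r − baseline)/amplitude."""
    if not amplitude > 0:
        raise ValueError("amplitude must be > 0")
    return (np.asarray(anisotropy, dtype=float) - baseline) / amplitude


def denormalize_curve(fraction, baseline: float, amplitude: float) -> np.ndarray:
    """Inverse of :func:`normalize_curve`."""
    if not amplitude > 0:
        raise ValueError("amplitude must be > 0")
    return baseline + amplitude * np.asarray(fraction, dtype=float)
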