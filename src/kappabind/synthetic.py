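"""Synthetic anisotropy titrations, EMSA species tables, and study fixtures.

Emulates the experiments the analysis modules consume: fluorescence
anisotropy titrations of 5 nM fluorescein-labeled DNA over a nM–μM range of
NF-κB dimer with i.i.d. Gaussian anisotropy noise, and electrophoretic
mobility-shift (EMSA) species fractions of 250 nM DNA over a fixed protein
series. Everything is deterministic under a base seed; replicate i of a
run draws from ``numpy.random.SeedSequence(seed + i)``, so a triplicate
experiment at seed 1 uses replicate seeds 1-3 and each replicate is
reproducible in isolation.

The fixture registry carries the study's seven hairpin sequences verbatim
and the tandem-promoter geometries: for each promoter an EMSA construct
honoring the printed total length and nonspecific stretch lengths, and a
labeled titration construct with 3-bp flanks so that a 5′ label on either
strand sits within the anisotropy proximity cutoff of its κB site. (The
printed EMSA lengths and the 3-bp-flank labeling geometry are mutually
inconsistent, so they are kept as distinct constructs.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anisotropy import LabelConfig, site_weights
from .equilibria import BindingParams, single_site_complex, two_site_occupancies
from .fitting import TitrationCurve
from .lattice import DNAConstruct, species_distribution

__all__ = [
    "NoiseModel",
    "generate_titration",
    "generate_emsa",
    "fixtures",
    "hairpin_sequences",
    "default_concentration_series",
    "EMSA_PROTEIN_SERIES_NM",
    "EMSA_DNA_NM",
]

#: EMSA protein series (nM) and DNA concentration (nM) used in the study
EMSA_PROTEIN_SERIES_NM = (0.0, 62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)
EMSA_DNA_NM = 250.0

#: hairpin DNA sequences used for the titration experiments (5′→3′);
#: the CCCCC run is the non-binding hairpin loop
HAIRPIN_SEQUENCES = {
    "IFN-beta": "GGGAAATTCCTCCCCCAGGAATTTCCC",
    "UK": "GGGAAAGTACTCCCCCAGTACTTTCCC",
    "RANTES": "GGGAGTTTCCTCCCCCAGGAAACTCCC",
    "HIV-LTR": "GGGACTTTCCTCCCCCAGGAAAGTCCC",
    "Random": "GTAGACGTGCTCCCCCAGCACGTCTAC",
    "NFKBIA-site1": "TGGAAATTCCCTCCCCCAGGGAATTTCCA",
    "NFKBIA-site2": "AGAGAAATCCCTCCCCCAGGGATTTCTCT",
}


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian anisotropy noise and replicate structure of a simulated run."""

    sigma: float = 0.003
    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def replicate_rngs(self) -> list[np.random.Generator]:
        """One independent stream per replicate.

        Replicate i draws from ``SeedSequence(seed + i)``, so replicate
        streams are addressable on their own: a 3-replicate run at seed 1
        is the same data as three 1-replicate runs at seeds 1, 2, 3.
        """
        return [
            np.random.default_rng(np.random.SeedSequence(self.seed + i))
            for i in range(self.n_replicates)
        ]


def default_concentration_series(
    c_min: float = 0.1,
    c_max: float = 2000.0,
    n_points: int = 12,
    include_zero: bool = True,
) -> np.ndarray:
    """Log-spaced protein series (nM), optionally prefixed with a zero point."""
    if not 0 < c_min < c_max:
        raise ValueError("need 0 < c_min < c_max")
    series = np.logspace(math.log10(c_min), math.log10(c_max), n_points)
    if include_zero:
        series = np.concatenate([[0.0], series])
    return series


def _model_signal(
    truth: BindingParams,
    construct: DNAConstruct,
    label: LabelConfig,
    d_total: float,
    conc: np.ndarray,
) -> np.ndarray:
    """Noise-free anisotropy of ``conc`` from the equilibrium + readout model."""
    n_sites = len(construct.specific_sites)
    if n_sites == 1:
        frac = np.array(
            [single_site_complex(x, d_total, truth.kd_site1) / d_total for x in conc]
        ) if d_total > 0 else np.zeros_like(conc)
        w = site_weights(construct, label)
        frac = frac * w[0]
    elif n_sites == 2:
        w = site_weights(construct, label)
        if w.sum() == 0:
            frac = np.zeros_like(conc)
        else:
            th1, th2 = two_site_occupancies(conc, d_total, truth)
            frac = (w[0] * th1 + w[1] * th2) / w.sum()
    else:
        raise ValueError("titration model supports 1- or 2-site constructs")
    return truth.baseline + truth.amplitude * frac


def generate_titration(
    truth: BindingParams,
    construct: DNAConstruct,
    label: LabelConfig,
    d_total: float,
    conc_series: np.ndarray,
    noise: NoiseModel,
) -> list[TitrationCurve]:
    """Simulate replicate anisotropy titrations of one labeled construct.

    The noise-free signal comes from the depletion-aware equilibrium model
    and the proximity readout rule; each replicate adds i.i.d. Gaussian
    noise of SD ``noise.sigma`` from its own seeded stream.
    """
    conc = np.asarray(conc_series, dtype=float)
    if len(conc) < 5:
        raise ValueError("need at least 5 concentration points")
    clean = _model_signal(truth, construct, label, d_total, conc)
    curves = []
    for rep, rng in enumerate(noise.replicate_rngs(), start=1):
        y = clean + rng.normal(0.0, noise.sigma, size=clean.shape)
        curves.append(
            TitrationCurve(
                construct=construct.name,
                label=label,
                replicate=rep,
                concentrations=conc,
                anisotropy=y,
                d_total=d_total,
            )
        )
    return curves


def generate_emsa(
    construct: DNAConstruct,
    p_series: np.ndarray = EMSA_PROTEIN_SERIES_NM,
    d_total: float = EMSA_DNA_NM,
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate EMSA band fractions over a protein series.

    Returns a tidy frame (p_total_nM, n, fraction): the lattice-model
    occupancy distribution at each protein concentration with optional
    truncated-Gaussian fractional noise, renormalized so each lane sums
    to 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for p in np.asarray(p_series, dtype=float):
        dist = species_distribution(construct, p, d_total)
        fr = dist.probabilities.copy()
        if noise_sd_fraction > 0:
            fr = np.clip(fr * (1.0 + rng.normal(0.0, noise_sd_fraction, fr.shape)), 0.0, None)
            if fr.sum() == 0:
                fr = dist.probabilities.copy()
            fr = fr / fr.sum()
        for n, f in enumerate(fr):
            rows.append({"p_total_nM": p, "n": n, "fraction": float(f)})
    return pd.DataFrame(rows)


def hairpin_sequences() -> dict[str, str]:
    """The study's seven hairpin sequences, 5′→3′."""
    return dict(HAIRPIN_SEQUENCES)


def fixtures(
    kd_specific_hiv: float = 1.7,
    kd_nfkbia: tuple = (1.7, 10.0),
    kd_nonspecific: float = math.inf,
) -> dict[str, DNAConstruct]:
    """Construct registry parameterized by the study's printed geometries.

    Default affinities are the RHD-heterodimer values (HIV-LTR equal sites
    1.7 nM; NFKBIA sites 1.7 and 10 nM); nonspecific binding is off unless
    a finite ``kd_nonspecific`` is supplied.

    Geometries:

    * ``hiv_ltr_emsa`` — 33 bp, two 10-bp sites separated by 4 bp, flanks
      2/7 bp, chosen so scrambling site 2 leaves a 21-bp nonspecific
      stretch and scrambling site 1 leaves 16 bp, as quantified from the
      gels. Scrambled variants keep the geometry with one site removed.
    * ``hiv_ltr_labeled`` — 30 bp, same sites with 3-bp flanks, the
      anisotropy-titration geometry (labels on either 5′ end sit within
      the proximity cutoff of the adjacent site).
    * ``nfkbia_emsa`` — 59 bp, two 10-bp sites separated by 19 bp, flanks
      10/10 bp (the printed length leaves 20 flank bp unconstrained).
    * ``nfkbia_labeled`` — 45 bp, 3-bp flanks, 19-bp separation.
    * one 27/29-bp single-site construct per hairpin, site at bp 1–10 so a
      5′ label reads it directly.
    """
    ns = kd_nonspecific
    fx = {
        "hiv_ltr_emsa": DNAConstruct(
            name="hiv_ltr_emsa",
            length=33,
            specific_sites=((3, 12), (17, 26)),
            kd_specific=(kd_specific_hiv, kd_specific_hiv),
            kd_nonspecific=ns,
        ),
        "hiv_ltr_emsa_scrambled_site1": DNAConstruct(
            name="hiv_ltr_emsa_scrambled_site1",
            length=33,
            specific_sites=((17, 26),),
            kd_specific=(kd_specific_hiv,),
            kd_nonspecific=ns,
        ),
        "hiv_ltr_emsa_scrambled_site2": DNAConstruct(
            name="hiv_ltr_emsa_scrambled_site2",
            length=33,
            specific_sites=((3, 12),),
            kd_specific=(kd_specific_hiv,),
            kd_nonspecific=ns,
        ),
        "hiv_ltr_labeled": DNAConstruct(
            name="hiv_ltr_labeled",
            length=30,
            specific_sites=((4, 13), (18, 27)),
            kd_specific=(kd_specific_hiv, kd_specific_hiv),
            kd_nonspecific=ns,
        ),
        "nfkbia_emsa": DNAConstruct(
            name="nfkbia_emsa",
            length=59,
            specific_sites=((11, 20), (40, 49)),
            kd_specific=kd_nfkbia,
            kd_nonspecific=ns,
        ),
        "nfkbia_labeled": DNAConstruct(
            name="nfkbia_labeled",
            length=45,
            specific_sites=((4, 13), (33, 42)),
            kd_specific=kd_nfkbia,
            kd_nonspecific=ns,
        ),
    }
    for name, seq in HAIRPIN_SEQUENCES.items():
        key = "hairpin_" + name.lower().replace("-", "_")
        fx[key] = DNAConstruct(
            name=key,
            length=len(seq),
            specific_sites=((1, 10),),
            kd_specific=(kd_specific_hiv,),
            kd_nonspecific=ns,
        )
    return fx


def write_fasta(path, sequences: dict[str, str] | None = None) -> None:
    """Write hairpin sequences (or any name→sequence map) as FASTA."""
    sequences = sequences or HAIRPIN_SEQUENCES
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def curves_to_frame(curves: list[TitrationCurve]) -> pd.DataFrame:
    """Tidy CSV-ready frame matching the fitting module's input schema."""
    rows = []
    for c in curves:
        for x, y in zip(c.concentrations, c.anisotropy):
            rows.append(
                {
                    "construct": c.construct,
                    "label": c.label.labeled_strand,
                    "replicate": c.replicate,
                    "conc_nM": x,
                    "anisotropy": y,
                    "d_total_nM": c.d_total,
                }
            )
    return pd.DataFrame(rows)


def frame_to_curves(
    df: pd.DataFrame, constructs: dict[str, DNAConstruct] | None = None
) -> list[TitrationCurve]:
    """Parse a titration CSV frame back into TitrationCurve objects.

    Label geometry is reconstructed from the construct registry (the
    fixture set by default) so forward/reverse labels map to the right
    fluorophore coordinate.
    """
    constructs = constructs if constructs is not None else fixtures()
    required = {"construct", "label", "replicate", "conc_nM", "anisotropy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    curves = []
    for (name, strand, rep), grp in df.groupby(
        ["construct", "label", "replicate"], sort=False
    ):
        if name in constructs:
            label = LabelConfig.for_construct(constructs[name], strand)
        else:
            label = LabelConfig(labeled_strand=strand)
        d_total = float(grp["d_total_nM"].iloc[0]) if "d_total_nM" in grp else 5.0
        curves.append(
            TitrationCurve(
                construct=name,
                label=label,
                replicate=int(rep),
                concentrations=grp["conc_nM"].to_numpy(float),
                anisotropy=grp["anisotropy"].to_numpy(float),
                d_total=d_total,
            )
        )
    return curves
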