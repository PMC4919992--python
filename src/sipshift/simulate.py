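"""Forward simulation of DNA-SIP isopycnic gradient experiments.

The generator reproduces the data structure of a CsCl density-gradient SIP
study: each taxon's DNA bands around a buoyant density set by its GC
content and ¹³C enrichment, the gradient is pulled from the bottom into 12
equal-width density fractions, per-fraction 16S copy totals are measured by
(noisy) qPCR, and per-fraction community composition is observed through
overdispersed compositional sequencing (Dirichlet-multinomial reads, or an
in-silico TRFLP digest collapsing taxa onto shared terminal-fragment
lengths).

Physical model
--------------
Band centre:  BD = a + b·GC + Δmax · (x − x_nat) / (1 − x_nat)

with ``a`` = 1.660 g/ml, ``b`` = 0.098 g/ml per unit GC (the classical
linear CsCl buoyant-density/GC relation) and ``Δmax`` = 0.036 g/ml, the
density gain of fully ¹³C-substituted DNA; ``x`` is the ¹³C atom fraction
and ``x_nat`` natural abundance. Within one gradient a taxon's DNA spreads
as a Gaussian band of standard deviation ``band_sigma`` around its centre,
plus a small uniform smear over the whole fraction window (fraction
``smear`` of its mass) mimicking the carry-over of DNA across CsCl
fractions that SIP gradients invariably show — without it the near-empty
heavy fractions of an unlabelled gradient would, after per-fraction
normalization, be occupied entirely by the far tail of the highest-GC
taxon, which real fingerprints do not do. Mass outside the fraction
window is reported as pellet (heavy) / top (light) tails rather than
silently renormalized, so per-taxon mass is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .isotope import ATOM13C_NATURAL
from .model import GradientFraction, GradientRun

__all__ = [
    "Taxon",
    "GradientConfig",
    "taxon_buoyant_density",
    "fraction_edges",
    "fractionate",
    "simulate_gradient",
    "insilico_trflp",
    "simulate_experiment",
    "make_community",
]


@dataclass(frozen=True)
class Taxon:
    """A simulated community member.

    base_abundance is its relative abundance in the unfractionated
    community; atom13c is the ¹³C atom fraction of its DNA carbon (natural
    abundance ≈ 0.0111 when unlabelled).
    """

    taxon_id: str
    gc: float
    atom13c: float = ATOM13C_NATURAL
    base_abundance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.taxon_id}: GC fraction {self.gc} outside [0, 1]")
        if not 0.0 <= self.atom13c <= 1.0:
            raise ValueError(
                f"{self.taxon_id}: atom13c {self.atom13c} outside [0, 1]"
            )
        if self.base_abundance < 0:
            raise ValueError(f"{self.taxon_id}: negative base abundance")

    @property
    def labelled(self) -> bool:
        """True if the taxon's DNA is ¹³C-enriched above natural abundance."""
        return self.atom13c > ATOM13C_NATURAL + 1e-6


@dataclass
class GradientConfig:
    """Parameters of one simulated gradient + sequencing observation.

    Defaults mirror a 12-fraction CsCl gradient centred near 1.72 g/ml,
    Gaussian band width 0.006 g/ml (bands span 3–5 fractions), sequencing
    depth 3240 reads per fraction, 10% qPCR noise, and moderate
    compositional overdispersion.
    """

    n_fractions: int = 12
    density_min: float = 1.665
    density_max: float = 1.775
    band_sigma: float = 0.006
    smear: float = 0.03
    seq_depth: int = 3240
    qpcr_cv: float = 0.10
    overdispersion: float = 200.0
    copy_scale: float = 1e8
    seed: int | None = None
    # buoyant density model constants
    bd_intercept: float = 1.660
    bd_gc_slope: float = 0.098
    bd_label_shift: float = 0.036

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if not self.density_min < self.density_max:
            raise ValueError("density_min must be below density_max")
        if self.seq_depth < 1:
            raise ValueError("seq_depth must be >= 1")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if not 0.0 <= self.smear < 1.0:
            raise ValueError("smear must be in [0, 1)")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive (or None)")


def taxon_buoyant_density(
    gc: float,
    atom13c: float = ATOM13C_NATURAL,
    *,
    intercept: float = 1.660,
    gc_slope: float = 0.098,
    label_shift: float = 0.036,
    atom13c_natural: float = ATOM13C_NATURAL,
) -> float:
    """Equilibrium buoyant density (g/ml) of a taxon's DNA.

    Linear in GC content, plus a ¹³C-labelling term that scales the
    full-substitution shift ``label_shift`` by the excess atom fraction.
    """
    gc_arr = np.asarray(gc, dtype=float)
    x = np.asarray(atom13c, dtype=float)
    if np.any(gc_arr < 0) or np.any(gc_arr > 1):
        raise ValueError("GC fraction outside [0, 1]")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("atom13c outside [0, 1]")
    bd = (
        intercept
        + gc_slope * gc_arr
        + label_shift * (x - atom13c_natural) / (1.0 - atom13c_natural)
    )
    return float(bd) if bd.ndim == 0 else bd


def fraction_edges(cfg: GradientConfig) -> np.ndarray:
    """Density edges of the fraction windows, heaviest first.

    Returns ``n_fractions + 1`` edges; fraction i (1-based) spans
    ``[edges[i], edges[i-1]]`` with ``edges[0] = density_max``.
    """
    return np.linspace(cfg.density_max, cfg.density_min, cfg.n_fractions + 1)


def fraction_densities(cfg: GradientConfig) -> np.ndarray:
    """Fraction midpoint densities, heaviest (fraction 1) first."""
    e = fraction_edges(cfg)
    return (e[:-1] + e[1:]) / 2.0


def _band_centres(taxa: Sequence[Taxon], cfg: GradientConfig) -> np.ndarray:
    return np.array(
        [
            taxon_buoyant_density(
                t.gc,
                t.atom13c,
                intercept=cfg.bd_intercept,
                gc_slope=cfg.bd_gc_slope,
                label_shift=cfg.bd_label_shift,
            )
            for t in taxa
        ]
    )


def fractionate(
    taxa: Sequence[Taxon], cfg: GradientConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribute each taxon's DNA mass over the fraction windows.

    The mass of taxon *t* in fraction *f* is its base abundance times
    ``(1 − smear)`` times the integral of Normal(BD_t, band_sigma) over
    *f*'s density interval (computed with the Gaussian CDF), plus an equal
    share ``smear / n_fractions`` of its mass smeared uniformly over the
    window. Band mass outside the window is returned separately so that
    per-taxon mass over fractions + tails equals the base abundance to
    machine precision.

    Returns
    -------
    (mass, tails)
        ``mass``: taxon × fraction DataFrame (columns = fraction index,
        fraction 1 heaviest); ``tails``: taxon × ['pellet', 'top'] with
        the truncated mass below the tube bottom window ('pellet', denser
        than density_max) and above it ('top', lighter than density_min).
    """
    if not taxa:
        raise ValueError("empty community")
    centres = _band_centres(taxa, cfg)
    base = np.array([t.base_abundance for t in taxa])
    edges = fraction_edges(cfg)  # decreasing
    # CDF at each edge for each taxon; edges decreasing -> use survival form
    z = (edges[None, :] - centres[:, None]) / cfg.band_sigma
    cdf = norm.cdf(z)  # taxon × edge, decreasing along axis 1
    band = 1.0 - cfg.smear
    frac_mass = base[:, None] * (
        band * (cdf[:, :-1] - cdf[:, 1:]) + cfg.smear / cfg.n_fractions
    )
    pellet = base * band * (1.0 - cdf[:, 0])  # denser than density_max
    top = base * band * cdf[:, -1]  # lighter than density_min
    ids = [t.taxon_id for t in taxa]
    mass = pd.DataFrame(
        frac_mass, index=ids, columns=range(1, cfg.n_fractions + 1)
    )
    tails = pd.DataFrame({"pellet": pellet, "top": top}, index=ids)
    return mass, tails


def _apply_treatment(taxa: Sequence[Taxon], treatment: str) -> list[Taxon]:
    """Force atom13c to natural abundance for a 12C/control gradient."""
    if treatment in ("12C", "control"):
        return [
            Taxon(t.taxon_id, t.gc, ATOM13C_NATURAL, t.base_abundance) for t in taxa
        ]
    if treatment == "13C":
        return list(taxa)
    raise ValueError(f"unknown treatment {treatment!r}")


def simulate_gradient(
    taxa: Sequence[Taxon],
    cfg: GradientConfig,
    treatment: str,
    *,
    soil: str = "D",
    replicate: int = 1,
    timepoint_days: int = 32,
    rng: np.random.Generator | None = None,
) -> GradientRun:
    """Simulate one fractionated gradient as observed data.

    In a ``"12C"`` (or control) gradient every taxon is forced to natural
    ¹³C abundance; in a ``"13C"`` gradient taxa keep the atom13c recorded
    on them, so only the designated labelled taxa band heavier. Per
    fraction, the 16S copy total is the fraction's DNA mass times a global
    copy scale with multiplicative lognormal qPCR noise (mean-preserving,
    CV = ``qpcr_cv``), and read counts are drawn Dirichlet-multinomially
    from the fraction's mass composition at ``seq_depth`` reads
    (concentration = ``overdispersion``; ``None`` gives plain multinomial
    sampling). Fully reproducible from ``cfg.seed`` / ``rng``.
    """
    if not taxa:
        raise ValueError("empty community")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eff_taxa = _apply_treatment(taxa, treatment)
    mass, tails = fractionate(eff_taxa, cfg)
    mat = mass.to_numpy()
    col_mass = mat.sum(axis=0)

    # qPCR totals: mean-preserving lognormal noise on true fraction mass
    if cfg.qpcr_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.qpcr_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=cfg.n_fractions)
    else:
        noise = np.ones(cfg.n_fractions)
    copies = col_mass * cfg.copy_scale * noise

    # compositional reads per fraction
    counts = np.zeros_like(mat, dtype=np.int64)
    for j in range(cfg.n_fractions):
        if col_mass[j] <= 0:
            raise ValueError(
                f"fraction {j + 1} received no DNA mass; widen the density "
                "window or increase band_sigma"
            )
        p = mat[:, j] / col_mass[j]
        support = p > 0
        if cfg.overdispersion is None:
            q = p[support]
        else:
            q = rng.dirichlet(cfg.overdispersion * p[support])
        counts[support, j] = rng.multinomial(cfg.seq_depth, q)

    dens = fraction_densities(cfg)
    fractions = [
        GradientFraction(index=i + 1, density=float(dens[i]))
        for i in range(cfg.n_fractions)
    ]
    run_id = f"{soil}_{treatment}_r{replicate}_t{timepoint_days}"
    return GradientRun(
        run_id=run_id,
        soil=soil,
        treatment=treatment,
        replicate=replicate,
        timepoint_days=timepoint_days,
        fractions=fractions,
        abundance=pd.DataFrame(counts, index=mass.index, columns=mass.columns),
        copies=copies,
        values_kind="counts",
        tail_mass={
            "pellet": tails["pellet"].sum(),
            "top": tails["top"].sum(),
        },
    )


def insilico_trflp(
    otu_matrix: pd.DataFrame, trf_map: Mapping[str, int]
) -> pd.DataFrame:
    """Collapse a taxon × fraction matrix onto terminal-fragment lengths.

    Emulates a restriction digest (e.g. MspI) in which distinct taxa can
    share a terminal fragment length: the TRF row is the sum of all mapped
    taxa. Every taxon must map to one integer TRF length in [50, 1000] bp.
    """
    missing = [t for t in otu_matrix.index if t not in trf_map]
    if missing:
        raise ValueError(f"taxa without a TRF length mapping: {missing}")
    lengths = {}
    for t in otu_matrix.index:
        length = trf_map[t]
        if not (isinstance(length, (int, np.integer)) and 50 <= length <= 1000):
            raise ValueError(
                f"taxon {t}: TRF length must be an integer in [50, 1000] bp, "
                f"got {length!r}"
            )
        lengths[t] = int(length)
    grouped = otu_matrix.groupby([lengths[t] for t in otu_matrix.index]).sum()
    grouped.index.name = "trf_bp"
    return grouped.sort_index()


@dataclass
class ExperimentDesign:
    """Factorial design of a paired-gradient SIP experiment."""

    soils: tuple[str, ...] = ("D", "F", "W")
    treatments: tuple[str, ...] = ("12C", "13C")
    replicates: int = 3
    timepoint_days: int = 32


def simulate_experiment(
    communities: Mapping[str, Sequence[Taxon]],
    cfg: GradientConfig,
    design: ExperimentDesign | None = None,
) -> list[GradientRun]:
    """Simulate a full soils × treatments × replicates set of gradients.

    Each run gets an independent child seed derived deterministically from
    ``cfg.seed`` via ``numpy.random.SeedSequence.spawn`` in a fixed
    (soil, treatment, replicate) order, so any single run is reproducible
    and the whole experiment is byte-identical across invocations. The
    labelled guild of each soil is whatever ``atom13c`` its community's
    taxa carry; the 12C arm forces all taxa to natural abundance.
    """
    if design is None:
        design = ExperimentDesign(soils=tuple(communities))
    missing = [s for s in design.soils if s not in communities]
    if missing:
        raise ValueError(f"no community provided for soil(s) {missing}")
    ss = np.random.SeedSequence(cfg.seed)
    n_runs = len(design.soils) * len(design.treatments) * design.replicates
    children = ss.spawn(n_runs)
    runs: list[GradientRun] = []
    k = 0
    for soil in design.soils:
        for treatment in design.treatments:
            for rep in range(1, design.replicates + 1):
                rng = np.random.default_rng(children[k])
                k += 1
                runs.append(
                    simulate_gradient(
                        communities[soil],
                        cfg,
                        treatment,
                        soil=soil,
                        replicate=rep,
                        timepoint_days=design.timepoint_days,
                        rng=rng,
                    )
                )
    return runs


def make_community(
    n_taxa: int,
    labelled_ids: Iterable[str] | int = 0,
    *,
    rng: np.random.Generator,
    labelled_atom13c: float = 0.99,
    labelled_abundance: tuple[float, float] = (0.02, 0.04),
    gc_range: tuple[float, float] = (0.30, 0.70),
    abundance_sigma: float = 1.2,
    prefix: str = "T",
) -> list[Taxon]:
    """Draw a random soil-like community with a designated labelled guild.

    Unlabelled taxa get lognormal relative abundances (few dominant, long
    tail of rare taxa, as in soil amplicon profiles); labelled taxa get
    abundances drawn uniformly from ``labelled_abundance`` so they sit
    above typical detection thresholds, and their DNA carries
    ``labelled_atom13c`` (default 0.99, a fully ¹³C-substituted substrate).
    GC contents are uniform over ``gc_range``. ``labelled_ids`` may be an
    integer (first k taxa) or explicit IDs.
    """
    ids = [f"{prefix}{i + 1:03d}" for i in range(n_taxa)]
    if isinstance(labelled_ids, int):
        labelled = set(ids[:labelled_ids])
    else:
        labelled = set(labelled_ids)
        unknown = labelled - set(ids)
        if unknown:
            raise ValueError(f"labelled ids not in community: {sorted(unknown)}")
    gc = rng.uniform(*gc_range, size=n_taxa)
    lab_mask = np.array([i in labelled for i in ids])
    abund = np.empty(n_taxa)
    abund[lab_mask] = rng.uniform(*labelled_abundance, size=lab_mask.sum())
    rest = rng.lognormal(0.0, abundance_sigma, size=(~lab_mask).sum())
    abund[~lab_mask] = rest / rest.sum() * (1.0 - abund[lab_mask].sum())
    return [
        Taxon(
            taxon_id=i,
            gc=float(g),
            atom13c=labelled_atom13c if i in labelled else ATOM13C_NATURAL,
            base_abundance=float(a),
        )
        for i, g, a in zip(ids, gc, abund)
    ]
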