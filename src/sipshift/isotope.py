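"""Stable-isotope arithmetic for SIP experiments.

Covers the three pieces of isotope bookkeeping a DNA-SIP study needs
outside the gradient itself:

* δ-notation (‰ vs V-PDB) and its conversion to/from ¹³C atom fraction;
* the chloroform fumigation-extraction mixing formula that recovers the
  δ¹³C of microbial biomass carbon from fumigated and non-fumigated soil
  extracts;
* amplification efficiency of a qPCR standard curve from its slope.

All δ values are per mil relative to the Vienna-Pee Dee Belemnite (V-PDB)
standard; concentrations are mg C per litre of extract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ¹³C/¹²C isotope ratio of the V-PDB reference standard.
R_VPDB = 0.0111802


def atom_fraction_natural(r_vpdb: float = R_VPDB) -> float:
    """¹³C atom fraction at natural abundance (δ¹³C = 0 ‰ vs V-PDB)."""
    return r_vpdb / (1.0 + r_vpdb)


#: ¹³C atom fraction of carbon at natural abundance (~1.106 atom%).
ATOM13C_NATURAL = atom_fraction_natural()


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One fumigation-extraction measurement pair.

    Parameters
    ----------
    delta_fum
        δ¹³C of the fumigated extract (‰ V-PDB).
    c_fum
        C concentration of the fumigated extract (mg/L). Must be positive
        and exceed ``c_nfum`` so that biomass C is positive.
    delta_nfum
        δ¹³C of the non-fumigated extract (‰ V-PDB).
    c_nfum
        C concentration of the non-fumigated extract (mg/L), non-negative.
    """

    delta_fum: float
    c_fum: float
    delta_nfum: float
    c_nfum: float

    def __post_init__(self) -> None:
        if self.c_nfum < 0:
            raise ValueError(
                f"non-fumigated C concentration must be >= 0, got {self.c_nfum}"
            )
        if self.c_fum <= 0:
            raise ValueError(
                f"fumigated C concentration must be > 0, got {self.c_fum}"
            )
        if self.c_fum <= self.c_nfum:
            raise ValueError(
                "fumigated C concentration must exceed the non-fumigated one "
                f"(got c_fum={self.c_fum}, c_nfum={self.c_nfum}): "
                "biomass C = c_fum - c_nfum would be non-positive"
            )

    @property
    def c_mic(self) -> float:
        """Microbial biomass C of the extract pair (mg/L)."""
        return self.c_fum - self.c_nfum


def delta13c_mic(m: IsotopeMeasurement) -> float:
    """δ¹³C of microbial biomass carbon from a fumigation-extraction pair.

    The fumigated extract is a two-pool mixture of biomass C (released by
    chloroform lysis) and the extractable background C also present in the
    non-fumigated extract. Isotope mass balance gives

        δ¹³C_mic = (δ_fum · C_fum − δ_nfum · C_nfum) / (C_fum − C_nfum)

    Returns
    -------
    float
        δ¹³C of microbial biomass (‰ V-PDB).
    """
    return (m.delta_fum * m.c_fum - m.delta_nfum * m.c_nfum) / m.c_mic


def qpcr_efficiency(slope: float) -> float:
    """Amplification efficiency of a qPCR standard curve.

    For a regression of Ct on log10(template copies) with slope ``slope``,
    the per-cycle amplification efficiency is

        Eff = 10^(−1/slope) − 1

    so a perfect doubling assay (slope = −1/log10(2) ≈ −3.32) gives 1.0.

    Parameters
    ----------
    slope
        Standard-curve slope; must be negative (Ct decreases with template).

    Returns
    -------
    float
        Efficiency as a fraction (0.94 means 94%).
    """
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def delta_to_atom_fraction(delta: float, r_vpdb: float = R_VPDB) -> float:
    """Convert δ¹³C (‰ V-PDB) to ¹³C atom fraction.

    R = R_VPDB · (δ/1000 + 1); atom fraction = R / (1 + R).
    """
    delta = np.asarray(delta, dtype=float) if np.ndim(delta) else float(delta)
    if np.any(np.asarray(delta) <= -1000.0):
        raise ValueError("delta <= -1000 permil implies a negative isotope ratio")
    r = r_vpdb * (np.asarray(delta) / 1000.0 + 1.0)
    out = r / (1.0 + r)
    return out if np.ndim(delta) else float(out)


def atom_fraction_to_delta(atom_fraction: float, r_vpdb: float = R_VPDB) -> float:
    """Convert ¹³C atom fraction to δ¹³C (‰ V-PDB). Inverse of
    :func:`delta_to_atom_fraction`."""
    x = np.asarray(atom_fraction, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("atom fraction must lie in [0, 1)")
    r = x / (1.0 - x)
    out = (r / r_vpdb - 1.0) * 1000.0
    return out if np.ndim(atom_fraction) else float(out)


ISOTOPE_TABLE_COLUMNS = [
    "sample_id",
    "timepoint_days",
    "treatment",
    "delta_fum",
    "c_fum",
    "delta_nfum",
    "c_nfum",
]


def read_isotope_table(path) -> pd.DataFrame:
    """Read fumigation-extraction measurements from a tab-separated file.

    Expected columns: sample_id, timepoint_days, treatment, delta_fum,
    c_fum, delta_nfum, c_nfum. One row per replicate measurement.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ISOTOPE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def summarize_delta13c_mic(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample δ¹³C_mic with replicates propagated as mean ± sd.

    δ¹³C_mic is computed per replicate row, then grouped by
    (sample_id, timepoint_days, treatment) and reported as mean, sd and n —
    the conventional presentation for triplicate fumigation extractions.
    """
    rows = df.apply(
        lambda r: delta13c_mic(
            IsotopeMeasurement(
                r["delta_fum"], r["c_fum"], r["delta_nfum"], r["c_nfum"]
            )
        ),
        axis=1,
    )
    out = df[["sample_id", "timepoint_days", "treatment"]].copy()
    out["delta13c_mic"] = rows
    g = out.groupby(["sample_id", "timepoint_days", "treatment"], sort=True)
    summary = g["delta13c_mic"].agg(mean="mean", sd="std", n="count").reset_index()
    return summary
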