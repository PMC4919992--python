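"""Identification of isotope-labelled taxa from paired gradient sets.

The screen follows the logic of a classical DNA-SIP comparison: every
labelled (¹³C) gradient has an unlabelled (¹²C) partner, and a taxon that
assimilated the labelled substrate shows an abundance shift towards the
heavier fractions of the ¹³C gradients. Three quantities make the screen
reproducible:

* the per-fraction **difference profile** — the mean difference in relative
  abundance between the ¹³C and ¹²C replicate gradients, the quantity a
  SIP difference plot displays;
* the **centre-of-mass buoyant density** of a taxon in a run — the
  abundance-weighted mean fraction density, whose ¹³C − ¹²C difference
  (``com_shift``) quantifies "shifted towards heavier fractions";
* the whole-community, copy-weighted density shift (``total_shift_check``)
  used to decide whether a timepoint shows labelling at all before any
  per-taxon screening.

A taxon is called labelled when its com_shift exceeds a density threshold
(default one 12-fraction width, 0.010 g/ml) and its difference profile is
positive in at least ``heavy_k`` heavy-side fractions — shifts in real
gradients develop gradually over at least two adjacent fractions, so a
single-fraction excursion is not accepted. An optional permutation test
(shuffling treatment labels across replicate gradients) attaches a p-value;
it is off by default, matching the conventional visual screen.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GradientRun, check_same_design

__all__ = [
    "DetectionParams",
    "ShiftResult",
    "TotalShiftResult",
    "reconstruct_total_community",
    "difference_profile",
    "bd_center_of_mass",
    "detect_labelled",
    "total_shift_check",
    "shift_table",
]


# ---------------------------------------------------------------------------
# community reconstruction
# ---------------------------------------------------------------------------

def reconstruct_total_community(
    run: GradientRun, weighting: str = "copies"
) -> pd.Series:
    """Reconstruct the unfractionated community from fraction profiles.

    Sums each taxon's relative abundance over fractions, weighting each
    fraction by its share of the 16S copy pool (``weighting="copies"``,
    the amount of DNA the fraction actually held) or equally
    (``"uniform"``). The result is a relative-abundance vector summing
    to 1.
    """
    run = run.normalized()
    if weighting == "copies":
        if run.copies is None:
            raise ValueError(f"run {run.run_id}: no qPCR copies for weighting")
        total = run.copies.sum()
        if total <= 0:
            raise ValueError(f"run {run.run_id}: all-zero qPCR copies")
        w = run.copies / total
    elif weighting == "uniform":
        w = np.full(run.n_fractions, 1.0 / run.n_fractions)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    vec = run.abundance.to_numpy() @ w
    return pd.Series(vec, index=run.abundance.index, name=run.run_id)


# ---------------------------------------------------------------------------
# difference profiles and centres of mass
# ---------------------------------------------------------------------------

def _mean_profile(runs: Sequence[GradientRun]) -> pd.DataFrame:
    """Mean relative-abundance matrix over replicate runs, aligned by
    fraction index and taxon union (absent taxa count as 0)."""
    mats = [r.normalized().abundance for r in runs]
    taxa = sorted(set(itertools.chain.from_iterable(m.index for m in mats)))
    acc = np.zeros((len(taxa), mats[0].shape[1]))
    for m in mats:
        acc += m.reindex(taxa, fill_value=0.0).to_numpy()
    return pd.DataFrame(acc / len(mats), index=taxa, columns=mats[0].columns)


def difference_profile(
    runs_13c: Sequence[GradientRun],
    runs_12c: Sequence[GradientRun],
    taxon: str | None = None,
) -> pd.DataFrame | pd.Series:
    """Per-fraction mean difference in relative abundance (¹³C − ¹²C).

    Fractions are aligned by index across the two replicate sets (the
    positional convention of comparing "heavier fractions" across
    gradients). Returns a taxon × fraction DataFrame, or a single taxon's
    Series if ``taxon`` is given.
    """
    if not runs_13c or not runs_12c:
        raise ValueError("both treatment arms need at least one run")
    n13 = check_same_design(runs_13c)
    n12 = check_same_design(runs_12c)
    if n13 != n12:
        raise ValueError(
            f"fraction counts differ between arms: {n13} (13C) vs {n12} (12C)"
        )
    delta = _mean_profile(runs_13c).subtract(
        _mean_profile(runs_12c), fill_value=0.0
    )
    if taxon is not None:
        if taxon not in delta.index:
            raise KeyError(f"taxon {taxon!r} absent from both arms")
        return delta.loc[taxon]
    return delta


def bd_center_of_mass(
    run: GradientRun, taxon: str, weighting: str = "copies"
) -> float:
    """Abundance-weighted mean buoyant density (g/ml) of one taxon.

    With ``weighting="copies"`` the taxon's relative abundance in each
    fraction is scaled by the fraction's 16S copy total, recovering the
    taxon's absolute DNA distribution over the gradient; ``"relative"``
    uses the relative abundances as they stand. Returns NaN (flagging the
    taxon as not evaluable) when the taxon carries no signal in the run.
    """
    run = run.normalized()
    if taxon not in run.abundance.index:
        return float("nan")
    a = run.abundance.loc[taxon].to_numpy()
    if weighting == "copies":
        if run.copies is None:
            raise ValueError(f"run {run.run_id}: no qPCR copies for weighting")
        m = a * run.copies
    elif weighting == "relative":
        m = a
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = m.sum()
    if total <= 0:
        return float("nan")
    return float(m @ run.densities / total)


# ---------------------------------------------------------------------------
# labelled-taxon detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    """Thresholds of the labelled-taxon screen.

    com_threshold
        Minimum ¹³C − ¹²C centre-of-mass density shift (g/ml) to call a
        taxon. Default 0.010, about one fraction width of a 12-fraction
        gradient.
    heavy_k
        The difference profile must be positive in at least this many
        heavy-side fractions (shifts develop over at least two adjacent
        fractions).
    min_abund
        Taxa below this relative abundance in the reconstructed total
        community are not evaluated.
    n_perm, alpha, seed
        Optional permutation test: shuffle treatment labels across
        replicate gradients ``n_perm`` times and require p ≤ alpha in
        addition to the thresholds. ``n_perm=0`` (default) disables it.
    weighting
        Centre-of-mass weighting, ``"copies"`` or ``"relative"``.
    """

    com_threshold: float = 0.010
    heavy_k: int = 2
    min_abund: float = 0.001
    n_perm: int = 0
    alpha: float = 0.05
    seed: int | None = None
    weighting: str = "copies"


@dataclass
class ShiftResult:
    """Per-taxon outcome of the labelled-taxon screen."""

    taxon_id: str
    delta_profile: np.ndarray
    com_12c: float
    com_13c: float
    com_shift: float
    heavy_gain: float
    labelled: bool
    p_value: float | None = None
    evaluable: bool = True
    total_abundance: float = field(default=float("nan"))


@dataclass
class TotalShiftResult:
    """Whole-community qPCR density-shift check."""

    shift: float
    detected: bool
    com_13c: float
    com_12c: float
    tolerance: float


def _com_components(
    runs: Sequence[GradientRun], taxa: Sequence[str], weighting: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-run numerators and denominators of pooled centre-of-mass.

    For run *r* and taxon *t*: num[t, r] = Σ_f density_f · m_{t,f},
    den[t, r] = Σ_f m_{t,f}. An arm's centre of mass is the ratio of the
    sums over its runs — pooling the replicates' mass rather than
    averaging per-replicate ratios, which is badly behaved for taxa with
    little signal in a single gradient.
    """
    num = np.zeros((len(taxa), len(runs)))
    den = np.zeros((len(taxa), len(runs)))
    for j, r in enumerate(runs):
        rn = r.normalized()
        a = rn.abundance.reindex(taxa, fill_value=0.0).to_numpy()
        if weighting == "copies":
            if rn.copies is None:
                raise ValueError(f"run {r.run_id}: no qPCR copies for weighting")
            m = a * (rn.copies / rn.copies.sum())
        else:
            m = a
        num[:, j] = m @ rn.densities
        den[:, j] = m.sum(axis=1)
    return num, den


def _pooled_com(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    n = num.sum(axis=1)
    d = den.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d > 0, n / np.where(d > 0, d, 1.0), np.nan)


def _copy_weighted_median_density(runs: Sequence[GradientRun]) -> float:
    """Median of the pooled copy-density distribution; defines 'heavy side'."""
    dens = np.concatenate([r.densities for r in runs])
    if any(r.copies is None for r in runs):
        w = np.ones_like(dens)
    else:
        w = np.concatenate([r.copies for r in runs])
    order = np.argsort(dens)
    cw = np.cumsum(w[order])
    return float(dens[order][np.searchsorted(cw, 0.5 * cw[-1])])


def detect_labelled(
    runs_13c: Sequence[GradientRun],
    runs_12c: Sequence[GradientRun],
    params: DetectionParams | None = None,
) -> list[ShiftResult]:
    """Screen taxa for buoyant-density shifts between treatment arms.

    Taxa are intersected across the two arms (a taxon observed in only
    one arm cannot be screened and is silently excluded — inspect the raw
    matrices for one-arm taxa rather than expecting a call). For each
    remaining taxon above ``min_abund`` the per-arm centre-of-mass
    densities, their difference, the per-fraction difference profile and
    the heavy-side gain are computed; the labelled call applies the
    thresholds documented on :class:`DetectionParams`.
    """
    if params is None:
        params = DetectionParams()
    if not runs_13c or not runs_12c:
        raise ValueError("each treatment arm needs at least one replicate run")
    delta = difference_profile(runs_13c, runs_12c)

    common = sorted(
        set.intersection(
            *(set(r.abundance.index) for r in (*runs_13c, *runs_12c))
        )
    )
    if not common:
        return []

    # mean total-community abundance over all runs (both arms)
    totals = np.zeros(len(common))
    all_runs = list(runs_13c) + list(runs_12c)
    weighting = params.weighting
    for r in all_runs:
        w = "uniform" if (weighting == "relative" or r.copies is None) else "copies"
        totals += (
            reconstruct_total_community(r, w).reindex(common, fill_value=0.0).to_numpy()
        )
    totals /= len(all_runs)

    num13, den13 = _com_components(runs_13c, common, weighting)
    num12, den12 = _com_components(runs_12c, common, weighting)
    mean13 = _pooled_com(num13, den13)
    mean12 = _pooled_com(num12, den12)

    median_density = _copy_weighted_median_density(list(runs_12c))
    dens = runs_12c[0].densities
    heavy = dens > median_density

    perm_shifts = None
    if params.n_perm > 0:
        if len(runs_13c) < 2 or len(runs_12c) < 2:
            warnings.warn(
                "permutation test skipped: need >= 2 replicates per arm",
                stacklevel=2,
            )
        else:
            rng = np.random.default_rng(params.seed)
            num = np.concatenate([num13, num12], axis=1)
            den = np.concatenate([den13, den12], axis=1)
            n13 = num13.shape[1]
            ncols = num.shape[1]
            perm_shifts = np.empty((len(common), params.n_perm))
            for b in range(params.n_perm):
                idx = rng.permutation(ncols)
                perm_shifts[:, b] = _pooled_com(
                    num[:, idx[:n13]], den[:, idx[:n13]]
                ) - _pooled_com(num[:, idx[n13:]], den[:, idx[n13:]])

    results: list[ShiftResult] = []
    dmat = delta.reindex(common, fill_value=0.0).to_numpy()
    for i, t in enumerate(common):
        prof = dmat[i]
        shift = mean13[i] - mean12[i]
        evaluable = np.isfinite(shift) and totals[i] >= params.min_abund
        heavy_gain = float(prof[heavy][prof[heavy] > 0].sum())
        n_heavy_pos = int((prof[heavy] > 0).sum())
        p = None
        if perm_shifts is not None and evaluable:
            p = float(
                (1 + np.sum(perm_shifts[i] >= shift)) / (1 + params.n_perm)
            )
        labelled = bool(
            evaluable
            and shift >= params.com_threshold
            and n_heavy_pos >= params.heavy_k
            and (p is None or p <= params.alpha)
        )
        results.append(
            ShiftResult(
                taxon_id=t,
                delta_profile=prof,
                com_12c=float(mean12[i]),
                com_13c=float(mean13[i]),
                com_shift=float(shift) if np.isfinite(shift) else float("nan"),
                heavy_gain=heavy_gain,
                labelled=labelled,
                p_value=p,
                evaluable=bool(evaluable),
                total_abundance=float(totals[i]),
            )
        )
    return results


def one_arm_taxa(
    runs_13c: Sequence[GradientRun], runs_12c: Sequence[GradientRun]
) -> dict[str, list[str]]:
    """Taxa observed in only one treatment arm.

    These cannot be screened for a density shift (no paired profile) and
    are never auto-called labelled; report them alongside the screen.
    """
    t13 = set(itertools.chain.from_iterable(r.abundance.index for r in runs_13c))
    t12 = set(itertools.chain.from_iterable(r.abundance.index for r in runs_12c))
    return {
        "only_13C": sorted(t13 - t12),
        "only_12C": sorted(t12 - t13),
    }


def shift_table(results: Sequence[ShiftResult]) -> pd.DataFrame:
    """Tabulate ShiftResults (one row per taxon, delta profile excluded)."""
    return pd.DataFrame(
        dict(
            taxon_id=[r.taxon_id for r in results],
            total_abundance=[r.total_abundance for r in results],
            com_12c=[r.com_12c for r in results],
            com_13c=[r.com_13c for r in results],
            com_shift=[r.com_shift for r in results],
            heavy_gain=[r.heavy_gain for r in results],
            p_value=[r.p_value for r in results],
            evaluable=[r.evaluable for r in results],
            labelled=[r.labelled for r in results],
        )
    ).set_index("taxon_id")


# ---------------------------------------------------------------------------
# whole-community shift
# ---------------------------------------------------------------------------

def _pool_com(run: GradientRun) -> float:
    if run.copies is None:
        raise ValueError(f"run {run.run_id}: qPCR copies required")
    total = run.copies.sum()
    if total <= 0:
        raise ValueError(f"run {run.run_id}: all-zero qPCR copies")
    return float(run.copies @ run.densities / total)


def total_shift_check(
    runs_13c: Sequence[GradientRun],
    runs_12c: Sequence[GradientRun],
    tolerance: float = 0.003,
) -> TotalShiftResult:
    """Copy-weighted mean-density shift of the whole 16S pool.

    Averages the copy-weighted mean buoyant density over replicates per
    arm and reports the ¹³C − ¹²C difference; "detected" when the shift
    is positive beyond ``tolerance`` (g/ml). This is the timepoint-level
    check that decides whether labelling is strong enough for per-taxon
    screening.
    """
    if not runs_13c or not runs_12c:
        raise ValueError("each treatment arm needs at least one run")
    com13 = float(np.mean([_pool_com(r) for r in runs_13c]))
    com12 = float(np.mean([_pool_com(r) for r in runs_12c]))
    shift = com13 - com12
    return TotalShiftResult(
        shift=shift,
        detected=shift > tolerance,
        com_13c=com13,
        com_12c=com12,
        tolerance=tolerance,
    )
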