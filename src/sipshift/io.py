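"""Readers, writers and profile-level preprocessing for fraction tables.

On-disk layout (tab-separated text, one directory per experiment):

* ``runs.tsv``       — run_id, soil, treatment, replicate, timepoint_days,
  values_kind
* ``fractions.tsv``  — run_id, fraction, density_g_ml, copies_16s
* ``abundance.tsv``  — taxon_id plus one ``run_id:fraction`` column per
  gradient fraction
* ``taxa.tsv``       — (simulator output) taxon_id, gc, atom13c, labelled,
  base_abundance

Preprocessing implements the standard fingerprint/amplicon rules: per-
profile normalization by total signal, exclusion of terminal fragments
below 50 bp or contributing <1% of a profile, and seeded rarefaction of
count tables to a common depth.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GradientFraction, GradientRun
from .simulate import Taxon

__all__ = [
    "write_fraction_tables",
    "read_fraction_tables",
    "write_taxa",
    "read_taxa",
    "normalize_profile",
    "filter_trfs",
    "rarefy",
]

RUNS_FILE = "runs.tsv"
FRACTIONS_FILE = "fractions.tsv"
ABUNDANCE_FILE = "abundance.tsv"
TAXA_FILE = "taxa.tsv"

_RUN_COLS = ["run_id", "soil", "treatment", "replicate", "timepoint_days", "values_kind"]
_FRACTION_COLS = ["run_id", "fraction", "density_g_ml", "copies_16s"]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fraction_tables(runs: Sequence[GradientRun], outdir) -> None:
    """Write a set of gradient runs to ``runs/fractions/abundance`` TSVs."""
    os.makedirs(outdir, exist_ok=True)
    run_rows, frac_rows, abund_cols = [], [], {}
    taxa_index = None
    for r in runs:
        run_rows.append(
            dict(
                run_id=r.run_id,
                soil=r.soil,
                treatment=r.treatment,
                replicate=r.replicate,
                timepoint_days=r.timepoint_days,
                values_kind=r.values_kind,
            )
        )
        copies = r.copies if r.copies is not None else [np.nan] * r.n_fractions
        for f, c in zip(r.fractions, copies):
            frac_rows.append(
                dict(
                    run_id=r.run_id,
                    fraction=f.index,
                    density_g_ml=f.density,
                    copies_16s=c,
                )
            )
        if taxa_index is None:
            taxa_index = list(r.abundance.index)
        elif list(r.abundance.index) != taxa_index:
            raise ValueError(
                f"run {r.run_id}: taxon rows differ from the first run; "
                "write runs with a shared taxon index"
            )
        for f in r.fractions:
            abund_cols[f"{r.run_id}:{f.index}"] = r.abundance[f.index].to_numpy()
    pd.DataFrame(run_rows, columns=_RUN_COLS).to_csv(
        os.path.join(outdir, RUNS_FILE), sep="\t", index=False
    )
    pd.DataFrame(frac_rows, columns=_FRACTION_COLS).to_csv(
        os.path.join(outdir, FRACTIONS_FILE), sep="\t", index=False
    )
    abund = pd.DataFrame(abund_cols, index=pd.Index(taxa_index))
    abund.to_csv(os.path.join(outdir, ABUNDANCE_FILE), sep="\t", index_label="taxon_id")


def write_taxa(taxa: Sequence[Taxon], path) -> None:
    """Write the simulator's ground-truth taxon table."""
    pd.DataFrame(
        dict(
            taxon_id=[t.taxon_id for t in taxa],
            gc=[t.gc for t in taxa],
            atom13c=[t.atom13c for t in taxa],
            labelled=[t.labelled for t in taxa],
            base_abundance=[t.base_abundance for t in taxa],
        )
    ).to_csv(path, sep="\t", index=False)


def read_taxa(path) -> list[Taxon]:
    df = pd.read_csv(path, sep="\t")
    return [
        Taxon(r.taxon_id, r.gc, r.atom13c, r.base_abundance)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_fraction_tables(indir) -> list[GradientRun]:
    """Read an experiment directory back into :class:`GradientRun` objects.

    Malformed input — missing columns, duplicate (run_id, fraction) rows,
    densities that do not strictly decrease with fraction index — raises a
    ValueError naming the offending run and rows.
    """
    runs_path = os.path.join(indir, RUNS_FILE)
    frac_path = os.path.join(indir, FRACTIONS_FILE)
    abund_path = os.path.join(indir, ABUNDANCE_FILE)
    runs_df = pd.read_csv(runs_path, sep="\t")
    frac_df = pd.read_csv(frac_path, sep="\t", float_precision="round_trip")
    abund = pd.read_csv(
        abund_path, sep="\t", index_col="taxon_id", float_precision="round_trip"
    )
    abund.index.name = None
    _require_columns(runs_df, _RUN_COLS, runs_path)
    _require_columns(frac_df, _FRACTION_COLS, frac_path)

    dup = frac_df.duplicated(["run_id", "fraction"])
    if dup.any():
        lines = (frac_df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(
            f"{frac_path}: duplicate (run_id, fraction) rows at lines {lines}"
        )

    runs = []
    for rr in runs_df.itertuples():
        sub = frac_df[frac_df["run_id"] == rr.run_id].sort_values("fraction")
        if sub.empty:
            raise ValueError(f"{frac_path}: no fractions for run {rr.run_id}")
        dens = sub["density_g_ml"].to_numpy()
        if not np.all(np.diff(dens) < 0):
            raise ValueError(
                f"run {rr.run_id}: fraction density must strictly decrease "
                "with fraction index (fraction 1 is the heaviest)"
            )
        fractions = [
            GradientFraction(index=int(f), density=float(d))
            for f, d in zip(sub["fraction"], dens)
        ]
        cols = [f"{rr.run_id}:{f.index}" for f in fractions]
        missing = [c for c in cols if c not in abund.columns]
        if missing:
            raise ValueError(f"{abund_path}: missing abundance columns {missing}")
        mat = abund[cols].copy()
        mat.columns = [f.index for f in fractions]
        copies = sub["copies_16s"].to_numpy(dtype=float)
        runs.append(
            GradientRun(
                run_id=rr.run_id,
                soil=str(rr.soil),
                treatment=str(rr.treatment),
                replicate=int(rr.replicate),
                timepoint_days=int(rr.timepoint_days),
                fractions=fractions,
                abundance=mat,
                copies=None if np.isnan(copies).all() else copies,
                values_kind=str(rr.values_kind),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# profile preprocessing
# ---------------------------------------------------------------------------

def normalize_profile(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize each fraction profile (column) by its total signal.

    Relative abundance of a TRF/OTU is its signal divided by the summed
    signal of its profile, so every column sums to 1. An all-zero column
    (an empty fraction) is an error rather than 0/0.
    """
    mat = raw.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative signal values")
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        empty = [c for c, s in zip(raw.columns, totals) if s <= 0]
        raise ValueError(f"empty fraction profile(s): {empty}")
    return pd.DataFrame(mat / totals, index=raw.index, columns=raw.columns)


def filter_trfs(
    matrix: pd.DataFrame,
    min_len_bp: int = 50,
    min_relabund: float = 0.01,
    *,
    lengths: Sequence[int] | None = None,
    relabund_basis: str = "prefilter",
) -> pd.DataFrame:
    """Apply the standard TRFLP exclusion rules and renormalize.

    Fragments shorter than ``min_len_bp`` bases are removed, and within
    each profile (fraction column) TRFs contributing less than
    ``min_relabund`` of the profile total are zeroed; rows left without
    signal anywhere are dropped and surviving columns renormalized to 1.

    ``relabund_basis`` selects the total against which the relative-
    abundance rule is judged: ``"prefilter"`` (default) uses the raw
    profile total, ``"postfilter"`` the total after the length filter.
    TRF lengths are taken from the integer row index unless ``lengths``
    is given.

    Raises if the filters remove every row.
    """
    if relabund_basis not in ("prefilter", "postfilter"):
        raise ValueError("relabund_basis must be 'prefilter' or 'postfilter'")
    if lengths is None:
        try:
            lens = matrix.index.astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(
                "row index is not integer TRF lengths; pass lengths="
            ) from exc
    else:
        lens = np.asarray(list(lengths), dtype=int)
        if len(lens) != len(matrix):
            raise ValueError("lengths does not match the number of rows")

    keep_len = lens >= min_len_bp
    mat = matrix.to_numpy(dtype=float)
    if relabund_basis == "prefilter":
        totals = mat.sum(axis=0)
    else:
        totals = mat[keep_len].sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a profile has no signal to judge the abundance rule on")

    out = mat.copy()
    out[~keep_len, :] = 0.0
    out[(out / totals) < min_relabund] = 0.0
    row_keep = out.sum(axis=1) > 0
    if not row_keep.any():
        raise ValueError(
            f"filters (min_len_bp={min_len_bp}, min_relabund={min_relabund}) "
            "removed every TRF"
        )
    filtered = pd.DataFrame(
        out[row_keep], index=matrix.index[row_keep], columns=matrix.columns
    )
    return normalize_profile(filtered)


def rarefy(
    counts: pd.DataFrame,
    depth: int = 3240,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Subsample each count column without replacement to a common depth.

    Reads are drawn multivariate-hypergeometrically (exact subsampling
    without replacement), so each column sums to exactly ``depth`` and the
    expected count of a taxon is ``depth`` times its input proportion.
    Columns shallower than ``depth`` raise an error naming them.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mat = counts.to_numpy()
    if not np.issubdtype(mat.dtype, np.integer):
        as_int = mat.astype(np.int64)
        if not np.array_equal(as_int, mat):
            raise ValueError("rarefaction needs integer read counts")
        mat = as_int
    if (mat < 0).any():
        raise ValueError("negative read counts")
    totals = mat.sum(axis=0)
    shallow = [c for c, s in zip(counts.columns, totals) if s < depth]
    if shallow:
        raise ValueError(
            f"sample(s) shallower than depth {depth}: {shallow}"
        )
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        if totals[j] == depth:
            out[:, j] = mat[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(mat[:, j], depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
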