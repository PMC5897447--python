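"""Reading, filtering and summarizing label-free protein quantification tables.

The entry format follows the MaxQuant ``proteinGroups.txt`` conventions:
a tab-delimited table with one row per protein group, identification
metadata (unique-peptide counts, reverse-database and
modification-site-only flags) and one label-free quantification (LFQ)
intensity column per LC-MS/MS run, where 0 encodes "not quantified".

Processing mirrors standard Perseus-style practice for serum LFQ data:

1. drop reverse hits and proteins identified only by modification site;
2. drop proteins with fewer than 2 unique peptides or quantified in
   fewer than 25% of runs (strict "<", so boundary cases are retained);
3. collapse technical replicates to per-sample medians of the non-zero
   replicate intensities, then log2-transform; all-zero cells become
   missing;
4. drop proteins quantified in fewer than 50% of samples.

Missing values are never imputed at any stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ProteinQuantTable",
    "ExpressionMatrix",
    "read_protein_groups",
    "read_sample_annotation",
    "filter_identifications",
    "collapse_replicates",
    "filter_sample_coverage",
    "per_child_zscore",
    "average_zscores_by_age",
    "paired_fold_changes",
    "normalize_srm",
]

log = logging.getLogger(__name__)

#: nominal follow-up sampling ages (months); cord samples are kept apart
DEFAULT_AGE_BINS = (3.0, 6.0, 12.0, 18.0, 24.0, 36.0)

#: half-width of the window for assigning a sample to its nearest age bin
AGE_BIN_TOLERANCE = 1.5


class FormatError(ValueError):
    """An input table is missing required columns or malformed."""


@dataclass
class ProteinQuantTable:
    """Raw per-run protein intensities with identification metadata.

    ``meta`` is indexed by ``protein_id`` with columns ``gene_name``,
    ``n_unique_peptides``, ``is_reverse`` and ``is_mod_site_only``;
    ``intensities`` shares the index and has one column per run, with 0
    meaning "not quantified in that run".
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensity tables must share an index")
        if self.meta.index.has_duplicates:
            dups = self.meta.index[self.meta.index.duplicated()].tolist()
            raise FormatError(f"duplicate protein ids: {dups[:5]}")
        if self.intensities.columns.has_duplicates:
            raise FormatError("run identifiers must be unique")
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise FormatError("intensities must be finite")
        if (vals < 0).any():
            raise FormatError("intensities must be non-negative")
        if (self.meta["n_unique_peptides"] < 0).any():
            raise FormatError("unique-peptide counts must be non-negative")

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    @property
    def runs(self) -> list:
        return list(self.intensities.columns)


@dataclass
class ExpressionMatrix:
    """Proteins x samples log2 intensities with explicit missingness.

    ``values`` is indexed by protein id with one column per biological
    sample; NaN marks "not quantified". ``annotation``, when present, is
    indexed by sample id and carries at least ``subject_id`` and
    ``age_months`` (plus gender/location/season/batch for modelling).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.annotation is not None:
            missing = [s for s in self.values.columns
                       if s not in self.annotation.index]
            if missing:
                raise ValueError(
                    f"samples missing from annotation: {missing[:5]}")

    @property
    def n_proteins(self) -> int:
        return len(self.values)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA",
                           float_format="%.10g", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path, annotation: pd.DataFrame | None = None
                 ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id",
                         na_values=["NA"])
        return cls(values=df, annotation=annotation)


# ---------------------------------------------------------------------------
# parsing

_DEFAULT_COLUMNS = {
    "protein_id": "Protein IDs",
    "gene_name": "Gene names",
    "n_unique_peptides": "Unique peptides",
    "is_reverse": "Reverse",
    "is_mod_site_only": "Only identified by site",
}


def _flag_column(series: pd.Series) -> pd.Series:
    """MaxQuant flags columns with '+' (empty otherwise)."""
    if series.dtype == bool:
        return series
    return series.fillna("").astype(str).str.strip().eq("+")


def read_protein_groups(path, run_ids: Sequence[str] | None = None,
                        intensity_prefix: str = "LFQ intensity ",
                        columns: Mapping[str, str] | None = None
                        ) -> ProteinQuantTable:
    """Parse a tab-delimited protein-groups table.

    Intensity columns are either named explicitly via ``run_ids`` or
    discovered by ``intensity_prefix`` (the prefix is stripped from the
    run identifier). Empty intensity cells parse as 0; malformed numeric
    cells are reported with a warning and treated as not quantified.

    Raises
    ------
    FormatError
        If a required column is absent (named in the message) or a
        protein id occurs twice.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("protein_id", "n_unique_peptides"):
        if colmap[key] not in raw.columns:
            raise FormatError(
                f"required column {colmap[key]!r} missing from {path}")

    if run_ids is not None:
        cols = []
        for r in run_ids:
            name = r if r in raw.columns else intensity_prefix + str(r)
            if name not in raw.columns:
                raise FormatError(f"intensity column for run {r!r} missing")
            cols.append(name)
        run_names = list(run_ids)
    else:
        cols = [c for c in raw.columns if c.startswith(intensity_prefix)]
        if not cols:
            raise FormatError(
                f"no intensity columns with prefix {intensity_prefix!r}")
        run_names = [c[len(intensity_prefix):] for c in cols]

    inten = raw[cols].apply(pd.to_numeric, errors="coerce")
    bad = int(inten.isna().sum().sum() - raw[cols].isna().sum().sum())
    if bad:
        warnings.warn(f"{bad} malformed numeric intensity cells set to 0")
    inten = inten.fillna(0.0)
    inten.columns = run_names

    meta = pd.DataFrame({
        "gene_name": raw.get(colmap["gene_name"],
                             pd.Series("", index=raw.index)).fillna(""),
        "n_unique_peptides": pd.to_numeric(
            raw[colmap["n_unique_peptides"]], errors="raise").astype(int),
        "is_reverse": _flag_column(raw.get(
            colmap["is_reverse"], pd.Series(False, index=raw.index))),
        "is_mod_site_only": _flag_column(raw.get(
            colmap["is_mod_site_only"], pd.Series(False, index=raw.index))),
    })
    ids = raw[colmap["protein_id"]]
    meta.index = pd.Index(ids, name="protein_id")
    inten.index = meta.index
    return ProteinQuantTable(meta=meta, intensities=inten)


def read_sample_annotation(path) -> pd.DataFrame:
    """Read a sample annotation table (TSV or CSV by extension).

    Requires ``sample_id`` and ``subject_id`` columns; returns a frame
    indexed by sample id.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    ann = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "subject_id"):
        if col not in ann.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    return ann.set_index("sample_id")


# ---------------------------------------------------------------------------
# filtering and collapsing

def filter_identifications(table: ProteinQuantTable,
                           min_unique_peptides: int = 2,
                           min_run_fraction: float = 0.25
                           ) -> ProteinQuantTable:
    """Identification-level filtering of a raw protein table.

    Retains exactly those proteins that are not reverse hits, not
    identified only by modification site, have at least
    ``min_unique_peptides`` unique peptides, and carry a non-zero
    intensity in at least ``min_run_fraction`` of runs. The removal
    rules are strict inequalities, so a protein quantified in exactly
    25% of runs is kept. Row order is preserved; the operation is
    idempotent.
    """
    if not (0 < min_run_fraction <= 1):
        raise ValueError("min_run_fraction must lie in (0, 1]")
    if min_unique_peptides < 1:
        raise ValueError("min_unique_peptides must be >= 1")
    frac = (table.intensities > 0).mean(axis=1)
    keep = (
        ~table.meta["is_reverse"]
        & ~table.meta["is_mod_site_only"]
        & (table.meta["n_unique_peptides"] >= min_unique_peptides)
        & (frac >= min_run_fraction)
    )
    if not keep.any():
        warnings.warn("identification filtering removed every protein")
    return ProteinQuantTable(meta=table.meta.loc[keep].copy(),
                             intensities=table.intensities.loc[keep].copy())


def collapse_replicates(table: ProteinQuantTable,
                        replicate_map: Mapping,
                        annotation: pd.DataFrame | None = None
                        ) -> ExpressionMatrix:
    """Collapse technical-replicate runs to per-sample log2 intensities.

    ``replicate_map`` assigns each run to its biological sample. Per
    (protein, sample) the median of the non-zero replicate intensities
    is taken; a cell whose replicates are all zero becomes missing.
    The collapsed value is then log2-transformed. Invariant to the
    order of replicates within a sample.
    """
    unassigned = [r for r in table.runs if r not in replicate_map]
    if unassigned:
        raise ValueError(f"runs without sample assignment: {unassigned[:5]}")
    samples: dict = {}
    for run in table.runs:
        samples.setdefault(replicate_map[run], []).append(run)
    out = {}
    for sample, runs in samples.items():
        block = table.intensities[runs].to_numpy(float)
        with warnings.catch_warnings():
            # all-zero replicate groups legitimately produce NaN medians
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.where(block > 0, block, np.nan), axis=1)
        out[sample] = np.log2(med)  # NaN (all-zero) stays NaN
    values = pd.DataFrame(out, index=table.intensities.index)
    return ExpressionMatrix(values=values, annotation=annotation)


def filter_sample_coverage(matrix: ExpressionMatrix,
                           min_sample_fraction: float = 0.5
                           ) -> ExpressionMatrix:
    """Drop proteins quantified in fewer than ``min_sample_fraction`` of samples.

    Strict "<" removal: a protein present in exactly half the samples is
    retained at the default threshold. ``min_sample_fraction=0`` is the
    identity. Idempotent.
    """
    if not (0 <= min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must lie in [0, 1]")
    frac = matrix.values.notna().mean(axis=1)
    keep = frac >= min_sample_fraction
    return ExpressionMatrix(values=matrix.values.loc[keep].copy(),
                            annotation=matrix.annotation)


# ---------------------------------------------------------------------------
# descriptive summaries

def per_child_zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each (protein, child) trajectory to mean 0, sd 1.

    The mean and sample standard deviation (n-1 denominator) are taken
    over the child's non-missing values for that protein; trajectories
    with fewer than two values or zero spread yield missing Z-scores
    (logged), never zeros. Missing inputs stay missing.
    """
    if matrix.annotation is None:
        raise ValueError("Z-scores require a sample annotation")
    subj = matrix.annotation.loc[matrix.values.columns, "subject_id"]
    z = pd.DataFrame(np.nan, index=matrix.values.index,
                     columns=matrix.values.columns)
    n_degenerate = 0
    for _, cols in matrix.values.columns.to_series().groupby(subj.values):
        block = matrix.values[cols.index]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        degenerate = (sd == 0) | sd.isna()
        n_degenerate += int((degenerate & block.notna().any(axis=1)).sum())
        zb = block.sub(mu, axis=0).div(sd.where(~degenerate), axis=0)
        z[cols.index] = zb
    if n_degenerate:
        log.info("per_child_zscore: %d degenerate trajectories set missing",
                 n_degenerate)
    return ExpressionMatrix(values=z, annotation=matrix.annotation)


def assign_age_bins(annotation: pd.DataFrame,
                    age_bins: Sequence[float] = DEFAULT_AGE_BINS,
                    tolerance: float = AGE_BIN_TOLERANCE) -> pd.Series:
    """Nearest-bin age assignment within ``tolerance`` months.

    Cord samples (``is_cord`` truthy) map to the label ``"cord"``;
    samples farther than the tolerance from every nominal age are left
    unassigned (NaN).
    """
    bins = np.asarray(age_bins, float)
    out = pd.Series(np.nan, index=annotation.index, dtype=object)
    is_cord = annotation.get(
        "is_cord", pd.Series(False, index=annotation.index)).astype(bool)
    out[is_cord] = "cord"
    ages = annotation.loc[~is_cord, "age_months"].to_numpy(float)
    idx = np.abs(ages[:, None] - bins[None, :]).argmin(axis=1)
    dist = np.abs(ages - bins[idx])
    labels = np.where(dist <= tolerance, bins[idx], np.nan)
    out[~is_cord] = labels
    return out


def average_zscores_by_age(zmatrix: ExpressionMatrix,
                           age_bins: Sequence[float] = DEFAULT_AGE_BINS,
                           tolerance: float = AGE_BIN_TOLERANCE
                           ) -> pd.DataFrame:
    """Average per-child Z-scores within nominal age groups.

    Returns a proteins x age-bins frame; the average in each bin is
    taken over the children that carry a value there. Together with
    :func:`per_child_zscore` this yields the cross-child mean temporal
    shape of each protein.
    """
    if zmatrix.annotation is None:
        raise ValueError("age-group averages require a sample annotation")
    bins = assign_age_bins(zmatrix.annotation.loc[zmatrix.values.columns],
                           age_bins, tolerance)
    cols = {}
    for b in ["cord"] + list(age_bins):
        members = bins.index[bins == b]
        if len(members):
            cols[b] = zmatrix.values[members].mean(axis=1)
    return pd.DataFrame(cols)


def paired_fold_changes(matrix: ExpressionMatrix,
                        subject_pairs: Sequence[tuple],
                        age_bins: Sequence[float] = DEFAULT_AGE_BINS,
                        tolerance: float = AGE_BIN_TOLERANCE) -> pd.DataFrame:
    """Median linear-scale fold change between paired subjects.

    For each pair of subjects (typically processed in the same batch)
    their samples are matched by nearest nominal age bin; at each shared
    bin the direction-agnostic fold change ``2 ** |log2 a - log2 b|`` is
    computed per protein, and the median across shared bins summarizes
    the pair. The output has one column per pair plus a
    ``median_fold_change`` column (median across pairs). Pairs without
    shared timepoints are skipped with a warning.
    """
    if matrix.annotation is None:
        raise ValueError("fold changes require a sample annotation")
    ann = matrix.annotation.loc[matrix.values.columns]
    bins = assign_age_bins(ann, age_bins, tolerance)
    out = {}
    for a, b in subject_pairs:
        pair_fc = []
        for bin_label in list(age_bins):
            sa = bins.index[(bins == bin_label)
                            & (ann["subject_id"] == a)]
            sb = bins.index[(bins == bin_label)
                            & (ann["subject_id"] == b)]
            if len(sa) == 0 or len(sb) == 0:
                continue
            va = matrix.values[sa].mean(axis=1)
            vb = matrix.values[sb].mean(axis=1)
            pair_fc.append(2.0 ** (va - vb).abs())
        if not pair_fc:
            warnings.warn(f"pair {(a, b)} has no shared timepoints; skipped")
            continue
        out[f"{a}|{b}"] = pd.concat(pair_fc, axis=1).median(axis=1)
    result = pd.DataFrame(out, index=matrix.values.index)
    result["median_fold_change"] = result.median(axis=1)
    return result


def normalize_srm(srm: pd.DataFrame,
                  reference_protein: str = "A1BG") -> ExpressionMatrix:
    """Normalize targeted SRM intensities against a reference protein.

    ``srm`` is a long table with columns ``protein_id``, ``peptide``,
    ``transition``, ``sample_id`` and ``intensity``. Per (protein,
    sample) the protein intensity is the sum of all its transition
    intensities; each is divided by the reference protein's intensity
    in the same sample and log2-transformed. The reference (by default
    alpha-1B-glycoprotein, a stable serum protein) must be quantified
    with non-zero intensity in every sample.
    """
    required = {"protein_id", "peptide", "transition", "sample_id",
                "intensity"}
    missing = required - set(srm.columns)
    if missing:
        raise FormatError(f"SRM table missing columns: {sorted(missing)}")
    if (srm["intensity"] < 0).any():
        raise ValueError("SRM intensities must be non-negative")
    totals = srm.pivot_table(index="protein_id", columns="sample_id",
                             values="intensity", aggfunc="sum")
    if reference_protein not in totals.index:
        raise ValueError(f"reference protein {reference_protein!r} absent")
    ref = totals.loc[reference_protein]
    bad = ref.index[(ref.isna()) | (ref <= 0)].tolist()
    if bad:
        raise ValueError(
            f"reference {reference_protein!r} missing or zero in "
            f"sample(s) {bad[:5]}")
    normalized = np.log2(totals.div(ref, axis=1).where(totals > 0))
    return ExpressionMatrix(values=normalized)
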