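"""Abundance tables, sample metadata, and the standard pre-processing transforms.

The analyses downstream operate on genus-level 16S count tables. Before any
network inference the counts are rarefied to a common depth (equal sequencing
effort), low-prevalence genera are dropped, and per-feature abundances are
inverse-rank transformed and residualized on host covariates. Hypertension
grades are assigned from systolic/diastolic blood pressure following clinical
guideline bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

#: Host covariates adjusted for throughout: the classical hypertension
#: confounders recorded per participant.
COVARIATE_COLUMNS = [
    "age",
    "sex",
    "bmi",
    "smoking",
    "antibiotics",
    "diabetes",
    "hypercholesterolemia",
    "obesity",
]

METADATA_COLUMNS = ["sample_id", "region", "sbp", "dbp"] + COVARIATE_COLUMNS


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountTable:
    """Samples x genera non-negative integer counts with phylum labels.

    Parameters
    ----------
    counts
        DataFrame indexed by sample ID with one column per genus.
    taxonomy
        Series mapping genus ID -> phylum label. May cover a superset of
        the table's genera.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in count table")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate genus IDs in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts in count table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def genus_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genera(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total read counts."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[sample_ids], self.taxonomy)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, taxonomy: pd.Series | None = None) -> "CountTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, taxonomy if taxonomy is not None else pd.Series(dtype=object))


def read_taxonomy(path) -> pd.Series:
    """Read a two-column genus/phylum TSV into a Series keyed by genus."""
    tax = pd.read_csv(path, sep="\t")
    return tax.set_index(tax.columns[0])[tax.columns[1]]


def write_taxonomy(taxonomy: pd.Series, path) -> None:
    df = taxonomy.rename("phylum").rename_axis("genus").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    meta = meta.set_index("sample_id")
    meta["grade"] = assign_grade(meta["sbp"].to_numpy(), meta["dbp"].to_numpy())
    meta["hypertension"] = (meta["grade"] >= 1).astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index()[METADATA_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rarefaction and filtering
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int = 10_000, seed: int = 0) -> CountTable:
    """Subsample every sample's reads without replacement to a fixed depth.

    Samples with fewer total reads than ``depth`` are dropped (and reported
    via a warning); retained rows sum exactly to ``depth``. Subsampling is a
    multivariate hypergeometric draw per sample, i.e. a uniform without-
    replacement subsample of the reads.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped) > 0:
        warnings.warn(
            f"rarefy: dropping {len(dropped)} samples below depth {depth}",
            stacklevel=2,
        )
    if len(keep) == 0:
        raise ValidationError(f"all samples below rarefaction depth {depth}")
    rows = []
    for sid in keep:
        row = table.counts.loc[sid].to_numpy(dtype=np.int64)
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    rare = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=keep, columns=table.genus_ids
    )
    return CountTable(rare, table.taxonomy)


def prevalence_filter(table: CountTable, min_prevalence: float = 0.10) -> CountTable:
    """Keep genera with nonzero counts in at least ceil(f * n_samples) samples."""
    if not 0 < min_prevalence <= 1:
        raise ValidationError("min_prevalence must be in (0, 1]")
    n = table.n_samples
    threshold = int(np.ceil(min_prevalence * n))
    present = (table.counts > 0).sum(axis=0)
    keep = table.genus_ids[present >= threshold]
    return CountTable(table.counts[keep], table.taxonomy)


# ---------------------------------------------------------------------------
# Hypertension grading
# ---------------------------------------------------------------------------

_SBP_EDGES = np.array([140.0, 160.0, 180.0])
_DBP_EDGES = np.array([90.0, 100.0, 110.0])


def assign_grade(sbp, dbp):
    """Hypertension grade 0-3 from blood pressure.

    Bands (half-open; the guideline's integer notation "140-159" etc. is
    shorthand for [140, 160)): grade 1 at SBP in [140,160) or DBP in
    [90,100); grade 2 at [160,180) or [100,110); grade 3 at >=180 or >=110.
    When the two measures imply different grades the maximum wins — the
    clinical convention.
    """
    sbp_arr = np.asarray(sbp, dtype=float)
    dbp_arr = np.asarray(dbp, dtype=float)
    if (sbp_arr <= 0).any() or (dbp_arr <= 0).any():
        raise ValidationError("blood pressure must be positive")
    g_sbp = np.searchsorted(_SBP_EDGES, sbp_arr, side="right")
    g_dbp = np.searchsorted(_DBP_EDGES, dbp_arr, side="right")
    grade = np.maximum(g_sbp, g_dbp)
    if np.isscalar(sbp) or np.ndim(sbp) == 0:
        return int(grade)
    return grade.astype(int)


# ---------------------------------------------------------------------------
# Feature transforms
# ---------------------------------------------------------------------------

def inverse_rank_transform(values, offset: float = 0.5):
    """Rank-based inverse normal transform, Phi^-1((rank - offset) / n).

    Ties receive average ranks; a constant vector maps to all zeros with a
    warning. The output depends on the ranks only, so it is invariant to any
    strictly monotone transform of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("inverse rank transform needs at least 2 values")
    if np.all(x == x[0]):
        warnings.warn("constant vector in inverse rank transform", stacklevel=2)
        return np.zeros_like(x)
    ranks = rankdata(x, method="average")
    return ndtri((ranks - offset) / x.size)


def residualize(values, covariates):
    """OLS residuals of ``values`` on an intercept plus the covariate columns.

    Collinear covariate columns are dropped with a warning so the design is
    full rank. Residuals are orthogonal to every retained covariate.
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValidationError("values and covariates have different lengths")
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # Greedy drop of columns that do not increase rank (intercept kept).
        keep = [0]
        for j in range(1, design.shape[1]):
            cand = design[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        warnings.warn(
            f"residualize: dropped {design.shape[1] - len(keep)} collinear columns",
            stacklevel=2,
        )
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def transform_features(
    features: pd.DataFrame, metadata: pd.DataFrame, covariates=COVARIATE_COLUMNS
) -> pd.DataFrame:
    """Inverse-rank transform each feature column, then residualize on covariates.

    This is the global normalization applied to genus and pathway abundances
    before differential testing and interaction modelling.
    """
    meta = metadata.loc[features.index]
    X = meta[list(covariates)].to_numpy(dtype=float)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in features.columns:
            z = inverse_rank_transform(features[col].to_numpy())
            out[col] = residualize(z, X)
    return pd.DataFrame(out, index=features.index)
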