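"""Trait standardisation, covariate correction, and expression filtering.

The association scans operate on strain-level residualised values.  Traits
are z-transformed per treatment arm, corrected for sex and experimenter by
ordinary least squares, and collapsed to unweighted strain means.
Expression counts are filtered for minimum depth, normalised to
log2(CPM+1), corrected for sex and library plate, and collapsed the same
way.  Both arms of the study are processed independently.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    """Raised for degenerate inputs (constant traits, aliased designs...)."""


def z_transform(x) -> pd.Series:
    """Standardise to mean 0, sample SD 1 (denominator n-1), keeping NaN.

    Raises :class:`PreprocessError` when fewer than two values are observed
    or the observed values are constant.
    """
    s = pd.Series(x, dtype=float)
    obs = s.dropna()
    if len(obs) < 2:
        raise PreprocessError(
            f"z_transform: {getattr(s, 'name', 'trait')} has {len(obs)} observed "
            "values; need at least 2"
        )
    sd = obs.std(ddof=1)
    if sd == 0:
        raise PreprocessError(
            f"z_transform: {getattr(s, 'name', 'trait')} is constant (zero variance)"
        )
    return (s - obs.mean()) / sd


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + dummy-coded categorical factors (first level dropped)."""
    parts = [pd.Series(1.0, index=covariates.index, name="Intercept")]
    for col in covariates.columns:
        dummies = pd.get_dummies(
            covariates[col].astype("category"), prefix=col, drop_first=True, dtype=float
        )
        parts.append(dummies)
    return pd.concat(parts, axis=1)


def residualize(y, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of ``y`` on dummy-coded categorical covariates.

    Missing values in ``y`` are ignored during the fit and preserved in the
    output.  A rank-deficient design raises :class:`PreprocessError` naming
    the aliased columns.
    """
    y = pd.Series(y, dtype=float)
    if not y.index.equals(covariates.index):
        covariates = covariates.loc[y.index]
    X = _design_matrix(covariates)
    obs = y.notna()
    Xo = X.loc[obs].to_numpy()
    rank = np.linalg.matrix_rank(Xo)
    if rank < Xo.shape[1]:
        # identify aliased columns by testing rank drop when removed
        aliased = []
        for j, name in enumerate(X.columns):
            keep = [k for k in range(Xo.shape[1]) if k != j]
            if np.linalg.matrix_rank(Xo[:, keep]) == rank:
                aliased.append(name)
        raise PreprocessError(f"residualize: rank-deficient design; aliased: {aliased}")
    beta, *_ = np.linalg.lstsq(Xo, y[obs].to_numpy(), rcond=None)
    out = pd.Series(np.nan, index=y.index, name=y.name)
    out[obs] = y[obs].to_numpy() - Xo @ beta
    return out


def residualize_frame(values: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualise every column of a complete (NaN-free) matrix at once."""
    if values.isna().any().any():
        return pd.DataFrame(
            {c: residualize(values[c], covariates) for c in values.columns},
            index=values.index,
        )
    X = _design_matrix(covariates.loc[values.index]).to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # delegate to the per-column path for a precise error message
        residualize(values.iloc[:, 0], covariates)
    Y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(Y - X @ beta, index=values.index, columns=values.columns)


def collapse_to_strain(
    values: pd.DataFrame, samples: pd.DataFrame, arm: str | None = None
) -> pd.DataFrame:
    """Unweighted per-strain means of animal/sample-level values.

    ``samples`` must be indexed by the same unit ids as ``values`` and carry
    ``strain_id`` and ``treatment`` columns.  When ``arm`` is given only
    that treatment's units contribute; strains with no units in the arm are
    dropped.  Means are over non-missing values only; an all-missing cell
    stays missing.
    """
    meta = samples.loc[values.index]
    if arm is not None:
        keep = meta["treatment"] == arm
        if not keep.any():
            raise PreprocessError(f"collapse_to_strain: no samples in arm {arm!r}")
        values = values.loc[keep]
        meta = meta.loc[keep]
    out = values.groupby(meta["strain_id"]).mean()
    out.index.name = "strain_id"
    return out.sort_index()


def filter_genes(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.5
) -> list[str]:
    """Genes with >= ``min_count`` reads in >= ``min_fraction`` of samples.

    ``counts`` is samples x genes.  Both boundaries are inclusive: a gene
    with exactly ``min_count`` reads in exactly half the samples is kept.
    """
    if counts.empty:
        raise PreprocessError("filter_genes: empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise PreprocessError("filter_genes: negative counts")
    ok = (counts >= min_count).sum(axis=0) / counts.shape[0] >= min_fraction
    return list(counts.columns[ok])


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) per sample; library size = row sum over retained genes."""
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    if (lib == 0).any():
        bad = list(counts.index[lib == 0])
        raise PreprocessError(f"normalize_counts: zero library size for {bad}")
    cpm = counts.to_numpy(dtype=float) / lib[:, None] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Composite paths used by the pipeline


def prepare_trait_matrix(
    traits: pd.DataFrame,
    samples: pd.DataFrame,
    arm: str,
    covariates: Sequence[str] = ("sex", "experimenter"),
    z: bool = True,
) -> pd.DataFrame:
    """Per-arm GWAS-ready strain x trait matrix.

    Order of operations: subset the arm, z-transform each trait across its
    animals, residualise on the covariates, then collapse to unweighted
    strain means.  Traits that are constant or nearly unobserved in the arm
    are dropped with a warning rather than failing the whole run.
    """
    meta = samples.loc[samples["treatment"] == arm]
    if meta.empty:
        raise PreprocessError(f"no samples in arm {arm!r}")
    sub = traits.loc[traits.index.intersection(meta.index)]
    meta = meta.loc[sub.index]
    cols = {}
    for trait in sub.columns:
        try:
            v = z_transform(sub[trait]) if z else sub[trait].astype(float)
            cols[trait] = residualize(v, meta[list(covariates)])
        except PreprocessError as e:
            warnings.warn(f"dropping trait {trait!r} in arm {arm}: {e}")
    if not cols:
        raise PreprocessError(f"no usable traits in arm {arm!r}")
    resid = pd.DataFrame(cols, index=sub.index)
    return collapse_to_strain(resid, samples, arm)


def prepare_expression_matrix(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    arm: str,
    covariates: Sequence[str] = ("sex", "plate"),
    min_count: int = 10,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-arm eQTL-ready strain x gene matrix.

    Filtering uses all samples (the expression filter is a property of the
    dataset, not the arm); normalisation, covariate correction and strain
    collapsing are then done within the arm.
    """
    kept = filter_genes(counts, min_count=min_count, min_fraction=min_fraction)
    norm = normalize_counts(counts[kept])
    meta = samples.loc[samples["treatment"] == arm]
    if meta.empty:
        raise PreprocessError(f"no samples in arm {arm!r}")
    sub = norm.loc[norm.index.intersection(meta.index)]
    resid = residualize_frame(sub, samples.loc[sub.index, list(covariates)])
    return collapse_to_strain(resid, samples, arm)
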