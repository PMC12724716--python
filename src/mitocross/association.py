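"""Linear-model association scans against mitochondrial markers, with
permutation-based family-wise error control.

The same engine serves trait-GWAS and trans-eQTL mapping: each strain-level
feature (a residualised trait or gene expression value) is regressed on the
dosage of each mitochondrial marker by ordinary least squares, giving a
two-sided t test for biallelic markers and a one-way ANOVA F test when a
marker segregates more than two founder alleles.

Because only a handful of distinct strain-distribution patterns exist among
the markers, per-test p values cannot simply be Bonferroni-corrected; the
family-wise error rate (FWER) is instead controlled empirically.  Under the
null, after z-transformation and residualisation, phenotypes are exchangeable
standard normals, so the null distribution of the minimum p value across
markers depends only on the genotype matrix.  ``permutation_threshold``
simulates that distribution once per genotype matrix and FWER level, and the
resulting p-value threshold is shared by every feature scanned against the
same genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

MIN_CLASS_SIZE = 3  # strains per dosage class required to test a marker


class AssociationError(ValueError):
    pass


@dataclass
class AssociationRecord:
    """One feature x marker linear-model test.

    ``reason`` is None for a completed test, else "monomorphic" or
    "underpowered" with the statistics left missing.  For markers with more
    than two alleles ``p`` comes from the joint F test and ``beta``, ``se``
    and ``t`` are undefined.
    """

    feature_id: str
    marker_id: str
    arm: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    df: int
    reason: str | None = None


def _class_counts(x: np.ndarray) -> np.ndarray:
    return np.unique(x, return_counts=True)[1]


def _skip_reason(x: np.ndarray, min_class_size: int) -> str | None:
    counts = _class_counts(x)
    if len(counts) < 2:
        return "monomorphic"
    if counts.min() < min_class_size:
        return "underpowered"
    return None


def _ols_biallelic(Y: np.ndarray, x: np.ndarray):
    """Vectorised simple OLS of each column of Y on x.

    Returns (beta, se, t, p, df) as arrays over features.
    """
    n = x.shape[0]
    df = n - 2
    xc = x - x.mean()
    sxx = float(xc @ xc)
    Yc = Y - Y.mean(axis=0)
    sxy = xc @ Yc
    syy = np.einsum("ij,ij->j", Yc, Yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, t, p, df


def _anova_multiallelic(Y: np.ndarray, x: np.ndarray):
    """Vectorised one-way ANOVA of each column of Y on dosage classes."""
    n = x.shape[0]
    classes, inv = np.unique(x, return_inverse=True)
    k = len(classes)
    df1, df2 = k - 1, n - k
    Yc = Y - Y.mean(axis=0)
    sst = np.einsum("ij,ij->j", Yc, Yc)
    ssb = np.zeros(Y.shape[1])
    for c in range(k):
        sel = inv == c
        m = Yc[sel].mean(axis=0)
        ssb += sel.sum() * m**2
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(F, df1, df2)
    p = np.clip(np.where(np.isfinite(F), p, np.finfo(float).tiny), np.finfo(float).tiny, 1.0)
    return p, df2


def fit_marker_association(
    y: pd.Series,
    dosage: pd.Series,
    feature_id: str = "feature",
    marker_id: str = "marker",
    arm: str = "",
    min_class_size: int = MIN_CLASS_SIZE,
) -> AssociationRecord:
    """OLS test of one strain-level feature against one marker's dosage.

    ``y`` and ``dosage`` are aligned on their (strain) index; missing
    feature values are dropped.  Markers that are monomorphic, or have a
    dosage class with fewer than ``min_class_size`` strains after dropping
    missing values, yield a skipped record with the reason recorded.
    """
    shared = y.index.intersection(dosage.index)
    yv = y.loc[shared].astype(float)
    obs = yv.notna()
    yv = yv[obs]
    xv = dosage.loc[shared][obs].to_numpy(dtype=float)
    n = len(yv)
    nan = float("nan")
    reason = _skip_reason(xv, min_class_size) if n else "underpowered"
    if reason:
        return AssociationRecord(feature_id, marker_id, arm, n, nan, nan, nan, nan, 0, reason)
    Y = yv.to_numpy(dtype=float)[:, None]
    if len(np.unique(xv)) == 2:
        beta, se, t, p, df = _ols_biallelic(Y, xv)
        return AssociationRecord(
            feature_id, marker_id, arm, n, float(beta[0]), float(se[0]),
            float(t[0]), float(p[0]), df,
        )
    p, df = _anova_multiallelic(Y, xv)
    return AssociationRecord(feature_id, marker_id, arm, n, nan, nan, nan, float(p[0]), df)


def scan(
    features: pd.DataFrame,
    genotypes: GenotypeMatrix,
    arm: str = "",
    min_class_size: int = MIN_CLASS_SIZE,
    min_shared_strains: int = 10,
) -> pd.DataFrame:
    """Scan every feature against every marker.

    ``features`` is a strain x feature matrix (traits or genes).  Returns a
    tidy table ordered by (feature, marker position) with columns
    feature_id, marker_id, position_bp, arm, n, beta, se, t, p, reason.
    The genotype fingerprint travels in ``DataFrame.attrs`` so downstream
    hit calling can verify the permutation threshold matches.
    """
    shared = features.index.intersection(genotypes.dosage.index).sort_values()
    if len(shared) < min_shared_strains:
        raise AssociationError(
            f"only {len(shared)} strains shared between features and genotypes "
            f"(need >= {min_shared_strains})"
        )
    F = features.loc[shared]
    D = genotypes.dosage.loc[shared]
    marker_order = list(genotypes.positions.sort_values().index)
    feat_ids = list(F.columns)
    Yfull = F.to_numpy(dtype=float)
    has_nan = np.isnan(Yfull).any(axis=0)

    rows: dict[str, list] = {c: [] for c in
                             ("feature_id", "marker_id", "position_bp", "arm",
                              "n", "beta", "se", "t", "p", "reason")}

    def emit(fid, mid, n, beta, se, t, p, reason):
        rows["feature_id"].append(fid)
        rows["marker_id"].append(mid)
        rows["position_bp"].append(int(genotypes.positions[mid]))
        rows["arm"].append(arm)
        rows["n"].append(n)
        rows["beta"].append(beta)
        rows["se"].append(se)
        rows["t"].append(t)
        rows["p"].append(p)
        rows["reason"].append(reason)

    nan = float("nan")
    clean_cols = ~has_nan
    Yclean = Yfull[:, clean_cols]
    clean_ids = [f for f, ok in zip(feat_ids, clean_cols) if ok]
    cache: dict[bytes, tuple] = {}
    for mid in marker_order:
        x = D[mid].to_numpy(dtype=float)
        reason = _skip_reason(x, min_class_size)
        if reason:
            for fid in feat_ids:
                emit(fid, mid, len(shared), nan, nan, nan, nan, reason)
            continue
        biallelic = len(np.unique(x)) == 2
        if clean_ids:
            key = x.tobytes()
            if key in cache:
                res = cache[key]
            elif biallelic:
                res = _ols_biallelic(Yclean, x)
                cache[key] = res
            else:
                pvals, df = _anova_multiallelic(Yclean, x)
                res = (None, None, None, pvals, df)
                cache[key] = res
            beta, se, t, pvals, _df = res
            for j, fid in enumerate(clean_ids):
                if beta is None:
                    emit(fid, mid, len(shared), nan, nan, nan, float(pvals[j]), None)
                else:
                    emit(fid, mid, len(shared), float(beta[j]), float(se[j]),
                         float(t[j]), float(pvals[j]), None)
        # features with missing values: per-feature fallback
        for fid in (f for f, ok in zip(feat_ids, clean_cols) if not ok):
            rec = fit_marker_association(
                F[fid], D[mid], fid, mid, arm, min_class_size=min_class_size
            )
            emit(fid, mid, rec.n, rec.beta, rec.se, rec.t, rec.p, rec.reason)

    out = pd.DataFrame(rows)
    out = out.sort_values(["feature_id", "position_bp"], kind="stable").reset_index(drop=True)
    out.attrs["genotype_fingerprint"] = genotypes.fingerprint()
    out.attrs["arm"] = arm
    return out


@dataclass
class PermutationThreshold:
    """Empirical FWER-controlling p-value threshold for one genotype matrix."""

    fwer_level: float
    p_threshold: float
    n_perm: int
    seed: int
    genotype_fingerprint: str

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise AssociationError(f"degenerate p threshold {self.p_threshold}")


def null_min_p_distribution(
    genotypes: GenotypeMatrix,
    n_perm: int,
    seed: int,
    min_class_size: int = MIN_CLASS_SIZE,
) -> np.ndarray:
    """Minimum p value across markers for ``n_perm`` simulated null traits.

    Null phenotypes are fresh standard-normal strain vectors (a child
    stream of ``seed``), matching what z-transformed, residualised traits
    look like under the null.  Markers with identical dosage columns give
    identical p values, so only distinct usable columns are evaluated.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    D = genotypes.dosage
    n = D.shape[0]
    cols = []
    seen = set()
    for mid in D.columns:
        x = D[mid].to_numpy(dtype=float)
        if _skip_reason(x, min_class_size):
            continue
        key = x.tobytes()
        if key not in seen:
            seen.add(key)
            cols.append(x)
    if not cols:
        raise AssociationError("no testable markers (all monomorphic/underpowered)")
    Y = rng.standard_normal((n, n_perm))
    pmin = np.ones(n_perm)
    for x in cols:
        if len(np.unique(x)) == 2:
            *_, p, _df = _ols_biallelic(Y, x)
        else:
            p, _df = _anova_multiallelic(Y, x)
        pmin = np.minimum(pmin, p)
    return pmin


def permutation_threshold(
    genotypes: GenotypeMatrix,
    fwer_level: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_class_size: int = MIN_CLASS_SIZE,
) -> PermutationThreshold:
    """FWER threshold = empirical ``fwer_level`` quantile (type-7) of the
    null min-p distribution.  One threshold serves every feature scanned
    against the same genotype matrix."""
    if not (0 < fwer_level < 1):
        raise AssociationError(f"fwer_level must be in (0,1), got {fwer_level}")
    if n_perm < 100:
        raise AssociationError(f"n_perm={n_perm} too small; need >= 100")
    if n_perm * fwer_level < 5:
        raise AssociationError(
            f"n_perm={n_perm} cannot resolve the {fwer_level} quantile; "
            f"increase n_perm to at least {int(np.ceil(5 / fwer_level))}"
        )
    pmin = null_min_p_distribution(genotypes, n_perm, seed, min_class_size)
    thr = float(np.quantile(pmin, fwer_level, method="linear"))
    return PermutationThreshold(
        fwer_level=fwer_level,
        p_threshold=thr,
        n_perm=n_perm,
        seed=seed,
        genotype_fingerprint=genotypes.fingerprint(),
    )


def permute_observed_threshold(
    y: pd.Series,
    genotypes: GenotypeMatrix,
    fwer_level: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_class_size: int = MIN_CLASS_SIZE,
) -> PermutationThreshold:
    """Per-feature alternative: permute the observed phenotype labels.

    Provided for comparison with the shared normal-draw threshold; under
    the null (exchangeable residuals) the two agree.
    """
    if n_perm < 100 or n_perm * fwer_level < 5:
        raise AssociationError("n_perm too small for the requested quantile")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    shared = y.index.intersection(genotypes.dosage.index).sort_values()
    yv = y.loc[shared].dropna()
    D = genotypes.dosage.loc[yv.index]
    base = yv.to_numpy(dtype=float)
    Y = np.empty((len(base), n_perm))
    for j in range(n_perm):
        Y[:, j] = rng.permutation(base)
    pmin = np.ones(n_perm)
    seen = set()
    for mid in D.columns:
        x = D[mid].to_numpy(dtype=float)
        if _skip_reason(x, min_class_size) or x.tobytes() in seen:
            continue
        seen.add(x.tobytes())
        if len(np.unique(x)) == 2:
            *_, p, _df = _ols_biallelic(Y, x)
        else:
            p, _df = _anova_multiallelic(Y, x)
        pmin = np.minimum(pmin, p)
    thr = float(np.quantile(pmin, fwer_level, method="linear"))
    return PermutationThreshold(fwer_level, thr, n_perm, seed, genotypes.fingerprint())


def significant_hits(
    records: pd.DataFrame, threshold: PermutationThreshold
) -> pd.DataFrame:
    """Per-feature hit summary at the permutation threshold.

    A feature is a hit iff its minimum p across markers is strictly below
    the threshold.  Each hit row carries the best marker (lowest p, ties
    broken by lowest genome position), its statistics, and the full list of
    markers passing the threshold.
    """
    fp = records.attrs.get("genotype_fingerprint")
    if fp is not None and fp != threshold.genotype_fingerprint:
        raise AssociationError(
            "genotype fingerprint mismatch: threshold was computed on a "
            "different genotype matrix than this scan"
        )
    cols = ["feature_id", "marker_id", "position_bp", "arm", "n", "beta", "se", "t", "p"]
    if records.empty:
        return pd.DataFrame(columns=cols + ["n_markers_passing", "markers_passing"])
    ok = records.dropna(subset=["p"]).sort_values(
        ["feature_id", "p", "position_bp"], kind="stable"
    )
    best = ok.groupby("feature_id", sort=True).first().reset_index()
    hits = best[best["p"] < threshold.p_threshold].copy()
    passing = ok[ok["p"] < threshold.p_threshold]
    agg = passing.sort_values("position_bp").groupby("feature_id")["marker_id"]
    markers_passing = agg.apply(lambda s: ";".join(s))
    n_passing = agg.size()
    hits["n_markers_passing"] = hits["feature_id"].map(n_passing).astype(int)
    hits["markers_passing"] = hits["feature_id"].map(markers_passing)
    return hits[cols + ["n_markers_passing", "markers_passing"]].reset_index(drop=True)
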