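"""Rank aggregation, preranked gene-set enrichment, over-representation and
rank-shift tests, and the dual-genome candidate overlap.

A trans-eQTL scan yields one signed t statistic per gene per marker.  To
obtain a single ranking per arm the statistics are aggregated per gene --
either the contrast with the maximum absolute statistic (keeping its sign;
used for haplotype contrasts where the strongest signal matters) or the
per-gene median across markers (used for the eQTL scan, where the handful
of correlated markers give a more stable central value).  The ranked list
feeds a classic weighted Kolmogorov-Smirnov preranked GSEA with a
gene-label permutation null.  Over-representation of an annotation (e.g.
MitoCarta membership) among hits is a one-sided hypergeometric test, and
rank distributions between arms are compared by a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass
class RankedGeneList:
    """Genes ordered by signed score, descending."""

    scores: pd.Series  # index: gene ids, values: signed statistics
    rule: str = "single"
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        if self.scores.index.has_duplicates:
            dupes = list(self.scores.index[self.scores.index.duplicated()])
            raise EnrichmentError(f"duplicate genes in ranking: {dupes[:5]}")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise EnrichmentError("non-finite scores in ranking")
        self.scores = self.scores.sort_values(ascending=False, kind="stable")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def ranks(self) -> pd.Series:
        """1-based rank of each gene (1 = highest score)."""
        return pd.Series(np.arange(1, len(self.scores) + 1), index=self.scores.index)


def aggregate_ranks_maxabs(statistics: pd.DataFrame) -> RankedGeneList:
    """Per gene, keep the signed statistic of largest magnitude.

    ``statistics`` is genes x contrasts; ties in magnitude are broken by
    the first contrast in column order.  Genes with no observed statistic
    are dropped and recorded on the result.
    """
    A = statistics.to_numpy(dtype=float)
    all_nan = np.isnan(A).all(axis=1)
    dropped = tuple(statistics.index[all_nan])
    if dropped:
        warnings.warn(f"aggregate_ranks_maxabs: dropping {len(dropped)} all-missing genes")
    A = A[~all_nan]
    absA = np.abs(A)
    absA = np.where(np.isnan(absA), -np.inf, absA)
    idx = absA.argmax(axis=1)  # first occurrence wins ties
    scores = A[np.arange(len(A)), idx]
    return RankedGeneList(
        pd.Series(scores, index=statistics.index[~all_nan], name="score"),
        rule="maxabs",
        dropped=dropped,
    )


def aggregate_ranks_median(statistics: pd.DataFrame) -> RankedGeneList:
    """Per-gene median statistic across markers (midpoint for even counts)."""
    A = statistics.to_numpy(dtype=float)
    all_nan = np.isnan(A).all(axis=1)
    dropped = tuple(statistics.index[all_nan])
    if dropped:
        warnings.warn(f"aggregate_ranks_median: dropping {len(dropped)} all-missing genes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(A[~all_nan], axis=1)
    return RankedGeneList(
        pd.Series(med, index=statistics.index[~all_nan], name="score"),
        rule="median",
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Preranked GSEA


def _running_sum_es(absw: np.ndarray, hit_idx: np.ndarray, n: int):
    """Weighted KS enrichment score from sorted hit positions.

    ``absw`` holds |score|^w for every ranked gene; ``hit_idx`` are the
    (sorted, 0-based) positions of the set members.  The running sum gains
    absw/sum(absw) at each hit and loses 1/(n-K) at each miss; the ES is
    the extremum of largest magnitude (positive wins exact ties).  Only the
    values at/just before hits need evaluating, so this is O(K).
    """
    K = len(hit_idx)
    w = absw[hit_idx]
    W = w.sum()
    if W <= 0:
        w = np.ones(K)
        W = float(K)
    cum = np.cumsum(w) / W
    miss = (hit_idx - np.arange(K)) / (n - K)
    dev_after = cum - miss                      # just after each hit
    dev_before = np.concatenate(([0.0], cum[:-1])) - miss  # just before
    hi = dev_after.max()
    lo = dev_before.min()
    if hi >= -lo:
        j = int(dev_after.argmax())
        return float(hi), hit_idx[: j + 1]
    j = int(dev_before.argmin())
    return float(lo), hit_idx[j:]


def _null_es(absw: np.ndarray, K: int, n: int, n_perm: int, rng) -> np.ndarray:
    """Null ES from random gene-label permutations (= random size-K sets)."""
    hits = np.sort(
        np.stack([rng.choice(n, size=K, replace=False) for _ in range(n_perm)]), axis=1
    )
    w = absw[hits]
    W = w.sum(axis=1, keepdims=True)
    W = np.where(W <= 0, K, W)
    cum = np.cumsum(w, axis=1) / W
    miss = (hits - np.arange(K)) / (n - K)
    dev_after = cum - miss
    dev_before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - miss
    hi = dev_after.max(axis=1)
    lo = dev_before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(
    ranked: RankedGeneList,
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Classic preranked GSEA with a gene-label permutation null.

    The running-sum statistic weights hits by |score|^``weight`` (weight 0
    recovers the unweighted KS statistic).  NES = ES divided by the mean
    |null ES| of matching sign; p is the fraction of matching-sign null ES
    at least as extreme, with a +1 small-sample correction so p is never
    exactly zero.  Benjamini-Hochberg adjustment is applied across the
    reported sets.  The leading edge runs from the top of the list to the
    ES extremum for positive ES, and from the extremum to the bottom for
    negative ES.
    """
    scores = ranked.scores
    n = len(scores)
    gene_pos = {g: i for i, g in enumerate(scores.index)}
    absw = np.abs(scores.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        hit_idx = np.sort([gene_pos[g] for g in set(members) if g in gene_pos])
        K = len(hit_idx)
        if K < min_size or K > max_size or K == n:
            warnings.warn(f"gsea_preranked: skipping set {name!r} (size {K} after universe intersection)")
            continue
        es, le_idx = _running_sum_es(absw, hit_idx, n)
        if K not in null_cache:
            null_cache[K] = _null_es(absw, K, n, n_perm, rng)
        null = null_cache[K]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same) == 0:
            nes, p = float("nan"), 1.0
        else:
            nes = es / np.abs(same).mean()
            p = (np.sum(np.abs(same) >= abs(es)) + 1) / (len(same) + 1)
        leading = [scores.index[i] for i in le_idx]
        rows.append((name, K, es, nes, p, ",".join(leading)))
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "size", "es", "nes", "p", "padj", "leading_edge"]
        )
    out = pd.DataFrame(rows, columns=["set_name", "size", "es", "nes", "p", "leading_edge"])
    out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["set_name", "size", "es", "nes", "p", "padj", "leading_edge"]]


# ---------------------------------------------------------------------------
# Over-representation and rank-shift tests


def overrepresentation_test(
    hits: Iterable[str], universe: Iterable[str], annotation: Iterable[str]
) -> float:
    """One-sided hypergeometric p for annotation enrichment among hits.

    p = P(X >= observed overlap) with X ~ Hypergeom(N=|universe|,
    K=|annotation ∩ universe|, n=|hits|).  Empty hit lists return 1 with a
    warning.
    """
    universe = set(universe)
    hits = set(hits)
    if not hits <= universe:
        raise EnrichmentError("hits must be a subset of the universe")
    annotation = set(annotation) & universe
    if not hits:
        warnings.warn("overrepresentation_test: empty hit list; p = 1")
        return 1.0
    N, K, n = len(universe), len(annotation), len(hits)
    k = len(hits & annotation)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rank_shift_test(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Uses exact enumeration when both groups have <= 8 values and no ties
    are present across the pooled data, otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EnrichmentError("rank_shift_test: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Dual-genome candidate overlap


def overlap_candidates(
    eqtl_hits: pd.DataFrame,
    external_list: Mapping[str, str] | pd.Series,
    marker_trait_labels: Mapping[str, Sequence[str]] | None = None,
    mitocarta: Iterable[str] | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intersect trans-eQTL hit genes with an external (nuclear) eQTL list.

    ``eqtl_hits`` is a per-gene hit summary (as from
    :func:`mitocross.association.significant_hits`); ``external_list`` maps
    gene -> its externally associated trait labels.  Each candidate row
    carries the gene's best model p and t, every associated marker
    position, trait labels mapped from those markers via the trait-GWAS
    (when supplied), the external labels, and MitoCarta membership.
    Sorted ascending by p.
    """
    external = pd.Series(dict(external_list)) if not isinstance(external_list, pd.Series) else external_list
    if external.empty:
        warnings.warn("overlap_candidates: empty external list")
    mitocarta = set(mitocarta or ())
    marker_trait_labels = marker_trait_labels or {}
    chrom = (
        annotation.set_index("gene_id")["chromosome"]
        if annotation is not None and "chromosome" in getattr(annotation, "columns", [])
        else None
    )
    rows = []
    for rec in eqtl_hits.itertuples():
        gene = rec.feature_id
        if gene not in external.index:
            continue
        markers = (rec.markers_passing or rec.marker_id).split(";")
        # trait labels for every passing marker, via the trait-GWAS mapping
        traits: list[str] = []
        for m in markers:
            traits.extend(marker_trait_labels.get(m, ()))
        rows.append(
            {
                "gene": gene,
                "model_p": rec.p,
                "t_statistic": rec.t,
                "markers": ";".join(markers),
                "position_bp": rec.position_bp,
                "chromosome": chrom.get(gene, "") if chrom is not None else "",
                "mito_gwas_traits": ";".join(sorted(set(traits))),
                "external_traits": external[gene],
                "is_mitocarta": gene in mitocarta,
            }
        )
    cols = ["gene", "model_p", "t_statistic", "markers", "position_bp",
            "chromosome", "mito_gwas_traits", "external_traits", "is_mitocarta"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols].sort_values("model_p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT gene-set files


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
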