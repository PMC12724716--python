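"""End-to-end orchestration of the three analyses.

``trait_gwas``, ``trans_eqtl`` and ``dendro_compare`` are the in-memory
cores; the ``run_*`` wrappers read a dataset directory (the layout written
by :func:`mitocross.synthetic.write_dataset`), execute the core, write
every output table as TSV with a stable column order, and record a run
manifest with file hashes so that a rerun with the same configuration and
seed can be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from . import association, dendro, enrichment, preprocess
from .genotypes import GenotypeMatrix, impute_genotypes, read_marker_table, read_strain_table
from .synthetic import DEFAULT_DYNAMIC_TRAITS, DEFAULT_STATIC_TRAITS

log = logging.getLogger("mitocross")

DEFAULT_FWER_LEVELS = (0.01, 0.05)


# ---------------------------------------------------------------------------
# Cores


def trait_gwas(
    traits: pd.DataFrame,
    samples: pd.DataFrame,
    genotypes: GenotypeMatrix,
    arms: Sequence[str] = ("Ctrl", "Iso"),
    fwer_levels: Sequence[float] = DEFAULT_FWER_LEVELS,
    n_perm: int = 2000,
    seed: int = 0,
    covariates: Sequence[str] = ("sex", "experimenter"),
) -> dict:
    """Per-arm trait scan with shared permutation thresholds.

    Each arm is processed independently: z-transform across the arm's
    animals, residualise on sex and experimenter, collapse to strain means,
    scan against every marker.  Thresholds depend only on the genotype
    matrix and are computed once per FWER level.
    """
    thresholds = {
        lvl: association.permutation_threshold(genotypes, lvl, n_perm, seed)
        for lvl in fwer_levels
    }
    out = {"thresholds": thresholds, "arms": {}}
    for arm in arms:
        t0 = time.perf_counter()
        strain_traits = preprocess.prepare_trait_matrix(
            traits, samples, arm, covariates=covariates
        )
        scan = association.scan(strain_traits, genotypes, arm=arm)
        hits = {lvl: association.significant_hits(scan, thr)
                for lvl, thr in thresholds.items()}
        out["arms"][arm] = {"strain_traits": strain_traits, "scan": scan, "hits": hits}
        log.info("trait GWAS arm %s: %d traits, %.2fs", arm,
                 strain_traits.shape[1], time.perf_counter() - t0)
    return out


def trans_eqtl(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame | None = None,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    external_list: pd.Series | None = None,
    marker_trait_labels: Mapping[str, Sequence[str]] | None = None,
    arms: Sequence[str] = ("Ctrl", "Iso"),
    fwer_levels: Sequence[float] = DEFAULT_FWER_LEVELS,
    n_perm: int = 2000,
    seed: int = 0,
    gsea_n_perm: int = 1000,
    covariates: Sequence[str] = ("sex", "plate"),
) -> dict:
    """Per-arm trans-eQTL scan plus the enrichment stages.

    Pipeline per arm: expression filter -> log2 CPM -> residualise on sex
    and plate -> strain means -> marker scan -> hits per FWER level ->
    median-rank aggregation -> preranked GSEA (when gene sets are given) ->
    MitoCarta over-representation.  Across arms, the rank distribution of
    MitoCarta genes is compared with a Wilcoxon rank-sum test, and hits are
    intersected with an external nuclear eQTL gene list when provided.
    """
    thresholds = {
        lvl: association.permutation_threshold(genotypes, lvl, n_perm, seed)
        for lvl in fwer_levels
    }
    mitocarta = set()
    if annotation is not None:
        mitocarta = set(annotation.loc[annotation["is_mitocarta"], "gene_id"])
    out = {"thresholds": thresholds, "arms": {}}
    ranked_by_arm = {}
    for arm in arms:
        t0 = time.perf_counter()
        expr = preprocess.prepare_expression_matrix(
            counts, samples, arm, covariates=covariates
        )
        scan = association.scan(expr, genotypes, arm=arm)
        hits = {lvl: association.significant_hits(scan, thr)
                for lvl, thr in thresholds.items()}
        stats_wide = scan.pivot_table(index="feature_id", columns="marker_id", values="t")
        ranked = enrichment.aggregate_ranks_median(stats_wide)
        ranked_by_arm[arm] = ranked
        gsea = None
        if gene_sets:
            gsea = enrichment.gsea_preranked(
                ranked, gene_sets, n_perm=gsea_n_perm, seed=seed
            )
        universe = list(expr.columns)
        overrep = {}
        for lvl, h in hits.items():
            overrep[lvl] = enrichment.overrepresentation_test(
                list(h["feature_id"]), universe, mitocarta
            ) if mitocarta else float("nan")
        mito_counts = {
            lvl: {
                "mitocarta": int(h["feature_id"].isin(mitocarta).sum()),
                "other": int((~h["feature_id"].isin(mitocarta)).sum()),
            }
            for lvl, h in hits.items()
        }
        out["arms"][arm] = {
            "expression": expr,
            "scan": scan,
            "hits": hits,
            "ranked": ranked,
            "gsea": gsea,
            "overrepresentation": overrep,
            "mitocarta_hit_counts": mito_counts,
            "n_genes_tested": len(universe),
        }
        log.info("trans-eQTL arm %s: %d genes, %.2fs", arm, len(universe),
                 time.perf_counter() - t0)

    # rank-shift of MitoCarta genes between arms
    if mitocarta and len(arms) == 2:
        a, b = arms
        ra = ranked_by_arm[a].ranks()
        rb = ranked_by_arm[b].ranks()
        shared = sorted(mitocarta & set(ra.index) & set(rb.index))
        out["mitocarta_rank_shift_p"] = (
            enrichment.rank_shift_test(ra.loc[shared], rb.loc[shared])
            if len(shared) >= 2 else float("nan")
        )

    if external_list is not None and len(arms) >= 1:
        lvl = max(fwer_levels)  # the counting level (5% in the study design)
        overlaps = {}
        for arm in arms:
            overlaps[arm] = enrichment.overlap_candidates(
                out["arms"][arm]["hits"][lvl],
                external_list,
                marker_trait_labels=marker_trait_labels,
                mitocarta=mitocarta,
                annotation=annotation,
            )
        out["overlap"] = overlaps
    return out


def dendro_compare(
    traits: pd.DataFrame,
    samples: pd.DataFrame,
    haplotypes: pd.Series,
    sequence_distances: pd.DataFrame,
    static_traits: Sequence[str],
    dynamic_traits: Sequence[str],
    arms: Sequence[str] = ("Ctrl", "Iso"),
    method: str = "average",
    L: float = 1.5,
) -> dict:
    """Tanglegram statistics per (trait class, arm).

    The haplotype-level trait matrix is the mean of strain means per
    haplotype per arm; the sequence side is the founder p-distance matrix.
    Returns per-cell :class:`~mitocross.dendro.TanglegramStats` plus both
    trees for serialisation.
    """
    out = {}
    classes = {"static": list(static_traits), "dynamic": list(dynamic_traits)}
    for arm in arms:
        strain_means = preprocess.collapse_to_strain(traits, samples, arm)
        hap = haplotypes.loc[strain_means.index]
        hap_means = strain_means.groupby(hap).mean()
        for cls, cols in classes.items():
            cols = [c for c in cols if c in hap_means.columns]
            if len(cols) < 2:
                continue
            stats = dendro.compare_trait_sequence_trees(
                hap_means[cols], sequence_distances, method=method, L=L
            )
            shared = [l for l in hap_means.index if l in sequence_distances.index]
            tm = hap_means.loc[shared, cols]
            z = (tm - tm.mean()) / tm.std(ddof=1)
            out[(cls, arm)] = {
                "stats": stats,
                "trait_tree": dendro.hcluster(z.dropna(axis=1), method=method),
                "sequence_tree": dendro.hcluster(
                    sequence_distances.loc[shared, shared],
                    metric="precomputed", method=method,
                ),
            }
    return out


# ---------------------------------------------------------------------------
# Dataset directory I/O


def load_dataset_dir(data_dir) -> dict:
    """Read the plain-text dataset layout written by ``write_dataset``."""
    from Bio import SeqIO

    data_dir = Path(data_dir)
    out = {
        "strains": read_strain_table(data_dir / "strain_table.csv"),
        "markers": read_marker_table(data_dir / "marker_table.csv"),
        "samples": pd.read_csv(data_dir / "samples.csv", index_col="sample_id"),
        "traits": pd.read_csv(data_dir / "traits.csv", index_col="sample_id"),
    }
    counts_path = data_dir / "counts.tsv"
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id").T
        counts.index.name = "sample_id"
        counts.columns.name = None
        out["counts"] = counts
    ann = data_dir / "gene_annotation.csv"
    if ann.exists():
        out["annotation"] = pd.read_csv(ann)
    fasta = data_dir / "founder_sequences.fasta"
    if fasta.exists():
        out["founder_sequences"] = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
        }
    gmt = data_dir / "gene_sets.gmt"
    if gmt.exists():
        out["gene_sets"] = enrichment.read_gmt(gmt)
    ext = data_dir / "external_eqtl_genes.csv"
    if ext.exists():
        df = pd.read_csv(ext, index_col=0)
        out["external_list"] = df.iloc[:, 0]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config: dict, seed: int, files: Sequence[Path]) -> Path:
    manifest = {
        "package": "mitocross",
        "version": __version__,
        "seed": seed,
        "config": config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "file_hashes": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


_SCAN_COLS = ["feature_id", "marker_id", "position_bp", "arm", "n",
              "beta", "se", "t", "p", "reason"]


def run_trait_gwas(
    data_dir, outdir, seed: int = 0, n_perm: int = 2000,
    fwer_levels: Sequence[float] = DEFAULT_FWER_LEVELS,
    arms: Sequence[str] = ("Ctrl", "Iso"),
) -> dict:
    """File-level trait-GWAS: read dataset dir, write scans/hits/thresholds."""
    data = load_dataset_dir(data_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = impute_genotypes(data["strains"], data["markers"])
    res = trait_gwas(
        data["traits"], data["samples"], geno,
        arms=arms, fwer_levels=fwer_levels, n_perm=n_perm, seed=seed,
    )
    files = []
    for arm, r in res["arms"].items():
        p = outdir / f"gwas_scan_{arm}.tsv"
        r["scan"][_SCAN_COLS].to_csv(p, sep="\t", index=False, float_format="%.10g")
        files.append(p)
        for lvl, h in r["hits"].items():
            p = outdir / f"gwas_hits_{arm}_fwer{lvl:g}.tsv"
            h.to_csv(p, sep="\t", index=False, float_format="%.10g")
            files.append(p)
    p = outdir / "gwas_thresholds.tsv"
    pd.DataFrame(
        [dataclasses.asdict(t) for t in res["thresholds"].values()]
    ).to_csv(p, sep="\t", index=False, float_format="%.10g")
    files.append(p)
    write_manifest(outdir, {"stage": "gwas", "n_perm": n_perm,
                            "fwer_levels": list(fwer_levels)}, seed, files)
    res["files"] = files
    return res


def marker_trait_label_map(gwas_result: dict, fwer_level: float) -> dict[str, list[str]]:
    """marker -> trait labels from trait-GWAS hits (markers passing FWER)."""
    out: dict[str, list[str]] = {}
    for arm, r in gwas_result["arms"].items():
        hits = r["hits"].get(fwer_level)
        if hits is None:
            continue
        for rec in hits.itertuples():
            for m in (rec.markers_passing or rec.marker_id).split(";"):
                out.setdefault(m, []).append(rec.feature_id)
    return {m: sorted(set(v)) for m, v in out.items()}


def run_trans_eqtl(
    data_dir, outdir, seed: int = 0, n_perm: int = 2000,
    fwer_levels: Sequence[float] = DEFAULT_FWER_LEVELS,
    arms: Sequence[str] = ("Ctrl", "Iso"),
    marker_trait_labels: Mapping[str, Sequence[str]] | None = None,
    gsea_n_perm: int = 1000,
) -> dict:
    """File-level trans-eQTL + enrichment + overlap."""
    data = load_dataset_dir(data_dir)
    if "counts" not in data:
        raise FileNotFoundError(f"no counts.tsv in {data_dir}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = impute_genotypes(data["strains"], data["markers"])
    res = trans_eqtl(
        data["counts"], data["samples"], geno,
        annotation=data.get("annotation"),
        gene_sets=data.get("gene_sets"),
        external_list=data.get("external_list"),
        marker_trait_labels=marker_trait_labels,
        arms=arms, fwer_levels=fwer_levels, n_perm=n_perm, seed=seed,
        gsea_n_perm=gsea_n_perm,
    )
    files = []
    for arm, r in res["arms"].items():
        p = outdir / f"eqtl_scan_{arm}.tsv"
        r["scan"][_SCAN_COLS].to_csv(p, sep="\t", index=False, float_format="%.10g")
        files.append(p)
        for lvl, h in r["hits"].items():
            p = outdir / f"eqtl_hits_{arm}_fwer{lvl:g}.tsv"
            h.to_csv(p, sep="\t", index=False, float_format="%.10g")
            files.append(p)
        p = outdir / f"eqtl_ranked_{arm}.tsv"
        r["ranked"].scores.to_csv(p, sep="\t", index_label="gene_id",
                                  header=["score"], float_format="%.10g")
        files.append(p)
        if r["gsea"] is not None:
            p = outdir / f"gsea_{arm}.tsv"
            r["gsea"].to_csv(p, sep="\t", index=False, float_format="%.10g")
            files.append(p)
        p = outdir / f"eqtl_summary_{arm}.tsv"
        rows = []
        for lvl in fwer_levels:
            counts = r["mitocarta_hit_counts"][lvl]
            rows.append({
                "fwer_level": lvl,
                "n_genes_tested": r["n_genes_tested"],
                "n_hits": counts["mitocarta"] + counts["other"],
                "n_hits_mitocarta": counts["mitocarta"],
                "n_hits_other": counts["other"],
                "overrepresentation_p": r["overrepresentation"][lvl],
            })
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
        files.append(p)
    if "overlap" in res:
        for arm, tab in res["overlap"].items():
            p = outdir / f"overlap_candidates_{arm}.tsv"
            tab.to_csv(p, sep="\t", index=False, float_format="%.10g")
            files.append(p)
    p = outdir / "eqtl_rank_shift.tsv"
    pd.DataFrame(
        [{"comparison": "mitocarta_ranks_between_arms",
          "p": res.get("mitocarta_rank_shift_p", float("nan"))}]
    ).to_csv(p, sep="\t", index=False, float_format="%.10g")
    files.append(p)
    write_manifest(outdir, {"stage": "eqtl", "n_perm": n_perm,
                            "fwer_levels": list(fwer_levels)}, seed, files)
    res["files"] = files
    return res


def run_dendro_compare(
    data_dir, outdir,
    static_traits: Sequence[str] | None = None,
    dynamic_traits: Sequence[str] | None = None,
    arms: Sequence[str] = ("Ctrl", "Iso"),
    method: str = "average", L: float = 1.5, seed: int = 0,
) -> dict:
    """File-level dendrogram comparison; writes stats table + Newick trees."""
    data = load_dataset_dir(data_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "founder_sequences" not in data:
        raise FileNotFoundError(f"no founder_sequences.fasta in {data_dir}")
    seq_dist = dendro.sequence_distance(data["founder_sequences"])
    trait_cols = list(data["traits"].columns)
    if static_traits is None or dynamic_traits is None:
        # fall back on the generator's default split, intersected with data
        static_traits = [t for t in DEFAULT_STATIC_TRAITS if t in trait_cols]
        dynamic_traits = [t for t in DEFAULT_DYNAMIC_TRAITS if t in trait_cols]
        if not static_traits and not dynamic_traits:
            mid = len(trait_cols) // 2
            static_traits, dynamic_traits = trait_cols[:mid], trait_cols[mid:]
    haplotypes = pd.Series(
        {s.strain_id: s.haplotype for s in data["strains"]}, name="haplotype"
    )
    res = dendro_compare(
        data["traits"], data["samples"], haplotypes, seq_dist,
        static_traits, dynamic_traits, arms=arms, method=method, L=L,
    )
    rows = []
    files = []
    for (cls, arm), r in res.items():
        s = r["stats"]
        rows.append({
            "trait_class": cls, "arm": arm,
            "entanglement": s.entanglement,
            "cpcc": s.cpcc,
            "exhaustive_entanglement": s.exhaustive_entanglement,
            "leaf_order_traits": ";".join(s.order1),
            "leaf_order_sequences": ";".join(s.order2),
        })
        for side in ("trait_tree", "sequence_tree"):
            p = outdir / f"{side}_{cls}_{arm}.nwk"
            p.write_text(r[side].to_newick() + "\n")
            files.append(p)
    p = outdir / "tanglegram_stats.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
    files.append(p)
    write_manifest(outdir, {"stage": "dendro", "linkage": method, "L": L}, seed, files)
    res["files"] = files
    return res
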