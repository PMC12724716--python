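"""Calibration, power and oracle-agreement studies on synthetic cohorts.

These are the package's own validation experiments: each function builds
synthetic data under stated study conditions, runs the relevant pipeline
stages from scratch, and returns the measured quantity.  They back both the
acceptance checks in the test-suite and ``scripts/acceptance.py``.

Problem sizes (replicate counts, permutation counts, gene-panel sizes) are
chosen so the full battery runs in minutes on one core while keeping
Monte-Carlo error well inside the margins being tested; they are stated in
each docstring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, preprocess
from .dendro import compare_trait_sequence_trees, sequence_distance
from .genotypes import impute_genotypes
from .synthetic import (
    PlantedEqtlEffect,
    PlantedTraitEffect,
    SimConfig,
    generate_dataset,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def ols_oracle_max_rel_error(n_instances: int = 100, seed: int = 0) -> float:
    """Worst relative disagreement between the scan OLS and a direct
    normal-equations solve over random biallelic instances (n <= 63)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(8, 64))
        x = (rng.random(n) < 0.5).astype(float)
        if min(x.sum(), n - x.sum()) < 3:
            continue
        y = rng.normal(size=n)
        beta, se, t, p, df = association._ols_biallelic(y[:, None], x)
        X = np.column_stack([np.ones(n), x])
        XtX = X.T @ X
        b = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ b
        s2 = float(resid @ resid) / (n - 2)
        se_ref = float(np.sqrt(s2 * np.linalg.inv(XtX)[1, 1]))
        worst = max(
            worst,
            abs(beta[0] - b[1]) / max(abs(b[1]), 1e-300),
            abs(se[0] - se_ref) / se_ref,
        )
        done += 1
    return worst


def _null_config(n_traits: int, seed: int, **kw) -> SimConfig:
    return SimConfig(
        static_traits=tuple(f"T{i:03d}" for i in range(n_traits)),
        dynamic_traits=(),
        n_genes=2,
        seed=seed,
        **kw,
    )


def fwer_calibration(
    n_traits: int = 500,
    n_perm: int = 2000,
    fwer_level: float = 0.05,
    seed: int = 0,
    arm: str = "Iso",
) -> dict:
    """Empirical family-wise error rate on a null cohort.

    Conditions: the default cohort structure (63 strains, 21 markers in 4
    patterns, 2 animals per strain per arm) with ``n_traits`` independent
    null traits; the permutation threshold uses ``n_perm`` draws.  Returns
    the fraction of traits declared hits at ``fwer_level`` -- which should
    match the level -- along with the threshold used.
    """
    cfg = _null_config(n_traits, seed)
    ds = generate_dataset(cfg)
    geno = impute_genotypes(ds.strain_table, ds.marker_table)
    thr = association.permutation_threshold(geno, fwer_level, n_perm, seed=seed + 1)
    strain_traits = preprocess.prepare_trait_matrix(ds.traits, ds.samples, arm)
    scan = association.scan(strain_traits, geno, arm=arm)
    hits = association.significant_hits(scan, thr)
    return {
        "fraction_hits": len(hits) / strain_traits.shape[1],
        "n_traits": strain_traits.shape[1],
        "p_threshold": thr.p_threshold,
        "fwer_level": fwer_level,
    }


def threshold_structure(n_perm: int = 10000, fwer_level: float = 0.05, seed: int = 0) -> dict:
    """Permutation threshold in two analytically understood regimes.

    With a single marker pattern the threshold must converge to the nominal
    level (one effective test); with four orthogonal balanced patterns it
    must approach the Sidak value 1 - (1 - a)^(1/4).
    """
    one = generate_dataset(_null_config(1, seed, n_patterns=1))
    g1 = impute_genotypes(one.strain_table, one.marker_table)
    thr1 = association.permutation_threshold(g1, fwer_level, n_perm, seed=seed + 1)

    four = generate_dataset(_null_config(1, seed))
    g4 = impute_genotypes(four.strain_table, four.marker_table)
    thr4 = association.permutation_threshold(g4, fwer_level, n_perm, seed=seed + 2)
    return {
        "single_pattern_threshold": thr1.p_threshold,
        "four_pattern_threshold": thr4.p_threshold,
        "sidak_reference": 1 - (1 - fwer_level) ** 0.25,
        "nominal": fwer_level,
        "n_perm": n_perm,
    }


def trait_power_study(
    n_reps: int = 200,
    effect: float = 1.5,
    fwer_level: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict:
    """Detection rate and effect-size recovery for a planted trait effect.

    Each replicate plants an ``effect``-sized (in animal-level noise-SD
    units) Iso-arm effect on one 4/4 marker of the default 63-strain
    cohort.  Detection runs the full GWAS path (z-transform, residualise,
    collapse, scan) against the shared permutation threshold; the effect
    size is re-estimated on raw strain means so that the estimate is in
    planted units.  Reports Iso detection rate, Ctrl false-detection rate,
    and the mean signed error of the beta estimate.
    """
    marker, trait = "Mit001", "CSA"
    seeds = _spawn_seeds(seed, n_reps)
    base = SimConfig(
        n_genes=2,
        static_traits=(trait,),
        dynamic_traits=(),
        planted_trait_effects=(PlantedTraitEffect(marker, trait, "Iso", effect),),
        seed=seeds[0],
    )
    detected = {"Iso": 0, "Ctrl": 0}
    betas = []
    for s in seeds:
        cfg = SimConfig(**{**base.__dict__, "seed": s})
        ds = generate_dataset(cfg)
        # marker allele draws (and hence dosage orientation) vary per seed,
        # so genotypes and the threshold are rebuilt per replicate
        geno = impute_genotypes(ds.strain_table, ds.marker_table)
        thr = association.permutation_threshold(geno, fwer_level, n_perm, seed=seed + 1)
        for arm in ("Iso", "Ctrl"):
            st = preprocess.prepare_trait_matrix(ds.traits, ds.samples, arm)
            scan = association.scan(st, geno, arm=arm)
            hits = association.significant_hits(scan, thr)
            detected[arm] += int(trait in set(hits["feature_id"]))
        raw = preprocess.collapse_to_strain(ds.traits, ds.samples, "Iso")
        rec = association.fit_marker_association(raw[trait], geno.dosage[marker])
        betas.append(rec.beta)
    return {
        "power": detected["Iso"] / n_reps,
        "ctrl_false_detection": detected["Ctrl"] / n_reps,
        "mean_beta_error": float(np.mean(betas) - effect),
        "mean_beta": float(np.mean(betas)),
        "planted_effect": effect,
        "n_reps": n_reps,
    }


def eqtl_power_study(
    n_reps: int = 200,
    log2_effect: float = 1.5,
    fwer_level: float = 0.05,
    n_perm: int = 2000,
    n_genes: int = 150,
    seed: int = 0,
) -> dict:
    """Detection rate for a planted marker -> gene expression effect.

    Each replicate plants a ``log2_effect`` Iso-arm eQTL on one gene of an
    ``n_genes`` panel and runs the full expression path (filter, log2 CPM,
    residualise on sex and plate, collapse, scan).  Also reports the
    fraction of non-planted genes called hits, which should not exceed the
    FWER level by more than Monte-Carlo noise.
    """
    marker, gene = "Mit002", "Gene00005"
    seeds = _spawn_seeds(seed + 17, n_reps)
    base = SimConfig(
        n_genes=n_genes,
        planted_eqtl_effects=(PlantedEqtlEffect(marker, gene, "Iso", log2_effect),),
        seed=seeds[0],
    )
    detected = 0
    null_hits = 0
    null_total = 0
    for s in seeds:
        cfg = SimConfig(**{**base.__dict__, "seed": s})
        ds = generate_dataset(cfg)
        geno = impute_genotypes(ds.strain_table, ds.marker_table)
        thr = association.permutation_threshold(geno, fwer_level, n_perm, seed=seed + 1)
        expr = preprocess.prepare_expression_matrix(ds.counts, ds.samples, "Iso")
        scan = association.scan(expr, geno, arm="Iso")
        hits = set(association.significant_hits(scan, thr)["feature_id"])
        detected += int(gene in hits)
        others = set(expr.columns) - {gene}
        null_hits += len(hits & others)
        null_total += len(others)
    return {
        "power": detected / n_reps,
        "null_hit_fraction": null_hits / null_total,
        "log2_effect": log2_effect,
        "n_reps": n_reps,
        "n_genes": n_genes,
    }


#: Trait layout of the dendrogram contrast study: number of traits driven
#: by each nested marker pattern, chosen so that after per-trait z-scoring
#: the trait-distance geometry orders haplotype splits the same way the
#: marker counts order the sequence distances.
_DENDRO_TRAITS_PER_PATTERN = (4, 2, 2, 1)


def dendro_contrast_study(
    n_reps: int = 200, effect: float = 2.5, seed: int = 0
) -> dict:
    """The stressed-arm tanglegram contrast as a measurable property.

    Uses the nested (phylogeny-like) marker patterns.  In each replicate
    the Iso arm's dynamic traits carry haplotype effects transmitted
    through the markers of every pattern (so trait similarity mirrors
    sequence similarity), while the Ctrl arm is pure noise.  Success means
    the effect arm shows strictly lower entanglement and higher cophenetic
    correlation than the null arm.
    """
    # representative marker of each nested pattern block (sizes 8, 6, 4, 3)
    reps = ("Mit001", "Mit009", "Mit015", "Mit019")
    dyn = []
    effects = []
    for p, (m, k) in enumerate(zip(reps, _DENDRO_TRAITS_PER_PATTERN)):
        for j in range(k):
            t = f"dT{p}{j}"
            dyn.append(t)
            effects.append(PlantedTraitEffect(m, t, "Iso", effect))
    seeds = _spawn_seeds(seed + 29, n_reps)
    success = 0
    stats = {a: {"es": [], "cpcc": []} for a in ("Ctrl", "Iso")}
    for s in seeds:
        cfg = SimConfig(
            n_genes=2,
            pattern_style="nested",
            dynamic_traits=tuple(dyn),
            static_traits=(),
            planted_trait_effects=tuple(effects),
            seed=s,
        )
        ds = generate_dataset(cfg)
        D = sequence_distance(ds.founder_sequences)
        hap = pd.Series({st.strain_id: st.haplotype for st in ds.strain_table})
        res = {}
        for arm in ("Ctrl", "Iso"):
            sm = preprocess.collapse_to_strain(ds.traits, ds.samples, arm)
            hm = sm.groupby(hap.loc[sm.index]).mean()
            res[arm] = compare_trait_sequence_trees(hm, D)
            stats[arm]["es"].append(res[arm].entanglement)
            stats[arm]["cpcc"].append(res[arm].cpcc)
        success += int(
            res["Iso"].entanglement < res["Ctrl"].entanglement
            and res["Iso"].cpcc > res["Ctrl"].cpcc
        )
    return {
        "success_rate": success / n_reps,
        "mean_es_effect_arm": float(np.mean(stats["Iso"]["es"])),
        "mean_es_null_arm": float(np.mean(stats["Ctrl"]["es"])),
        "mean_cpcc_effect_arm": float(np.mean(stats["Iso"]["cpcc"])),
        "mean_cpcc_null_arm": float(np.mean(stats["Ctrl"]["cpcc"])),
        "n_reps": n_reps,
        "planted_effect": effect,
    }


def gsea_calibration(
    n_universe: int = 500,
    set_size: int = 20,
    n_random_sets: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """NES behaviour for random and maximally enriched gene sets."""
    from .enrichment import RankedGeneList, gsea_preranked

    rng = np.random.default_rng(seed)
    scores = pd.Series(
        np.sort(rng.normal(size=n_universe))[::-1],
        index=[f"g{i:04d}" for i in range(n_universe)],
    )
    ranked = RankedGeneList(scores)
    random_sets = {
        f"r{i}": list(rng.choice(ranked.genes, size=set_size, replace=False))
        for i in range(n_random_sets)
    }
    res = gsea_preranked(ranked, random_sets, n_perm=200, seed=seed + 1)
    top = {"top": ranked.genes[:set_size]}
    res_top = gsea_preranked(ranked, top, n_perm=n_perm, seed=seed + 2)
    return {
        "random_set_mean_nes": float(res["nes"].mean()),
        "top_set_es": float(res_top.loc[0, "es"]),
        "top_set_p": float(res_top.loc[0, "p"]),
        "n_random_sets": n_random_sets,
    }
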