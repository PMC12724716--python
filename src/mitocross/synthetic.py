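"""Synthetic Collaborative-Cross-like cohorts with a planted-effect registry.

The generator emulates the statistical structure the analysis assumes: a
panel of inbred strains partitioned into 8 maternal founder haplotypes, a
small set of mitochondrial markers whose founder strain-distribution
patterns fall into only a few distinct bipartitions, animals in two
treatment arms (Ctrl / Iso) with sex, experimenter and library-plate
covariates, continuous traits built from additive effect layers, and
negative-binomial expression counts.  Marker -> trait and marker -> gene
effects can be planted with known, arm-specific sizes; the returned truth
registry makes every downstream stage testable for parameter recovery and
error-rate calibration without external data.

Default cohort structure: 63 strains across haplotypes A-H, 21 markers in
4 distinct patterns, 2 animals per strain per arm, 12,439 nuclear genes of
which ~9% carry a MitoCarta membership flag.

All randomness flows from a single seed through named child streams, so a
fixed seed reproduces the dataset bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    FOUNDERS,
    MT_GENOME_LENGTH,
    MarkerDefinition,
    StrainRecord,
    impute_genotypes,
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


DEFAULT_STATIC_TRAITS = ("THW", "LVW", "RVW", "RAW", "LAW", "CSA", "FibrosisPct")
DEFAULT_DYNAMIC_TRAITS = ("dEF", "dFS", "dHR", "dLVMass")

#: Balanced 4/4 founder bipartitions (Walsh patterns): orthogonal designs,
#: so distinct patterns give nearly independent marker tests.
_WALSH_PATTERNS = (
    (0, 0, 0, 0, 1, 1, 1, 1),
    (0, 0, 1, 1, 0, 0, 1, 1),
    (0, 1, 0, 1, 0, 1, 0, 1),
    (0, 1, 1, 0, 1, 0, 0, 1),
    (0, 0, 1, 1, 1, 1, 0, 0),
    (0, 1, 0, 1, 1, 0, 1, 0),
    (0, 1, 1, 0, 0, 1, 1, 0),
)

#: Nested (phylogeny-like) bipartitions: each entry lists the minor-side
#: founder indices.  Mimics hierarchically related founder mt-genomes, where
#: marker splits refine one another instead of crossing.
_NESTED_MINORS = (
    (4, 5, 6, 7),  # E-H vs A-D (deepest split)
    (2, 3),        # C,D
    (6, 7),        # G,H
    (1,),          # B
    (5,),          # F
    (3,),          # D
    (7,),          # H
)


def _nested_block_sizes(n_markers: int, n_patterns: int) -> list[int]:
    """Markers per pattern for the nested style: decreasing with split
    depth (older splits accumulate more variants), every pattern >= 1."""
    weights = np.arange(n_patterns, 0, -1, dtype=float)
    raw = np.floor(weights / weights.sum() * n_markers).astype(int)
    raw = np.maximum(raw, 1)
    while raw.sum() > n_markers:
        raw[np.argmax(raw)] -= 1
    i = 0
    while raw.sum() < n_markers:
        raw[i % n_patterns] += 1
        i += 1
    return list(raw)

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class PlantedTraitEffect:
    """marker -> trait effect of ``beta`` (in animal-level noise-SD units
    when noise_sd=1) added to animals of ``arm`` carrying the minor allele."""

    marker: str
    trait: str
    arm: str
    beta: float


@dataclass(frozen=True)
class PlantedEqtlEffect:
    """marker -> gene log2 expression shift for minor-allele strains in ``arm``."""

    marker: str
    gene: str
    arm: str
    log2_effect: float


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_strains: int = 63
    founders: tuple[str, ...] = FOUNDERS
    strains_per_haplotype: Mapping[str, int] | None = None
    n_markers: int = 21
    n_patterns: int = 4
    pattern_style: str = "balanced"
    animals_per_strain_arm: int = 2
    arms: tuple[str, str] = ("Ctrl", "Iso")
    n_experimenters: int = 3
    n_plates: int = 5
    static_traits: tuple[str, ...] = DEFAULT_STATIC_TRAITS
    dynamic_traits: tuple[str, ...] = DEFAULT_DYNAMIC_TRAITS
    n_genes: int = 12439
    mitocarta_fraction: float = 1140 / 12439
    planted_trait_effects: tuple[PlantedTraitEffect, ...] = ()
    planted_eqtl_effects: tuple[PlantedEqtlEffect, ...] = ()
    strain_sd: float = 0.5
    noise_sd: float = 1.0
    sex_effect_sd: float = 0.5
    batch_effect_sd: float = 0.3
    expr_sex_sd: float = 0.1
    expr_plate_sd: float = 0.2
    expr_strain_sd: float = 0.15
    nb_dispersion: float = 0.1
    genome_length: int = MT_GENOME_LENGTH
    extra_mutations_per_founder: int = 25
    min_planted_gene_mean: float = 50.0
    seed: int = 0

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.static_traits) + tuple(self.dynamic_traits)

    def resolved_strain_counts(self) -> dict[str, int]:
        if self.strains_per_haplotype is not None:
            counts = dict(self.strains_per_haplotype)
            if set(counts) != set(self.founders):
                raise ConfigurationError(
                    "strains_per_haplotype: keys must equal the founder set"
                )
            if sum(counts.values()) != self.n_strains:
                raise ConfigurationError(
                    f"strains_per_haplotype: counts sum to {sum(counts.values())}, "
                    f"expected n_strains={self.n_strains}"
                )
            return counts
        base, rem = divmod(self.n_strains, len(self.founders))
        return {
            f: base + (1 if i < rem else 0) for i, f in enumerate(self.founders)
        }

    def marker_ids(self) -> list[str]:
        return [f"Mit{i + 1:03d}" for i in range(self.n_markers)]

    def gene_ids(self) -> list[str]:
        return [f"Gene{i + 1:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ConfigurationError("n_strains must be positive")
        if len(self.founders) != len(set(self.founders)):
            raise ConfigurationError("founders: duplicate labels")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be positive")
        if self.n_patterns < 1 or self.n_patterns > self.n_markers:
            raise ConfigurationError(
                f"n_patterns must be in [1, n_markers]; got {self.n_patterns}"
            )
        if self.pattern_style not in ("balanced", "nested"):
            raise ConfigurationError(
                f"pattern_style must be 'balanced' or 'nested'; got {self.pattern_style!r}"
            )
        if len(self.arms) != 2 or len(set(self.arms)) != 2:
            raise ConfigurationError("arms must be two distinct labels")
        for name in ("strain_sd", "noise_sd", "sex_effect_sd", "batch_effect_sd",
                     "expr_sex_sd", "expr_plate_sd", "expr_strain_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not (0 <= self.mitocarta_fraction <= 1):
            raise ConfigurationError("mitocarta_fraction must be in [0, 1]")
        if self.genome_length < self.n_markers:
            raise ConfigurationError(
                "genome_length must be at least n_markers (sequence length "
                "must accommodate every marker position)"
            )
        self.resolved_strain_counts()
        markers = set(self.marker_ids())
        traits = set(self.traits)
        genes = set(self.gene_ids())
        for eff in self.planted_trait_effects:
            if eff.marker not in markers:
                raise ConfigurationError(f"planted_trait_effects: unknown marker {eff.marker!r}")
            if eff.trait not in traits:
                raise ConfigurationError(f"planted_trait_effects: unknown trait {eff.trait!r}")
            if eff.arm not in self.arms:
                raise ConfigurationError(f"planted_trait_effects: unknown arm {eff.arm!r}")
        for eff in self.planted_eqtl_effects:
            if eff.marker not in markers:
                raise ConfigurationError(f"planted_eqtl_effects: unknown marker {eff.marker!r}")
            if eff.gene not in genes:
                raise ConfigurationError(f"planted_eqtl_effects: unknown gene {eff.gene!r}")
            if eff.arm not in self.arms:
                raise ConfigurationError(f"planted_eqtl_effects: unknown arm {eff.arm!r}")


@dataclass
class SyntheticTruth:
    """Planted-effect registry plus generator-internal parameters."""

    trait_effects: tuple[PlantedTraitEffect, ...]
    eqtl_effects: tuple[PlantedEqtlEffect, ...]
    gene_baseline: pd.Series
    trait_variance: dict[str, dict[str, float]]


@dataclass
class SyntheticDataset:
    """One simulated cohort: tables, counts, sequences, and ground truth."""

    config: SimConfig
    strain_table: list[StrainRecord]
    marker_table: list[MarkerDefinition]
    samples: pd.DataFrame      # sample_id -> strain_id, sex, treatment, experimenter, plate
    traits: pd.DataFrame       # animals x traits
    counts: pd.DataFrame       # samples x genes (integer)
    annotation: pd.DataFrame   # gene_id, chromosome, is_mitocarta, is_mt_encoded
    founder_sequences: dict[str, str]
    truth: SyntheticTruth


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named child streams, all derived from one seed."""
    names = ("markers", "traits", "counts", "sequences", "annotation", "extras")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _marker_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    pos = np.linspace(1, config.genome_length, config.n_markers + 2)[1:-1]
    return np.unique(np.round(pos).astype(int))


def _founder_patterns(config: SimConfig, rng: np.random.Generator) -> list[dict[str, int]]:
    """One 0/1 founder bipartition per pattern.

    ``balanced`` style uses orthogonal 4/4 Walsh bipartitions, so distinct
    patterns behave like (nearly) independent tests -- the regime in which
    multiple-testing thresholds are easiest to reason about.  ``nested``
    style uses hierarchically refining splits, mimicking phylogenetically
    related founder mt-genomes whose marker splits nest rather than cross.
    Beyond the built-in patterns, random balanced bipartitions fill in.
    """
    nf = len(config.founders)
    pats: list[dict[str, int]] = []
    if nf == 8 and config.pattern_style == "nested":
        for minors in _NESTED_MINORS[: config.n_patterns]:
            bits = [1 if i in minors else 0 for i in range(nf)]
            pats.append(dict(zip(config.founders, bits)))
    elif nf == 8:
        for row in _WALSH_PATTERNS[: config.n_patterns]:
            pats.append(dict(zip(config.founders, row)))
    while len(pats) < config.n_patterns:
        bits = np.zeros(nf, dtype=int)
        bits[rng.choice(nf, size=nf // 2, replace=False)] = 1
        cand = dict(zip(config.founders, bits))
        if cand not in pats and 0 < sum(bits) < nf:
            pats.append(cand)
    return pats


def build_marker_table(config: SimConfig, rng: np.random.Generator | None = None
                       ) -> tuple[list[MarkerDefinition], list[int]]:
    """Marker definitions plus the pattern index of each marker.

    Markers are assigned round-robin to the distinct patterns, so markers
    within a pattern have perfectly correlated genotypes -- mirroring a
    mitochondrial genome where many markers carry few independent signals.
    """
    if rng is None:
        rng = _streams(config.seed)["markers"]
    positions = _marker_positions(config, rng)
    patterns = _founder_patterns(config, rng)
    if config.pattern_style == "nested":
        sizes = _nested_block_sizes(config.n_markers, config.n_patterns)
        assignment = [p for p, s in enumerate(sizes) for _ in range(s)]
    else:
        assignment = [i % config.n_patterns for i in range(config.n_markers)]
    markers = []
    for i, mid in enumerate(config.marker_ids()):
        pat = patterns[assignment[i]]
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_b, alt_b = _BASES[ref].decode(), _BASES[alt].decode()
        alleles = {f: (alt_b if pat[f] else ref_b) for f in config.founders}
        markers.append(MarkerDefinition(mid, int(positions[i]), alleles))
    return markers, assignment


def build_strain_table(config: SimConfig) -> list[StrainRecord]:
    counts = config.resolved_strain_counts()
    out = []
    i = 0
    for f in config.founders:
        for _ in range(counts[f]):
            i += 1
            out.append(StrainRecord(f"CC{i:03d}", f))
    return out


def build_sample_table(config: SimConfig, strains: Sequence[StrainRecord]) -> pd.DataFrame:
    """Animal-level metadata.

    Sex alternates within strain (guaranteeing both sexes wherever at least
    two animals exist); experimenter and plate are assigned round-robin so
    every covariate level is estimable.
    """
    rows = []
    k = 0
    for s in strains:
        a = 0
        for arm in config.arms:
            for _ in range(config.animals_per_strain_arm):
                rows.append(
                    {
                        "sample_id": f"{s.strain_id}_{arm}_{a + 1}",
                        "strain_id": s.strain_id,
                        "sex": "M" if a % 2 == 0 else "F",
                        "treatment": arm,
                        "experimenter": f"E{k % config.n_experimenters + 1}",
                        "plate": f"P{k % config.n_plates + 1}",
                    }
                )
                a += 1
                k += 1
    return pd.DataFrame(rows).set_index("sample_id")


def generate_founder_sequences(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Aligned founder mt-DNA stand-ins embedding the marker alleles.

    All founders share one random background sequence; each founder then
    carries its marker alleles at the marker positions plus a disjoint set
    of private mutations, so pairwise Hamming distances equal the marker
    mismatch count plus twice ``extra_mutations_per_founder``.  Distances
    therefore group founders exactly as the marker patterns do.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed)["sequences"]
    markers, _ = build_marker_table(config, _streams(config.seed)["markers"])
    L = config.genome_length
    base = _BASES[rng.integers(0, 4, size=L)]
    marker_pos = {m.position_bp - 1 for m in markers}
    nf = len(config.founders)
    e = config.extra_mutations_per_founder
    free = np.setdiff1d(np.arange(L), np.fromiter(marker_pos, dtype=int))
    if e * nf > len(free):
        raise ConfigurationError(
            "extra_mutations_per_founder too large for genome_length"
        )
    private = rng.choice(free, size=e * nf, replace=False) if e else np.array([], int)
    seqs = {}
    for i, f in enumerate(config.founders):
        arr = base.copy()
        for m in markers:
            arr[m.position_bp - 1] = m.founder_alleles[f].encode()
        for p in private[i * e : (i + 1) * e]:
            cur = np.where(_BASES == arr[p])[0][0]
            arr[p] = _BASES[(cur + 1) % 4]
        seqs[f] = arr.tobytes().decode()
    return seqs


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate a full cohort under ``config``; deterministic per seed.

    Trait model (per animal): trait mean + arm offset + sex effect +
    experimenter effect + strain random effect (shared across arms) +
    planted marker effects applied through the strain's haplotype allele +
    Gaussian noise.

    Count model (per sample x gene): negative binomial with log-normal
    gene baselines and log2-scale plate, sex, strain and planted-eQTL
    effects; a single dispersion parameter.  Genes carrying a planted eQTL
    get their baseline floored at ``min_planted_gene_mean`` so a planted
    effect is a statement about an expressed gene.
    """
    config.validate()
    rngs = _streams(config.seed)

    strains = build_strain_table(config)
    markers, _ = build_marker_table(config, rngs["markers"])
    samples = build_sample_table(config, strains)
    geno = impute_genotypes(strains, markers, genome_length=config.genome_length)

    # --- traits -----------------------------------------------------------
    rng = rngs["traits"]
    n_samp = len(samples)
    strain_of = samples["strain_id"].to_numpy()
    sex_f = (samples["sex"] == "F").to_numpy(dtype=float)
    arm_of = samples["treatment"].to_numpy()
    exp_codes, exp_levels = pd.factorize(samples["experimenter"])
    strain_ids = [s.strain_id for s in strains]
    strain_index = {s: i for i, s in enumerate(strain_ids)}
    srow = np.array([strain_index[s] for s in strain_of])

    planted_by_trait: dict[str, list[PlantedTraitEffect]] = {}
    for eff in config.planted_trait_effects:
        planted_by_trait.setdefault(eff.trait, []).append(eff)

    trait_cols = {}
    trait_variance: dict[str, dict[str, float]] = {}
    for trait in config.traits:
        base = rng.normal(0.0, 2.0)
        arm_shift = {a: rng.normal(0.0, 1.0) for a in config.arms}
        sex_coef = rng.normal(0.0, config.sex_effect_sd)
        exp_eff = rng.normal(0.0, config.batch_effect_sd, size=len(exp_levels))
        strain_eff = rng.normal(0.0, config.strain_sd, size=len(strain_ids))
        y = (
            base
            + np.array([arm_shift[a] for a in arm_of])
            + sex_coef * sex_f
            + exp_eff[exp_codes]
            + strain_eff[srow]
            + rng.normal(0.0, config.noise_sd, size=n_samp)
        )
        for eff in planted_by_trait.get(trait, ()):
            dose = geno.dosage[eff.marker].to_numpy(dtype=float)[srow]
            y = y + eff.beta * dose * (arm_of == eff.arm)
        trait_cols[trait] = y
        trait_variance[trait] = {
            "strain": config.strain_sd**2,
            "noise": config.noise_sd**2,
            "sex": sex_coef**2 * 0.25,
            "experimenter": float(np.var(exp_eff)),
        }
    traits = pd.DataFrame(trait_cols, index=samples.index)

    # --- counts -----------------------------------------------------------
    rng = rngs["counts"]
    gene_ids = config.gene_ids()
    n_genes = config.n_genes
    baseline = np.exp(rng.normal(np.log(100.0), 1.2, size=n_genes))
    planted_genes = {eff.gene for eff in config.planted_eqtl_effects}
    gindex = {g: i for i, g in enumerate(gene_ids)}
    for g in planted_genes:
        baseline[gindex[g]] = max(baseline[gindex[g]], config.min_planted_gene_mean)

    plate_codes, plate_levels = pd.factorize(samples["plate"])
    plate_eff = rng.normal(0.0, config.expr_plate_sd, size=(len(plate_levels), n_genes))
    sex_eff = rng.normal(0.0, config.expr_sex_sd, size=n_genes)
    strain_eff = rng.normal(0.0, config.expr_strain_sd, size=(len(strain_ids), n_genes))

    log2mu = (
        np.log2(baseline)[None, :]
        + plate_eff[plate_codes]
        + sex_eff[None, :] * sex_f[:, None]
        + strain_eff[srow]
    )
    for eff in config.planted_eqtl_effects:
        dose = geno.dosage[eff.marker].to_numpy(dtype=float)[srow]
        log2mu[:, gindex[eff.gene]] += eff.log2_effect * dose * (arm_of == eff.arm)
    mu = 2.0**log2mu
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts, index=samples.index, columns=gene_ids)

    # --- annotation -------------------------------------------------------
    rng = rngs["annotation"]
    n_mito = int(round(config.mitocarta_fraction * n_genes))
    mito = np.zeros(n_genes, dtype=bool)
    if n_mito:
        mito[rng.choice(n_genes, size=n_mito, replace=False)] = True
    chroms = [str(c) for c in range(1, 20)] + ["X"]
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": rng.choice(chroms, size=n_genes),
            "is_mitocarta": mito,
            "is_mt_encoded": False,
        }
    )

    sequences = generate_founder_sequences(config, rngs["sequences"])

    truth = SyntheticTruth(
        trait_effects=tuple(config.planted_trait_effects),
        eqtl_effects=tuple(config.planted_eqtl_effects),
        gene_baseline=pd.Series(baseline, index=gene_ids, name="baseline_mean"),
        trait_variance=trait_variance,
    )
    return SyntheticDataset(
        config=config,
        strain_table=strains,
        marker_table=markers,
        samples=samples,
        traits=traits,
        counts=counts,
        annotation=annotation,
        founder_sequences=sequences,
        truth=truth,
    )


def synthetic_gene_sets(
    dataset: SyntheticDataset, n_sets: int = 6, set_size: int = 50, seed: int | None = None
) -> dict[str, list[str]]:
    """Small synthetic GMT-style collection for exercising the GSEA stage:
    random sets, plus a MitoCarta set and one seeded with planted genes."""
    rng = np.random.default_rng(
        _streams(dataset.config.seed)["extras"] if seed is None else seed
    )
    genes = list(dataset.counts.columns)
    sets = {
        f"SYNTH_RANDOM_{i + 1}": sorted(
            rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        )
        for i in range(n_sets)
    }
    mito = list(dataset.annotation.loc[dataset.annotation["is_mitocarta"], "gene_id"])
    if mito:
        sets["SYNTH_MITOCARTA"] = mito
    planted = sorted({e.gene for e in dataset.truth.eqtl_effects})
    if planted:
        extra = [g for g in genes if g not in planted]
        n_pad = min(len(extra), max(0, set_size - len(planted)))
        pad = rng.choice(extra, size=n_pad, replace=False)
        sets["SYNTH_PLANTED"] = sorted(planted + list(pad))
    return sets


def synthetic_external_list(
    dataset: SyntheticDataset, n_genes: int = 30, seed: int | None = None
) -> pd.Series:
    """Stand-in for an external nuclear-eQTL gene list (synthetic): a random
    gene subset, guaranteed to include any planted eQTL genes, mapped to
    fake trait labels."""
    rng = np.random.default_rng(
        _streams(dataset.config.seed)["extras"].integers(2**31) if seed is None else seed
    )
    genes = list(dataset.counts.columns)
    planted = sorted({e.gene for e in dataset.truth.eqtl_effects})
    others = [g for g in genes if g not in planted]
    n_extra = min(len(others), max(0, n_genes - len(planted)))
    extra = list(rng.choice(others, size=n_extra, replace=False))
    chosen = planted + extra
    labels = rng.choice(["LV", "Lung", "EF.21", "LA"], size=len(chosen))
    return pd.Series(labels, index=chosen, name="external_traits")


# ---------------------------------------------------------------------------
# Writers


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every table of the dataset in plain-text formats.

    Layout: strain_table.csv, marker_table.csv, samples.csv, traits.csv,
    counts.tsv (genes x samples), gene_annotation.csv,
    founder_sequences.fasta, gene_sets.gmt, external_eqtl_genes.csv,
    truth.json.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "strain_table.csv"
    pd.DataFrame(
        [{"strain_id": s.strain_id, "haplotype": s.haplotype} for s in dataset.strain_table]
    ).to_csv(p, index=False)
    paths["strain_table"] = p

    p = outdir / "marker_table.csv"
    rows = []
    for m in dataset.marker_table:
        row = {"marker_id": m.marker_id, "position_bp": m.position_bp}
        row.update({f"allele_{f}": m.founder_alleles[f] for f in dataset.config.founders})
        rows.append(row)
    pd.DataFrame(rows).to_csv(p, index=False)
    paths["marker_table"] = p

    p = outdir / "samples.csv"
    dataset.samples.to_csv(p, index_label="sample_id")
    paths["samples"] = p

    p = outdir / "traits.csv"
    dataset.traits.to_csv(p, index_label="sample_id")
    paths["traits"] = p

    p = outdir / "counts.tsv"
    dataset.counts.T.to_csv(p, sep="\t", index_label="gene_id")
    paths["counts"] = p

    p = outdir / "gene_annotation.csv"
    dataset.annotation.to_csv(p, index=False)
    paths["annotation"] = p

    p = outdir / "founder_sequences.fasta"
    records = [
        SeqRecord(Seq(s), id=f, description="synthetic founder mt-DNA")
        for f, s in dataset.founder_sequences.items()
    ]
    SeqIO.write(records, str(p), "fasta")
    paths["founder_sequences"] = p

    p = outdir / "gene_sets.gmt"
    write_gmt(synthetic_gene_sets(dataset), p, description="synthetic")
    paths["gene_sets"] = p

    p = outdir / "external_eqtl_genes.csv"
    synthetic_external_list(dataset).to_csv(p, index_label="gene_id")
    paths["external_list"] = p

    p = outdir / "truth.json"
    truth = {
        "trait_effects": [dataclasses.asdict(e) for e in dataset.truth.trait_effects],
        "eqtl_effects": [dataclasses.asdict(e) for e in dataset.truth.eqtl_effects],
        "trait_variance": dataset.truth.trait_variance,
        "seed": dataset.config.seed,
    }
    p.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth"] = p
    return paths
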