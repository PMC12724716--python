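"""Mitochondrial genotypes of inbred strains from maternal founder haplotypes.

In an eight-founder recombinant inbred panel such as the Collaborative
Cross, mitochondria are inherited maternally and without recombination, so
every strain carries the complete mt-DNA sequence of exactly one founder.
Given the maternal founder haplotype of each strain and a table of founder
alleles at a set of mt-genome markers, the strain genotypes are determined
exactly -- no probabilistic imputation is involved.  By construction the
genotype matrix has at most eight distinct rows, and markers sharing a
founder strain-distribution pattern are statistically redundant; this
module derives the genotypes and characterises that redundancy.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical founder haplotype labels, one per founder line.
FOUNDERS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Default mitochondrial genome length in bp (mouse mt-DNA reference).
MT_GENOME_LENGTH = 16299


class GenotypeError(ValueError):
    """Raised for inconsistent strain/marker inputs."""


@dataclass(frozen=True)
class StrainRecord:
    """One inbred strain and its maternal founder haplotype."""

    strain_id: str
    haplotype: str


@dataclass(frozen=True)
class MarkerDefinition:
    """A mitochondrial marker: id, 1-based position, founder -> allele map."""

    marker_id: str
    position_bp: int
    founder_alleles: Mapping[str, str]

    def alleles_present(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.founder_alleles.values())))


@dataclass
class GenotypeMatrix:
    """Strains x markers allele symbols plus a numeric dosage encoding.

    ``dosage`` codes the major allele (most frequent among the founders,
    ties broken alphabetically) as 0 and minor alleles as 1, 2, ... in
    decreasing founder-frequency order.  For biallelic markers the dosage
    column is therefore 0/1.
    """

    alleles: pd.DataFrame
    dosage: pd.DataFrame
    allele_map: dict[str, dict[str, int]]
    positions: pd.Series
    haplotypes: pd.Series = field(default=None)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.alleles.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.alleles.columns)

    def n_alleles(self, marker_id: str) -> int:
        return len(self.allele_map[marker_id])

    def fingerprint(self) -> str:
        """Stable hash of the dosage matrix, strain ids and marker ids.

        Permutation thresholds are only valid for the genotype matrix they
        were computed on; the fingerprint ties the two together.
        """
        h = hashlib.sha256()
        h.update(",".join(self.alleles.index).encode())
        h.update(b"|")
        h.update(",".join(self.alleles.columns).encode())
        h.update(b"|")
        h.update(np.ascontiguousarray(self.dosage.to_numpy(dtype=np.int64)).tobytes())
        return h.hexdigest()


def impute_genotypes(
    strains: Sequence[StrainRecord],
    markers: Sequence[MarkerDefinition],
    genome_length: int = MT_GENOME_LENGTH,
) -> GenotypeMatrix:
    """Derive the strain x marker genotype matrix from founder haplotypes.

    Each strain's allele at a marker is the allele of its maternal founder,
    so strains sharing a haplotype get identical rows.  Raises
    :class:`GenotypeError` when a marker lacks an allele for some strain's
    haplotype, when a haplotype label is unknown, or when a position falls
    outside ``[1, genome_length]``.
    """
    if not strains or not markers:
        raise GenotypeError("need at least one strain and one marker")
    founder_set = set()
    for m in markers:
        founder_set.update(m.founder_alleles)
    for s in strains:
        if s.haplotype not in founder_set:
            raise GenotypeError(
                f"strain {s.strain_id!r}: unknown haplotype {s.haplotype!r}"
            )
    strain_ids = [s.strain_id for s in strains]
    if len(set(strain_ids)) != len(strain_ids):
        raise GenotypeError("duplicate strain ids")
    haplos = {s.strain_id: s.haplotype for s in strains}
    needed = sorted({s.haplotype for s in strains})

    allele_cols: dict[str, list[str]] = {}
    dosage_cols: dict[str, list[int]] = {}
    allele_map: dict[str, dict[str, int]] = {}
    positions: dict[str, int] = {}
    for m in markers:
        if not (1 <= m.position_bp <= genome_length):
            raise GenotypeError(
                f"marker {m.marker_id!r}: position {m.position_bp} outside "
                f"[1, {genome_length}]"
            )
        for hap in needed:
            if hap not in m.founder_alleles:
                raise GenotypeError(
                    f"marker {m.marker_id!r}: no allele for founder {hap!r}"
                )
        # Major allele = most frequent among the declared founders,
        # alphabetical on ties; remaining alleles coded by decreasing count.
        counts: dict[str, int] = {}
        for a in m.founder_alleles.values():
            counts[a] = counts.get(a, 0) + 1
        order = sorted(counts, key=lambda a: (-counts[a], a))
        amap = {a: i for i, a in enumerate(order)}
        allele_map[m.marker_id] = amap
        col = [m.founder_alleles[haplos[s]] for s in strain_ids]
        allele_cols[m.marker_id] = col
        dosage_cols[m.marker_id] = [amap[a] for a in col]
        positions[m.marker_id] = m.position_bp

    marker_ids = [m.marker_id for m in markers]
    if len(set(marker_ids)) != len(marker_ids):
        raise GenotypeError("duplicate marker ids")
    alleles = pd.DataFrame(allele_cols, index=strain_ids, columns=marker_ids)
    dosage = pd.DataFrame(dosage_cols, index=strain_ids, columns=marker_ids)
    return GenotypeMatrix(
        alleles=alleles,
        dosage=dosage,
        allele_map=allele_map,
        positions=pd.Series(positions, name="position_bp"),
        haplotypes=pd.Series(haplos, name="haplotype").loc[strain_ids],
    )


@dataclass(frozen=True)
class PatternGroup:
    """Markers that share one founder strain-distribution pattern.

    ``complement_flags[i]`` is True when ``markers[i]`` carries the same
    biallelic bipartition as the representative with major/minor labels
    swapped -- an identical test up to sign.
    """

    representative: str
    markers: tuple[str, ...]
    complement_flags: tuple[bool, ...]


def _canonical_pattern(col: np.ndarray) -> tuple[tuple[int, ...], bool]:
    """Relabel dosage codes by first appearance; for 0/1 columns also fold
    complements together.  Returns (canonical tuple, complemented?)."""
    relab: dict[int, int] = {}
    out = []
    for v in col:
        if v not in relab:
            relab[v] = len(relab)
        out.append(relab[v])
    canon = tuple(out)
    # after first-appearance relabelling a column and its complement map to
    # the same tuple; flag columns whose first strain carried a nonzero code
    complemented = bool(col[0] != 0) and len(relab) == 2
    return canon, complemented


def distinct_patterns(g: GenotypeMatrix) -> list[PatternGroup]:
    """Partition markers into groups with identical strain-distribution
    patterns (identical or complementary dosage columns)."""
    if g.dosage.empty:
        raise GenotypeError("empty genotype matrix")
    groups: dict[tuple[int, ...], list[tuple[str, bool]]] = {}
    order: list[tuple[int, ...]] = []
    for mid in g.marker_ids:
        canon, comp = _canonical_pattern(g.dosage[mid].to_numpy())
        if canon not in groups:
            groups[canon] = []
            order.append(canon)
        groups[canon].append((mid, comp))
    out = []
    for canon in order:
        members = groups[canon]
        # representative: first member by genome position
        rep = min(members, key=lambda mc: g.positions[mc[0]])[0]
        rep_comp = dict(members)[rep]
        out.append(
            PatternGroup(
                representative=rep,
                markers=tuple(m for m, _ in members),
                complement_flags=tuple(c != rep_comp for _, c in members),
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_strain_table(path) -> list[StrainRecord]:
    """Read a strain table CSV with columns strain_id, haplotype."""
    df = pd.read_csv(path, dtype=str)
    return [StrainRecord(r.strain_id, r.haplotype) for r in df.itertuples()]


def read_marker_table(path, founders: Iterable[str] = FOUNDERS) -> list[MarkerDefinition]:
    """Read a marker table CSV: marker_id, position_bp, allele_A..allele_H."""
    df = pd.read_csv(path, dtype={"marker_id": str})
    founders = list(founders)
    out = []
    for r in df.itertuples():
        alleles = {f: str(getattr(r, f"allele_{f}")) for f in founders}
        out.append(MarkerDefinition(str(r.marker_id), int(r.position_bp), alleles))
    return out


def write_genotype_tables(g: GenotypeMatrix, allele_path, dosage_path) -> None:
    g.alleles.to_csv(allele_path, sep="\t", index_label="strain_id")
    g.dosage.to_csv(dosage_path, sep="\t", index_label="strain_id")
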