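import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitocross import association
from mitocross.genotypes import FOUNDERS, MarkerDefinition, StrainRecord, impute_genotypes
from tests.conftest import ols_normal_equations


def make_genotypes(columns: dict[str, list[int]], positions=None):
    """Build a GenotypeMatrix directly from dosage columns (one strain per
    row) by routing through impute_genotypes with one haplotype per strain
    pattern -- keeps the object construction on the public path."""
    n = len(next(iter(columns.values())))
    # use one synthetic founder per distinct row
    rows = list(zip(*columns.values()))
    distinct = sorted(set(rows))
    assert len(distinct) <= 8, "test helper supports <= 8 distinct rows"
    hap_of_row = {r: FOUNDERS[i] for i, r in enumerate(distinct)}
    strains = [StrainRecord(f"s{i:02d}", hap_of_row[r]) for i, r in enumerate(rows)]
    markers = []
    for j, (mid, col) in enumerate(columns.items()):
        alleles = {}
        for f in FOUNDERS:
            rows_f = [r for r in distinct if hap_of_row[r] == f]
            bit = rows_f[0][j] if rows_f else 0
            alleles[f] = "G" if bit else "A"
        pos = positions[mid] if positions else (j + 1) * 100
        markers.append(MarkerDefinition(mid, pos, alleles))
    return impute_genotypes(strains, markers)


class TestFit:
    def test_hand_solved_ols(self):
        y = pd.Series([0.1, -0.1, 0.0, 1.1, 0.9, 1.0], index=[f"s{i:02d}" for i in range(6)])
        g = make_genotypes({"m1": [0, 0, 0, 1, 1, 1]})
        rec = association.fit_marker_association(y, g.dosage["m1"])
        assert rec.beta == pytest.approx(1.0)
        assert rec.reason is None
        # closed form: se^2 = s2/Sxx with s2 = rss/(n-2)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        beta, se, _ = ols_normal_equations(y.to_numpy(), X)
        assert rec.se == pytest.approx(se[1], rel=1e-12)
        assert rec.t == pytest.approx(beta[1] / se[1], rel=1e-12)
        assert rec.p == pytest.approx(2 * stats.t.sf(abs(rec.t), 4), rel=1e-12)

    def test_monomorphic_skipped(self):
        y = pd.Series(np.arange(8.0), index=[f"s{i:02d}" for i in range(8)])
        g = make_genotypes({"m1": [0] * 8})
        rec = association.fit_marker_association(y, g.dosage["m1"])
        assert rec.reason == "monomorphic"
        assert np.isnan(rec.p)

    def test_small_class_skipped(self):
        y = pd.Series(np.arange(8.0), index=[f"s{i:02d}" for i in range(8)])
        g = make_genotypes({"m1": [1, 0, 0, 0, 0, 0, 0, 0]})
        rec = association.fit_marker_association(y, g.dosage["m1"])
        assert rec.reason == "underpowered"

    def test_oracle_agreement_random_instances(self, rng):
        """OLS results match an independent normal-equations solver."""
        for _ in range(25):
            n = int(rng.integers(8, 64))
            x = (rng.random(n) < 0.5).astype(float)
            if min(x.sum(), n - x.sum()) < 3:
                continue
            y = pd.Series(rng.normal(size=n), index=[f"s{i:02d}" for i in range(n)])
            g = make_genotypes({"m1": x.astype(int).tolist()})
            rec = association.fit_marker_association(y, g.dosage["m1"])
            beta, se, _ = ols_normal_equations(y.to_numpy(), np.column_stack([np.ones(n), x]))
            assert rec.beta == pytest.approx(beta[1], rel=1e-10)
            assert rec.se == pytest.approx(se[1], rel=1e-10)


class TestScan:
    def test_identical_patterns_share_p(self, genotypes63, rng):
        feats = pd.DataFrame(
            {"t1": rng.normal(size=63)}, index=genotypes63.strain_ids
        )
        scan = association.scan(feats, genotypes63)
        assert len(scan) == 21
        assert scan["p"].round(12).nunique() == 4  # one value per pattern

    def test_feature_equal_to_dosage_attains_min_p(self, genotypes63, rng):
        dose = genotypes63.dosage["Mit003"].astype(float)
        feats = pd.DataFrame(
            {"self": dose + rng.normal(0, 1e-6, size=len(dose)), "noise": rng.normal(size=len(dose))},
            index=genotypes63.strain_ids,
        )
        scan = association.scan(feats, genotypes63)
        sub = scan[scan["feature_id"] == "self"]
        best = sub.loc[sub["p"].idxmin(), "marker_id"]
        assert best in ("Mit003",) or (
            genotypes63.dosage[best] == genotypes63.dosage["Mit003"]
        ).all()

    def test_strain_order_and_marker_label_invariance(self, genotypes63, rng):
        feats = pd.DataFrame(
            {"t1": rng.normal(size=63), "t2": rng.normal(size=63)},
            index=genotypes63.strain_ids,
        )
        a = association.scan(feats, genotypes63)
        b = association.scan(feats.iloc[::-1], genotypes63)
        pd.testing.assert_frame_equal(a, b)

    def test_no_shared_strains_errors(self, genotypes63):
        feats = pd.DataFrame({"t": [1.0]}, index=["nope"])
        with pytest.raises(association.AssociationError, match="shared"):
            association.scan(feats, genotypes63)

    def test_null_p_uniform(self, genotypes63, rng):
        """Under the null the per-marker p values are U(0,1)."""
        feats = pd.DataFrame(
            rng.normal(size=(63, 2000)),
            index=genotypes63.strain_ids,
            columns=[f"f{i}" for i in range(2000)],
        )
        scan = association.scan(feats[sorted(feats.columns)], genotypes63)
        p = scan.loc[scan["marker_id"] == "Mit001", "p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_missing_values_fall_back_per_feature(self, genotypes63, rng):
        feats = pd.DataFrame(
            {"t1": rng.normal(size=63), "t2": rng.normal(size=63)},
            index=genotypes63.strain_ids,
        )
        feats.iloc[:5, 1] = np.nan
        scan = association.scan(feats, genotypes63)
        n2 = scan.loc[scan["feature_id"] == "t2", "n"].unique()
        assert list(n2) == [58]


class TestThreshold:
    def test_reproducible_and_validated(self, genotypes63):
        a = association.permutation_threshold(genotypes63, 0.05, 500, seed=3)
        b = association.permutation_threshold(genotypes63, 0.05, 500, seed=3)
        assert a.p_threshold == b.p_threshold
        with pytest.raises(association.AssociationError, match="n_perm"):
            association.permutation_threshold(genotypes63, 0.05, 50, seed=3)
        with pytest.raises(association.AssociationError, match="quantile|n_perm"):
            association.permutation_threshold(genotypes63, 0.001, 200, seed=3)

    def test_single_effective_test_approaches_nominal(self):
        g = make_genotypes({f"m{j}": [0, 0, 0, 0, 1, 1, 1, 1] for j in range(3)})
        thr = association.permutation_threshold(g, 0.10, 4000, seed=5)
        assert thr.p_threshold == pytest.approx(0.10, abs=0.02)

    def test_permute_observed_agrees_under_null(self, genotypes63, rng):
        y = pd.Series(rng.normal(size=63), index=genotypes63.strain_ids)
        shared = association.permutation_threshold(genotypes63, 0.05, 3000, seed=9)
        perfeat = association.permute_observed_threshold(y, genotypes63, 0.05, 3000, seed=9)
        assert perfeat.p_threshold == pytest.approx(shared.p_threshold, abs=0.01)


class TestHits:
    def test_empty_records(self, genotypes63):
        thr = association.permutation_threshold(genotypes63, 0.05, 200, seed=1)
        empty = pd.DataFrame(
            columns=["feature_id", "marker_id", "position_bp", "arm", "n",
                     "beta", "se", "t", "p", "reason"]
        )
        empty.attrs["genotype_fingerprint"] = genotypes63.fingerprint()
        assert association.significant_hits(empty, thr).empty

    def test_strict_inequality_at_threshold(self, genotypes63):
        thr = association.permutation_threshold(genotypes63, 0.05, 200, seed=1)
        rec = pd.DataFrame(
            {
                "feature_id": ["f1"], "marker_id": ["Mit001"], "position_bp": [100],
                "arm": ["Iso"], "n": [63], "beta": [0.1], "se": [0.1], "t": [1.0],
                "p": [thr.p_threshold], "reason": [None],
            }
        )
        rec.attrs["genotype_fingerprint"] = genotypes63.fingerprint()
        assert association.significant_hits(rec, thr).empty

    def test_fingerprint_mismatch_errors(self, genotypes63):
        thr = association.permutation_threshold(genotypes63, 0.05, 200, seed=1)
        rec = pd.DataFrame(
            {
                "feature_id": ["f1"], "marker_id": ["m"], "position_bp": [1],
                "arm": [""], "n": [63], "beta": [0.1], "se": [0.1], "t": [1.0],
                "p": [1e-9], "reason": [None],
            }
        )
        rec.attrs["genotype_fingerprint"] = "different"
        with pytest.raises(association.AssociationError, match="fingerprint"):
            association.significant_hits(rec, thr)

    def test_best_marker_tie_broken_by_position(self, genotypes63):
        thr = association.permutation_threshold(genotypes63, 0.05, 200, seed=1)
        rec = pd.DataFrame(
            {
                "feature_id": ["f1", "f1"],
                "marker_id": ["far", "near"],
                "position_bp": [5000, 100],
                "arm": ["", ""], "n": [63, 63], "beta": [1, 1], "se": [0.1, 0.1],
                "t": [10.0, 10.0], "p": [1e-9, 1e-9], "reason": [None, None],
            }
        )
        rec.attrs["genotype_fingerprint"] = genotypes63.fingerprint()
        hits = association.significant_hits(rec, thr)
        assert list(hits["marker_id"]) == ["near"]
        assert hits.loc[0, "markers_passing"] == "near;far"


def test_multiallelic_marker_uses_joint_f_test():
    """Three founder alleles at one marker: the scan reports an F-derived p
    consistent with one-way ANOVA."""
    cols = [0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2]
    n = len(cols)
    strains = [StrainRecord(f"s{i:02d}", "ABC"[cols[i]]) for i in range(n)]
    alleles = {f: {"A": "A", "B": "C", "C": "G"}.get(f, "A") for f in FOUNDERS}
    mk = MarkerDefinition("m1", 10, alleles)
    g = impute_genotypes(strains, [mk])
    rng = np.random.default_rng(0)
    y = pd.Series(rng.normal(size=n), index=[s.strain_id for s in strains])
    rec = association.fit_marker_association(y, g.dosage["m1"])
    groups = [y.to_numpy()[np.array(cols) == c] for c in (0, 1, 2)]
    f_oracle = stats.f_oneway(*groups)
    assert rec.p == pytest.approx(f_oracle.pvalue, rel=1e-10)
    assert np.isnan(rec.beta)
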