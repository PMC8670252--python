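"""Antisense pairing, Pearson correlation, quadrant classification."""

import numpy as np
import pandas as pd
import pytest

from saltomics.errors import ValidationError
from saltomics.expression import ExpressionTable
from saltomics.features import FeatureSet, FeatureType, GenomicFeature
from saltomics.pairs import (
    CATEGORIES,
    CATEGORY_UNCLASSIFIED,
    classify_pairs,
    find_antisense_pairs,
    pair_correlation,
)


def fset(*triples):
    """triples: (id, type, start, end, strand)"""
    return FeatureSet(
        GenomicFeature(fid, ftype, "chr", s, e, strand)
        for fid, ftype, s, e, strand in triples
    )


class TestFindAntisensePairs:
    def test_basic_overlap(self):
        fs = fset(("a1", FeatureType.asRNA, 100, 200, "-"),
                  ("m1", FeatureType.mRNA, 150, 400, "+"))
        out = find_antisense_pairs(fs)
        assert len(out) == 1
        assert out.iloc[0].overlap_bp == 50

    def test_half_open_adjacency_is_no_pair(self):
        fs = fset(("a1", FeatureType.asRNA, 100, 200, "-"),
                  ("m1", FeatureType.mRNA, 200, 400, "+"))
        assert len(find_antisense_pairs(fs)) == 0

    def test_three_prime_end_overlap_still_pairs(self):
        # an asRNA starting downstream of the gene but covering its 3' end
        fs = fset(("m1", FeatureType.mRNA, 1000, 2000, "+"),
                  ("a1", FeatureType.asRNA, 1900, 2500, "-"))
        out = find_antisense_pairs(fs)
        assert len(out) == 1 and out.iloc[0].overlap_bp == 100

    def test_same_strand_never_pairs(self):
        fs = fset(("a1", FeatureType.asRNA, 100, 200, "+"),
                  ("m1", FeatureType.mRNA, 150, 400, "+"))
        assert len(find_antisense_pairs(fs)) == 0

    def test_multi_mrna_asrna_yields_multiple_records(self):
        fs = fset(("a1", FeatureType.asRNA, 100, 500, "-"),
                  ("m1", FeatureType.mRNA, 50, 200, "+"),
                  ("m2", FeatureType.mRNA, 300, 600, "+"))
        out = find_antisense_pairs(fs)
        assert sorted(out.mrna_id) == ["m1", "m2"]


class TestPairCorrelation:
    def test_self_and_negation(self):
        v = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        assert pair_correlation(v, v) == pytest.approx(1.0)
        assert pair_correlation(v, -v) == pytest.approx(-1.0)

    def test_linear_scaling(self):
        assert pair_correlation([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12]) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.normal(size=(2, 6))
            num = ((a - a.mean()) * (b - b.mean())).sum()
            den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
            assert pair_correlation(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_degenerate_inputs(self):
        assert np.isnan(pair_correlation([1, 1, 1, 1], [1, 2, 3, 4]))
        assert np.isnan(pair_correlation([1, np.nan, 3, 4], [1, 2, 3, 4]))
        with pytest.raises(ValidationError):
            pair_correlation([1, 2, 3], [1, 2])


def make_per_rep(profiles):
    cols = pd.MultiIndex.from_tuples(
        [(0.5, 1), (0.5, 2), (2.0, 1), (2.0, 2), (24.0, 1), (24.0, 2)],
        names=["timepoint", "replicate"],
    )
    return ExpressionTable(pd.DataFrame(profiles, columns=cols), value_kind="log2fc")


def classify_oracle(pairs, profiles, assignments, directions, de_ids, r_min=0.65):
    """Brute-force reimplementation of the classification rules."""
    out = {}
    for _, row in pairs.iterrows():
        a, m = row.asrna_id, row.mrna_id
        pa, pm = np.asarray(profiles[a]), np.asarray(profiles[m])
        if np.std(pa) == 0 or np.std(pm) == 0:
            r = np.nan
        else:
            r = np.corrcoef(pa, pm)[0, 1]
        cat = CATEGORY_UNCLASSIFIED
        if (
            assignments.get(a) is not None
            and assignments.get(m) is not None
            and a in de_ids
            and m in de_ids
            and not np.isnan(r)
            and abs(r) >= r_min
        ):
            da, dm = directions[assignments[a]], directions[assignments[m]]
            if da != dm and r <= -r_min:
                cat = "as_up_m_down" if da == "induced" else "as_down_m_up"
            elif da == dm and r >= r_min:
                cat = "both_up" if da == "induced" else "both_down"
        out[(a, m)] = cat
    return out


def random_instance(rng, n_pairs=20):
    triples = []
    profiles = {}
    assignments = {}
    de_ids = set()
    rows = []
    directions = ("induced", "induced", "repressed", "repressed")
    for i in range(n_pairs):
        a, m = f"a{i}", f"m{i}"
        base = i * 1000
        triples.append((m, FeatureType.mRNA, base, base + 400, "+"))
        triples.append((a, FeatureType.asRNA, base + 100, base + 300, "-"))
        for fid in (a, m):
            profiles[fid] = rng.normal(0, 1, 6)
            if rng.random() < 0.8:
                assignments[fid] = int(rng.integers(4))
            if rng.random() < 0.8:
                de_ids.add(fid)
        rows.append((a, m))
    fs = FeatureSet(
        GenomicFeature(t[0], t[1], "chr", t[2], t[3], t[4]) for t in triples
    )
    return fs, profiles, assignments, de_ids, directions


class TestClassifyPairs:
    DIRECTIONS = ("induced", "induced", "repressed", "repressed")

    def run(self, profiles, assignments, de_feature_ids, r_min=0.65):
        ids = list(profiles)
        table = make_per_rep([profiles[i] for i in ids])
        table.data.index = pd.Index(ids)
        pairs = find_antisense_pairs(self.features)
        assign = pd.Series(
            {i: assignments.get(i, pd.NA) for i in ids}, dtype="Int64"
        )
        de = pd.DataFrame(
            [dict(feature_id=i, timepoint=0.5, log2fc=2.0, p_value=0.01,
                  p_adjusted=0.02, status="up") for i in de_feature_ids]
        )
        if de.empty:
            de = pd.DataFrame(columns=["feature_id", "timepoint", "log2fc",
                                       "p_value", "p_adjusted", "status"])
        return classify_pairs(pairs, table, assign, self.DIRECTIONS, de, r_min)

    features = fset(("a0", FeatureType.asRNA, 100, 300, "-"),
                    ("m0", FeatureType.mRNA, 50, 400, "+"))

    def test_inverse_pair_classified(self):
        v = np.array([2.0, 2.1, 1.0, 1.1, 0.1, 0.0])
        out = self.run({"a0": v, "m0": -v}, {"a0": 0, "m0": 2}, {"a0", "m0"})
        assert out.iloc[0].category == "as_up_m_down"

    def test_below_threshold_boundary(self):
        rng = np.random.default_rng(1)
        # construct two vectors with r just below 0.65
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for _ in range(1000):
            b = a + rng.normal(0, 2.4, 6)
            r = np.corrcoef(a, b)[0, 1]
            if 0.55 < r < 0.649:
                break
        out = self.run({"a0": a, "m0": b}, {"a0": 0, "m0": 1}, {"a0", "m0"})
        assert out.iloc[0].category == CATEGORY_UNCLASSIFIED

    def test_ineligible_without_cluster(self):
        v = np.array([2.0, 2.1, 1.0, 1.1, 0.1, 0.0])
        out = self.run({"a0": v, "m0": v}, {"m0": 1}, {"a0", "m0"})
        assert not out.iloc[0].eligible
        assert out.iloc[0].category == CATEGORY_UNCLASSIFIED

    def test_ineligible_without_de(self):
        v = np.array([2.0, 2.1, 1.0, 1.1, 0.1, 0.0])
        out = self.run({"a0": v, "m0": v}, {"a0": 0, "m0": 1}, {"a0"})
        assert not out.iloc[0].eligible

    def test_matches_brute_force_oracle(self):
        """Random 20-pair instances classified identically by an independent
        rule-by-rule reimplementation."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            fs, profiles, assignments, de_ids, directions = random_instance(rng)
            pairs = find_antisense_pairs(fs)
            ids = list(profiles)
            table = make_per_rep([profiles[i] for i in ids])
            table.data.index = pd.Index(ids)
            assign = pd.Series({i: assignments.get(i, pd.NA) for i in ids}, dtype="Int64")
            de = pd.DataFrame(
                [dict(feature_id=i, timepoint=0.5, log2fc=2.0, p_value=0.01,
                      p_adjusted=0.02, status="up") for i in sorted(de_ids)]
            )
            got = classify_pairs(pairs, table, assign, directions, de)
            expected = classify_oracle(pairs, profiles, assignments, directions, de_ids)
            for _, row in got.iterrows():
                assert row.category == expected[(row.asrna_id, row.mrna_id)]

    def test_counts_conservation(self):
        """Eligible pairs = sum over quadrants + eligible-but-weak-r."""
        rng = np.random.default_rng(3)
        fs, profiles, assignments, de_ids, directions = random_instance(rng, 30)
        pairs = find_antisense_pairs(fs)
        ids = list(profiles)
        table = make_per_rep([profiles[i] for i in ids])
        table.data.index = pd.Index(ids)
        assign = pd.Series({i: assignments.get(i, pd.NA) for i in ids}, dtype="Int64")
        de = pd.DataFrame(
            [dict(feature_id=i, timepoint=0.5, log2fc=2.0, p_value=0.01,
                  p_adjusted=0.02, status="up") for i in sorted(de_ids)]
        )
        out = classify_pairs(pairs, table, assign, directions, de)
        eligible = out[out.eligible]
        in_quadrant = eligible.category.isin(CATEGORIES).sum()
        weak = (eligible.category == CATEGORY_UNCLASSIFIED).sum()
        assert in_quadrant + weak == len(eligible)
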