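"""tRNA-fragment analytics: coverage, end classes, clustering, probe cores."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mitosrna as m
from mitosrna.genome import Feature, GenomeAnnotation
from mitosrna.trf import classify_end


def _mini_genome():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    feats = [Feature("t_h", "tRNA", 20, 80, "heavy", "tRNA-x"),
             Feature("t_l", "tRNA", 100, 160, "light", "tRNA-y")]
    return GenomeAnnotation(seq, features=feats, name="g")


class TestCoverageProfile:
    def _setup(self, genome, seq, count):
        cat = m.build_catalog([seq], genome)
        norm = pd.DataFrame({"s1": [count]}, index=[seq], dtype=float)
        return cat, norm

    def test_single_read_rectangular_profile(self):
        g = _mini_genome()
        seq = g.sequence[30:50]
        cat, norm = self._setup(g, seq, 5.0)
        prof = m.coverage_profile(cat, norm, g, "t_h", ["s1"], flank=5)
        # feature positions 10..29 (read at genome 30..50, feature starts at 20)
        assert (prof.loc[10:29] == 5.0).all()
        assert prof.drop(prof.loc[10:29].index).sum() == 0

    def test_conservation_of_mass(self, toy_genome, truth):
        cat = m.build_catalog(truth["sequence"], toy_genome)
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(rng.uniform(0, 10, size=(len(truth), 2)),
                            index=truth["sequence"], columns=["s1", "s2"])
        flank = 5
        fid = next(f for f in truth["parent_feature_id"].unique()
                   if toy_genome.feature(f).start >= flank
                   and toy_genome.feature(f).end <= len(toy_genome) - flank)
        feat = toy_genome.feature(fid)
        prof = m.coverage_profile(cat, norm, toy_genome, fid, ["s1", "s2"], flank)
        # independent recount: weight x overlap length with the window
        expected = 0.0
        for seq, row in cat.table.iterrows():
            w = float(norm.loc[seq].sum())
            lo, hi = feat.start - flank, feat.end + flank
            ov = max(0, min(hi, row["end"]) - max(lo, row["start"]))
            expected += w * ov
        assert prof.sum() == pytest.approx(expected)

    def test_empty_sample_set_gives_zero_profile(self):
        g = _mini_genome()
        cat, norm = self._setup(g, g.sequence[30:50], 5.0)
        prof = m.coverage_profile(cat, norm, g, "t_h", [])
        assert (prof == 0).all()

    def test_unknown_feature_raises(self):
        g = _mini_genome()
        cat, norm = self._setup(g, g.sequence[30:50], 5.0)
        with pytest.raises(KeyError):
            m.coverage_profile(cat, norm, g, "nope", ["s1"])


class TestClassifyEnd:
    def test_three_prime_at_feature_end(self):
        g = _mini_genome()
        f = g.feature("t_h")
        assert classify_end(f.end - 20, f.end, f, len(g)) == "three_prime"

    def test_five_prime_with_tolerance(self):
        g = _mini_genome()
        f = g.feature("t_h")
        assert classify_end(f.start + 2, f.start + 22, f, len(g)) == "five_prime"

    def test_full_length(self):
        g = _mini_genome()
        f = g.feature("t_h")
        assert classify_end(f.start, f.end, f, len(g)) == "full_length"

    def test_internal(self):
        g = _mini_genome()
        f = g.feature("t_h")
        assert classify_end(f.start + 10, f.start + 30, f, len(g)) == "internal"

    def test_no_overlap_raises(self):
        g = _mini_genome()
        f = g.feature("t_h")
        with pytest.raises(ValueError):
            classify_end(f.end + 5, f.end + 25, f, len(g))

    def test_orientation_consistency_on_light_strand(self):
        """The same fragment keeps its class when the feature is flipped."""
        g = _mini_genome()
        f = g.feature("t_l")  # light strand: feature 5' end is at f.end
        # fragment at the feature's 3' end = heavy-coordinate start of the feature
        assert classify_end(f.start, f.start + 20, f, len(g)) == "three_prime"
        assert classify_end(f.end - 20, f.end, f, len(g)) == "five_prime"

    def test_planted_end_classes_recovered(self, toy_genome, truth):
        for _, row in truth.iterrows():
            hits = m.exact_align(row["sequence"], toy_genome)
            feat = toy_genome.feature(row["parent_feature_id"])
            hit = next(h for h in hits
                       if interlocks(h, feat, len(toy_genome)))
            got = classify_end(hit.start, hit.end, feat, len(toy_genome), tau=2)
            assert got == row["end_class"], row["variant_id"]


def interlocks(hit, feat, L):
    a = {(hit.start + i) % L for i in range(hit.end - hit.start)}
    b = {p % L for p in range(feat.start, feat.end)}
    return bool(a & b)


class TestClusterExpression:
    def _patterns(self, n_per=10, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[4.0, 0, 0, 0], [0, 4.0, 0, 0], [0, 0, 0, 4.0]])
        rows, labels = [], []
        for ci, c in enumerate(centers):
            for _ in range(n_per):
                rows.append(c + rng.normal(0, noise, size=4))
                labels.append(ci)
        return pd.DataFrame(rows), np.array(labels)

    def test_recovers_well_separated_planted_partition(self):
        x, labels = self._patterns()
        model = m.cluster_expression(x, k=3, seed=1)
        # perfect agreement up to label permutation
        mapping = {}
        for lab in np.unique(labels):
            got = model.assignments[labels == lab]
            assert got.nunique() == 1
            mapping[lab] = got.iloc[0]
        assert len(set(mapping.values())) == 3

    def test_k_equals_rows_gives_zero_wcss(self):
        x = pd.DataFrame(np.eye(4) * 3.0)
        model = m.cluster_expression(x, k=4, seed=0)
        assert model.wcss == pytest.approx(0.0)

    def test_deterministic_under_seed(self):
        x, _ = self._patterns(noise=1.0, seed=3)
        a = m.cluster_expression(x, k=3, seed=5)
        b = m.cluster_expression(x, k=3, seed=5)
        assert (a.assignments == b.assignments).all()

    def test_k_larger_than_rows_raises(self):
        with pytest.raises(ValueError):
            m.cluster_expression(pd.DataFrame(np.ones((2, 3))), k=5)

    def test_rows_assigned_to_nearest_centroid(self):
        x, _ = self._patterns(noise=0.5, seed=2)
        model = m.cluster_expression(x, k=3, seed=0)
        d = ((x.to_numpy()[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        assert (d.argmin(axis=1) == model.assignments.to_numpy()).all()


def lcs_oracle(seqs):
    """Longest common substring length by substring-set intersection."""
    def subs(s):
        return {s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1)}
    common = set.intersection(*(subs(s) for s in seqs))
    return max((len(s) for s in common), default=0)


class TestConservedCore:
    def test_single_sequence_is_its_own_core(self):
        pc = m.find_conserved_core(["ACGTACGT"])
        assert pc.core == "ACGTACGT"
        assert pc.probe == m.revcomp("ACGTACGT")

    def test_jittered_variant_triple(self):
        """Core of end-jittered variants; value frozen from the substring
        oracle (the second variant lacks the leading A, so 16 nt here)."""
        seqs = ["AAGTCCCGGCTGGCGAATTT", "GTCCCGGCTGGCGAATAC",
                "TAGTCCCGGCTGGCGAAT"]
        pc = m.find_conserved_core(seqs)
        assert pc.core_length == lcs_oracle(seqs) == 16
        assert all(pc.core in s for s in seqs)
        assert pc.probe == m.revcomp(pc.core)

    def test_disjoint_sequences_flagged_degenerate(self):
        pc = m.find_conserved_core(["AAAA", "CCCC"])
        assert pc.core_length == 0
        assert pc.degenerate

    def test_leftmost_tie_break(self):
        # two disjoint common 2-mers; the leftmost in the first sequence wins
        pc = m.find_conserved_core(["ACTTGG", "GGAAAC"])
        assert pc.core == "AC"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dynamic_programming_oracle(self, seed):
        rng = np.random.default_rng(seed)
        motif = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 9))))
        seqs = []
        for _ in range(3):
            n = int(rng.integers(8, 30))
            s = "".join(rng.choice(list("ACGT"), size=n))
            if rng.random() < 0.7:  # usually embed a shared motif
                i = int(rng.integers(0, n - 1))
                s = s[:i] + motif + s[i:]
            seqs.append(s[:30])
        assert m.find_conserved_core(seqs).core_length == lcs_oracle(seqs)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            m.find_conserved_core([])


class TestMitosFraction:
    def _norm(self):
        return pd.DataFrame({"s1": [10.0, 30.0], "s2": [20.0, 40.0]},
                            index=["a", "b"])

    def test_all_mito_is_one(self):
        flags = pd.Series({"a": "mito", "b": "mito"})
        assert m.mitos_fraction(self._norm(), flags, ["s1", "s2"]) == 1.0

    def test_no_mito_is_zero(self):
        flags = pd.Series({"a": "decoy", "b": "decoy"})
        assert m.mitos_fraction(self._norm(), flags, ["s1"]) == 0.0

    def test_recount(self):
        flags = pd.Series({"a": "mito", "b": "decoy"})
        got = m.mitos_fraction(self._norm(), flags, ["s1", "s2"])
        assert got == pytest.approx((10 + 20) / (10 + 20 + 30 + 40))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            m.mitos_fraction(self._norm(), pd.Series({"a": "mito"}), [])


class TestTraitCorrelation:
    def _traits(self, values):
        return pd.DataFrame({"lt50": values},
                            index=pd.Index(["D2", "WS36", "WS40", "WS42"],
                                           name="stage"))

    def test_perfect_positive(self):
        frac = pd.Series([0.1, 0.2, 0.3, 0.4], index=["D2", "WS36", "WS40", "WS42"])
        r, p = m.trait_correlation(frac, self._traits([1, 2, 3, 4]), "lt50")
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        frac = pd.Series([1.0, 2.0, 3.0, 4.0], index=["D2", "WS36", "WS40", "WS42"])
        r, p = m.trait_correlation(frac, self._traits([4, 3, 2, 1]), "lt50")
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=4)
        y = rng.uniform(size=4)
        frac = pd.Series(x, index=["D2", "WS36", "WS40", "WS42"])
        r, p = m.trait_correlation(frac, self._traits(y), "lt50")
        rx = x - x.mean()
        ry = y - y.mean()
        r_hand = (rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        t = r_hand * np.sqrt(2 / (1 - r_hand ** 2))
        from scipy import stats
        p_hand = 2 * stats.t.sf(abs(t), df=2)
        assert r == pytest.approx(r_hand)
        assert p == pytest.approx(p_hand)

    def test_too_few_points_raises(self):
        frac = pd.Series([0.1, 0.2], index=["D2", "WS36"])
        with pytest.raises(ValueError):
            m.trait_correlation(frac, self._traits([1, 2, 3, 4]), "lt50")

    def test_zero_variance_flagged(self):
        frac = pd.Series([0.5] * 4, index=["D2", "WS36", "WS40", "WS42"])
        r, p = m.trait_correlation(frac, self._traits([1, 2, 3, 4]), "lt50")
        assert np.isnan(r)
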