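"""Decision trees: split selection vs exhaustive oracle, pruning, CV."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from vagv6.dtree import (accuracy, best_split, cross_validate, induce_tree,
                         ph_odor_trees, predict, prune_tree)


def split_oracle(features, labels, min_leaf=2):
    """Independent exhaustive search for the maximum-gain-ratio split,
    including the numeric-threshold MDL penalty."""
    def ent(ys):
        n = len(ys)
        return -sum((c / n) * math.log2(c / n)
                    for c in Counter(ys).values())

    n = len(labels)
    base = ent(labels)
    best = None
    for feat in features.columns:
        x = features[feat].to_numpy(float)
        svals = sorted(set(x))
        m = len(svals) - 1
        if m <= 0:
            continue
        for lo, hi in zip(svals, svals[1:]):
            thr = (lo + hi) / 2
            mask = x <= thr
            k = int(mask.sum())
            if k < min_leaf or n - k < min_leaf:
                continue
            gain = base - (k / n) * ent(labels[mask]) \
                - ((n - k) / n) * ent(labels[~mask]) - math.log2(m) / n
            if gain <= 1e-12:
                continue
            p = k / n
            si = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
            cand = (gain / si, gain, feat, thr)
            if best is None or cand[:2] > best[:2]:
                best = cand
    return best


class TestBestSplit:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(8):
            n = 60
            X = pd.DataFrame(rng.random((n, 4)), columns=list("abcd"))
            y = np.where(X["b"] + 0.3 * rng.random(n) < 0.6, "u", "v")
            got = best_split(X, y)
            want = split_oracle(X, y)
            assert (got is None) == (want is None)
            if got is not None:
                ratio_w, _, feat_w, thr_w = want
                assert got[0] == feat_w
                assert got[1] == pytest.approx(thr_w)
                assert got[2] == pytest.approx(ratio_w)

    def test_no_split_on_constant_labels(self):
        X = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.4]})
        assert best_split(X, np.array(["x"] * 4)) is None


class TestInduce:
    def test_constant_labels_single_leaf(self):
        X = pd.DataFrame({"a": np.linspace(0, 1, 10)})
        t = induce_tree(X, np.array(["x"] * 10))
        assert t.is_leaf and t.label == "x"

    def test_separable_data_one_split(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.random(100), "g": rng.random(100)})
        y = np.where(X["f"] < 0.5, "lo", "hi")
        t = induce_tree(X, y)
        assert t.feature == "f"
        assert accuracy(t, X, y) == 1.0

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            induce_tree(pd.DataFrame(index=range(4)), np.array(["x"] * 4))

    def test_prediction_deterministic(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((50, 3)), columns=list("abc"))
        y = np.where(X["a"] < 0.4, "p", "q")
        t = induce_tree(X, y)
        assert (predict(t, X) == predict(t, X)).all()


class TestPrune:
    def test_noise_labels_pruned_to_tiny_tree(self):
        """Balanced pure-noise labels: the pruned tree collapses to at most
        three nodes."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((200, 5)), columns=list("abcde"))
        y = rng.permutation(np.array(["x", "y"] * 100))
        t = prune_tree(induce_tree(X, y))
        assert t.n_nodes() <= 3

    def test_separable_data_untouched(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.random(100)})
        y = np.where(X["f"] < 0.5, "lo", "hi")
        raw = induce_tree(X, y)
        pruned = prune_tree(raw)
        assert pruned.n_nodes() == raw.n_nodes() == 3
        assert accuracy(pruned, X, y) == 1.0

    def test_single_leaf_passthrough(self):
        X = pd.DataFrame({"a": [0.1, 0.9, 0.5, 0.2]})
        t = induce_tree(X, np.array(["x"] * 4))
        assert prune_tree(t).is_leaf


class TestCrossValidate:
    def test_separable_data_perfect_cv(self):
        # separable with a clear margin around the class boundary
        rng = np.random.default_rng(4)
        f = np.concatenate([rng.uniform(0, 0.45, 40),
                            rng.uniform(0.55, 1, 40)])
        X = pd.DataFrame({"f": f, "g": rng.random(80)})
        y = np.where(X["f"] < 0.5, "lo", "hi")
        rep = cross_validate(X, y, seed=0)
        assert rep.cv_accuracy == 1.0
        assert rep.training_accuracy == 1.0

    def test_label_permutation_near_chance(self):
        """Permuted labels: CV accuracy within 3 SE of the majority rate."""
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.random((200, 4)), columns=list("abcd"))
        y = rng.permutation(np.array(["x"] * 120 + ["y"] * 80))
        rep = cross_validate(X, y, seed=1)
        maj = 0.6
        se = math.sqrt(maj * (1 - maj) / 200)
        assert abs(rep.cv_accuracy - maj) <= 3 * se

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((60, 3)), columns=list("abc"))
        y = np.where(X["a"] + 0.2 * rng.random(60) < 0.5, "p", "q")
        r1 = cross_validate(X, y, seed=5)
        r2 = cross_validate(X, y, seed=5)
        assert r1.cv_accuracy == r2.cv_accuracy

    def test_small_class_falls_back_unstratified(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.random(30)})
        y = np.array(["rare"] * 3 + ["common"] * 27)
        with pytest.warns(UserWarning, match="unstratified"):
            cross_validate(X, y, k=10, seed=0)


class TestClinicalTrees:
    def test_wired_rule_structure_recovered(self, panel):
        """A cohort generated with the published rule structure (pH is low
        iff L. crispatus is abundant, or failing that L. iners dominates)
        yields a pH tree whose top splits are those two organisms."""
        rng = np.random.default_rng(9)
        from vagv6 import synthetic
        from vagv6.synthetic import CLINICAL_COLUMNS

        rows = []
        names = [t.name for t in panel]
        arch = synthetic.default_archetypes(panel)
        for i in range(220):
            a = arch[int(rng.integers(len(arch)))]
            p = synthetic.sample_community(a, rng, panel)
            crisp = p[names.index("Lactobacillus crispatus")]
            iners = p[names.index("Lactobacillus iners")]
            low_ph = crisp > 0.136 or iners > 0.488
            counts = rng.multinomial(20000, p)
            row = {"followup": 0, "subject_id": f"P{i}",
                   "sample_id": f"S{i}", "nugent": 0,
                   "amsel_discharge": np.nan, "amsel_odor": np.nan,
                   "amsel_clue": np.nan,
                   "ph": 4.0 if low_ph else 5.0, "amsel_score": np.nan,
                   "total_reads": int(counts.sum())}
            row.update({nm: int(c) for nm, c in zip(names, counts)})
            rows.append(row)
        df = pd.DataFrame(rows)[CLINICAL_COLUMNS + names]
        cohort = synthetic.CohortTable(df, names)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = ph_odor_trees(cohort, seed=0)
        tree = reports["ph"].tree
        top = {tree.feature}
        if not tree.low.is_leaf:
            top.add(tree.low.feature)
        if not tree.high.is_leaf:
            top.add(tree.high.feature)
        assert "Lactobacillus crispatus" in top
        assert "Lactobacillus iners" in top
        assert reports["ph"].training_accuracy > 0.9
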