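import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abcfam import synthetic
from abcfam.compare import family_size_tests, kruskal_wallis, posthoc_letters
from abcfam.errors import ValidationError
from abcfam.pipeline import FamilySizeMatrix


class TestKruskalWallis:
    def test_worked_two_group_example(self):
        res = kruskal_wallis({"A": [1, 2], "B": [3, 4]})
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_identical_multisets_give_zero(self):
        res = kruskal_wallis({"A": [1, 5, 9], "B": [9, 1, 5]})
        assert res.H == pytest.approx(0.0)

    def test_monotone_transform_invariance(self):
        data = {"A": [1.0, 2.5, 3.0], "B": [4.0, 0.5], "C": [2.0, 6.0]}
        transformed = {g: [np.exp(v) for v in vs] for g, vs in data.items()}
        assert kruskal_wallis(data).H == pytest.approx(
            kruskal_wallis(transformed).H, abs=1e-12
        )

    def test_all_identical_values(self):
        res = kruskal_wallis({"A": [3, 3], "B": [3, 3]})
        assert res.H == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_with_and_without_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            if rng.random() < 0.5:  # ties
                data = {f"g{i}": rng.integers(0, 6, int(rng.integers(3, 12))).astype(float)
                        for i in range(k)}
            else:
                data = {f"g{i}": rng.standard_normal(int(rng.integers(3, 12)))
                        for i in range(k)}
            try:
                expected = stats.kruskal(*data.values())
            except ValueError:  # scipy refuses all-identical data
                continue
            res = kruskal_wallis(data)
            assert res.H == pytest.approx(expected.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(expected.pvalue, abs=1e-9)

    def test_single_group_raises(self):
        with pytest.raises(ValidationError):
            kruskal_wallis({"A": [1, 2, 3]})


class TestPosthocLetters:
    def test_identical_groups_share_a_letter(self):
        data = synthetic.make_grouped_counts(3, k_groups=4, n_per_group=10,
                                             base_mean=8.0)
        letters = posthoc_letters(data)
        assert set(letters.values()) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        data = {"lo": list(range(1, 11)), "hi": list(range(100, 110))}
        letters = posthoc_letters(data)
        assert letters["lo"] != letters["hi"]
        assert not set(letters["lo"]) & set(letters["hi"])

    def test_letters_contiguous_along_rank_order(self):
        rng = np.random.default_rng(8)
        data = {"a": (rng.poisson(4, 12) + 0.0).tolist(),
                "b": (rng.poisson(8, 12) + 0.0).tolist(),
                "c": (rng.poisson(16, 12) + 0.0).tolist(),
                "d": (rng.poisson(40, 12) + 0.0).tolist()}
        letters = posthoc_letters(data)
        mean_ranks = kruskal_wallis(data).mean_ranks
        order = sorted(data, key=lambda g: -mean_ranks[g])
        for letter in set("".join(letters.values())):
            members = [i for i, g in enumerate(order) if letter in letters[g]]
            assert members == list(range(members[0], members[-1] + 1))

    def test_relabelling_symmetry(self):
        data = {"x": [1.0, 2, 3, 8], "y": [4.0, 5, 6, 7], "z": [20.0, 21, 22, 23]}
        letters = posthoc_letters(data)
        renamed = {"z": data["z"], "y": data["y"], "x": data["x"]}
        assert posthoc_letters(renamed) == letters

    def test_constant_shift_invariance(self):
        data = {"x": [1.0, 2, 3], "y": [9.0, 10, 11], "z": [2.0, 3, 4]}
        shifted = {g: [v + 100 for v in vs] for g, vs in data.items()}
        assert posthoc_letters(shifted) == posthoc_letters(data)

    def test_highest_mean_rank_gets_letter_a(self):
        data = {"lo": list(range(1, 11)), "hi": list(range(100, 110))}
        letters = posthoc_letters(data)
        assert letters["hi"] == "a"


def _matrix(seed, shift_family=None, shift=0, orders=("Diptera", "Hemiptera",
                                                      "Lepidoptera", "Coleoptera"),
            n_per_order=12):
    rng = np.random.default_rng(seed)
    rows, meta_rows = {}, {}
    means = {"A": 8, "BF": 4, "BH": 6, "C": 14, "D": 4, "E": 1, "F": 3, "G": 15, "H": 3}
    for oi, order in enumerate(orders):
        for i in range(n_per_order):
            sp = f"{order[:3]}{i}"
            counts = {}
            for fam, mu in means.items():
                bump = shift if (fam == shift_family and oi == 0) else 0
                counts[fam] = int(rng.poisson(mu + bump))
            counts["total"] = sum(counts.values())
            rows[sp] = counts
            meta_rows[sp] = {"taxon_order": order, "busco_single_copy_pct": 95.0}
    return FamilySizeMatrix(
        counts=pd.DataFrame.from_dict(rows, orient="index"),
        meta=pd.DataFrame.from_dict(meta_rows, orient="index"),
    )


class TestFamilySizeTests:
    def test_constant_family_has_zero_h(self):
        m = _matrix(1)
        m.counts["E"] = 2
        table = family_size_tests(m)
        assert (table.loc[table.family == "E", "H"] == 0).all()

    def test_shifted_family_flagged_significant(self):
        """A +8 shift in one order's BF counts is detected; power over seeds."""
        hits = 0
        false_hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table = family_size_tests(_matrix(seed, shift_family="BF", shift=8),
                                      adjust_across_families=False)
            per_family = table.drop_duplicates("family").set_index("family")
            if per_family.loc["BF", "p_value"] < 0.05:
                hits += 1
            quiet = [f for f in ("A", "D", "E", "F", "H") ]
            false_hits += sum(per_family.loc[f, "p_value"] < 0.05 for f in quiet)
        assert hits >= 95
        assert false_hits / (n_seeds * 5) < 0.15

    def test_small_groups_dropped(self):
        # every order below min_group_n species -> nothing testable
        table = family_size_tests(_matrix(2, n_per_order=2))
        assert table.empty

    def test_empty_matrix_raises(self):
        empty = FamilySizeMatrix(counts=pd.DataFrame(), meta=pd.DataFrame())
        with pytest.raises(ValidationError):
            family_size_tests(empty)

    def test_across_family_bonferroni(self):
        m = _matrix(3)
        table = family_size_tests(m)
        per_family = table.drop_duplicates("family")
        for _, row in per_family.iterrows():
            assert row.p_adjusted == pytest.approx(min(1.0, row.p_value * 10))
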