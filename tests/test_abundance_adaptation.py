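from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import pytest

from hostadapt import (
    NON_ADAPTED,
    OtuTable,
    ValidationError,
    adapted_label,
    classify_abundance,
    classify_abundance_table,
    pairwise_rank_test,
    replace_zeros,
    shared_label,
)
from hostadapt.abundance_adaptation import PairwiseTestResult, decide_label

HOSTS = ("chicken", "human", "pig")
PAIRS = [frozenset(p) for p in combinations(HOSTS, 2)]


class TestReplaceZeros:
    def test_zero_becomes_inverse_depth(self):
        counts = pd.DataFrame({"s": [0, 10000]}, index=["a", "b"])
        zr = replace_zeros(OtuTable(counts, {"s": "human"}))
        assert zr.fractions.at["a", "s"] == pytest.approx(0.0001)
        assert zr.replaced.at["a", "s"]

    def test_observed_cell_is_count_over_depth(self):
        counts = pd.DataFrame({"s": [50, 9950]}, index=["a", "b"])
        zr = replace_zeros(OtuTable(counts, {"s": "human"}))
        assert zr.fractions.at["a", "s"] == pytest.approx(0.005)
        assert not zr.replaced.at["a", "s"]

    def test_positivity_and_replacement_equality(self, make_random_table):
        table = make_random_table(2)
        zr = replace_zeros(table)
        assert (zr.fractions > 0).all().all()
        inv_depth = 1.0 / table.depths
        for otu, sample in zip(*np.nonzero(zr.replaced.to_numpy())):
            assert (
                zr.fractions.iat[otu, sample] == inv_depth.iloc[sample]
            )


class TestPairwiseRankTest:
    def test_identical_groups_not_significant(self):
        res = pairwise_rank_test([1, 2, 3, 4], [1, 2, 3, 4], alpha=0.01)
        assert res.p_value >= 0.99
        assert not res.significant
        assert res.higher_host is None

    def test_exact_p_matches_permutation_enumeration(self):
        # enumerate all 8!/(4!4!) labelings of the pooled ranks
        pooled = list(range(1, 9))
        observed = sum(pooled[:4])
        mean_sum = sum(pooled) / 2
        hits = total = 0
        for idx in combinations(range(8), 4):
            total += 1
            if abs(sum(pooled[i] for i in idx) - mean_sum) >= abs(observed - mean_sum):
                hits += 1
        expected = hits / total  # = 2/70
        res = pairwise_rank_test([1, 2, 3, 4], [5, 6, 7, 8], host_a="a", host_b="b")
        assert res.p_value == pytest.approx(expected, abs=1e-12)
        assert res.higher_host == "b"

    @pytest.mark.parametrize("p,expected", [(0.009, True), (0.010, False)])
    def test_significance_is_strictly_below_alpha(self, p, expected):
        res = PairwiseTestResult("a", "b", p_value=p, higher_host="a", alpha=0.01)
        assert res.significant is expected

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            pairwise_rank_test([1.0], [1.0, 2.0])


def _all_patterns():
    """Every combination of pairwise outcomes: each pair is either
    non-significant or significant with one of its two hosts higher."""
    states_per_pair = []
    for pair in PAIRS:
        a, b = sorted(pair)
        states_per_pair.append([(False, None), (True, a), (True, b)])
    for combo in product(*states_per_pair):
        sig = {pair: s for pair, (s, _) in zip(PAIRS, combo)}
        higher = {pair: h for pair, (_, h) in zip(PAIRS, combo)}
        yield sig, higher


def _matching_rules(sig, higher):
    """Independent re-statement of the rule table; returns all rules that fire."""
    fired = []
    for h in HOSTS:
        others = [o for o in HOSTS if o != h]
        if all(sig[frozenset((h, o))] for o in others) and all(
            higher[frozenset((h, o))] == h for o in others
        ):
            fired.append(adapted_label(h))
    for h1, h2 in combinations(HOSTS, 2):
        (h3,) = set(HOSTS) - {h1, h2}
        if (
            sig[frozenset((h1, h3))] and higher[frozenset((h1, h3))] == h1
            and sig[frozenset((h2, h3))] and higher[frozenset((h2, h3))] == h2
            and not sig[frozenset((h1, h2))]
        ):
            fired.append(shared_label(h1, h2))
    return fired


class TestRuleEngine:
    def test_every_pattern_yields_exactly_one_label(self):
        n = 0
        for sig, higher in _all_patterns():
            fired = _matching_rules(sig, higher)
            assert len(fired) <= 1, f"ambiguous pattern {sig} {higher}: {fired}"
            label = decide_label(HOSTS, sig, higher)
            assert label == (fired[0] if fired else NON_ADAPTED)
            n += 1
        assert n == 27

    def test_adapted_regardless_of_third_pair(self):
        # chicken significantly above human and pig; human-vs-pig outcome irrelevant
        for hp_state in [(False, None), (True, "human"), (True, "pig")]:
            sig = {
                frozenset(("chicken", "human")): True,
                frozenset(("chicken", "pig")): True,
                frozenset(("human", "pig")): hp_state[0],
            }
            higher = {
                frozenset(("chicken", "human")): "chicken",
                frozenset(("chicken", "pig")): "chicken",
                frozenset(("human", "pig")): hp_state[1],
            }
            assert decide_label(HOSTS, sig, higher) == adapted_label("chicken")

    def test_shared_pair_above_third_host(self):
        sig = {
            frozenset(("chicken", "human")): True,
            frozenset(("pig", "human")): True,
            frozenset(("chicken", "pig")): False,
        }
        higher = {
            frozenset(("chicken", "human")): "chicken",
            frozenset(("pig", "human")): "pig",
            frozenset(("chicken", "pig")): None,
        }
        assert decide_label(HOSTS, sig, higher) == shared_label("chicken", "pig")

    def test_only_extremes_differ_is_non_adapted(self):
        # abundance order human > chicken > pig, only human-vs-pig significant
        sig = {
            frozenset(("human", "pig")): True,
            frozenset(("human", "chicken")): False,
            frozenset(("chicken", "pig")): False,
        }
        higher = {
            frozenset(("human", "pig")): "human",
            frozenset(("human", "chicken")): None,
            frozenset(("chicken", "pig")): None,
        }
        assert decide_label(HOSTS, sig, higher) == NON_ADAPTED

    def test_all_non_significant_is_non_adapted(self):
        sig = {p: False for p in PAIRS}
        higher = {p: None for p in PAIRS}
        assert decide_label(HOSTS, sig, higher) == NON_ADAPTED

    def test_host_permutation_symmetry(self):
        sig = {
            frozenset(("chicken", "human")): True,
            frozenset(("chicken", "pig")): True,
            frozenset(("human", "pig")): False,
        }
        higher = {
            frozenset(("chicken", "human")): "chicken",
            frozenset(("chicken", "pig")): "chicken",
            frozenset(("human", "pig")): None,
        }
        base = decide_label(HOSTS, sig, higher)
        for perm in permutations(HOSTS):
            mapping = dict(zip(HOSTS, perm))
            psig = {frozenset(mapping[h] for h in pair): v for pair, v in sig.items()}
            phigher = {
                frozenset(mapping[h] for h in pair): (mapping[v] if v else None)
                for pair, v in higher.items()
            }
            relabelled = decide_label(perm, psig, phigher)
            assert relabelled == base.replace("chicken", mapping["chicken"])


class TestClassifyAbundance:
    def test_clear_host_specific_signal(self):
        rng = np.random.default_rng(0)
        groups = {
            "chicken": rng.lognormal(0, 0.2, 15) * 1e-2,
            "human": rng.lognormal(0, 0.2, 15) * 1e-4,
            "pig": rng.lognormal(0, 0.2, 15) * 1e-4,
        }
        call = classify_abundance("x", groups, alpha=0.01)
        assert call.label == adapted_label("chicken")
        assert call.abundance_order[0] == "chicken"

    def test_two_hosts_redirects_to_presence_classifier(self):
        with pytest.raises(ValidationError, match="presence"):
            classify_abundance("x", {"a": [1, 2], "b": [1, 2]})

    def test_table_classifier_requires_three_hosts(self, toy_table):
        with pytest.raises(ValidationError, match="3 hosts"):
            classify_abundance_table(toy_table)
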