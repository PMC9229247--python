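"""Abundance-based host-adaptation classifier for three-host comparisons.

The classifier works on zero-replaced relative abundances: zero counts are
substituted with 1/(sample read depth) so that every cell is strictly
positive and rank tests are well defined.  For each OTU, the three pairwise
host comparisons are tested with a two-sided rank test (p < alpha strict,
no multiple-testing correction), and the pattern of significant differences
determines the label:

* ``adapted:h`` — host ``h`` is significantly more abundant than BOTH other
  hosts, irrespective of the outcome of the third pairwise comparison;
* ``shared:h1+h2`` — both ``h1`` and ``h2`` are significantly more abundant
  than the remaining host, while ``h1`` vs ``h2`` is not significant;
* ``non_adapted`` — everything else, in particular: no significant pair; or
  only the extreme pair (top vs bottom of the abundance order) significant
  with both middle-involving pairs non-significant.  Any significance
  pattern not matched above also falls here (conservative sink).

The rule set is specific to exactly three host groups; for two or more than
three hosts use the presence/absence classifier instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    NON_ADAPTED,
    AnalysisConfig,
    OtuTable,
    ValidationError,
    adapted_label,
    shared_label,
)

__all__ = [
    "ZeroReplacedAbundance",
    "PairwiseTestResult",
    "AdaptationCallAbundance",
    "replace_zeros",
    "pairwise_rank_test",
    "decide_label",
    "classify_abundance",
    "classify_abundance_table",
    "calls_to_frame",
    "label_counts",
]


@dataclass
class ZeroReplacedAbundance:
    """Strictly positive per-sample fractions with a replaced-cell mask.

    ``fractions`` holds count/depth for observed cells and 1/depth for cells
    whose count was zero; ``replaced`` flags the latter.
    """

    fractions: pd.DataFrame
    replaced: pd.DataFrame


def replace_zeros(table: OtuTable) -> ZeroReplacedAbundance:
    """Zero-replace a count table into strictly positive fractions."""
    depths = table.depths
    fractions = table.counts / depths
    replaced = table.counts == 0
    floor = pd.DataFrame(
        np.broadcast_to((1.0 / depths).to_numpy(), table.counts.shape),
        index=table.counts.index,
        columns=table.counts.columns,
    )
    fractions = fractions.mask(replaced, floor)
    return ZeroReplacedAbundance(fractions=fractions, replaced=replaced)


@dataclass(frozen=True)
class PairwiseTestResult:
    """Two-sided rank-test comparison of one OTU's abundance in two hosts."""

    host_a: str
    host_b: str
    p_value: float
    higher_host: str | None  # larger central abundance (median, tie -> mean rank)
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def hosts(self) -> frozenset[str]:
        return frozenset((self.host_a, self.host_b))


def _higher_host(a: np.ndarray, b: np.ndarray, host_a: str, host_b: str) -> str | None:
    """Host with the larger central abundance; median first, then mean rank."""
    med_a, med_b = np.median(a), np.median(b)
    if med_a > med_b:
        return host_a
    if med_b > med_a:
        return host_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    mean_a = ranks[: len(a)].mean()
    mean_b = ranks[len(a):].mean()
    if mean_a > mean_b:
        return host_a
    if mean_b > mean_a:
        return host_b
    return None


def pairwise_rank_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.01,
    host_a: str = "a",
    host_b: str = "b",
) -> PairwiseTestResult:
    """Two-sided two-group rank test on strictly positive abundances.

    Small tie-free samples use the exact rank-sum null distribution; larger
    or tied samples use the tie-corrected normal approximation without
    continuity correction, which coincides with a two-group Kruskal–Wallis
    chi-square test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"rank test needs >= 2 values per group; got {a.size} and {b.size}"
        )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=False, method="auto"
    )
    return PairwiseTestResult(
        host_a=host_a,
        host_b=host_b,
        p_value=float(min(res.pvalue, 1.0)),
        higher_host=_higher_host(a, b, host_a, host_b),
        alpha=alpha,
    )


@dataclass(frozen=True)
class AdaptationCallAbundance:
    """Per-OTU abundance-classifier verdict with its supporting evidence."""

    otu_id: str
    label: str
    tests: tuple[PairwiseTestResult, PairwiseTestResult, PairwiseTestResult]
    abundance_order: tuple[str, str, str]  # hosts, most to least abundant


def decide_label(
    hosts: Sequence[str],
    significant: Mapping[frozenset, bool],
    higher: Mapping[frozenset, str | None],
) -> str:
    """Map a three-host significance pattern to a single adaptation label.

    Pure rule engine: ``significant`` and ``higher`` are keyed by the
    frozenset of each host pair.  Exactly one label applies to any pattern;
    unmatched patterns fall through to ``non_adapted``.
    """
    hosts = list(hosts)
    if len(hosts) != 3:
        raise ValidationError(f"rule engine is defined for exactly 3 hosts; got {hosts}")
    for h in hosts:
        others = [o for o in hosts if o != h]
        if all(
            significant[frozenset((h, o))] and higher[frozenset((h, o))] == h
            for o in others
        ):
            return adapted_label(h)
    for h1, h2 in combinations(hosts, 2):
        (h3,) = set(hosts) - {h1, h2}
        if (
            significant[frozenset((h1, h3))]
            and higher[frozenset((h1, h3))] == h1
            and significant[frozenset((h2, h3))]
            and higher[frozenset((h2, h3))] == h2
            and not significant[frozenset((h1, h2))]
        ):
            return shared_label(h1, h2)
    return NON_ADAPTED


def classify_abundance(
    otu_id: str,
    abundances_by_host: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
) -> AdaptationCallAbundance:
    """Classify one OTU from its zero-replaced abundances in three hosts."""
    hosts = list(abundances_by_host)
    if len(hosts) != 3:
        raise ValidationError(
            f"abundance classifier requires exactly 3 hosts (got {len(hosts)}); "
            "use the presence/absence classifier for other host counts"
        )
    groups = {h: np.asarray(abundances_by_host[h], dtype=float) for h in hosts}
    for h, vals in groups.items():
        if vals.size < 2:
            raise ValidationError(f"host {h!r} has fewer than 2 samples")

    tests = tuple(
        pairwise_rank_test(groups[h1], groups[h2], alpha=alpha, host_a=h1, host_b=h2)
        for h1, h2 in combinations(hosts, 2)
    )
    significant = {t.hosts: t.significant for t in tests}
    higher = {t.hosts: t.higher_host for t in tests}

    # abundance order: median desc, then mean desc, then host label
    order = tuple(
        sorted(
            hosts,
            key=lambda h: (-np.median(groups[h]), -np.mean(groups[h]), h),
        )
    )
    label = decide_label(hosts, significant, higher)
    return AdaptationCallAbundance(
        otu_id=str(otu_id), label=label, tests=tests, abundance_order=order
    )


def classify_abundance_table(
    table: OtuTable,
    config: AnalysisConfig | None = None,
) -> list[AdaptationCallAbundance]:
    """Zero-replace a three-host table and classify every OTU."""
    config = config or AnalysisConfig()
    hosts = table.hosts
    if len(hosts) != 3:
        raise ValidationError(
            f"abundance classifier requires exactly 3 hosts; table has {hosts}; "
            "use the presence/absence classifier for other host counts"
        )
    zr = replace_zeros(table)
    samples = {h: table.samples_of(h) for h in hosts}
    calls = []
    for otu_id in table.otu_ids:
        row = zr.fractions.loc[otu_id]
        groups = {h: row[samples[h]].to_numpy() for h in hosts}
        calls.append(classify_abundance(otu_id, groups, alpha=config.significance_alpha))
    return calls


def calls_to_frame(calls: Sequence[AdaptationCallAbundance]) -> pd.DataFrame:
    """Tabulate calls: one row per OTU with label, p-values and order."""
    rows = []
    for call in calls:
        row: dict = {"otu_id": call.otu_id, "label": call.label}
        for t in call.tests:
            pair = "_".join(sorted((t.host_a, t.host_b)))
            row[f"p_{pair}"] = t.p_value
            row[f"higher_{pair}"] = t.higher_host or ""
        row["abundance_order"] = ">".join(call.abundance_order)
        rows.append(row)
    return pd.DataFrame(rows).set_index("otu_id")


def label_counts(calls: Sequence[AdaptationCallAbundance]) -> pd.Series:
    """Count OTUs per label (the Venn-style summary of a classifier run)."""
    return pd.Series([c.label for c in calls]).value_counts().sort_index()
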