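"""Core-OTU selection: keep the common and representative taxa.

An OTU is retained iff BOTH hold (both inequalities strict):

* prevalence — it is present (count ≥ 1) in more than ``prevalence_threshold``
  of the samples of at least one host group, and
* abundance — it forms more than ``abundance_threshold`` of the total reads
  of at least one sample (relative abundance over ALL OTUs in the input
  table, not over the retained set).

Both criteria exclude rare taxa before any host-adaptation classification.
When a host group should enter the comparison only partially (e.g. only
adult individuals), pass the explicit ``include_samples`` list rather than
editing the table in place; the report records the thresholds used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .data_model import AnalysisConfig, OtuTable, occurrence_counts, relative_abundance

__all__ = ["FilterReport", "filter_core_otus"]


@dataclass
class FilterReport:
    """Outcome of the core filter, with per-OTU diagnostics for every input OTU."""

    retained_otu_ids: list[str]
    diagnostics: pd.DataFrame  # index otu_id; max_prevalence, best_host, max_abundance, passes
    prevalence_threshold: float
    abundance_threshold: float

    def retained_table(self, table: OtuTable) -> OtuTable:
        return table.subset_otus(self.retained_otu_ids)


def filter_core_otus(
    table: OtuTable,
    config: AnalysisConfig | None = None,
    *,
    prevalence_threshold: float | None = None,
    abundance_threshold: float | None = None,
    include_samples: Sequence[str] | None = None,
) -> FilterReport:
    """Apply the dual prevalence/abundance criterion to every OTU.

    Parameters
    ----------
    table
        Full OTU table; relative abundance is evaluated against each
        sample's total reads over all OTUs of this table.
    config
        Supplies default thresholds; the keyword arguments override it.
    include_samples
        Optional explicit sample-inclusion list: the filter is evaluated on
        this subset only (all hosts' sample counts shrink accordingly).
    """
    config = config or AnalysisConfig()
    prev_thr = config.prevalence_threshold if prevalence_threshold is None else prevalence_threshold
    abund_thr = config.abundance_threshold if abundance_threshold is None else abundance_threshold

    if include_samples is not None:
        table = table.subset_samples(include_samples)

    occ = occurrence_counts(table)
    n_per_host = pd.Series({h: table.n_samples(h) for h in table.hosts})
    prev_frac = occ / n_per_host  # columns align on host labels

    rel = relative_abundance(table)
    max_abund = rel.max(axis=1)

    max_prev = prev_frac.max(axis=1)
    best_host = prev_frac.idxmax(axis=1)
    passes_prev = (prev_frac > prev_thr).any(axis=1)
    passes_abund = max_abund > abund_thr
    passes = passes_prev & passes_abund

    diagnostics = pd.DataFrame(
        {
            "max_prevalence": max_prev,
            "best_host": best_host,
            "max_abundance": max_abund,
            "passes_prevalence": passes_prev,
            "passes_abundance": passes_abund,
            "retained": passes,
        },
        index=table.counts.index,
    )
    retained = list(diagnostics.index[diagnostics["retained"]])
    return FilterReport(
        retained_otu_ids=retained,
        diagnostics=diagnostics,
        prevalence_threshold=prev_thr,
        abundance_threshold=abund_thr,
    )
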