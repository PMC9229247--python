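"""Shared-core detection across an arbitrary set of host species.

An OTU belongs to the shared core iff, for EVERY host in the requested set,
it is present in strictly more than ``core_prevalence`` of that host's
samples ("more than half" at the default 0.5).  This is the criterion used
to ask which gut bacteria are common to distantly related hosts — e.g.
humans, pigs, chickens and an Antarctic penguin outgroup — and it is
antitone in both the threshold and the host set: raising the threshold or
adding a host can only shrink the core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .data_model import OtuTable, ValidationError, occurrence_counts

__all__ = ["CoreMembershipReport", "shared_core"]


@dataclass
class CoreMembershipReport:
    """Core membership with per-OTU per-host prevalence diagnostics."""

    core_otu_ids: list[str]
    prevalence: pd.DataFrame  # index otu_id, one fraction column per host
    core_prevalence: float
    hosts: tuple[str, ...]


def shared_core(
    table: OtuTable,
    hosts: Iterable[str] | None = None,
    core_prevalence: float = 0.5,
) -> CoreMembershipReport:
    """OTUs present in more than ``core_prevalence`` of every host's samples.

    ``hosts`` defaults to every host in the table.  Unknown host labels are
    an error; the strict inequality means e.g. 9 samples require ≥ 5
    occurrences at the default threshold.
    """
    if not (0.0 < core_prevalence < 1.0):
        raise ValidationError(f"core_prevalence must lie in (0, 1); got {core_prevalence}")
    host_list = list(table.hosts) if hosts is None else [str(h).strip().lower() for h in hosts]
    if not host_list:
        raise ValidationError("empty host set")
    unknown = [h for h in host_list if h not in table.hosts]
    if unknown:
        raise ValidationError(f"unknown host(s): {unknown}")

    occ = occurrence_counts(table)[host_list]
    n_per_host = pd.Series({h: table.n_samples(h) for h in host_list})
    prevalence = occ / n_per_host
    in_core = (prevalence > core_prevalence).all(axis=1)
    return CoreMembershipReport(
        core_otu_ids=list(prevalence.index[in_core]),
        prevalence=prevalence,
        core_prevalence=core_prevalence,
        hosts=tuple(host_list),
    )
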