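"""Presence/absence host-adaptation classifier and sliding-window profiles.

This classifier uses occurrence (in how many samples of each host an OTU is
detected) as the only criterion, which makes it robust to the overall
compositional differences between host microbiotas and applicable to any
number of host groups (≥ 2).

For each OTU and each host ``h`` the adaptation margin is::

    margin(h) = occurrence(h) − Σ occurrence(h') over all other hosts h'

An OTU is ``adapted:h`` iff margin(h) > 0 — it occurs in more samples of
``h`` than in all other hosts' samples combined.  At most one host can have
a positive margin, so labels are unambiguous; an OTU with no positive
margin is ``non_adapted``.  The positive margin doubles as the adaptation
*strength*, used to order each host's adapted OTUs from most host-restricted
to most relaxed, along which sliding-window taxonomic or oxygen-trait
composition profiles are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .data_model import (
    NON_ADAPTED,
    OtuTable,
    TaxonomyAnnotation,
    TraitAnnotation,
    ValidationError,
    adapted_label,
    occurrence_counts,
)

__all__ = [
    "PresenceProfile",
    "WindowProfile",
    "classify_presence",
    "classify_presence_table",
    "profiles_to_frame",
    "order_by_strength",
    "sliding_window_composition",
]


@dataclass(frozen=True)
class PresenceProfile:
    """Occurrence counts, margins and presence-based label for one OTU."""

    otu_id: str
    occurrences: dict[str, int]
    margins: dict[str, int]
    label: str
    strength: int | None  # focal-host margin; None unless adapted

    @property
    def total_occurrence(self) -> int:
        return sum(self.occurrences.values())


def classify_presence(
    occurrences: Mapping[str, int], otu_id: str = ""
) -> PresenceProfile:
    """Classify one OTU from its per-host occurrence counts."""
    if not occurrences:
        raise ValidationError("empty host set")
    occ = {str(h): int(v) for h, v in occurrences.items()}
    for h, v in occ.items():
        if v < 0:
            raise ValidationError(f"negative occurrence {v} for host {h!r}")
    total = sum(occ.values())
    margins = {h: v - (total - v) for h, v in occ.items()}
    positive = [h for h, m in margins.items() if m > 0]
    # provable from the definition: two positive margins would require each
    # host to exceed the combined total of the others
    assert len(positive) <= 1, f"multiple positive margins: {margins}"
    if positive:
        (focal,) = positive
        return PresenceProfile(
            otu_id=str(otu_id),
            occurrences=occ,
            margins=margins,
            label=adapted_label(focal),
            strength=margins[focal],
        )
    return PresenceProfile(
        otu_id=str(otu_id), occurrences=occ, margins=margins,
        label=NON_ADAPTED, strength=None,
    )


def classify_presence_table(table: OtuTable) -> list[PresenceProfile]:
    """Presence-classify every OTU of a table (≥ 2 host groups)."""
    if len(table.hosts) < 2:
        raise ValidationError(
            f"presence classifier needs >= 2 hosts; table has {table.hosts}"
        )
    occ = occurrence_counts(table)
    return [
        classify_presence(occ.loc[otu_id].to_dict(), otu_id=otu_id)
        for otu_id in table.otu_ids
    ]


def profiles_to_frame(profiles: Sequence[PresenceProfile]) -> pd.DataFrame:
    """One row per OTU: per-host occurrences and margins, label, strength."""
    rows = []
    for p in profiles:
        row: dict = {"otu_id": p.otu_id}
        for h, v in p.occurrences.items():
            row[f"occ_{h}"] = v
        for h, m in p.margins.items():
            row[f"margin_{h}"] = m
        row["label"] = p.label
        row["strength"] = p.strength if p.strength is not None else ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("otu_id")


def order_by_strength(profiles: Sequence[PresenceProfile], host: str) -> list[str]:
    """Order a host's adapted OTUs from strongest to weakest adaptation.

    Descending margin; ties broken by descending occurrence in the focal
    host, then ascending otu_id, so the ordering is deterministic.
    """
    host = str(host).strip().lower()
    focal = [p for p in profiles if p.label == adapted_label(host)]
    focal.sort(key=lambda p: (-p.margins[host], -p.occurrences[host], p.otu_id))
    return [p.otu_id for p in focal]


@dataclass
class WindowProfile:
    """Per-window category fractions along an ordered OTU list."""

    otu_ids: tuple[str, ...]
    window_size: int
    step: int
    fractions: pd.DataFrame  # index: window start position; columns: categories


def sliding_window_composition(
    ordered_otu_ids: Sequence[str],
    annotation: TaxonomyAnnotation | TraitAnnotation | Mapping[str, str],
    window_size: int = 8,
    step: int = 1,
    rank: str | None = None,
) -> WindowProfile:
    """Fraction of OTUs per category in each sliding window.

    ``annotation`` may be a taxonomy (categorised at ``rank``, default
    phylum), a trait annotation, or any otu_id → category mapping.  OTUs
    missing from the annotation count as ``unknown``; categories with no
    member in a window are reported as 0.
    """
    otu_ids = [str(o) for o in ordered_otu_ids]
    n = len(otu_ids)
    if window_size < 1:
        raise ValidationError(f"window_size must be >= 1; got {window_size}")
    if step < 1:
        raise ValidationError(f"step must be >= 1; got {step}")
    if window_size > n:
        raise ValidationError(f"window_size {window_size} exceeds number of OTUs {n}")

    if isinstance(annotation, TaxonomyAnnotation):
        rank = rank or "phylum"
        lookup = {o: annotation.rank_of(o, rank) for o in otu_ids}
        known = annotation.categories(rank)
    elif isinstance(annotation, TraitAnnotation):
        lookup = {o: annotation.trait_of(o) for o in otu_ids}
        known = annotation.categories()
    else:
        lookup = {o: str(annotation.get(o, "unknown")) for o in otu_ids}
        known = sorted(set(annotation.values()))

    categories = sorted(set(known) | set(lookup.values()) | {"unknown"})
    cats = [lookup[o] for o in otu_ids]
    starts = range(0, n - window_size + 1, step)
    rows = []
    for s in starts:
        window = cats[s : s + window_size]
        rows.append({c: window.count(c) / window_size for c in categories})
    fractions = pd.DataFrame(rows, index=pd.Index(starts, name="window_start"))
    return WindowProfile(
        otu_ids=tuple(otu_ids), window_size=window_size, step=step, fractions=fractions
    )
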