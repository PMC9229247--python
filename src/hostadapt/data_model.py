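"""Core data types and tabular I/O for multi-host OTU analyses.

The single source of occurrence and abundance facts is the :class:`OtuTable`:
an integer count matrix (OTUs in rows, samples in columns) together with a
sample → host-species map.  Everything downstream — core filtering, the
abundance-based and presence/absence host-adaptation classifiers, the shared
core detector — consumes this object, plus optional per-OTU taxonomy
(ranked lineages) and oxygen-survival trait annotations.

File dialects
-------------
* counts: TSV, first column ``otu_id``, remaining columns are sample ids,
  integer cells.  A BIOM 1.0 (JSON) table is accepted as an alternative.
* metadata: TSV with columns ``sample_id`` and ``host``.
* taxonomy: TSV ``otu_id`` + ranks phylum…species; missing ranks are
  recorded as ``unclassified``.
* traits: TSV ``otu_id<TAB>oxygen_trait`` with a controlled vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "OtuTable",
    "TaxonomyAnnotation",
    "TraitAnnotation",
    "AnalysisConfig",
    "OXYGEN_TRAITS",
    "TAXONOMIC_RANKS",
    "UNCLASSIFIED",
    "NON_ADAPTED",
    "adapted_label",
    "shared_label",
    "read_otu_table",
    "read_biom_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_traits",
    "write_traits",
    "relative_abundance",
    "occurrence_counts",
]

#: Controlled vocabulary for oxygen-survival traits.  ``non_spore_forming``
#: denotes a strict anaerobe with no specific adaptation for aerobic survival.
OXYGEN_TRAITS = (
    "spore_forming",
    "aerotolerant",
    "facultative_anaerobe",
    "non_spore_forming",
    "unknown",
)

TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"

#: Label carried by OTUs with no host preference.
NON_ADAPTED = "non_adapted"


def adapted_label(host: str) -> str:
    """Label for an OTU adapted to a single host species."""
    return f"adapted:{host}"


def shared_label(host_a: str, host_b: str) -> str:
    """Label for an OTU shared by a pair of hosts (order-insensitive)."""
    return "shared:" + "+".join(sorted((host_a, host_b)))


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant.

    The message names the offending row/column so malformed inputs fail
    loudly instead of being silently dropped.
    """


def _normalise_host(label: object) -> str:
    return str(label).strip().lower()


class OtuTable:
    """Integer OTU × sample count matrix with a sample → host map.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as index and sample ids as columns; every
        cell must be a non-negative integer and every column (sample) must
        have total depth ≥ 1.
    host_of
        Mapping (or Series) sample_id → host label.  Host labels are
        case-normalised (lower-cased, stripped) and otherwise compared
        verbatim.  Every sample in ``counts`` must have a host.
    """

    def __init__(self, counts: pd.DataFrame, host_of: Mapping[str, str] | pd.Series):
        counts = pd.DataFrame(counts).copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate otu_id(s): {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")

        if counts.size:
            try:
                arr = counts.to_numpy(dtype=float)
            except (TypeError, ValueError):
                numeric = counts.apply(pd.to_numeric, errors="coerce")
                r, c = np.argwhere(numeric.isna().to_numpy())[0]
                raise ValidationError(
                    f"non-numeric count {counts.iat[r, c]!r} at otu "
                    f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
                ) from None
            if np.any(~np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                r, c = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise ValidationError(
                    f"non-integer count {counts.iat[r, c]!r} at otu "
                    f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
                )
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative count {counts.iat[r, c]!r} at otu "
                    f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
                )
            counts = counts.astype(np.int64)

        hosts = pd.Series(dict(host_of) if not isinstance(host_of, pd.Series) else host_of)
        hosts.index = hosts.index.astype(str)
        hosts = hosts.map(_normalise_host)
        missing = [s for s in counts.columns if s not in hosts.index]
        if missing:
            raise ValidationError(f"sample(s) without a host label: {missing}")
        hosts = hosts.loc[counts.columns]

        depths = counts.sum(axis=0)
        empty = depths.index[depths < 1].tolist()
        if empty:
            raise ValidationError(f"sample(s) with zero total reads: {empty}")

        self.counts = counts
        self.host_of = hosts

    # -- basic views -----------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def hosts(self) -> list[str]:
        """Distinct host labels in first-appearance order."""
        return list(dict.fromkeys(self.host_of))

    @property
    def depths(self) -> pd.Series:
        """Per-sample total read count (column sums)."""
        return self.counts.sum(axis=0)

    def samples_of(self, host: str) -> list[str]:
        host = _normalise_host(host)
        return list(self.host_of.index[self.host_of == host])

    def n_samples(self, host: str) -> int:
        return len(self.samples_of(host))

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        sample_ids = [str(s) for s in sample_ids]
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample_id(s): {missing}")
        return OtuTable(self.counts[sample_ids], self.host_of.loc[sample_ids])

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        otu_ids = [str(o) for o in otu_ids]
        missing = [o for o in otu_ids if o not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown otu_id(s): {missing}")
        return OtuTable(self.counts.loc[otu_ids], self.host_of)

    def restrict_hosts(self, hosts: Iterable[str]) -> "OtuTable":
        """Keep only samples whose host is in ``hosts``."""
        wanted = {_normalise_host(h) for h in hosts}
        unknown = wanted - set(self.hosts)
        if unknown:
            raise ValidationError(f"unknown host(s): {sorted(unknown)}")
        keep = [s for s in self.sample_ids if self.host_of[s] in wanted]
        return self.subset_samples(keep)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OtuTable({len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples, "
            f"hosts={self.hosts})"
        )


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances: each count divided by its column sum.

    Every column of the result sums to 1 (to within floating-point error).
    """
    return table.counts / table.depths


def occurrence_counts(table: OtuTable) -> pd.DataFrame:
    """Per-OTU, per-host occurrence: number of samples with count ≥ 1.

    Returns a DataFrame indexed by otu_id with one integer column per host,
    in host first-appearance order.
    """
    present = table.counts >= 1
    out = {}
    for host in table.hosts:
        out[host] = present[table.samples_of(host)].sum(axis=1)
    return pd.DataFrame(out, index=table.counts.index)


class TaxonomyAnnotation:
    """Per-OTU ranked lineage (phylum … species).

    OTUs absent from the annotation are reported as ``unknown`` downstream;
    missing lower ranks within an annotated lineage are ``unclassified``.
    """

    ranks = TAXONOMIC_RANKS

    def __init__(self, lineages: pd.DataFrame):
        frame = pd.DataFrame(lineages).copy()
        frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate otu_id(s) in taxonomy: {dups}")
        for rank in self.ranks:
            if rank not in frame.columns:
                frame[rank] = UNCLASSIFIED
        frame = frame[list(self.ranks)].fillna(UNCLASSIFIED).astype(str)
        frame = frame.replace("", UNCLASSIFIED)
        bad = frame.index[frame["phylum"] == UNCLASSIFIED]
        # an annotated OTU must at least name a phylum; fully unknown OTUs
        # should simply be left out of the annotation
        if len(bad):
            raise ValidationError(f"taxonomy rows without a phylum: {list(bad)}")
        self.lineages = frame

    def __contains__(self, otu_id: str) -> bool:
        return str(otu_id) in self.lineages.index

    def __len__(self) -> int:
        return len(self.lineages)

    def rank_of(self, otu_id: str, rank: str = "phylum", default: str = "unknown") -> str:
        if rank not in self.ranks:
            raise ValidationError(f"unknown taxonomic rank {rank!r}")
        otu_id = str(otu_id)
        if otu_id not in self.lineages.index:
            return default
        return self.lineages.at[otu_id, rank]

    def category_of(self, otu_id: str) -> str:
        """Default window category: the phylum."""
        return self.rank_of(otu_id, "phylum")

    def categories(self, rank: str = "phylum") -> list[str]:
        if rank not in self.ranks:
            raise ValidationError(f"unknown taxonomic rank {rank!r}")
        return sorted(self.lineages[rank].unique())


class TraitAnnotation:
    """Per-OTU oxygen-survival trait from the controlled vocabulary."""

    vocabulary = OXYGEN_TRAITS

    def __init__(self, traits: Mapping[str, str] | pd.Series):
        series = pd.Series(dict(traits) if not isinstance(traits, pd.Series) else traits)
        series.index = series.index.astype(str)
        series = series.astype(str)
        if series.index.has_duplicates:
            dups = series.index[series.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate otu_id(s) in traits: {dups}")
        bad = series[~series.isin(self.vocabulary)]
        if len(bad):
            raise ValidationError(
                "oxygen_trait outside controlled vocabulary "
                f"{self.vocabulary}: {dict(bad.head(5))}"
            )
        self.traits = series

    def __contains__(self, otu_id: str) -> bool:
        return str(otu_id) in self.traits.index

    def __len__(self) -> int:
        return len(self.traits)

    def trait_of(self, otu_id: str) -> str:
        return self.traits.get(str(otu_id), "unknown")

    category_of = trait_of

    def categories(self) -> list[str]:
        return list(self.vocabulary)


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across pipeline stages.

    prevalence_threshold
        Core filter keeps an OTU only if, in at least one host, it occurs in
        strictly more than this fraction of that host's samples (default 0.5,
        i.e. "more than half").
    abundance_threshold
        ... and only if it forms strictly more than this fraction of total
        reads in at least one sample (default 0.005, i.e. 0.5%).
    significance_alpha
        Pairwise rank tests call a difference significant iff p < alpha
        (default 0.01, strict).
    window_size, window_step
        Sliding-window width (default 8 OTUs) and step (default 1) for
        composition profiles along the adaptation-strength ordering.
    core_prevalence
        "More than half" threshold for the multi-host shared core.
    """

    prevalence_threshold: float = 0.5
    abundance_threshold: float = 0.005
    significance_alpha: float = 0.01
    window_size: int = 8
    window_step: int = 1
    core_prevalence: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence_threshold", "abundance_threshold",
                     "significance_alpha", "core_prevalence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")
        if self.window_size < 1:
            raise ValidationError(f"window_size must be >= 1; got {self.window_size}")
        if self.window_step < 1:
            raise ValidationError(f"window_step must be >= 1; got {self.window_step}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValidationError(f"cannot parse TSV {path}: {exc}") from exc


def read_otu_table(counts_path: str | Path, metadata_path: str | Path) -> OtuTable:
    """Read a counts TSV plus a sample metadata TSV into a validated table.

    Samples present in the counts file but missing from the metadata cause a
    :class:`ValidationError`; extra metadata rows are ignored.
    """
    raw = _read_tsv(counts_path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{counts_path}: expected otu_id column plus sample columns")
    counts = raw.set_index(raw.columns[0])
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & counts.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{counts_path}: non-numeric count {counts.iat[r, c]!r} at otu "
            f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
        )

    meta = _read_tsv(metadata_path)
    cols = {c.lower(): c for c in meta.columns}
    if "sample_id" not in cols or "host" not in cols:
        raise ValidationError(f"{metadata_path}: metadata must have columns sample_id, host")
    meta = meta.rename(columns={cols["sample_id"]: "sample_id", cols["host"]: "host"})
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{metadata_path}: duplicate sample_id(s): {dups}")
    if meta["host"].isna().any():
        rows = meta.loc[meta["host"].isna(), "sample_id"].tolist()
        raise ValidationError(f"{metadata_path}: missing host for sample(s): {rows}")
    host_of = meta.set_index("sample_id")["host"]
    return OtuTable(numeric, host_of)


def read_biom_otu_table(path: str | Path, metadata_path: str | Path | None = None) -> OtuTable:
    """Read a BIOM 1.0 (JSON dialect) OTU table.

    Hosts are taken from each column's ``metadata.host`` entry, or from a
    separate metadata TSV if ``metadata_path`` is given.
    """
    doc = json.loads(Path(path).read_text())
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        matrix_type = doc.get("matrix_type", "dense")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from exc
    mat = np.zeros(shape)
    if matrix_type == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    elif matrix_type == "dense":
        mat[:] = np.asarray(data)
    else:
        raise ValidationError(f"{path}: unsupported matrix_type {matrix_type!r}")
    counts = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)

    if metadata_path is not None:
        meta = _read_tsv(metadata_path)
        host_of = meta.set_index(meta.columns[0])[meta.columns[1]]
    else:
        host_of = {}
        for col in doc["columns"]:
            md = col.get("metadata") or {}
            if "host" not in md:
                raise ValidationError(
                    f"{path}: sample {col['id']!r} has no host in its column metadata"
                )
            host_of[col["id"]] = md["host"]
    return OtuTable(counts, host_of)


def write_otu_table(table: OtuTable, counts_path: str | Path,
                    metadata_path: str | Path) -> None:
    counts = table.counts.copy()
    counts.index.name = "otu_id"
    counts.to_csv(counts_path, sep="\t")
    meta = table.host_of.rename("host").to_frame()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyAnnotation:
    frame = _read_tsv(path)
    if frame.columns[0].lower() != "otu_id":
        raise ValidationError(f"{path}: first taxonomy column must be otu_id")
    frame = frame.set_index(frame.columns[0])
    frame.columns = [c.lower() for c in frame.columns]
    return TaxonomyAnnotation(frame)


def write_taxonomy(taxonomy: TaxonomyAnnotation, path: str | Path) -> None:
    out = taxonomy.lineages.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_traits(path: str | Path) -> TraitAnnotation:
    frame = _read_tsv(path)
    cols = [c.lower() for c in frame.columns]
    if "otu_id" not in cols or "oxygen_trait" not in cols:
        raise ValidationError(f"{path}: traits TSV must have columns otu_id, oxygen_trait")
    frame.columns = cols
    return TraitAnnotation(frame.set_index("otu_id")["oxygen_trait"])


def write_traits(traits: TraitAnnotation, path: str | Path) -> None:
    out = traits.traits.rename("oxygen_trait").to_frame()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")
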