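"""Synthetic multi-host OTU tables with planted host-adaptation structure.

The generator plants four kinds of OTUs — host-specific, pairwise-shared,
ubiquitous, and background noise — across a configurable set of host groups,
so that every pipeline stage (core filter, abundance classifier, presence
classifier, shared-core detector) can be checked against known ground truth.

Generative model, per OTU i and sample j (host h):

1. read depth: ``depth_j ~ round(LogNormal(depth_log_mean, depth_log_sd))``,
   floored at 1000 reads;
2. occurrence: ``present_ij ~ Bernoulli(π_in)`` if h is a focal host of
   OTU i's planted class, else ``Bernoulli(π_out)``;
3. intensity: ``λ_ij = μ · Gamma(shape, 1/shape) · present_ij`` with
   ``μ = μ_in`` (focal) or ``μ_out`` (non-focal); the unit-mean gamma
   multiplier adds the overdispersion real count data show;
4. counts: column j is ``Multinomial(depth_j, λ_·j / Σ λ_·j)``, so column
   sums equal the drawn depths exactly (a Dirichlet-multinomial-like model).

Oxygen-survival traits are drawn per planted class from ``trait_mix``
(spore-formers enriched among ubiquitous OTUs by default), and taxonomy is
drawn from a small fixed lineage pool with host-adapted classes skewed
toward Bacteroidetes and broadly distributed classes toward Firmicutes.
All randomness flows through one ``numpy`` Generator seeded by ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    NON_ADAPTED,
    OXYGEN_TRAITS,
    OtuTable,
    TaxonomyAnnotation,
    TraitAnnotation,
    ValidationError,
    adapted_label,
    shared_label,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SimulatedDataset",
    "RecoveryReport",
    "simulate_otu_table",
    "evaluate_recovery",
    "read_truth",
    "write_truth",
]

UBIQUITOUS = "ubiquitous"
NOISE = "noise"

_DEFAULT_TRAIT_MIX: dict[str, dict[str, float]] = {
    # spore-formers dominate the ubiquitous class; host-adapted OTUs are
    # mostly strict anaerobes without aerobic-survival adaptations
    "adapted": {"non_spore_forming": 0.6, "spore_forming": 0.1,
                "aerotolerant": 0.1, "facultative_anaerobe": 0.1, "unknown": 0.1},
    "shared": {"non_spore_forming": 0.2, "spore_forming": 0.4,
               "aerotolerant": 0.15, "facultative_anaerobe": 0.15, "unknown": 0.1},
    "ubiquitous": {"non_spore_forming": 0.05, "spore_forming": 0.7,
                   "aerotolerant": 0.1, "facultative_anaerobe": 0.1, "unknown": 0.05},
    "noise": {"non_spore_forming": 0.25, "spore_forming": 0.25,
              "aerotolerant": 0.2, "facultative_anaerobe": 0.2, "unknown": 0.1},
}

_PHYLUM_MIX: dict[str, dict[str, float]] = {
    "adapted": {"Bacteroidetes": 0.7, "Firmicutes": 0.2, "Proteobacteria": 0.1},
    "shared": {"Firmicutes": 0.5, "Bacteroidetes": 0.3, "Proteobacteria": 0.2},
    "ubiquitous": {"Firmicutes": 0.8, "Proteobacteria": 0.15, "Actinobacteria": 0.05},
    "noise": {"Firmicutes": 0.5, "Proteobacteria": 0.3, "Actinobacteria": 0.2},
}

# class, order, family, genus pools per phylum (species left unclassified)
_LINEAGES: dict[str, list[tuple[str, str, str, str]]] = {
    "Bacteroidetes": [
        ("Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
        ("Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
        ("Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Parabacteroides"),
        ("Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes"),
    ],
    "Firmicutes": [
        ("Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"),
        ("Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
        ("Clostridia", "Clostridiales", "Peptostreptococcaceae", "Terrisporobacter"),
        ("Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
        ("Negativicutes", "Selenomonadales", "Veillonellaceae", "Megamonas"),
    ],
    "Proteobacteria": [
        ("Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
        ("Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae", "Campylobacter"),
    ],
    "Actinobacteria": [
        ("Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    ],
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults emulate a four-host faecal survey: human 44, pig 50, chicken 37
    and penguin 9 samples, per-sample depths lognormal with median ≈ 3×10⁴
    reads (bulk of the mass in 10⁴–10⁵), and planted classes with strong
    occurrence (π_in vs π_out) and abundance (μ_in vs μ_out) contrast.
    """

    hosts: tuple[tuple[str, int], ...] = (
        ("human", 44), ("pig", 50), ("chicken", 37), ("penguin", 9),
    )
    n_adapted_per_host: int = 40
    n_shared_per_pair: int = 10
    n_ubiquitous: int = 20
    n_noise: int = 20
    occurrence_in: float = 0.9
    occurrence_out: float = 0.05
    mean_in: float = 10.0
    mean_out: float = 0.2
    gamma_shape: float = 2.0
    depth_log_mean: float = math.log(3.0e4)
    depth_log_sd: float = 0.5
    trait_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TRAIT_MIX.items()}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.hosts:
            raise ValidationError("spec needs at least one host")
        labels = [h for h, _ in self.hosts]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate host labels: {labels}")
        for h, n in self.hosts:
            if n < 1:
                raise ValidationError(f"host {h!r} needs >= 1 sample; got {n}")
        for name in ("occurrence_in", "occurrence_out"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
        if self.mean_out <= 0 or self.mean_in < self.mean_out:
            raise ValidationError(
                f"need mean_in >= mean_out > 0 (fold_change >= 1); "
                f"got {self.mean_in}, {self.mean_out}"
            )
        if self.gamma_shape <= 0:
            raise ValidationError(f"gamma_shape must be > 0; got {self.gamma_shape}")
        if self.depth_log_sd < 0:
            raise ValidationError(f"depth_log_sd must be >= 0; got {self.depth_log_sd}")
        for kind, mix in self.trait_mix.items():
            if kind not in _DEFAULT_TRAIT_MIX:
                raise ValidationError(f"unknown planted-class kind in trait_mix: {kind!r}")
            if set(mix) - set(OXYGEN_TRAITS):
                raise ValidationError(f"trait_mix[{kind!r}] uses unknown traits")
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError(f"trait_mix[{kind!r}] must sum to 1; got {total}")

    @property
    def fold_change(self) -> float:
        return self.mean_in / self.mean_out

    @property
    def host_labels(self) -> list[str]:
        return [h for h, _ in self.hosts]

    def planted_classes(self) -> list[tuple[str, frozenset[str], int]]:
        """(class label, focal host set, n OTUs) for every planted class."""
        out: list[tuple[str, frozenset[str], int]] = []
        labels = self.host_labels
        for h in labels:
            out.append((adapted_label(h), frozenset({h}), self.n_adapted_per_host))
        for i, h1 in enumerate(labels):
            for h2 in labels[i + 1:]:
                out.append((shared_label(h1, h2), frozenset({h1, h2}),
                            self.n_shared_per_pair))
        out.append((UBIQUITOUS, frozenset(labels), self.n_ubiquitous))
        out.append((NOISE, frozenset(), self.n_noise))
        return out

    @classmethod
    def three_host_benchmark(cls, rng_seed: int = 0) -> "SyntheticSpec":
        """Strong-signal three-host benchmark: 15 samples/host, 40 OTUs per
        planted class, π_in 0.95 vs π_out 0.05, 50-fold abundance contrast."""
        return cls(
            hosts=(("human", 15), ("pig", 15), ("chicken", 15)),
            n_adapted_per_host=40, n_shared_per_pair=40,
            n_ubiquitous=40, n_noise=40,
            occurrence_in=0.95, occurrence_out=0.05,
            mean_in=10.0, mean_out=0.2,
            rng_seed=rng_seed,
        )

    @classmethod
    def null_benchmark(cls, rng_seed: int = 0) -> "SyntheticSpec":
        """Null counterpart of the benchmark: fold_change 1 and π_in = π_out,
        so planted classes are statistically indistinguishable across hosts."""
        return cls(
            hosts=(("human", 15), ("pig", 15), ("chicken", 15)),
            n_adapted_per_host=40, n_shared_per_pair=40,
            n_ubiquitous=40, n_noise=40,
            occurrence_in=0.95, occurrence_out=0.95,
            mean_in=10.0, mean_out=10.0,
            rng_seed=rng_seed,
        )


@dataclass
class SyntheticTruth:
    """Planted per-OTU class labels and assigned oxygen traits."""

    frame: pd.DataFrame  # index otu_id; columns planted_class, oxygen_trait

    @property
    def classes(self) -> pd.Series:
        return self.frame["planted_class"]

    @property
    def traits(self) -> pd.Series:
        return self.frame["oxygen_trait"]

    def expected_calls(self, mode: str = "abundance") -> pd.Series:
        """Label each classifier should ideally assign per planted class.

        ``abundance``: adapted and pairwise-shared classes keep their label,
        ubiquitous and noise OTUs are expected ``non_adapted``.
        ``presence``: only adapted classes keep their label — a pairwise-
        shared OTU occurs widely in two hosts and cannot have a positive
        single-host margin.
        """
        if mode not in ("abundance", "presence"):
            raise ValidationError(f"mode must be 'abundance' or 'presence'; got {mode!r}")

        def expect(cls: str) -> str:
            if cls.startswith("adapted:"):
                return cls
            if cls.startswith("shared:") and mode == "abundance":
                return cls
            return NON_ADAPTED

        return self.classes.map(expect)


class SimulatedDataset(NamedTuple):
    table: OtuTable
    taxonomy: TaxonomyAnnotation
    traits: TraitAnnotation
    truth: SyntheticTruth


def _choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _kind(planted_class: str) -> str:
    if planted_class.startswith("adapted:"):
        return "adapted"
    if planted_class.startswith("shared:"):
        return "shared"
    return planted_class  # ubiquitous / noise


def simulate_otu_table(spec: SyntheticSpec) -> SimulatedDataset:
    """Draw one synthetic dataset; identical spec (incl. seed) ⇒ identical output."""
    rng = np.random.default_rng(spec.rng_seed)

    sample_ids: list[str] = []
    host_of: dict[str, str] = {}
    for host, n in spec.hosts:
        for i in range(n):
            sid = f"{host}_{i + 1:03d}"
            sample_ids.append(sid)
            host_of[sid] = host
    n_samples = len(sample_ids)
    host_per_sample = np.array([host_of[s] for s in sample_ids])

    classes = spec.planted_classes()
    otu_ids: list[str] = []
    planted: list[str] = []
    focal_sets: list[frozenset[str]] = []
    for label, focal, n in classes:
        for _ in range(n):
            otu_ids.append(f"otu{len(otu_ids) + 1:04d}")
            planted.append(label)
            focal_sets.append(focal)
    n_otus = len(otu_ids)
    if n_otus == 0:
        raise ValidationError("spec plants zero OTUs")

    depths = np.maximum(
        1000, np.round(rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, n_samples))
    ).astype(np.int64)

    focal_mask = np.zeros((n_otus, n_samples), dtype=bool)
    for i, focal in enumerate(focal_sets):
        if focal:
            focal_mask[i] = np.isin(host_per_sample, list(focal))
    pi = np.where(focal_mask, spec.occurrence_in, spec.occurrence_out)
    mu = np.where(focal_mask, spec.mean_in, spec.mean_out)

    present = rng.random((n_otus, n_samples)) < pi
    noise = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_shape, (n_otus, n_samples))
    intensity = mu * noise * present

    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        w = intensity[:, j]
        total = w.sum()
        if total <= 0:  # pathological all-absent column: park the reads somewhere
            w = np.zeros(n_otus)
            w[rng.integers(n_otus)] = 1.0
            total = 1.0
        counts[:, j] = rng.multinomial(depths[j], w / total)

    table = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids), host_of)

    trait_assign = [
        _choice(rng, spec.trait_mix[_kind(cls)]) for cls in planted
    ]
    lineage_rows = []
    for cls in planted:
        phylum = _choice(rng, _PHYLUM_MIX[_kind(cls)])
        cls_, order, family, genus = _LINEAGES[phylum][rng.integers(len(_LINEAGES[phylum]))]
        lineage_rows.append(
            {"phylum": phylum, "class": cls_, "order": order,
             "family": family, "genus": genus, "species": "unclassified"}
        )
    taxonomy = TaxonomyAnnotation(pd.DataFrame(lineage_rows, index=otu_ids))
    traits = TraitAnnotation(pd.Series(trait_assign, index=otu_ids))
    truth = SyntheticTruth(
        pd.DataFrame(
            {"planted_class": planted, "oxygen_trait": trait_assign},
            index=pd.Index(otu_ids, name="otu_id"),
        )
    )
    return SimulatedDataset(table=table, taxonomy=taxonomy, traits=traits, truth=truth)


@dataclass
class RecoveryReport:
    """Confusion matrix of planted classes (rows) vs called labels (columns)."""

    confusion: pd.DataFrame
    per_class_accuracy: pd.Series
    accuracy: float


def evaluate_recovery(
    calls: Mapping[str, str] | pd.Series,
    truth: SyntheticTruth,
    expected: Mapping[str, str] | pd.Series | None = None,
) -> RecoveryReport:
    """Score classifier calls against planted truth.

    ``expected`` maps each otu_id to the label the classifier should assign
    (defaults to the planted class itself; use
    :meth:`SyntheticTruth.expected_calls` for classifier-appropriate
    expectations).  Calls and truth must cover exactly the same otu_ids.
    """
    calls = pd.Series(dict(calls) if not isinstance(calls, pd.Series) else calls)
    calls.index = calls.index.astype(str)
    truth_classes = truth.classes
    if set(calls.index) != set(truth_classes.index):
        missing = sorted(set(truth_classes.index) ^ set(calls.index))[:5]
        raise ValidationError(f"calls and truth cover different otu_ids (e.g. {missing})")
    calls = calls.loc[truth_classes.index]

    if expected is None:
        expected = truth_classes
    expected = pd.Series(dict(expected) if not isinstance(expected, pd.Series) else expected)
    expected = expected.loc[truth_classes.index]

    confusion = pd.crosstab(truth_classes, calls)
    confusion.index.name = "planted_class"
    confusion.columns.name = "called_label"

    hit = calls == expected
    per_class = hit.groupby(truth_classes).mean().rename("accuracy")
    return RecoveryReport(
        confusion=confusion,
        per_class_accuracy=per_class,
        accuracy=float(hit.mean()),
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth.frame.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> SyntheticTruth:
    frame = pd.read_csv(path, sep="\t", dtype=str).set_index("otu_id")
    if not {"planted_class", "oxygen_trait"} <= set(frame.columns):
        raise ValidationError(f"{path}: truth TSV needs planted_class and oxygen_trait columns")
    return SyntheticTruth(frame)
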