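"""End-to-end orchestration: filter → classify → windows → core, with a manifest.

``run_pipeline`` ties the stages together on file inputs, writes every
report as TSV and records a YAML manifest (config snapshot, input digests,
per-stage OTU counts and output paths).  The manifest contains no
timestamps, so rerunning with identical inputs and configuration produces
byte-identical outputs.  Any stage failure aborts with the stage name and
the offending record in the message.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance_adaptation import (
    AdaptationCallAbundance,
    calls_to_frame,
    classify_abundance_table,
    label_counts,
)
from .core_filter import filter_core_otus
from .data_model import (
    NON_ADAPTED,
    AnalysisConfig,
    OtuTable,
    TaxonomyAnnotation,
    TraitAnnotation,
    ValidationError,
    adapted_label,
    read_otu_table,
    read_taxonomy,
    read_traits,
    relative_abundance,
    write_otu_table,
)
from .multihost_core import shared_core
from .presence_adaptation import (
    classify_presence_table,
    order_by_strength,
    profiles_to_frame,
    sliding_window_composition,
)

__all__ = ["PipelineConfig", "PipelineError", "RunManifest", "run_pipeline"]

#: relative-abundance threshold separating "low" from "high" cells in the
#: presence report (0.1%)
HEATMAP_THRESHOLD = 0.001


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Pipeline-level options on top of :class:`AnalysisConfig`.

    comparative_hosts
        The hosts entering the adaptation classifiers.  Defaults to all
        hosts when the table has exactly three; with more hosts it must be
        set explicitly (the abundance rule engine is a three-host rule set).
    core_hosts
        Hosts for the shared-core stage; defaults to every host in the table.
    include_samples
        Optional explicit sample-inclusion list applied before the core
        filter (e.g. to restrict one host to adults only).
    """

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    comparative_hosts: tuple[str, ...] | None = None
    core_hosts: tuple[str, ...] | None = None
    include_samples: tuple[str, ...] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        analysis_keys = set(AnalysisConfig.__dataclass_fields__)
        analysis = AnalysisConfig(**{k: v for k, v in data.items() if k in analysis_keys})
        extra = {k: v for k, v in data.items() if k not in analysis_keys}
        known = {"comparative_hosts", "core_hosts", "include_samples"}
        unknown = set(extra) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        tup = lambda v: tuple(v) if v is not None else None  # noqa: E731
        return cls(
            analysis=analysis,
            comparative_hosts=tup(extra.get("comparative_hosts")),
            core_hosts=tup(extra.get("core_hosts")),
            include_samples=tup(extra.get("include_samples")),
        )

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis.to_dict(),
            "comparative_hosts": list(self.comparative_hosts) if self.comparative_hosts else None,
            "core_hosts": list(self.core_hosts) if self.core_hosts else None,
            "include_samples": list(self.include_samples) if self.include_samples else None,
        }


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    config: dict
    inputs: dict  # name -> {path, sha256}
    stages: list  # [{name, n_otus_in, n_otus_out, outputs: [...]}]

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "tool": "hostadapt",
            "version": self.version,
            "config": self.config,
            "inputs": self.inputs,
            "stages": self.stages,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path) -> str:
    # outputs are recorded by name, relative to the run directory, so that
    # reruns into different directories stay byte-identical
    frame.to_csv(path, sep="\t")
    return path.name


def _ratio_table(
    calls: Sequence[AdaptationCallAbundance],
    taxonomy: TaxonomyAnnotation,
    hosts: Sequence[str],
) -> pd.DataFrame:
    """Adapted : broadly-distributed OTU ratio per host per phylum.

    For host h, the numerator counts OTUs labelled adapted to h and the
    denominator counts h's OTUs found in at least one other host: pairwise-
    shared labels involving h plus OTUs of similar abundance in all hosts.
    Raw integers are emitted beside the 2-dp (round-half-even) ratio.
    """
    labels = pd.Series({c.otu_id: c.label for c in calls})
    phyla = pd.Series({c.otu_id: taxonomy.rank_of(c.otu_id, "phylum") for c in calls})
    rows = []
    for host in hosts:
        for phylum in sorted(phyla.unique()):
            in_phylum = phyla == phylum
            adapted = int(((labels == adapted_label(host)) & in_phylum).sum())
            broadly = labels.map(
                lambda lab: lab == NON_ADAPTED
                or (lab.startswith("shared:")
                    and host in lab.split(":", 1)[1].split("+"))
            )
            shared = int((broadly & in_phylum).sum())
            rows.append(
                {
                    "host": host,
                    "phylum": phylum,
                    "n_adapted": adapted,
                    "n_broadly_distributed": shared,
                    "ratio": round(adapted / shared, 2) if shared else "",
                }
            )
    return pd.DataFrame(rows).set_index(["host", "phylum"])


def _window_frames(
    profiles,
    annotation,
    hosts: Sequence[str],
    window_size: int,
    step: int,
) -> pd.DataFrame:
    """Long-format window fractions per block (one block per adapted host
    plus the non-adapted block); blocks shorter than the window are skipped."""
    blocks: dict[str, list[str]] = {}
    for host in hosts:
        blocks[f"adapted:{host}"] = order_by_strength(profiles, host)
    non_adapted = [p for p in profiles if p.label == NON_ADAPTED]
    non_adapted.sort(key=lambda p: (-p.total_occurrence, p.otu_id))
    blocks[NON_ADAPTED] = [p.otu_id for p in non_adapted]

    rows = []
    for block, otu_ids in blocks.items():
        if len(otu_ids) < window_size:
            continue
        wp = sliding_window_composition(otu_ids, annotation, window_size, step)
        for start, frac in wp.fractions.iterrows():
            for category, value in frac.items():
                rows.append(
                    {"block": block, "window_start": start,
                     "category": category, "fraction": value}
                )
    return pd.DataFrame(rows, columns=["block", "window_start", "category", "fraction"])


def run_pipeline(
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
    traits_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path = "hostadapt_out",
) -> RunManifest:
    """Run every stage on file inputs and write reports + manifest to ``outdir``."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = config.analysis
    stages: list[dict] = []

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # ---- load ---------------------------------------------------------
    def _load():
        table = read_otu_table(counts_path, metadata_path)
        taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else TaxonomyAnnotation(
            pd.DataFrame(columns=list(TaxonomyAnnotation.ranks))
        )
        traits = read_traits(traits_path) if traits_path else TraitAnnotation(pd.Series(dtype=str))
        return table, taxonomy, traits

    table, taxonomy, traits = stage("load")(_load)
    inputs = {"counts": {"path": str(counts_path), "sha256": _sha256(counts_path)},
              "metadata": {"path": str(metadata_path), "sha256": _sha256(metadata_path)}}
    if taxonomy_path:
        inputs["taxonomy"] = {"path": str(taxonomy_path), "sha256": _sha256(taxonomy_path)}
    if traits_path:
        inputs["traits"] = {"path": str(traits_path), "sha256": _sha256(traits_path)}
    stages.append({"name": "load", "n_otus_in": len(table.otu_ids),
                   "n_otus_out": len(table.otu_ids), "outputs": []})

    # ---- core filter --------------------------------------------------
    def _filter():
        report = filter_core_otus(
            table, analysis, include_samples=config.include_samples
        )
        filtered = table.subset_otus(report.retained_otu_ids)
        outs = [
            _write(report.diagnostics, outdir / "filter_diagnostics.tsv"),
        ]
        write_otu_table(filtered, outdir / "filtered_counts.tsv",
                        outdir / "filtered_metadata.tsv")
        outs += ["filtered_counts.tsv", "filtered_metadata.tsv"]
        return report, filtered, outs

    report, filtered, outs = stage("filter")(_filter)
    stages.append({"name": "filter", "n_otus_in": len(table.otu_ids),
                   "n_otus_out": len(filtered.otu_ids), "outputs": outs})

    # ---- comparative subset -------------------------------------------
    def _comparative():
        if config.comparative_hosts is not None:
            hosts = [h.strip().lower() for h in config.comparative_hosts]
        elif len(table.hosts) <= 3:
            hosts = table.hosts
        else:
            raise ValidationError(
                f"table has {len(table.hosts)} hosts {table.hosts}; set "
                "comparative_hosts to choose the hosts entering the classifiers"
            )
        return hosts, filtered.restrict_hosts(hosts)

    comp_hosts, comp_table = stage("comparative-subset")(_comparative)

    # ---- abundance classifier (exactly 3 hosts) -----------------------
    abundance_calls: list[AdaptationCallAbundance] | None = None
    if len(comp_hosts) == 3:
        def _abundance():
            calls = classify_abundance_table(comp_table, analysis)
            frame = calls_to_frame(calls)
            counts_frame = label_counts(calls).rename("n_otus").to_frame()
            counts_frame.index.name = "label"
            phylum = pd.Series(
                {c.otu_id: taxonomy.rank_of(c.otu_id, "phylum") for c in calls}
            )
            cross = pd.crosstab(phylum, frame["label"])
            cross.index.name = "phylum"
            outs = [
                _write(frame, outdir / "abundance_calls.tsv"),
                _write(counts_frame, outdir / "abundance_label_counts.tsv"),
                _write(cross, outdir / "abundance_phylum_by_label.tsv"),
                _write(_ratio_table(calls, taxonomy, comp_hosts),
                       outdir / "abundance_adapted_shared_ratio.tsv"),
            ]
            return calls, outs

        abundance_calls, outs = stage("classify-abundance")(_abundance)
        stages.append({"name": "classify-abundance",
                       "n_otus_in": len(comp_table.otu_ids),
                       "n_otus_out": len(abundance_calls), "outputs": outs})

    # ---- presence classifier ------------------------------------------
    def _presence():
        profiles = classify_presence_table(comp_table)
        frame = profiles_to_frame(profiles)
        # low/high heat-map annotation: per-host mean relative abundance
        rel = relative_abundance(comp_table)
        for host in comp_hosts:
            mean_abund = rel[comp_table.samples_of(host)].mean(axis=1)
            frame[f"abundance_{host}"] = (
                (mean_abund >= HEATMAP_THRESHOLD)
                .map({True: "high", False: "low"})
                .reindex(frame.index)
            )
        counts_frame = (
            pd.Series([p.label for p in profiles]).value_counts().sort_index()
            .rename("n_otus").to_frame()
        )
        counts_frame.index.name = "label"
        outs = [
            _write(frame, outdir / "presence_calls.tsv"),
            _write(counts_frame, outdir / "presence_label_counts.tsv"),
        ]
        return profiles, outs

    profiles, outs = stage("classify-presence")(_presence)
    stages.append({"name": "classify-presence",
                   "n_otus_in": len(comp_table.otu_ids),
                   "n_otus_out": len(profiles), "outputs": outs})

    # ---- sliding windows ----------------------------------------------
    def _windows():
        outs = []
        for name, annotation in (("phylum", taxonomy), ("trait", traits)):
            frame = _window_frames(
                profiles, annotation, comp_hosts,
                analysis.window_size, analysis.window_step,
            )
            outs.append(_write(frame.set_index("block") if len(frame) else frame,
                               outdir / f"windows_{name}.tsv"))
        return outs

    outs = stage("windows")(_windows)
    stages.append({"name": "windows", "n_otus_in": len(profiles),
                   "n_otus_out": len(profiles), "outputs": outs})

    # ---- multi-host shared core ---------------------------------------
    def _core():
        core_hosts = (
            [h.strip().lower() for h in config.core_hosts]
            if config.core_hosts is not None else table.hosts
        )
        core_table = table.subset_otus(filtered.otu_ids)
        core = shared_core(core_table, core_hosts, analysis.core_prevalence)
        frame = core.prevalence.loc[core.core_otu_ids]
        frame.index.name = "otu_id"
        return core, [_write(frame, outdir / "core_otus.tsv")]

    core, outs = stage("core")(_core)
    stages.append({"name": "core", "n_otus_in": len(filtered.otu_ids),
                   "n_otus_out": len(core.core_otu_ids), "outputs": outs})

    manifest = RunManifest(
        version=__version__,
        config=config.to_dict(),
        inputs=inputs,
        stages=stages,
    )
    manifest.to_yaml(outdir / "manifest.yaml")
    return manifest
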