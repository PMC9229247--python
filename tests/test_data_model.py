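import json

import numpy as np
import pandas as pd
import pytest

from hostadapt import (
    AnalysisConfig,
    OtuTable,
    TaxonomyAnnotation,
    TraitAnnotation,
    ValidationError,
    occurrence_counts,
    read_biom_otu_table,
    read_otu_table,
    relative_abundance,
    write_otu_table,
)
from hostadapt.synthetic_data import SyntheticSpec, simulate_otu_table


class TestOtuTableValidation:
    def test_negative_count_names_cell(self):
        counts = pd.DataFrame({"s1": [1, -1]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="b.*s1"):
            OtuTable(counts, {"s1": "human"})

    def test_non_integer_count_rejected(self):
        counts = pd.DataFrame({"s1": [1.5, 2]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="non-integer"):
            OtuTable(counts, {"s1": "human"})

    def test_duplicate_ids_rejected(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="duplicate otu_id"):
            OtuTable(counts, {"s1": "human", "s2": "human"})

    def test_sample_without_host_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [1]}, index=["a"])
        with pytest.raises(ValidationError, match="s2"):
            OtuTable(counts, {"s1": "human"})

    def test_zero_depth_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=["a"])
        with pytest.raises(ValidationError, match="zero total reads"):
            OtuTable(counts, {"s1": "human", "s2": "pig"})

    def test_host_labels_case_normalised(self, toy_table):
        counts = toy_table.counts
        table = OtuTable(counts, {"h1": "Human ", "h2": "HUMAN", "p1": "Pig", "p2": "pig"})
        assert table.hosts == ["human", "pig"]


class TestIO:
    def test_round_trip_fixture(self, toy_table, tmp_path):
        write_otu_table(toy_table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_otu_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.otu_ids == toy_table.otu_ids
        assert back.sample_ids == toy_table.sample_ids
        assert back.counts.equals(toy_table.counts)
        assert (back.host_of == toy_table.host_of).all()

    def test_round_trip_simulated_table(self, tmp_path):
        spec = SyntheticSpec(
            hosts=(("human", 6), ("pig", 6)),
            n_adapted_per_host=60, n_shared_per_pair=40,
            n_ubiquitous=20, n_noise=20, rng_seed=11,
        )
        table = simulate_otu_table(spec).table
        assert len(table.otu_ids) == 200
        write_otu_table(table, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_otu_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.counts.equals(table.counts)

    def test_counts_file_with_negative_value_cites_cell(self, tmp_path):
        (tmp_path / "c.tsv").write_text("otu_id\ts1\ts2\na\t3\t-1\n")
        (tmp_path / "m.tsv").write_text("sample_id\thost\ns1\thuman\ns2\tpig\n")
        with pytest.raises(ValidationError, match="a.*s2"):
            read_otu_table(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_metadata_missing_sample_fails(self, tmp_path):
        (tmp_path / "c.tsv").write_text("otu_id\ts1\ts2\na\t3\t1\n")
        (tmp_path / "m.tsv").write_text("sample_id\thost\ns1\thuman\n")
        with pytest.raises(ValidationError, match="s2"):
            read_otu_table(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_biom_json_sparse_matches_tsv(self, toy_table, tmp_path):
        doc = {
            "format": "Biological Observation Matrix 1.0.0",
            "matrix_type": "sparse",
            "shape": [len(toy_table.otu_ids), len(toy_table.sample_ids)],
            "rows": [{"id": o, "metadata": None} for o in toy_table.otu_ids],
            "columns": [
                {"id": s, "metadata": {"host": toy_table.host_of[s]}}
                for s in toy_table.sample_ids
            ],
            "data": [
                [i, j, int(v)]
                for i, row in enumerate(toy_table.counts.to_numpy())
                for j, v in enumerate(row)
                if v
            ],
        }
        (tmp_path / "t.biom").write_text(json.dumps(doc))
        back = read_biom_otu_table(tmp_path / "t.biom")
        assert back.counts.equals(toy_table.counts)
        assert (back.host_of == toy_table.host_of).all()


class TestRelativeAbundance:
    def test_forced_arithmetic(self):
        table = OtuTable(
            pd.DataFrame({"s": [5, 15, 80]}, index=["a", "b", "c"]), {"s": "human"}
        )
        rel = relative_abundance(table)
        assert rel["s"].tolist() == [0.05, 0.15, 0.80]

    def test_single_otu_all_ones(self):
        table = OtuTable(
            pd.DataFrame({"s1": [7], "s2": [3]}, index=["a"]),
            {"s1": "human", "s2": "pig"},
        )
        assert (relative_abundance(table) == 1.0).all().all()

    def test_columns_sum_to_one(self, make_random_table):
        for seed in range(5):
            rel = relative_abundance(make_random_table(seed))
            assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-9)


class TestOccurrenceCounts:
    def test_forced_by_presence_definition(self):
        table = OtuTable(
            pd.DataFrame(
                [[0, 3, 0, 7], [1, 1, 1, 1]],
                index=["a", "filler"],
                columns=["s1", "s2", "s3", "s4"],
            ),
            {"s1": "h", "s2": "h", "s3": "p", "s4": "p"},
        )
        occ = occurrence_counts(table)
        assert occ.loc["a"].to_dict() == {"h": 1, "p": 1}

    def test_all_zero_row(self, toy_table):
        counts = toy_table.counts.copy()
        counts.loc["otuZ"] = 0
        occ = occurrence_counts(OtuTable(counts, toy_table.host_of))
        assert (occ.loc["otuZ"] == 0).all()

    def test_matches_naive_recount(self, make_random_table):
        table = make_random_table(3)
        occ = occurrence_counts(table)
        for otu in table.otu_ids:
            for host in table.hosts:
                naive = sum(
                    table.counts.at[otu, s] >= 1 for s in table.samples_of(host)
                )
                assert occ.at[otu, host] == naive

    def test_host_sum_equals_presence_total(self, make_random_table):
        table = make_random_table(4)
        occ = occurrence_counts(table)
        presence_total = (table.counts >= 1).sum(axis=1)
        assert (occ.sum(axis=1) == presence_total).all()


class TestAnnotations:
    def test_taxonomy_fills_unclassified_and_requires_phylum(self):
        tax = TaxonomyAnnotation(pd.DataFrame({"phylum": ["Firmicutes"]}, index=["a"]))
        assert tax.rank_of("a", "genus") == "unclassified"
        assert tax.rank_of("missing") == "unknown"
        with pytest.raises(ValidationError, match="phylum"):
            TaxonomyAnnotation(pd.DataFrame({"genus": ["Blautia"]}, index=["a"]))

    def test_trait_vocabulary_enforced(self):
        traits = TraitAnnotation({"a": "spore_forming"})
        assert traits.trait_of("a") == "spore_forming"
        assert traits.trait_of("missing") == "unknown"
        with pytest.raises(ValidationError, match="vocabulary"):
            TraitAnnotation({"a": "anaerobic"})


class TestAnalysisConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prevalence_threshold": 0.0},
            {"abundance_threshold": 1.0},
            {"significance_alpha": -0.1},
            {"window_size": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            AnalysisConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        (tmp_path / "c.yaml").write_text("significance_alpha: 0.05\nwindow_size: 4\n")
        cfg = AnalysisConfig.from_yaml(tmp_path / "c.yaml")
        assert cfg.significance_alpha == 0.05
        assert cfg.window_size == 4
        assert cfg.prevalence_threshold == 0.5
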