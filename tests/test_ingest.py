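import numpy as np
import pandas as pd
import pytest

from phosnet.ingest import (
    ColumnError,
    apply_site_filters,
    merge_replicate_tables,
    read_design,
    read_phospho_table,
)
from phosnet.synthetic import (
    SimulationConfig,
    simulate_network,
    simulate_timecourse,
    write_design,
    write_maxquant_like,
)

from conftest import make_table

HEADER = "Protein\tPosition\tAmino acid\tLocalization prob\tReverse\tPotential contaminant"


def _write_sites(tmp_path, rows, samples, name="sites.tsv"):
    cols = "\t".join(f"{s}___1" for s in samples)
    lines = [f"{HEADER}\t{cols}"] + rows
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


def _design_frame(samples, condition="control", replicate="r1"):
    return pd.DataFrame(
        {
            "condition": condition,
            "time_min": [6.0 * i for i in range(len(samples))],
            "replicate": replicate,
        },
        index=pd.Index(samples, name="sample_column"),
    )


class TestReadPhosphoTable:
    def test_empty_file_with_header_gives_zero_records(self, tmp_path):
        samples = ["I_a", "I_b"]
        path = _write_sites(tmp_path, [], samples)
        table = read_phospho_table(path, _design_frame(samples))
        assert table.n_sites == 0
        assert list(table.intensities.columns) == samples

    def test_five_rows_four_samples(self, tmp_path):
        samples = ["I_a", "I_b", "I_c", "I_d"]
        rows = [
            f"P{i}\t{10 * i}\tS\t0.9\t\t\t100\t200\t0\t400" for i in range(1, 6)
        ]
        table = read_phospho_table(
            _write_sites(tmp_path, rows, samples), _design_frame(samples)
        )
        assert table.n_sites == 5
        assert table.intensities.shape == (5, 4)
        # zero intensities preserved as 0, not missing
        assert (table.intensities["I_c"] == 0).all()

    def test_localization_prob_field_mapping(self, tmp_path):
        samples = ["I_a"]
        table = read_phospho_table(
            _write_sites(tmp_path, ["P1\t10\tS\t0.9\t\t\t5"], samples),
            _design_frame(samples),
        )
        assert table.meta["localization_prob"].iloc[0] == 0.9

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Protein\tAmino acid\tLocalization prob\tI_a___1\nP1\tS\t0.9\t5\n")
        with pytest.raises(ColumnError, match="position"):
            read_phospho_table(path, _design_frame(["I_a"]))

    def test_orphan_intensity_column_errors(self, tmp_path):
        path = tmp_path / "orphan.tsv"
        path.write_text(f"{HEADER}\tI_a___1\tI_zzz___1\nP1\t10\tS\t0.9\t\t\t5\t6\n")
        with pytest.raises(ColumnError, match="I_zzz"):
            read_phospho_table(path, _design_frame(["I_a"]))

    def test_case_insensitive_aliases(self, tmp_path):
        path = tmp_path / "alias.tsv"
        path.write_text(
            "proteins\tPositions within proteins\tAminoAcid\tLocalization Probability\tI_a___1\n"
            "P1\t10\tT\t0.8\t7\n"
        )
        table = read_phospho_table(path, _design_frame(["I_a"]))
        key = table.intensities.index[0]
        assert key == ("P1", 10, "T", 1)

    def test_multiplicity_expansion_skips_all_blank_slices(self, tmp_path):
        path = tmp_path / "mult.tsv"
        path.write_text(
            f"{HEADER}\tI_a___1\tI_a___2\n"
            "P1\t10\tS\t0.9\t\t\t5\t3\n"
            "P2\t20\tS\t0.9\t\t\t8\t\n"
        )
        table = read_phospho_table(path, _design_frame(["I_a"]))
        keys = set(table.intensities.index)
        assert ("P1", 10, "S", 1) in keys and ("P1", 10, "S", 2) in keys
        assert ("P2", 20, "S", 2) not in keys
        assert table.n_sites == 3


class TestMerge:
    def _table(self, samples, proteins, condition, replicate):
        design = _design_frame(samples, condition, replicate)
        vals = np.arange(len(proteins) * len(samples), dtype=float).reshape(
            len(proteins), len(samples)
        ) + 1
        return make_table(vals, design, proteins=proteins)

    def test_single_table_identity(self):
        t = self._table(["I_a"], ["P1", "P2"], "control", "r1")
        merged = merge_replicate_tables([t])
        pd.testing.assert_frame_equal(merged.intensities, t.intensities)

    def test_disjoint_keys_union_cardinality(self):
        t1 = self._table(["I_a"], ["P1", "P2", "P3"], "control", "r1")
        t2 = self._table(["I_b"], ["P4", "P5", "P6", "P7"], "control", "r2")
        merged = merge_replicate_tables([t1, t2])
        assert merged.n_sites == 7
        # sites absent from one file read 0 ("not detected") in its samples
        assert merged.intensities.loc[("P1", 101, "S", 1), "I_b"] == 0

    def test_shared_key_unions_intensity_maps(self):
        t1 = self._table(["I_a"], ["P1"], "control", "r1")
        t2 = self._table(["I_b"], ["P1"], "control", "r2")
        merged = merge_replicate_tables([t1, t2])
        assert merged.n_sites == 1
        row = merged.intensities.iloc[0]
        assert row["I_a"] == 1 and row["I_b"] == 1

    def test_merge_conserves_distinct_keys(self, rng):
        protein_sets = [
            [f"P{i}" for i in rng.choice(20, size=rng.integers(2, 8), replace=False)]
            for _ in range(3)
        ]
        tables = [
            self._table([f"I_{j}"], sorted(ps), "control", f"r{j}")
            for j, ps in enumerate(protein_sets)
        ]
        merged = merge_replicate_tables(tables)
        assert merged.n_sites == len(set().union(*map(set, protein_sets)))

    def test_colliding_sample_key_errors(self):
        t1 = self._table(["I_a"], ["P1"], "control", "r1")
        t2 = self._table(["I_b"], ["P2"], "control", "r1")  # same (cond,time,rep)
        with pytest.raises(ValueError, match="colliding"):
            merge_replicate_tables([t1, t2])

    def test_localization_prob_merged_by_maximum(self):
        t1 = self._table(["I_a"], ["P1"], "control", "r1")
        t2 = self._table(["I_b"], ["P1"], "control", "r2")
        t1.meta["localization_prob"] = 0.8
        t2.meta["localization_prob"] = 0.95
        merged = merge_replicate_tables([t1, t2])
        assert merged.meta["localization_prob"].iloc[0] == 0.95


class TestSiteFilters:
    def _table_with_probs(self, probs):
        design = _design_frame(["I_a"])
        t = make_table(np.ones((len(probs), 1)), design)
        t.meta["localization_prob"] = probs
        return t

    @pytest.mark.parametrize(
        "prob,kept", [(0.74, False), (0.75, True), (0.76, True), (1.0, True)]
    )
    def test_localization_threshold_boundary(self, prob, kept):
        out = apply_site_filters(self._table_with_probs([prob]))
        assert (out.n_sites == 1) is kept

    def test_contaminant_and_reverse_removed(self):
        t = self._table_with_probs([1.0, 1.0, 1.0])
        t.meta.iloc[0, t.meta.columns.get_loc("is_contaminant")] = True
        t.meta.iloc[1, t.meta.columns.get_loc("is_reverse")] = True
        assert apply_site_filters(t).n_sites == 1

    def test_identity_on_clean_table(self):
        t = self._table_with_probs([1.0, 0.9])
        out = apply_site_filters(t)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_idempotent(self):
        t = self._table_with_probs([0.74, 0.75, 0.9])
        once = apply_site_filters(t)
        twice = apply_site_filters(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)


def test_write_read_round_trip_bit_exact(tmp_path):
    net = simulate_network(2, 4, seed=3)
    table = simulate_timecourse(
        net, SimulationConfig(noise_sd=0.3, seed=3), n_background=5
    )
    write_maxquant_like(table, tmp_path / "sites.tsv")
    write_design(table, tmp_path / "design.tsv")
    design = read_design(tmp_path / "design.tsv")
    back = read_phospho_table(tmp_path / "sites.tsv", design)
    a = table.intensities.sort_index()
    b = back.intensities.sort_index()[a.columns]
    assert a.index.equals(b.index)
    assert (a.to_numpy() == b.to_numpy()).all()
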