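import numpy as np
import pandas as pd
import pytest

from deepedna import datasets, diversity
from deepedna.diversity import (
    count_distinct_taxa,
    depth_category,
    esv_counts_per_sample,
    method_overlap,
    rank_resolution_summary,
    taxon_detection_table,
)
from deepedna.io import ESVTable, Lineage, SampleMeta
from deepedna.taxonomy import Assignment


class TestDepthCategory:
    @pytest.mark.parametrize(
        "depth,expected",
        [(0, "shallow"), (499, "shallow"), (500, "mid"), (1400, "mid"), (1401, "deep"), (2600, "deep")],
    )
    def test_boundaries(self, depth, expected):
        assert depth_category(depth) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_category(-1)


def fish(rank="species", marker="12Steleo", esv="e1", score=100.0,
         family="Moridae", genus="Antimora", species="Antimora rostrata"):
    lin = Lineage("Metazoa", "Chordata", "Actinopteri", "Gadiformes",
                  family, genus, species)
    cut = {"species": "species", "genus": "genus", "family": "family",
           "above_family": "order"}[rank]
    return Assignment(
        esv_id=esv, assigned=lin.truncate(cut), best_score=score,
        assigned_rank=rank, n_tied_hits=1, marker=marker,
    )


class TestESVCounts:
    def test_counts_nonzero_esvs(self):
        table = ESVTable(
            marker="12Steleo",
            counts=pd.DataFrame(
                {
                    "esv_id": ["e1", "e2", "e3", "e1", "e2"],
                    "sample_id": ["s1", "s1", "s1", "s2", "s2"],
                    "read_count": [5, 1, 2, 0, 0],
                }
            ),
        )
        counts = esv_counts_per_sample(table)
        assert counts["s1"] == 3
        assert counts["s2"] == 0

    def test_recovers_generator_richness(self):
        rng = np.random.default_rng(5)
        truth = {f"s{i}": int(rng.integers(0, 9)) for i in range(6)}
        rows = []
        for sample, richness in truth.items():
            for e in range(8):
                rows.append(
                    {"esv_id": f"e{e}", "sample_id": sample,
                     "read_count": int(rng.integers(1, 50)) if e < richness else 0}
                )
        table = ESVTable(marker="m", counts=pd.DataFrame(rows))
        counts = esv_counts_per_sample(table)
        assert {s: int(counts[s]) for s in truth} == truth


class TestRankResolution:
    def test_counts_nest_and_percentages(self):
        assignments = (
            [fish(esv=f"sp{i}") for i in range(4)]
            + [fish("genus", esv=f"g{i}") for i in range(3)]
            + [fish("family", esv=f"f{i}") for i in range(2)]
            + [fish("above_family", esv="af0", score=92.0)]
            + [fish("species", esv="low", score=85.0)]  # below group score floor
        )
        row = rank_resolution_summary(assignments, group="fish").iloc[0]
        assert row["n_group_esv"] == 10
        assert row["n_family"] == 9 and row["n_genus"] == 7 and row["n_species"] == 4
        assert row["n_species"] <= row["n_genus"] <= row["n_family"] <= row["n_group_esv"]
        assert row["pct_family"] == 90.0
        assert row["pct_species"] == 40.0

    def test_zero_group_esvs_reports_zero_percentages(self):
        copepod = Assignment(
            "e1",
            Lineage("Metazoa", "Arthropoda", "Copepoda"),
            95.0,
            "above_family",
            1,
            marker="18SV9M",
        )
        row = rank_resolution_summary([copepod], group="fish").iloc[0]
        assert row["n_group_esv"] == 0 and row["pct_family"] == 0.0

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            rank_resolution_summary([fish()], group="birds")


def meta(sample_id, depth, control=False):
    return SampleMeta(sample_id, "ST01", "T1", 2019, depth,
                      "bottom" if depth > 50 else "surface", 1.5,
                      dna_conc=20.0, is_control=control)


class TestDetectionTable:
    def setup_method(self):
        self.metadata = [
            meta("s_deep", 2000.0),
            meta("s_mid", 800.0),
            meta("s_shallow", 10.0),
            meta("s_ctrl", 10.0, control=True),
        ]

    def table(self, rows):
        return ESVTable(marker="12Steleo", counts=pd.DataFrame(
            rows, columns=["esv_id", "sample_id", "read_count"]
        ))

    def test_deep_only_taxon(self):
        t = self.table([("e1", "s_deep", 12), ("e1", "s_mid", 0)])
        df = taxon_detection_table([fish()], [t], self.metadata)
        row = df.iloc[0]
        assert bool(row.deep) and not row.mid and not row.shallow
        assert row.n_samples == 1

    def test_control_only_taxon_absent(self):
        t = self.table([("e1", "s_ctrl", 50)])
        df = taxon_detection_table([fish()], [t], self.metadata)
        assert df.empty

    def test_same_genus_species_and_genus_rows_distinct(self):
        t = self.table([("e1", "s_deep", 5), ("e2", "s_mid", 5)])
        assignments = [fish(esv="e1"), fish("genus", esv="e2")]
        df = taxon_detection_table(assignments, [t], self.metadata)
        assert len(df) == 2
        assert set(df["species"]) == {"Antimora rostrata", ""}

    def test_generator_truth_recovered_exactly(self):
        rng = np.random.default_rng(11)
        cats = {"s_deep": "deep", "s_mid": "mid", "s_shallow": "shallow"}
        taxa = [("Moridae", "Antimora", f"Antimora sp{i}") for i in range(6)]
        truth, rows, assignments = {}, [], []
        for i, (fam, gen, sp) in enumerate(taxa):
            esv = f"e{i}"
            assignments.append(fish(esv=esv, family=fam, genus=gen, species=sp))
            placed = rng.choice(list(cats), size=rng.integers(1, 4), replace=False)
            truth[sp] = {cats[s] for s in placed}
            for s in placed:
                rows.append((esv, s, int(rng.integers(1, 99))))
        df = taxon_detection_table(assignments, [self.table(rows)], self.metadata)
        for _, row in df.iterrows():
            expected = truth[row["species"]]
            got = {c for c in ("deep", "mid", "shallow") if row[c]}
            assert got == expected
            assert row["n_samples"] == len(expected)


class TestCountDistinct:
    def test_bundled_survey_counts(self):
        df = datasets.load_fish_detections()
        assert count_distinct_taxa(df, "family") == 21
        assert count_distinct_taxa(df, "genus") == 23
        assert count_distinct_taxa(df, "species") == 15

    def test_deep_category_restriction(self):
        df = datasets.load_fish_detections()
        assert count_distinct_taxa(df, "family", "deep") == 11
        assert count_distinct_taxa(df, "genus", "deep") == 11
        assert count_distinct_taxa(df, "species", "deep") == 8

    def test_name_counted_once_across_rows(self):
        df = pd.DataFrame(
            {
                "order": ["O", "O"], "family": ["F", "F"],
                "genus": ["G", "G"], "species": ["", ""],
                "deep": [True, False], "mid": [False, True],
                "shallow": [False, False], "n_samples": [1, 1],
            }
        )
        assert count_distinct_taxa(df, "family") == 1

    def test_empty_table(self):
        assert count_distinct_taxa(pd.DataFrame(), "family") == 0


class TestMethodOverlap:
    @pytest.mark.parametrize(
        "edna,conv,expected",
        [
            ({"a", "b", "c", "d", "e"}, {"a", "b", "c", "d", "e"}, (0, 5, 0)),
            ({"a", "b", "c"}, {"x", "y"}, (3, 0, 2)),
            ({"a", "b", "c", "d"}, {"c", "d", "e"}, (2, 2, 1)),
        ],
    )
    def test_partition(self, edna, conv, expected):
        got = method_overlap(edna, conv)
        assert got == expected
        assert got[0] + got[1] == len(edna)


def test_every_noncontrol_sample_in_exactly_one_category():
    from deepedna import simulate

    samples = simulate.make_metadata_and_concentration(seed=3)
    noncontrol = [s for s in samples if not s.is_control]
    cats = [depth_category(s.depth_m) for s in noncontrol]
    assert len(cats) == len(noncontrol)
    assert sum(cats.count(c) for c in ("shallow", "mid", "deep")) == len(noncontrol)
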