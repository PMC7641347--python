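import numpy as np
import pandas as pd
import pytest

from deepedna import simulate
from deepedna.io import ESVTable, Lineage, SampleMeta
from deepedna.occupancy import (
    DetectionArray,
    OccupancyModel,
    build_detection_array,
    fit_occupancy,
    summarize_posterior,
)
from deepedna.taxonomy import Assignment


def assignment(esv, marker, species="Antimora rostrata", rank="species"):
    lin = Lineage("Metazoa", "Chordata", "Actinopteri", "Gadiformes",
                  "Moridae", "Antimora", species)
    if rank == "family":
        lin = lin.truncate("family")
    return Assignment(esv, lin, 100.0, rank, 1, marker=marker)


def meta(sample_id, station, depth):
    return SampleMeta(sample_id, station, "T1", 2019, depth, "bottom", 1.5)


def table(marker, rows):
    return ESVTable(marker=marker, counts=pd.DataFrame(
        rows, columns=["esv_id", "sample_id", "read_count"]
    ))


class TestBuildDetectionArray:
    def setup_method(self):
        self.metadata = [
            meta("A-1", "ST01", 2000.0), meta("A-2", "ST01", 2000.0),
            meta("A-3", "ST01", 2000.0),
            meta("B-1", "ST02", 800.0), meta("B-2", "ST02", 800.0),
            meta("B-3", "ST02", 800.0),
        ]

    def test_single_detection_lands_in_right_cell(self):
        tables = [
            table("m1", [("e1", sid, 0) for sid in
                         ["A-1", "A-2", "A-3", "B-1", "B-2", "B-3"]]),
            table("m2", [("e1", sid, 0) for sid in
                         ["A-1", "A-2", "A-3", "B-1", "B-2", "B-3"]]),
        ]
        tables[0].counts.loc[
            (tables[0].counts.sample_id == "A-2"), "read_count"
        ] = 7
        arr = build_detection_array(
            [assignment("e1", "m1"), assignment("e1", "m2")], tables,
            self.metadata, rank="species",
        )
        assert arr.shape == (1, 2, 3, 2)
        assert arr.y.sum() == 1
        assert arr.y[0, 0, 1, 0] == 1  # site ST01@2000m, replicate 2, marker m1

    def test_family_rank_aggregates_congeners(self):
        t = table("m1", [("e1", "A-1", 5), ("e2", "A-2", 5)])
        assignments = [
            assignment("e1", "m1", species="Antimora rostrata"),
            assignment("e2", "m1", species="Antimora microlepis"),
        ]
        arr = build_detection_array(assignments, [t], self.metadata[:3], rank="family")
        assert arr.taxa == ["Moridae"]
        assert arr.y[0, 0, :2, 0].sum() == 2

    def test_missing_marker_cells_are_nan(self):
        t1 = table("m1", [("e1", sid, 1) for sid in ["A-1", "A-2", "A-3"]])
        t2 = table("m2", [("e1", "A-1", 1)])  # replicates 2,3 never amplified
        arr = build_detection_array(
            [assignment("e1", "m1"), assignment("e1", "m2")], [t1, t2],
            self.metadata[:3], rank="species",
        )
        assert np.isnan(arr.y[0, 0, 1, 1]) and np.isnan(arr.y[0, 0, 2, 1])
        assert arr.y[0, 0, 0, 1] == 1

    def test_generator_truth_recovered(self):
        data, truth = simulate.make_detection_history(
            n_taxa=3, n_sites=4, n_replicates=2, n_markers=2,
            hyper=simulate.OccupancyTruth(mu_alpha=(1.0, 0.0)), seed=2,
        )
        # route the simulated detections through ESV tables and back
        metadata, tables, assignments = [], [], []
        rows = {m: [] for m in data.markers}
        for i, site in enumerate(data.sites):
            for j in range(2):
                sid = f"{site}-{j + 1}"
                metadata.append(meta(sid, site, data.depth_m[i]))
                for m, marker in enumerate(data.markers):
                    for k, taxon in enumerate(data.taxa):
                        rows[marker].append(
                            (f"esv_{taxon}", sid, int(data.y[k, i, j, m]))
                        )
        for marker in data.markers:
            tables.append(table(marker, rows[marker]))
            for k, taxon in enumerate(data.taxa):
                assignments.append(
                    assignment(f"esv_{taxon}", marker, species=f"{taxon} fish")
                )
        arr = build_detection_array(assignments, tables, metadata, rank="species")
        assert arr.shape == data.shape
        # taxa sort alphabetically in both constructions
        np.testing.assert_array_equal(arr.y, data.y)


class TestDetectionArrayValidation:
    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError, match="0, 1 or missing"):
            DetectionArray(
                y=np.full((1, 2, 2, 1), 0.5), depth_m=[100, 200],
                taxa=["t"], sites=["a", "b"], markers=["m"],
            )

    def test_inconsistent_missing_pattern_rejected(self):
        y = np.zeros((2, 2, 2, 1))
        y[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing pattern"):
            DetectionArray(y=y, depth_m=[100, 200], taxa=["t1", "t2"],
                           sites=["a", "b"], markers=["m"])


class TestSummarizePosterior:
    def test_constant_chains_flagged_with_mean(self):
        draws = np.full((2, 100), 3.25)
        row = summarize_posterior(draws).iloc[0]
        assert row["mean"] == 3.25
        assert np.isnan(row["rhat"]) and not row["converged"]

    def test_single_chain_rhat_missing(self):
        draws = np.random.default_rng(0).normal(size=(1, 200))
        assert np.isnan(summarize_posterior(draws).iloc[0]["rhat"])

    def test_same_distribution_chains_converge(self):
        draws = np.random.default_rng(1).normal(size=(2, 2000))
        row = summarize_posterior(draws).iloc[0]
        assert row["rhat"] < 1.05 and row["converged"]

    def test_uniform_quantiles_near_nominal(self):
        draws = np.random.default_rng(2).uniform(size=(2, 20000))
        row = summarize_posterior(draws).iloc[0]
        assert row["q2.5"] == pytest.approx(0.025, abs=0.01)
        assert row["q97.5"] == pytest.approx(0.975, abs=0.01)


class TestSampler:
    def small_data(self, seed=0, **kw):
        kwargs = dict(n_taxa=4, n_sites=8, n_replicates=2, n_markers=2,
                      hyper=simulate.OccupancyTruth(mu_alpha=(0.5, -0.5)))
        kwargs.update(kw)
        return simulate.make_detection_history(seed=seed, **kwargs)

    def test_identical_seed_identical_draws(self):
        data, _ = self.small_data()
        r1 = fit_occupancy(data, draws=150, burnin=100, chains=2, seed=9)
        r2 = fit_occupancy(data, draws=150, burnin=100, chains=2, seed=9)
        for key in r1.posterior:
            np.testing.assert_array_equal(r1.posterior[key], r2.posterior[key])

    def test_taxon_relabelling_permutes_posteriors(self):
        data, _ = self.small_data()
        perm = [2, 0, 3, 1]
        permuted = DetectionArray(
            y=data.y[perm], depth_m=data.depth_m,
            taxa=[data.taxa[k] for k in perm], sites=data.sites,
            markers=data.markers,
        )
        r1 = fit_occupancy(data, draws=150, burnin=100, chains=2, seed=4)
        r2 = fit_occupancy(permuted, draws=150, burnin=100, chains=2, seed=4)
        # same seeded sampler on relabelled data: posterior summaries for a
        # given taxon agree regardless of its index position
        for taxon in data.taxa:
            a = np.sort(r1.posterior["theta"][:, :, data.taxa.index(taxon)], axis=None)
            b = np.sort(
                r2.posterior["theta"][:, :, permuted.taxa.index(taxon)], axis=None
            )
            # the latent-state draws consume randomness in index order, so
            # chains differ draw-by-draw; distributions must still agree
            assert abs(a.mean() - b.mean()) < 0.15

    def test_all_zero_taxon_runs_and_shifts_low(self):
        data, _ = self.small_data()
        y = data.y.copy()
        y[0] = 0.0
        silent = DetectionArray(y=y, depth_m=data.depth_m, taxa=data.taxa,
                                sites=data.sites, markers=data.markers)
        res = fit_occupancy(silent, draws=200, burnin=150, chains=2, seed=3)
        psi = res.occupancy_prob().mean(axis=(0, 1))
        detected = (np.nan_to_num(y).max(axis=(2, 3)) > 0).mean(axis=1)
        assert psi[0] < 0.6  # no free lunch for a never-detected taxon
        assert psi[np.argmax(detected)] > psi[0]

    def test_community_mean_detection_transform(self):
        data, _ = self.small_data()
        res = fit_occupancy(data, draws=100, burnin=80, chains=2, seed=5)
        res.posterior["mu_alpha"][:] = 0.0
        np.testing.assert_allclose(res.community_mean_detection("marker1"), 0.5)
        with pytest.raises(ValueError, match="unknown marker"):
            res.community_mean_detection("nope")

    def test_perfect_detection_limit_matches_naive_occupancy(self):
        hyper = simulate.OccupancyTruth(
            mu_alpha=(4.0,), sigma_alpha=0.01, mu_theta=8.0, sigma_theta=0.01
        )
        data, _ = simulate.make_detection_history(
            n_taxa=4, n_sites=200, n_replicates=3, n_markers=1,
            hyper=hyper, seed=3,
        )
        model = OccupancyModel(data, fix_theta=1.0, fix_detection=1.0)
        res = model.fit(draws=600, burnin=300, chains=2, seed=5)
        psihat = res.occupancy_prob().mean(axis=(0, 1))
        naive = (np.nan_to_num(data.y).max(axis=(2, 3)) > 0).mean(axis=1)
        assert np.abs(psihat - naive).max() < 0.02
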