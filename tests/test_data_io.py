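"""Inclusion filters, life-stage rules and photoquadrat aggregation."""

import numpy as np
import pandas as pd
import pytest

from coralfish.data_io import (
    DetectionHistory,
    LifeStageRuleGap,
    aggregate_cover,
    assign_life_stage,
    filter_species,
    read_detections,
    read_site_covariates,
    select_corals,
    write_detections,
    write_site_covariates,
)


def _benthic_rows(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "quadrat_id", "subunit_id", "taxon",
            "points_on_taxon", "total_points",
        ],
    )


class TestAggregateCover:
    def test_single_cell(self):
        b = _benthic_rows([("A", "q1", 1, "Siderastrea", 25, 50)])
        cov = aggregate_cover(b)
        assert cov.covers.loc["A", "Siderastrea"] == pytest.approx(50.0)

    def test_mean_over_quadrats(self):
        # quadrat means 10% and 0% -> site 5%
        b = _benthic_rows(
            [("A", "q1", 1, "coral", 5, 50), ("A", "q2", 1, "coral", 0, 50)]
        )
        cov = aggregate_cover(b)
        assert cov.covers.loc["A", "coral"] == pytest.approx(5.0)

    def test_nested_means_match_bruteforce(self, rng):
        # 3 sites x 4 quadrats x 5 subunits, random point counts
        taxa = ["coral", "turf", "sand"]
        rows, truth = [], {}
        for s in "ABC":
            per_site = []
            for q in range(4):
                per_quadrat = []
                for u in range(1, 6):
                    counts = rng.multinomial(50, [0.1, 0.5, 0.4])
                    for t, c in zip(taxa, counts):
                        rows.append((s, f"q{q}", u, t, int(c), 50))
                    per_quadrat.append(counts / 50)
                per_site.append(np.mean(per_quadrat, axis=0))
            truth[s] = np.mean(per_site, axis=0) * 100
        cov = aggregate_cover(_benthic_rows(rows))
        for s in "ABC":
            for t, expected in zip(taxa, truth[s]):
                assert cov.covers.loc[s, t] == pytest.approx(expected, abs=1e-10)

    def test_absent_taxon_counts_as_zero(self):
        b = _benthic_rows(
            [("A", "q1", 1, "coral", 50, 50), ("A", "q2", 1, "turf", 50, 50)]
        )
        cov = aggregate_cover(b)
        assert cov.covers.loc["A", "coral"] == pytest.approx(50.0)

    def test_idempotent_on_preaggregated(self):
        pre = pd.DataFrame(
            {"site_id": ["A", "A", "B"], "taxon": ["coral", "turf", "coral"],
             "cover": [0.04, 0.6, 0.0]}
        )
        cov = aggregate_cover(pre)
        again = aggregate_cover(
            cov.covers.div(100).reset_index().melt(
                id_vars="site_id", var_name="taxon", value_name="cover"
            )
        )
        pd.testing.assert_frame_equal(cov.covers, again.covers)

    def test_unknown_site_rejected(self):
        b = _benthic_rows([("ghost", "q1", 1, "coral", 1, 50)])
        with pytest.raises(ValueError, match="unknown site"):
            aggregate_cover(b, known_sites=["A"])

    def test_zero_total_points_rejected(self):
        b = _benthic_rows([("A", "q1", 1, "coral", 0, 0)])
        with pytest.raises(ValueError, match="total_points"):
            aggregate_cover(b)


class TestSelectCorals:
    def _cov(self, presence):
        covers = pd.DataFrame(presence, dtype=float) * 2.0
        covers["turf"] = 50.0
        from coralfish.data_io import SiteCovariates

        return SiteCovariates(covers=covers)

    def test_threshold_and_order(self):
        cov = self._cov(
            {"wide": [1] * 23 + [0] * 13, "mid": [1] * 5 + [0] * 31,
             "rare": [1] * 3 + [0] * 33, "absent": [0] * 36}
        )
        assert select_corals(cov, min_sites=4) == ["wide", "mid"]

    def test_turf_never_selected(self):
        cov = self._cov({"c": [1] * 10})
        assert "turf" not in select_corals(cov, min_sites=1)

    def test_empty(self):
        cov = self._cov({"c": [0] * 6})
        assert select_corals(cov) == []

    def test_min_sites_validated(self):
        cov = self._cov({"c": [1] * 6})
        with pytest.raises(ValueError):
            select_corals(cov, min_sites=0)


class TestLifeStage:
    @pytest.mark.parametrize(
        "length,TL,expected",
        [
            (12.0, 20.0, "adult"),     # large species, above 10 cm
            (8.0, 20.0, "juvenile"),   # large species, at/below 10 cm
            (10.0, 20.0, "juvenile"),  # boundary: adult requires > 10
            (6.0, 12.0, "adult"),      # mid species, above 5 cm
            (5.0, 12.0, "juvenile"),   # boundary: adult requires > 5
            (1.0, 4.0, "adult"),       # tiny species always adult
            (16.0, 16.0, "adult"),     # TL exactly 16 uses the 8-16 rule
        ],
    )
    def test_rules(self, length, TL, expected):
        assert assign_life_stage(length, TL) == expected

    def test_gap_band_warns_and_uses_fallback(self):
        with pytest.warns(LifeStageRuleGap):
            assert assign_life_stage(6.0, 6.5) == "adult"
        with pytest.warns(LifeStageRuleGap):
            assert assign_life_stage(4.0, 6.5, gap_policy="adult") == "adult"
        with pytest.warns(LifeStageRuleGap), pytest.raises(ValueError):
            assign_life_stage(4.0, 6.5, gap_policy="error")

    def test_positive_lengths_required(self):
        with pytest.raises(ValueError):
            assign_life_stage(0.0, 10.0)


def _history(y, n_occ=None):
    y = np.asarray(y, dtype=float)
    S, J, K = y.shape
    return DetectionHistory(
        sites=[f"s{i}" for i in range(S)],
        occasions=[[f"p{j}" for j in range(J)] for _ in range(S)],
        species=[(f"sp{k}", "adult") for k in range(K)],
        y=y,
    )


class TestFilterSpecies:
    def test_drops_zero_detection_species(self):
        y = np.zeros((2, 2, 3))
        y[0, 0, 0] = 1
        y[1, 1, 2] = 1
        dh, report = filter_species(_history(y))
        assert report.n_input == 3 and report.n_kept == 2
        assert ("sp1", "adult") in report.dropped_zero_detections
        assert (dh.detections_per_species() >= 1).all()

    def test_drops_unresolved(self):
        y = np.ones((1, 2, 4))
        dh, report = filter_species(_history(y), unresolved=["sp0", "sp3"])
        assert report.n_kept == 2
        assert {s for s, _ in dh.species} == {"sp1", "sp2"}

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError, match="entire assemblage"):
            filter_species(_history(np.zeros((1, 2, 2))))


class TestRoundTrips:
    def test_detections_roundtrip(self, tmp_path, rng):
        y = (rng.random((4, 3, 5)) < 0.3).astype(float)
        y[0, 2, :] = np.nan  # ragged site with 2 occasions
        dh = DetectionHistory(
            sites=["a", "b", "c", "d"],
            occasions=[["p0", "p1"]] + [["p0", "p1", "p2"]] * 3,
            species=[(f"sp{k}", "adult") for k in range(5)],
            y=y,
        )
        path = tmp_path / "det.csv"
        write_detections(dh, path)
        back = read_detections(path)
        assert back.sites == dh.sites
        assert back.species == dh.species
        assert back.n_occasions.tolist() == dh.n_occasions.tolist()
        np.testing.assert_array_equal(np.nan_to_num(back.y, nan=-1),
                                      np.nan_to_num(dh.y, nan=-1))

    def test_covariates_roundtrip(self, tmp_path):
        from coralfish.data_io import SiteCovariates

        covers = pd.DataFrame(
            {"coral": [0.0, 4.25, 19.2], "turf": [15.0, 57.0, 81.0]},
            index=pd.Index(["a", "b", "c"], name="site_id"),
        )
        depth = pd.Series(["shallow", "deep", "deep"], index=covers.index)
        cov = SiteCovariates(covers=covers, depth_class=depth)
        path = tmp_path / "cov.csv"
        write_site_covariates(cov, path)
        back = read_site_covariates(path)
        pd.testing.assert_frame_equal(back.covers, covers)
        assert back.depth_class.tolist() == depth.tolist()

    def test_ragged_design_has_no_sentinels(self):
        df = pd.DataFrame(
            {
                "site": ["a", "a", "b"],
                "plot": ["p0", "p1", "p0"],
                "species": ["x", "x", "x"],
                "stage": ["adult"] * 3,
                "detected": [1, 0, 1],
            }
        )
        dh = DetectionHistory.from_long(df)
        assert dh.n_occasions.tolist() == [2, 1]
        assert np.isnan(dh.y[1, 1, 0])
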