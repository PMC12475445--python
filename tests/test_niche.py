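import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon, box

from microniche.io_formats import RegionAnnotation
from microniche.niche import (
    call_contacts,
    compartment_area_fractions,
    composition_by_front_distance,
    contact_fractions,
    exocrine_composition,
    proximity_intensity_compare,
)
from microniche.synthetic import SyntheticConfig, generate_cohort, generate_lobule_cells
from oracles import brute_distance


def _cell(cid, x, y, cls="tumor", roi="r1", comp="lobule", **extra):
    return {
        "cell_id": cid, "x_um": x, "y_um": y, "tissue_class": cls,
        "roi_id": roi, "compartment": comp, **extra,
    }


class TestCallContacts:
    def test_radius_rule(self):
        cells = pd.DataFrame([_cell("c1", 0.0, 0.0)])
        regions = [
            RegionAnnotation("adm1", box(12, -5, 20, 5), tissue_class="adm", roi_id="r1"),
            RegionAnnotation("duct1", box(30, -5, 40, 5), tissue_class="duct", roi_id="r1"),
        ]
        table = call_contacts(cells, regions, radius_um=20.0)
        row = table.iloc[0]
        assert row["contact_adm"] and not row["contact_duct"]
        assert row["dist_adm"] == pytest.approx(12.0)
        assert np.isnan(row["dist_duct"])

    def test_cell_inside_fibrosis_polygon(self):
        cells = pd.DataFrame([_cell("c1", 5.0, 5.0)])
        regions = [RegionAnnotation("f1", box(0, 0, 10, 10), tissue_class="fibrosis", roi_id="r1")]
        row = call_contacts(cells, regions).iloc[0]
        assert row["contact_fibrosis"] and row["dist_fibrosis"] == 0.0

    def test_unknown_region_class_maps_to_other(self):
        cells = pd.DataFrame([_cell("c1", 0.0, 0.0)])
        regions = [RegionAnnotation("x", box(1, -1, 3, 1), tissue_class="mystery", roi_id="r1")]
        row = call_contacts(cells, regions).iloc[0]
        assert row["contact_other"]

    def test_no_tumor_cells_warns_empty(self, caplog):
        cells = pd.DataFrame([_cell("c1", 0.0, 0.0, cls="acinar")])
        with caplog.at_level("WARNING"):
            table = call_contacts(cells, [])
        assert table.empty
        assert "no tumor cells" in caplog.text

    def test_front_distance_filled(self):
        cells = pd.DataFrame([_cell("c1", 10.0, 0.0)])
        regions = [RegionAnnotation("f", LineString([(0, -50), (0, 50)]), role="front", roi_id="r1")]
        row = call_contacts(cells, regions).iloc[0]
        assert row["distance_to_front"] == pytest.approx(10.0)

    def test_matches_brute_force_on_synthetic_roi(self, rng):
        cfg = SyntheticConfig(seed=13, n_tumors=1, rois_per_compartment=1,
                              tumor_cells_per_roi=(60, 80), niche_cells_per_roi=200,
                              roi_size_um=250.0)
        cohort = generate_cohort(cfg)
        table = call_contacts(cohort.cells, cohort.regions, radius_um=20.0)
        cells = cohort.cells
        for roi, grp in table.groupby("roi_id"):
            others = cells[(cells.roi_id == roi) & (cells.tissue_class != "tumor")]
            specs = {
                i: {"type": "point", "xy": (r.x_um, r.y_um), "cls": r.tissue_class}
                for i, r in enumerate(others.itertuples(index=False))
            }
            tumor = cells[(cells.roi_id == roi) & (cells.tissue_class == "tumor")]
            tumor = tumor.set_index("cell_id")
            for _, row in grp.iterrows():
                q = (tumor.loc[row.cell_id, "x_um"], tumor.loc[row.cell_id, "y_um"])
                nearest = {}
                for spec in specs.values():
                    d = brute_distance(q, spec)
                    if d < 20.0 and d < nearest.get(spec["cls"], np.inf):
                        nearest[spec["cls"]] = d
                for cls in ("acinar", "adm", "duct", "islet", "fibrosis", "immune"):
                    assert row[f"contact_{cls}"] == (cls in nearest)
                    if cls in nearest:
                        assert row[f"dist_{cls}"] == pytest.approx(nearest[cls], abs=1e-9)

    def test_row_order_invariance(self, small_cohort):
        t1 = call_contacts(small_cohort.cells, small_cohort.regions)
        shuffled = small_cohort.cells.sample(frac=1.0, random_state=0)
        t2 = call_contacts(shuffled, small_cohort.regions)
        k = ["roi_id", "cell_id"]
        pd.testing.assert_frame_equal(
            t1.sort_values(k).reset_index(drop=True),
            t2.sort_values(k).reset_index(drop=True),
        )


class TestContactFractions:
    def _table(self, contact_rows):
        classes = ("fibrosis", "adm")
        rows = []
        for i, touched in enumerate(contact_rows):
            row = {"cell_id": f"c{i}", "roi_id": "r1", "compartment": "lobule",
                   "distance_to_front": np.nan}
            for c in classes:
                row[f"contact_{c}"] = c in touched
                row[f"dist_{c}"] = 1.0 if c in touched else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def test_only_fibrosis(self):
        out = contact_fractions(self._table([{"fibrosis"}, {"fibrosis"}]))
        out = out.set_index("tissue_class")
        assert out.loc["fibrosis", "fraction_cells"] == 1.0
        assert out.loc["fibrosis", "share"] == 1.0
        assert out.loc["adm", "fraction_cells"] == 0.0

    def test_hand_count_two_cells(self):
        out = contact_fractions(self._table([{"fibrosis"}, {"fibrosis", "adm"}]))
        out = out.set_index("tissue_class")
        assert out.loc["fibrosis", "fraction_cells"] == 1.0
        assert out.loc["adm", "fraction_cells"] == 0.5
        assert out.loc["fibrosis", "share"] == pytest.approx(2 / 3)
        assert out.loc["adm", "share"] == pytest.approx(1 / 3)

    def test_shares_sum_to_one(self, small_cohort):
        table = call_contacts(small_cohort.cells, small_cohort.regions)
        out = contact_fractions(table)
        for _, grp in out.groupby("compartment"):
            if grp["n_contacting"].sum():
                assert grp["share"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_group_key(self):
        with pytest.raises(ValueError, match="group"):
            contact_fractions(self._table([{"adm"}]), group_by="nope")


class TestCompositionByFrontDistance:
    def test_single_populated_bin(self):
        table = pd.DataFrame(
            [
                {"cell_id": "c1", "roi_id": "r", "compartment": "lobule",
                 "distance_to_front": 5.0, "contact_adm": True, "dist_adm": 3.0},
                {"cell_id": "c2", "roi_id": "r", "compartment": "lobule",
                 "distance_to_front": 5.5, "contact_adm": False, "dist_adm": np.nan},
            ]
        )
        profile = composition_by_front_distance(table, bin_width_um=10.0)
        assert set(profile.frame["bin_start"]) == {0.0}
        assert profile.frame.iloc[0]["fraction"] == 0.5

    def test_empty_bin_is_na_not_zero(self):
        table = pd.DataFrame(
            [
                {"cell_id": "c1", "roi_id": "r", "compartment": "lobule",
                 "distance_to_front": 25.0, "contact_adm": True, "dist_adm": 1.0},
            ]
        )
        profile = composition_by_front_distance(table, bin_width_um=10.0)
        first = profile.frame[profile.frame.bin_start == 0.0].iloc[0]
        assert np.isnan(first["fraction"]) and first["n_cells"] == 0

    def test_na_distance_counted_in_remainder(self):
        table = pd.DataFrame(
            [
                {"cell_id": "c1", "roi_id": "r", "compartment": "lobule",
                 "distance_to_front": np.nan, "contact_adm": True, "dist_adm": 1.0},
            ]
        )
        profile = composition_by_front_distance(table, bin_width_um=10.0)
        assert profile.n_unbinned == 1

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            composition_by_front_distance(pd.DataFrame(), bin_width_um=0.0)

    def test_aggregate_equals_contact_fractions(self, small_cohort):
        table = call_contacts(small_cohort.cells, small_cohort.regions)
        lobular = table.dropna(subset=["distance_to_front"])
        profile = composition_by_front_distance(lobular, bin_width_um=10.0)
        cf = contact_fractions(lobular.assign(compartment="all")).set_index("tissue_class")
        agg = profile.frame.dropna(subset=["fraction"])
        for cls, grp in agg.groupby("tissue_class"):
            pooled = (grp["fraction"] * grp["n_cells"]).sum() / grp["n_cells"].sum()
            assert pooled == pytest.approx(cf.loc[cls, "fraction_cells"], abs=1e-12)

    def test_planted_adm_enrichment_decays(self):
        cfg = SyntheticConfig(seed=21, n_tumors=6, rois_per_compartment=2,
                              tumor_cells_per_roi=(250, 300), niche_cells_per_roi=900,
                              roi_size_um=400.0)
        cohort = generate_cohort(cfg)
        table = call_contacts(cohort.cells, cohort.regions)
        lobular = table.dropna(subset=["distance_to_front"])
        profile = composition_by_front_distance(lobular, bin_width_um=40.0)
        adm = profile.frame[(profile.frame.tissue_class == "adm")
                            & (profile.frame.n_cells >= 100)]
        fractions = adm.sort_values("bin_start")["fraction"].to_numpy()
        # monotone decay within noise: first populated bin clearly above last
        assert fractions[0] > fractions[-1]


class TestCompartmentAreaFractions:
    def test_rectangles_30_60_10(self):
        anns = [
            RegionAnnotation("a", box(0, 0, 3, 10), tissue_class="lobular"),
            RegionAnnotation("b", box(5, 0, 11, 10), tissue_class="stromal"),
            RegionAnnotation("c", box(20, 0, 21, 10), tissue_class="other"),
        ]
        out = compartment_area_fractions(anns)
        assert out == pytest.approx({"lobular": 0.3, "stromal": 0.6, "other": 0.1})

    def test_single_class(self):
        anns = [RegionAnnotation("a", box(0, 0, 5, 5), tissue_class="lobular")]
        out = compartment_area_fractions(anns)
        assert out["lobular"] == 1.0

    def test_overlap_of_different_classes_errors(self):
        anns = [
            RegionAnnotation("a", box(0, 0, 10, 10), tissue_class="lobular"),
            RegionAnnotation("b", box(5, 5, 15, 15), tissue_class="stromal"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            compartment_area_fractions(anns)

    def test_matches_shoelace_oracle(self, rng):
        # random disjoint convex polygons; areas via the shoelace formula
        anns = []
        areas = {"lobular": 0.0, "stromal": 0.0, "other": 0.0}
        for i, cls in enumerate(["lobular"] * 3 + ["stromal"] * 3 + ["other"] * 2):
            cx, cy = 100.0 * i, 0.0
            pts = np.column_stack(
                [cx + rng.uniform(-30, 30, 7), cy + rng.uniform(-30, 30, 7)]
            )
            poly = Polygon(pts).convex_hull
            anns.append(RegionAnnotation(f"p{i}", poly, tissue_class=cls))
            xy = np.asarray(poly.exterior.coords)
            x, y = xy[:-1, 0], xy[:-1, 1]
            areas[cls] += 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        total = sum(areas.values())
        out = compartment_area_fractions(anns)
        for cls in areas:
            assert out[cls] == pytest.approx(areas[cls] / total, abs=1e-9)


class TestExocrineComposition:
    def _lobule(self, region_id="lob1", stage="mild"):
        return RegionAnnotation(region_id, box(0, 0, 100, 100), role="lobule",
                                attributes={"atrophy_stage": stage})

    def test_hand_count(self):
        rows = []
        flags = [(True, False)] * 4 + [(True, True)] * 3 + [(False, True)] * 2 + [(False, False)]
        for i, (a, k) in enumerate(flags):
            rows.append(_cell(f"c{i}", 10.0 + i, 10.0, cls="acinar",
                              positive_AMY=a, positive_KRT19=k, lobule_id="lob1"))
        out = exocrine_composition(pd.DataFrame(rows), [self._lobule()])
        row = out.iloc[0]
        assert row["fraction_amy_only"] == pytest.approx(0.4)
        assert row["fraction_double_positive"] == pytest.approx(0.3)
        assert row["fraction_krt19_only"] == pytest.approx(0.2)
        assert row["atrophy_stage"] == "mild"

    def test_all_amy_only(self):
        rows = [_cell(f"c{i}", 5.0, 5.0, cls="acinar", positive_AMY=True,
                      positive_KRT19=False, lobule_id="lob1") for i in range(5)]
        out = exocrine_composition(pd.DataFrame(rows), [self._lobule()])
        assert out.iloc[0]["fraction_amy_only"] == 1.0
        assert out.iloc[0]["fraction_double_positive"] == 0.0

    def test_tumor_cells_excluded(self):
        rows = [
            _cell("c0", 5.0, 5.0, cls="acinar", positive_AMY=True, positive_KRT19=False,
                  lobule_id="lob1"),
            _cell("c1", 6.0, 6.0, cls="tumor", positive_AMY=False, positive_KRT19=True,
                  lobule_id="lob1"),
        ]
        out = exocrine_composition(pd.DataFrame(rows), [self._lobule()])
        assert out.iloc[0]["n_cells"] == 1
        assert out.iloc[0]["fraction_amy_only"] == 1.0

    def test_empty_lobule_na(self):
        rows = [_cell("c0", 5.0, 5.0, cls="acinar", positive_AMY=True,
                      positive_KRT19=False, lobule_id="lob1")]
        out = exocrine_composition(
            pd.DataFrame(rows), [self._lobule(), self._lobule("lob2", "severe")]
        )
        assert np.isnan(out.set_index("lobule_id").loc["lob2", "fraction_amy_only"])

    def test_containment_assignment(self):
        rows = [_cell("c0", 5.0, 5.0, cls="acinar", positive_AMY=True, positive_KRT19=False)]
        out = exocrine_composition(pd.DataFrame(rows), [self._lobule()])
        assert out.iloc[0]["n_cells"] == 1

    def test_planted_stage_pattern(self, rng):
        cfg = SyntheticConfig()
        rows = []
        lobules = []
        means = {}
        for i, stage in enumerate(["minimal", "mild", "moderate", "severe", "end-stage"]):
            lob_geom = box(200.0 * i, 0, 200.0 * i + 100, 100)
            lob = RegionAnnotation(f"lob{i}", lob_geom, role="lobule",
                                   attributes={"atrophy_stage": stage})
            lobules.append(lob)
            rows.append(generate_lobule_cells(cfg, stage, 1500, lob_geom, f"lob{i}", rng))
            means[stage] = cfg.atrophy_composition[stage]
        out = exocrine_composition(pd.concat(rows, ignore_index=True), lobules)
        out = out.set_index("atrophy_stage")
        for stage, (fa, fd, fk) in means.items():
            assert out.loc[stage, "fraction_amy_only"] == pytest.approx(fa, abs=0.04)
            assert out.loc[stage, "fraction_double_positive"] == pytest.approx(fd, abs=0.04)
        # double positives peak at mild/moderate, acinar declines with atrophy
        dd = out["fraction_double_positive"]
        assert dd[["mild", "moderate"]].max() > dd[["minimal", "end-stage"]].max()
        assert out["fraction_amy_only"]["minimal"] > out["fraction_amy_only"]["end-stage"]


class TestProximityIntensityCompare:
    def _frame(self, tumor_xy, intensities, counterstain=1.0, ref_xy=((0.0, 0.0),)):
        rows = []
        for i, (x, y) in enumerate(ref_xy):
            rows.append(_cell(f"a{i}", x, y, cls="acinar"))
        for i, ((x, y), inten) in enumerate(zip(tumor_xy, intensities)):
            rows.append(_cell(f"t{i}", x, y, cls="tumor", intensity_M=inten,
                              counterstain_intensity=counterstain))
        return pd.DataFrame(rows)

    def test_equal_intensity_gives_one_and_p_one(self):
        xy = [(5.0, 0.0), (6.0, 0.0), (50.0, 0.0), (60.0, 0.0)]
        df = self._frame(xy, [1.0, 1.0, 1.0, 1.0])
        per, tests = proximity_intensity_compare(df, "acinar", ["M"])
        assert (per["normalized_intensity"] == 1.0).all()
        assert tests.iloc[0]["pvalue"] == 1.0

    def test_strict_group_rule(self):
        df = self._frame([(19.0, 0.0), (20.0, 0.0)], [1.0, 1.0])
        per, _ = proximity_intensity_compare(df, "acinar", ["M"])
        groups = per.set_index("cell_id")["group"]
        assert groups["t0"] == "within"
        assert groups["t1"] == "above"

    def test_zero_counterstain_excluded(self):
        df = self._frame([(5.0, 0.0), (6.0, 0.0)], [1.0, 2.0], counterstain=1.0)
        df.loc[df.cell_id == "t1", "counterstain_intensity"] = 0.0
        per, _ = proximity_intensity_compare(df, "acinar", ["M"])
        assert set(per["cell_id"]) == {"t0"}

    def test_normalization_by_counterstain(self):
        df = self._frame([(5.0, 0.0)], [3.0], counterstain=2.0)
        per, _ = proximity_intensity_compare(df, "acinar", ["M"])
        assert per.iloc[0]["normalized_intensity"] == pytest.approx(1.5)

    def test_planted_shift_detected(self, rng):
        # simulation oracle: near-group mean x1.5 with lognormal noise
        n_rep, n = 200, 400
        hits = 0
        for _ in range(n_rep):
            near = rng.lognormal(np.log(1.5), 0.5, n)
            far = rng.lognormal(0.0, 0.5, n)
            xy = [(5.0, float(i)) for i in range(n)] + [(500.0, float(i)) for i in range(n)]
            refs = [(0.0, float(i)) for i in range(n)]
            df = self._frame(xy, np.concatenate([near, far]), ref_xy=refs)
            _, tests = proximity_intensity_compare(df, "acinar", ["M"])
            if tests.iloc[0]["pvalue_bh"] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95
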