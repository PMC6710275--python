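"""Assignment, lineage classification, binning, H-scores, intensity mode."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from puncta import (
    AssignmentParams,
    BinningScheme,
    CellRecord,
    SpotRecord,
    assign_spots,
    classify_bin,
    classify_lineage,
    h_score,
    intensity_score,
)
from puncta.cells import build_cells, cells_from_truth
from puncta.segment import NucleusRecord


def _nucleus(nid, x, y):
    return NucleusRecord(
        id=nid,
        centroid_um=(x, y),
        coords=np.zeros((1, 2), dtype=int),
        area_um2=50.0,
        roundness=0.9,
        mean_intensity=0.5,
    )


def _spot(x, y, probe="PPIB", copies=1):
    return SpotRecord(
        probe=probe,
        centroid_um=(x, y),
        area_um2=0.6,
        integrated_intensity=1.5,
        peak_intensity=0.1,
        copies=copies,
    )


def _cell(cid, copies, probe="TREM2", lineage="microglia"):
    scheme = BinningScheme()
    return CellRecord(
        cell_id=cid,
        nucleus=None,
        probe_copies={probe: copies},
        lineage=lineage,
        bins={probe: classify_bin(copies, scheme)},
    )


class TestAssignment:
    def test_spot_beyond_max_radius_unassigned(self):
        nuclei = [_nucleus(1, 0.0, 0.0)]
        spots = [_spot(30.0, 0.0)]
        assign_spots(nuclei, spots)
        assert spots[0].cell_id is None

    def test_spot_within_radius_assigned(self):
        nuclei = [_nucleus(1, 0.0, 0.0)]
        spots = [_spot(24.9, 0.0)]
        assign_spots(nuclei, spots)
        assert spots[0].cell_id == 1

    def test_exact_tie_goes_to_lowest_id(self):
        nuclei = [_nucleus(7, 0.0, 0.0), _nucleus(3, 20.0, 0.0)]
        spots = [_spot(10.0, 0.0)]
        assign_spots(nuclei, spots)
        assert spots[0].cell_id == 3

    def test_duplicate_ids_rejected(self):
        nuclei = [_nucleus(1, 0.0, 0.0), _nucleus(1, 5.0, 0.0)]
        with pytest.raises(ValueError):
            assign_spots(nuclei, [_spot(1.0, 1.0)])

    def test_matches_brute_force_oracle_on_random_configurations(self):
        rng = np.random.default_rng(20)
        params = AssignmentParams()
        for _ in range(20):
            nuclei = [
                _nucleus(i + 1, x, y)
                for i, (x, y) in enumerate(rng.uniform(0, 200, size=(50, 2)))
            ]
            spots = [_spot(x, y) for x, y in rng.uniform(0, 200, size=(500, 2))]
            assign_spots(nuclei, spots, params)
            for s in spots:
                best, best_d = None, np.inf
                for n in nuclei:  # independent all-pairs oracle
                    d = np.hypot(
                        n.centroid_um[0] - s.centroid_um[0],
                        n.centroid_um[1] - s.centroid_um[1],
                    )
                    if d < best_d or (d == best_d and best is not None and n.id < best):
                        best, best_d = n.id, d
                expected = best if best_d <= params.max_cell_radius_um else None
                assert s.cell_id == expected

    def test_assigned_spot_distance_invariant(self, processed_scene):
        """Every assigned spot is within 25 µm of its nucleus and at least
        as close to it as to any other nucleus."""
        nuclei, spots = processed_scene[3], processed_scene[4]
        centers = {n.id: np.array(n.centroid_um) for n in nuclei}
        allc = np.array([n.centroid_um for n in nuclei])
        for s in spots:
            if s.cell_id is None:
                continue
            p = np.array(s.centroid_um)
            d_own = np.linalg.norm(centers[s.cell_id] - p)
            assert d_own <= 25.0 + 1e-9
            d_all = np.linalg.norm(allc - p, axis=1)
            assert d_own <= d_all.min() + 1e-9


class TestLineage:
    def test_single_positive_marker(self):
        assert classify_lineage({"P2RY12": 2, "SLC1A2": 0, "MAP2": 0}) == "microglia"

    def test_below_threshold_unclassified(self):
        assert classify_lineage({"P2RY12": 1, "SLC1A2": 0, "MAP2": 0}) == "unclassified"

    def test_two_markers_multiple(self):
        assert classify_lineage({"SLC1A2": 3, "MAP2": 2}) == "multiple"

    def test_custom_min_count(self):
        assert classify_lineage({"MAP2": 1}, min_count=1) == "neuron"


class TestBinning:
    @pytest.mark.parametrize(
        "copies,expected",
        [
            (0, 0),
            (1, 1),
            (2, 1),
            (3, 1),
            (4, 2),
            (9, 2),
            (10, 3),
            (15, 3),
            (16, 4),
            (100, 4),
        ],
    )
    def test_class_boundaries_at_printed_minima(self, copies, expected):
        assert classify_bin(copies) == expected

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            classify_bin(-1)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            classify_bin(3, BinningScheme(minima={1: 4, 2: 4, 3: 10, 4: 16}))

    @given(st.integers(min_value=0, max_value=60), st.integers(min_value=0, max_value=60))
    @settings(max_examples=100, derandomize=True)
    def test_bin_monotone_in_copies(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_bin(lo) <= classify_bin(hi)


class TestHScore:
    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4])
    def test_uniform_class_scores_100k(self, k):
        minima = BinningScheme().minima
        copies = 0 if k == 0 else minima[k]
        cells = [_cell(i, copies) for i in range(40)]
        res = h_score(cells, "TREM2", denominator="all")
        assert res.h_score == pytest.approx(100.0 * k)
        assert sum(res.percent_per_class.values()) == pytest.approx(100.0)

    def test_mixed_classes(self):
        cells = [_cell(i, 1) for i in range(10)] + [_cell(i + 10, 4) for i in range(10)]
        res = h_score(cells, "TREM2", denominator="all")
        assert res.h_score == pytest.approx(150.0)  # 1×50 + 2×50

    def test_probe_positive_denominator_excludes_negatives(self):
        cells = [_cell(1, 0), _cell(2, 16), _cell(3, 16)]
        res = h_score(cells, "TREM2", denominator="probe_positive")
        assert res.n_cells == 2
        assert res.h_score == pytest.approx(400.0)

    def test_lineage_denominator(self):
        cells = [
            _cell(1, 16, lineage="microglia"),
            _cell(2, 0, lineage="microglia"),
            _cell(3, 16, lineage="neuron"),
        ]
        res = h_score(cells, "TREM2", denominator="lineage:microglia")
        assert res.n_cells == 2 and res.h_score == pytest.approx(200.0)

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            h_score([_cell(1, 0)], "TREM2", denominator="probe_positive")

    def test_raising_one_cell_class_never_decreases_score(self):
        rng = np.random.default_rng(4)
        copies = rng.integers(0, 20, size=30).tolist()
        cells = [_cell(i, int(c)) for i, c in enumerate(copies)]
        base = h_score(cells, "TREM2", denominator="all").h_score
        for i in range(len(cells)):
            bumped = [_cell(j, int(c)) for j, c in enumerate(copies)]
            bumped[i] = _cell(i, copies[i] + 10)
            assert h_score(bumped, "TREM2", denominator="all").h_score >= base


class TestIntensityScore:
    def test_no_lineage_cells_is_an_error(self):
        with pytest.raises(ValueError):
            intensity_score(np.ones((8, 8)), [_cell(1, 0, lineage="microglia")], "neuron")

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(0)
        im = rng.uniform(0, 0.2, size=(64, 64))
        cells = [_cell(1, 0, lineage="neuron"), _cell(2, 0, lineage="neuron")]
        s1 = intensity_score(im, cells, "neuron", background=0.0)
        s2 = intensity_score(2 * im, cells, "neuron", background=0.0)
        assert s2 == pytest.approx(2 * s1)

    def test_synthetic_total_intensity_per_cell(self, default_scene):
        cfg, field, truth = default_scene
        n = len(truth.nuclei)
        cells = [_cell(i, 0, lineage="neuron") for i in range(n)]
        score = intensity_score(field.channels["PPIB"], cells, "neuron")
        expected = cfg.unit_copy_intensity * truth.total_copies("PPIB") / n
        assert score == pytest.approx(expected, rel=0.2)


def test_build_cells_aggregates_assigned_spots():
    nuclei = [_nucleus(1, 10.0, 10.0), _nucleus(2, 60.0, 60.0)]
    spots = [
        _spot(11.0, 10.0, probe="TREM2", copies=3),
        _spot(9.0, 10.0, probe="TREM2", copies=2),
        _spot(60.0, 61.0, probe="P2RY12", copies=2),
        _spot(150.0, 150.0, probe="TREM2", copies=5),  # unassignable
    ]
    assign_spots(nuclei, spots)
    cells = build_cells(nuclei, spots, test_probes=["TREM2"])
    by_id = {c.cell_id: c for c in cells}
    assert by_id[1].probe_copies["TREM2"] == 5
    assert by_id[1].bins["TREM2"] == 2
    assert by_id[2].lineage == "microglia"
    assert by_id[2].probe_copies.get("TREM2", 0) == 0


def test_cells_from_truth_reproduces_generator_counts(default_scene):
    _, _, truth = default_scene
    cells = cells_from_truth(truth, test_probes=["PPIB"])
    assert len(cells) == len(truth.nuclei)
    for c in cells:
        assert c.probe_copies["PPIB"] == truth.cell_probe_copies.get(
            (c.cell_id, "PPIB"), 0
        )
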