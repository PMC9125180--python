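import numpy as np
import pandas as pd
import pytest

from pawtrack import (
    AreaSpec,
    InteractionEvent,
    define_fields,
    detect_interactions,
    events_to_frame,
    import_posit_dict,
    occupancy,
    summarize_interactions,
)
from pawtrack.spatial import write_events_bed

from conftest import make_table
from oracles import interactions_oracle


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def test_single_point_occupancy():
    t = make_table({"s": np.full((10, 2), 5.0)})
    m = occupancy(t, "s", bins=10, extent=((0, 10), (0, 10)))
    assert m.counts.shape == (10, 10)
    assert m.counts.max() == 10
    assert m.counts.sum() == 10


def test_uniform_grid_one_per_bin():
    # bin centers of a 5x5 grid over [0, 5)^2
    centers = np.arange(5) + 0.5
    pts = np.array([(x, y) for x in centers for y in centers])
    t = make_table({"s": pts})
    m = occupancy(t, "s", bins=5, extent=((0, 5), (0, 5)))
    np.testing.assert_array_equal(m.counts, np.ones((5, 5)))


@pytest.mark.parametrize("bins", [5, 10, 50])
def test_occupancy_conservation(bins):
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 640, size=(777, 2))
    xy[10] = np.nan  # one invalid frame
    t = make_table({"s": xy})
    m = occupancy(t, "s", bins=bins)
    assert m.n_valid_frames == 776


def test_occupancy_pools_multiple_animals():
    a = make_table({"s": np.full((5, 2), 1.0)})
    b = make_table({"s": np.full((7, 2), 3.0)})
    m = occupancy([a, b], "s", bins=4, extent=((0, 4), (0, 4)))
    assert m.counts.sum() == 12


def test_occupancy_no_valid_frames_errors():
    t = make_table({"s": np.full((3, 2), np.nan)})
    with pytest.raises(ValueError):
        occupancy(t, "s")


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------

def test_rectangle_area_definition():
    a = AreaSpec.rectangle("obj1", 430, 35, 90, 75)
    assert (a.origin_x, a.origin_y, a.width, a.height) == (430, 35, 90, 75)
    assert a.contains(np.array([[470.0, 70.0]]))[0]
    # half-open: right/bottom edge is outside, origin is inside
    assert not a.contains(np.array([[520.0, 70.0]]))[0]
    assert a.contains(np.array([[430.0, 35.0]]))[0]


def test_legacy_posit_importer():
    areas = import_posit_dict(
        {"Obj_1": [1, 0, 0, 0, 430, 35, 90, 75],
         "Obj_2": [1, 0, 0, 0, 430, 380, 90, 75]}
    )
    assert [a.label for a in areas] == ["Obj_1", "Obj_2"]
    assert areas[1].origin_y == 380


def test_invalid_areas_rejected():
    with pytest.raises(ValueError):
        AreaSpec.circle("c", 0, 0, 0)
    with pytest.raises(ValueError, match="duplicate"):
        define_fields([AreaSpec.rectangle("a", 0, 0, 1, 1),
                       AreaSpec.rectangle("a", 5, 5, 1, 1)])


def test_circle_boundary_is_closed():
    c = AreaSpec.circle("c", 0, 0, 2.0)
    assert c.contains(np.array([[2.0, 0.0]]))[0]
    assert not c.contains(np.array([[2.0 + 1e-9, 0.0]]))[0]


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def test_single_visit_run():
    xy = np.full((20, 2), 100.0)
    xy[5:10] = [5.0, 5.0]
    t = make_table({"snout": xy}, fps=30)
    events = detect_interactions(t, "snout", [AreaSpec.rectangle("A", 0, 0, 10, 10)])
    assert len(events) == 1
    ev = events[0]
    assert (ev.start_frame, ev.end_frame) == (5, 9)
    assert ev.duration_s == pytest.approx(5 / 30)


def test_no_entry_yields_empty_list():
    t = make_table({"snout": np.full((20, 2), 100.0)}, fps=30)
    assert detect_interactions(
        t, "snout", [AreaSpec.circle("c", 0, 0, 1)]
    ) == []


def test_interactions_match_per_frame_oracle():
    rng = np.random.default_rng(12)
    xy = np.cumsum(rng.normal(scale=3.0, size=(2000, 2)), axis=0) + 50
    t = make_table({"snout": xy}, fps=30)
    areas = [
        AreaSpec.rectangle("R", 30, 30, 40, 40),
        AreaSpec.circle("C", 55, 55, 25),  # overlaps the rectangle
    ]
    events = detect_interactions(t, "snout", areas)
    got = [(e.area_label, e.start_frame, e.end_frame) for e in events]
    assert got == interactions_oracle(xy, areas, 30)
    assert len(events) > 5  # scenario actually exercises both areas


def test_events_invariant_under_joint_translation():
    rng = np.random.default_rng(13)
    xy = np.cumsum(rng.normal(scale=2.0, size=(500, 2)), axis=0) + 20
    areas = [AreaSpec.rectangle("R", 10, 10, 20, 20)]
    t0 = make_table({"s": xy}, fps=30)
    t1 = make_table({"s": xy + [123.0, -45.0]}, fps=30)
    moved = [a.translated(123.0, -45.0) for a in areas]
    e0 = [(e.start_frame, e.end_frame) for e in detect_interactions(t0, "s", areas)]
    e1 = [(e.start_frame, e.end_frame) for e in detect_interactions(t1, "s", moved)]
    assert e0 == e1


def test_min_frames_debounce():
    xy = np.full((20, 2), 100.0)
    xy[3] = [5.0, 5.0]       # 1-frame blip
    xy[8:12] = [5.0, 5.0]    # 4-frame visit
    t = make_table({"s": xy}, fps=30)
    area = [AreaSpec.rectangle("A", 0, 0, 10, 10)]
    assert len(detect_interactions(t, "s", area)) == 2
    assert len(detect_interactions(t, "s", area, min_frames=2)) == 1


# ---------------------------------------------------------------------------
# summaries and export
# ---------------------------------------------------------------------------

def test_summary_counts_and_times():
    events = [
        InteractionEvent("A", 0, 29, 1.0),
        InteractionEvent("A", 60, 89, 1.0),
    ]
    s = summarize_interactions(events, ["A", "B"])
    assert s["A"]["n_interactions"] == 2
    assert s["A"]["total_time_s"] == pytest.approx(2.0)
    assert s["B"]["n_interactions"] == 0
    assert s["B"]["total_time_s"] == 0.0
    assert s.table["total_time_s"].sum() == pytest.approx(
        sum(e.duration_s for e in events)
    )


def test_event_table_and_bed_export(tmp_path):
    events = [InteractionEvent("A", 5, 9, 5 / 30)]
    df = events_to_frame(events, fps=30)
    assert list(df.columns) == [
        "area", "start_frame", "end_frame", "start_s", "end_s", "duration_s"
    ]
    assert df.loc[0, "end_s"] == pytest.approx(10 / 30)
    bed = tmp_path / "events.bed"
    write_events_bed(events, bed)
    assert bed.read_text() == "A\t5\t10\n"
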