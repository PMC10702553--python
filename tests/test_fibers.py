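"""Fiber extraction, myelin assignment and morphometric selection."""

from collections import deque

import numpy as np
import pytest

from gratio import extract_fibers, select_fibers
from gratio.fibers import SelectionCriteria, fibers_table, instance_maps
from gratio.mask import AXON, BACKGROUND, MYELIN, LabelMask
from gratio.phantom import rasterize_fiber
from tests.conftest import match_design


def bfs_geodesic_distances(labels, axon_cc, comp_id):
    """4-connected geodesic distance from one axon component through axon|myelin."""
    support = labels != BACKGROUND
    dist = np.full(labels.shape, np.inf)
    q = deque()
    for r, c in np.argwhere(axon_cc == comp_id):
        dist[r, c] = 0
        q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < labels.shape[0] and 0 <= nc < labels.shape[1]:
                if support[nr, nc] and dist[nr, nc] == np.inf:
                    dist[nr, nc] = dist[r, c] + 1
                    q.append((nr, nc))
    return dist


def test_phantom_counts_match_designs(clean_scene):
    fibers = extract_fibers(clean_scene.mask)
    assert len(fibers) == len(clean_scene.fibers)
    for f in fibers:
        design = match_design(clean_scene, f.centroid)
        axon_px, myelin_px = rasterize_fiber(design, clean_scene.mask.shape)
        assert f.axon_area_px == int(axon_px.sum())
        assert f.myelin_area_px == int(myelin_px.sum())


def test_empty_mask_gives_empty_list():
    mask = LabelMask(np.zeros((32, 32), dtype=np.int64))
    assert extract_fibers(mask) == []


def test_partition_invariant(defect_scene):
    fibers, unassigned = extract_fibers(defect_scene.mask, return_unassigned=True)
    counts = defect_scene.mask.class_counts()
    assert sum(f.axon_area_px for f in fibers) == counts[AXON]
    assert sum(f.myelin_area_px for f in fibers) + int(unassigned.sum()) == counts[MYELIN]


def test_touching_rings_myelin_assigned_by_geodesic_distance():
    """Two fibers sharing a myelin boundary: every myelin pixel goes to the
    geodesically nearest axon (ties may go to either)."""
    from scipy import ndimage

    labels = np.zeros((64, 64), dtype=np.int64)
    rr, cc = np.indices(labels.shape)
    for center_c, in ((22,), (42,)):  # overlapping rings, disjoint axons
        d2 = (rr - 32) ** 2 + (cc - center_c) ** 2
        labels[d2 <= 12**2] = MYELIN
    for center_c, in ((22,), (42,)):
        d2 = (rr - 32) ** 2 + (cc - center_c) ** 2
        labels[d2 <= 6**2] = AXON
    mask = LabelMask(labels)
    fibers = extract_fibers(mask)
    assert len(fibers) == 2
    union = np.zeros_like(labels, dtype=bool)
    for f in fibers:
        union[f.myelin_pixels] = True
    assert int(union.sum()) == int((labels == MYELIN).sum())  # exact partition

    axon_cc, _ = ndimage.label(labels == AXON, structure=np.ones((3, 3), dtype=bool))
    dists = {f.fiber_id: bfs_geodesic_distances(labels, axon_cc, f.fiber_id + 1) for f in fibers}
    for f in fibers:
        other = [g for g in fibers if g.fiber_id != f.fiber_id][0]
        own = dists[f.fiber_id][f.myelin_pixels]
        rival = dists[other.fiber_id][f.myelin_pixels]
        assert (own <= rival).all()  # never assigned to a strictly farther axon


def test_unassigned_myelin_reported():
    labels = np.zeros((32, 32), dtype=np.int64)
    labels[4:8, 4:8] = MYELIN  # orphan ring fragment, no axon anywhere near
    labels[20:24, 20:24] = AXON
    fibers, unassigned = extract_fibers(LabelMask(labels), return_unassigned=True)
    assert len(fibers) == 1
    assert fibers[0].myelin_area_px == 0
    assert int(unassigned.sum()) == 16


def _square_mask(n_px_side, code=AXON, size=40):
    labels = np.zeros((size, size), dtype=np.int64)
    labels[4 : 4 + n_px_side, 4 : 4 + n_px_side] = code
    return LabelMask(labels)


def test_area_boundary_49_vs_50():
    """'Smaller than 50 pixels' is strict: 49 px excluded, 50 px retained."""
    mask49 = _square_mask(7)  # 49 px
    f49 = select_fibers(extract_fibers(mask49))[0]
    assert not f49.selected and f49.exclusion_reasons == frozenset({"area"})

    labels = np.zeros((40, 40), dtype=np.int64)
    labels[4:9, 4:14] = AXON  # 5x10 = 50 px
    f50 = select_fibers(extract_fibers(LabelMask(labels)))[0]
    assert f50.selected and f50.exclusion_reasons == frozenset()


def test_elongated_ellipse_excluded_by_eccentricity():
    """Ellipse a=40, b=10: eccentricity sqrt(1-1/16) ~ 0.968 > 0.95."""
    rr, cc = np.indices((64, 128))
    inside = ((cc - 64) / 40.0) ** 2 + ((rr - 32) / 10.0) ** 2 <= 1.0
    labels = np.where(inside, AXON, 0).astype(np.int64)
    f = select_fibers(extract_fibers(LabelMask(labels)))[0]
    assert f.axon_eccentricity == pytest.approx(np.sqrt(1 - (10 / 40) ** 2), abs=0.005)
    assert not f.selected and f.exclusion_reasons == frozenset({"eccentricity"})


def test_circular_axon_selected():
    rr, cc = np.indices((40, 40))
    labels = np.where((rr - 20) ** 2 + (cc - 20) ** 2 <= 100, AXON, 0).astype(np.int64)
    f = select_fibers(extract_fibers(LabelMask(labels)))[0]
    assert f.selected
    assert f.axon_eccentricity < 0.2 and f.axon_solidity > 0.9


def test_selection_is_pure_and_order_preserving(defect_scene):
    fibers = extract_fibers(defect_scene.mask)
    once = select_fibers(fibers)
    twice = select_fibers(once)
    assert [f.fiber_id for f in once] == [f.fiber_id for f in fibers]
    assert [(f.selected, f.exclusion_reasons) for f in once] == [
        (f.selected, f.exclusion_reasons) for f in twice
    ]
    assert sum(f.selected for f in once) <= len(fibers)


def test_defect_fibers_excluded_for_designed_reason(defect_scene):
    expected = {"oblique": {"eccentricity"}, "incomplete": {"solidity"}, "undersized": {"area"}}
    fibers = select_fibers(extract_fibers(defect_scene.mask))
    for f in fibers:
        design = match_design(defect_scene, f.centroid)
        if design.defect == "none":
            assert f.selected
        else:
            assert f.exclusion_reasons == frozenset(expected[design.defect])


def test_border_exclusion_flag():
    labels = np.zeros((30, 30), dtype=np.int64)
    labels[0:10, 10:20] = AXON  # touches top border, area 100, compact
    fibers = extract_fibers(LabelMask(labels))
    assert fibers[0].touches_border
    assert select_fibers(fibers)[0].selected  # default: border not excluded
    flagged = select_fibers(fibers, exclude_border=True)[0]
    assert not flagged.selected and "border" in flagged.exclusion_reasons


def test_tables_and_instance_maps(defect_scene):
    fibers = select_fibers(extract_fibers(defect_scene.mask))
    table = fibers_table(fibers)
    assert len(table) == len(fibers)
    assert table["selected"].sum() == sum(f.selected for f in fibers)
    maps = instance_maps(fibers, defect_scene.mask.shape)
    assert maps.shape == (2,) + defect_scene.mask.shape
    assert maps.max() == len(fibers)


def test_criteria_validation():
    with pytest.raises(ValueError):
        SelectionCriteria(max_eccentricity=1.2)
    with pytest.raises(ValueError):
        SelectionCriteria(min_area_px=0)
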