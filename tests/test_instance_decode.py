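import numpy as np
import pytest
from scipy import ndimage

from cystseg import (
    BinaryMask3D,
    InstanceMap3D,
    SemanticMap3D,
    decode_final,
    decode_initial,
    dilate_instances,
    downsample_labels,
    encode_erosion,
    filter_small,
    open_instances,
    recover_lost_cores,
    split_cores,
    total_cyst_volume,
    upsample_exam,
)
from cystseg.edgecore import CORE, CROSS3D, EDGE

from conftest import digitized_sphere


def sem_from_core(core):
    return SemanticMap3D(np.where(core, CORE, 0).astype(np.uint8), (1, 1, 1))


# ---------------------------------------------------------------------------
# decode_initial
# ---------------------------------------------------------------------------


def test_decode_initial_empty_and_separated():
    assert decode_initial(sem_from_core(np.zeros((5, 5, 5), bool))).data.max() == 0

    sem = np.zeros((7, 5, 5), dtype=np.uint8)
    sem[1, 2, 2] = CORE
    sem[2, 2, 2] = EDGE
    sem[3, 2, 2] = CORE
    out = decode_initial(SemanticMap3D(sem, (1, 1, 1)))
    assert out.labels().size == 2
    assert out.data[1, 2, 2] == 1  # scan order labelling
    assert out.data[3, 2, 2] == 2


def test_decode_initial_diagonal_cores_stay_separate():
    """18-adjacent (diagonal) cores are distinct under 6-connectivity."""
    core = np.zeros((6, 6, 6), bool)
    core[2, 2, 2] = True
    core[3, 3, 2] = True
    out = decode_initial(sem_from_core(core))
    assert out.labels().size == 2


# ---------------------------------------------------------------------------
# split_cores
# ---------------------------------------------------------------------------


def test_split_isolated_sphere_single_label():
    s = digitized_sphere((16, 16, 16), (8, 8, 8), 5.0)
    ws = split_cores(BinaryMask3D(s.astype(np.uint8), (1, 1, 1)))
    assert ws.labels().size == 1
    assert np.array_equal(ws.data > 0, s)  # no internal ridge voxels lost


def test_split_dumbbell_in_two():
    """Two radius-4 spheres, centres 6 apart: the overlapping neck must be
    cut into exactly 2 labels, separated near the mid-plane."""
    g = digitized_sphere((24, 16, 16), (8, 8, 8), 4.0)
    g |= digitized_sphere((24, 16, 16), (14, 8, 8), 4.0)
    ws = split_cores(BinaryMask3D(g.astype(np.uint8), (1, 1, 1)))
    assert ws.labels().size == 2
    # each original sphere centre belongs to a different label
    assert ws.data[8, 8, 8] != 0 and ws.data[14, 8, 8] != 0
    assert ws.data[8, 8, 8] != ws.data[14, 8, 8]


def test_split_empty():
    ws = split_cores(BinaryMask3D(np.zeros((6, 6, 6), np.uint8), (1, 1, 1)))
    assert ws.labels().size == 0


# ---------------------------------------------------------------------------
# recover_lost_cores
# ---------------------------------------------------------------------------


def test_recover_noop_when_all_labelled():
    s = digitized_sphere((12, 12, 12), (6, 6, 6), 4.0)
    core = BinaryMask3D(s.astype(np.uint8), (1, 1, 1))
    ws = split_cores(core)
    out = recover_lost_cores(core, ws)
    assert np.array_equal(out.data, ws.data)


def test_recover_missed_core_gets_next_label():
    core = np.zeros((10, 6, 6), bool)
    core[1:3, 2, 2] = True  # 2-voxel blob the watershed "missed"
    core[6:9, 2:5, 2:5] = True
    ws = np.zeros((10, 6, 6), dtype=np.int32)
    ws[6:9, 2:5, 2:5] = 4  # pretend watershed labelled only the big blob
    out = recover_lost_cores(
        BinaryMask3D(core.astype(np.uint8), (1, 1, 1)), InstanceMap3D(ws, (1, 1, 1))
    )
    assert out.data[1, 2, 2] == 5  # one plus the last label
    assert (out.data > 0).sum() == core.sum()


def test_recovery_conservation_on_dumbbell():
    """After recovery every core voxel carries exactly one positive label
    (ridge voxels join recovered components or become their own labels)."""
    g = digitized_sphere((24, 16, 16), (8, 8, 8), 4.0)
    g |= digitized_sphere((24, 16, 16), (14, 8, 8), 4.0)
    core = BinaryMask3D(g.astype(np.uint8), (1, 1, 1))
    out = recover_lost_cores(core, split_cores(core))
    assert (out.data > 0).sum() == g.sum()


def test_recover_rejects_labels_outside_core():
    core = BinaryMask3D(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
    ws = np.zeros((4, 4, 4), dtype=np.int32)
    ws[1, 1, 1] = 1
    with pytest.raises(ValueError):
        recover_lost_cores(core, InstanceMap3D(ws, (1, 1, 1)))


# ---------------------------------------------------------------------------
# dilate_instances
# ---------------------------------------------------------------------------


def brute_dilate_instances(labels):
    """Per-voxel oracle implementing the dilation contract directly:
    an unlabelled voxel joins the 6-neighbour with the largest core EDT,
    ties to the smallest label; one round."""
    data = labels.data
    edt = ndimage.distance_transform_edt(data > 0)
    out = data.copy()
    for idx in np.argwhere(data == 0):
        best = None  # (edt, -label): max edt, then smallest label
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = tuple(idx + d)
            if all(0 <= n[a] < data.shape[a] for a in range(3)) and data[n] > 0:
                key = (edt[n], -int(data[n]))
                if best is None or key > best:
                    best = key
        if best is not None:
            out[tuple(idx)] = -best[1]
    return out


def test_dilate_single_voxel():
    m = np.zeros((5, 5, 5), dtype=np.int32)
    m[2, 2, 2] = 1
    out = dilate_instances(InstanceMap3D(m, (1, 1, 1)))
    assert (out.data > 0).sum() == 7


def test_dilate_matches_per_voxel_oracle():
    data = np.zeros((10, 10, 6), dtype=np.int32)
    data[2:5, 2:5, 1:4] = 1
    data[5:8, 4:8, 2:5] = 2
    data[1, 8, 1] = 3
    labels = InstanceMap3D(data, (1, 1, 1))
    out = dilate_instances(labels)
    oracle = brute_dilate_instances(labels)
    assert np.array_equal(out.data, oracle)


def test_dilate_inverts_erosion_on_opened_sphere():
    s = digitized_sphere((12, 12, 12), (6, 6, 6), 4.0).astype(int)
    opened = open_instances(InstanceMap3D(s, (1, 1, 1)))
    sem = encode_erosion(opened)
    core = InstanceMap3D((sem.data == CORE).astype(np.int32), (1, 1, 1))
    out = dilate_instances(core)
    assert np.array_equal(out.data > 0, opened.data > 0)


# ---------------------------------------------------------------------------
# filter_small
# ---------------------------------------------------------------------------


def test_filter_small_boundary_and_relabel():
    data = np.zeros((20, 5, 5), dtype=np.int32)
    data[0:3, 0, 0] = 2  # 3 voxels -> removed
    data[5:15, 1, 1] = 5  # 10 voxels -> kept
    data[16:20, 2, 2] = 9  # exactly 4 voxels -> kept
    out = filter_small(InstanceMap3D(data, (1, 1, 1)), min_voxels=4)
    counts = np.bincount(out.data.ravel())
    assert np.array_equal(out.labels(), [1, 2])
    assert counts[1] == 10 and counts[2] == 4
    with pytest.raises(ValueError):
        filter_small(out, min_voxels=0)


# ---------------------------------------------------------------------------
# decode_final
# ---------------------------------------------------------------------------


def test_decode_final_empty():
    sem = SemanticMap3D(np.zeros((12, 12, 6), np.uint8), (1, 1, 1))
    out = decode_final(sem, (4, 4, 2))
    assert out.labels().size == 0
    assert out.shape == (4, 4, 2)


def test_decode_final_round_trip(roundtrip_exam):
    """Reference-standard round trip: encode the opened up-sampled truth,
    decode, and compare with the opened truth on the acquisition grid.
    Instance count is preserved exactly, TCV to within 0.1%, no output
    instance is smaller than 4 voxels, and every label is 6-connected."""
    vol, _, truth = roundtrip_exam
    _, up = upsample_exam(vol, truth, inplane_target=128)
    opened = open_instances(up)
    ref = downsample_labels(opened, truth.shape)
    dec = decode_final(encode_erosion(opened), truth.shape)

    assert dec.labels().size == ref.labels().size
    tcv_ref = total_cyst_volume(ref)
    assert abs(total_cyst_volume(dec) - tcv_ref) / tcv_ref <= 1e-3

    counts = np.bincount(dec.data.ravel())
    assert (counts[1:] >= 4).all()
    for lab in dec.labels():
        _, n = ndimage.label(dec.data == lab, structure=CROSS3D)
        assert n == 1
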