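import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitescan.errors import ValidationError
from sitescan.geometry import (
    AQUEOUS,
    HEADGROUP,
    HYDROPHOBIC_CORE,
    BACKBONE_NAMES,
    DistanceSeries,
    MembraneSlab,
    annotate_depth,
    block_average,
    ca_distance_series,
    iterative_superpose,
    kabsch_superpose,
    rmsd_series,
    truncate_sidechain,
)
from sitescan.structio import Atom, Structure
from sitescan.synth import synth_trajectory


def rotation_z(deg):
    t = np.radians(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
    )


def random_rotation(rng):
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ---------------------------------------------------------------------------
# kabsch_superpose
# ---------------------------------------------------------------------------

def test_identical_points_zero_rmsd():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    R, t, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-10)


def test_rigid_motion_recovered():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(8, 3))
    Rz = rotation_z(90.0)
    moved = pts @ Rz.T + np.array([1.0, -2.0, 3.0])
    R, t, rmsd = kabsch_superpose(moved, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    # recovered rotation is the inverse of the applied one
    np.testing.assert_allclose(R, Rz.T, atol=1e-9)
    np.testing.assert_allclose(moved @ R.T + t, pts, atol=1e-9)


def test_proper_rotation_even_for_reflected_input():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 3))
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    R, _, _ = kabsch_superpose(mirrored, pts)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_rmsd_is_stochastic_lower_bound():
    """Returned transform evaluates to the reported RMSD and beats 1,000
    random candidate rigid transforms."""
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(5, 3)) * 4.0
    jittered = pts + rng.normal(scale=0.3, size=(5, 3))
    R, t, rmsd = kabsch_superpose(jittered, pts)
    direct = np.sqrt(np.mean(np.sum((jittered @ R.T + t - pts) ** 2, axis=1)))
    assert rmsd == pytest.approx(direct)
    for _ in range(1000):
        Rc = random_rotation(rng)
        tc = rng.normal(scale=2.0, size=3)
        cand = np.sqrt(np.mean(np.sum((jittered @ Rc.T + tc - pts) ** 2, axis=1)))
        assert cand >= rmsd - 1e-9


def test_rigid_premotion_invariance():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(20, 3))
    target = pts + rng.normal(scale=0.5, size=(20, 3))
    _, _, base = kabsch_superpose(pts, target)
    for seed in range(5):
        r2 = np.random.default_rng(seed)
        moved = pts @ random_rotation(r2).T + r2.normal(scale=10.0, size=3)
        _, _, rmsd = kabsch_superpose(moved, target)
        assert rmsd == pytest.approx(base, abs=1e-9)


def test_count_mismatch_rejected():
    with pytest.raises(ValidationError):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def test_collinear_rejected():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValidationError):
        kabsch_superpose(pts, pts + 1.0)


def test_iterative_superpose_drops_outliers():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(50, 3)) * 5.0
    target = pts + rng.normal(scale=0.1, size=(50, 3))
    target[:5] += 25.0  # a divergent "linker"
    _, _, rmsd, keep = iterative_superpose(pts, target)
    assert keep.sum() == 45
    assert not keep[:5].any()
    assert rmsd < 0.3


# ---------------------------------------------------------------------------
# rmsd_series
# ---------------------------------------------------------------------------

def test_identical_frames_all_zero(two_atom_structure):
    s = two_atom_structure([([0, 0, 0], [3, 4, 0])] * 4)
    # need >= 3 atoms for superposition: use a bigger structure
    atoms = [
        Atom(serial=i + 1, name="CA", resname="ALA", chain="A", resid=i + 1,
             xyz=[float(i), float(i % 2), 0.5 * i], element="C")
        for i in range(5)
    ]
    s = Structure([atoms, atoms, atoms], id="x")
    np.testing.assert_allclose(rmsd_series(s), np.zeros(3), atol=1e-9)


def test_translated_frame_zero_after_superposition():
    rng = np.random.default_rng(6)
    base = [
        Atom(serial=i + 1, name="CA", resname="ALA", chain="A", resid=i + 1,
             xyz=rng.normal(size=3), element="C")
        for i in range(6)
    ]
    shifted = [
        Atom(serial=a.serial, name=a.name, resname=a.resname, chain=a.chain,
             resid=a.resid, xyz=a.xyz + np.array([5.0, -3.0, 2.0]), element="C")
        for a in base
    ]
    s = Structure([base, shifted], id="x")
    out = rmsd_series(s)
    assert out[0] == 0.0
    assert out[1] == pytest.approx(0.0, abs=1e-9)


def test_jittered_trajectory_matches_analytic_expectation(bundle):
    """Per-coordinate N(0, sigma^2) jitter on every atom gives an expected
    RMSD of ~ sigma * sqrt(3) (superposition removes a negligible 6 of the
    3N degrees of freedom)."""
    structure, _ = bundle
    sigma = 0.5
    traj = synth_trajectory(structure, n_frames=100, jitter_sd=sigma, seed=9)
    values = rmsd_series(traj, ref_frame_index=0)
    mean_rmsd = values[1:].mean()
    assert mean_rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)


def test_reference_entry_exact_zero_and_nonnegative(bundle):
    structure, _ = bundle
    traj = synth_trajectory(structure, n_frames=10, jitter_sd=1.0, seed=10)
    values = rmsd_series(traj, ref_frame_index=4)
    assert values[4] == 0.0
    assert (values >= 0).all()


def test_empty_selection_rejected(bundle):
    structure, _ = bundle
    with pytest.raises(ValidationError):
        rmsd_series(structure, selection=lambda a: a.name == "ZZ")


# ---------------------------------------------------------------------------
# ca_distance_series
# ---------------------------------------------------------------------------

def test_ca_distance_345(two_atom_structure):
    s = two_atom_structure([([0, 0, 0], [3, 4, 0])])
    series = ca_distance_series(s, (("A", 1), ("A", 2)))
    assert series.values[0] == pytest.approx(5.0)


def test_same_residue_distance_zero(two_atom_structure):
    s = two_atom_structure([([1, 2, 3], [4, 5, 6])])
    series = ca_distance_series(s, (("A", 1), ("A", 1)))
    assert series.values[0] == 0.0


def test_scripted_distances_recovered(two_atom_structure):
    script = [4.0, 5.5, 7.25, 3.125]
    s = two_atom_structure([([0, 0, 0], [d, 0, 0]) for d in script])
    series = ca_distance_series(s, (("A", 1), ("A", 2)))
    np.testing.assert_allclose(series.values, script, atol=1e-6)
    assert len(series) == 4


def test_missing_ca_names_residue(two_atom_structure):
    s = two_atom_structure([([0, 0, 0], [1, 0, 0])])
    with pytest.raises(ValidationError, match="A:9"):
        ca_distance_series(s, (("A", 1), ("A", 9)))


def test_distance_series_invariants():
    with pytest.raises(ValidationError):
        DistanceSeries(pair=(("A", 1), ("A", 2)), values=[-1.0])
    with pytest.raises(ValidationError):
        DistanceSeries(pair=(("A", 1), ("A", 2)), values=[np.nan])


# ---------------------------------------------------------------------------
# block_average
# ---------------------------------------------------------------------------

def block_average_oracle(values, window):
    out = []
    for start in range(0, len(values), window):
        chunk = values[start:start + window]
        out.append(sum(chunk) / len(chunk))
    return out


def test_block_average_forced():
    np.testing.assert_allclose(block_average(list(range(1, 11)), 10), [5.5])


def test_block_average_5000_to_500():
    values = np.random.default_rng(0).normal(size=5000)
    assert block_average(values, 10).shape == (500,)


def test_block_average_partial_tail():
    np.testing.assert_allclose(block_average([1.0, 2.0, 3.0], 2), [1.5, 3.0])


def test_block_average_empty():
    assert block_average([], 10).size == 0


def test_block_average_bad_window():
    with pytest.raises(ValidationError):
        block_average([1.0], 0)


@given(
    st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
    st.integers(min_value=1, max_value=30),
)
@settings(max_examples=60, deadline=None)
def test_block_average_matches_oracle(values, window):
    np.testing.assert_allclose(
        block_average(values, window), block_average_oracle(values, window), rtol=1e-12, atol=1e-9
    )


@given(st.integers(min_value=1, max_value=20), st.integers(min_value=1, max_value=12))
@settings(max_examples=40, deadline=None)
def test_block_average_preserves_mean_when_divisible(n_blocks, window):
    rng = np.random.default_rng(n_blocks * 100 + window)
    values = rng.normal(size=n_blocks * window)
    smoothed = block_average(values, window)
    assert smoothed.mean() == pytest.approx(values.mean(), abs=1e-12)


# ---------------------------------------------------------------------------
# annotate_depth
# ---------------------------------------------------------------------------

def make_ca_structure(zs):
    atoms = [
        Atom(serial=i + 1, name="CA", resname="ALA", chain="A", resid=i + 1,
             xyz=[0.0, 0.0, z], element="C")
        for i, z in enumerate(zs)
    ]
    return Structure([atoms], id="z")


def test_depth_core_center():
    slab = MembraneSlab(z_lower=-15.0, z_upper=15.0, headgroup_width=8.0)
    labels = annotate_depth(make_ca_structure([0.0]), slab)
    assert labels[("A", 1, "")] == HYDROPHOBIC_CORE


def test_depth_headgroup_outside_plane():
    slab = MembraneSlab(z_lower=-15.0, z_upper=15.0, headgroup_width=8.0)
    labels = annotate_depth(make_ca_structure([15.0 + 4.0]), slab)
    assert labels[("A", 1, "")] == HEADGROUP


def test_depth_aqueous_beyond():
    slab = MembraneSlab(z_lower=-15.0, z_upper=15.0, headgroup_width=8.0)
    labels = annotate_depth(make_ca_structure([40.0, -40.0]), slab)
    assert set(labels.values()) == {AQUEOUS}


def test_depth_matches_direct_conditional():
    rng = np.random.default_rng(7)
    zs = rng.uniform(-50, 50, size=200)
    slab = MembraneSlab(z_lower=-13.0, z_upper=14.0, headgroup_width=6.0)
    labels = annotate_depth(make_ca_structure(zs), slab)
    for i, z in enumerate(zs):
        if -13.0 <= z <= 14.0:
            expected = HYDROPHOBIC_CORE
        elif -19.0 <= z <= 20.0:
            expected = HEADGROUP
        else:
            expected = AQUEOUS
        assert labels[("A", i + 1, "")] == expected


def test_depth_partitions_every_residue(bundle):
    structure, _ = bundle
    slab = MembraneSlab(z_lower=10.0, z_upper=30.0)
    labels = annotate_depth(structure, slab)
    ca_residues = {a.residue_key for a in structure.models[0] if a.name == "CA"}
    assert set(labels) == ca_residues
    assert all(v in (HYDROPHOBIC_CORE, HEADGROUP, AQUEOUS) for v in labels.values())


def test_slab_validation():
    with pytest.raises(ValidationError):
        MembraneSlab(z_lower=5.0, z_upper=-5.0)
    with pytest.raises(ValidationError):
        MembraneSlab(z_lower=-5.0, z_upper=5.0, headgroup_width=0.0)


# ---------------------------------------------------------------------------
# truncate_sidechain
# ---------------------------------------------------------------------------

def make_residue(resname, names, chain="A", resid=1, serial0=0):
    return [
        Atom(serial=serial0 + i + 1, name=n, resname=resname, chain=chain,
             resid=resid, xyz=[float(i), 0.0, 0.0])
        for i, n in enumerate(names)
    ]


def test_arg_to_gly_leaves_backbone():
    arg = make_residue(
        "ARG", ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"]
    )
    s = Structure([arg], id="r")
    out = truncate_sidechain(s, "A", 1, "GLY")
    names = [a.name for a in out.models[0]]
    assert names == ["N", "CA", "C", "O"]
    assert out.models[0][0].resname == "GLY"
    assert [a.serial for a in out.models[0]] == [1, 2, 3, 4]


def test_oxt_is_kept():
    arg = make_residue("ARG", ["N", "CA", "C", "O", "OXT", "CB"])
    out = truncate_sidechain(Structure([arg], id="r"), "A", 1, "GLY")
    assert [a.name for a in out.models[0]] == ["N", "CA", "C", "O", "OXT"]


def test_ala_to_ala_identity():
    ala = make_residue("ALA", ["N", "CA", "C", "O", "CB"])
    s = Structure([ala], id="a")
    out = truncate_sidechain(s, "A", 1, "ALA")
    assert [a.name for a in out.models[0]] == ["N", "CA", "C", "O", "CB"]
    np.testing.assert_allclose(out.coords(0), s.coords(0))


def test_proline_unsupported():
    pro = make_residue("PRO", ["N", "CA", "C", "O", "CB", "CG", "CD"])
    with pytest.raises(ValidationError, match="proline"):
        truncate_sidechain(Structure([pro], id="p"), "A", 1, "GLY")


def test_missing_cb_for_ala_target():
    gly = make_residue("SER", ["N", "CA", "C", "O"])
    with pytest.raises(ValidationError, match="CB"):
        truncate_sidechain(Structure([gly], id="g"), "A", 1, "ALA")


def test_missing_residue():
    ala = make_residue("ALA", ["N", "CA", "C", "O", "CB"])
    with pytest.raises(ValidationError):
        truncate_sidechain(Structure([ala], id="a"), "B", 99, "GLY")


def test_bundle_gly_truncation_backbone_count(bundle):
    """GLY-truncating any residue of the synthetic bundle leaves exactly
    its backbone atoms (the bundle carries no PRO/GLY)."""
    structure, _ = bundle
    residues = structure.residues()[:10]
    for chain, resid, _, resname in residues:
        assert resname not in ("PRO", "GLY")
        out = truncate_sidechain(structure, chain, resid, "GLY")
        kept = [
            a for a in out.models[0] if a.chain == chain and a.resid == resid
        ]
        backbone_before = [
            a for a in structure.models[0]
            if a.chain == chain and a.resid == resid and a.name in BACKBONE_NAMES
        ]
        assert len(kept) == len(backbone_before)
        # other residues untouched
        assert out.n_atoms == structure.n_atoms - 1  # exactly CB removed
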