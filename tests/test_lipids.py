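"""Trajectory I/O, leaflet assignment, residency, traces, propensity, RMSF."""

import numpy as np
import pandas as pd
import pytest

from mechanokit import synth
from mechanokit.lipids import (
    Trajectory,
    assign_leaflets,
    contact_propensity,
    read_trajectory,
    residency_histogram,
    rmsd_series,
    rmsf,
    select,
    write_trajectory,
    z_trace,
)


def tiny_bilayer(n_frames=4, z=(20.0, -20.0)):
    """Two single-atom lipids at fixed heights."""
    top = pd.DataFrame(
        {
            "name": ["P", "P"],
            "element": ["P", "P"],
            "resname": ["LYPG", "LYPG"],
            "resid": [1, 2],
            "segment": ["lipid", "lipid"],
        }
    )
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 0, 2] = z[0]
    coords[:, 1, 2] = z[1]
    return Trajectory(topology=top, coords=coords, dt_ns=1.0)


class TestIO:
    def test_multimodel_pdb_round_trip(self, tmp_path, membrane_traj):
        t, _ = membrane_traj
        sub = Trajectory(t.topology, t.coords[:5], t.dt_ns, None if t.box is None else t.box[:5])
        p = tmp_path / "traj.pdb"
        write_trajectory(sub, str(p))
        t2 = read_trajectory(str(p))
        assert t2.n_frames == 5
        assert t2.n_atoms == sub.n_atoms
        np.testing.assert_allclose(t2.coords, sub.coords, atol=5e-3)
        assert list(t2.topology["resname"]) == list(sub.topology["resname"])

    def test_gro_topology_with_pdb_frames(self, tmp_path, membrane_traj):
        t, _ = membrane_traj
        sub = Trajectory(t.topology, t.coords[:3], t.dt_ns)
        gro = tmp_path / "top.gro"
        frames = tmp_path / "frames.pdb"
        write_trajectory(sub, str(gro), format="gro")
        write_trajectory(sub, str(frames), format="pdb")
        t2 = read_trajectory(str(gro), str(frames))
        assert t2.n_frames == 3 and t2.n_atoms == sub.n_atoms

    def test_read_stride_thins_frames(self, tmp_path, membrane_traj):
        t, _ = membrane_traj
        sub = Trajectory(t.topology, t.coords[:20], t.dt_ns)
        p = tmp_path / "s.pdb"
        write_trajectory(sub, str(p))
        t2 = read_trajectory(str(p), stride=10)
        assert t2.n_frames == 2
        np.testing.assert_allclose(t2.coords[1], sub.coords[10], atol=5e-3)

    def test_stride(self, membrane_traj):
        t, _ = membrane_traj
        assert t.strided(10).n_frames == t.n_frames // 10
        assert t.strided(10).dt_ns == pytest.approx(10 * t.dt_ns)

    def test_segment_classification(self, membrane_traj):
        t, _ = membrane_traj
        assert set(t.topology["segment"]) == {"protein", "lipid"}


class TestLeaflets:
    def test_two_lipids_split(self):
        t = tiny_bilayer()
        leaf = assign_leaflets(t)
        assert leaf[1].all() and not leaf[2].any()

    def test_all_equal_z_assigned_lower_with_warning(self):
        t = tiny_bilayer(z=(5.0, 5.0))
        with pytest.warns(UserWarning, match="midplane"):
            leaf = assign_leaflets(t)
        assert not leaf.to_numpy().any()

    def test_generator_labels_recovered_every_frame(self, membrane_traj):
        t, manifest = membrane_traj
        leaf = assign_leaflets(t)
        for resid, label in manifest["leaflet"].items():
            col = leaf[int(resid)]
            if label == "upper":
                assert col.all()
            else:
                assert not col.any()

    def test_single_lipid_errors(self):
        t = tiny_bilayer()
        t1 = Trajectory(t.topology.iloc[:1], t.coords[:, :1], 1.0)
        with pytest.raises(ValueError):
            assign_leaflets(t1)


class TestResidency:
    def test_single_fixed_lipid_single_hot_bin(self):
        top = pd.DataFrame(
            {
                "name": ["P", "P", "CA"],
                "element": ["P", "P", "C"],
                "resname": ["LYPG", "LYPG", "ALA"],
                "resid": [1, 2, 3],
                "segment": ["lipid", "lipid", "protein"],
            }
        )
        coords = np.zeros((100, 3, 3))
        coords[:, 0, :] = [3.0, -2.0, 20.0]
        coords[:, 1, 2] = -20.0
        t = Trajectory(top, coords, 1.0)
        grid = residency_histogram(t, "LYPG", stride=1, center=np.zeros(2))
        assert (grid.density == 1.0).sum() == 1
        assert grid.counts.sum() == 100
        x, y = grid.argmax_xy()
        assert abs(x - 3.0) <= 1.25 and abs(y + 2.0) <= 1.25

    def test_counts_conservation_with_dropped(self, membrane_traj):
        t, manifest = membrane_traj
        grid = residency_histogram(t, "LYPG", stride=1)
        leaf = assign_leaflets(t)
        n_upper_lypg = sum(
            1 for rid, lab in manifest["leaflet"].items() if lab == "upper"
            and t.topology.loc[t.topology.resid == int(rid), "resname"].iloc[0] == "LYPG"
        )
        total = n_upper_lypg * t.n_frames
        assert grid.counts.sum() + grid.dropped == total

    def test_argmax_in_pocket(self, membrane_traj):
        t, manifest = membrane_traj
        grid = residency_histogram(t, "LYPG", stride=1)
        x, y = grid.argmax_xy()
        px, py = manifest["pocket_center_xy"]
        assert np.hypot(x - px, y - py) <= manifest["pocket_radius"]

    def test_translation_invariance(self, membrane_traj):
        t, _ = membrane_traj
        shifted = Trajectory(t.topology, t.coords + np.array([13.0, -7.0, 0.0]), t.dt_ns, t.box)
        g1 = residency_histogram(t, "LYPG", stride=2)
        g2 = residency_histogram(shifted, "LYPG", stride=2)
        np.testing.assert_array_equal(g1.counts, g2.counts)

    def test_uniform_positions_match_multinomial(self):
        rng = np.random.default_rng(42)
        n_frames, n_lipids = 500, 100
        top = pd.DataFrame(
            {
                "name": ["P"] * n_lipids + ["CA"],
                "element": ["P"] * n_lipids + ["C"],
                "resname": ["LYPG"] * n_lipids + ["ALA"],
                "resid": list(range(1, n_lipids + 1)) + [999],
                "segment": ["lipid"] * n_lipids + ["protein"],
            }
        )
        coords = np.zeros((n_frames, n_lipids + 1, 3))
        coords[:, :n_lipids, 0] = rng.uniform(-37.5, 37.5, (n_frames, n_lipids))
        coords[:, :n_lipids, 1] = rng.uniform(-37.5, 37.5, (n_frames, n_lipids))
        coords[:, :n_lipids, 2] = 20.0
        coords[:, -1, 2] = 0.0
        # one lower-leaflet lipid so the midplane sits below the slab
        coords[:, 0, 2] = -20.0
        t = Trajectory(top, coords, 1.0)
        grid = residency_histogram(t, "LYPG", stride=1, center=np.zeros(2))
        n_obs = grid.counts.sum()
        p = 1.0 / (30 * 30)
        expected = n_obs * p
        sd = np.sqrt(n_obs * p * (1 - p))
        assert np.all(np.abs(grid.counts - expected) <= 4 * sd)

    def test_unknown_lipid_type_errors(self, membrane_traj):
        t, _ = membrane_traj
        with pytest.raises(ValueError, match="present"):
            residency_histogram(t, "NOPE")


class TestZTrace:
    def test_fixed_at_midplane_is_zero(self):
        t = tiny_bilayer(n_frames=6)
        top = t.topology.copy()
        top.loc[len(top)] = ["P", "P", "LYPG", 3, "lipid"]
        coords = np.zeros((6, 3, 3))
        coords[:, 0, 2] = 20.0
        coords[:, 1, 2] = -20.0
        coords[:, 2, 2] = 0.0  # exactly at the midplane
        t = Trajectory(top, coords, 1.0)
        tr = z_trace(t, 3)
        np.testing.assert_allclose(tr.z, 0.0, atol=1e-9)

    def test_planted_extraction_recovered(self):
        t, manifest = synth.gen_membrane_trajectory(n_frames=90, extraction=(60, 15.0), seed=31)
        tr = z_trace(t, manifest["tagged_resid"])
        rise = tr.z[-1] - tr.z[:10].mean()
        assert rise == pytest.approx(15.0, abs=1.0)

    def test_stride_halves_frames(self, membrane_traj):
        t, manifest = membrane_traj
        tr = z_trace(t, manifest["tagged_resid"], stride=2)
        assert len(tr.z) == t.n_frames // 2

    def test_missing_lipid_errors(self, membrane_traj):
        t, _ = membrane_traj
        with pytest.raises(KeyError):
            z_trace(t, 10_000)


class TestPropensity:
    def test_distant_lipid_all_zero(self, membrane_traj):
        t, manifest = membrane_traj
        # a non-tagged lipid wanders the box; pocket residues may rarely touch
        # it, but a lipid pinned far away never does
        top = t.topology.copy()
        coords = t.coords.copy()
        far = top[top.segment == "lipid"].resid.iloc[-1]
        idx = (top.resid == far).to_numpy()
        coords[:, idx, :2] = 5.0  # fixed corner, >40 Å from the protein
        t2 = Trajectory(top, coords, t.dt_ns)
        df = contact_propensity(t2, int(far))
        assert (df["propensity"] == 0).all()

    def test_exactly_matches_planted_schedule(self, membrane_traj):
        t, manifest = membrane_traj
        df = contact_propensity(t, manifest["tagged_resid"])
        pocket = df[df.resid.isin(manifest["pocket_resids"])]
        expected = len(manifest["contact_frames"]) / t.n_frames
        assert set(pocket["propensity"]) == {expected}
        assert (pocket["n_contact_frames"] == len(manifest["contact_frames"])).all()

    def test_permanent_occupancy_gives_one(self):
        t, manifest = synth.gen_membrane_trajectory(
            n_frames=20, pocket_occupancy_fraction=1.0, seed=33
        )
        df = contact_propensity(t, manifest["tagged_resid"])
        pocket = df[df.resid.isin(manifest["pocket_resids"])]
        assert (pocket["propensity"] == 1.0).all()

    def test_empty_selection_errors(self, membrane_traj):
        t, manifest = membrane_traj
        with pytest.raises(ValueError):
            contact_propensity(t, manifest["tagged_resid"], protein_resids=[99999])


class TestRmsfRmsd:
    def test_static_trajectory_zero(self):
        t, _ = synth.gen_membrane_trajectory(n_frames=10, jitter_sigma=0.0, seed=41)
        r = rmsf(t)
        assert r["rmsf"].max() == pytest.approx(0.0, abs=1e-9)
        rd = rmsd_series(t)
        assert rd["rmsd"].max() == pytest.approx(0.0, abs=1e-9)

    def test_rigid_tumbling_zero_after_superposition(self):
        t, _ = synth.gen_membrane_trajectory(n_frames=6, jitter_sigma=0.0, seed=42)
        prot = select(t, segment="protein")
        rng = np.random.default_rng(3)
        coords = t.coords.copy()
        for f in range(t.n_frames):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            coords[f] = coords[f] @ Q.T + rng.normal(0, 5, 3)
        t2 = Trajectory(t.topology, coords, t.dt_ns)
        rd = rmsd_series(t2)
        assert rd["rmsd"].max() == pytest.approx(0.0, abs=1e-6)

    def test_gaussian_jitter_rmsf_closed_form(self):
        sigma = 0.5
        t, manifest = synth.gen_membrane_trajectory(n_frames=400, jitter_sigma=sigma, seed=43)
        r = rmsf(t)
        jittered = r[r.resid.isin(manifest["column_resids"])]
        ratio = jittered["rmsf"].mean() / (sigma * np.sqrt(3))
        assert ratio == pytest.approx(1.0, abs=0.07)

    def test_too_few_frames_error(self, membrane_traj):
        t, _ = membrane_traj
        t1 = Trajectory(t.topology, t.coords[:1], t.dt_ns)
        with pytest.raises(ValueError):
            rmsf(t1)
        with pytest.raises(ValueError):
            rmsd_series(t1)
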