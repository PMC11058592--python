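"""Interaction detection, state-conditioned occupancy, and network
differencing."""

import numpy as np
import pytest

from loopshift import (DetectorConfig, LoopSystemSpec, PlantRule, Topology,
                       detect_contacts, detect_hbonds, interaction_occupancy,
                       make_reference_states, network_difference,
                       plant_interactions, residue_projection,
                       simulate_loop_ensemble)
from loopshift.interactions import (BACKBONE_NAMES, HBondDetector,
                                    _is_acceptor, _is_donor, _pair_allowed)
from loopshift.states import StateLabelSeries
from loopshift.errors import ConfigError, EmptySeriesError


def _topology(atoms):
    """atoms: list of (name, element, res_idx, res_name)."""
    return Topology.from_fields(
        atom_ids=range(1, len(atoms) + 1),
        atom_names=[a[0] for a in atoms], elements=[a[1] for a in atoms],
        residue_indices=[a[2] for a in atoms],
        residue_names=[a[3] for a in atoms],
        chain_ids=["A"] * len(atoms))


def brute_force_hbond_scan(coords, top, d_max, angle_min, mode):
    """Independent exhaustive scan re-implementing the geometric criteria
    with plain loops."""
    found = set()
    n = top.n_atoms
    for d in range(n):
        if not _is_donor(top, d):
            continue
        for a in range(n):
            if not _is_acceptor(top, a) or not _pair_allowed(top, d, a):
                continue
            if np.linalg.norm(coords[d] - coords[a]) > d_max:
                continue
            if mode == "heavy_only":
                found.add((d, a))
                continue
            for h in range(n):
                if top.elements[h].upper() != "H":
                    continue
                if (top.residue_indices[h] != top.residue_indices[d]
                        or top.chain_ids[h] != top.chain_ids[d]):
                    continue
                if np.linalg.norm(coords[h] - coords[d]) > 1.25:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                    found.add((d, a))
                    break
    return found


class TestHBondDetection:
    def test_ideal_linear_geometry_detected(self):
        top = _topology([("N", "N", 1, "ALA"), ("H", "H", 1, "ALA"),
                         ("O", "O", 5, "GLY")])
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        keys = detect_hbonds(coords, top)
        assert len(keys) == 1
        (key,) = keys
        assert key.kind == "hbond" and key.backbone

    def test_long_distance_not_detected(self):
        top = _topology([("N", "N", 1, "ALA"), ("H", "H", 1, "ALA"),
                         ("O", "O", 5, "GLY")])
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        assert detect_hbonds(coords, top) == set()

    def test_bent_geometry_not_detected(self):
        top = _topology([("N", "N", 1, "ALA"), ("H", "H", 1, "ALA"),
                         ("O", "O", 5, "GLY")])
        # acceptor at right angle from the N-H bond: D-H...A angle = 90 deg
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]])
        assert detect_hbonds(coords, top) == set()

    def test_proline_backbone_nitrogen_never_donates(self):
        top = _topology([("N", "N", 1, "PRO"), ("O", "O", 5, "GLY")])
        coords = np.array([[0, 0, 0], [2.9, 0, 0]])
        assert detect_hbonds(coords, top, mode="heavy_only") == set()
        # the same geometry with a non-proline donor is detected
        top2 = _topology([("N", "N", 1, "ALA"), ("O", "O", 5, "GLY")])
        assert len(detect_hbonds(coords, top2, mode="heavy_only")) == 1

    @pytest.mark.parametrize("mode", ["heavy_only", "with_hydrogens"])
    def test_matches_exhaustive_scan_on_random_frames(self, mode, rng):
        names = [("N", "N"), ("O", "O"), ("CA", "C"), ("NZ", "N"),
                 ("OE1", "O"), ("H", "H"), ("CB", "C")]
        res_names = ["ALA", "LYS", "GLU", "SER", "PRO"]
        for _ in range(10):
            atoms = []
            for i in range(30):
                nm, el = names[rng.integers(len(names))]
                atoms.append((nm, el, int(rng.integers(1, 9)),
                              res_names[rng.integers(len(res_names))]))
            top = _topology(atoms)
            coords = rng.uniform(0, 12, size=(30, 3))
            det = HBondDetector(top, DetectorConfig(hbond_mode=mode))
            got = {(int(det.pair_d[k]), int(det.pair_a[k]))
                   for k in np.nonzero(det.pair_mask(coords[None])[0])[0]}
            oracle = brute_force_hbond_scan(coords, top, 3.5, 135.0, mode)
            assert got == oracle


class TestContacts:
    def test_far_apart_no_contact(self):
        top = _topology([("CB", "C", 1, "ALA"), ("CB", "C", 5, "ALA")])
        coords = np.array([[0, 0, 0], [20.0, 0, 0]])
        assert detect_contacts(coords, top) == set()

    def test_arg_glu_salt_bridge(self):
        top = _topology([("NH1", "N", 1, "ARG"), ("OE1", "O", 5, "GLU")])
        coords = np.array([[0, 0, 0], [3.5, 0, 0]])
        keys = detect_contacts(coords, top)
        assert len(keys) == 1 and next(iter(keys)).kind == "saltbridge"

    def test_matches_exhaustive_pair_scan(self, rng):
        atoms = []
        for i in range(25):
            res = int(rng.integers(1, 8))
            nm, el = [("CB", "C"), ("NH1", "N"), ("OE1", "O"), ("CA", "C")][rng.integers(4)]
            rn = ["ARG", "GLU", "ALA"][rng.integers(3)]
            atoms.append((nm, el, res, rn))
        top = _topology(atoms)
        for _ in range(10):
            coords = rng.uniform(0, 10, size=(25, 3))
            got = {(k.res_i, k.res_j) for k in detect_contacts(coords, top)}
            oracle = set()
            sc = [i for i in range(25) if top.atom_names[i] not in BACKBONE_NAMES]
            for a in sc:
                for b in sc:
                    ra, rb = int(top.residue_indices[a]), int(top.residue_indices[b])
                    if ra >= rb:
                        continue
                    if np.linalg.norm(coords[a] - coords[b]) <= 4.5:
                        oracle.add((ra, rb))
            assert got == oracle


def _planted_system(occupancy, seed=0, n_replicas=3, n_frames=400,
                    stationary=(0.4, 0.3, 0.3)):
    from loopshift import sticky_transition_matrix
    spec = LoopSystemSpec(
        n_replicas=n_replicas, n_frames=n_frames, seed=seed,
        transition_matrix=sticky_transition_matrix(stationary, 0.2),
        interaction_sites=((28, "NZ", "N"), (40, "OE1", "O")),
        residue_names={28: "LYS", 40: "GLU"})
    refs, top = make_reference_states(spec)
    ens, truth = simulate_loop_ensemble(spec, refs, top)
    nz = int(top.atom_ids[np.nonzero((top.residue_indices == 28)
                                     & (top.atom_names == "NZ"))[0][0]])
    oe = int(top.atom_ids[np.nonzero((top.residue_indices == 40)
                                     & (top.atom_names == "OE1"))[0][0]])
    rule = PlantRule(donor_atom_id=nz, acceptor_atom_id=oe,
                     state="wide_open", occupancy=occupancy)
    ens = plant_interactions(ens, truth, [rule], seed=seed + 1)
    return spec, top, ens, truth


class TestOccupancy:
    def test_full_occupancy_recovered_exactly(self):
        spec, top, ens, truth = _planted_system(1.0)
        tab = interaction_occupancy(ens, truth,
                                    DetectorConfig(hbond_mode="heavy_only"))
        hits = {k: v for (k, s), v in tab.pooled.items()
                if s == "wide_open" and k.res_i == 28 and k.res_j == 40
                and k.kind == "hbond"}
        assert len(hits) == 1
        assert next(iter(hits.values())) == 1.0
        # the LYS/GLU pair at 2.9 A is simultaneously a salt bridge
        assert any(k.kind == "saltbridge" and s == "wide_open"
                   for (k, s) in tab.pooled)

    def test_partial_occupancy_within_binomial_ci(self):
        spec, top, ens, truth = _planted_system(0.6, seed=4, n_frames=800)
        tab = interaction_occupancy(ens, truth,
                                    DetectorConfig(hbond_mode="heavy_only"))
        occ = [v for (k, s), v in tab.pooled.items()
               if s == "wide_open" and k.res_i == 28][0]
        n = int(sum(tab.state_frames["wide_open"]))
        margin = 2.58 * np.sqrt(0.6 * 0.4 / n)
        assert abs(occ - 0.6) < margin

    def test_zero_occupancy_key_absent(self):
        spec, top, ens, truth = _planted_system(0.0, seed=5)
        tab = interaction_occupancy(ens, truth,
                                    DetectorConfig(hbond_mode="heavy_only"))
        assert not any(k.res_i == 28 and k.res_j == 40 and s == "wide_open"
                       for (k, s) in tab.pooled)

    def test_empty_state_warns_and_is_omitted(self):
        labels = np.zeros((2, 50), dtype=np.int8)  # closed only
        spec = LoopSystemSpec(n_replicas=2, n_frames=50, seed=6)
        refs, top = make_reference_states(spec)
        ens, _ = simulate_loop_ensemble(spec, refs, top)
        lab = StateLabelSeries(labels=labels, thresholds_used={})
        with pytest.warns(UserWarning, match="zero frames"):
            tab = interaction_occupancy(ens, lab,
                                        DetectorConfig(hbond_mode="heavy_only"))
        assert "wide_open" not in tab.state_frames

    def test_occupancy_invariant_to_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        from loopshift import ReplicaEnsemble
        spec, top, ens, truth = _planted_system(0.7, seed=7)
        cfg = DetectorConfig(hbond_mode="heavy_only")
        t1 = interaction_occupancy(ens, truth, cfg)
        R = Rotation.from_euler("xyz", [10, 60, -30], degrees=True).as_matrix()
        moved = ReplicaEnsemble(topology=top, coords=ens.coords @ R.T + 3.0,
                                frame_interval_ps=100.0)
        t2 = interaction_occupancy(moved, truth, cfg)
        assert t1.pooled == t2.pooled


class TestNetworkDiff:
    def test_identical_tables_zero_delta(self):
        spec, top, ens, truth = _planted_system(0.5, seed=8)
        cfg = DetectorConfig(hbond_mode="heavy_only")
        tab = interaction_occupancy(ens, truth, cfg)
        diff = network_difference(tab, tab, "wide_open")
        assert np.allclose(diff["delta"], 0.0)

    def test_planted_09_vs_01_is_rank_one(self):
        cfg = DetectorConfig(hbond_mode="heavy_only")
        _, _, ens_a, tr_a = _planted_system(0.9, seed=9)
        _, _, ens_b, tr_b = _planted_system(0.1, seed=10)
        ta = interaction_occupancy(ens_a, tr_a, cfg)
        tb = interaction_occupancy(ens_b, tr_b, cfg)
        diff = network_difference(ta, tb, "wide_open")
        top_row = diff.iloc[0]
        assert top_row["res_i"] == 28 and top_row["res_j"] == 40
        assert abs(top_row["delta"] - 0.8) < 0.1
        assert top_row["rank"] == 1

    def test_key_only_in_one_table_union_convention(self):
        cfg = DetectorConfig(hbond_mode="heavy_only")
        _, _, ens_a, tr_a = _planted_system(0.5, seed=11)
        _, _, ens_b, tr_b = _planted_system(0.0, seed=12)
        ta = interaction_occupancy(ens_a, tr_a, cfg)
        tb = interaction_occupancy(ens_b, tr_b, cfg)
        diff = network_difference(ta, tb, "wide_open")
        row = diff[(diff.res_i == 28) & (diff.res_j == 40)].iloc[0]
        assert row["occ_b"] == 0.0 and row["delta"] > 0.3

    def test_antisymmetry(self):
        cfg = DetectorConfig(hbond_mode="heavy_only")
        _, _, ens_a, tr_a = _planted_system(0.8, seed=13)
        _, _, ens_b, tr_b = _planted_system(0.2, seed=14)
        ta = interaction_occupancy(ens_a, tr_a, cfg)
        tb = interaction_occupancy(ens_b, tr_b, cfg)
        d_ab = network_difference(ta, tb, "wide_open").set_index("key")["delta"]
        d_ba = network_difference(tb, ta, "wide_open").set_index("key")["delta"]
        for k in d_ab.index:
            assert abs(d_ab[k] + d_ba[k]) < 1e-12

    def test_state_absent_from_both_rejected(self):
        spec, top, ens, truth = _planted_system(0.5, seed=15)
        cfg = DetectorConfig(hbond_mode="heavy_only")
        tab = interaction_occupancy(ens, truth, cfg)
        with pytest.raises(EmptySeriesError):
            network_difference(tab, tab, "other")


class TestResidueProjection:
    def test_single_interaction_scores_both_residues(self):
        import pandas as pd
        diff = pd.DataFrame([{"res_i": 354, "res_j": 361, "delta": 0.8}])
        scores = residue_projection(diff)
        assert scores == {354: 0.8, 361: 0.8}

    def test_conservation_sum_rule(self, rng):
        import pandas as pd
        rows = [{"res_i": int(rng.integers(1, 20)),
                 "res_j": int(rng.integers(20, 40)),
                 "delta": float(rng.normal())} for _ in range(30)]
        diff = pd.DataFrame(rows)
        scores = residue_projection(diff)
        assert abs(sum(scores.values()) - 2 * diff["delta"].abs().sum()) < 1e-9


def test_conflicting_plant_rules_rejected():
    spec = LoopSystemSpec(n_replicas=1, n_frames=10, seed=1,
                          interaction_sites=((28, "NZ", "N"), (40, "OE1", "O")))
    refs, top = make_reference_states(spec)
    ens, truth = simulate_loop_ensemble(spec, refs, top)
    r1 = PlantRule(donor_atom_id=29, acceptor_atom_id=42,
                   state="closed", occupancy=0.5)
    r2 = PlantRule(donor_atom_id=29, acceptor_atom_id=42,
                   state="open", occupancy=0.5)
    with pytest.raises(ConfigError):
        plant_interactions(ens, truth, [r1, r2])
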