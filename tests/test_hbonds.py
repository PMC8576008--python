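"""Hydrogen-bond detection geometry and fraction statistics."""

import numpy as np
import pandas as pd
import pytest

from cellufacet.hbonds import (
    HBondCriteria,
    MissingHydrogenError,
    detect_hbonds,
    detect_hbonds_trajectory,
    fraction_summary,
    max_fraction,
    mean_fraction,
    mean_fraction_unweighted,
    persistence_filter,
    sample_fractions,
    terminal_position_labels,
)
from cellufacet.synth import PlantedContact, SyntheticTrajectoryConfig, generate_trajectory


def contact_frame(factory, distance, angle_deg, donor="O2", acceptor="O6"):
    """Donor hydroxyl at the origin, acceptor placed at the requested
    O...O distance and D-H...A angle by elementary trigonometry."""
    b = 0.96
    theta = np.deg2rad(angle_deg)
    d_ha = np.array([-np.cos(theta), np.sin(theta), 0.0])
    p = b * d_ha[0]
    rho = -p + np.sqrt(p * p - (b * b - distance * distance))
    acc = np.array([b, 0.0, 0.0]) + rho * d_ha
    assert np.isclose(np.linalg.norm(acc), distance)
    return factory(
        [
            (0, 1, donor, (0.0, 0.0, 0.0)),
            (0, 1, "H" + donor, (b, 0.0, 0.0)),
            (0, 2, acceptor, tuple(acc)),
            (0, 2, "H" + acceptor, tuple(acc + np.array([0.0, 0.0, 0.96]))),
        ]
    )


class TestDetect:
    def test_planted_contact_detected_and_typed(self, frame_factory):
        frame = contact_frame(frame_factory, 2.75, 161.0)
        rec = detect_hbonds(frame)
        rec = rec[rec.hb_type == "O2H..O6"]
        assert len(rec) == 1
        assert rec.oo_distance.iloc[0] == pytest.approx(2.75, abs=1e-6)
        assert rec.dha_angle.iloc[0] == pytest.approx(161.0, abs=1e-6)

    def test_beyond_distance_cutoff(self, frame_factory):
        frame = contact_frame(frame_factory, 4.0, 161.0)
        assert detect_hbonds(frame).empty

    def test_angle_failure(self, frame_factory):
        frame = contact_frame(frame_factory, 2.7, 90.0)
        rec = detect_hbonds(frame)
        assert rec[rec.hb_type == "O2H..O6"].empty

    def test_missing_hydrogens_raise_with_fallback_hint(self, frame_factory):
        frame = frame_factory(
            [(0, 1, "O2", (0, 0, 0)), (0, 2, "O6", (2.7, 0, 0))]
        )
        with pytest.raises(MissingHydrogenError, match="distance"):
            detect_hbonds(frame)
        rec = detect_hbonds(frame, HBondCriteria(distance_only=True))
        assert len(rec[rec.hb_type == "O2H..O6"]) == 1

    def test_directed_types_distinct(self, frame_factory):
        # O6 can donate back to O2: a different directed type
        frame = contact_frame(frame_factory, 2.75, 161.0, donor="O6", acceptor="O2")
        rec = detect_hbonds(frame)
        assert "O6H..O2" in set(rec.hb_type)
        assert "O2H..O6" not in set(rec.hb_type)

    def test_brute_force_oracle_equality(self, frame_factory):
        """Production (tree-accelerated) search equals an all-pairs scan."""
        rng = np.random.default_rng(20240917)
        criteria = HBondCriteria()
        donors = {"O2": "HO2", "O3": "HO3", "O6": "HO6"}
        for trial in range(10):
            spec = []
            n_res = 8
            for r in range(1, n_res + 1):
                base = rng.uniform(0, 8, size=3)
                o_name = ["O2", "O3", "O6", "O4", "O5"][r % 5]
                spec.append((0, r, o_name, tuple(base)))
                if o_name in donors:
                    h = base + rng.normal(size=3) * 0.4
                    h = base + 0.96 * (h - base) / np.linalg.norm(h - base)
                    spec.append((0, r, donors[o_name], tuple(h)))
            frame = frame_factory(spec)
            got = detect_hbonds(frame, criteria)
            expected = brute_force_hbonds(frame, criteria)
            got_keys = set(
                map(tuple, got[["donor_res", "donor_atom", "acceptor_res",
                                "acceptor_atom"]].to_numpy())
            )
            assert got_keys == expected

    def test_rigid_transform_invariance(self, frame_factory):
        from scipy.spatial.transform import Rotation

        frame = contact_frame(frame_factory, 2.75, 161.0)
        before = detect_hbonds(frame)
        rng = np.random.default_rng(3)
        R = Rotation.random(rng=rng).as_matrix()
        frame.coord = frame.coord @ R.T + rng.normal(size=3) * 5
        after = detect_hbonds(frame)
        key = ["donor_res", "donor_atom", "acceptor_res", "acceptor_atom"]
        before = before.sort_values(key).reset_index(drop=True)
        after = after.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            before.drop(columns=["oo_distance", "dha_angle"]),
            after.drop(columns=["oo_distance", "dha_angle"]),
        )
        np.testing.assert_allclose(before.oo_distance, after.oo_distance, atol=1e-6)


def brute_force_hbonds(frame, criteria):
    """O(N^2) all-pairs reference detector (keys only)."""
    out = set()
    n = frame.array_length()
    hyd = {
        (frame.chain_index[i], frame.res_id[i], frame.atom_name[i]): i
        for i in range(n)
    }
    for i in range(n):
        dn = frame.atom_name[i]
        if dn not in criteria.donors:
            continue
        hi = hyd.get((frame.chain_index[i], frame.res_id[i], "H" + dn))
        for j in range(n):
            an = frame.atom_name[j]
            if j == i or an not in criteria.acceptors:
                continue
            same_res = (
                frame.chain_index[i] == frame.chain_index[j]
                and frame.res_id[i] == frame.res_id[j]
            )
            if same_res and criteria.exclude_intra_residue:
                continue
            d = np.linalg.norm(frame.coord[j] - frame.coord[i])
            if d > criteria.max_oo_distance:
                continue
            u = frame.coord[i] - frame.coord[hi]
            v = frame.coord[j] - frame.coord[hi]
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang < criteria.min_dha_angle:
                continue
            out.add((frame.res_id[i], dn, frame.res_id[j], an))
    return out


class TestFractions:
    def records(self, counts_by_sample):
        rows = []
        for sample, counts in counts_by_sample.items():
            for hb_type, x in counts.items():
                rows.extend([(sample, hb_type)] * x)
        return pd.DataFrame(rows, columns=["sample", "hb_type"])

    def test_fraction_normalization(self):
        fr = sample_fractions(self.records({0: {"O2H..O2": 3, "O6H..O6": 1}}))
        by_type = fr.set_index("hb_type").fraction
        assert by_type["O2H..O2"] == pytest.approx(0.75)
        assert by_type["O6H..O6"] == pytest.approx(0.25)
        fr_single = sample_fractions(self.records({0: {"A": 5}}))
        assert fr_single.fraction.iloc[0] == 1.0

    def test_fractions_sum_to_one_per_sample(self):
        rng = np.random.default_rng(12)
        counts = {
            s: {f"t{k}": int(c) for k, c in enumerate(rng.multinomial(30, [0.5, 0.3, 0.2])) if c}
            for s in range(50)
        }
        fr = sample_fractions(self.records(counts))
        sums = fr.groupby("sample").fraction.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_max_fraction_and_tie_rule(self):
        fr = sample_fractions(self.records({1: {"A": 2, "B": 8}, 2: {"A": 9, "B": 1}}))
        value, sample = max_fraction(fr, "A")
        assert (value, sample) == (0.9, 2)
        tie = sample_fractions(self.records({3: {"A": 1, "B": 1}, 1: {"A": 1, "B": 1}}))
        value, sample = max_fraction(tie, "A")
        assert (value, sample) == (0.5, 1)
        with pytest.raises(KeyError):
            max_fraction(fr, "absent")

    def test_weighted_mean_fraction(self):
        # F = 0.4 with N=30 and 0.6 with N=10 -> (0.4*30 + 0.6*10)/40 = 0.45
        fr = sample_fractions(
            self.records({0: {"A": 12, "B": 18}, 1: {"A": 6, "B": 4}})
        )
        fbar = mean_fraction(fr)
        assert fbar["A"] == pytest.approx(0.45, abs=1e-15)
        # equal N reduces exactly to the plain mean
        fr_eq = sample_fractions(self.records({0: {"A": 4, "B": 6}, 1: {"A": 6, "B": 4}}))
        assert mean_fraction(fr_eq)["A"] == pytest.approx(
            mean_fraction_unweighted(fr_eq)["A"], abs=1e-15
        )

    def test_equal_n_identity_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            counts = {
                s: {f"t{k}": int(c) for k, c in enumerate(rng.multinomial(40, [0.4, 0.4, 0.2])) if c}
                for s in range(10)
            }
            fr = sample_fractions(self.records(counts))
            w = mean_fraction(fr)
            u = mean_fraction_unweighted(fr)
            assert np.allclose(w.sort_index(), u.sort_index(), atol=1e-15)

    def test_max_dominates_mean(self):
        rng = np.random.default_rng(4)
        counts = {
            s: {f"t{k}": int(c) for k, c in enumerate(rng.multinomial(25, [0.6, 0.25, 0.15])) if c}
            for s in range(40)
        }
        fr = sample_fractions(self.records(counts))
        fbar = mean_fraction(fr)
        for hb_type in fbar.index:
            fmax, _ = max_fraction(fr, hb_type)
            assert fmax >= fbar[hb_type] - 1e-12

    def test_monte_carlo_multinomial_recovery(self):
        probs = {"A": 0.5, "B": 0.3, "C": 0.2}
        n_samples, n_per = 5000, 20
        rng = np.random.default_rng(20240917)
        draws = rng.multinomial(n_per, list(probs.values()), size=n_samples)
        counts = {
            s: {t: int(c) for t, c in zip(probs, row) if c}
            for s, row in enumerate(draws)
        }
        fr = sample_fractions(self.records(counts))
        fbar = mean_fraction(fr)
        total = n_samples * n_per
        for t, p in probs.items():
            se = np.sqrt(p * (1 - p) / total)
            assert abs(fbar[t] - p) <= 3 * se

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mean_fraction(sample_fractions(pd.DataFrame(columns=["sample", "hb_type"])))

    def test_persistence_filter(self):
        fbar = pd.Series({"A": 0.9, "B": 0.5})
        assert persistence_filter(fbar, 0.6) == ["A"]
        assert persistence_filter(fbar, 0.0) == ["A", "B"]
        boundary = pd.Series({"A": 0.60})
        assert persistence_filter(boundary, 0.60) == []  # strictly greater


class TestPositions:
    @pytest.mark.parametrize(
        "i,dp,expected",
        [
            (2, 12, {1: "terminal", 2: "proximal", 12: "distal"}),
            (2, 2, {1: "terminal", 2: "proximal"}),
            (2, 1, {1: "terminal"}),
        ],
    )
    def test_terminal_proximal_distal(self, i, dp, expected):
        from cellufacet.crystal import assemble_nanocrystal

        model = assemble_nanocrystal(i, dp, "O")
        labels = terminal_position_labels(model)
        chain0 = labels[labels.chain_index == 0].set_index("res_id").position
        for res, pos in expected.items():
            assert chain0[res] == pos
        if dp > 2:
            assert (chain0.loc[3:] == "distal").all()


class TestTrajectoryStatistics:
    def test_planted_occupancy_recovery(self, model_3o4):
        contact = PlantedContact(0, 1, "O2", 1, 1, "O6", occupancy=0.7)
        cfg = SyntheticTrajectoryConfig(n_frames=200, seed=8, contacts=[contact])
        traj, truth = generate_trajectory(model_3o4, cfg)
        rec = detect_hbonds_trajectory(traj, scope="all", model=model_3o4)
        hits = rec[
            (rec.donor_chain == 0) & (rec.donor_res == 1) & (rec.donor_atom == "O2")
            & (rec.acceptor_chain == 1) & (rec.acceptor_res == 1)
            & (rec.acceptor_atom == "O6")
        ]
        occ = hits["sample"].nunique() / cfg.n_frames
        p = contact.occupancy
        se = np.sqrt(p * (1 - p) / cfg.n_frames)
        assert abs(occ - p) <= 3 * se
        assert truth["contacts"][0]["realized_occupancy"] == pytest.approx(occ)

    def test_terminal_scope_restricts_residues(self, model_3o4):
        cfg = SyntheticTrajectoryConfig(n_frames=5, seed=9)
        traj, _ = generate_trajectory(model_3o4, cfg)
        rec = detect_hbonds_trajectory(traj, scope="terminal", model=model_3o4)
        if not rec.empty:
            assert set(rec.donor_res) | set(rec.acceptor_res) <= {1, 2}

    def test_summary_layout(self, model_3o4):
        contact = PlantedContact(0, 1, "O2", 1, 1, "O6", occupancy=1.0)
        cfg = SyntheticTrajectoryConfig(n_frames=10, seed=10, contacts=[contact])
        traj, _ = generate_trajectory(model_3o4, cfg)
        rec = detect_hbonds_trajectory(traj, scope="all", model=model_3o4)
        summary = fraction_summary(rec)
        assert {"hb_type", "mean_fraction", "f_max", "argmax_sample",
                "mean_oo_distance", "mean_dha_angle"} <= set(summary.columns)
        row = summary[summary.hb_type == "O2H..O6"].iloc[0]
        assert row.f_max >= row.mean_fraction
        assert 2.6 <= row.mean_oo_distance <= 2.9
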