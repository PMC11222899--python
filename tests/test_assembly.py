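"""Ring flipping, hydrogen-bond scoring, registry optimisation, stacking."""

import numpy as np
import pytest

from peptube import assembly, rings
from peptube.assembly import (
    flip_ring,
    optimize_registry,
    rotate_ring,
    score_hbonds,
    stack_rings,
    translate_ring,
)
from peptube.errors import GeometryError
from peptube.cgmap import map_to_beads
from peptube.rings import AtomRecord, RingGeometry, build_ring, check_chirality
from peptube.sequences import make_design, parse_sequence


class TestFlip:
    def test_flip_is_an_involution(self, ring8):
        twice = flip_ring(flip_ring(ring8))
        assert np.allclose(twice.coordinates(), ring8.coordinates(), atol=1e-9)

    def test_flip_inverts_carbonyl_offsets(self, ring8):
        flipped = flip_ring(ring8)
        for i in range(1, 9):
            z0 = ring8.atom(i, "O").position[2] - ring8.atom(i, "C").position[2]
            z1 = flipped.atom(i, "O").position[2] - flipped.atom(i, "C").position[2]
            assert z1 == pytest.approx(-z0, abs=1e-9)

    def test_flip_preserves_handedness(self, ring8):
        assert check_chirality(flip_ring(ring8)) == check_chirality(ring8)


def toy_pair():
    """One perfect collinear donor/acceptor pair, everything else far away."""
    seq = parse_sequence("GGGG")
    far = 100.0
    lower_atoms, upper_atoms = [], []
    for i in range(1, 5):
        for n in ("N", "CA"):
            lower_atoms.append(AtomRecord(n, n[0], i, np.array([far + 10.0 * i, 0.0, 0.0])))
            upper_atoms.append(AtomRecord(n, n[0], i, np.array([-far - 10.0 * i, 0.0, 0.0])))
        lower_atoms.append(AtomRecord("C", "C", i, np.array([far + 10.0 * i, 5.0, 0.0])))
        lower_atoms.append(AtomRecord("O", "O", i, np.array([far + 10.0 * i, 5.0, 1.0])))
        upper_atoms.append(AtomRecord("C", "C", i, np.array([-far - 10.0 * i, 5.0, 0.0])))
        upper_atoms.append(AtomRecord("O", "O", i, np.array([-far - 10.0 * i, 5.0, 1.0])))
    # the interacting carbonyl: C below origin, O at origin, pointing +z
    lower_atoms[-2].position = np.array([0.0, 0.0, -1.231])
    lower_atoms[-1].position = np.array([0.0, 0.0, 0.0])
    # the interacting amide: H at 2.0, N at 3.01 above the O
    upper_atoms.append(AtomRecord("H", "H", 1, np.array([0.0, 0.0, 2.0])))
    upper_atoms[0].position = np.array([0.0, 0.0, 3.01])  # N of residue 1
    lower = RingGeometry(lower_atoms, seq)
    upper = RingGeometry(upper_atoms, seq)
    return lower, upper


class TestScoreHbonds:
    def test_distant_rings_score_zero(self, ring8):
        upper = translate_ring(ring8, np.array([0.0, 0.0, 50.0]))
        assert score_hbonds(ring8, upper) == 0

    def test_collinear_toy_geometry_counts_one(self):
        lower, upper = toy_pair()
        assert score_hbonds(lower, upper, d_max=2.5, theta_min=120.0) == 1

    def test_toy_pair_fails_tighter_distance_cutoff(self):
        lower, upper = toy_pair()
        assert score_hbonds(lower, upper, d_max=1.9, theta_min=120.0) == 0

    def test_resolution_mismatch_rejected(self, ring8, cg_mapping):
        cg = map_to_beads(ring8, cg_mapping)
        with pytest.raises(GeometryError) as err:
            score_hbonds(ring8, cg)
        assert err.value.code == "RESOLUTION_MISMATCH"

    def test_matches_independent_all_pairs_oracle(self, rng):
        """Greedy best-distance matching re-implemented from scratch."""
        for _ in range(10):
            text = "".join(rng.choice(list("AGSTLV"), size=6))
            lower = build_ring(parse_sequence(text))
            upper = flip_ring(build_ring(parse_sequence(text)))
            upper = rotate_ring(upper, float(rng.uniform(0, 360)))
            upper = translate_ring(upper, np.array([0, 0, float(rng.uniform(4.0, 5.5))]))
            assert score_hbonds(lower, upper) == oracle_count(lower, upper, 2.5, 120.0)


def oracle_count(lower, upper, d_max, theta_min):
    pairs = []
    for a, b in ((lower, upper), (upper, lower)):
        for res in a.sequence.residues:
            h = a.find(res.position, "H")
            if h is None:
                continue
            n = a.atom(res.position, "N").position
            for res2 in b.sequence.residues:
                o = b.atom(res2.position, "O").position
                d = np.linalg.norm(o - h.position)
                v1 = n - h.position
                v2 = o - h.position
                ang = np.degrees(np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
                if d <= d_max and ang >= theta_min:
                    pairs.append((d, (id(a), res.position), (id(b), res2.position)))
    pairs.sort(key=lambda p: p[0])
    used_d, used_a, n = set(), set(), 0
    for d, dk, ak in pairs:
        if dk in used_d or ak in used_a:
            continue
        used_d.add(dk)
        used_a.add(ak)
        n += 1
    return n


class TestOptimizeRegistry:
    def test_single_point_scan_returns_zero_angle(self, ring8):
        upper = translate_ring(flip_ring(ring8), np.array([0.0, 0.0, 4.7]))
        angle, score = optimize_registry(ring8, upper, scan_step=360.0)
        assert angle == 0.0
        assert score == score_hbonds(ring8, upper)

    def test_homo_ring_score_is_periodic_and_angle_in_first_period(self, ring8):
        # the backbone repeats every residue, but the amide up/down pattern
        # alternates with residue parity, so the donor/acceptor arrangement
        # (and with it the registry score) repeats every TWO residues:
        # period 720/n degrees, confirmed by the brute-force scan table.
        upper = translate_ring(flip_ring(ring8), np.array([0.0, 0.0, 4.7]))
        step = 5.0
        table = {a: score_hbonds(ring8, rotate_ring(upper, a))
                 for a in np.arange(0.0, 360.0, step)}
        period = 720.0 / 8
        for a, s in table.items():
            assert s == table[(a + period) % 360.0]
        angle, score = optimize_registry(ring8, upper, scan_step=step)
        assert 0.0 <= angle < period
        assert score == max(table.values())

    def test_returned_score_dominates_full_scan(self, ring8):
        upper = translate_ring(flip_ring(ring8), np.array([0.0, 0.0, 4.7]))
        angle, score = optimize_registry(ring8, upper, scan_step=10.0)
        for a in np.arange(0.0, 360.0, 10.0):
            assert score >= score_hbonds(ring8, rotate_ring(upper, float(a)))


class TestStackRings:
    def test_single_ring_design(self, ring8):
        design = make_design(["RRKWLWLW"], [])
        model = stack_rings(design, [ring8.copy()])
        assert model.n_rings == 1 and model.interfaces == []

    def test_octamer_stack_has_seven_bonded_interfaces(self, octamer_model):
        assert octamer_model.n_rings == 8
        assert len(octamer_model.interfaces) == 7
        for itf in octamer_model.interfaces:
            assert itf.orientation == "antiparallel"
            assert itf.hbond_count >= 1

    def test_centroid_spacing_equals_rise(self, octamer_model):
        z = [r.centroid[2] for r in octamer_model.rings]
        for lo, hi, itf in zip(z, z[1:], octamer_model.interfaces):
            assert hi - lo == pytest.approx(itf.rise, abs=1e-9)

    def test_stacking_is_rigid(self, ring8, octamer_model):
        ref = ring8.coordinates()
        ref_d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
        for ring in octamer_model.rings:
            c = ring.coordinates()
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            assert np.allclose(d, ref_d, atol=1e-9)

    def test_registry_is_optimal_under_rescan(self, ring8, octamer_model):
        lower = octamer_model.rings[0]
        itf = octamer_model.interfaces[0]
        upper = octamer_model.rings[1]
        for a in np.arange(0.0, 360.0, 5.0):
            assert itf.hbond_count >= score_hbonds(lower, rotate_ring(upper, float(a)))

    def test_ring_zero_is_never_transformed(self, ring8):
        design_p = make_design(["RRKWLWLW"] * 2, ["parallel"])
        design_a = make_design(["RRKWLWLW"] * 2, ["antiparallel"])
        mp = stack_rings(design_p, [ring8.copy(), ring8.copy()], scan_step=15.0)
        ma = stack_rings(design_a, [ring8.copy(), ring8.copy()], scan_step=15.0)
        assert np.array_equal(mp.rings[0].coordinates(), ring8.coordinates())
        assert np.array_equal(ma.rings[0].coordinates(), ring8.coordinates())

    def test_cg_stack_uses_geometric_registry(self, ring8, cg_mapping):
        cg = map_to_beads(ring8, cg_mapping)
        design = make_design(["RRKWLWLW"] * 3, ["antiparallel", "parallel"])
        model = stack_rings(design, [cg.copy() for _ in range(3)])
        assert model.interfaces[0].registry_angle == pytest.approx(180.0 / 8)
        assert model.interfaces[1].registry_angle == 0.0
        assert all(i.hbond_count == 0 for i in model.interfaces)
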