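"""Cubical persistence: analytic cases, oracle equivalence, stability."""

import itertools

import numpy as np
import pytest

from topoliver.homology import (
    FilteredCubicalComplex,
    NonMonotoneError,
    betti_curve,
    brute_force_betti,
    build_complex,
    cap_infinite,
    compute_persistence,
)


def finite(diagram, dim):
    return [(iv.birth, iv.death) for iv in diagram.by_dim(dim) if np.isfinite(iv.death)]


class TestBuildComplex:
    def test_single_pixel_cell_counts_and_values(self):
        cplx = build_complex(np.array([[3.0]]))
        assert (cplx.n_vertices, cplx.n_edges, cplx.n_faces) == (4, 4, 1)
        assert np.all(cplx.vertex_values == 3.0)
        assert np.all(cplx.hedge_values == 3.0)
        assert np.all(cplx.vedge_values == 3.0)

    def test_shared_faces_carry_the_minimum(self):
        # 1x2 image (a, b), a < b: the shared vertical edge and its vertices carry a
        cplx = build_complex(np.array([[1.0, 2.0]]))
        assert cplx.vedge_values[0, 1] == 1.0  # edge between the two pixels
        assert cplx.vertex_values[0, 1] == 1.0
        assert cplx.vertex_values[1, 1] == 1.0
        assert cplx.vertex_values[0, 2] == 2.0

    def test_monotone_on_random_images(self, rng):
        for _ in range(10):
            cplx = build_complex(rng.random((5, 5)))
            cplx.validate_monotone()
            # exhaustive face/coface spot check: every edge of every face
            r, c = cplx.shape
            for i in range(r):
                for j in range(c):
                    fv = cplx.face_values[i, j]
                    assert cplx.hedge_values[i, j] <= fv
                    assert cplx.hedge_values[i + 1, j] <= fv
                    assert cplx.vedge_values[i, j] <= fv
                    assert cplx.vedge_values[i, j + 1] <= fv

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            build_complex(np.array([[1.0, np.nan]]))

    def test_tampered_complex_rejected(self, rng):
        cplx = build_complex(rng.random((4, 4)))
        cplx.vertex_values[2, 2] = 10.0  # vertex above its cofaces
        with pytest.raises(NonMonotoneError):
            compute_persistence(cplx)


class TestAnalyticDiagrams:
    def test_constant_image(self):
        d = compute_persistence(build_complex(np.full((4, 4), 2.5)))
        assert [(iv.dim, iv.birth, iv.death) for iv in d.intervals] == [(0, 2.5, np.inf)]
        assert d.intervals[0].essential

    def test_annulus(self, annulus_3x3):
        d = compute_persistence(build_complex(annulus_3x3))
        assert [(iv.birth, iv.death) for iv in d.by_dim(1)] == [(0.0, 1.0)]
        ess = d.essentials
        assert len(ess) == 1 and ess[0].dim == 0 and ess[0].birth == 0.0

    def test_two_blobs_merge_at_background(self, two_blob_image):
        d = compute_persistence(build_complex(two_blob_image))
        assert finite(d, 0) == [(0.0, 1.0)]  # one component dies at the merge
        assert len(d.essentials) == 1
        assert d.essentials[0].birth == 0.0
        assert d.by_dim(1) == ()

    def test_one_essential_h0_per_component(self):
        # two plateaus separated by a bright wall still form one component
        # (the wall itself is a pixel); a truly disconnected complex is
        # impossible for a full rectangular image, so essentials == 1
        img = np.array([[0.0, 9.0, 1.0]])
        d = compute_persistence(build_complex(img))
        assert len(d.essentials) == 1


class TestBruteForceOracle:
    def test_below_global_min(self, rng):
        img = rng.random((6, 6)) + 1.0
        assert brute_force_betti(img, 0.5) == (0, 0)

    def test_annulus_euler_count(self, annulus_3x3):
        # chi = 16 - 24 + 8 = 0 over the 8 closed border pixels, 1 component
        assert brute_force_betti(annulus_3x3, 0.0) == (1, 1)

    def test_full_image_contractible(self, rng):
        img = rng.random((7, 5))
        assert brute_force_betti(img, img.max()) == (1, 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_betti_curve_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 8, size=(8, 8)).astype(float)
        curve = betti_curve(compute_persistence(build_complex(img)))
        for eps, b0, b1 in zip(curve.thresholds, curve.b0, curve.b1):
            assert (b0, b1) == brute_force_betti(img, eps)

    def test_euler_consistency(self, rng):
        # sum_k (-1)^k b_k(eps) = chi(eps) at every threshold
        img = rng.integers(0, 10, size=(8, 8)).astype(float)
        cplx = build_complex(img)
        curve = betti_curve(compute_persistence(cplx))
        for eps, b0, b1 in zip(curve.thresholds, curve.b0, curve.b1):
            V = np.count_nonzero(cplx.vertex_values <= eps)
            E = np.count_nonzero(cplx.hedge_values <= eps) + np.count_nonzero(
                cplx.vedge_values <= eps
            )
            F = np.count_nonzero(cplx.face_values <= eps)
            assert b0 - b1 == V - E + F


def bottleneck_small(pts_a, pts_b):
    """Brute-force bottleneck distance with diagonal augmentation (tiny inputs)."""
    proj = lambda p: ((p[0] + p[1]) / 2, (p[0] + p[1]) / 2)
    aug_a = list(pts_a) + [proj(q) for q in pts_b]
    aug_b = list(pts_b) + [proj(p) for p in pts_a]
    diag_a = [False] * len(pts_a) + [True] * len(pts_b)
    diag_b = [False] * len(pts_b) + [True] * len(pts_a)

    def cost(i, j):
        if diag_a[i] and diag_b[j]:
            return 0.0
        return max(abs(aug_a[i][0] - aug_b[j][0]), abs(aug_a[i][1] - aug_b[j][1]))

    best = np.inf
    for perm in itertools.permutations(range(len(aug_b))):
        best = min(best, max((cost(i, j) for i, j in enumerate(perm)), default=0.0))
    return best


class TestStability:
    @pytest.mark.parametrize("seed", range(3))
    def test_perturbation_moves_diagram_at_most_delta(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 4, size=(3, 3)).astype(float)
        delta = 0.2
        pert = img + rng.uniform(-delta, delta, img.shape)
        for dim in (0, 1):
            a = finite(compute_persistence(build_complex(img)), dim)
            b = finite(compute_persistence(build_complex(pert)), dim)
            if len(a) + len(b) > 7:
                continue  # keep the factorial matching tractable
            assert bottleneck_small(a, b) <= delta + 1e-12
        # essential H0 birth (global min) moves by at most delta
        assert abs(img.min() - pert.min()) <= delta


class TestCapInfinite:
    def test_cap_to_max(self):
        d = compute_persistence(build_complex(np.array([[0.0, 1.0]])))
        capped = cap_infinite(d)
        assert all(np.isfinite(iv.death) for iv in capped.intervals)
        assert capped.essentials[0].death == 1.0

    def test_drop(self):
        d = compute_persistence(build_complex(np.array([[0.0, 1.0]])))
        assert cap_infinite(d, "drop").essentials == ()

    def test_idempotent(self, rng):
        d = compute_persistence(build_complex(rng.random((4, 4))))
        once = cap_infinite(d)
        assert cap_infinite(once) == once

    def test_unknown_policy(self):
        d = compute_persistence(build_complex(np.zeros((2, 2))))
        with pytest.raises(ValueError, match="policy"):
            cap_infinite(d, "nope")


class TestBettiCurveShape:
    def test_constant_image_b0_is_one_from_value_onward(self):
        d = compute_persistence(build_complex(np.full((3, 3), 1.5)))
        curve = betti_curve(d, thresholds=np.array([1.0, 1.5, 2.0]))
        assert list(curve.b0) == [0, 1, 1]
        assert list(curve.b1) == [0, 0, 0]

    def test_b1_vanishes_at_max(self, rng):
        img = rng.random((6, 6))
        curve = betti_curve(compute_persistence(build_complex(img)))
        assert curve.b1[-1] == 0
        assert curve.b0[-1] == 1
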