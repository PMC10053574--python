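import itertools

import numpy as np
import pytest

from oracles import fuse_highpass_scalar, fuse_lowpass_scalar
from xgifuse.config import FusionConfig, SCMParams
from xgifuse.errors import ValidationError
from xgifuse.fusion import fuse_highpass, fuse_lowpass, fuse_tricontrast
from xgifuse.image_io import TriContrastSet


def _ignition_grid():
    """All integer ignition triples in [0, 10]^3 laid out as one image."""
    triples = np.array(list(itertools.product(range(11), repeat=3)), dtype=float)
    side = (121, 11)  # 1331 pixels
    return [t.reshape(side) for t in triples.T], triples


class TestLowpassRule:
    def test_identical_ignitions_pick_ac(self, rng):
        L = [rng.random((16, 16)) for _ in range(3)]
        T = np.full((16, 16), 5.0)
        out = fuse_lowpass(*L, T, T, T, a=0.55)
        assert np.array_equal(out, L[0])

    def test_a_near_one_tracks_ac(self, rng):
        L = [rng.random((16, 16)) for _ in range(3)]
        T = [rng.integers(1, 10, (16, 16)) for _ in range(3)]
        out = fuse_lowpass(*L, *T, a=0.99)
        assert np.array_equal(out, L[0])

    def test_single_pixel_score_evaluation(self, rng):
        L = [np.full((16, 16), v) for v in (0.1, 0.2, 0.3)]
        T = [np.full((16, 16), t, dtype=float) for t in (1, 3, 2)]
        out = fuse_lowpass(*L, *T, a=0.55)
        # scores (0.55, 1.35, 0.90) -> DPC wins
        assert np.all(out == 0.2)

    @pytest.mark.parametrize("a", [0.3, 0.55, 0.7])
    def test_matches_scalar_enumeration(self, a, rng):
        (t_ac, t_dpc, t_dfc), triples = _ignition_grid()
        L = [rng.random(t_ac.shape) for _ in range(3)]
        out = fuse_lowpass(*L, t_ac, t_dpc, t_dfc, a=a)
        for idx, (ta, tp, tf) in enumerate(triples):
            i, j = divmod(idx, 11)
            expected = fuse_lowpass_scalar(
                L[0][i, j], L[1][i, j], L[2][i, j], ta, tp, tf, a)
            assert out[i, j] == expected


class TestHighpassRule:
    WEIGHTS = (0.41, 0.29, 0.30)

    def _const(self, shape, values):
        return [np.full(shape, v, dtype=float) for v in values]

    def test_single_dominant_channel_selected(self):
        H = self._const((8, 8), (1.0, 2.0, 3.0))
        T = self._const((8, 8), (10, 2, 2))
        out = fuse_highpass(*H, *T, self.WEIGHTS, Tth=1.0)
        assert np.all(out == 1.0)

    def test_no_dominance_blends_all_three(self):
        H = self._const((8, 8), (1.0, 2.0, 3.0))
        T = self._const((8, 8), (5, 5, 5))
        out = fuse_highpass(*H, *T, self.WEIGHTS, Tth=1.0)
        assert np.allclose(out, 0.41 * 1 + 0.29 * 2 + 0.30 * 3)

    def test_pair_dominance_averages_the_pair(self):
        H = self._const((8, 8), (1.0, 2.0, 3.0))
        T = self._const((8, 8), (8, 7, 2))
        out = fuse_highpass(*H, *T, self.WEIGHTS, Tth=1.0)
        assert np.all(out == 1.5)

    @pytest.mark.parametrize("tth", [0.0, 1.0, 3.0])
    def test_matches_scalar_enumeration_all_triples(self, tth, rng):
        (t_ac, t_dpc, t_dfc), triples = _ignition_grid()
        H = [rng.standard_normal(t_ac.shape) for _ in range(3)]
        b, c, d = self.WEIGHTS
        out = fuse_highpass(*H, t_ac, t_dpc, t_dfc, self.WEIGHTS, Tth=tth)
        for idx, (ta, tp, tf) in enumerate(triples):
            i, j = divmod(idx, 11)
            expected = fuse_highpass_scalar(
                H[0][i, j], H[1][i, j], H[2][i, j], ta, tp, tf, b, c, d, tth)
            assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_output_in_convex_hull(self, rng):
        """Every case is a convex combination of the three coefficients."""
        (t_ac, t_dpc, t_dfc), _ = _ignition_grid()
        H = [rng.standard_normal(t_ac.shape) for _ in range(3)]
        out = fuse_highpass(*H, t_ac, t_dpc, t_dfc, self.WEIGHTS, Tth=1.0)
        lo = np.minimum(np.minimum(H[0], H[1]), H[2])
        hi = np.maximum(np.maximum(H[0], H[1]), H[2])
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_bad_weight_sum_rejected(self, rng):
        H = [rng.random((8, 8)) for _ in range(3)]
        T = [np.ones((8, 8))] * 3
        with pytest.raises(ValidationError, match="sum to 1"):
            fuse_highpass(*H, *T, (0.5, 0.5, 0.5), Tth=1.0)


class TestFullFusion:
    def test_identity_fusion(self, rng, fast_scm):
        """Three identical inputs reproduce the input: AC wins the low band
        and the high-band blend of identical coefficients is the identity."""
        img = rng.random((64, 64))
        tri = TriContrastSet(img, img, img)
        cfg = FusionConfig(nsct_levels=(2, 2), scm=fast_scm)
        fused = fuse_tricontrast(tri, cfg)
        assert np.abs(fused - img).max() < 1e-6

    def test_deterministic(self, phantom_small, fast_scm):
        cfg = FusionConfig(nsct_levels=(2, 2), scm=fast_scm)
        a = fuse_tricontrast(phantom_small.tri, cfg)
        b = fuse_tricontrast(phantom_small.tri, cfg)
        assert np.array_equal(a, b)

    def test_shape_mismatch_propagates(self, rng):
        with pytest.raises(ValidationError):
            fuse_lowpass(rng.random((8, 8)), rng.random((8, 8)), rng.random((8, 9)),
                         np.ones((8, 8)), np.ones((8, 8)), np.ones((8, 9)), a=0.5)
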