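import numpy as np
import pytest

from emseg.bias_field import (BiasEstimationError, correct, estimate_bias,
                              from_working_space, polynomial_basis,
                              to_working_space)
from emseg.em_core import initialize_state
from emseg.image_io import Volume, phantom_tissue_config
from emseg.phantom import apply_bias
from emseg.priors import PriorAtlas


def _phantom_setup(clean_phantom):
    """Noise-free session, one-hot posteriors, atlas, head mask."""
    sess = clean_phantom.session
    post = clean_phantom.atlas.maps
    atlas = clean_phantom.atlas
    state = initialize_state(sess, post, class_names=atlas.class_names)
    mask = clean_phantom.labels.data > 0
    return sess, state, post, atlas, mask


class TestPolynomialBasis:
    def test_constant_first_and_count(self):
        A = polynomial_basis((4, 4, 4), 2)
        assert A.shape == (10, 64)  # C(2+3,3) terms of total degree <= 2
        np.testing.assert_array_equal(A[0], 1.0)

    def test_nested_bases(self):
        lo = polynomial_basis((5, 5, 5), 1)
        hi = polynomial_basis((5, 5, 5), 2)
        np.testing.assert_array_equal(hi[: lo.shape[0]], lo)


class TestEstimateBias:
    def test_zero_residual_zero_field(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        # intensities equal blended class means exactly -> residual 0
        bias = estimate_bias(sess, state, post, atlas, order=2, mask=mask,
                             space="linear")
        for m in sess.modalities:
            assert np.abs(bias.fields[m]).max() < 1e-8

    def test_linear_ramp_recovered(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        shape = sess.reference.shape
        x = np.linspace(-1, 1, shape[0])[:, None, None]
        ramp = np.broadcast_to(2.5 * x, shape)
        stack = sess.stack() + ramp
        bias = estimate_bias(stack, state, post, atlas, order=1, mask=mask,
                             space="linear")
        expected = ramp - ramp[mask].mean()
        np.testing.assert_allclose(bias.fields["0"][mask], expected[mask],
                                   atol=1e-6)

    def test_constant_offset_removed_by_mean_constraint(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        stack = sess.stack() + 42.0
        bias = estimate_bias(stack, state, post, atlas, order=2, mask=mask,
                             space="linear")
        assert np.abs(bias.fields["0"]).max() < 1e-6

    def test_field_mean_zero_over_mask(self, noisy_phantom):
        sess = noisy_phantom.session
        atlas = noisy_phantom.atlas
        post = atlas.maps
        state = initialize_state(sess, post, class_names=atlas.class_names)
        mask = noisy_phantom.labels.data > 0
        bias = estimate_bias(sess, state, post, atlas, order=3, mask=mask)
        for m in sess.modalities:
            assert abs(bias.fields[m][mask].mean()) < 1e-9

    def test_higher_order_never_increases_weighted_rss(self, noisy_phantom):
        sess = noisy_phantom.session
        atlas = noisy_phantom.atlas
        post = atlas.maps
        state = initialize_state(sess, post, class_names=atlas.class_names)
        mask = noisy_phantom.labels.data > 0
        Y = sess.stack()
        N = Y[0].size
        P = post.reshape(post.shape[0], N)
        eligible = np.array([c.use_in_bias for c in atlas.configs])
        var = state.covariances[:, 0, 0]
        w = (P[eligible] / var[eligible, None]).sum(axis=0) * mask.ravel()
        elig_mass = P[eligible].sum(axis=0)
        blended = np.where(elig_mass > 0,
                           (state.means[eligible, 0] @ P[eligible])
                           / np.maximum(elig_mass, 1e-300), Y[0].ravel())
        resid = Y[0].ravel() - blended
        rss = []
        for order in (1, 2, 3, 4):
            bias = estimate_bias(sess, state, post, atlas, order=order,
                                 mask=mask)
            r = resid - bias.fields["T1"].ravel()
            rss.append(float((w * r**2).sum()))
        assert all(b <= a + 1e-6 * abs(a) for a, b in zip(rss, rss[1:]))

    def test_only_bias_eligible_tissues_influence_fit(self, noisy_phantom):
        sess = noisy_phantom.session
        atlas = noisy_phantom.atlas
        post = atlas.maps.copy()
        state = initialize_state(sess, post, class_names=atlas.class_names)
        mask = noisy_phantom.labels.data > 0
        b1 = estimate_bias(sess, state, post, atlas, order=2, mask=mask)
        # zero the posteriors of every flag-false tissue (only Air here)
        post2 = post.copy()
        for k, cfg in enumerate(atlas.configs):
            if not cfg.use_in_bias:
                post2[k] = 0.0
        b2 = estimate_bias(sess, state, post2, atlas, order=2, mask=mask)
        for m in sess.modalities:
            np.testing.assert_allclose(b1.fields[m], b2.fields[m], atol=1e-9)

    def test_no_eligible_mass_errors(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        bad = post.copy()
        for k, cfg in enumerate(atlas.configs):
            if cfg.use_in_bias:
                bad[k] = 0.0
        with pytest.raises(BiasEstimationError, match="bias-eligible"):
            estimate_bias(sess, state, bad, atlas, order=2, mask=mask)


class TestCorrect:
    def test_zero_field_identity(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        bias = estimate_bias(sess, state, post, atlas, order=2, mask=mask)
        bias.fields = {m: np.zeros(sess.reference.shape)
                       for m in sess.modalities}
        out = correct(sess, bias)
        np.testing.assert_array_equal(out.stack(), sess.stack())

    def test_mask_mean_preserved(self, noisy_phantom):
        sess = noisy_phantom.session
        atlas = noisy_phantom.atlas
        post = atlas.maps
        state = initialize_state(sess, post, class_names=atlas.class_names)
        mask = noisy_phantom.labels.data > 0
        bias = estimate_bias(sess, state, post, atlas, order=3, mask=mask)
        out = correct(sess, bias)
        for j, m in enumerate(sess.modalities):
            assert out.stack()[j][mask].mean() == pytest.approx(
                sess.stack()[j][mask].mean(), abs=1e-9)

    def test_recovery_of_additive_ramp(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        shape = sess.reference.shape
        x = np.linspace(-1, 1, shape[0])[:, None, None]
        ramp = np.broadcast_to(1.5 * x, shape)
        corrupted = sess.with_stack(sess.stack() + ramp)
        bias = estimate_bias(corrupted, state, post, atlas, order=2, mask=mask,
                             space="linear")
        fixed = correct(corrupted, bias)
        # recovered up to the removed mask-mean constant
        resid = fixed.stack()[0] - sess.stack()[0]
        assert np.abs(resid[mask] - resid[mask].mean()).max() < 1e-6


class TestWorkingSpace:
    def test_round_trip_identity(self):
        vol = Volume(np.linspace(1, 100, 4 ** 3).reshape(4, 4, 4))
        u, eps = to_working_space(vol)
        back = from_working_space(u, eps)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-12)

    def test_multiplicative_becomes_additive(self, rng):
        v = rng.uniform(10, 100, size=(5, 5, 5))
        f = rng.uniform(0.8, 1.2, size=(5, 5, 5))
        lhs = np.log(v * f) - np.log(v)
        np.testing.assert_allclose(lhs, np.log(f), atol=1e-12)

    def test_nonpositive_offset_rejected(self):
        vol = Volume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            to_working_space(vol, eps=0.0)

    def test_log_space_multiplicative_bias_recovery(self, clean_phantom):
        """rf=20 multiplicative corruption: estimated log-space field
        correlates >= 0.95 with log(true field)."""
        sess = clean_phantom.session
        atlas = clean_phantom.atlas
        mask = clean_phantom.labels.data > 0
        biased, truth = {}, {}
        for m in sess.modalities:
            out, fld = apply_bias(sess.fused_volume(m), 20.0, seed=31)
            biased[m] = out
            truth[m] = fld
        work = {}
        for m in sess.modalities:
            u, _ = to_working_space(biased[m])
            work[m] = u
        from emseg.image_io import ImageSession
        ws = ImageSession(list(sess.modalities),
                          {m: [work[m]] for m in sess.modalities})
        post = atlas.maps
        state = initialize_state(ws, post, class_names=atlas.class_names)
        bias = estimate_bias(ws, state, post, atlas, order=4, mask=mask)
        for m in sess.modalities:
            est = bias.fields[m][mask]
            ref = np.log(truth[m].data[mask])
            r = np.corrcoef(est, ref)[0, 1]
            assert r >= 0.95, f"{m}: corr {r:.3f}"

    def test_idempotence_on_corrected_session(self, clean_phantom):
        sess, state, post, atlas, mask = _phantom_setup(clean_phantom)
        shape = sess.reference.shape
        x = np.linspace(-1, 1, shape[0])[:, None, None]
        corrupted = sess.with_stack(sess.stack()
                                    + np.broadcast_to(3.0 * x, shape))
        bias = estimate_bias(corrupted, state, post, atlas, order=2, mask=mask,
                             space="linear")
        fixed = correct(corrupted, bias)
        again = estimate_bias(fixed, state, post, atlas, order=2, mask=mask,
                              space="linear")
        scale = np.abs(sess.stack()).max()
        for m in fixed.modalities:
            assert np.abs(again.fields[m]).max() < 1e-3 * scale
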