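import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selffi.losses import (EmbeddingBatch, batch_contrastive_loss,
                           batch_contrastive_loss_and_grad, cosine_similarity,
                           info_nce, total_loss)
from selffi.experiments import naive_batch_loss


def random_batch(rng, n_pairs, dim):
    z = rng.normal(size=(2 * n_pairs, dim))
    links = [(2 * i, 2 * i + 1) for i in range(n_pairs)]
    return z, links


class TestCosineSimilarity:
    @pytest.mark.parametrize("a, b, expected", [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 1), (1, 0), 1 / np.sqrt(2)),
        ((1, 2, 3), (-1, -2, -3), -1.0),
    ])
    def test_closed_forms(self, a, b, expected):
        assert cosine_similarity(np.array(a, float), np.array(b, float)) == \
            pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(np.zeros(3), np.ones(3))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 6))
        s = cosine_similarity(a, b)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        assert cosine_similarity(3.7 * a, 0.2 * b) == pytest.approx(s, abs=1e-12)


class TestInfoNce:
    def test_uniform_similarity_closed_forms(self):
        # all pairwise similarities equal: ln(K+1) with the positive in the
        # denominator, ln K in the bare printed form
        anchor = np.array([0.3, 0.3])
        positive = np.array([1.5, 1.5])
        negatives = [np.array([0.7, 0.7])] * 7
        assert info_nce(anchor, positive, negatives, 1.0, True) == \
            pytest.approx(np.log(8), abs=1e-9)
        assert info_nce(anchor, positive, negatives, 1.0, False) == \
            pytest.approx(np.log(7), abs=1e-9)

    def test_matches_scalar_reference(self):
        rng = np.random.default_rng(12)
        d, k, tau = 16, 31, 0.07
        anchor, positive = rng.normal(size=(2, d))
        negatives = [rng.normal(size=d) for _ in range(k)]
        s_pos = cosine_similarity(anchor, positive) / tau
        den = sum(np.exp(cosine_similarity(anchor, n) / tau) for n in negatives)
        expected = -np.log(np.exp(s_pos) / (den + np.exp(s_pos)))
        assert info_nce(anchor, positive, negatives, tau, True) == \
            pytest.approx(expected, abs=1e-6)

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError):
            info_nce(np.ones(2), np.ones(2), [], 0.1)

    def test_printed_form_can_go_negative_ntxent_cannot(self):
        # positive similarity far above the single negative
        anchor = np.array([1.0, 0.0])
        positive = np.array([1.0, 0.0])
        negatives = [np.array([-1.0, 0.0])]
        assert info_nce(anchor, positive, negatives, 0.07, False) < 0
        assert info_nce(anchor, positive, negatives, 0.07, True) >= 0


class TestBatchLoss:
    def test_orthogonal_duplicated_pairs_closed_form(self):
        # 4 mutually orthogonal pairs, each positive duplicated: per anchor
        # sim(pos)=1 and six negatives at sim 0, so with tau=1 the loss is
        # log((e + 6)/e)
        z = np.repeat(np.eye(4), 2, axis=0)
        links = [(0, 1), (2, 3), (4, 5), (6, 7)]
        got = batch_contrastive_loss(EmbeddingBatch(z=z, pair_links=links,
                                                    temperature=1.0))
        assert got == pytest.approx(np.log((np.e + 6) / np.e), abs=1e-9)

    def test_equals_naive_double_loop(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n_pairs = int(rng.integers(2, 8))
            dim = int(rng.integers(2, 32))
            z, links = random_batch(rng, n_pairs, dim)
            tau = float(rng.uniform(0.05, 1.0))
            for flag in (True, False):
                batch = EmbeddingBatch(z=z, pair_links=links, temperature=tau)
                got = batch_contrastive_loss(batch, flag)
                want = naive_batch_loss(z, links, tau, flag)
                assert got == pytest.approx(want, abs=1e-6)

    def test_pair_permutation_invariance(self):
        rng = np.random.default_rng(3)
        z, links = random_batch(rng, 5, 8)
        a = batch_contrastive_loss(EmbeddingBatch(z=z, pair_links=links,
                                                  temperature=0.2))
        perm = [links[i] for i in (3, 0, 4, 1, 2)]
        b = batch_contrastive_loss(EmbeddingBatch(z=z, pair_links=perm,
                                                  temperature=0.2))
        assert a == pytest.approx(b, abs=1e-9)

    def test_temperature_sharpening_monotone(self):
        # positives strictly more similar than every negative: cooling the
        # temperature can only sharpen the softmax toward the positive
        rng = np.random.default_rng(5)
        base = np.eye(3)
        z = np.vstack([np.repeat(base, 2, axis=0)])
        z = z + rng.normal(scale=0.01, size=z.shape)
        links = [(0, 1), (2, 3), (4, 5)]
        taus = [1.0, 0.5, 0.2, 0.07]
        losses = [batch_contrastive_loss(EmbeddingBatch(z=z, pair_links=links,
                                                        temperature=t))
                  for t in taus]
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        z, links = random_batch(rng, 3, 4)
        batch = EmbeddingBatch(z=z.copy(), pair_links=links, temperature=0.3)
        _, grad = batch_contrastive_loss_and_grad(batch)
        eps = 1e-6
        for i, j in [(0, 0), (2, 3), (5, 1)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            lp = batch_contrastive_loss(EmbeddingBatch(z=zp, pair_links=links,
                                                       temperature=0.3))
            lm = batch_contrastive_loss(EmbeddingBatch(z=zm, pair_links=links,
                                                       temperature=0.3))
            assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_gradient_step_pulls_positives_together(self):
        # one descent step on a 2-pair toy batch must increase the
        # positive-pair cosine similarity
        rng = np.random.default_rng(11)
        z, links = random_batch(rng, 2, 3)
        batch = EmbeddingBatch(z=z.copy(), pair_links=links, temperature=0.5)
        _, grad = batch_contrastive_loss_and_grad(batch)
        z2 = z - 0.05 * grad
        before = np.mean([cosine_similarity(z[a], z[p]) for a, p in links])
        after = np.mean([cosine_similarity(z2[a], z2[p]) for a, p in links])
        assert after > before

    def test_degenerate_links_rejected(self):
        z = np.eye(4)
        with pytest.raises(ValueError):
            EmbeddingBatch(z=z, pair_links=[(1, 1)], temperature=0.1)
        with pytest.raises(ValueError):
            EmbeddingBatch(z=z, pair_links=[(0, 9)], temperature=0.1)
        with pytest.raises(ValueError):
            EmbeddingBatch(z=z, pair_links=[(0, 1)], temperature=0.0)


class TestTotalLoss:
    @pytest.mark.parametrize("parts, weights, expected", [
        ((0.5, 0.0, 0.0), (1, 1, 1), 0.5),
        ((1.0, 2.0, 3.0), (1, 1, 1), 6.0),
        ((1.0, 2.0, 3.0), (1, 0, 0), 1.0),
    ])
    def test_weighted_sums(self, parts, weights, expected):
        bd = total_loss(*parts, weights=weights)
        assert bd.total == pytest.approx(expected)

    def test_absent_components_are_skipped(self):
        bd = total_loss(0.7, None, None)
        assert bd.total == pytest.approx(0.7)
        assert bd.bilateral is None and bd.multimodality is None

    def test_unit_weight_total_is_exact_sum(self):
        bd = total_loss(1.25, 2.5, 0.125)
        assert bd.total == bd.pair_instance + bd.bilateral + bd.multimodality
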