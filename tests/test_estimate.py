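import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import random_valid_model
from noctograph.circstats import circular_diff
from noctograph.estimate import (
    bedtime_histogram,
    estimate_batch,
    estimate_bedtime,
    estimates_to_frame,
    make_templates,
)
from noctograph.fingerprint import N_BINS, CircadianFingerprint, compute_fingerprint
from noctograph.ingest import LocalizedPosts
from noctograph.model import eval_model
from noctograph.synthetic import simulate_user
from noctograph.ingest import localize


@pytest.fixture(scope="module")
def templates(ref_model):
    return make_templates(ref_model)


def _fp(values, n_posts=1000):
    return CircadianFingerprint(values=np.asarray(values) / np.sum(values),
                                n_posts=n_posts)


class TestMakeTemplates:
    def test_midnight_template_is_reindexed_model(self, ref_model, templates):
        vals = eval_model(ref_model)
        # clock bin i of the 00:00 template holds the model at x = i bins
        np.testing.assert_allclose(templates.templates[0], np.roll(vals, -48))

    def test_adjacent_templates_are_rotations(self, templates):
        t0 = templates.templates[0]
        np.testing.assert_allclose(templates.templates[4], np.roll(t0, 4))

    def test_every_template_sums_to_one(self, templates):
        np.testing.assert_allclose(templates.templates.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_bedtime_is_45_min_after_parabola_start(self, ref_model, templates):
        # with S = 0.75 the template's bedtime label sits 45 minutes after
        # the first parabolic bin — the two published descriptions agree
        assert ref_model.S == 0.75
        vals = eval_model(ref_model)
        first_parabolic_rel = np.flatnonzero(~np.isclose(vals, ref_model.d))[0]
        assert (48 - first_parabolic_rel) * 15 == 45


class TestEstimateBedtime:
    def test_self_match(self, templates):
        k = 92  # 23:00
        est = estimate_bedtime(_fp(templates.templates[k]), templates)
        assert est.bedtime == 23 * 60
        assert est.rho == pytest.approx(1.0)

    def test_rotation_equivariance_exact(self, templates):
        rng = np.random.default_rng(4)
        base = 0.8 * templates.templates[90] + 0.2 * rng.dirichlet(np.ones(N_BINS))
        e0 = estimate_bedtime(_fp(base), templates)
        for j in range(96):
            ej = estimate_bedtime(_fp(np.roll(base, j)), templates)
            assert ej.bedtime == (e0.bedtime + 15 * j) % 1440

    def test_sampled_user_recovered(self, ref_model, templates):
        epochs = simulate_user(90, 5000, ref_model, seed=123)  # 01:30
        fp = compute_fingerprint(localize(epochs, "UTC"))
        est = estimate_bedtime(fp, templates)
        assert circular_diff(est.bedtime, 90) <= 0.5

    def test_spearman_matches_scipy(self, templates):
        # dual route: the rank-vector implementation vs scipy's spearmanr
        rng = np.random.default_rng(5)
        fpv = rng.dirichlet(np.ones(N_BINS))
        est = estimate_bedtime(_fp(fpv), templates)
        k = est.bedtime // 15
        rho_scipy = spearmanr(fpv, templates.templates[k]).statistic
        assert est.rho == pytest.approx(rho_scipy, abs=1e-12)
        # and the winner really is the scipy argmax too
        all_scipy = [spearmanr(fpv, t).statistic for t in templates.templates]
        assert est.rho == pytest.approx(max(all_scipy), abs=1e-12)

    def test_degenerate_fingerprint_flagged(self, templates):
        single_bin = CircadianFingerprint(values=np.eye(N_BINS)[10], n_posts=3)
        est = estimate_bedtime(single_bin, templates)
        assert est.status == "degenerate"
        assert est.bedtime is None and est.rho is None


class TestEstimateBatch:
    def test_min_posts_floor(self, templates):
        rng = np.random.default_rng(6)
        users = [
            LocalizedPosts("u300", "UTC", rng.integers(0, 1440, 300)),
            LocalizedPosts("u100", "UTC", rng.integers(0, 1440, 100)),
            LocalizedPosts("u260", "UTC", rng.integers(0, 1440, 260)),
        ]
        out = estimate_batch(users, templates, min_posts=250)
        statuses = {e.author_id: e.status for e in out}
        assert statuses["u100"] == "too_few_posts"
        assert sum(s != "too_few_posts" for s in statuses.values()) == 2

    def test_empty_input(self, templates):
        assert estimate_batch([], templates) == []

    def test_batch_equals_single_calls(self, ref_model, templates):
        users = []
        for i, bt in enumerate((60, 1380, 90)):
            epochs = simulate_user(bt, 400, ref_model, seed=100 + i)
            users.append(localize(epochs, "UTC", f"u{i}"))
        batch = estimate_batch(users, templates, min_posts=250)
        for lp, est in zip(users, batch):
            single = estimate_bedtime(compute_fingerprint(lp), templates,
                                      lp.author_id)
            assert (est.bedtime, est.rho) == (single.bedtime, single.rho)

    def test_output_table_and_histogram(self, ref_model, templates):
        epochs = simulate_user(1380, 400, ref_model, seed=8)
        out = estimate_batch([localize(epochs, "UTC", "ua")], templates)
        df = estimates_to_frame(out)
        assert list(df.columns) == ["author_id", "estimated_bedtime", "rho",
                                    "n_posts", "status"]
        hist = bedtime_histogram(out)
        assert hist.sum() == 1
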