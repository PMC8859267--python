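import numpy as np
import pandas as pd
import pytest

from m6apattern import generate_cohort
from m6apattern.io import ClinicalTable, fpkm_to_tpm, log2_transform
from m6apattern.score import (
    M6AScoreModel,
    ScoreTable,
    compute_m6ascore,
    filter_prognostic_genes,
    fit_score_model,
    score_associations,
    stratify_by_score,
)
from m6apattern.survival import cox_fit

from .conftest import make_matrix, small_config


def _survival_clinical(rng, samples, latent=None):
    n = len(samples)
    if latent is None:
        latent = np.zeros(n)
    hazard = 0.03 * np.exp(np.log(2.0) * latent)
    t = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0, 80, n)
    event = (t <= censor).astype(int)
    time = np.maximum(np.minimum(t, censor), 0.01)
    return ClinicalTable(pd.DataFrame(
        {"time_months": time, "event": event}, index=samples
    ))


@pytest.fixture(scope="module")
def prognostic_fixture():
    # 40 of 200 genes carry a planted survival association
    rng = np.random.default_rng(77)
    n, G, k = 200, 200, 40
    latent = rng.normal(0, 1, n)
    X = rng.normal(0, 1, (G, n))
    X[:k] += 0.85 * latent  # planted association, per-gene HR ~ 1.8 on z-scale
    samples = [f"s{i}" for i in range(n)]
    m = make_matrix(X, samples=samples)
    clin = _survival_clinical(rng, samples, latent)
    return m, clin, k


class TestFilterPrognosticGenes:
    def test_planted_recovery(self, prognostic_fixture):
        m, clin, k = prognostic_fixture
        kept, stats = filter_prognostic_genes(m, clin, m.genes)
        planted = set(m.genes[:k])
        tp = len(set(kept) & planted)
        fp = len(kept) - tp
        assert tp >= 32
        assert fp <= 15
        assert set(stats.columns) == {"p", "coef"}

    def test_threshold_one_keeps_all(self, prognostic_fixture):
        m, clin, _ = prognostic_fixture
        kept, _ = filter_prognostic_genes(m, clin, m.genes, p_thresh=1.0)
        assert set(kept) == set(m.genes)

    def test_null_calibration_binomial_band(self):
        # shuffled survival: retained count ~ Binomial(G, p_thresh)
        G, n, p_thresh = 100, 100, 0.05
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            samples = [f"s{i}" for i in range(n)]
            m = make_matrix(rng.normal(0, 1, (G, n)), samples=samples)
            clin = _survival_clinical(rng, samples)
            try:
                kept, _ = filter_prognostic_genes(m, clin, m.genes, p_thresh=p_thresh)
                counts.append(len(kept))
            except ValueError:
                counts.append(0)  # < 2 retained is a valid null outcome
        mean = np.mean(counts)
        se = np.sqrt(G * p_thresh * (1 - p_thresh) / 20)
        assert abs(mean - G * p_thresh) < 2.58 * se + 1.0

    def test_too_few_survivors_rejected(self, rng):
        m = make_matrix(rng.normal(0, 1, (5, 40)))
        clin = _survival_clinical(rng, m.samples)
        with pytest.raises(ValueError, match="PCA impossible"):
            filter_prognostic_genes(m, clin, m.genes, p_thresh=1e-12)


class TestFitScoreModel:
    def test_duplication_invariance(self, rng):
        X = rng.normal(0, 1, (10, 20))
        m = make_matrix(X)
        dup = make_matrix(np.hstack([X, X]), genes=m.genes,
                          samples=m.samples + [f"{s}b" for s in m.samples])
        a = fit_score_model(m)
        b = fit_score_model(dup)
        np.testing.assert_allclose(a.loading1, b.loading1, atol=1e-8)
        np.testing.assert_allclose(a.loading2, b.loading2, atol=1e-8)

    def test_gene_order_permutation_invariance(self, rng):
        X = rng.normal(0, 1, (12, 15))
        m = make_matrix(X)
        perm = rng.permutation(12)
        m2 = make_matrix(X[perm], genes=[m.genes[i] for i in perm], samples=m.samples)
        s1 = compute_m6ascore(fit_score_model(m), m).scores
        s2 = compute_m6ascore(fit_score_model(m2), m2).scores
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)

    def test_rank_two_matrix_fully_explained(self, rng):
        u = rng.normal(0, 1, 30)
        v = rng.normal(0, 1, 30)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0, 1, 8)
        X = np.outer(a, u) + np.outer(b, v) + rng.normal(0, 1, (8, 1)) * 0
        m = make_matrix(X)
        model = fit_score_model(m)
        assert sum(model.explained_variance) == pytest.approx(1.0, abs=1e-6)

    def test_loadings_orthonormal(self, rng):
        m = make_matrix(rng.normal(0, 1, (9, 14)))
        model = fit_score_model(m)
        assert np.linalg.norm(model.loading1) == pytest.approx(1.0, abs=1e-10)
        assert abs(model.loading1 @ model.loading2) < 1e-10

    def test_rank_deficient_rejected(self, rng):
        row = rng.normal(0, 1, 10)
        X = np.vstack([row, 2 * row, -row])  # rank 1
        with pytest.raises(ValueError, match="rank"):
            fit_score_model(make_matrix(X))

    def test_json_round_trip(self, rng, tmp_path):
        m = make_matrix(rng.normal(0, 1, (6, 9)))
        model = fit_score_model(m)
        model.to_json(tmp_path / "model.json")
        back = M6AScoreModel.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(back.loading1, model.loading1)
        assert back.sign == model.sign
        assert back.genes == model.genes


class TestComputeScore:
    def test_mean_profile_scores_zero(self, rng):
        X = rng.normal(0, 1, (7, 12))
        m = make_matrix(X)
        model = fit_score_model(m)
        probe = make_matrix(model.means[:, None], genes=m.genes, samples=["mean_sample"])
        table = compute_m6ascore(model, probe)
        assert table.scores.iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_identical_samples_identical_scores(self, rng):
        X = rng.normal(0, 1, (7, 10))
        X[:, 5] = X[:, 4]
        m = make_matrix(X)
        table = compute_m6ascore(fit_score_model(m), m)
        assert table.scores.iloc[4] == pytest.approx(table.scores.iloc[5])

    def test_svd_projection_oracle_3x4(self):
        X = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [0.5, 2.5, 1.0, 4.5],
        ])
        m = make_matrix(X)
        model = fit_score_model(m)
        # independent oracle: direct SVD projection of the z-scored matrix,
        # with each component oriented by the documented pivot rule
        # (largest-|loading| entry positive); overall sign free (sigma)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        for c in (0, 1):
            if U[np.argmax(np.abs(U[:, c])), c] < 0:
                U[:, c] *= -1
                Vt[c] *= -1
        oracle = S[0] * Vt[0] + S[1] * Vt[1]
        got = compute_m6ascore(model, m).scores.to_numpy()
        sigma = model.sign
        np.testing.assert_allclose(got, sigma * oracle, atol=1e-8)

    def test_training_scores_match_svd(self, rng):
        X = rng.normal(0, 1, (15, 25))
        m = make_matrix(X)
        model = fit_score_model(m)
        got = compute_m6ascore(model, m).scores.to_numpy()
        Z = (X - model.means[:, None]) / model.sds[:, None]
        expected = model.sign * (model.loading1 + model.loading2) @ Z
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_missing_gene_named(self, rng):
        m = make_matrix(rng.normal(0, 1, (5, 8)))
        model = fit_score_model(m)
        sub = make_matrix(rng.normal(0, 1, (4, 8)), genes=m.genes[:4])
        with pytest.raises(ValueError, match=m.genes[4]):
            compute_m6ascore(model, sub)


class TestStratify:
    def test_planted_risk_groups(self):
        rng = np.random.default_rng(5)
        cfg = small_config(seed=31)
        b = generate_cohort(cfg)
        m = log2_transform(fpkm_to_tpm(b.expression))
        kept, stats = filter_prognostic_genes(m, b.clinical, b.truth.de_genes)
        model = fit_score_model(m.subset_genes(kept), stats)
        table = stratify_by_score(compute_m6ascore(model, m), b.clinical,
                                  n_permutations=0)
        t, e, s = b.clinical.survival(None)
        hi = (table.groups.loc[s] == "high").astype(float)
        fit = cox_fit(t, e, hi.to_numpy())
        assert np.exp(fit.beta[0]) > 1.0
        assert fit.p[0] < 0.05

    def test_constant_scores_rejected(self, rng):
        samples = [f"s{i}" for i in range(20)]
        clin = _survival_clinical(rng, samples)
        table = ScoreTable(scores=pd.Series(1.0, index=samples))
        with pytest.raises(ValueError):
            stratify_by_score(table, clin, n_permutations=0)

    def test_monotone_transform_same_grouping(self, rng):
        samples = [f"s{i}" for i in range(40)]
        latent = rng.normal(0, 1, 40)
        clin = _survival_clinical(rng, samples, latent)
        t1 = stratify_by_score(ScoreTable(scores=pd.Series(latent, index=samples)),
                               clin, n_permutations=0)
        t2 = stratify_by_score(ScoreTable(scores=pd.Series(np.exp(latent), index=samples)),
                               clin, n_permutations=0)
        assert t1.groups.equals(t2.groups)


class TestScoreAssociations:
    def test_planted_cluster_ordering(self, rng):
        samples = [f"s{i}" for i in range(90)]
        cluster = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30, index=samples)
        mus = {"A": 2.0, "B": 0.0, "C": -2.0}
        scores = pd.Series(
            [mus[c] + rng.normal(0, 0.5) for c in cluster], index=samples
        )
        rep = score_associations(ScoreTable(scores=scores), clusters=cluster)
        assert rep.cluster_kw.p_value < 0.01
        med = rep.medians["cluster"]
        assert med["C"] < med["B"] < med["A"]

    def test_independent_response_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(200)]
            scores = pd.Series(rng.normal(0, 1, 200), index=samples)
            response = pd.Series(rng.binomial(1, 0.4, 200), index=samples)
            rep = score_associations(ScoreTable(scores=scores), response=response)
            aucs.append(rep.response_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_identical_scores_kw_error_path(self):
        samples = [f"s{i}" for i in range(30)]
        cluster = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=samples)
        scores = pd.Series(1.0, index=samples)
        with pytest.raises(ValueError):
            score_associations(ScoreTable(scores=scores), clusters=cluster)

    def test_no_overlap_rejected(self, rng):
        scores = pd.Series(rng.normal(0, 1, 5), index=[f"s{i}" for i in range(5)])
        cluster = pd.Series(["A", "B"], index=["x1", "x2"])
        with pytest.raises(ValueError, match="overlap"):
            score_associations(ScoreTable(scores=scores), clusters=cluster)
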