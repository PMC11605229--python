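import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from proxidiff.coexpression import (
    CoexpressionNetwork,
    adjacency_matrix,
    detect_modules,
    module_trait,
    pick_soft_power,
    tom_similarity,
)
from proxidiff.exceptions import ValidationError
from proxidiff.simulate import ExpressionSimConfig, generate_expression


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap for small matrices."""
    n = len(a)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def _module_sim(seed, noise_sd=0.5, loading=0.8):
    config = ExpressionSimConfig.with_layout(
        160, module_sizes=[40, 40, 40], loading_mean=loading,
        noise_sd=noise_sd, n_controls=30, n_cases=30, seed=seed,
    )
    return generate_expression(config)


# --- TOM -------------------------------------------------------------------


def test_tom_empty_graph():
    a = np.zeros((5, 5))
    tom = tom_similarity(a)
    assert np.allclose(tom, np.eye(5))


def test_tom_complete_graph():
    n = 6
    a = np.ones((n, n)) - np.eye(n)
    tom = tom_similarity(a)
    assert np.allclose(tom, 1.0)


def test_tom_matches_triple_loop_oracle(rng):
    for _ in range(5):
        a = random_adjacency(rng, 8)
        assert np.max(np.abs(tom_similarity(a) - tom_oracle(a))) < 1e-12


def test_tom_star_graph_equals_adjacency(rng):
    # star: no two-paths between leaves through other leaves except the hub;
    # leaf-leaf TOM reduces to the shared-hub term, checked against oracle
    a = np.zeros((6, 6))
    a[0, 1:] = a[1:, 0] = rng.uniform(0.2, 0.9, 5)
    assert np.max(np.abs(tom_similarity(a) - tom_oracle(a))) < 1e-12


def test_tom_validates_input(rng):
    bad = rng.uniform(0, 1, (4, 4))
    with pytest.raises(ValidationError, match="symmetric"):
        tom_similarity(bad)
    a = random_adjacency(rng, 4)
    np.fill_diagonal(a, 0.5)
    with pytest.raises(ValidationError, match="diagonal"):
        tom_similarity(a)


def test_tom_entries_in_unit_interval(rng):
    for _ in range(5):
        tom = tom_similarity(random_adjacency(rng, 12))
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
        assert np.allclose(tom, tom.T)


# --- soft power ------------------------------------------------------------


def test_power_monotonicity(rng):
    expr = pd.DataFrame(rng.normal(0, 1, (40, 20)))
    a3 = adjacency_matrix(expr, 3).to_numpy()
    a5 = adjacency_matrix(expr, 5).to_numpy()
    off = ~np.eye(40, dtype=bool)
    strict = (a3 > 0) & (a3 < 1) & off
    assert (a5[strict] < a3[strict]).all()


def test_soft_power_on_module_structure():
    expr, _, _ = _module_sim(seed=21)
    beta, table = pick_soft_power(expr)
    assert 3 <= beta <= 12
    assert table.loc[beta, "signed_r2"] >= 0.8


def test_soft_power_degenerate_saturated_network():
    base = np.linspace(0, 1, 12)
    expr = pd.DataFrame(
        np.outer(np.arange(1, 41), base) + 1.0,
        index=[f"G{i}" for i in range(40)],
    )
    with pytest.warns(UserWarning, match="degenerate"):
        beta, _ = pick_soft_power(expr)
    assert beta == 1


def test_too_few_genes_rejected(rng):
    expr = pd.DataFrame(rng.normal(0, 1, (10, 8)))
    with pytest.raises(ValidationError, match=">= 30 genes"):
        pick_soft_power(expr)


# --- module detection ------------------------------------------------------


def test_two_modules_zero_noise_perfect_recovery():
    config = ExpressionSimConfig.with_layout(
        80, module_sizes=[40, 40], loading_mean=1.0, loading_sd=0.0,
        noise_sd=0.0, n_controls=15, n_cases=15, seed=9,
    )
    expr, _, truth = generate_expression(config)
    tom = tom_similarity(adjacency_matrix(expr, 6))
    labels = detect_modules(tom)
    assert adjusted_rand_score(truth["module"], labels) == 1.0


def test_module_recovery_with_noise():
    aris = []
    for seed in range(3):
        expr, _, truth = _module_sim(seed=30 + seed)
        labels = CoexpressionNetwork(expr).fit().labels
        aris.append(adjusted_rand_score(truth["module"], labels))
    assert np.mean(aris) >= 0.8


def test_pure_noise_mostly_unassigned():
    config = ExpressionSimConfig.with_layout(
        200, noise_sd=1.0, n_controls=30, n_cases=30, seed=44,
    )
    expr, _, _ = generate_expression(config)
    labels = CoexpressionNetwork(expr).fit().labels
    assert (labels == 0).mean() >= 0.9


def test_small_clusters_relabeled_zero(rng):
    a = np.zeros((30, 30))
    a[:25, :25] = 0.9
    np.fill_diagonal(a, 0.0)
    tom = tom_similarity(a)
    labels = detect_modules(tom, cut_height=0.95, min_size=20)
    assert (labels[:25] == 1).all()
    assert (labels[25:] == 0).all()


# --- eigengenes and trait correlation --------------------------------------


def test_identical_gene_module_eigengene_correlates_one(rng):
    profile = rng.normal(0, 1, 20)
    expr = pd.DataFrame(
        np.tile(profile, (5, 1)), index=[f"G{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(20)],
    )
    labels = pd.Series([1] * 5, index=expr.index)
    eig, stats = module_trait(expr, labels, trait=rng.normal(size=20))
    member_corr = np.corrcoef(eig[1].to_numpy(), profile)[0, 1]
    assert member_corr == pytest.approx(1.0, abs=1e-10)
    assert eig[1].std(ddof=0) == pytest.approx(1.0)


def test_planted_trait_direction_recovered(rng):
    """A module whose latent factor is shifted down in cases yields a
    negative eigengene-trait correlation."""
    n = 60
    is_case = np.array([0] * 30 + [1] * 30, dtype=float)
    factor = -1.0 * is_case + rng.normal(0, 0.5, n)
    loadings = rng.normal(1.0, 0.1, 40)
    expr = pd.DataFrame(
        np.outer(loadings, factor) + rng.normal(0, 0.5, (40, n)),
        index=[f"G{i}" for i in range(40)],
        columns=[f"s{i}" for i in range(n)],
    )
    labels = pd.Series([1] * 40, index=expr.index)
    _, stats = module_trait(expr, labels, is_case)
    assert stats.loc[1, "r"] < 0
    assert stats.loc[1, "p"] < 0.01


def test_eigengene_sign_flip_tracks_members(rng):
    """Negating every member gene negates the oriented eigengene (it follows
    the members), so the trait correlation flips sign with |r| preserved."""
    expr = pd.DataFrame(rng.normal(0, 1, (10, 25)),
                        index=[f"G{i}" for i in range(10)])
    expr.iloc[:] += np.outer(rng.normal(1, 0.1, 10), rng.normal(0, 1, 25))
    labels = pd.Series([1] * 10, index=expr.index)
    trait = rng.normal(size=25)
    _, s1 = module_trait(expr, labels, trait)
    _, s2 = module_trait(-expr, labels, trait)
    assert s1.loc[1, "r"] == pytest.approx(-s2.loc[1, "r"], abs=1e-10)
    assert s1.loc[1, "p"] == pytest.approx(s2.loc[1, "p"], abs=1e-10)


def test_eigengene_gene_order_invariance(rng):
    expr = pd.DataFrame(rng.normal(0, 1, (12, 18)),
                        index=[f"G{i}" for i in range(12)])
    labels = pd.Series([1] * 12, index=expr.index)
    trait = rng.normal(size=18)
    _, s1 = module_trait(expr, labels, trait)
    perm = expr.sample(frac=1.0, random_state=3)
    _, s2 = module_trait(perm, labels.reindex(perm.index), trait)
    assert s1.loc[1, "r"] == pytest.approx(s2.loc[1, "r"], abs=1e-10)


def test_trait_length_validated(rng):
    expr = pd.DataFrame(rng.normal(0, 1, (5, 10)))
    labels = pd.Series([1] * 5, index=expr.index)
    with pytest.raises(ValidationError, match="trait length"):
        module_trait(expr, labels, np.zeros(7))


def test_network_summary(expression_planted):
    _, expr, phenotype, _ = expression_planted
    # module genes plus unstructured genes: a scale-free-ish topology needs
    # a majority of low-connectivity nodes
    sub = pd.concat([expr.iloc[:120], expr.iloc[260:]])
    results = CoexpressionNetwork(sub).fit()
    results.module_trait((phenotype == "case").astype(float).to_numpy())
    text = results.summary()
    assert "soft power" in text
    assert "module-trait" in text
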