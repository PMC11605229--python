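import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxidiff.enrichment import (
    GeneSetEnrichment,
    enrichment_score,
    gsea,
    rank_genes,
)
from proxidiff.exceptions import ValidationError
from proxidiff.simulate import planted_set_collection


# --- independent oracles ---------------------------------------------------


def s2n_oracle(case: np.ndarray, ctrl: np.ndarray) -> float:
    """Plain-loop signal-to-noise with the floored denominators."""
    mean_c, mean_k = case.mean(), ctrl.mean()
    sd_c = max(case.std(ddof=1), 0.2 * abs(mean_c), 1e-8)
    sd_k = max(ctrl.std(ddof=1), 0.2 * abs(mean_k), 1e-8)
    return (mean_c - mean_k) / (sd_c + sd_k)


def es_oracle(metric: list[float], hits: list[bool], p: float) -> float:
    """Brute-force running-sum ES over an already-ranked list."""
    total = sum(abs(m) ** p for m, h in zip(metric, hits) if h)
    if total == 0:
        total = sum(hits)
        weights = [1.0 if h else 0.0 for h in hits]
    else:
        weights = [abs(m) ** p if h else 0.0 for m, h in zip(metric, hits)]
    n_miss = len(hits) - sum(hits)
    deviations, running_hit, running_miss = [], 0.0, 0.0
    for w, h in zip(weights, hits):
        running_hit += w / total
        running_miss += (0 if h else 1) / n_miss
        deviations.append(running_hit - running_miss)
    # same tie rule as the implementation: earliest position within 1e-12
    # of the maximal absolute deviation
    top = max(abs(d) for d in deviations)
    return next(d for d in deviations if abs(d) >= top - 1e-12)


# --- ranking ---------------------------------------------------------------


def test_s2n_matches_direct_computation(rng):
    expr = pd.DataFrame(
        rng.normal(0, 1, (5, 8)),
        index=[f"G{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(8)],
    )
    phenotype = pd.Series(["case"] * 4 + ["control"] * 4, index=expr.columns)
    ranked = rank_genes(expr, phenotype)
    for gene in expr.index:
        expected = s2n_oracle(
            expr.loc[gene].iloc[:4].to_numpy(), expr.loc[gene].iloc[4:].to_numpy()
        )
        assert ranked[gene] == pytest.approx(expected, abs=1e-12)
    assert (np.diff(ranked.to_numpy()) <= 1e-15).all()  # sorted descending


def test_s2n_null_gene_is_zero():
    expr = pd.DataFrame(
        [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 2, 3, 4, 5, 6.0]],
        index=["NULLG", "OTHER"],
        columns=[f"s{i}" for i in range(6)],
    )
    phenotype = pd.Series(["case"] * 3 + ["control"] * 3, index=expr.columns)
    assert rank_genes(expr, phenotype)["NULLG"] == 0.0


def test_s2n_scale_invariant(rng):
    expr = pd.DataFrame(rng.normal(5, 2, (6, 10)),
                        index=[f"G{i}" for i in range(6)],
                        columns=[f"s{i}" for i in range(10)])
    phenotype = pd.Series(["case"] * 5 + ["control"] * 5, index=expr.columns)
    r1 = rank_genes(expr, phenotype)
    r2 = rank_genes(expr * 3.7, phenotype)
    pd.testing.assert_series_equal(r1, r2)


def test_small_group_rejected(rng):
    expr = pd.DataFrame(rng.normal(0, 1, (4, 5)),
                        index=list("ABCD"), columns=[f"s{i}" for i in range(5)])
    phenotype = pd.Series(["case"] * 2 + ["control"] * 3, index=expr.columns)
    with pytest.raises(ValidationError, match=">= 3 samples"):
        rank_genes(expr, phenotype)


# --- enrichment score ------------------------------------------------------


def _ranked(values, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    return pd.Series(values, index=genes)


def test_es_top_gene_unweighted_is_one():
    ranked = _ranked([3.0, 2.0, 1.0, -1.0])
    es, _ = enrichment_score(ranked, {"G0"}, weight_p=0)
    assert es == pytest.approx(1.0)


def test_es_bottom_gene_unweighted_is_minus_one():
    ranked = _ranked([3.0, 2.0, 1.0, -1.0])
    es, _ = enrichment_score(ranked, {"G3"}, weight_p=0)
    assert es == pytest.approx(-1.0)


def test_es_matches_brute_force(rng):
    for _ in range(20):
        metric = np.sort(rng.normal(0, 1, 10))[::-1]
        ranked = _ranked(metric)
        members = rng.choice(10, size=3, replace=False)
        gene_set = {f"G{i}" for i in members}
        es, running = enrichment_score(ranked, gene_set, weight_p=1)
        hits = [g in gene_set for g in ranked.index]
        assert es == pytest.approx(es_oracle(list(metric), hits, 1.0), abs=1e-12)
        assert len(running) == 10


def test_es_bounds_and_negation(rng):
    metric = np.sort(rng.normal(0, 2, 30))[::-1]
    ranked = _ranked(metric)
    gene_set = {f"G{i}" for i in range(0, 30, 4)}
    es, _ = enrichment_score(ranked, gene_set)
    # negating the metric reverses the list: ES flips sign, |ES| preserved
    flipped = pd.Series(-metric[::-1], index=ranked.index[::-1])
    es_neg, _ = enrichment_score(flipped, gene_set)
    assert es_neg == pytest.approx(-es, abs=1e-12)
    assert -1 <= es <= 1


def test_es_rejects_degenerate_sets():
    ranked = _ranked([2.0, 1.0, -1.0])
    with pytest.raises(ValidationError):
        enrichment_score(ranked, {"ABSENT"})
    with pytest.raises(ValidationError):
        enrichment_score(ranked, {"G0", "G1", "G2"})


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_es_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    metric = np.sort(rng.normal(0, 1, n))[::-1]
    k = int(rng.integers(1, n))
    gene_set = {f"G{i}" for i in rng.choice(n, size=k, replace=False)}
    es, _ = enrichment_score(_ranked(metric), gene_set)
    assert -1.0 <= es <= 1.0


# --- full GSEA -------------------------------------------------------------


def test_nominal_p_matches_exhaustive_enumeration(rng):
    """With 3-vs-3 samples there are exactly 20 label splits; the nominal p
    must equal the directly enumerated permutation p."""
    genes = [f"G{i:02d}" for i in range(30)]
    samples = [f"s{i}" for i in range(6)]
    expr = pd.DataFrame(rng.normal(0, 1, (30, 6)), index=genes, columns=samples)
    expr.iloc[:8, :3] += 1.0  # modest real signal
    phenotype = pd.Series(["case"] * 3 + ["control"] * 3, index=samples)
    gene_set = set(genes[:8])

    result = gsea(expr, phenotype, {"S": gene_set}, n_perm=1000, seed=0,
                  min_size=2)
    assert result.attrs["exhaustive"]
    assert result.attrs["n_perm"] == 20

    # oracle: enumerate every split with plain-loop s2n + running sum
    X = expr.to_numpy()
    def split_es(case_cols):
        metric = {
            g: s2n_oracle(X[i, list(case_cols)],
                          X[i, [j for j in range(6) if j not in case_cols]])
            for i, g in enumerate(genes)
        }
        order = sorted(genes, key=lambda g: (-metric[g], g))
        hits = [g in gene_set for g in order]
        return es_oracle([metric[g] for g in order], hits, 1.0)

    observed = split_es((0, 1, 2))
    perm = [split_es(c) for c in itertools.combinations(range(6), 3)]
    same_sign = [e for e in perm if (e >= 0) == (observed >= 0)]
    p_oracle = (1 + sum(abs(e) >= abs(observed) for e in same_sign)) / (
        1 + len(same_sign)
    )
    assert result.loc["S", "es"] == pytest.approx(observed, abs=1e-12)
    assert result.loc["S", "p"] == pytest.approx(p_oracle, abs=1e-15)


def test_planted_set_dominates(expression_planted):
    config, expr, phenotype, _ = expression_planted
    sets = planted_set_collection(config)
    result = gsea(expr, phenotype, sets, n_perm=300, seed=2)
    top = result["nes"].abs().idxmax()
    assert top == "PLANTED"
    assert result.loc["PLANTED", "q"] < 0.05
    assert result.loc["PLANTED", "enriched_in"] == "case"
    assert result.loc["PLANTED", "es"] > 0


def test_gsea_deterministic_and_order_invariant(expression_planted):
    config, expr, phenotype, _ = expression_planted
    sets = planted_set_collection(config)
    r1 = gsea(expr, phenotype, sets, n_perm=100, seed=5)
    r2 = gsea(expr, phenotype, sets, n_perm=100, seed=5)
    shuffled = expr.sample(frac=1.0, random_state=1)
    r3 = gsea(shuffled, phenotype, sets, n_perm=100, seed=5)
    pd.testing.assert_frame_equal(r1, r2)
    pd.testing.assert_frame_equal(r1, r3)


def test_size_filter_drops_sets(expression_planted):
    config, expr, phenotype, _ = expression_planted
    sets = dict(planted_set_collection(config))
    sets["TINY"] = ["G0001", "G0002"]
    result = gsea(expr, phenotype, sets, n_perm=100, seed=0)
    assert "TINY" not in result.index
    with pytest.raises(ValidationError):
        gsea(expr, phenotype, {"TINY": ["G0001", "G0002"]}, n_perm=100, seed=0)


def test_model_results_wrapper(expression_planted):
    config, expr, phenotype, _ = expression_planted
    fitted = GeneSetEnrichment(
        expr, phenotype, planted_set_collection(config)
    ).fit(n_perm=150, seed=3)
    assert "PLANTED" in fitted.significant(0.05).index
    assert "sets tested" in fitted.summary()
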