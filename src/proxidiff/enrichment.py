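"""Weighted Kolmogorov–Smirnov gene-set enrichment with permutation FDR.

The engine follows the classic two-group GSEA recipe: genes are ranked by a
signal-to-noise metric, the enrichment score (ES) of a set is the signed
maximal deviation of a weighted running sum over the ranked list, the null
is built by permuting phenotype labels (exhaustively when fewer distinct
label splits exist than requested permutations), NES normalizes each ES by
the mean magnitude of same-sign permuted scores, and the FDR q is the
ratio of permuted to observed NES tail fractions, clipped to [0, 1] and
made monotone.

Conventions (each a config knob): weight ``p = 1``; metric ties broken by
gene id; the gene universe is the expression matrix after dropping
zero-variance rows; sets outside [15, 500] genes are dropped with a log
line.  Zeros on the permutation scale count toward the positive side.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def _infer_classes(phenotype: pd.Series) -> tuple[str, str]:
    labels = list(dict.fromkeys(phenotype))
    if len(labels) != 2:
        raise ValidationError(
            f"phenotype must have exactly two classes, got {sorted(set(labels))}"
        )
    if set(labels) == {"case", "control"}:
        return "case", "control"
    return labels[0], labels[1]


def _s2n(X: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene row; sd floored at max(sd, 0.2|mean|, 1e-8)."""
    a, b = X[:, pos], X[:, ~pos]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum.reduce([a.std(axis=1, ddof=1), 0.2 * np.abs(mean_a),
                              np.full(len(X), 1e-8)])
    sd_b = np.maximum.reduce([b.std(axis=1, ddof=1), 0.2 * np.abs(mean_b),
                              np.full(len(X), 1e-8)])
    return (mean_a - mean_b) / (sd_a + sd_b)


def rank_genes(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    metric: str = "s2n",
    classes: tuple[str, str] | None = None,
) -> pd.Series:
    """Rank genes by a two-group metric, descending; ties broken by gene id.

    ``classes = (positive, negative)``; by default ``("case", "control")``
    when those labels are present, else the two labels in order of first
    appearance.  Each group needs at least 3 samples.
    """
    if metric != "s2n":
        raise ValidationError(f"unknown ranking metric {metric!r}")
    phenotype = phenotype.reindex(expr.columns)
    if phenotype.isna().any():
        raise ValidationError("phenotype missing for some samples")
    pos_label, neg_label = classes or _infer_classes(phenotype)
    pos = (phenotype == pos_label).to_numpy()
    neg = (phenotype == neg_label).to_numpy()
    if pos.sum() < 3 or neg.sum() < 3:
        raise ValidationError(
            "each phenotype group needs >= 3 samples for a permutation null"
        )
    # deterministic tie-break: lexicographic gene order, then stable sort
    ordered = expr.loc[sorted(expr.index), list(expr.columns)]
    values = _s2n(ordered.to_numpy(dtype=float)[:, pos | neg], pos[pos | neg])
    series = pd.Series(values, index=ordered.index, name="s2n")
    return series.sort_values(ascending=False, kind="stable")


def _es_core(metric_sorted: np.ndarray, is_hit: np.ndarray, weight_p: float):
    n = len(metric_sorted)
    n_hits = int(is_hit.sum())
    weights = np.where(is_hit, np.abs(metric_sorted) ** weight_p, 0.0)
    total = weights.sum()
    if total == 0:  # all hit metrics are zero: fall back to equal weights
        weights = is_hit.astype(float)
        total = float(n_hits)
    p_hit = np.cumsum(weights) / total
    p_miss = np.cumsum(~is_hit) / (n - n_hits)
    running = p_hit - p_miss
    # deterministic tie rule: earliest position within 1e-12 of the maximal
    # absolute deviation (exact +/- ties can occur on small lists)
    magnitude = np.abs(running)
    peak = int(np.argmax(magnitude >= magnitude.max() - 1e-12))
    return float(running[peak]), running


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0):
    """ES and the running sum for one gene set on a ranked list.

    The set must intersect the ranked universe and be a proper subset of it.
    """
    members = {str(g).upper() for g in gene_set}
    is_hit = np.fromiter(
        (str(g).upper() in members for g in ranked.index), bool, len(ranked)
    )
    n_hits = int(is_hit.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked universe")
    if n_hits == len(ranked):
        raise ValidationError("gene set equals the ranked universe")
    return _es_core(ranked.to_numpy(dtype=float), is_hit, weight_p)


def _restrict_sets(gene_sets, universe, min_size, max_size):
    uni = set(universe)
    kept: dict[str, list[str]] = {}
    for name, members in gene_sets.items():
        inside = sorted({str(g).upper() for g in members} & uni)
        if not (min_size <= len(inside) <= max_size) or len(inside) == len(uni):
            logger.info(
                "dropping set %s: %d genes in universe outside [%d, %d]",
                name, len(inside), min_size, max_size,
            )
            continue
        kept[name] = inside
    return kept


def _label_splits(n_samples: int, n_pos: int, n_perm: int, rng: np.random.Generator):
    """Positive-class masks of the permutation null.

    Exhaustive enumeration of all C(n, n_pos) splits when that count does
    not exceed ``n_perm``; otherwise ``n_perm`` random splits.
    """
    n_distinct = math.comb(n_samples, n_pos)
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, n_samples), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n_samples), n_pos)):
            masks[i, list(combo)] = True
        return masks, True
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n_samples, size=n_pos, replace=False)] = True
    return masks, False


def gsea(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    gene_sets: dict,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    classes: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group GSEA over a gene-set collection.

    Returns one row per retained set: ``size``, ``es``, ``nes``, ``p``
    (nominal, permutation), ``q`` (FDR, ratio method), ``enriched_in``
    (phenotype label at the leading edge), sorted by NES descending.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; p-values are coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    pos_label, neg_label = classes or _infer_classes(phenotype.reindex(expr.columns))

    variances = expr.var(axis=1, ddof=0)
    universe = expr.index[variances > 0]
    n_dropped = len(expr) - len(universe)
    if n_dropped:
        logger.info("dropping %d zero-variance gene(s) from the universe", n_dropped)
    expr = expr.loc[sorted(universe), list(expr.columns)]  # lexicographic order

    sets = _restrict_sets(gene_sets, expr.index, min_size, max_size)
    if not sets:
        raise ValidationError("no gene set survives the size/universe restriction")

    X = expr.to_numpy(dtype=float)
    genes = expr.index
    membership = {
        name: np.fromiter((g in set(members) for g in genes), bool, len(genes))
        for name, members in sets.items()
    }

    pheno = phenotype.reindex(expr.columns)
    pos_obs = (pheno == pos_label).to_numpy()
    if pos_obs.sum() < 3 or (~pos_obs).sum() < 3:
        raise ValidationError("each phenotype group needs >= 3 samples")

    def all_es(pos_mask: np.ndarray) -> dict[str, float]:
        metric = _s2n(X, pos_mask)
        order = np.argsort(-metric, kind="stable")
        metric_sorted = metric[order]
        return {
            name: _es_core(metric_sorted, hit[order], weight_p)[0]
            for name, hit in membership.items()
        }

    es_obs = all_es(pos_obs)
    masks, exhaustive = _label_splits(len(pheno), int(pos_obs.sum()), n_perm, rng)
    es_perm = np.array(
        [list(all_es(mask).values()) for mask in masks]
    )  # (n_perm, n_sets), column order = sets order
    set_names = list(sets)

    rows = []
    nes_perm_pool: list[float] = []
    for j, name in enumerate(set_names):
        es = es_obs[name]
        perm = es_perm[:, j]
        same_sign = perm >= 0 if es >= 0 else perm < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(perm[same_sign]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_same)
        scale_pos = np.abs(perm[perm >= 0]).mean() if (perm >= 0).any() else np.nan
        scale_neg = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else np.nan
        scale = scale_pos if es >= 0 else scale_neg
        if not np.isfinite(scale) or scale == 0:
            scale = np.abs(perm).mean()
        nes = es / scale if scale else np.nan
        # pool sign-matched normalized permutation scores for the FDR ratio
        for e in perm:
            s = scale_pos if e >= 0 else scale_neg
            if np.isfinite(s) and s > 0:
                nes_perm_pool.append(e / s)
        rows.append({"set": name, "size": int(membership[name].sum()),
                     "es": es, "nes": nes, "p": p,
                     "enriched_in": pos_label if es >= 0 else neg_label})

    frame = pd.DataFrame(rows).set_index("set")
    frame["q"] = _fdr_ratio(frame["nes"].to_numpy(), np.asarray(nes_perm_pool))
    frame = frame[["size", "es", "nes", "p", "q", "enriched_in"]]
    frame.attrs["n_perm"] = len(masks)
    frame.attrs["exhaustive"] = exhaustive
    if (frame["q"] == 0).any():
        logger.info(
            "%d set(s) report q = 0 at %d permutations",
            int((frame["q"] == 0).sum()), len(masks),
        )
    return frame.sort_values("nes", ascending=False, kind="stable")


def _fdr_ratio(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """GSEA ratio FDR: permuted vs observed NES tail fractions, per sign."""
    q = np.full(len(nes_obs), np.nan)
    finite_obs = nes_obs[np.isfinite(nes_obs)]
    perm = nes_perm[np.isfinite(nes_perm)]
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (perm >= nes).mean() if perm.size else 0.0
            den = (finite_obs >= nes).mean()
        else:
            num = (perm <= nes).mean() if perm.size else 0.0
            den = (finite_obs <= nes).mean()
        q[i] = min(1.0, num / den) if den > 0 else np.nan
    # monotone: a more extreme NES never gets a larger q; step-up style, each
    # set takes the minimum raw q over itself and all less extreme sets of
    # the same sign
    for positive in (True, False):
        idx = [
            i for i in range(len(nes_obs))
            if np.isfinite(nes_obs[i]) and ((nes_obs[i] >= 0) == positive)
        ]
        idx.sort(key=lambda i: abs(nes_obs[i]))  # least extreme first
        best = np.inf
        for i in idx:
            best = min(best, q[i])
            q[i] = best
    return q


def prerank(
    ranked: pd.Series,
    gene_sets: dict,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null (random same-size sets)."""
    rng = np.random.default_rng(seed)
    sets = _restrict_sets(gene_sets, ranked.index, min_size, max_size)
    if not sets:
        raise ValidationError("no gene set survives the size/universe restriction")
    metric = ranked.to_numpy(dtype=float)
    n = len(metric)
    rows = []
    nes_pool: list[float] = []
    for name, members in sets.items():
        member_set = set(members)
        is_hit = np.fromiter((g in member_set for g in ranked.index), bool, n)
        es, _ = _es_core(metric, is_hit, weight_p)
        k = int(is_hit.sum())
        perm = np.empty(n_perm)
        hit = np.zeros(n, dtype=bool)
        for i in range(n_perm):
            hit[:] = False
            hit[rng.choice(n, size=k, replace=False)] = True
            perm[i], _ = _es_core(metric, hit, weight_p)
        same_sign = perm >= 0 if es >= 0 else perm < 0
        p = (1 + int((np.abs(perm[same_sign]) >= abs(es)).sum())) / (1 + int(same_sign.sum()))
        scale_pos = np.abs(perm[perm >= 0]).mean() if (perm >= 0).any() else np.nan
        scale_neg = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else np.nan
        scale = scale_pos if es >= 0 else scale_neg
        if not np.isfinite(scale) or scale == 0:
            scale = np.abs(perm).mean()
        nes = es / scale if scale else np.nan
        for e in perm:
            s = scale_pos if e >= 0 else scale_neg
            if np.isfinite(s) and s > 0:
                nes_pool.append(e / s)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p,
                     "enriched_in": "top" if es >= 0 else "bottom"})
    frame = pd.DataFrame(rows).set_index("set")
    frame["q"] = _fdr_ratio(frame["nes"].to_numpy(), np.asarray(nes_pool))
    return frame[["size", "es", "nes", "p", "q", "enriched_in"]].sort_values(
        "nes", ascending=False, kind="stable"
    )


class GeneSetEnrichment:
    """Model object for two-group gene-set enrichment.

    ``GeneSetEnrichment(expr, phenotype, gene_sets).fit(n_perm=..., seed=...)``
    returns an :class:`EnrichmentResults` whose ``frame`` is the per-set
    table produced by :func:`gsea`.
    """

    def __init__(self, expr, phenotype, gene_sets, *, weight_p: float = 1.0,
                 min_size: int = 15, max_size: int = 500,
                 classes: tuple[str, str] | None = None):
        self.expr = expr
        self.phenotype = phenotype
        self.gene_sets = dict(gene_sets)
        self.weight_p = weight_p
        self.min_size = min_size
        self.max_size = max_size
        self.classes = classes

    def fit(self, n_perm: int = 1000, seed: int | None = None) -> "EnrichmentResults":
        frame = gsea(
            self.expr, self.phenotype, self.gene_sets,
            n_perm=n_perm, seed=seed, weight_p=self.weight_p,
            min_size=self.min_size, max_size=self.max_size, classes=self.classes,
        )
        return EnrichmentResults(self, frame)


@dataclass
class EnrichmentResults:
    model: GeneSetEnrichment
    frame: pd.DataFrame

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["q"] < q_threshold]

    def summary(self, top: int = 10) -> str:
        lines = [
            "Gene-set enrichment results",
            "===========================",
            f"sets tested:       {len(self.frame)}",
            f"permutations:      {self.frame.attrs.get('n_perm', 'NA')}"
            + (" (exhaustive)" if self.frame.attrs.get("exhaustive") else ""),
            f"q < 0.05:          {int((self.frame['q'] < 0.05).sum())}",
            "",
            self.frame.head(top).to_string(float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)
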