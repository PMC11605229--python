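"""Minimal weighted co-expression network analysis.

The pipeline is the standard one: soft-threshold the absolute gene-gene
correlation into an adjacency (``a_ij = |cor|^beta``, beta chosen by a
scale-free topology fit), convert to topological overlap (TOM), cluster the
dissimilarity ``1 - TOM`` with average linkage, cut the tree at a fixed
height, and summarize each module by its eigengene (first principal
component of the standardized member submatrix) whose correlation with a
per-sample trait gives the module-trait direction.

Kept deliberately small: unsigned network, static tree cut, no module
merging or dynamic cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import ValidationError


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    variances = expr.var(axis=1, ddof=0)
    constant = expr.index[variances == 0]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant gene row(s)", stacklevel=3
        )
        expr = expr.drop(index=constant)
    return expr


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins connectivity into ``n_bins`` equal-count bins, estimates the
    density p(k) per bin (bin fraction / bin width), and regresses
    log10 p(k) on log10 mean k.  Returns ``(signed_r2, slope)`` where the
    R^2 carries a negative sign when the slope is positive (a scale-free
    network must have decreasing p(k)).
    """
    k = np.asarray(k, dtype=float)
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValidationError("fewer than 2 usable connectivity bins")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_k, log_p = [], []
    for b in range(len(edges) - 1):
        mask = which == b
        if not mask.any():
            continue
        width = edges[b + 1] - edges[b]
        mean_k = k[mask].mean()
        density = mask.mean() / width if width > 0 else np.nan
        if mean_k > 0 and density and np.isfinite(density) and density > 0:
            log_k.append(np.log10(mean_k))
            log_p.append(np.log10(density))
    if len(log_k) < 2:
        raise ValidationError("fewer than 2 usable connectivity bins")
    if np.ptp(log_k) < 1e-8:
        raise ValidationError("connectivity has no spread (saturated network)")
    fit = stats.linregress(log_k, log_p)
    r2 = fit.rvalue**2
    return (-r2 if fit.slope > 0 else r2), fit.slope


def pick_soft_power(
    expr: pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by scale-free topology fit.

    Returns ``(beta, fit_table)``: the smallest power whose signed R^2
    reaches ``r2_target``, or the argmax of signed R^2 when none does.
    """
    expr = _drop_constant(expr)
    if len(expr) < 30:
        raise ValidationError("need >= 30 genes to assess scale-free topology")
    corr = np.abs(np.corrcoef(expr.to_numpy(dtype=float)))
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in powers:
        adjacency = corr**beta
        k = adjacency.sum(axis=1)
        try:
            signed_r2, slope = scale_free_fit(k, n_bins)
        except ValidationError:
            signed_r2, slope = np.nan, np.nan
        rows.append({"power": int(beta), "signed_r2": signed_r2, "slope": slope,
                     "mean_k": k.mean()})
    table = pd.DataFrame(rows).set_index("power")
    ok = table.index[table["signed_r2"] >= r2_target]
    if len(ok):
        beta = int(ok[0])
    else:  # degenerate or weak topology: fall back to the best fit
        if table["signed_r2"].isna().all():
            # saturated/constant connectivity (e.g. all |r| = 1): every power
            # is equivalent, so keep the smallest
            warnings.warn("scale-free fit degenerate for every power; "
                          "falling back to the smallest", stacklevel=2)
            beta = int(table.index[0])
        else:
            beta = int(table["signed_r2"].idxmax())
    return beta, table


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|cor|^beta`` with zero diagonal."""
    expr = _drop_constant(expr)
    corr = np.abs(np.corrcoef(expr.to_numpy(dtype=float))) ** beta
    np.fill_diagonal(corr, 0.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def tom_similarity(adjacency) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_{u != i,j} a_iu a_uj``; diagonal set to 1.  Input must be
    symmetric with zero diagonal and entries in [0, 1].
    """
    frame_in = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(dtype=float) if frame_in else np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max(initial=0.0) > 1e-12:
        raise ValidationError("adjacency diagonal must be zero")
    if a.min(initial=0.0) < -1e-12 or a.max(initial=0.0) > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    # shared-neighbor term: (A @ A)_ij sums over all u, including u = i, j,
    # but those contribute a_ii a_ij = 0 since the diagonal is zero
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if frame_in:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def detect_modules(
    tom, cut_height: float = 0.95, min_size: int = 20
) -> pd.Series | np.ndarray:
    """Average-linkage modules from a static cut of the 1 - TOM dendrogram.

    Clusters smaller than ``min_size`` are relabeled 0 (unassigned); the
    rest are renumbered 1, 2, ... by decreasing size.
    """
    frame_in = isinstance(tom, pd.DataFrame)
    t = tom.to_numpy(dtype=float) if frame_in else np.asarray(tom, float)
    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip(dissim, 0.0, None), checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = np.zeros(len(t), dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= min_size].sort_values(ascending=False)
    for new, old in enumerate(kept.index, start=1):
        labels[raw == old] = new
    if kept.empty:
        warnings.warn("no cluster reaches min_size; all genes unassigned",
                      stacklevel=2)
    if frame_in:
        return pd.Series(labels, index=tom.index, name="module")
    return labels


def _eigengene(member_expr: np.ndarray) -> np.ndarray:
    """Unit-variance first-PC sample scores of a standardized gene block."""
    sd = member_expr.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (member_expr - member_expr.mean(axis=1, keepdims=True)) / sd
    if z.shape[0] == 1:
        scores = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0]
    scores = scores - scores.mean()
    scale = scores.std(ddof=0)
    if scale > 0:
        scores = scores / scale
    # orient: mean correlation with member genes must be non-negative
    member_corr = (z * scores).mean(axis=1)
    if member_corr.mean() < 0:
        scores = -scores
    return scores


def module_trait(
    expr: pd.DataFrame, labels: pd.Series, trait
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eigengenes and eigengene-trait correlations per module.

    Returns ``(eigengenes, stats)``: eigengenes is samples × modules;
    stats has one row per module with Pearson ``r`` and its t-transform
    p-value against the trait.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape != (expr.shape[1],):
        raise ValidationError("trait length must equal the sample count")
    labels = labels.reindex(expr.index)
    modules = sorted(int(m) for m in labels.unique() if m != 0)
    if not modules:
        raise ValidationError("no assigned module (all labels 0)")
    eigengenes = {}
    rows = []
    for m in modules:
        block = expr.loc[labels == m].to_numpy(dtype=float)
        scores = _eigengene(block)
        eigengenes[m] = scores
        r, p = stats.pearsonr(scores, trait)
        rows.append({"module": m, "n_genes": int((labels == m).sum()),
                     "r": r, "p": p})
    eig = pd.DataFrame(eigengenes, index=expr.columns)
    eig.columns.name = "module"
    return eig, pd.DataFrame(rows).set_index("module")


class CoexpressionNetwork:
    """Model object wrapping the full co-expression workflow.

    ``CoexpressionNetwork(expr).fit()`` picks the soft power, builds the
    TOM, detects modules and returns a :class:`CoexpressionResults`.
    """

    def __init__(self, expr: pd.DataFrame, *, powers=range(1, 21),
                 r2_target: float = 0.8, cut_height: float = 0.95,
                 min_size: int = 20):
        self.expr = _drop_constant(expr)
        self.powers = powers
        self.r2_target = r2_target
        self.cut_height = cut_height
        self.min_size = min_size

    def fit(self) -> "CoexpressionResults":
        beta, fit_table = pick_soft_power(self.expr, self.powers, self.r2_target)
        adjacency = adjacency_matrix(self.expr, beta)
        tom = tom_similarity(adjacency)
        labels = detect_modules(tom, self.cut_height, self.min_size)
        return CoexpressionResults(self, beta, fit_table, labels)


@dataclass
class CoexpressionResults:
    model: CoexpressionNetwork
    power: int
    fit_table: pd.DataFrame
    labels: pd.Series
    _trait_stats: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_modules(self) -> int:
        return int((np.unique(self.labels) != 0).sum())

    def module_trait(self, trait) -> tuple[pd.DataFrame, pd.DataFrame]:
        eig, table = module_trait(self.model.expr, self.labels, trait)
        self._trait_stats = table
        return eig, table

    def summary(self) -> str:
        counts = self.labels.value_counts().sort_index()
        lines = [
            "Co-expression modules",
            "=====================",
            f"genes:        {len(self.labels)}",
            f"soft power:   {self.power} "
            f"(signed R2 = {self.fit_table.loc[self.power, 'signed_r2']:.3f})",
            f"modules:      {self.n_modules} "
            f"(unassigned: {int(counts.get(0, 0))})",
        ]
        if self._trait_stats is not None:
            lines += ["", "module-trait correlations:",
                      self._trait_stats.to_string(float_format=lambda x: f"{x:.4g}")]
        return "\n".join(lines)
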