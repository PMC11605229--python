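"""Set arithmetic tying interactor calls to disease gene-set enrichment.

Operates on an enrichment table holding, for each hallmark gene set, the
direction, NES and FDR q in two disease conditions (idiopathic and ischemic
cardiomyopathy).  The packaged fixtures transcribe the published table of
the 50 hallmark sets and the companion table of per-set interacting
proteins, so the whole stage runs offline.

The list-overlap test is an exact upper-tail hypergeometric computed by
summation in log space, cross-checkable against scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .exceptions import ValidationError

CONDITIONS = ("idiopathic", "ischemic")

#: overlap configuration reported by the source study: ~20,000 human
#: protein-coding genes as background, 382- and 387-protein lists, 22 shared
PUBLISHED_OVERLAP = {"background_n": 20_000, "size_a": 382, "size_b": 387,
                     "overlap": 22, "p": 3.69e-7}


def _data_path(name: str):
    return resources.files("proxidiff.data").joinpath(name)


def load_hallmark_table() -> pd.DataFrame:
    """Packaged fixture: 50 hallmark sets × (direction, NES, q) per condition.

    The ``proteins`` column carries the interacting proteins reported per
    set (comma-joined, possibly empty).
    """
    with resources.as_file(_data_path("table1_hallmark.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype={"proteins": str})
    frame["proteins"] = frame["proteins"].fillna("")
    return frame.set_index("hallmark")


def load_interactor_sets() -> pd.DataFrame:
    """Packaged fixture: the 15 sets with >= 3 interacting proteins."""
    with resources.as_file(_data_path("table2_sets.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    return frame.set_index("gene_set")


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def significant_sets(
    table: pd.DataFrame, condition: str, q_threshold: float = 0.05
) -> dict[str, str]:
    """Sets with q < threshold in one condition, mapped to their direction."""
    if condition not in CONDITIONS:
        raise ValidationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    q_col, dir_col = f"q_{condition}", f"direction_{condition}"
    hits = table[table[q_col] < q_threshold]
    return dict(zip(hits.index, hits[dir_col]))


@dataclass(frozen=True)
class VennResult:
    both: frozenset
    only_a: frozenset
    only_b: frozenset

    @property
    def either(self) -> frozenset:
        return self.both | self.only_a | self.only_b

    @property
    def counts(self) -> dict[str, int]:
        return {"both": len(self.both), "only_a": len(self.only_a),
                "only_b": len(self.only_b), "either": len(self.either)}


def venn_compare(sets_a, sets_b) -> VennResult:
    """Two-way Venn of set-name collections (dicts or iterables)."""
    a, b = set(sets_a), set(sets_b)
    return VennResult(frozenset(a & b), frozenset(a - b), frozenset(b - a))


@dataclass
class InteractorMapping:
    """Interactors grouped by gene set, plus those in no set."""

    per_set: dict[str, list[str]]
    unmapped: list[str]

    def counts(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.per_set.items()}


def map_interactors(interactors, gene_sets) -> InteractorMapping:
    """Intersect an interactor list with every gene set (case-insensitive)."""
    if not gene_sets:
        raise ValidationError("empty gene-set collection")
    pool = {_norm(p) for p in interactors}
    per_set = {
        name: sorted(pool & {_norm(g) for g in members})
        for name, members in gene_sets.items()
    }
    covered = set().union(*per_set.values()) if per_set else set()
    return InteractorMapping(per_set=per_set, unmapped=sorted(pool - covered))


def sets_with_min(
    mapping: InteractorMapping, set_filter=None, min_n: int = 3
) -> list[str]:
    """Sets (within ``set_filter``) with >= min_n mapped interactors.

    Sorted by count descending, then name.
    """
    names = mapping.per_set.keys() if set_filter is None else set_filter
    unknown = sorted(set(names) - mapping.per_set.keys())
    if unknown:
        raise ValidationError(f"set_filter names not in mapping: {', '.join(unknown)}")
    hits = [n for n in names if len(mapping.per_set[n]) >= min_n]
    return sorted(hits, key=lambda n: (-len(mapping.per_set[n]), n))


def union_count(mapping: InteractorMapping, set_names) -> int:
    """Distinct proteins across the named sets."""
    unknown = sorted(set(set_names) - mapping.per_set.keys())
    if unknown:
        raise ValidationError(f"set names not in mapping: {', '.join(unknown)}")
    members: set[str] = set()
    for name in set_names:
        members |= set(mapping.per_set[name])
    return len(members)


def fixture_mapping(table: pd.DataFrame | None = None) -> InteractorMapping:
    """Interactor-per-set mapping read off the packaged hallmark fixture."""
    if table is None:
        table = load_hallmark_table()
    per_set = {
        name: sorted({_norm(p) for p in row.split(",") if p.strip()})
        for name, row in table["proteins"].items()
    }
    return InteractorMapping(per_set=per_set, unmapped=[])


# --------------------------------------------------------------------------
# hypergeometric list overlap


@dataclass(frozen=True)
class OverlapResult:
    background_n: int
    size_a: int
    size_b: int
    overlap: int
    expected: float
    p: float

    def __str__(self) -> str:
        return (
            f"overlap {self.overlap} of {self.size_a} x {self.size_b} lists "
            f"(background {self.background_n}; expected {self.expected:.2f}); "
            f"one-sided hypergeometric p = {self.p:.3g}"
        )


def hypergeom_upper_tail(k: int, background_n: int, size_a: int, size_b: int) -> float:
    """Exact P(X >= k) for overlap of two lists, summed in log space."""
    if min(k, background_n, size_a, size_b) < 0:
        raise ValidationError("all overlap-test counts must be non-negative")
    if max(size_a, size_b) > background_n:
        raise ValidationError("list larger than the background")
    if k == 0:
        return 1.0
    upper = min(size_a, size_b)
    if k > upper:
        return 0.0

    def log_choose(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    log_total = log_choose(background_n, size_b)
    terms = [
        log_choose(size_a, x) + log_choose(background_n - size_a, size_b - x) - log_total
        for x in range(k, upper + 1)
        if size_b - x <= background_n - size_a
    ]
    return float(min(1.0, np.exp(logsumexp(terms))))


def overlap_test(list_a, list_b, background_n: int = 20_000) -> OverlapResult:
    """One-sided hypergeometric test of the overlap between two lists.

    Symbols are compared case-insensitively.  ``background_n`` defaults to
    the ~20,000 human protein-coding genes.
    """
    a = {_norm(x) for x in list_a}
    b = {_norm(x) for x in list_b}
    if background_n < len(a | b):
        raise ValidationError("background_n smaller than the union of the lists")
    k = len(a & b)
    p = hypergeom_upper_tail(k, background_n, len(a), len(b))
    return OverlapResult(
        background_n=background_n,
        size_a=len(a),
        size_b=len(b),
        overlap=k,
        expected=len(a) * len(b) / background_n,
        p=p,
    )


def overlap_test_counts(
    overlap: int, size_a: int, size_b: int, background_n: int = 20_000
) -> OverlapResult:
    """Overlap test from published counts rather than explicit lists."""
    if overlap > min(size_a, size_b):
        raise ValidationError("overlap exceeds the smaller list")
    return OverlapResult(
        background_n=background_n,
        size_a=size_a,
        size_b=size_b,
        overlap=overlap,
        expected=size_a * size_b / background_n,
        p=hypergeom_upper_tail(overlap, background_n, size_a, size_b),
    )
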