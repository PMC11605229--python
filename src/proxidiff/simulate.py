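"""Synthetic data generators for the two study arms.

``generate_bioid`` emulates a five-condition BioID proximity-labeling
experiment in log2 intensity space.  Each protein belongs to exactly one of
four classes — true proximity interactor, biotin-background binder,
over-expression-responsive, or null — and receives the corresponding
additive effect in the conditions where that effect is physically present:

* biotin background ``b`` in every biotin-treated condition
  (``BAG3_Biotin``, ``BioID``, ``AC16_Biotin``);
* over-expression ``o`` in every bait-transfected condition
  (``BAG3_Biotin``, ``BAG3``);
* true proximity ``t`` only where bait, ligase and biotin coincide
  (``BAG3_Biotin``).

Under this model the triple-contrast corrected effect
``(t + o) - b - (o - b) = t`` is exactly unbiased for the proximity effect,
which downstream tests exploit.  Missingness is intensity-dependent: a cell
drops out with probability ``logistic((lod_threshold - value) /
lod_steepness)``, mimicking the left-censoring of label-free MS.

``generate_expression`` emulates a two-group expression study (modeled on a
myocardium case/control design: 16 controls versus ~86-108 cases) with
planted gene-set mean shifts for the enrichment stage and latent-factor
co-expression modules for the network stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ValidationError

CONDITIONS = ("BAG3_Biotin", "BioID", "BAG3", "AC16_Biotin", "AC16")
BIOTIN_TREATED = frozenset({"BAG3_Biotin", "BioID", "AC16_Biotin"})
BAIT_TRANSFECTED = frozenset({"BAG3_Biotin", "BAG3"})
PROXIMITY = frozenset({"BAG3_Biotin"})

CLASSES = ("interactor", "biotin_background", "oe_responsive", "null")


@dataclass(frozen=True)
class BioIDSimConfig:
    """Parameters of the five-condition BioID simulation (log2 units)."""

    n_proteins: int = 1000
    n_replicates: int = 3
    #: fractions over (interactor, biotin_background, oe_responsive, null)
    class_fractions: tuple[float, float, float, float] = (0.1, 0.2, 0.2, 0.5)
    #: (mu_t, mu_b, mu_o): mean proximity / background / over-expression effect.
    #: Proximity labeling of genuine interactors is strong (~8-fold); biotin
    #: background and over-expression artifacts are modest (~2-fold).
    effect_means_log2: tuple[float, float, float] = (3.0, 1.0, 1.0)
    effect_sd_log2: tuple[float, float, float] = (0.5, 0.5, 0.5)
    baseline_mean: float = 22.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    #: logistic limit-of-detection; None disables missingness
    lod_threshold: float | None = 16.0
    lod_steepness: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        fracs = np.asarray(self.class_fractions, dtype=float)
        if len(fracs) != 4 or (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "class_fractions must be 4 non-negative numbers summing to 1"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if any(sd < 0 for sd in self.effect_sd_log2):
            raise ValidationError("effect_sd_log2 entries must be >= 0")
        if self.lod_steepness <= 0:
            raise ValidationError("lod_steepness must be > 0")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class IntensityTable:
    """Log2 protein intensities plus the sample→condition design.

    ``values``: proteins × samples DataFrame with NaN marking missing cells.
    ``design``: Series mapping each sample id to one of the five conditions.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate protein ids: {', '.join(map(str, dups))}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {', '.join(map(str, dups))}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples absent from design: {', '.join(missing)}")
        bad = sorted(set(self.design) - set(CONDITIONS))
        if bad:
            raise ValidationError(
                f"unknown condition labels: {', '.join(bad)}; "
                f"expected one of {', '.join(CONDITIONS)}"
            )

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        return [s for s in self.values.columns if self.design[s] == condition]

    def to_tsv(self, values_path, design_path, header_lines=()) -> None:
        from . import io

        io.write_matrix(self.values, values_path, header_lines)
        io.write_design(self.design, design_path, header_lines)

    @classmethod
    def from_tsv(cls, values_path, design_path) -> "IntensityTable":
        from . import io

        return cls(io.read_matrix(values_path), io.read_design(design_path))


def _class_counts(n: int, fractions: Sequence[float]) -> np.ndarray:
    counts = np.array([int(round(f * n)) for f in fractions])
    counts[-1] = n - counts[:-1].sum()
    if counts[-1] < 0:
        raise ValidationError("class_fractions round to more proteins than n_proteins")
    return counts


def generate_bioid(config: BioIDSimConfig) -> tuple[IntensityTable, pd.DataFrame]:
    """Simulate a five-condition BioID intensity table with ground truth.

    Returns ``(table, truth)`` where ``truth`` has one row per protein with
    columns ``label`` (protein class) and the realized log2 effects
    ``t``, ``b``, ``o`` (zero outside the protein's own class).
    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    counts = _class_counts(n, config.class_fractions)
    labels = np.repeat(CLASSES, counts)

    mu_t, mu_b, mu_o = config.effect_means_log2
    sd_t, sd_b, sd_o = config.effect_sd_log2
    t = np.zeros(n)
    b = np.zeros(n)
    o = np.zeros(n)
    t[labels == "interactor"] = rng.normal(mu_t, sd_t, counts[0])
    b[labels == "biotin_background"] = rng.normal(mu_b, sd_b, counts[1])
    o[labels == "oe_responsive"] = rng.normal(mu_o, sd_o, counts[2])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)

    samples = [
        f"{cond}_{r}" for cond in CONDITIONS for r in range(1, config.n_replicates + 1)
    ]
    conditions = np.repeat(CONDITIONS, config.n_replicates)
    in_biotin = np.isin(conditions, list(BIOTIN_TREATED)).astype(float)
    in_bait = np.isin(conditions, list(BAIT_TRANSFECTED)).astype(float)
    in_prox = np.isin(conditions, list(PROXIMITY)).astype(float)

    signal = (
        baseline[:, None]
        + np.outer(b, in_biotin)
        + np.outer(o, in_bait)
        + np.outer(t, in_prox)
    )
    values = signal + rng.normal(0.0, config.noise_sd, signal.shape)

    # uniform draws come last so that changing only lod_threshold keeps the
    # stream identical (common random numbers → monotone missingness)
    u = rng.uniform(size=values.shape)
    if config.lod_threshold is not None:
        p_missing = expit((config.lod_threshold - values) / config.lod_steepness)
        values = np.where(u < p_missing, np.nan, values)

    width = len(str(n))
    proteins = pd.Index([f"P{i + 1:0{width}d}" for i in range(n)], name="protein")
    table = IntensityTable(
        values=pd.DataFrame(values, index=proteins, columns=samples),
        design=pd.Series(conditions, index=pd.Index(samples, name="sample"),
                         name="condition"),
    )
    truth = pd.DataFrame({"label": labels, "t": t, "b": b, "o": o}, index=proteins)
    return table, truth


# --------------------------------------------------------------------------
# two-group expression studies


@dataclass(frozen=True)
class PlantedSet:
    """A gene set whose case-group mean is shifted by ``delta`` (log2)."""

    name: str
    gene_indices: tuple[int, ...]
    delta: float


@dataclass(frozen=True)
class ModuleSpec:
    """A latent-factor co-expression module; members load on one factor."""

    gene_indices: tuple[int, ...]
    loading_mean: float = 0.8
    loading_sd: float = 0.1


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 1000
    n_controls: int = 16
    n_cases: int = 86
    planted_sets: tuple[PlantedSet, ...] = ()
    modules: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 3 or self.n_cases < 3:
            raise ValidationError("each phenotype group needs >= 3 samples")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        seen: set[int] = set()
        for module in self.modules:
            idx = set(module.gene_indices)
            if idx & seen:
                raise ValidationError("modules must not share genes")
            seen |= idx
        for group, name in [
            *[(m.gene_indices, "module") for m in self.modules],
            *[(s.gene_indices, s.name) for s in self.planted_sets],
        ]:
            arr = np.asarray(group)
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_genes):
                raise ValidationError(f"{name}: gene index out of range")

    @classmethod
    def with_layout(
        cls,
        n_genes: int,
        *,
        set_sizes: Sequence[tuple[str, int, float]] = (),
        module_sizes: Sequence[int] = (),
        loading_mean: float = 0.8,
        loading_sd: float = 0.1,
        **kwargs,
    ) -> "ExpressionSimConfig":
        """Carve disjoint consecutive index blocks: modules first, then sets."""
        cursor = 0
        modules = []
        for size in module_sizes:
            modules.append(
                ModuleSpec(tuple(range(cursor, cursor + size)), loading_mean, loading_sd)
            )
            cursor += size
        planted = []
        for name, size, delta in set_sizes:
            planted.append(PlantedSet(name, tuple(range(cursor, cursor + size)), delta))
            cursor += size
        if cursor > n_genes:
            raise ValidationError("layout exceeds n_genes")
        return cls(
            n_genes=n_genes,
            planted_sets=tuple(planted),
            modules=tuple(modules),
            **kwargs,
        )

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def generate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a genes × samples expression matrix with planted structure.

    Returns ``(expr, phenotype, truth)``: ``phenotype`` holds the labels
    ``control`` / ``case``; ``truth`` has per-gene ``module`` (0 =
    unassigned), ``loading``, and comma-joined planted-set membership.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_controls + config.n_cases
    samples = [f"ctrl_{i + 1}" for i in range(config.n_controls)] + [
        f"case_{i + 1}" for i in range(config.n_cases)
    ]
    phenotype = pd.Series(
        ["control"] * config.n_controls + ["case"] * config.n_cases,
        index=pd.Index(samples, name="sample"),
        name="phenotype",
    )
    is_case = (phenotype == "case").to_numpy(dtype=float)

    values = np.zeros((config.n_genes, n_samples))
    module_label = np.zeros(config.n_genes, dtype=int)
    loading = np.zeros(config.n_genes)
    for m, module in enumerate(config.modules, start=1):
        factor = rng.normal(size=n_samples)
        idx = np.asarray(module.gene_indices)
        loads = rng.normal(module.loading_mean, module.loading_sd, idx.size)
        values[idx] += np.outer(loads, factor)
        module_label[idx] = m
        loading[idx] = loads

    set_membership = [[] for _ in range(config.n_genes)]
    for planted in config.planted_sets:
        idx = np.asarray(planted.gene_indices)
        values[idx] += planted.delta * is_case[None, :]
        for g in idx:
            set_membership[g].append(planted.name)

    values += rng.normal(0.0, config.noise_sd, values.shape)

    width = len(str(config.n_genes))
    genes = pd.Index(
        [f"G{i + 1:0{width}d}" for i in range(config.n_genes)], name="gene"
    )
    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "module": module_label,
            "loading": loading,
            "planted_sets": [",".join(s) for s in set_membership],
        },
        index=genes,
    )
    return expr, phenotype, truth


def planted_set_collection(config: ExpressionSimConfig) -> dict[str, list[str]]:
    """Gene-symbol membership of the planted sets (for the enrichment stage)."""
    width = len(str(config.n_genes))
    return {
        planted.name: [f"G{i + 1:0{width}d}" for i in planted.gene_indices]
        for planted in config.planted_sets
    }
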