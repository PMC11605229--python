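"""Triple-contrast corrected proximity-interaction effect and interactor calls.

The raw bait-vs-ligase contrast (``BAG3_Biotin`` vs ``BioID``) confounds
true proximity with two artifacts: proteins that stick to biotin itself and
proteins whose abundance rises under bait over-expression.  The corrected
effect subtracts one contrast for each artifact:

    corrected = log2FC(BAG3_Biotin vs BioID)
              - log2FC(AC16_Biotin vs AC16)      # biotin background
              - log2FC(BAG3 vs BioID)            # over-expression

A protein is called an interactor when the main contrast's BH-adjusted
p-value is below ``alpha`` and the corrected effect is positive (the
positivity gate can alternatively be applied to the raw main fold change
via ``positivity="main"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .quantify import contrast, normalize_median
from .simulate import IntensityTable

#: the three contrasts (name, group_a, group_b) of the correction scheme
CONTRAST_SCHEME = (
    ("main", "BAG3_Biotin", "BioID"),
    ("biotin", "AC16_Biotin", "AC16"),
    ("oe", "BAG3", "BioID"),
)


def corrected_effect(fc_main, fc_biotin, fc_oe):
    """``fc_main - fc_biotin - fc_oe`` with finiteness validation.

    Accepts scalars or aligned arrays; a non-finite value raises an error
    naming the offending contrast.
    """
    parts = {"main": fc_main, "biotin": fc_biotin, "oe": fc_oe}
    for name, value in parts.items():
        arr = np.asarray(value, dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError(f"non-finite log2FC in the {name!r} contrast")
    return (
        np.asarray(fc_main, dtype=float)
        - np.asarray(fc_biotin, dtype=float)
        - np.asarray(fc_oe, dtype=float)
    )


def call_interactors(
    main: pd.DataFrame,
    biotin: pd.DataFrame,
    oe: pd.DataFrame,
    *,
    alpha: float = 0.05,
    positivity: str = "corrected",
) -> pd.DataFrame:
    """Join the three contrast tables and call interactors.

    Proteins untestable in the main contrast are never called.  A protein
    untestable in (or absent from) a correction contrast has that term set
    to 0 and is flagged ``correction_imputed``.  Rows are sorted by
    corrected effect descending, ties broken by protein id.
    """
    if positivity not in {"corrected", "main"}:
        raise ValidationError("positivity must be 'corrected' or 'main'")
    universe = main.index
    if len(universe) == 0:
        raise ValidationError("main contrast is empty")
    if len(universe.intersection(biotin.index)) == 0 and len(
        universe.intersection(oe.index)
    ) == 0:
        raise ValidationError("contrast tables share no proteins")

    def correction_term(frame: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        fc = frame["log2fc"].reindex(universe)
        usable = frame["testable"].reindex(universe, fill_value=False).astype(bool)
        imputed = ~usable
        return fc.where(usable, 0.0), imputed

    fc_biotin, imp_biotin = correction_term(biotin)
    fc_oe, imp_oe = correction_term(oe)
    imputed = imp_biotin | imp_oe
    n_imputed = int((imputed & main["testable"]).sum())
    if n_imputed:
        warnings.warn(
            f"{n_imputed} protein(s) missing a correction contrast; "
            "that term treated as 0",
            stacklevel=2,
        )

    fc_main = main["log2fc"]
    effect = fc_main.fillna(0.0) - fc_biotin - fc_oe
    effect = effect.where(main["testable"], np.nan)
    q_main = main["q"]
    gate = effect if positivity == "corrected" else fc_main
    called = main["testable"] & (q_main < alpha) & (gate > 0)

    result = pd.DataFrame(
        {
            "fc_main": fc_main,
            "fc_biotin": fc_biotin,
            "fc_oe": fc_oe,
            "corrected_effect": effect,
            "q_main": q_main,
            "called": called.fillna(False).astype(bool),
            "correction_imputed": imputed,
        },
        index=universe,
    )
    # sort by corrected effect descending; a stable sort on the id-ordered
    # frame breaks ties by protein id, making reruns reproducible
    result = result.sort_index().sort_values(
        "corrected_effect", ascending=False, kind="stable", na_position="last"
    )
    return result


class BioIDInteractionModel:
    """Five-condition BioID differential-interaction model.

    Parameters
    ----------
    table
        :class:`~proxidiff.simulate.IntensityTable` of log2 intensities.
    alpha
        BH-adjusted significance threshold on the main contrast.
    min_obs
        Minimum observed replicates per group for a protein to be testable.
    normalize
        Median-equalize sample columns before contrasting.  Off by default:
        equalize-medians assumes most proteins are unchanged between
        samples, which a bait channel where half the proteome carries
        biotin/over-expression/proximity effects violates — normalization
        would then subtract real signal.  Enable it for real tables whose
        columns carry technical loading shifts.
    positivity
        Which effect the positivity gate applies to: ``"corrected"``
        (default) or ``"main"``.
    """

    def __init__(
        self,
        table: IntensityTable,
        *,
        alpha: float = 0.05,
        min_obs: int = 2,
        normalize: bool = False,
        positivity: str = "corrected",
    ):
        if not isinstance(table, IntensityTable):
            raise ValidationError("table must be an IntensityTable")
        if not 0 < alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.table = table
        self.alpha = alpha
        self.min_obs = min_obs
        self.normalize = normalize
        self.positivity = positivity

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, design: pd.Series, **kwargs):
        return cls(IntensityTable(values=values, design=design), **kwargs)

    def fit(self) -> "InteractionResults":
        table = normalize_median(self.table) if self.normalize else self.table
        contrasts = {
            name: contrast(table, a, b, min_obs=self.min_obs)
            for name, a, b in CONTRAST_SCHEME
        }
        frame = call_interactors(
            contrasts["main"],
            contrasts["biotin"],
            contrasts["oe"],
            alpha=self.alpha,
            positivity=self.positivity,
        )
        return InteractionResults(self, frame, contrasts)


@dataclass
class InteractionResults:
    """Fitted corrected-interaction results.

    ``frame`` holds one row per protein (sorted by corrected effect):
    the three log2 fold changes, the corrected effect, the main contrast's
    BH-adjusted p, and the call flag.
    """

    model: BioIDInteractionModel
    frame: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]

    @property
    def called(self) -> pd.Index:
        return self.frame.index[self.frame["called"]]

    @property
    def n_called(self) -> int:
        return int(self.frame["called"].sum())

    def confusion(self, truth: pd.DataFrame) -> dict[str, float]:
        """Sensitivity/FDR of the calls against simulation ground truth."""
        labels = truth["label"].reindex(self.frame.index)
        called = self.frame["called"]
        true_pos = int((called & (labels == "interactor")).sum())
        n_called = int(called.sum())
        n_interactors = int((labels == "interactor").sum())
        return {
            "n_called": n_called,
            "true_positives": true_pos,
            "sensitivity": true_pos / n_interactors if n_interactors else np.nan,
            "fdr": (n_called - true_pos) / n_called if n_called else 0.0,
        }

    def summary(self, top: int = 10) -> str:
        lines = [
            "BioID corrected-interaction results",
            "===================================",
            f"proteins:            {len(self.frame)}",
            f"testable (main):     {int(self.contrasts['main']['testable'].sum())}",
            f"alpha (BH, main):    {self.model.alpha}",
            f"positivity gate:     {self.model.positivity} effect > 0",
            f"called interactors:  {self.n_called}",
            "",
            f"top {top} by corrected effect:",
            self.frame.head(top).to_string(
                float_format=lambda x: f"{x:.4f}",
                columns=[
                    "fc_main",
                    "fc_biotin",
                    "fc_oe",
                    "corrected_effect",
                    "q_main",
                    "called",
                ],
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, header_lines=()) -> None:
        from . import io

        io.write_matrix(
            self.frame.assign(
                called=self.frame["called"].astype(int),
                correction_imputed=self.frame["correction_imputed"].astype(int),
            ),
            path,
            header_lines,
        )
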