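"""Questionnaire scale scoring.

Turns item-level Likert responses into the seven observed variables used by the
risk model -- positive/negative coping (PC, NC; item means), positive/negative
affect (PA, NA; item sums, optionally z-scored), life satisfaction (LS),
cognitive reappraisal (CR) and expression suppression (ES; item sums) -- plus
the CES-D depression total (sum of 20 items scored 0-3, range 0-60).

Also provides the validity-item ("polygraph") exclusion rule and Cronbach's
alpha for internal-consistency reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError, ValidationError

__all__ = [
    "ScaleDefinition",
    "ReliabilityResult",
    "DEFAULT_SCALES",
    "FEATURE_COLUMNS",
    "score_scales",
    "apply_validity_filter",
    "cronbach_alpha",
]

#: Order of the seven observed variables everywhere in the package.
FEATURE_COLUMNS = ["pc", "nc", "pa", "na", "ls", "cr", "es"]


@dataclass(frozen=True)
class ScaleDefinition:
    """One questionnaire scale and how its subscales are aggregated.

    Parameters
    ----------
    name:
        Scale identifier; item columns are named ``<name>_<item#>`` (1-based).
    n_items:
        Number of items in the scale.
    item_range:
        Inclusive ``(min, max)`` legal integer response.
    subscales:
        Map subscale-name -> ``(item_numbers, aggregation)`` where
        ``aggregation`` is ``"sum"`` or ``"mean"`` and item numbers are
        1-based.
    reverse_items:
        1-based item numbers recoded as ``min + max - value`` before scoring.
    """

    name: str
    n_items: int
    item_range: tuple[int, int]
    subscales: dict[str, tuple[tuple[int, ...], str]]
    reverse_items: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        lo, hi = self.item_range
        if lo >= hi:
            raise ValidationError(f"{self.name}: item_range min must be < max")
        for sub, (items, agg) in self.subscales.items():
            if agg not in ("sum", "mean"):
                raise ValidationError(f"{self.name}/{sub}: unknown aggregation {agg!r}")
            bad = [i for i in items if not 1 <= i <= self.n_items]
            if bad:
                raise ValidationError(f"{self.name}/{sub}: item numbers {bad} out of 1..{self.n_items}")

    def columns(self) -> list[str]:
        return [f"{self.name}_{i}" for i in range(1, self.n_items + 1)]

    def subscale_bounds(self, subscale: str) -> tuple[float, float]:
        """Theoretical (min, max) of a subscale score."""
        items, agg = self.subscales[subscale]
        lo, hi = self.item_range
        if agg == "sum":
            return lo * len(items), hi * len(items)
        return float(lo), float(hi)


# PA/NA assignment: the standard PANAS positive-affect items are
# 1,3,5,9,10,12,14,16,17,19; negative affect is the complement.
_PA_ITEMS = (1, 3, 5, 9, 10, 12, 14, 16, 17, 19)
_NA_ITEMS = tuple(i for i in range(1, 21) if i not in _PA_ITEMS)

DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (
    ScaleDefinition(
        name="ces",
        n_items=20,
        item_range=(0, 3),
        subscales={"ces": (tuple(range(1, 21)), "sum")},
    ),
    ScaleDefinition(
        name="panas",
        n_items=20,
        item_range=(1, 5),
        subscales={"pa": (_PA_ITEMS, "sum"), "na": (_NA_ITEMS, "sum")},
    ),
    ScaleDefinition(
        name="ls",
        n_items=5,
        item_range=(1, 7),
        subscales={"ls": (tuple(range(1, 6)), "sum")},
    ),
    ScaleDefinition(
        name="wcq",
        n_items=20,
        item_range=(0, 3),
        subscales={
            "pc": (tuple(range(1, 13)), "mean"),
            "nc": (tuple(range(13, 21)), "mean"),
        },
    ),
    ScaleDefinition(
        name="erq",
        n_items=10,
        item_range=(1, 7),
        subscales={"cr": ((1, 3, 5, 7, 8, 10), "sum"), "es": ((2, 4, 6, 9), "sum")},
    ),
)


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha for one scale."""

    scale: str
    cronbach_alpha: float
    n_items: int
    n_respondents: int


def _validate_items(items: pd.DataFrame, scale: ScaleDefinition) -> pd.DataFrame:
    cols = scale.columns()
    missing_cols = [c for c in cols if c not in items.columns]
    if missing_cols:
        raise ValidationError(f"scale {scale.name!r}: missing item columns {missing_cols}")
    block = items[cols].astype(float)
    lo, hi = scale.item_range
    values = block.to_numpy()
    finite = np.isfinite(values)
    bad = finite & ((values < lo) | (values > hi) | (values != np.round(values)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        pid = items.index[r] if items.index.name else r
        raise ValidationError(
            f"participant {pid!r}: scale {scale.name!r} item {cols[c]!r} value "
            f"{values[r, c]!r} outside integer range [{lo}, {hi}]"
        )
    return block


def score_scales(
    items: pd.DataFrame,
    defs: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
    panas_zscore: bool = True,
) -> pd.DataFrame:
    """Score item-level responses into subscale scores.

    Parameters
    ----------
    items:
        One row per participant, item columns named ``<scale>_<item#>``.
        A ``participant_id`` column is carried through if present. NaN marks
        a missing item.
    defs:
        Scale definitions; defaults to CES-D / PANAS / life-satisfaction /
        WCQ / ERQ.
    panas_zscore:
        Also attach ``pa_z``/``na_z``, z-scored over rows with complete PANAS
        responses (sample sd, ddof=1).

    Returns
    -------
    DataFrame with one column per subscale plus ``missing_reasons`` (empty
    string, or `;`-separated ``<scale>:missing_items`` codes). Rows with any
    missing item in a scale get NaN for that scale's subscales.
    """
    out = pd.DataFrame(index=items.index)
    if "participant_id" in items.columns:
        out["participant_id"] = items["participant_id"]
    reasons = pd.Series("", index=items.index, dtype=object)
    for scale in defs:
        block = _validate_items(items, scale)
        if scale.reverse_items:
            lo, hi = scale.item_range
            for i in scale.reverse_items:
                col = f"{scale.name}_{i}"
                block[col] = lo + hi - block[col]
        incomplete = block.isna().any(axis=1)
        for sub, (item_nums, agg) in scale.subscales.items():
            cols = [f"{scale.name}_{i}" for i in item_nums]
            score = block[cols].sum(axis=1) if agg == "sum" else block[cols].mean(axis=1)
            score[incomplete] = np.nan
            out[sub] = score
        if incomplete.any():
            reasons[incomplete] += f"{scale.name}:missing_items;"
    out["missing_reasons"] = reasons.str.rstrip(";")
    if panas_zscore and {"pa", "na"} <= set(out.columns):
        for col in ("pa", "na"):
            v = out[col]
            sd = v.std(ddof=1)
            out[f"{col}_z"] = (v - v.mean()) / sd if sd > 0 else np.nan
    return out


def apply_validity_filter(
    responses: pd.DataFrame,
    n_items: int = 10,
    max_mistakes: int = 4,
    mistakes_col: str = "polygraph_mistakes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants failing the validity-item check.

    A participant is excluded when their number of mistakes on the ``n_items``
    validity ("polygraph") items strictly exceeds ``max_mistakes`` (the
    screening rule is "more than 4 of 10").

    Returns ``(retained, report)`` where ``report`` lists the excluded rows
    with their mistake counts.
    """
    counts = responses[mistakes_col].astype(int)
    if ((counts < 0) | (counts > n_items)).any():
        bad = responses.loc[(counts < 0) | (counts > n_items)].index[:5].tolist()
        raise ValidationError(
            f"mistake counts outside [0, {n_items}] at rows {bad}"
        )
    excluded = counts > max_mistakes
    report = responses.loc[excluded, [c for c in (("participant_id", mistakes_col)) if c in responses.columns]].copy()
    report["reason"] = f"mistakes>{max_mistakes}"
    retained = responses.loc[~excluded].copy()
    assert len(retained) + len(report) == len(responses)
    return retained, report


def cronbach_alpha(items: np.ndarray | pd.DataFrame, scale: str = "") -> ReliabilityResult:
    """Cronbach's alpha: ``m/(m-1) * (1 - sum(var_i) / var_total)``.

    Variances are sample variances (ddof=1). Rows with missing values must be
    dropped by the caller.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2:
        raise ValidationError("item matrix must be 2-dimensional")
    n, m = x.shape
    if m < 2 or n < 2:
        raise ValidationError("alpha needs >= 2 items and >= 2 respondents")
    if np.isnan(x).any():
        raise ValidationError("item matrix contains missing values; drop incomplete rows first")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    alpha = m / (m - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(scale=scale, cronbach_alpha=float(alpha), n_items=m, n_respondents=n)
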