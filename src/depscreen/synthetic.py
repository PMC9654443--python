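"""Synthetic cohort generator.

Emulates the statistical structure the screening analysis assumes: each
participant carries a latent mental-pattern state; conditional on the state
the seven observed subscale variables are multivariate Gaussian (in z-units);
and the CES-D total is drawn from a per-state integer interval so that the
low state exclusively occupies low CES values and the high state exclusively
occupies high CES values, with a configurable overlap between adjacent
states. That construction gives exclusive-range recovery a knowable ground
truth, which a Gaussian CES|state model would not.

Optionally the generator inverts the scoring maps to emit item-level Likert
responses consistent with each scale's legal range, so the scoring stage can
be exercised end to end.

Defaults are the package's reference study conditions: n=1128 participants,
three states with weights (0.21, 0.49, 0.30), CES intervals
[0,9]/[8,22]/[21,60] (overlap 2, hence exclusive ground truth [0,7] and
[23,60]), and z-profiles in which the high-risk state is markedly low on both
positive and negative affect relative to the non-risk state while coping,
life satisfaction and emotion-regulation scores barely differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .scoring import DEFAULT_SCALES, FEATURE_COLUMNS, ScaleDefinition

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "RAW_ANCHORS"]

_DEFAULT_WEIGHTS = (0.21, 0.49, 0.30)

# z-profiles per state (rows: nonrisk, medium, risk; columns: FEATURE_COLUMNS
# pc nc pa na ls cr es). Signs follow the reference cohort contrasts: the
# risk state sits well below the non-risk state on both PA and NA while the
# remaining five variables separate only weakly.
_DEFAULT_MEANS = (
    (0.40, 0.30, 1.00, 0.80, 0.10, -0.10, -0.20),
    (-0.10, -0.10, -0.10, 0.10, 0.00, 0.20, 0.20),
    (-0.10, -0.10, -0.80, -0.90, -0.05, -0.10, 0.00),
)

_DEFAULT_INTERVALS = ((0, 9), (8, 22), (21, 60))

#: Raw-scale anchors (mean, sd) used to translate z-unit subscale draws into
#: raw questionnaire totals for item-level generation; taken from published
#: whole-cohort descriptive statistics of an undergraduate sample.
RAW_ANCHORS: dict[str, tuple[float, float]] = {
    "pc": (2.943, 0.50),
    "nc": (2.270, 0.51),
    "pa": (29.016, 7.60),
    "na": (22.879, 7.72),
    "ls": (17.211, 5.74),
    "cr": (22.188, 3.74),
    "es": (11.326, 3.07),
}


def _default_covs(n_states: int, rho: float = 0.15) -> np.ndarray:
    d = len(FEATURE_COLUMNS)
    cov = np.full((d, d), rho) + (1.0 - rho) * np.eye(d)
    return np.broadcast_to(cov, (n_states, d, d)).copy()


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    ``state_means`` are in z-units; ``ces_state_intervals`` are inclusive
    integer intervals within [0, 60] from which each state's CES totals are
    drawn uniformly. ``overlap_width`` documents (and is validated against)
    how far adjacent intervals overlap. ``invalid_rate`` > 0 adds a
    ``polygraph_mistakes`` column with that expected fraction of participants
    failing the validity rule (count > 4 of 10).
    """

    n_participants: int = 1128
    n_states: int = 3
    state_weights: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_WEIGHTS))
    state_means: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_MEANS))
    state_covs: np.ndarray | None = None
    ces_state_intervals: tuple[tuple[int, int], ...] = _DEFAULT_INTERVALS
    overlap_width: int = 2
    item_level: bool = False
    invalid_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_weights = np.asarray(self.state_weights, dtype=float)
        self.state_means = np.asarray(self.state_means, dtype=float)
        if self.state_covs is None:
            self.state_covs = _default_covs(self.n_states)
        self.state_covs = np.asarray(self.state_covs, dtype=float)
        self.validate()

    def validate(self) -> None:
        d = len(FEATURE_COLUMNS)
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if self.n_states <= 0:
            raise ConfigError("n_states must be positive")
        if self.state_weights.shape != (self.n_states,):
            raise ConfigError("state_weights must have length n_states")
        if abs(self.state_weights.sum() - 1.0) > 1e-12 or (self.state_weights < 0).any():
            raise ConfigError("state_weights must be a probability vector summing to 1")
        if self.state_means.shape != (self.n_states, d):
            raise ConfigError(f"state_means must be {self.n_states}x{d}")
        if self.state_covs.shape != (self.n_states, d, d):
            raise ConfigError(f"state_covs must be {self.n_states}x{d}x{d}")
        for k, cov in enumerate(self.state_covs):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ConfigError(f"state_covs[{k}] is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ConfigError(f"state_covs[{k}] is not positive definite")
        if len(self.ces_state_intervals) != self.n_states:
            raise ConfigError("one CES interval per state required")
        for lo, hi in self.ces_state_intervals:
            if not (0 <= lo <= hi <= 60):
                raise ConfigError(f"CES interval [{lo},{hi}] must satisfy 0 <= lo <= hi <= 60")
        for (lo1, hi1), (lo2, hi2) in zip(self.ces_state_intervals, self.ces_state_intervals[1:]):
            got = hi1 - lo2 + 1
            if got != self.overlap_width:
                raise ConfigError(
                    f"adjacent intervals [{lo1},{hi1}] and [{lo2},{hi2}] overlap by "
                    f"{got}, expected overlap_width={self.overlap_width}"
                )
        if not 0.0 <= self.invalid_rate < 1.0:
            raise ConfigError("invalid_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort: latent truth, features, CES totals, optional items."""

    true_states: np.ndarray
    feature_table: pd.DataFrame
    ces_total: np.ndarray
    item_responses: pd.DataFrame | None
    provenance: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        """Participant-level table: participant_id, ces, the 7 features, true_state."""
        df = pd.DataFrame({"participant_id": np.arange(len(self.true_states))})
        df["ces"] = self.ces_total
        for col in FEATURE_COLUMNS:
            df[col] = self.feature_table[col].to_numpy()
        df["true_state"] = self.true_states
        if "polygraph_mistakes" in self.feature_table.columns:
            df["polygraph_mistakes"] = self.feature_table["polygraph_mistakes"].to_numpy()
        return df


def _distribute_total(total: int, n_items: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly spread an integer total over items bounded in [lo, hi].

    Starts at the floor and adds unit increments to uniformly chosen items
    that still have headroom; exact when lo*n <= total <= hi*n.
    """
    total = int(np.clip(total, lo * n_items, hi * n_items))
    values = np.full(n_items, lo, dtype=int)
    remaining = total - lo * n_items
    while remaining > 0:
        open_items = np.flatnonzero(values < hi)
        take = min(remaining, len(open_items))
        chosen = rng.choice(open_items, size=take, replace=False)
        values[chosen] += 1
        remaining -= take
    return values


def _items_for_subscale(
    scale: ScaleDefinition,
    subscale: str,
    target: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    item_nums, agg = scale.subscales[subscale]
    lo, hi = scale.item_range
    total = target * len(item_nums) if agg == "mean" else target
    values = _distribute_total(int(round(total)), len(item_nums), lo, hi, rng)
    return {f"{scale.name}_{i}": int(v) for i, v in zip(item_nums, values)}


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort under the configured latent-state model.

    Deterministic for a fixed seed: a single root ``SeedSequence(seed)`` is
    split into four independent child streams (states, features, CES totals,
    item/validity responses), so enabling item-level output does not perturb
    the participant-level draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_state, rng_feat, rng_ces, rng_items = (np.random.default_rng(s) for s in ss.spawn(4))
    n = config.n_participants

    states = rng_state.choice(config.n_states, size=n, p=config.state_weights)
    features = np.empty((n, len(FEATURE_COLUMNS)))
    for k in range(config.n_states):
        idx = np.flatnonzero(states == k)
        if len(idx):
            features[idx] = rng_feat.multivariate_normal(
                config.state_means[k], config.state_covs[k], size=len(idx), method="cholesky"
            )
    intervals = np.asarray(config.ces_state_intervals)
    ces = rng_ces.integers(intervals[states, 0], intervals[states, 1] + 1)

    feature_table = pd.DataFrame(features, columns=FEATURE_COLUMNS)
    if config.invalid_rate > 0:
        fails = rng_items.random(n) < config.invalid_rate
        mistakes = np.where(
            fails,
            rng_items.integers(5, 11, size=n),
            np.minimum(rng_items.binomial(4, 0.1, size=n), 4),
        )
        feature_table["polygraph_mistakes"] = mistakes

    item_responses = None
    if config.item_level:
        item_responses = _build_item_table(features, ces, rng_items)

    return SyntheticCohort(
        true_states=states,
        feature_table=feature_table,
        ces_total=np.asarray(ces, dtype=int),
        item_responses=item_responses,
        provenance=replace(config),
    )


def _build_item_table(features: np.ndarray, ces: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Invert the scoring maps: raw targets from z-draws, then item spreads."""
    scales = {s.name: s for s in DEFAULT_SCALES}
    rows = []
    for i in range(len(ces)):
        row: dict[str, int] = {"participant_id": i}
        row.update(_items_for_subscale(scales["ces"], "ces", float(ces[i]), rng))
        for j, sub in enumerate(FEATURE_COLUMNS):
            mean, sd = RAW_ANCHORS[sub]
            raw = mean + features[i, j] * sd
            scale = next(s for s in DEFAULT_SCALES if sub in s.subscales)
            lo, hi = scale.subscale_bounds(sub)
            row.update(_items_for_subscale(scale, sub, float(np.clip(raw, lo, hi)), rng))
        rows.append(row)
    return pd.DataFrame(rows)
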