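"""Risk patterning: the screening procedure itself.

Participants are ordered by their CES-D depression total into a
pseudo-sequence (the sorted axis stands in for the progression of depressive
severity), the Gaussian-emission HMM is fitted on the seven standardized
subscale features along that axis, states are decoded and relabelled by the
mean CES of their members (ascending: nonrisk < medium < risk), and each
state's *exclusive covered range* -- the maximal CES intervals occupied by
that state and no other -- is extracted. The inner boundaries of the nonrisk
and risk exclusive ranges are the screening thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hmm
from .exceptions import InsufficientDataError, ValidationError
from .scoring import FEATURE_COLUMNS

__all__ = [
    "SortedSequence",
    "RiskStateMap",
    "RiskModel",
    "build_sequence",
    "fit_risk_states",
    "exclusive_ranges",
    "screen_new",
    "risk_labels",
]


@dataclass
class SortedSequence:
    """Participants sorted by CES (stable, id tie-break) with standardized features."""

    order: np.ndarray  # positions into the original cohort table
    ids: np.ndarray
    observations: np.ndarray  # (T, 7), standardized when requested
    ces_sorted: np.ndarray
    feature_means: np.ndarray  # training standardizer statistics
    feature_sds: np.ndarray
    standardized: bool


@dataclass
class RiskStateMap:
    """State -> risk label map with coverage and exclusive CES ranges."""

    state_labels: dict[int, str]
    state_mean_z: pd.DataFrame  # K x 7, decoded-state means of standardized features
    coverage: dict[int, set[int]]  # CES values attained by each state's members
    exclusive: dict[int, list[tuple[int, int]]]
    group_sizes: dict[int, list[int]]  # participants inside each exclusive range

    def thresholds_table(self) -> pd.DataFrame:
        rows = []
        for k, label in self.state_labels.items():
            ranges = self.exclusive.get(k, [])
            if not ranges:
                rows.append({"state": k, "label": label, "ces_lo": np.nan, "ces_hi": np.nan, "n": 0})
            for (lo, hi), n in zip(ranges, self.group_sizes.get(k, [])):
                rows.append({"state": k, "label": label, "ces_lo": lo, "ces_hi": hi, "n": n})
        return pd.DataFrame(rows)


@dataclass
class RiskModel:
    """Everything needed to screen new respondents."""

    params: hmm.HmmParameters
    path: hmm.StatePath
    risk_map: RiskStateMap
    sequence: SortedSequence
    fit_report: hmm.FitReport


def risk_labels(n_states: int) -> list[str]:
    """Canonical ascending-risk label names for K states."""
    if n_states == 1:
        return ["all"]
    if n_states == 2:
        return ["nonrisk", "risk"]
    if n_states == 3:
        return ["nonrisk", "medium", "risk"]
    return ["nonrisk"] + [f"medium_{i}" for i in range(1, n_states - 1)] + ["risk"]


def build_sequence(
    cohort: pd.DataFrame,
    standardize: bool = True,
    id_col: str = "participant_id",
) -> SortedSequence:
    """Order participants by CES into the pseudo-sequence.

    Stable sort by (CES ascending, participant id ascending). When
    ``standardize`` is on, each of the seven feature columns is z-scored
    (mean 0, sample sd 1) over the included participants.
    """
    needed = ["ces"] + FEATURE_COLUMNS
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if cohort[needed].isna().any().any():
        raise ValidationError("missing values among CES or the 7 features; drop or impute first")
    ids = cohort[id_col].to_numpy() if id_col in cohort.columns else np.arange(len(cohort))
    ces = cohort["ces"].to_numpy()
    if len(cohort) < 2:
        raise InsufficientDataError("need at least 2 complete rows")
    order = np.lexsort((ids, ces))
    X = cohort[FEATURE_COLUMNS].to_numpy(dtype=float)[order]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if standardize:
        if (sds == 0).any():
            raise ValidationError("zero-variance feature column; cannot standardize")
        X = (X - means) / sds
    return SortedSequence(
        order=order,
        ids=ids[order],
        observations=X,
        ces_sorted=ces[order].astype(int),
        feature_means=means,
        feature_sds=sds,
        standardized=standardize,
    )


def exclusive_ranges(
    states: np.ndarray | hmm.StatePath, ces_sorted: np.ndarray
) -> tuple[dict[int, list[tuple[int, int]]], dict[int, list[int]], dict[int, set[int]]]:
    """Maximal CES intervals covered by exactly one decoded state.

    For every CES value present, the set of decoded states among its
    participants is computed; for each state, maximal contiguous runs of
    present values where only that state occurs become exclusive ranges.
    Absent CES values (gaps) are bridged when flanked by exclusive values of
    the same state, so a range like [23, 60] may span unoccupied totals.

    Returns ``(exclusive, group_sizes, coverage)``.
    """
    s = states.states if isinstance(states, hmm.StatePath) else np.asarray(states)
    ces = np.asarray(ces_sorted)
    if len(s) != len(ces):
        raise ValidationError("state path and CES vector lengths differ")
    values = np.unique(ces)
    owners: dict[int, set[int]] = {int(v): set(s[ces == v].tolist()) for v in values}
    coverage: dict[int, set[int]] = {}
    for v, states_at_v in owners.items():
        for k in states_at_v:
            coverage.setdefault(int(k), set()).add(v)

    exclusive: dict[int, list[tuple[int, int]]] = {int(k): [] for k in np.unique(s)}
    group_sizes: dict[int, list[int]] = {int(k): [] for k in np.unique(s)}
    run_state: int | None = None
    run_lo = run_hi = 0
    for v in values:
        sole = next(iter(owners[int(v)])) if len(owners[int(v)]) == 1 else None
        if sole is not None and sole == run_state:
            run_hi = int(v)
        else:
            if run_state is not None:
                exclusive[run_state].append((run_lo, run_hi))
            run_state = int(sole) if sole is not None else None
            run_lo = run_hi = int(v)
    if run_state is not None:
        exclusive[run_state].append((run_lo, run_hi))
    for k, ranges in exclusive.items():
        for lo, hi in ranges:
            group_sizes[k].append(int(((ces >= lo) & (ces <= hi)).sum()))
    return exclusive, group_sizes, coverage


def _risk_map_from_path(
    path: hmm.StatePath, seq: SortedSequence, n_states: int
) -> RiskStateMap:
    s = path.states
    ces = seq.ces_sorted
    mean_ces = np.full(n_states, np.inf)
    for k in range(n_states):
        members = ces[s == k]
        if len(members):
            mean_ces[k] = members.mean()
    # ascending mean CES -> ascending risk; empty states sort last
    occupied = [k for k in range(n_states) if np.isfinite(mean_ces[k])]
    ranking = sorted(occupied, key=lambda k: mean_ces[k])
    labels = risk_labels(len(ranking))
    state_labels = {k: labels[i] for i, k in enumerate(ranking)}
    for k in range(n_states):
        state_labels.setdefault(k, "empty")

    excl, sizes, cov = exclusive_ranges(s, ces)
    z = seq.observations
    rows = {}
    for k in range(n_states):
        members = z[s == k]
        rows[k] = members.mean(axis=0) if len(members) else np.full(z.shape[1], np.nan)
    state_mean_z = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_COLUMNS)
    return RiskStateMap(
        state_labels=state_labels,
        state_mean_z=state_mean_z,
        coverage=cov,
        exclusive=excl,
        group_sizes=sizes,
    )


def fit_risk_states(
    seq: SortedSequence,
    n_states: int = 3,
    decode: str = "gamma_argmax",
    escalate_restarts: int = 30,
    **hmm_config,
) -> RiskModel:
    """Fit the HMM along the sorted axis and extract the risk-state map.

    Decoding defaults to the per-participant posterior argmax
    (``gamma_argmax``); ``decode="viterbi"`` uses the joint MAP path. If the
    decoded path leaves a state empty, the fit is escalated once with
    ``escalate_restarts`` restarts before accepting the degenerate solution
    with a warning.
    """
    if decode not in ("gamma_argmax", "viterbi"):
        raise ValidationError(f"unknown decode method {decode!r}")
    params, report = hmm.fit_em(seq.observations, n_states, **hmm_config)
    path = _decode(params, seq.observations, decode)
    if len(np.unique(path.states)) < n_states:
        warnings.warn("a decoded state is empty; escalating restarts once")
        cfg = dict(hmm_config)
        cfg["n_restarts"] = escalate_restarts
        cfg["seed"] = cfg.get("seed", 0) + 1_000_003
        params2, report2 = hmm.fit_em(seq.observations, n_states, **cfg)
        path2 = _decode(params2, seq.observations, decode)
        if len(np.unique(path2.states)) > len(np.unique(path.states)) or (
            report2.log_likelihood_trace[-1] > report.log_likelihood_trace[-1]
        ):
            params, report, path = params2, report2, path2
    risk_map = _risk_map_from_path(path, seq, n_states)
    return RiskModel(params=params, path=path, risk_map=risk_map, sequence=seq, fit_report=report)


def _decode(params: hmm.HmmParameters, X: np.ndarray, method: str) -> hmm.StatePath:
    if method == "viterbi":
        return hmm.viterbi(params, X)
    return hmm.decode_gamma_argmax(hmm.log_forward_backward(params, X))


def screen_new(model: RiskModel, features: np.ndarray | dict) -> tuple[str, np.ndarray]:
    """Screen one new respondent from their seven subscale scores.

    The feature vector (raw scale if the model was trained standardized) is
    z-scored with the training statistics; the single-observation posterior
    over states under the chain's stationary distribution gives the risk
    label (argmax, ties to the lower state index) and the full posterior.
    """
    if isinstance(features, dict):
        missing = [c for c in FEATURE_COLUMNS if c not in features]
        if missing:
            raise ValidationError(f"missing features {missing}")
        x = np.array([features[c] for c in FEATURE_COLUMNS], dtype=float)
    else:
        x = np.asarray(features, dtype=float).ravel()
    if x.shape != (len(FEATURE_COLUMNS),) or not np.isfinite(x).all():
        raise ValidationError("feature vector must be 7 finite values")
    if model.sequence.standardized:
        x = (x - model.sequence.feature_means) / model.sequence.feature_sds
    params = model.params
    log_w = np.log(params.stationary_distribution() + 1e-300)
    log_b = hmm._log_emission(x[None, :], params.means, params.covariances)[0]
    log_post = log_w + log_b
    log_post -= np.max(log_post)
    post = np.exp(log_post)
    post /= post.sum()
    k = int(np.argmax(post))
    return model.risk_map.state_labels[k], post
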