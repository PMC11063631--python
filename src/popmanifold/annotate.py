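"""Behavioral parameterization of the manifold by mutual information.

Behavioral variables become per-bin label vectors: each of the six
trial-outcome classes marks the 3–6 s window after its cue onsets (binary);
slow continuous covariates (pupil size, cumulative consumed rewards) are
split into eight equal-count bins, evaluated only on task-free time — the
final 3 s of inter-trial intervals following correct rejections — so that
ongoing state rather than trial events drives the comparison.  Association
with the cluster labels (central-cloud sentinel included as a level) is
quantified by mutual information on the joint contingency table, in nats,
with a circular-shift shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinnedSession

TRIAL_OUTCOME_VARIABLES = (
    "reward_hit",
    "reward_miss",
    "aversive_fa",
    "aversive_cr",
    "neutral_fa",
    "neutral_cr",
)
CONTINUOUS_VARIABLES = ("pupil", "cum_reward")

OUTCOME_WINDOW_S = (3.0, 6.0)   # post-cue window isolating the outcome period
ITI_TAIL_S = 3.0                # final seconds of ITI entering continuous masks
N_CONTINUOUS_BINS = 8


@dataclass
class BehaviorLabels:
    variable: str
    labels: np.ndarray        # 0/1 for outcomes; 1..8 for continuous
    valid_mask: np.ndarray    # bins entering the contingency table


def _outcome_labels(session: BinnedSession, variable: str) -> BehaviorLabels:
    T = session.n_bins
    trials = session.trial_table()
    match = trials[trials["trial_class"] == variable]
    if len(match) == 0:
        raise ValueError(f"no trials of class {variable!r}")
    labels = np.zeros(T, dtype=int)
    lo = int(round(OUTCOME_WINDOW_S[0] / session.bin_s))
    hi = int(round(OUTCOME_WINDOW_S[1] / session.bin_s))
    for cue_bin in match["cue_bin"]:
        labels[int(cue_bin) + lo: min(int(cue_bin) + hi, T)] = 1
    return BehaviorLabels(variable, labels, np.ones(T, dtype=bool))


def iti_tail_mask(session: BinnedSession) -> np.ndarray:
    """Final 3 s of inter-trial intervals following correct rejections."""
    T = session.n_bins
    trials = session.trial_table()
    cue_bins = trials["cue_bin"].to_numpy().astype(int)
    mask = np.zeros(T, dtype=bool)
    n_tail = int(round(ITI_TAIL_S / session.bin_s))
    cr_idx = np.flatnonzero(
        trials["trial_class"].isin(["aversive_cr", "neutral_cr"]).to_numpy()
    )
    for i in cr_idx:
        # ITI after trial i ends at the next cue (or the task-epoch end)
        if i + 1 < len(cue_bins):
            end = cue_bins[i + 1]
        else:
            end = T
        mask[max(end - n_tail, 0): end] = True
    return mask


def _continuous_labels(session: BinnedSession, variable: str) -> BehaviorLabels:
    if variable not in session.covariates.columns:
        raise ValueError(f"covariate {variable!r} missing from session")
    values = session.covariates[variable].to_numpy()
    T = session.n_bins
    values = values[:T]
    mask = iti_tail_mask(session)[: len(values)]
    valid_values = values[mask]
    edges = np.quantile(valid_values, np.linspace(0, 1, N_CONTINUOUS_BINS + 1))
    if np.unique(edges).size < 2:
        raise ValueError(
            f"covariate {variable!r} is constant on the valid mask; octiles undefined"
        )
    labels = np.zeros(len(values), dtype=int)
    binned = np.clip(
        np.searchsorted(edges[1:-1], valid_values, side="right") + 1,
        1,
        N_CONTINUOUS_BINS,
    )
    labels[mask] = binned
    full_mask = np.zeros(T, dtype=bool)
    full_mask[: len(values)] = mask
    full_labels = np.zeros(T, dtype=int)
    full_labels[: len(values)] = labels
    return BehaviorLabels(variable, full_labels, full_mask)


def build_labels(session: BinnedSession, variable: str) -> BehaviorLabels:
    """Per-bin label vector for one behavioral variable."""
    if variable in TRIAL_OUTCOME_VARIABLES:
        return _outcome_labels(session, variable)
    if variable in CONTINUOUS_VARIABLES:
        return _continuous_labels(session, variable)
    raise ValueError(f"unknown behavioral variable {variable!r}")


# ------------------------------------------------------- mutual information

@dataclass
class MIResult:
    mi: float
    contingency: np.ndarray
    null: np.ndarray
    p: float


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xv.size, yv.size))
    np.add.at(table, (xi, yi), 1.0)
    return table


def mutual_information_table(table: np.ndarray) -> float:
    """MI in nats from a joint count table (0·log 0 treated as 0)."""
    p = table / table.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def mutual_information(
    cluster_labels: np.ndarray, behavior: BehaviorLabels
) -> float:
    """MI between per-bin cluster labels (sentinel included) and behavior."""
    cluster_labels = np.asarray(cluster_labels)
    mask = behavior.valid_mask
    if cluster_labels.shape[0] != mask.shape[0]:
        raise ValueError("cluster labels and behavior labels differ in length")
    if mask.sum() < 10:
        raise ValueError("fewer than 10 valid bins in the overlap")
    return mutual_information_table(
        _contingency(cluster_labels[mask], behavior.labels[mask])
    )


def mi_shuffle_test(
    cluster_labels: np.ndarray,
    behavior: BehaviorLabels,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> MIResult:
    """Circular-shift shuffle null for the cluster–behavior MI.

    Behavior labels restricted to the valid mask are circularly shifted by a
    random offset per shuffle, preserving their autocorrelation; the p-value
    is the fraction of null MI values at or above the observed one.
    """
    if n_shuffle < 100:
        raise ValueError("n_shuffle must be >= 100")
    cluster_labels = np.asarray(cluster_labels)
    mask = behavior.valid_mask
    c = cluster_labels[mask]
    b = behavior.labels[mask]
    obs = mutual_information_table(_contingency(c, b))
    rng = np.random.default_rng(seed)
    n = b.size
    null = np.empty(n_shuffle)
    for s in range(n_shuffle):
        shift = int(rng.integers(1, n))
        null[s] = mutual_information_table(_contingency(c, np.roll(b, shift)))
    p = float(np.mean(null >= obs))
    return MIResult(
        mi=obs, contingency=_contingency(c, b), null=null, p=p
    )
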