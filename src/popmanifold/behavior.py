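"""Lick-train analysis around the go/no-go task.

Anticipatory-lick onsets are detected per trial as the first pair of licks
after cue onset whose inter-lick interval falls below the session threshold
1/(μ + C·σ) seconds, where μ and σ are the mean and SD across trials of the
per-trial lick rate in the first 0.5 s of cue presentation and C is 0.1 for
water sessions, 0.35 for food sessions.  The cluster-sequence onset on
rewarded trials is the first central-cloud → cluster transition into
whichever of the two most response-window-occupying clusters correlates best
with the lick onsets.  Lick patterns are compared after a forward 100-frame
sliding mean (~3.3 s at 31 Hz), and free-consumption epochs yield
pseudo-trials anchored at lick-bout onsets for task/free comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .dynamics import TrialMatrix

LICK_RATE_CONSTANT = {"water": 0.1, "food": 0.35}
CUE_RATE_WINDOW_S = 0.5       # first 15 frames of cue presentation
RESPONSE_WINDOW_S = 4.0       # cue onset to end of the response period
SMOOTH_FRAMES = 100


@dataclass
class LickOnsetParams:
    mu: float                 # mean cue-period lick rate (licks/s)
    sigma: float              # SD of cue-period lick rate (licks/s)
    C: float
    threshold_s: float

    @classmethod
    def from_trials(
        cls, trial_lick_times: list[np.ndarray], cue_times: np.ndarray, C: float
    ) -> "LickOnsetParams":
        """Per-trial lick rates over the first 0.5 s of cue, across all trials."""
        rates = []
        for licks, cue in zip(trial_lick_times, cue_times):
            licks = np.asarray(licks)
            n = np.sum((licks >= cue) & (licks < cue + CUE_RATE_WINDOW_S))
            rates.append(n / CUE_RATE_WINDOW_S)
        rates = np.asarray(rates, dtype=float)
        mu = float(rates.mean())
        sigma = float(rates.std())
        denom = mu + C * sigma
        if denom <= 0:
            raise ValueError("no cue-period licks anywhere; threshold undefined")
        return cls(mu=mu, sigma=sigma, C=C, threshold_s=1.0 / denom)


def detect_lick_onset(
    lick_times: np.ndarray,
    cue_time: float,
    params: LickOnsetParams,
    response_window_s: float = RESPONSE_WINDOW_S,
) -> float | None:
    """Onset of the first licking bout in the response window, or None.

    A bout starts at the first lick pair after cue onset whose inter-lick
    interval is below ``params.threshold_s``; the onset is the time of the
    first lick of that pair and must fall within the response window.
    """
    licks = np.sort(np.asarray(lick_times, dtype=float))
    licks = licks[(licks >= cue_time) & (licks < cue_time + response_window_s + 1.0)]
    if licks.size < 2:
        return None
    intervals = np.diff(licks)
    for i, ili in enumerate(intervals):
        if ili < params.threshold_s:
            onset = licks[i]
            if onset < cue_time + response_window_s:
                return float(onset)
            return None
    return None


def session_lick_onsets(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    reward_type: str = "water",
    response_window_s: float = RESPONSE_WINDOW_S,
) -> tuple[np.ndarray, LickOnsetParams]:
    """Per-trial anticipatory-lick onsets (NaN where none detected)."""
    licks = events.loc[events["event"] == "lick", "time_s"].to_numpy()
    cue_times = trials["cue_time_s"].to_numpy()
    per_trial = [
        licks[(licks >= c) & (licks < c + response_window_s + 2.0)]
        for c in cue_times
    ]
    C = LICK_RATE_CONSTANT[reward_type]
    params = LickOnsetParams.from_trials(per_trial, cue_times, C)
    onsets = np.full(len(cue_times), np.nan)
    for i, (lt, c) in enumerate(zip(per_trial, cue_times)):
        onset = detect_lick_onset(lt, c, params, response_window_s)
        if onset is not None:
            onsets[i] = onset
    return onsets, params


# ------------------------------------------------------------ cluster onset

def detect_cluster_onset(
    tm: TrialMatrix,
    lick_onsets: np.ndarray,
    cue_times: np.ndarray,
    bin_s: float,
    response_window_bins: tuple[int, int] = (4, 8),
) -> tuple[np.ndarray, int]:
    """Per-trial cluster-sequence onsets and the chosen cluster.

    Candidates are the two clusters with highest occupancy in the response
    window (bins after cue onset, default the 2 s after cue offset).  For
    each candidate the per-trial onset is the first sentinel→candidate
    transition; the candidate whose onsets correlate best (Pearson) with the
    lick onsets is chosen.  Trials without such a transition get NaN.
    """
    seqs = tm.sequences
    lo, hi = response_window_bins
    window = seqs[:, lo:hi]
    vals, counts = np.unique(window[window > 0], return_counts=True)
    if vals.size == 0:
        raise ValueError("no cluster occupancy in the response window")
    candidates = vals[np.argsort(counts)[::-1][:2]].tolist()

    def onsets_for(cand: int) -> np.ndarray:
        out = np.full(seqs.shape[0], np.nan)
        for t in range(seqs.shape[0]):
            row = seqs[t]
            hits = np.flatnonzero((row[1:] == cand) & (row[:-1] == -1)) + 1
            if hits.size:
                # bin centers: the transition happened somewhere inside the
                # bin, so the center is the unbiased time estimate
                out[t] = cue_times[t] + (hits[0] + 0.5) * bin_s
        return out

    if len(candidates) == 1:
        return onsets_for(candidates[0]), int(candidates[0])

    best, best_r = None, -np.inf
    for cand in candidates:
        ons = onsets_for(cand)
        ok = ~np.isnan(ons) & ~np.isnan(lick_onsets)
        if ok.sum() < 3 or np.std(ons[ok]) == 0 or np.std(lick_onsets[ok]) == 0:
            r = -np.inf
        else:
            r = pearsonr(ons[ok], lick_onsets[ok]).statistic
        if r > best_r:
            best, best_r = cand, r
    if best is None:
        # correlations undefined for both candidates (too few paired onsets);
        # fall back to the higher-occupancy candidate
        best = candidates[0]
    return onsets_for(best), int(best)


# ---------------------------------------------------------- lick similarity

def smooth_licks(binary: np.ndarray, window: int = SMOOTH_FRAMES) -> np.ndarray:
    """Forward sliding mean with fixed 1/window divisor, truncated at the end."""
    binary = np.asarray(binary, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(binary)])
    n = binary.size
    ends = np.minimum(np.arange(n) + window, n)
    return (csum[ends] - csum[:-1]) / window


def lick_similarity(
    a: np.ndarray, b: np.ndarray, eps: float = 1e-6, window: int = SMOOTH_FRAMES
) -> float:
    """1/(ε + ‖SL_a − SL_b‖₂) on smoothed binary lick patterns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("lick patterns differ in length")
    sa, sb = smooth_licks(a, window), smooth_licks(b, window)
    return float(1.0 / (eps + np.linalg.norm(sa - sb)))


# ----------------------------------------------------------- pseudo-trials

@dataclass
class PseudoTrials:
    onsets_s: np.ndarray           # second lick of each qualifying pair
    windows_s: np.ndarray          # (start, end) per pseudo-trial
    gap_used_s: float
    label_sequences: np.ndarray | None = None
    lick_patterns: np.ndarray | None = None


def build_pseudo_trials(
    lick_times: np.ndarray,
    epoch: tuple[float, float],
    gap_s: float = 1.0,
    fallback_gap_s: float = 0.5,
    min_count: int = 5,
    pre_s: float = 2.0,
    post_s: float = 4.0,
    labels: np.ndarray | None = None,
    bin_s: float | None = None,
    frame_hz: float | None = None,
) -> PseudoTrials:
    """Pseudo-trials anchored at free-consumption lick-bout onsets.

    Bout onsets are the second lick of consecutive pairs separated by more
    than ``gap_s`` (falling back to ``fallback_gap_s`` when fewer than
    ``min_count`` result); each window spans [onset − 2 s, onset + 4 s) and
    overlapping windows are removed greedily in time order.
    """
    licks = np.sort(np.asarray(lick_times, dtype=float))
    licks = licks[(licks >= epoch[0]) & (licks < epoch[1])]
    if licks.size < 2:
        raise ValueError("free-consumption epoch contains fewer than 2 licks")

    def candidates(gap: float) -> np.ndarray:
        gaps = np.diff(licks)
        return licks[1:][gaps > gap]

    gap_used = gap_s
    cands = candidates(gap_s)
    if cands.size < min_count:
        gap_used = fallback_gap_s
        cands = candidates(fallback_gap_s)
    if cands.size == 0:
        raise ValueError("no pseudo-trial candidates at either gap threshold")

    kept, last_end = [], -np.inf
    for onset in cands:
        start, end = onset - pre_s, onset + post_s
        if start >= last_end and start >= epoch[0] and end <= epoch[1]:
            kept.append(onset)
            last_end = end
    onsets = np.asarray(kept)
    windows = np.column_stack([onsets - pre_s, onsets + post_s])

    label_seqs = None
    patterns = None
    if labels is not None and bin_s is not None:
        n_bins = int(round((pre_s + post_s) / bin_s))
        rows = []
        for start, _ in windows:
            b0 = int(np.floor(start / bin_s))
            if b0 >= 0 and b0 + n_bins <= labels.shape[0]:
                rows.append(labels[b0: b0 + n_bins])
        label_seqs = np.asarray(rows) if rows else None
    if frame_hz is not None:
        n_frames = int(round((pre_s + post_s) * frame_hz))
        patterns = np.zeros((onsets.size, n_frames))
        for i, (start, _) in enumerate(windows):
            rel = licks - start
            frames = np.round(rel * frame_hz).astype(int)
            frames = frames[(frames >= 0) & (frames < n_frames)]
            patterns[i, frames] = 1.0
    return PseudoTrials(
        onsets_s=onsets,
        windows_s=windows,
        gap_used_s=gap_used,
        label_sequences=label_seqs,
        lick_patterns=patterns,
    )


def rate_matched_selection(
    task_rates: np.ndarray, pseudo_rates: np.ndarray
) -> np.ndarray:
    """Pseudo-trial indices whose first-2 s lick rate lies within μ ± σ of the task's."""
    task_rates = np.asarray(task_rates, dtype=float)
    pseudo_rates = np.asarray(pseudo_rates, dtype=float)
    if task_rates.size == 0 or pseudo_rates.size == 0:
        raise ValueError("both rate sets must be nonempty")
    mu, sd = task_rates.mean(), task_rates.std()
    keep = np.flatnonzero((pseudo_rates >= mu - sd) & (pseudo_rates <= mu + sd))
    if keep.size == 0:
        import warnings

        warnings.warn("no pseudo-trials within the task lick-rate band")
    return keep


def first2s_lick_rate(
    lick_times: np.ndarray, onsets: np.ndarray, window_s: float = 2.0
) -> np.ndarray:
    """Mean lick rate (licks/s) in the first 2 s after each onset."""
    licks = np.asarray(lick_times)
    return np.asarray(
        [
            np.sum((licks >= o) & (licks < o + window_s)) / window_s
            for o in np.asarray(onsets)
        ]
    )
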