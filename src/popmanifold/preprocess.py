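"""Session containers and preprocessing of ΔF/F traces.

Raw sessions hold neuron × frame ΔF/F traces acquired at ~31 Hz together with
behavioral event and covariate tables.  Downstream analyses all operate on the
:class:`BinnedSession`: traces down-sampled by averaging consecutive frames
into ~0.5 s bins, outlier neurons removed, and each neuron z-scored (optionally
per acquisition run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: max-ΔF/F outlier thresholds (percent) per microscope tag
MICROSCOPE_THRESHOLDS = {"A": 2000.0, "B": 5000.0}

DEFAULT_FRAMES_PER_BIN = 15


@dataclass
class Session:
    """One imaging day: ΔF/F traces plus behavior.

    Attributes
    ----------
    dff : ndarray, shape (n_neurons, n_frames)
        ΔF/F traces (percent), 31 Hz.
    frame_hz : float
        Acquisition rate.
    run_bounds : list of (int, int)
        Half-open frame intervals partitioning the frame axis into runs.
    events : DataFrame
        Columns ``time_s``, ``event`` (cue_on | lick | reward | epoch_start |
        epoch_end), ``cue_type`` (reward | aversive | neutral | ""),
        ``responded`` (bool).
    covariates : DataFrame
        Columns ``time_s``, ``pupil``, ``cum_reward`` (one row per bin).
    microscope_id : str
        Selects the outlier threshold (see :data:`MICROSCOPE_THRESHOLDS`).
    reward_type : str
        "water" or "food"; selects the lick-bout constant downstream.
    """

    dff: np.ndarray
    frame_hz: float = 31.0
    run_bounds: list[tuple[int, int]] = field(default_factory=list)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    microscope_id: str = "A"
    reward_type: str = "water"

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff)
        if self.dff.ndim != 2:
            raise ValueError("dff must be neuron × frame (2-D)")
        if not self.run_bounds:
            self.run_bounds = [(0, self.dff.shape[1])]
        self._check_run_bounds()

    def _check_run_bounds(self) -> None:
        n_frames = self.dff.shape[1]
        bounds = sorted(self.run_bounds)
        prev_end = 0
        for start, end in bounds:
            if start != prev_end or end <= start:
                raise ValueError(
                    f"run_bounds {self.run_bounds} do not partition [0, {n_frames})"
                )
            prev_end = end
        if prev_end != n_frames:
            raise ValueError("run_bounds do not cover all frames")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_hz


@dataclass
class BinnedSession:
    """Z-scored neuron × time-bin matrix with bin-aligned behavior."""

    z: np.ndarray
    bin_s: float
    kept_neurons: np.ndarray
    bin_events: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    run_bin_bounds: list[tuple[int, int]] = field(default_factory=list)
    per_run_zscore: bool = False
    frame_hz: float = 31.0
    reward_type: str = "water"

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]

    def trial_table(self) -> pd.DataFrame:
        """Per-trial class / cue-time / cue-bin table derived from cue events."""
        cues = self.bin_events[self.bin_events["event"] == "cue_on"]
        classes = []
        for _, row in cues.iterrows():
            resp = "fa" if row["responded"] else "cr"
            if row["cue_type"] == "reward":
                resp = "hit" if row["responded"] else "miss"
            classes.append(f"{row['cue_type']}_{resp}")
        return pd.DataFrame(
            {
                "trial_class": classes,
                "cue_time_s": cues["time_s"].to_numpy(),
                "cue_bin": cues["bin"].to_numpy(),
            }
        ).reset_index(drop=True)


def bin_traces(dff: np.ndarray, frames_per_bin: int = DEFAULT_FRAMES_PER_BIN) -> np.ndarray:
    """Average every ``frames_per_bin`` consecutive frames; drop the partial tail.

    With 15 frames at 31 Hz each bin spans ~0.5 s.
    """
    if frames_per_bin < 1:
        raise ValueError("frames_per_bin must be >= 1")
    dff = np.asarray(dff)
    n_frames = dff.shape[-1]
    n_bins = n_frames // frames_per_bin
    if n_bins == 0:
        raise ValueError(
            f"fewer frames ({n_frames}) than one bin ({frames_per_bin} frames)"
        )
    trimmed = dff[..., : n_bins * frames_per_bin]
    return trimmed.reshape(*dff.shape[:-1], n_bins, frames_per_bin).mean(
        axis=-1, dtype=np.float64
    )


def exclude_outlier_neurons(dff: np.ndarray, threshold_pct: float) -> np.ndarray:
    """Indices of neurons whose maximum ΔF/F stays at or below ``threshold_pct``.

    Abnormally high transients indicate segmentation or neuropil artifacts;
    the threshold is calibrated per microscope (2000% / 5000%).
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    dff = np.asarray(dff)
    kept = np.flatnonzero(dff.max(axis=1) <= threshold_pct)
    if kept.size == 0:
        raise ValueError("all neurons excluded as outliers; empty dataset")
    return kept


def zscore(binned: np.ndarray, spans: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Z-score each neuron within each span (population SD, divisor n).

    ``spans`` are half-open bin intervals; default is one span covering the
    whole matrix.  A zero-variance neuron within a span is an error (its
    z-score is undefined), reported by neuron index.
    """
    binned = np.asarray(binned, dtype=float)
    if spans is None:
        spans = [(0, binned.shape[1])]
    out = np.empty_like(binned)
    for start, end in spans:
        if end - start < 2:
            raise ValueError(f"span ({start}, {end}) has fewer than 2 bins")
        block = binned[:, start:end]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)  # population SD
        flat = np.flatnonzero(sd.ravel() == 0)
        if flat.size:
            raise ValueError(
                f"zero-variance neuron(s) {flat.tolist()} in span ({start}, {end})"
            )
        out[:, start:end] = (block - mu) / sd
    return out


def preprocess_session(
    session: Session,
    frames_per_bin: int = DEFAULT_FRAMES_PER_BIN,
    per_run_zscore: bool = False,
    threshold_pct: float | None = None,
) -> BinnedSession:
    """Full preprocessing: outlier exclusion → binning → z-scoring.

    Outlier exclusion is applied to the raw frame-resolution traces.  Event
    times are re-indexed to bins as ``floor(time_s / bin_s)``.
    """
    if threshold_pct is None:
        threshold_pct = MICROSCOPE_THRESHOLDS.get(session.microscope_id, 2000.0)
    kept = exclude_outlier_neurons(session.dff, threshold_pct)
    binned = bin_traces(session.dff[kept], frames_per_bin)
    bin_s = frames_per_bin / session.frame_hz

    run_bin_bounds = []
    for start, end in session.run_bounds:
        b0, b1 = start // frames_per_bin, end // frames_per_bin
        b1 = min(b1, binned.shape[1])
        if b1 > b0:
            run_bin_bounds.append((b0, b1))
    # guard against truncation gaps at run edges
    run_bin_bounds = _repartition(run_bin_bounds, binned.shape[1])

    spans = run_bin_bounds if per_run_zscore else None
    z = zscore(binned, spans)

    bin_events = session.events.copy()
    if len(bin_events):
        bin_events["bin"] = np.floor(bin_events["time_s"].to_numpy() / bin_s).astype(int)
    else:
        bin_events["bin"] = pd.Series(dtype=int)

    covariates = session.covariates.copy()
    if len(covariates):
        covariates = covariates.iloc[: binned.shape[1]].reset_index(drop=True)

    return BinnedSession(
        z=z,
        bin_s=bin_s,
        kept_neurons=kept,
        bin_events=bin_events,
        covariates=covariates,
        run_bin_bounds=run_bin_bounds,
        per_run_zscore=per_run_zscore,
        frame_hz=session.frame_hz,
        reward_type=session.reward_type,
    )


def _repartition(bounds: list[tuple[int, int]], n_bins: int) -> list[tuple[int, int]]:
    """Force bin-level run bounds into a clean partition of [0, n_bins)."""
    if not bounds:
        return [(0, n_bins)]
    fixed = []
    prev = 0
    for i, (b0, b1) in enumerate(sorted(bounds)):
        b0 = prev
        if i == len(bounds) - 1:
            b1 = n_bins
        fixed.append((b0, b1))
        prev = b1
    return [(a, b) for a, b in fixed if b > a]
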