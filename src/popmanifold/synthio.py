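"""Synthetic go/no-go imaging sessions with known latent structure.

The generator emulates the statistical structure the manifold analysis
assumes: multi-neuron ΔF/F traces driven by a discrete latent state process
with one central state (0) and seven peripheral states (1..7); six
trial-outcome classes of a go/no-go task (reward hit/miss, aversive and
neutral false-alarm/correct-rejection); a stereotyped 2–3-state sequence on
rewarded trials whose onset lags anticipatory-lick onset by ~1 s; slow
population drift tracking cumulative rewards; a pupil-like slow covariate
that modulates which peripheral states background excursions visit; and an
optional free-consumption epoch of lick bouts.

Every random draw is controlled by ``SimConfig.seed`` (byte-identical output
for a fixed seed).  Geometric fixtures (``generate_geometry``) provide point
sets with analytically known dimension/topology for the estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import Session

N_STATES = 8  # 0 = central cloud, 1..7 = peripheral clusters
BINS_PER_TRIAL = 24
CUE_BIN_IN_TRIAL = 4

TRIAL_CLASSES = (
    "reward_hit",
    "reward_miss",
    "aversive_fa",
    "aversive_cr",
    "neutral_fa",
    "neutral_cr",
)


@dataclass
class SimConfig:
    """Parameters of one synthetic session.

    Notes on defaults: 50 trials per class × 6 classes × 24 bins/trial plus a
    2-minute free-consumption epoch gives ~7,450 half-second bins, matching a
    typical multi-run imaging day; ``noise_sd`` is in the same (z-like) units
    as the state loading patterns, whose entries are ~N(0, 1).
    """

    n_neurons: int = 200
    n_trials_per_class: int = 50
    bin_s: float = 0.5          # nominal; actual width is frames_per_bin / frame_hz
    frame_hz: float = 31.0
    frames_per_bin: int = 15
    noise_sd: float = 1.0
    seed: int = 0
    reward_state_sequence: tuple[int, ...] = (3, 5, 2)
    free_epoch: bool = True
    free_duration_s: float = 120.0
    free_state_sequence: tuple[int, ...] = (6, 4)
    # latent dynamics
    excursion_prob: float = 0.18     # per central bin, background excursion start
    chain_prob: float = 0.35         # chance an excursion chains to the next state
    onset_lag_mean_s: float = 1.0    # cluster-sequence onset lag after lick onset
    onset_lag_sd_s: float = 0.15
    # behavior
    baseline_lick_hz: float = 0.2
    burst_lick_hz: float = 8.0
    # couplings
    drift_gain: float = 0.5          # satiety drift amplitude (z-units)
    pupil_state_beta: float = 0.8    # pupil modulation of excursion targets
    reward_type: str = "water"

    def validate(self) -> None:
        if self.n_neurons <= 0 or self.n_trials_per_class <= 0:
            raise ValueError("n_neurons and n_trials_per_class must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (2 <= len(self.reward_state_sequence) <= 3):
            raise ValueError("reward_state_sequence must list 2-3 cluster ids")
        for s in self.reward_state_sequence + self.free_state_sequence:
            if not (1 <= s <= 7):
                raise ValueError("state ids must lie in 1..7")


@dataclass
class GroundTruth:
    """Latent variables behind one emitted session."""

    state_sequence: np.ndarray          # per-bin latent state id
    loading_matrix: np.ndarray          # neuron × state mean activity
    lick_onsets: np.ndarray             # per-trial anticipatory onset (s; NaN if none)
    cluster_onsets: np.ndarray          # per-trial latent sequence onset (s; NaN)
    trials: pd.DataFrame                # trial_class, cue_time_s, cue_bin
    label_permutation: np.ndarray = field(
        default_factory=lambda: np.arange(N_STATES)
    )

    def transition_counts(self) -> np.ndarray:
        """8 × 8 transition counts of the latent state sequence."""
        seq = self.state_sequence
        counts = np.zeros((N_STATES, N_STATES))
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
        return counts


def _dwell_continue_prob(state: int) -> float:
    # distinct per-state dwell probabilities give each cluster a unique
    # transition-matrix diagonal, which the cross-session alignment exploits
    return 0.30 + 0.07 * (state - 1)


def _draw_latents(config: SimConfig, rng: np.random.Generator) -> dict:
    bin_s = config.frames_per_bin / config.frame_hz
    n_trials = config.n_trials_per_class * len(TRIAL_CLASSES)
    classes = np.repeat(TRIAL_CLASSES, config.n_trials_per_class)
    rng.shuffle(classes)

    n_task_bins = n_trials * BINS_PER_TRIAL
    n_free_bins = int(config.free_duration_s / bin_s) if config.free_epoch else 0
    n_bins = n_task_bins + n_free_bins

    # slow pupil latent: AR(1), standardized afterwards
    pupil = np.empty(n_bins)
    x = 0.0
    for t in range(n_bins):
        x = 0.98 * x + rng.normal(0.0, 0.2)
        pupil[t] = x
    pupil_z = (pupil - pupil.mean()) / (pupil.std() + 1e-12)

    states = np.zeros(n_bins, dtype=np.int64)

    def run_excursion(t: int, stop: int) -> int:
        """Background excursion starting at bin t; returns next free bin."""
        state = _pick_target(rng, pupil_z[t], config.pupil_state_beta)
        while t < stop:
            states[t] = state
            t += 1
            if rng.random() >= _dwell_continue_prob(state):
                if state != 0 and rng.random() < config.chain_prob:
                    state = state % 7 + 1
                else:
                    return t
        return t

    # background dynamics over the whole session (overwritten by trial motifs)
    t = 0
    while t < n_bins:
        if rng.random() < config.excursion_prob:
            t = run_excursion(t, n_bins)
        else:
            states[t] = 0
            t += 1

    trials = pd.DataFrame(
        {
            "trial_class": classes,
            "cue_bin": np.arange(n_trials) * BINS_PER_TRIAL + CUE_BIN_IN_TRIAL,
        }
    )
    trials["cue_time_s"] = trials["cue_bin"] * bin_s

    lick_onsets = np.full(n_trials, np.nan)
    cluster_onsets = np.full(n_trials, np.nan)
    lick_frames: list[int] = []
    reward_times = np.full(n_trials, np.nan)

    frames_per_bin = config.frames_per_bin
    n_frames = n_bins * frames_per_bin
    p_base = config.baseline_lick_hz / config.frame_hz
    p_burst = config.burst_lick_hz / config.frame_hz

    # baseline licking everywhere
    base_licks = np.flatnonzero(rng.random(n_frames) < p_base)
    burst_windows: list[tuple[float, float]] = []

    for i, row in trials.iterrows():
        cue_t = row["cue_time_s"]
        cls = row["trial_class"]
        responded = cls in ("reward_hit", "aversive_fa", "neutral_fa")
        if not responded:
            continue
        u = cue_t + rng.uniform(0.2, 1.8)  # anticipatory lick onset
        lick_onsets[i] = u
        if cls == "reward_hit":
            reward_t = max(u, cue_t + 2.0)  # first response-window lick triggers it
            reward_times[i] = reward_t
            burst_end = reward_t + 3.0
            # stereotyped cluster sequence, onset lagging the lick onset
            lag = np.clip(
                rng.normal(config.onset_lag_mean_s, config.onset_lag_sd_s), 0.4, 1.6
            )
            onset_t = u + lag
            cluster_onsets[i] = onset_t
            _write_sequence(
                states,
                start_bin=int(onset_t / bin_s),
                stop_bin=min((i + 1) * BINS_PER_TRIAL + CUE_BIN_IN_TRIAL - 2, n_bins),
                path=_back_and_forth(config.reward_state_sequence),
                rng=rng,
            )
        elif cls == "aversive_fa":
            burst_end = u + 1.0
        else:
            burst_end = u + 2.0
        burst_windows.append((u, burst_end))

    # free-consumption epoch: lick bouts separated by >1 s gaps
    free_start_s = n_task_bins * bin_s
    bout_onsets = []
    if config.free_epoch:
        t_s = free_start_s + rng.uniform(2.0, 4.0)
        end_s = n_bins * bin_s - 4.0
        while t_s < end_s:
            dur = rng.uniform(1.5, 3.0)
            bout_onsets.append(t_s)
            burst_windows.append((t_s, t_s + dur))
            _write_sequence(
                states,
                start_bin=int(t_s / bin_s),
                stop_bin=min(int((t_s + dur) / bin_s) + 1, n_bins),
                path=_back_and_forth(config.free_state_sequence),
                rng=rng,
            )
            t_s += dur + rng.uniform(2.0, 5.0)

    burst_licks = []
    for start_s, end_s in burst_windows:
        f0 = int(round(start_s * config.frame_hz))
        f1 = min(int(round(end_s * config.frame_hz)), n_frames)
        if f0 >= n_frames:
            continue
        frames = f0 + np.flatnonzero(rng.random(f1 - f0) < p_burst)
        burst_licks.append(np.concatenate(([f0], frames)))  # guarantee onset lick
    all_licks = np.unique(
        np.concatenate([base_licks] + burst_licks) if burst_licks else base_licks
    )

    # cumulative rewards per bin
    cum_reward = np.zeros(n_bins)
    for rt in reward_times[~np.isnan(reward_times)]:
        cum_reward[int(rt / bin_s):] += 1

    return {
        "bin_s": bin_s,
        "n_bins": n_bins,
        "n_frames": n_frames,
        "states": states,
        "trials": trials,
        "lick_onsets": lick_onsets,
        "cluster_onsets": cluster_onsets,
        "lick_frames": all_licks,
        "reward_times": reward_times,
        "pupil": pupil_z,
        "cum_reward": cum_reward,
        "free_start_s": free_start_s if config.free_epoch else None,
        "bout_onsets": bout_onsets,
    }


def _pick_target(rng: np.random.Generator, pupil_z: float, beta: float) -> int:
    w = np.exp(beta * pupil_z * (np.arange(1, 8) - 4) / 3.0)
    return int(rng.choice(np.arange(1, 8), p=w / w.sum()))


def _back_and_forth(seq: tuple[int, ...]) -> list[int]:
    """Expand (a, b, c) to the a↔b alternation then c pattern seen on trials."""
    if len(seq) == 2:
        a, b = seq
        return [a, b, a, b]
    a, b, c = seq
    return [a, b, a, b, c]


def _write_sequence(
    states: np.ndarray,
    start_bin: int,
    stop_bin: int,
    path: list[int],
    rng: np.random.Generator,
) -> None:
    t = start_bin
    for state in path:
        dwell = int(rng.integers(1, 5))  # 1-4 bins per visited state
        for _ in range(dwell):
            if t >= stop_bin:
                return
            states[t] = state
            t += 1


def _emit(
    config: SimConfig,
    latents: dict,
    loading: np.ndarray,
    noise_rng: np.random.Generator,
) -> np.ndarray:
    n_frames = latents["n_frames"]
    state_per_frame = np.repeat(latents["states"], config.frames_per_bin)
    # float32 is the storage convention for traces; keep float64 in the
    # noiseless case so emitted bins reproduce the loading columns exactly
    dtype = np.float32 if config.noise_sd > 0 else np.float64
    dff = loading[:, state_per_frame].astype(dtype)
    if config.drift_gain:
        total = max(latents["cum_reward"][-1], 1.0)
        drift_frac = np.repeat(latents["cum_reward"] / total, config.frames_per_bin)
        dff += (
            config.drift_gain
            * np.outer(loading_drift_pattern(loading), drift_frac)
        ).astype(dff.dtype)
    if config.noise_sd > 0:
        dff += config.noise_sd * noise_rng.standard_normal(
            (config.n_neurons, n_frames), dtype=np.float32
        )
    return dff


def loading_drift_pattern(loading: np.ndarray) -> np.ndarray:
    """Deterministic per-neuron drift direction derived from the loadings."""
    v = loading[:, 1:].sum(axis=1)
    norm = np.linalg.norm(v)
    if norm == 0:
        return np.zeros(loading.shape[0])
    return v / norm * np.sqrt(loading.shape[0])


def _events_table(config: SimConfig, latents: dict) -> pd.DataFrame:
    rows = []
    for _, row in latents["trials"].iterrows():
        responded = row["trial_class"] in ("reward_hit", "aversive_fa", "neutral_fa")
        rows.append(
            (row["cue_time_s"], "cue_on", row["trial_class"].split("_")[0], responded)
        )
    for f in latents["lick_frames"]:
        rows.append((f / config.frame_hz, "lick", "", False))
    for rt in latents["reward_times"]:
        if not np.isnan(rt):
            rows.append((rt, "reward", "", False))
    if latents["free_start_s"] is not None:
        rows.append((latents["free_start_s"], "epoch_start", "", False))
        rows.append((latents["n_bins"] * latents["bin_s"], "epoch_end", "", False))
    events = pd.DataFrame(
        rows, columns=["time_s", "event", "cue_type", "responded"]
    ).sort_values("time_s", kind="stable")
    return events.reset_index(drop=True)


def generate_session(
    config: SimConfig,
) -> tuple[Session, GroundTruth]:
    """Emit one synthetic session plus its ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_dyn, rng_load, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    latents = _draw_latents(config, rng_dyn)
    loading = np.zeros((config.n_neurons, N_STATES))
    loading[:, 1:] = rng_load.standard_normal((config.n_neurons, 7))
    dff = _emit(config, latents, loading, rng_noise)

    covariates = pd.DataFrame(
        {
            "time_s": (np.arange(latents["n_bins"]) + 0.5) * latents["bin_s"],
            "pupil": latents["pupil"],
            "cum_reward": latents["cum_reward"],
        }
    )
    session = Session(
        dff=dff,
        frame_hz=config.frame_hz,
        run_bounds=[(0, latents["n_frames"])],
        events=_events_table(config, latents),
        covariates=covariates,
        reward_type=config.reward_type,
    )
    truth = GroundTruth(
        state_sequence=latents["states"],
        loading_matrix=loading,
        lick_onsets=latents["lick_onsets"],
        cluster_onsets=latents["cluster_onsets"],
        trials=latents["trials"],
    )
    return session, truth


def generate_paired_sessions(
    config: SimConfig,
    permutation: np.ndarray,
    noise_seed: int | None = None,
) -> tuple[tuple[Session, GroundTruth], tuple[Session, GroundTruth]]:
    """Two sessions sharing one latent trajectory, ids relabeled in the second.

    ``permutation`` must be a bijection on {1..7} extended by 0 ↦ 0 (length-8
    array with ``permutation[i]`` the new id of state ``i``).  The second
    session keeps the dynamics but relabels state ids, permutes the loading
    columns consistently, and redraws the observation noise (or reuses a
    frozen ``noise_seed``).
    """
    perm = np.asarray(permutation)
    if perm.shape != (N_STATES,) or perm[0] != 0 or sorted(perm.tolist()) != list(
        range(N_STATES)
    ):
        raise ValueError(
            "permutation must be a bijection on {1..7} extended by 0 -> 0"
        )
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)
    rng_dyn = np.random.default_rng(seeds[0])
    rng_load = np.random.default_rng(seeds[1])

    latents = _draw_latents(config, rng_dyn)
    loading_a = np.zeros((config.n_neurons, N_STATES))
    loading_a[:, 1:] = rng_load.standard_normal((config.n_neurons, 7))
    loading_b = np.zeros_like(loading_a)
    loading_b[:, perm] = loading_a

    def build(loading, states, noise_rng, label_perm):
        lat = dict(latents)
        lat["states"] = states
        dff = _emit(config, lat, loading, noise_rng)
        covariates = pd.DataFrame(
            {
                "time_s": (np.arange(lat["n_bins"]) + 0.5) * lat["bin_s"],
                "pupil": lat["pupil"],
                "cum_reward": lat["cum_reward"],
            }
        )
        session = Session(
            dff=dff,
            frame_hz=config.frame_hz,
            run_bounds=[(0, lat["n_frames"])],
            events=_events_table(config, lat),
            covariates=covariates,
            reward_type=config.reward_type,
        )
        truth = GroundTruth(
            state_sequence=states,
            loading_matrix=loading,
            lick_onsets=lat["lick_onsets"],
            cluster_onsets=lat["cluster_onsets"],
            trials=lat["trials"],
            label_permutation=label_perm,
        )
        return session, truth

    rng_noise_a = np.random.default_rng(seeds[2])
    rng_noise_b = np.random.default_rng(
        noise_seed if noise_seed is not None else seeds[3]
    )
    pair_a = build(loading_a, latents["states"], rng_noise_a, np.arange(N_STATES))
    pair_b = build(loading_b, perm[latents["states"]], rng_noise_b, perm)
    return pair_a, pair_b


def generate_geometry(
    kind: str, n: int, params: dict | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray | None]:
    """Geometric fixtures with known intrinsic dimension / topology.

    kind="cube-d"     — uniform samples from a unit d-cube (params: d).
    kind="ring"       — noisy unit circle in the plane (params: noise_sd).
    kind="blobs+cloud"— 7 well-separated Gaussian blobs around a central
                        Gaussian cloud (params: dim, central_frac, blob_sd,
                        cloud_sd, radius); returns (points, labels) with
                        label 0 for the cloud and 1..7 for the blobs.

    Returns (points, labels); labels is None except for blobs+cloud.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "cube-d":
        d = int(params.get("d", 3))
        return rng.uniform(0.0, 1.0, size=(n, d)), None
    if kind == "ring":
        noise_sd = float(params.get("noise_sd", 0.0))
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        if noise_sd:
            pts += rng.normal(0.0, noise_sd, size=pts.shape)
        return pts, None
    if kind == "blobs+cloud":
        dim = int(params.get("dim", 6))
        central_frac = float(params.get("central_frac", 0.06))
        blob_sd = float(params.get("blob_sd", 0.5))
        cloud_sd = float(params.get("cloud_sd", 0.8))
        radius = float(params.get("radius", 8.0))
        if dim < 6:
            raise ValueError("blobs+cloud needs dim >= 6 (7 equidistant blobs)")
        n_central = int(round(central_frac * n))
        per_blob = np.full(7, (n - n_central) // 7)
        per_blob[: (n - n_central) % 7] += 1
        # regular-simplex arrangement: all pairwise blob distances equal, so
        # no blob pair is arbitrarily easier to merge than another
        E = np.eye(7) - 1.0 / 7.0
        U, S, _ = np.linalg.svd(E)
        centers6 = U[:, :6] * S[:6]
        centers6 = centers6 / np.linalg.norm(centers6, axis=1, keepdims=True) * radius
        centers = np.zeros((7, dim))
        centers[:, :6] = centers6
        pts = [rng.normal(0.0, cloud_sd, size=(n_central, dim))]
        labels = [np.zeros(n_central, dtype=int)]
        for k in range(7):
            pts.append(centers[k] + rng.normal(0.0, blob_sd, size=(per_blob[k], dim)))
            labels.append(np.full(per_blob[k], k + 1, dtype=int))
        return np.vstack(pts), np.concatenate(labels)
    raise ValueError(f"unknown geometry kind: {kind!r}")
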