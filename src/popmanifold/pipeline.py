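"""End-to-end analysis of one session: preprocess → embed → cluster → annotate.

Convenience driver tying the stages together with the standard parameters;
each stage remains individually callable for custom analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import annotate, behavior, clustering, dimensionality, dynamics, embedding
from .preprocess import BinnedSession, Session, preprocess_session


@dataclass
class SessionAnalysis:
    binned: BinnedSession
    embedding: embedding.Embedding
    dim_estimate: dimensionality.DimEstimate
    clusters: clustering.ManifoldClustering
    trial_matrix: dynamics.TrialMatrix
    transition: dynamics.TransitionMatrix
    mi: dict[str, annotate.MIResult]
    lick_onsets: np.ndarray
    cluster_onsets: np.ndarray
    chosen_cluster: int | None


def analyze_session(
    session: Session,
    seed: int = 0,
    per_run_zscore: bool = False,
    mi_variables: tuple[str, ...] = ("reward_hit", "pupil", "cum_reward"),
    n_shuffle: int = 200,
) -> SessionAnalysis:
    """Run the full single-session pipeline with default parameters."""
    binned = preprocess_session(session, per_run_zscore=per_run_zscore)
    emb = embedding.two_round_reduce(binned.z)
    # dimension estimated on the denoised round-1 (20-dim) coordinates, as in
    # the iterative procedure; duplicates from collapsed bins are merged
    pts20 = np.unique(np.round(emb.stage_coords[0], 9), axis=0)
    dim = dimensionality.estimate_dimension(pts20)
    cfg = clustering.optimize_config(emb.coords, seed=seed)
    clusters = clustering.consensus_labels(emb.coords, cfg, seed=seed + 1)

    trials = binned.trial_table()
    tm = dynamics.build_trial_matrix(clusters, trials)
    transition = dynamics.transition_matrix(clusters, binned.run_bin_bounds)

    mi = {}
    for var in mi_variables:
        try:
            lab = annotate.build_labels(binned, var)
            mi[var] = annotate.mi_shuffle_test(
                clusters.labels, lab, n_shuffle=max(100, n_shuffle), seed=seed + 2
            )
        except ValueError:
            continue

    lick_onsets, _ = behavior.session_lick_onsets(
        binned.bin_events, trials, reward_type=binned.reward_type
    )
    usable = np.isin(np.arange(len(trials)), np.arange(tm.sequences.shape[0]))
    rewarded = trials["trial_class"].to_numpy() == "reward_hit"
    cluster_onsets = np.full(len(trials), np.nan)
    chosen = None
    rew_rows = np.flatnonzero(rewarded & usable)
    if rew_rows.size >= 5:
        rew_tm = dynamics.TrialMatrix(
            tm.sequences[rew_rows],
            tm.classes[rew_rows],
            tm.onsets[rew_rows],
        )
        ons, chosen = behavior.detect_cluster_onset(
            rew_tm,
            lick_onsets[rew_rows],
            trials["cue_time_s"].to_numpy()[rew_rows],
            binned.bin_s,
        )
        cluster_onsets[rew_rows] = ons
    return SessionAnalysis(
        binned=binned,
        embedding=emb,
        dim_estimate=dim,
        clusters=clusters,
        trial_matrix=tm,
        transition=transition,
        mi=mi,
        lick_onsets=lick_onsets,
        cluster_onsets=cluster_onsets,
        chosen_cluster=chosen,
    )
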