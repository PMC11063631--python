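"""Trial-aligned cluster sequences, similarity, and cross-session decoding.

Each trial is summarized as the sequence of 20 manifold-cluster labels
(10 s of 0.5-s bins) following cue onset, with −1 for the central point
cloud.  Cosine similarity between label sequences defines trial similarity;
decoding assigns a test trial the class whose training trials maximize the
summed similarity.  To decode across sessions, cluster labels are first
translated by aligning the leaf orders of hierarchically clustered
transition-probability matrices: each session's 8 × 8 row-stochastic matrix
over {sentinel, clusters} is Ward-clustered on its rows, and the k-th label
in one leaf order maps to the k-th in the other.

Dendrogram leaf order as produced by the linkage solver is not invariant
under relabeling of the rows, so the subtrees at every internal node are
oriented canonically by an invariant of the matrix itself — the mean
self-transition (dwell) probability of the member labels — with label index
as final tie-break.  This makes the translation recover a pure relabeling
exactly when the clusters' transition profiles are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .clustering import ManifoldClustering

TRIAL_BINS = 20   # 10 s of ~0.5 s bins


@dataclass
class TrialMatrix:
    sequences: np.ndarray     # M × 20 label sequences
    classes: np.ndarray       # per-trial class names
    onsets: np.ndarray        # per-trial cue bin
    n_dropped: int = 0        # trials too close to the session end


@dataclass
class TransitionMatrix:
    P: np.ndarray             # 8 × 8 row-stochastic over label_order's labels
    labels: np.ndarray        # label ids indexing P's rows/cols
    leaf_order: np.ndarray    # permutation of labels from hierarchical clustering


@dataclass
class DecodingResult:
    predicted: np.ndarray
    accuracy: dict[str, float]
    overall_accuracy: float
    null: np.ndarray = field(repr=False, default=None)          # overall, per perm
    null_by_class: dict[str, np.ndarray] | None = field(repr=False, default=None)
    p: dict[str, float] | None = None


def _label_array(clustering: ManifoldClustering | np.ndarray) -> np.ndarray:
    if isinstance(clustering, ManifoldClustering):
        return clustering.labels
    return np.asarray(clustering)


def build_trial_matrix(
    clustering: ManifoldClustering | np.ndarray,
    trials: pd.DataFrame,
    n_bins: int = TRIAL_BINS,
) -> TrialMatrix:
    """M × 20 label sequences for bins [cue, cue + 20) of each trial."""
    labels = _label_array(clustering)
    T = labels.shape[0]
    rows, classes, onsets = [], [], []
    dropped = 0
    for _, row in trials.iterrows():
        cue = int(row["cue_bin"])
        if cue + n_bins > T:
            dropped += 1
            continue
        rows.append(labels[cue: cue + n_bins])
        classes.append(row["trial_class"])
        onsets.append(cue)
    if not rows:
        raise ValueError("no usable trials (all too close to session end)")
    return TrialMatrix(
        sequences=np.asarray(rows),
        classes=np.asarray(classes),
        onsets=np.asarray(onsets),
        n_dropped=dropped,
    )


def trial_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two label sequences (labels as numeric vectors)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    assert na > 0 and nb > 0, "label sequences are nonzero by construction"
    return float(a @ b / (na * nb))


def pairwise_trial_similarity(
    tm: TrialMatrix, other: TrialMatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full similarity matrix and (for the symmetric case) the pooled lower triangle."""
    A = tm.sequences.astype(float)
    B = A if other is None else other.sequences.astype(float)
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    S = An @ Bn.T
    if other is None:
        pooled = S[np.tril_indices_from(S, k=-1)]
    else:
        pooled = S.ravel()
    return S, pooled


# ------------------------------------------------------ transition matrices

def _canonical_leaf_order(P: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Ward leaf order with subtrees oriented by mean dwell probability."""
    n = P.shape[0]
    Z = sch.linkage(pdist(P), method="ward")
    diag = np.diag(P)

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        lw, rw = walk(left), walk(right)
        lkey = (float(np.mean(diag[lw])), min(lw))
        rkey = (float(np.mean(diag[rw])), min(rw))
        return lw + rw if lkey <= rkey else rw + lw

    order = walk(2 * n - 2)
    return labels[np.asarray(order)]


def transition_matrix(
    clustering: ManifoldClustering | np.ndarray,
    run_bin_bounds: list[tuple[int, int]] | None = None,
    include_diagonal: bool = True,
    require_labels: np.ndarray | None = None,
) -> TransitionMatrix:
    """Row-stochastic transition matrix over {sentinel, clusters 1..K}.

    Transitions across run boundaries are excluded.  Self-transitions (dwell)
    are counted by default — dwell structure is what distinguishes clusters.
    If ``require_labels`` is given (e.g. the full 8-label set for the
    cross-session analysis), a session missing any of them is rejected — such
    datasets cannot be aligned and are excluded.
    """
    seq = _label_array(clustering)
    labels = np.unique(seq)
    if require_labels is not None:
        missing = sorted(set(np.asarray(require_labels).tolist()) - set(labels.tolist()))
        if missing:
            raise ValueError(
                f"label(s) {missing} never occur; dataset excluded from alignment"
            )
    idx = {lab: i for i, lab in enumerate(labels)}
    n = labels.size
    counts = np.zeros((n, n))
    bounds = run_bin_bounds or [(0, seq.shape[0])]
    for b0, b1 in bounds:
        sub = seq[b0:b1]
        src = np.fromiter((idx[s] for s in sub[:-1]), int, len(sub) - 1)
        dst = np.fromiter((idx[s] for s in sub[1:]), int, len(sub) - 1)
        np.add.at(counts, (src, dst), 1.0)
    if not include_diagonal:
        np.fill_diagonal(counts, 0.0)
    row_sums = counts.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(
            f"label(s) {labels[zero].tolist()} have no outgoing transitions; "
            "dataset excluded"
        )
    P = counts / row_sums[:, None]
    return TransitionMatrix(
        P=P, labels=labels, leaf_order=_canonical_leaf_order(P, labels)
    )


def translate_labels(
    ref: TransitionMatrix, other: TransitionMatrix
) -> dict[int, int]:
    """Map other's labels onto ref's by matching leaf-order positions."""
    if ref.leaf_order.size != other.leaf_order.size:
        raise ValueError("transition matrices have different label counts")
    return {
        int(o): int(r) for o, r in zip(other.leaf_order, ref.leaf_order)
    }


def apply_label_mapping(tm: TrialMatrix, mapping: dict[int, int]) -> TrialMatrix:
    seq = tm.sequences
    out = np.empty_like(seq)
    for src, dst in mapping.items():
        out[seq == src] = dst
    return TrialMatrix(out, tm.classes, tm.onsets, tm.n_dropped)


# ----------------------------------------------------------------- decoding

def _class_scores(S: np.ndarray, train_classes: np.ndarray) -> tuple[np.ndarray, list]:
    class_names = sorted(set(train_classes))
    scores = np.stack(
        [S[:, train_classes == c].sum(axis=1) for c in class_names], axis=1
    )
    return scores, class_names


def _accuracy_per_class(
    predicted: np.ndarray, true: np.ndarray
) -> dict[str, float]:
    out = {}
    for c in sorted(set(true)):
        mask = true == c
        out[str(c)] = float(np.mean(predicted[mask] == c))
    return out


def decode_across(
    ref_tm: TrialMatrix,
    train_tm: TrialMatrix,
    mapping: dict[int, int] | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> DecodingResult:
    """Decode ref trials' classes from train trials by summed cosine similarity.

    Each ref trial is assigned argmax over classes of the sum of similarities
    to the train trials of that class.  The null shuffles the class labels of
    both datasets n_perm times; p per class is the fraction of null
    accuracies at or above the observed one.
    """
    if mapping is not None:
        train_tm = apply_label_mapping(train_tm, mapping)
    S, _ = pairwise_trial_similarity(ref_tm, train_tm)
    scores, class_names = _class_scores(S, train_tm.classes)
    predicted = np.asarray(class_names)[scores.argmax(axis=1)]
    accuracy = _accuracy_per_class(predicted, ref_tm.classes)
    overall = float(np.mean(predicted == ref_tm.classes))

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(accuracy)))
    null_overall = np.empty(n_perm)
    acc_keys = sorted(accuracy)
    for s in range(n_perm):
        ref_cls = rng.permutation(ref_tm.classes)
        train_cls = rng.permutation(train_tm.classes)
        sc, names = _class_scores(S, train_cls)
        pred = np.asarray(names)[sc.argmax(axis=1)]
        acc = _accuracy_per_class(pred, ref_cls)
        null[s] = [acc.get(k, 0.0) for k in acc_keys]
        null_overall[s] = float(np.mean(pred == ref_cls))
    p = {
        k: float(np.mean(null[:, i] >= accuracy[k]))
        for i, k in enumerate(acc_keys)
    }
    return DecodingResult(
        predicted=predicted,
        accuracy=accuracy,
        overall_accuracy=overall,
        null=null_overall,
        null_by_class={k: null[:, i] for i, k in enumerate(acc_keys)},
        p=p,
    )


# ------------------------------------------------------------ baselines

def mean_activity_sequences(
    z: np.ndarray, tm: TrialMatrix, n_bins: int = TRIAL_BINS
) -> np.ndarray:
    """Per-trial sequences of mean population activity (one scalar per bin)."""
    mean_act = z.mean(axis=0)
    seqs = np.stack([mean_act[o: o + n_bins] for o in tm.onsets])
    if np.any(np.linalg.norm(seqs, axis=1) == 0):
        raise ValueError("zero-norm mean-activity sequence; cosine undefined")
    return seqs


def state_axis_projection(
    z: np.ndarray, thirsty_mask: np.ndarray, quenched_mask: np.ndarray
) -> np.ndarray:
    """Per-bin projection on the thirsty−quenched population axis.

    Scaled so the mean thirsty pattern projects to 1 and the mean quenched
    pattern to 0.
    """
    if thirsty_mask.sum() == 0 or quenched_mask.sum() == 0:
        raise ValueError("anchor-state bin sets must be nonempty")
    x_t = z[:, thirsty_mask].mean(axis=1)
    x_q = z[:, quenched_mask].mean(axis=1)
    axis = x_t - x_q
    denom = float(axis @ axis)
    if denom == 0:
        raise ValueError("thirsty and quenched anchors coincide")
    return ((z - x_q[:, None]).T @ axis) / denom


def baseline_decoder(
    ref_feats: np.ndarray,
    ref_classes: np.ndarray,
    train_feats: np.ndarray,
    train_classes: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> DecodingResult:
    """Summed-cosine decoding on scalar per-bin feature sequences."""
    ref_tm = TrialMatrix(ref_feats, ref_classes, np.arange(len(ref_classes)))
    train_tm = TrialMatrix(
        train_feats, train_classes, np.arange(len(train_classes))
    )
    norms = np.concatenate(
        [np.linalg.norm(ref_feats, axis=1), np.linalg.norm(train_feats, axis=1)]
    )
    if np.any(norms == 0):
        raise ValueError("zero-norm feature sequence; cosine undefined")
    return decode_across(ref_tm, train_tm, mapping=None, n_perm=n_perm, seed=seed)
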