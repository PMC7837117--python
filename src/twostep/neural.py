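"""Trial-aligned neural population analyses.

Works on deconvolved event-like activity sampled at the acquisition rate
(10 Hz).  Trials are aligned by linearly time-warping the choice-to-outcome
interval to the session median, resampling to 20 Hz and Gaussian smoothing
(50 ms SD).  On the aligned tensor the module provides per-neuron/timepoint
linear regression with coefficients of partial determination (CPD),
circular-shift permutation nulls with Benjamini-Hochberg correction,
cross-validated representation projections, trial-type PCA trajectories, and
10-location population decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .task import Session

__all__ = [
    "NeuralSession",
    "TrialTensor",
    "time_warp_align",
    "neural_design",
    "cpd_regression",
    "CPDResult",
    "circular_shift_permutation",
    "PermCPDResult",
    "representation_projection",
    "trial_type_pca",
    "decode_locations",
    "benjamini_hochberg",
]

LOG2_OFFSET = 1.0  # log2(x + LOG2_OFFSET); deconvolved activity contains zeros


@dataclass
class NeuralSession:
    """Per-neuron deconvolved activity plus per-trial event timestamps.

    ``activity`` is (n_neurons, n_frames) non-negative at ``frame_rate`` Hz;
    ``choice_times`` / ``outcome_times`` are in seconds on the same clock and
    strictly increasing within each trial (outcome after choice).
    """

    activity: np.ndarray
    choice_times: np.ndarray
    outcome_times: np.ndarray
    behavior: Session
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.choice_times = np.asarray(self.choice_times, dtype=float)
        self.outcome_times = np.asarray(self.outcome_times, dtype=float)
        if (self.activity < 0).any():
            raise ValueError("activity must be non-negative")
        if len(self.choice_times) != len(self.outcome_times):
            raise ValueError("event arrays must have equal length")
        if np.any(self.outcome_times <= self.choice_times):
            raise ValueError("each trial's outcome must follow its choice")
        if self.behavior is not None and len(self.choice_times) != self.behavior.n_trials:
            raise ValueError("event times and behavioural session disagree on trial count")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.choice_times)

    @property
    def mean_event_rate(self) -> float:
        """Mean rate of non-zero activity frames (events per second per neuron)."""
        return float((self.activity > 0).mean() * self.frame_rate)


@dataclass
class TrialTensor:
    """Time-warped activity aligned on a fixed grid across trials.

    ``values`` is (n_trials, n_neurons, n_timepoints) at ``fs`` Hz; the grid
    spans 1,000 ms before choice to 1,000 ms after outcome, with the
    choice-to-outcome segment of every trial linearly rescaled to the session
    median so that ``choice_index`` and ``outcome_index`` are common to all
    trials.
    """

    values: np.ndarray
    fs: float
    choice_index: int
    outcome_index: int
    median_interval: float
    behavior: Session
    transform: str = "raw"

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def time_axis(self) -> np.ndarray:
        """Grid times in seconds relative to choice (warped segment runs from
        0 to the median interval; post-outcome times continue beyond it)."""
        return (np.arange(self.n_timepoints) - self.choice_index) / self.fs


def time_warp_align(
    neural_session: NeuralSession,
    fs_out: float = 20.0,
    pre: float = 1.0,
    post: float = 1.0,
    smooth_sd: float = 0.05,
    log2: bool = False,
    median_interval: Optional[float] = None,
) -> TrialTensor:
    """Align activity across trials by warping choice->outcome to the median.

    Per trial, grid samples in the choice-to-outcome segment are read from the
    original recording at times rescaled by (trial duration / median
    duration); pre-choice and post-outcome segments are unwarped.  The
    resampled (upsampled to ``fs_out``) traces are Gaussian smoothed with
    ``smooth_sd`` seconds SD; ``log2`` applies log2(x + 1) afterwards.

    ``median_interval`` overrides the session median; analyses that pool
    neurons across sessions need every tensor on the same grid, so pass the
    cohort-level median there.
    """
    ns = neural_session
    if ns.n_trials == 0:
        raise ValueError("need at least one complete trial")
    durations = ns.outcome_times - ns.choice_times
    med = (float(np.median(durations)) if median_interval is None
           else float(median_interval))

    n_pre = int(round(pre * fs_out))
    n_warp = max(int(round(med * fs_out)), 1)
    n_post = int(round(post * fs_out))
    T = n_pre + n_warp + 1 + n_post
    choice_idx, outcome_idx = n_pre, n_pre + n_warp

    frame_t = np.arange(ns.activity.shape[1]) / ns.frame_rate
    rel_pre = (np.arange(n_pre) - n_pre) / fs_out           # [-pre, 0)
    rel_warp = np.arange(n_warp + 1) / fs_out               # [0, med] nominal
    rel_post = np.arange(1, n_post + 1) / fs_out            # (0, post]

    values = np.empty((ns.n_trials, ns.n_neurons, T))
    for i in range(ns.n_trials):
        scale = durations[i] / med
        t_abs = np.concatenate([
            ns.choice_times[i] + rel_pre,
            ns.choice_times[i] + rel_warp * scale,
            ns.outcome_times[i] + rel_post,
        ])
        for j in range(ns.n_neurons):
            values[i, j] = np.interp(t_abs, frame_t, ns.activity[j])

    if smooth_sd > 0:
        values = gaussian_filter1d(values, sigma=smooth_sd * fs_out, axis=2)
    transform = "raw"
    if log2:
        values = np.log2(values + LOG2_OFFSET)
        transform = "log2"
    return TrialTensor(values=values, fs=fs_out, choice_index=choice_idx,
                       outcome_index=outcome_idx, median_interval=med,
                       behavior=ns.behavior, transform=transform)


# ---------------------------------------------------------------------------
# Designs for neural regressions

def _pm(x: np.ndarray) -> np.ndarray:
    """{0,1} -> +-0.5."""
    return np.asarray(x, dtype=float) - 0.5


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Product of two +-0.5 codes rescaled back to +-0.5 (0 if either is 0)."""
    return 2.0 * a * b


def _block_change_mask(labels: np.ndarray, n_mask: int) -> np.ndarray:
    """True for trials within ``n_mask`` trials after a change in ``labels``
    (the subject's knowledge of the block state is ambiguous there)."""
    mask = np.zeros(labels.size, dtype=bool)
    for c in np.flatnonzero(np.diff(labels.astype(int)) != 0) + 1:
        mask[c:c + n_mask] = True
    return mask


def neural_design(session: Session, kind: str = "events",
                  n_mask: int = 20) -> tuple[np.ndarray, tuple[str, ...]]:
    """Trial-level predictor matrix for the activity regressions.

    ``events``: choice, second step, outcome and their two-way interactions.
    ``transition_block`` adds the state of the transition probabilities, the
    common/rare transition, and its interactions with choice and second step.
    ``reward_block`` adds the reward-probability state (-0.5/0/+0.5 for
    left-good/neutral/right-good) and its interactions.  Block-state
    predictors are coded 0 for ``n_mask`` trials after the relevant change.
    An intercept column (named ``intercept``) is always included.
    """
    ch, ss, out = _pm(session.choice), _pm(session.second_step), _pm(session.outcome)
    cols = {"intercept": np.ones(session.n_trials),
            "choice": ch, "second_step": ss, "outcome": out,
            "choice_x_second_step": _interact(ch, ss),
            "choice_x_outcome": _interact(ch, out),
            "second_step_x_outcome": _interact(ss, out)}
    if kind == "transition_block":
        tp = _pm(session.transition_state == 0)
        tp[_block_change_mask(session.transition_state, n_mask)] = 0.0
        cols["trans_probs"] = tp
        cols["common_rare"] = _pm(session.common_transition)
        cols["choice_x_trans_probs"] = _interact(ch, tp)
        cols["second_step_x_trans_probs"] = _interact(ss, tp)
    elif kind == "reward_block":
        rp = np.select([session.reward_state == 0, session.reward_state == 2],
                       [-0.5, 0.5], default=0.0)
        rp[_block_change_mask(session.reward_state, n_mask)] = 0.0
        cols["reward_probs"] = rp
        cols["choice_x_reward_probs"] = _interact(ch, rp)
        cols["second_step_x_reward_probs"] = _interact(ss, rp)
        cols["transition_x_reward_probs"] = _interact(_pm(session.common_transition), rp)
    elif kind != "events":
        raise ValueError(f"unknown design kind {kind!r}")
    names = tuple(cols)
    return np.column_stack(list(cols.values())), names


# ---------------------------------------------------------------------------
# CPD regression

@dataclass
class CPDResult:
    """Population CPD time courses and per-neuron regression weights.

    ``cpd`` is (n_predictors, n_timepoints): the mean over neurons of each
    neuron's coefficient of partial determination.  ``neuron_cpd`` keeps the
    per-neuron values (n_predictors, n_neurons, n_timepoints) for pooling
    across sessions; ``weights`` are the full-model least-squares
    coefficients (n_predictors, n_neurons, n_timepoints).
    """

    predictors: tuple[str, ...]
    cpd: np.ndarray
    neuron_cpd: np.ndarray
    weights: np.ndarray


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[0] <= X.shape[1]:
        raise ValueError("trial count must exceed predictor count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y under least squares on X."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return (R * R).sum(axis=0), beta


def cpd_regression(
    tensor: TrialTensor,
    X: np.ndarray,
    names: Sequence[str],
    predictors: Optional[Sequence[str]] = None,
    trial_mask: Optional[np.ndarray] = None,
) -> CPDResult:
    """Per-neuron, per-timepoint linear regression with CPDs.

    CPD(p) = (SSE_reduced(p) - SSE_full) / SSE_reduced(p): the fraction of
    variance uniquely explained by predictor p beyond the other predictors.
    The intercept is never treated as a predictor of interest.
    """
    names = tuple(names)
    if predictors is None:
        predictors = tuple(n for n in names if n != "intercept")
    if trial_mask is not None:
        X = X[trial_mask]
        V = tensor.values[trial_mask]
    else:
        V = tensor.values
    _check_design(X, names)
    n_tr, n_nrn, T = V.shape
    Y = V.reshape(n_tr, n_nrn * T)

    sse_full, beta = _sse(X, Y)
    weights = beta.reshape(len(names), n_nrn, T)
    # columns fitted essentially perfectly by the reduced model contribute 0
    floor = 1e-12 * np.maximum((Y * Y).sum(axis=0), 1e-30)
    neuron_cpd = np.zeros((len(predictors), n_nrn, T))
    for k, pred in enumerate(predictors):
        j = names.index(pred)
        Xr = np.delete(X, j, axis=1)
        sse_red, _ = _sse(Xr, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            cpd = np.where(sse_red > floor, (sse_red - sse_full) / sse_red, 0.0)
        neuron_cpd[k] = np.clip(cpd, 0.0, 1.0).reshape(n_nrn, T)
    return CPDResult(predictors=tuple(predictors), cpd=neuron_cpd.mean(axis=1),
                     neuron_cpd=neuron_cpd, weights=weights)


def benjamini_hochberg(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-up FDR procedure: boolean significance mask over the flattened
    family of tests."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = flat[order] <= thresh
    sig = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        sig[order[: k + 1]] = True
    return sig.reshape(p.shape)


@dataclass
class PermCPDResult:
    predictors: tuple[str, ...]
    cpd: np.ndarray                 # pooled population CPD (n_pred, T)
    p_values: np.ndarray            # (n_pred, T), uncorrected
    significant: np.ndarray         # (n_pred, T), BH-corrected within predictor
    n_perm: int


def _pooled_cpd(session_data: Sequence[tuple], predictors, shifts=None) -> np.ndarray:
    """Neuron-weighted population CPD across sessions, optionally with the
    design of each session circularly shifted by a number of trials."""
    shapes = {t.n_timepoints for t, _, _ in session_data}
    if len(shapes) > 1:
        raise ValueError(
            "sessions are aligned on different grids; re-run time_warp_align "
            "with a shared median_interval before pooling")
    chunks = []
    for k, (tensor, X, names) in enumerate(session_data):
        Xk = np.roll(X, shifts[k], axis=0) if shifts is not None else X
        res = cpd_regression(tensor, Xk, names, predictors=predictors)
        chunks.append(res.neuron_cpd)
    return np.concatenate(chunks, axis=1).mean(axis=1)


def circular_shift_permutation(
    session_data: Sequence[tuple],
    predictors: Sequence[str],
    n_perm: int = 5000,
    rng: Optional[np.random.Generator] = None,
    alpha: float = 0.05,
) -> PermCPDResult:
    """Permutation null for population CPDs by circularly shifting each
    session's predictors relative to its neural activity by a random number
    of trials (preserving trial autocorrelations in both).

    ``session_data`` is a sequence of (TrialTensor, design matrix, names).
    p(predictor, t) is the fraction of permutations whose pooled CPD is >=
    the true CPD; significance is BH-corrected across timepoints within each
    predictor.
    """
    total_trials = sum(t.n_trials for t, _, _ in session_data)
    if len(session_data) < 2 and total_trials < 20:
        raise ValueError("need >= 2 sessions or >= 20 trials")
    rng = rng if rng is not None else np.random.default_rng(0)
    predictors = tuple(predictors)
    true_cpd = _pooled_cpd(session_data, predictors)
    count = np.zeros_like(true_cpd)
    for _ in range(n_perm):
        shifts = [int(rng.integers(0, t.n_trials)) for t, _, _ in session_data]
        perm = _pooled_cpd(session_data, predictors, shifts)
        count += perm >= true_cpd
    p = count / n_perm
    sig = np.array([benjamini_hochberg(p[k], alpha) for k in range(p.shape[0])])
    return PermCPDResult(predictors=predictors, cpd=true_cpd, p_values=p,
                         significant=sig, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Representation projections (cross-validated)

@dataclass
class ProjectionResult:
    projection_ref1: np.ndarray     # (T,) time course onto the t_ref1 axis
    projection_ref2: np.ndarray
    ref_cosine: float               # alignment of the two reference axes
    t_ref1: int
    t_ref2: int


def _half_weights(tensor, X, names, idx) -> np.ndarray:
    n_tr = len(idx)
    V = tensor.values[idx]
    Y = V.reshape(n_tr, -1)
    _, beta = _sse(X[idx], Y)
    return beta.reshape(len(names), tensor.n_neurons, tensor.n_timepoints)


def representation_projection(
    tensor: TrialTensor,
    X: np.ndarray,
    names: Sequence[str],
    predictor: str,
    t_ref1: Optional[int] = None,
    t_ref2: Optional[int] = None,
) -> ProjectionResult:
    """Time courses of two population representations of one predictor.

    Unit projection vectors are built from the per-neuron regression weights
    at two reference timepoints (defaults: midway between choice and outcome,
    and 250 ms after outcome).  To avoid selection bias, axes defined on odd
    trials are applied to weights from even trials and vice versa; the two
    cross-validated time courses are averaged.
    """
    names = tuple(names)
    j = names.index(predictor)
    if t_ref1 is None:
        t_ref1 = (tensor.choice_index + tensor.outcome_index) // 2
    if t_ref2 is None:
        t_ref2 = tensor.outcome_index + int(round(0.25 * tensor.fs))
    if not (0 <= t_ref1 < tensor.n_timepoints and 0 <= t_ref2 < tensor.n_timepoints):
        raise ValueError("reference timepoints fall outside the grid")

    idx = np.arange(tensor.n_trials)
    halves = [idx[0::2], idx[1::2]]
    proj1 = np.zeros(tensor.n_timepoints)
    proj2 = np.zeros(tensor.n_timepoints)
    cosines = []
    for define, apply_ in ((0, 1), (1, 0)):
        w_def = _half_weights(tensor, X, names, halves[define])[j]
        w_app = _half_weights(tensor, X, names, halves[apply_])[j]
        u1 = w_def[:, t_ref1]
        u2 = w_def[:, t_ref2]
        u1 = u1 / max(np.linalg.norm(u1), 1e-12)
        u2 = u2 / max(np.linalg.norm(u2), 1e-12)
        proj1 += u1 @ w_app / 2.0
        proj2 += u2 @ w_app / 2.0
        cosines.append(float(u1 @ u2))
    return ProjectionResult(projection_ref1=proj1, projection_ref2=proj2,
                            ref_cosine=float(np.mean(cosines)),
                            t_ref1=t_ref1, t_ref2=t_ref2)


# ---------------------------------------------------------------------------
# Trial-type PCA trajectories

@dataclass
class TrialTypePCAResult:
    axes: np.ndarray                # (n_neurons, n_pc) principal axes
    trajectories: np.ndarray        # (n_types, n_pc, T)
    explained_variance_ratio: np.ndarray
    type_labels: list


def trial_type_pca(tensor: TrialTensor, n_pc: int = 5) -> TrialTypePCAResult:
    """Principal axes of cross-trial-type variance and per-type trajectories.

    Trial types are the 8 combinations of (choice, second step, outcome).
    Each neuron's cross-type mean time course (the non-selective activity) is
    subtracted from its per-type means; PCA on the [neurons x (types *
    timepoints)] matrix yields the space capturing the most cross-trial-type
    variance, into which the type-mean trajectories are projected.
    """
    b = tensor.behavior
    labels = list(zip(b.choice.tolist(), b.second_step.tolist(), b.outcome.tolist()))
    types = [(c, s, o) for c in (0, 1) for s in (0, 1) for o in (0, 1)]
    type_means = []
    for tt in types:
        mask = np.array([lab == tt for lab in labels])
        if not mask.any():
            raise ValueError(f"trial type {tt} not present")
        type_means.append(tensor.values[mask].mean(axis=0))
    M = np.stack(type_means)                       # (8, neurons, T)
    selective = M - M.mean(axis=0, keepdims=True)
    n_nrn, T = selective.shape[1], selective.shape[2]
    D = selective.transpose(1, 0, 2).reshape(n_nrn, len(types) * T)
    U, S, _ = np.linalg.svd(D, full_matrices=False)
    n_pc = min(n_pc, S.size)
    var = S ** 2
    total = var.sum()
    # degenerate input (no cross-type variance at all) reports zero ratios
    ratio = var[:n_pc] / total if total > 0 else np.zeros(n_pc)
    axes = U[:, :n_pc]
    traj = np.einsum("nk,tnj->tkj", axes, selective)
    return TrialTypePCAResult(axes=axes, trajectories=traj,
                              explained_variance_ratio=ratio,
                              type_labels=types)


# ---------------------------------------------------------------------------
# Location decoding

@dataclass
class DecodeResult:
    accuracy: float
    confusion: np.ndarray           # (10, 10), rows sum to 1
    n_sessions_included: int
    dropped_sessions: list = field(default_factory=list)
    per_repeat_accuracy: np.ndarray = field(default_factory=lambda: np.array([]))


N_LOCATIONS = 10


def _location_samples(tensor: TrialTensor) -> tuple[np.ndarray, np.ndarray]:
    """Window-averaged activity and location labels for one session.

    The 10 locations: pre-choice x choice (2), post-choice x choice x second
    step (4), post-outcome x second step x outcome (4).  Windows are 250 ms,
    half-open: pre-choice starts 300 ms before choice, post-choice is centred
    between choice and outcome, post-outcome starts 100 ms after outcome.
    """
    fs = tensor.fs
    w = max(int(round(0.25 * fs)), 1)
    pre0 = tensor.choice_index - int(round(0.3 * fs))
    mid = (tensor.choice_index + tensor.outcome_index) // 2
    post0 = tensor.outcome_index + int(round(0.1 * fs))
    windows = [(pre0, pre0 + w), (mid - w // 2, mid - w // 2 + w), (post0, post0 + w)]
    for a, b in windows:
        if a < 0 or b > tensor.n_timepoints:
            raise ValueError("decoding window falls outside the aligned grid")
    beh = tensor.behavior
    feats, labels = [], []
    for t in range(tensor.n_trials):
        c, s, o = int(beh.choice[t]), int(beh.second_step[t]), int(beh.outcome[t])
        locs = (c, 2 + 2 * c + s, 6 + 2 * s + o)
        for (a, b), loc in zip(windows, locs):
            feats.append(tensor.values[t, :, a:b].mean(axis=1))
            labels.append(loc)
    return np.array(feats), np.array(labels)


def decode_locations(
    tensors: Sequence[TrialTensor],
    rng: Optional[np.random.Generator] = None,
    n_visits: int = 10,
    n_repeats: int = 10,
    n_folds: int = 10,
    C: float = 1.0,
    shuffle_labels: bool = False,
    verbose: bool = False,
) -> DecodeResult:
    """Decode task-space location from population activity.

    Per repeat, ``n_visits`` visits to each location are drawn per session and
    like-location population vectors concatenated across sessions; location is
    predicted by L2-regularised multinomial logistic regression under
    stratified k-fold cross-validation, and accuracy averaged over repeats.
    Sessions lacking ``n_visits`` visits to every location are dropped (with a
    log message when ``verbose``).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    per_session = []
    dropped = []
    for k, tensor in enumerate(tensors):
        feats, labels = _location_samples(tensor)
        counts = np.bincount(labels, minlength=N_LOCATIONS)
        if (counts >= n_visits).all():
            per_session.append((feats, labels))
        else:
            dropped.append(k)
            if verbose:
                print(f"decode_locations: session {k} dropped "
                      f"(min visits {counts.min()} < {n_visits})")
    if not per_session:
        raise ValueError("no session has enough visits to every location")

    accs = np.empty(n_repeats)
    confusion = np.zeros((N_LOCATIONS, N_LOCATIONS))
    y = np.repeat(np.arange(N_LOCATIONS), n_visits)
    for rep in range(n_repeats):
        blocks = []
        for feats, labels in per_session:
            cols = []
            for loc in range(N_LOCATIONS):
                idx = np.flatnonzero(labels == loc)
                pick = rng.choice(idx, size=n_visits, replace=False)
                cols.append(feats[pick])
            blocks.append(np.concatenate(cols, axis=0))
        Xall = np.concatenate(blocks, axis=1)       # (10*n_visits, total neurons)
        y_rep = rng.permutation(y) if shuffle_labels else y
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        correct = 0
        for train, test in skf.split(Xall, y_rep):
            clf = LogisticRegression(C=C, max_iter=2000)
            clf.fit(Xall[train], y_rep[train])
            pred = clf.predict(Xall[test])
            correct += int((pred == y_rep[test]).sum())
            for yt, yp in zip(y_rep[test], pred):
                confusion[yt, yp] += 1
        accs[rep] = correct / y.size
    confusion /= confusion.sum(axis=1, keepdims=True)
    return DecodeResult(accuracy=float(accs.mean()), confusion=confusion,
                        n_sessions_included=len(per_session),
                        dropped_sessions=dropped, per_repeat_accuracy=accs)
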