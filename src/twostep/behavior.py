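"""Behavioural statistics: stay probabilities, hierarchical logistic
regressions of choice, reversal curves, permutation and bootstrap tests, and
cross-subject effect regressions.

All choice regressions predict the current first-step choice (top = 1) from
signed trial-history predictors coded +-0.5, where the sign convention is
"positive loading = repeat the referenced choice".  The hierarchical fits are
delegated to :mod:`twostep.hierfit` with a Bernoulli likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .hierfit import BernoulliLikelihood, PopulationPrior, em_fit
from .task import Session

__all__ = [
    "stay_probability",
    "ChoiceDesign",
    "build_design",
    "RegressionResult",
    "fit_choice_regression",
    "reversal_curve",
    "permutation_test_stim",
    "permutation_test_interaction",
    "bootstrap_loading_test",
    "cross_subject_effect_regression",
    "two_tailed_count_p",
]

ONE_TRIAL_BACK_PREDICTORS = (
    "bias_top_bottom", "bias_rotational", "choice", "correct",
    "outcome", "transition", "trans_x_out",
)
LAGGED_BASES = ("choice", "outcome", "transition", "trans_x_out")
LAG_BINS = ((1, 1), (2, 2), (3, 4), (5, 8), (9, 12))
#: Predictors the opto analyses report (Bonferroni family for the two-step task).
OPTO_PREDICTORS = ("outcome", "transition", "trans_x_out")


def two_tailed_count_p(m: int, n: int) -> float:
    """Two-sided p-value from a count of m extreme draws out of n:
    P = 2 min(m/n, 1 - m/n), floored at the minimum attainable 2/n."""
    return max(2.0 * min(m / n, 1.0 - m / n), 2.0 / n)


# ---------------------------------------------------------------------------
# Stay probabilities

def stay_probability(sessions: Sequence[Session]) -> pd.DataFrame:
    """Fraction of trials the subject repeated its previous choice, split by
    the previous trial's (transition, outcome).

    Computed per subject then averaged; categories a subject never saw are
    absent from that subject's rows.  Returns a tidy frame with per-subject
    rows and a ``"mean"`` row per category.
    """
    if not sessions or all(s.n_trials < 2 for s in sessions):
        raise ValueError("need at least one session with >= 2 trials")
    rows = []
    by_subject: dict[str, dict] = {}
    for s in sessions:
        if s.n_trials < 2:
            continue
        stay = (s.choice[1:] == s.choice[:-1]).astype(float)
        common = s.common_transition[:-1]
        rewarded = s.outcome[:-1].astype(bool)
        d = by_subject.setdefault(s.subject_id, {})
        for com in (True, False):
            for rew in (True, False):
                mask = (common == com) & (rewarded == rew)
                k, n = stay[mask].sum(), int(mask.sum())
                key = (com, rew)
                prev = d.get(key, (0.0, 0))
                d[key] = (prev[0] + k, prev[1] + n)
    for subj, cats in sorted(by_subject.items()):
        for (com, rew), (k, n) in cats.items():
            if n > 0:
                rows.append({"subject": subj, "transition": "common" if com else "rare",
                             "outcome": int(rew), "stay_probability": k / n, "n_trials": n})
    df = pd.DataFrame(rows)
    means = (df.groupby(["transition", "outcome"], as_index=False)
               .agg(stay_probability=("stay_probability", "mean"),
                    n_trials=("n_trials", "sum")))
    means.insert(0, "subject", "mean")
    return pd.concat([df, means], ignore_index=True)


# ---------------------------------------------------------------------------
# Design matrices

@dataclass
class ChoiceDesign:
    """Per-session design matrices and responses for a choice regression.

    ``X[i]`` has one row per included response trial of session i; ``stim[i]``
    carries the stimulation flag of the response trial (None when the session
    has no stimulation data).  ``exclusion_fraction`` is the fraction of
    candidate response trials dropped by the post-transition-reversal rule.
    """

    names: tuple[str, ...]
    X: list
    y: list
    stim: list
    subjects: list
    exclusion_fraction: float

    @property
    def n_sessions(self) -> int:
        return len(self.X)

    def datasets(self, unit: str = "session") -> tuple[list, list]:
        """Group (X, y) pairs by fitting unit; returns (datasets, subject per unit)."""
        if unit == "session":
            return [(x, y) for x, y in zip(self.X, self.y)], list(self.subjects)
        order: dict[str, list[int]] = {}
        for i, subj in enumerate(self.subjects):
            order.setdefault(subj, []).append(i)
        datasets = [(np.vstack([self.X[i] for i in idx]),
                     np.concatenate([self.y[i] for i in idx]))
                    for idx in order.values()]
        return datasets, list(order.keys())


def _signed(prev_choice_sign: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Code 'repeat the referenced choice' predictors: +-0.5 with sign carried
    by the referenced choice (top = +1, bottom = -1)."""
    return prev_choice_sign * (indicator - 0.5)


def _transition_reversal_exclusion(session: Session, n_exclude: int) -> np.ndarray:
    """Boolean mask of trials falling within ``n_exclude`` trials after a
    reversal in the transition probabilities (common/rare ambiguous there)."""
    excl = np.zeros(session.n_trials, dtype=bool)
    changes = np.flatnonzero(np.diff(session.transition_state.astype(int)) != 0) + 1
    for c in changes:
        excl[c:c + n_exclude] = True
    return excl


def build_design(
    sessions: Sequence[Session],
    kind: str = "one_trial_back",
    n_exclude: int = 20,
    exclude_lag_sources: bool = False,
) -> ChoiceDesign:
    """Build per-trial predictor matrices for the choice regressions.

    kinds: ``one_trial_back`` (bias, rotational bias, choice, correct,
    outcome, transition, transition-outcome interaction of the previous
    trial), ``lagged`` (choice/outcome/transition/interaction summed over lag
    bins 1, 2, 3-4, 5-8, 9-12 plus the two biases), and ``reversal_lagged``
    (bias plus choice and outcome at lags 1-3, for the reversal-learning
    task, with no reversal exclusion).

    Response trials within ``n_exclude`` trials of a transition-probability
    reversal are dropped; by default they still serve as lag-history sources
    (set ``exclude_lag_sources`` to drop them there too).
    """
    if kind == "one_trial_back":
        max_lag, names = 1, list(ONE_TRIAL_BACK_PREDICTORS)
    elif kind == "lagged":
        max_lag = max(b for _, b in LAG_BINS)
        names = ["bias_top_bottom", "bias_rotational"] + [
            f"{base}_lag{a}" if a == b else f"{base}_lag{a}-{b}"
            for base in LAGGED_BASES for a, b in LAG_BINS]
    elif kind == "reversal_lagged":
        max_lag = 3
        names = ["bias"] + [f"{base}_lag{l}" for base in ("choice", "outcome")
                            for l in (1, 2, 3)]
    else:
        raise ValueError(f"unknown design kind {kind!r}")

    Xs, ys, stims, subjects = [], [], [], []
    n_candidate = n_excluded = 0
    for s in sessions:
        if s.n_trials <= max_lag:
            raise ValueError(
                f"session {s.subject_id}/{s.session_id} shorter than max lag {max_lag}")
        sign = 2.0 * s.choice - 1.0                       # referenced-choice sign
        common = s.common_transition.astype(float)
        outcome = s.outcome.astype(float)
        corr = s.correct_choice_per_trial
        was_correct = np.where(corr < 0, np.nan, (s.choice == corr).astype(float))

        per_lag = {
            "choice": s.choice - 0.5,
            "outcome": _signed(sign, outcome),
            "transition": _signed(sign, common),
            "trans_x_out": _signed(sign, (common == outcome).astype(float)),
            "correct": np.where(np.isnan(was_correct), 0.0, _signed(sign, was_correct)),
        }

        t = np.arange(max_lag, s.n_trials)                # response trials
        cols = []
        for name in names:
            if name in ("bias_top_bottom", "bias"):
                cols.append(np.full(t.size, 0.5))
            elif name == "bias_rotational":
                cols.append(s.second_step[t - 1] - 0.5)
            elif kind == "one_trial_back":
                cols.append(per_lag[name][t - 1])
            else:
                base, lag = name.rsplit("_lag", 1)
                a, b = (map(int, lag.split("-")) if "-" in lag else (int(lag), int(lag)))
                x = np.zeros(t.size)
                for l in range(a, b + 1):
                    x += per_lag[base][t - l]
                cols.append(x)
        X = np.column_stack(cols)
        y = s.choice[t].astype(float)

        keep = np.ones(t.size, dtype=bool)
        if kind != "reversal_lagged" and n_exclude > 0:
            excl = _transition_reversal_exclusion(s, n_exclude)
            keep = ~excl[t]
            if exclude_lag_sources:
                for l in range(1, max_lag + 1):
                    keep &= ~excl[t - l]
        n_candidate += t.size
        n_excluded += int((~keep).sum())
        Xs.append(X[keep])
        ys.append(y[keep])
        stims.append(None if s.stim is None else s.stim[t][keep].astype(int))
        subjects.append(s.subject_id)

    frac = n_excluded / n_candidate if n_candidate else 0.0
    return ChoiceDesign(names=tuple(names), X=Xs, y=ys, stim=stims,
                        subjects=subjects, exclusion_fraction=frac)


# ---------------------------------------------------------------------------
# Hierarchical logistic fits

@dataclass
class RegressionResult:
    """Population-level loadings of a hierarchical choice regression.

    ``mu`` is the population mean per predictor; ``ci`` the bootstrap 95%
    confidence interval on the mean (resampling subjects with replacement);
    ``p_values`` the two-sided bootstrap p-values; ``subject_loadings`` the
    per-subject mean MAP loadings (one row per subject).
    """

    names: tuple[str, ...]
    mu: np.ndarray
    ci: np.ndarray
    p_values: np.ndarray
    subject_loadings: np.ndarray
    subject_ids: list
    prior: PopulationPrior
    unit_maps: np.ndarray
    p_value_method: str = "bootstrap"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.names, "loading": self.mu,
            "ci_low": self.ci[0], "ci_high": self.ci[1], "p": self.p_values,
        })


def _fit_hierarchical_logistic(datasets, names, seed=0, **em_kwargs):
    em_kwargs.setdefault("max_iter", 50)
    em_kwargs.setdefault("tol", 1e-3)
    lik = BernoulliLikelihood(names)
    return em_fit(datasets, lik, seed=seed, **em_kwargs)


def fit_choice_regression(
    design: ChoiceDesign,
    unit: str = "session",
    n_boot: int = 5000,
    seed: int = 0,
    **em_kwargs,
) -> RegressionResult:
    """Hierarchical logistic regression of choice on the design's predictors.

    Fits a population Gaussian over per-unit coefficient vectors by EM, then
    bootstraps the cross-subject mean of per-subject MAP loadings for CIs and
    two-sided p-values.
    """
    datasets, unit_subjects = design.datasets(unit)
    em = _fit_hierarchical_logistic(datasets, design.names, seed=seed, **em_kwargs)
    unit_maps = np.array([f.m for f in em.fits])

    subj_ids = sorted(set(unit_subjects))
    subj_loadings = np.array([
        unit_maps[[i for i, s in enumerate(unit_subjects) if s == subj]].mean(axis=0)
        for subj in subj_ids])

    rng = np.random.default_rng(seed + 1)
    ci, p = _bootstrap_mean_ci(subj_loadings, n_boot, rng)
    return RegressionResult(names=design.names, mu=em.prior.mu, ci=ci, p_values=p,
                            subject_loadings=subj_loadings, subject_ids=subj_ids,
                            prior=em.prior, unit_maps=unit_maps)


def _bootstrap_mean_ci(subject_loadings: np.ndarray, n_boot: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = subject_loadings.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    means = subject_loadings[idx].mean(axis=1)          # (n_boot, p)
    ci = np.percentile(means, [2.5, 97.5], axis=0)
    m_pos = (means > 0).sum(axis=0)
    p = np.array([two_tailed_count_p(int(m), n_boot) for m in m_pos])
    return ci, p


def bootstrap_loading_test(
    subject_loadings: np.ndarray,
    n_boot: int = 5000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Two-sided bootstrap test of per-predictor population means against 0:
    resample subjects with replacement, count resamples with positive mean."""
    subject_loadings = np.atleast_2d(np.asarray(subject_loadings, dtype=float))
    if subject_loadings.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    rng = rng if rng is not None else np.random.default_rng(0)
    _, p = _bootstrap_mean_ci(subject_loadings, n_boot, rng)
    return p


# ---------------------------------------------------------------------------
# Reversal curves

@dataclass
class ReversalCurveResult:
    """Average probability of the post-reversal correct choice as a function
    of trials since reversal, with an exponential fit
    p(t) = p_end - (p_end - p_0) exp(-t / tau)."""

    trajectory: np.ndarray
    n_per_trial: np.ndarray
    tau: float
    p_end: float
    p_0: float
    n_reversals: int
    informative: bool


def _find_reversals(session: Session, kind: str) -> np.ndarray:
    """Trial indices at which a reversal of the requested kind begins."""
    ts, rs = session.transition_state.astype(int), session.reward_state.astype(int)
    change = np.flatnonzero((np.diff(ts) != 0) | (np.diff(rs) != 0)) + 1
    out = []
    for c in change:
        d_ts = ts[c] != ts[c - 1]
        d_rs = rs[c] != rs[c - 1]
        is_reward_rev = d_rs and rs[c] != 1 and rs[c - 1] != 1 and not d_ts
        is_trans_rev = d_ts and not d_rs and rs[c] != 1
        if (kind == "reward" and is_reward_rev) or (kind == "transition" and is_trans_rev) \
                or (kind == "any" and (is_reward_rev or is_trans_rev)):
            out.append(c)
    return np.asarray(out, dtype=int)


def reversal_curve(
    sessions: Sequence[Session],
    kind: str = "any",
    n_post: int = 20,
    n_pre: int = 5,
) -> ReversalCurveResult:
    """Choice-probability trajectory around reversals and its exponential time
    constant.

    A reversal flips which first-step action is correct, either through the
    reward probabilities or the transition probabilities.  ``p_0`` is the
    pre-reversal baseline probability of the (new) post-reversal correct
    choice; the exponential is fitted to the trial-averaged trajectory by
    least squares.  The fit is flagged uninformative when the trajectory does
    not rise appreciably above baseline.
    """
    num = np.zeros(n_post)
    den = np.zeros(n_post)
    pre_num = pre_den = 0.0
    n_rev = 0
    for s in sessions:
        corr = s.correct_choice_per_trial
        for c in _find_reversals(s, kind):
            new_correct = corr[c]
            if new_correct < 0:
                continue
            n_rev += 1
            hi = min(c + n_post, s.n_trials)
            seg = (s.choice[c:hi] == new_correct).astype(float)
            num[:hi - c] += seg
            den[:hi - c] += 1
            lo = max(c - n_pre, 0)
            pre = (s.choice[lo:c] == new_correct).astype(float)
            pre_num += pre.sum()
            pre_den += pre.size
    if n_rev == 0:
        raise ValueError(f"no reversals of kind {kind!r} found")
    traj = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    p_0 = pre_num / pre_den if pre_den else 0.5

    t = np.arange(n_post, dtype=float)
    ok = den > 0
    # informative only if the trajectory rises above baseline by more than
    # binomial noise on the sparsest point
    noise = 3.0 * np.sqrt(0.25 / max(den[ok].min(), 1.0))
    informative = bool(np.nanmax(traj) - p_0 > max(0.05, noise))
    tau = p_end = np.nan
    if informative:
        try:
            popt, _ = curve_fit(
                lambda tt, tau_, pe: pe - (pe - p_0) * np.exp(-tt / tau_),
                t[ok], traj[ok], p0=(5.0, max(traj[ok].max(), p_0 + 0.1)),
                bounds=([1e-3, 0.0], [200.0, 1.0]), maxfev=10000)
            tau, p_end = float(popt[0]), float(popt[1])
        except RuntimeError:
            informative = False
    return ReversalCurveResult(trajectory=traj, n_per_trial=den, tau=tau,
                               p_end=p_end, p_0=float(p_0), n_reversals=n_rev,
                               informative=informative)


# ---------------------------------------------------------------------------
# Permutation tests for stimulation effects

def _split_by_stim(design: ChoiceDesign, stim_masks: list) -> tuple[list, list]:
    stim_sets, non_sets = [], []
    for X, y, m in zip(design.X, design.y, stim_masks):
        stim_sets.append((X[m], y[m]))
        non_sets.append((X[~m], y[~m]))
    return stim_sets, non_sets


def _delta_mu(design: ChoiceDesign, stim_masks: list, seed: int, **em_kwargs) -> np.ndarray:
    stim_sets, non_sets = _split_by_stim(design, stim_masks)
    em_s = _fit_hierarchical_logistic(stim_sets, design.names, seed=seed, **em_kwargs)
    em_n = _fit_hierarchical_logistic(non_sets, design.names, seed=seed, **em_kwargs)
    return em_s.prior.mu - em_n.prior.mu


@dataclass
class StimTestResult:
    names: tuple[str, ...]
    delta_mu: np.ndarray
    p_uncorrected: np.ndarray
    p_bonferroni: np.ndarray
    reported: tuple[str, ...]
    n_perm: int


def permutation_test_stim(
    design: ChoiceDesign,
    n_perm: int = 5000,
    seed: int = 0,
    reported: Sequence[str] = OPTO_PREDICTORS,
    min_trials: int = 3,
    **em_kwargs,
) -> StimTestResult:
    """Permutation test for differences in regression loadings between
    stimulated and non-stimulated trials.

    The hierarchical model is fitted separately to stimulated and
    non-stimulated trials; the observed population-mean difference is compared
    with an ensemble of refits in which stimulation labels are shuffled across
    trials within each session.  Two-sided p-values follow the
    count-of-extremes rule, Bonferroni-corrected over the reported predictors.
    """
    if any(st is None for st in design.stim):
        raise ValueError("design has sessions without stimulation flags")
    masks = [st.astype(bool) for st in design.stim]
    for i, m in enumerate(masks):
        if m.sum() < min_trials or (~m).sum() < min_trials:
            raise ValueError(f"session {i} has fewer than {min_trials} trials "
                             "in one stimulation condition")
    em_kwargs.setdefault("max_iter", 20)
    em_kwargs.setdefault("tol", 1e-3)
    delta_true = _delta_mu(design, masks, seed, **em_kwargs)

    rng = np.random.default_rng(seed + 1)
    M = np.zeros(len(design.names), dtype=int)
    for _ in range(n_perm):
        perm_masks = []
        for m in masks:
            shuffled = m.copy()
            rng.shuffle(shuffled)
            perm_masks.append(shuffled)
        d = _delta_mu(design, perm_masks, seed, **em_kwargs)
        M += d > delta_true
    p = np.array([two_tailed_count_p(int(m), n_perm) for m in M])
    k = len(reported)
    p_bonf = np.array([
        min(p[i] * k, 1.0) if name in reported else np.nan
        for i, name in enumerate(design.names)])
    return StimTestResult(names=design.names, delta_mu=delta_true,
                          p_uncorrected=p, p_bonferroni=p_bonf,
                          reported=tuple(reported), n_perm=n_perm)


def permutation_test_interaction(
    design_a: ChoiceDesign,
    design_b: ChoiceDesign,
    n_perm: int = 5000,
    seed: int = 0,
    **em_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Group x stimulation interaction: difference of stimulation-effect
    differences between two subject groups, with a null built by permuting
    subjects between groups.  Returns (delta_true, p per predictor)."""
    if design_a.names != design_b.names:
        raise ValueError("designs must share predictors")
    if set(design_a.subjects) & set(design_b.subjects):
        raise ValueError("subject ids overlap between the two groups")
    em_kwargs.setdefault("max_iter", 20)
    em_kwargs.setdefault("tol", 1e-3)

    def group_delta(design):
        masks = [st.astype(bool) for st in design.stim]
        return _delta_mu(design, masks, seed, **em_kwargs)

    delta_true = group_delta(design_a) - group_delta(design_b)

    # Pool sessions by subject and reassign whole subjects to groups.
    subjects: dict[str, list[int]] = {}
    pool_design = ChoiceDesign(
        names=design_a.names,
        X=design_a.X + design_b.X, y=design_a.y + design_b.y,
        stim=design_a.stim + design_b.stim,
        subjects=design_a.subjects + design_b.subjects,
        exclusion_fraction=0.0)
    for i, subj in enumerate(pool_design.subjects):
        subjects.setdefault(subj, []).append(i)
    subj_ids = list(subjects)
    n_a = len(set(design_a.subjects))

    rng = np.random.default_rng(seed + 1)
    M = np.zeros(len(design_a.names), dtype=int)
    for _ in range(n_perm):
        order = rng.permutation(len(subj_ids))
        idx_a = [i for k in order[:n_a] for i in subjects[subj_ids[k]]]
        idx_b = [i for k in order[n_a:] for i in subjects[subj_ids[k]]]

        def sub(idx):
            return ChoiceDesign(names=pool_design.names,
                                X=[pool_design.X[i] for i in idx],
                                y=[pool_design.y[i] for i in idx],
                                stim=[pool_design.stim[i] for i in idx],
                                subjects=[pool_design.subjects[i] for i in idx],
                                exclusion_fraction=0.0)
        d = group_delta(sub(idx_a)) - group_delta(sub(idx_b))
        M += d > delta_true
    p = np.array([two_tailed_count_p(int(m), n_perm) for m in M])
    return delta_true, p


# ---------------------------------------------------------------------------
# Cross-subject effect regression

@dataclass
class EffectRegressionResult:
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    p_values: np.ndarray
    r_squared: float
    correlation_gmb: float


def cross_subject_effect_regression(
    effects: np.ndarray,
    subject_params: pd.DataFrame,
    predictors: Sequence[str] = ("G_mb", "G_mf", "G_mo", "P_m"),
) -> EffectRegressionResult:
    """Ordinary least squares of per-subject optogenetic effects (e.g., the
    stimulation-induced change in the transition loading) on RL model
    parameters, plus the simple correlation with the model-based weight."""
    import statsmodels.api as sm

    effects = np.asarray(effects, dtype=float)
    if effects.size < 6:
        raise ValueError("need at least 6 subjects")
    X = sm.add_constant(subject_params.loc[:, list(predictors)].to_numpy(dtype=float))
    fit = sm.OLS(effects, X).fit()
    g_mb = subject_params["G_mb"].to_numpy(dtype=float)
    corr = float(np.corrcoef(effects, g_mb)[0, 1])
    return EffectRegressionResult(
        predictor_names=tuple(predictors),
        coefficients=fit.params[1:], p_values=fit.pvalues[1:],
        r_squared=float(fit.rsquared), correlation_gmb=corr)
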