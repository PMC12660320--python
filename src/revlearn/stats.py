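"""Behavioural statistics for reversal-learning sessions.

Three core analyses, mirroring a standard within-subject stimulation design,
plus companions:

- **Win-stay regression** (Analysis A): per subject x block x condition OLS
  of WinStay(t+1) on Reward(t), choiceStickiness(t) and isHPScreen(t+1),
  where WinStay is +1 for win-stay, -1 for win-switch and 0 otherwise. The
  per-subject coefficients (averaged over blocks) go into a one-way
  condition ANOVA with Bonferroni-corrected paired post-hoc t-tests and
  paired Cohen's D. A model-based variant replaces Reward(t) with the
  trial's prediction error.
- **Block-wise contrasts** (Analysis B): uncorrected paired t-tests of the
  Analysis-A coefficients between two conditions, separately per block, to
  trace an effect over time.
- **Learning curves** (Analysis C): the rate of choosing the
  high-probability symbol by position within a contingency period, smoothed
  with a 5-trial running average; a model-based variant uses the expected
  value of the high-probability symbol. A linear mixed model (random
  intercept per subject) contrasts the trial-level high-probability choice
  rate between conditions.

Companions: maladaptive win-stay on low-probability pairs, exploratory
metrics (post-learning accuracy, perseveration errors, post-error
adjustment), and a two-group Mann-Whitney rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError, DataError
from .models import LatentTrajectory


# ---------------------------------------------------------------------------
# Win-stay coding and regression (Analysis A)
# ---------------------------------------------------------------------------

def code_winstay(
    trials: pd.DataFrame,
    latents: LatentTrajectory | None = None,
    source: str = "raw_reward",
) -> pd.DataFrame:
    """Code win-stay behaviour for one session.

    One row per pair of consecutive trials (t, t+1) within a block:

    - ``winstay``: +1 if trial t was rewarded and the symbol chosen at t is
      chosen again at t+1; -1 if t was rewarded, that symbol is shown at t+1
      but not chosen; 0 otherwise (including when the rotation does not show
      the symbol again at t+1, and after unrewarded trials).
    - ``reward``: the outcome at t (or the prediction error at t when
      ``source="model_pe"``, which requires ``latents``).
    - ``stickiness``: 1 if the choice at t repeats the choice at t-1
      (0 on the first trial of a block and when either choice is missing).
    - ``is_hp_next``: 1 if the high-probability symbol is on screen at t+1.
    - ``valid``: both trials non-lost; only valid rows enter the regression.
    """
    if source not in ("raw_reward", "model_pe"):
        raise DataError(f"unknown source {source!r}")
    if source == "model_pe" and latents is None:
        raise DataError("source='model_pe' requires a LatentTrajectory")

    block = trials["block"].to_numpy(dtype=np.int64)
    s_left = trials["sym_left"].to_numpy(dtype=float)
    s_right = trials["sym_right"].to_numpy(dtype=float)
    chosen = trials["chosen"].to_numpy(dtype=float)
    outcome = trials["outcome"].to_numpy(dtype=float)
    lost = trials["lost"].to_numpy(dtype=bool)
    hp = trials["hp_symbol"].to_numpy(dtype=float)
    n = len(block)

    regressor = outcome
    if source == "model_pe":
        pe = latents.table["pe"].to_numpy(dtype=float)
        if len(pe) != n:
            raise DataError("latents not aligned with trials")
        regressor = pe

    if n < 2:
        return pd.DataFrame(columns=["t", "block", "winstay", "reward",
                                     "stickiness", "is_hp_next", "valid"])

    # stickiness at t: choice repeats the previous trial's choice (NaN-safe
    # because lost trials are masked out explicitly)
    stick = np.zeros(n, dtype=np.int64)
    prev_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = (block[1:] == block[:-1]) & ~lost[1:] & ~lost[:-1]
    rep = np.zeros(n, dtype=bool)
    rep[1:] = chosen[1:] == chosen[:-1]
    stick[prev_ok & rep] = 1

    t_idx = np.nonzero(block[1:] == block[:-1])[0]  # cross-block pairs excluded
    nxt = t_idx + 1
    valid = ~lost[t_idx] & ~lost[nxt]
    avail = (chosen[t_idx] == s_left[nxt]) | (chosen[t_idx] == s_right[nxt])
    rewarded = outcome[t_idx] == 1
    stay = chosen[nxt] == chosen[t_idx]
    winstay = np.where(valid & rewarded & avail, np.where(stay, 1, -1), 0)
    is_hp_next = ((hp[nxt] == s_left[nxt]) | (hp[nxt] == s_right[nxt])).astype(np.int64)

    return pd.DataFrame({
        "t": t_idx,
        "block": block[t_idx],
        "winstay": winstay.astype(np.int64),
        "reward": np.where(valid, regressor[t_idx], np.nan),
        "stickiness": stick[t_idx],
        "is_hp_next": is_hp_next,
        "valid": valid,
    })


@dataclass(frozen=True)
class RegressionResult:
    """Per-session (or per-block) win-stay regression coefficients."""

    intercept: float
    beta_reward: float
    beta_stickiness: float
    beta_ishp: float
    n_obs: int
    source: str = "raw_reward"
    subject: str | None = None
    condition: str | None = None
    block: object | None = None


_DESIGN_NAMES = ("reward", "stickiness", "is_hp_next")


def winstay_regression(coding: pd.DataFrame, source: str = "raw_reward",
                       min_rows: int = 8) -> RegressionResult:
    """Ordinary least squares of WinStay(t+1) on the three regressors.

    A constant (rank-deficient) regressor yields an undefined (NaN)
    coefficient with a warning rather than a crash; the remaining
    coefficients come from the reduced design.
    """
    rows = coding[coding["valid"]]
    if len(rows) < min_rows:
        raise DataError(f"need >= {min_rows} valid rows, got {len(rows)}")
    y = rows["winstay"].to_numpy(dtype=float)
    X_full = rows[list(_DESIGN_NAMES)].to_numpy(dtype=float)

    keep = [j for j in range(X_full.shape[1])
            if np.ptp(X_full[:, j]) > 0]
    dropped = [j for j in range(X_full.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(
            "constant regressor(s) dropped from win-stay design: "
            + ", ".join(_DESIGN_NAMES[j] for j in dropped))
    X = np.column_stack([np.ones(len(y))] + [X_full[:, j] for j in keep])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    betas = [np.nan, np.nan, np.nan]
    for pos, j in enumerate(keep):
        betas[j] = float(coef[1 + pos])
    return RegressionResult(
        intercept=float(coef[0]), beta_reward=betas[0],
        beta_stickiness=betas[1], beta_ishp=betas[2],
        n_obs=len(y), source=source,
    )


def winstay_betas(
    trials: pd.DataFrame,
    source: str = "raw_reward",
    latents_by_session: Mapping[tuple, LatentTrajectory] | None = None,
    per_block: bool = True,
) -> pd.DataFrame:
    """Win-stay regression coefficients per subject x condition (x block).

    For the model-based variant, pass ``latents_by_session`` keyed by
    ``(subject, condition)`` with trajectories aligned row-for-row with each
    session's trials.
    """
    rows = []
    for (subject, condition), sess in trials.groupby(["subject", "condition"], sort=True):
        sess = sess.reset_index(drop=True)
        latents = None
        if source == "model_pe":
            latents = latents_by_session[(subject, condition)]
        coding = code_winstay(sess, latents=latents, source=source)
        units = coding.groupby("block", sort=True) if per_block else [("all", coding)]
        for blk, unit in units:
            try:
                r = winstay_regression(unit, source=source)
            except DataError:
                warnings.warn(f"skipping {subject}/{condition}/block {blk}: too few valid rows")
                continue
            rows.append({
                "subject": subject, "condition": condition, "block": blk,
                "intercept": r.intercept, "beta_reward": r.beta_reward,
                "beta_stickiness": r.beta_stickiness, "beta_ishp": r.beta_ishp,
                "n_obs": r.n_obs,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Condition-level comparison (the ANOVA of Analysis A)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairResult:
    """Paired post-hoc comparison between two conditions."""

    cond_a: str
    cond_b: str
    t_stat: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohens_d: float


@dataclass(frozen=True)
class GroupComparison:
    """One-way condition ANOVA with paired post-hocs and paired Cohen's D."""

    f_stat: float
    df_between: int
    df_within: int
    p_anova: float
    pairs: tuple[PairResult, ...]
    n_subjects: int
    coefficient: str


def _paired_test(a: np.ndarray, b: np.ndarray):
    """(t, p, paired Cohen's d, df); zero-variance differences give t=0, d=0."""
    diff = a - b
    df = len(diff) - 1
    sd = diff.std(ddof=1) if len(diff) > 1 else 0.0
    if sd == 0.0:
        t, p, d = 0.0, 1.0, 0.0
    else:
        t, p = sps.ttest_rel(a, b)
        d = float(diff.mean() / sd)
    return t, p, d, df


def condition_anova(betas: pd.DataFrame, coefficient: str = "beta_reward") -> GroupComparison:
    """One-way ANOVA of a regression coefficient across conditions.

    Coefficients are first averaged over blocks within each subject x
    condition; subjects missing any condition are dropped with a warning.
    All condition pairs get two-sided paired t-tests with Bonferroni
    correction and the paired Cohen's D (mean difference over the standard
    deviation of the differences).
    """
    per_subject = (betas.groupby(["subject", "condition"], sort=False)[coefficient]
                   .mean().reset_index())
    wide = per_subject.pivot(index="subject", columns="condition", values=coefficient)
    conditions = [c for c in pd.unique(betas["condition"])]
    wide = wide[conditions]
    complete = wide.dropna()
    if len(complete) < len(wide):
        dropped = sorted(set(wide.index) - set(complete.index))
        warnings.warn(f"dropping subject(s) with missing conditions: {dropped}")
    if len(complete) < 2:
        raise DataError("need at least 2 complete subjects for the condition ANOVA")

    groups = [complete[c].to_numpy() for c in conditions]
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = sps.f_oneway(*groups)

    pair_list = list(combinations(conditions, 2))
    pairs = []
    for ca, cb in pair_list:
        t, p, d, df = _paired_test(complete[ca].to_numpy(), complete[cb].to_numpy())
        pairs.append(PairResult(
            cond_a=ca, cond_b=cb, t_stat=float(t), df=df, p_raw=float(p),
            p_bonferroni=min(1.0, len(pair_list) * float(p)), cohens_d=d))

    k = len(conditions)
    n = len(complete)
    return GroupComparison(
        f_stat=float(f_stat), df_between=k - 1, df_within=k * n - k,
        p_anova=float(p_anova), pairs=tuple(pairs), n_subjects=n,
        coefficient=coefficient,
    )


def blockwise_contrast(
    betas: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    coefficient: str = "beta_reward",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-block paired t-tests between two conditions (Analysis B).

    Deliberately uncorrected for multiple comparisons: the blocks trace a
    predefined effect over time. Blocks with fewer than 3 paired subjects
    are skipped with a warning. ``t_stat`` is for condition_a minus
    condition_b, so swapping the conditions flips every sign.
    """
    sub = betas[betas["condition"].isin([cond_a, cond_b])]
    rows = []
    for blk, unit in sub.groupby("block", sort=True):
        wide = unit.pivot_table(index="subject", columns="condition",
                                values=coefficient).dropna()
        if len(wide) < 3:
            warnings.warn(f"block {blk}: fewer than 3 paired subjects, skipped")
            continue
        t, p, d, df = _paired_test(wide[cond_a].to_numpy(), wide[cond_b].to_numpy())
        rows.append({"block": blk, "n": len(wide), "t_stat": float(t), "df": df,
                     "p": float(p), "significant": bool(p < alpha)})
    return pd.DataFrame(rows, columns=["block", "n", "t_stat", "df", "p", "significant"])


# ---------------------------------------------------------------------------
# Learning curves (Analysis C)
# ---------------------------------------------------------------------------

def learning_curve(
    trials: pd.DataFrame,
    reversal_period: int = 25,
    window: int = 5,
    source: str = "choice",
    latents: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """High-probability choice rate (or expected value) by within-period position.

    Trials are aligned on their position within a contingency period
    (``trial % reversal_period``). The ``choice`` source averages the
    indicator of choosing the high-probability symbol over the trials where
    it is on screen; the ``model`` source averages the model's expected
    value of the high-probability symbol over all trials (``latents`` must
    then be a table aligned row-for-row with ``trials`` carrying
    ``v_sym0..2``). A centred ``window``-trial running average smooths the
    curve (window 1 is the identity; edges use the truncated window). The
    standard error is across subjects, or across contingency periods for a
    single-subject input.
    """
    if window < 1:
        raise ConfigError(f"window: must be >= 1, got {window}")
    if window > reversal_period:
        raise ConfigError(
            f"window: running-average window ({window}) exceeds the reversal period ({reversal_period})")

    df = trials.reset_index(drop=True).copy()
    df["position"] = df["trial"].to_numpy(dtype=np.int64) % reversal_period

    if source == "choice":
        on_screen = (df["hp_symbol"] == df["sym_left"]) | (df["hp_symbol"] == df["sym_right"])
        mask = on_screen & ~df["lost"].astype(bool)
        df["value"] = np.where(mask, (df["chosen"] == df["hp_symbol"]).astype(float), np.nan)
    elif source == "model":
        if latents is None:
            raise DataError("source='model' requires aligned latent values")
        lat = latents.table if isinstance(latents, LatentTrajectory) else latents
        lat = lat.reset_index(drop=True)
        if len(lat) != len(df):
            raise DataError("latents not aligned with trials")
        local = (df["hp_symbol"].to_numpy(dtype=np.int64)
                 - 3 * df["block"].to_numpy(dtype=np.int64))
        v = lat[["v_sym0", "v_sym1", "v_sym2"]].to_numpy()
        df["value"] = v[np.arange(len(df)), local]
    else:
        raise DataError(f"unknown source {source!r}")

    if "subject" in df.columns and df["subject"].nunique() > 1:
        unit_key = "subject"
    else:
        # single session: use the contingency period as the averaging unit
        df["_period"] = (df["block"].astype(str) + ":"
                         + (df["trial"] // reversal_period).astype(str))
        unit_key = "_period"

    per_unit = df.groupby([unit_key, "position"])["value"].mean().unstack("position")
    per_unit = per_unit.reindex(columns=range(reversal_period))
    raw = per_unit.mean(axis=0)
    n_units = per_unit.notna().sum(axis=0)
    sem = per_unit.std(axis=0, ddof=1) / np.sqrt(n_units.clip(lower=1))

    smoothed = raw.rolling(window, center=True, min_periods=1).mean()
    return pd.DataFrame({
        "position": np.arange(reversal_period, dtype=np.int64),
        "raw": raw.to_numpy(),
        "smoothed": smoothed.to_numpy(),
        "sem": sem.to_numpy(),
    })


@dataclass(frozen=True)
class MixedModelResult:
    """Condition fixed effect from a random-intercept mixed model."""

    estimate: float
    t_stat: float
    p_value: float
    n_obs: int
    method: str  # "mixed" or "ols" (single-subject fallback)


def hp_choice_mixed_model(trials: pd.DataFrame, cond_a: str, cond_b: str) -> MixedModelResult:
    """Trial-level mixed model of high-probability choice on condition.

    Restricted to trials where the high-probability symbol is on screen,
    the binary choose-high indicator is regressed on condition (coded 0 for
    ``cond_a``, 1 for ``cond_b``) with a per-subject random intercept,
    fitted by REML. With a single subject the model degenerates to ordinary
    regression (warned). The estimate is the cond_b minus cond_a effect.
    """
    import statsmodels.api as sm

    df = trials[trials["condition"].isin([cond_a, cond_b])].copy()
    on_screen = (df["hp_symbol"] == df["sym_left"]) | (df["hp_symbol"] == df["sym_right"])
    df = df[on_screen & ~df["lost"].astype(bool)]
    if df.empty:
        raise DataError("no usable trials for the mixed model")
    y = (df["chosen"] == df["hp_symbol"]).astype(float).to_numpy()
    x = (df["condition"] == cond_b).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(y)), x])

    if df["subject"].nunique() < 2:
        warnings.warn("single subject: mixed model degenerates to ordinary regression")
        res = sm.OLS(y, X).fit()
        return MixedModelResult(float(res.params[1]), float(res.tvalues[1]),
                                float(res.pvalues[1]), len(y), "ols")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are expected
        model = sm.MixedLM(y, X, groups=df["subject"].to_numpy())
        res = model.fit(reml=True)
    return MixedModelResult(float(res.params[1]), float(res.tvalues[1]),
                            float(res.pvalues[1]), len(y), "mixed")


# ---------------------------------------------------------------------------
# Maladaptive win-stay on low-probability pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaladaptiveResult:
    """Maladaptive win-stay: repeating a rewarded low-probability choice.

    ``rates`` holds the per-subject x condition stay/switch score in
    [-1, +1] (+1 = always repeats the rewarded low-probability symbol when
    it next appears alongside the high-probability symbol, -1 = never).
    ``tests`` are per-condition one-sample t-tests against zero, and
    ``anova`` the condition-level comparison of the rates.
    """

    rates: pd.DataFrame
    tests: pd.DataFrame
    anova: GroupComparison | None


def _maladaptive_codes(sess: pd.DataFrame) -> list[int]:
    block = sess["block"].to_numpy(dtype=np.int64)
    s_left = sess["sym_left"].to_numpy(dtype=float)
    s_right = sess["sym_right"].to_numpy(dtype=float)
    chosen = sess["chosen"].to_numpy(dtype=float)
    outcome = sess["outcome"].to_numpy(dtype=float)
    lost = sess["lost"].to_numpy(dtype=bool)
    hp = sess["hp_symbol"].to_numpy(dtype=float)
    n = len(block)

    codes = []
    for t in range(n):
        if lost[t] or outcome[t] != 1:
            continue
        if hp[t] in (s_left[t], s_right[t]):
            continue  # both shown symbols must be low-probability
        s = chosen[t]
        for u in range(t + 1, n):
            if block[u] != block[t]:
                break
            if lost[u]:
                continue
            pair_u = (s_left[u], s_right[u])
            if s in pair_u and hp[u] in pair_u:
                codes.append(1 if chosen[u] == s else -1)
                break
    return codes


def maladaptive_winstay(trials: pd.DataFrame) -> MaladaptiveResult:
    """Rate of repeating a rewarded low-probability choice against the better option.

    Qualifying events are trials where both shown symbols carry the low
    reward probability and the choice was rewarded; the score records
    whether the same symbol is chosen again on the next trial where it
    appears together with the high-probability symbol. Subjects with no
    qualifying events in a condition are excluded with a warning.
    """
    rows = []
    for (subject, condition), sess in trials.groupby(["subject", "condition"], sort=True):
        codes = _maladaptive_codes(sess.reset_index(drop=True))
        if not codes:
            warnings.warn(f"{subject}/{condition}: no maladaptive win-stay events, excluded")
            continue
        rows.append({"subject": subject, "condition": condition,
                     "rate": float(np.mean(codes)), "n_events": len(codes)})
    rates = pd.DataFrame(rows, columns=["subject", "condition", "rate", "n_events"])
    if rates.empty:
        raise DataError("no maladaptive win-stay events in the dataset")

    tests = []
    for cond, unit in rates.groupby("condition", sort=False):
        vals = unit["rate"].to_numpy()
        if len(vals) > 1 and vals.std(ddof=1) > 0:
            t, p = sps.ttest_1samp(vals, 0.0)
        else:
            t, p = (0.0, 1.0) if np.allclose(vals, 0) else (np.inf * np.sign(vals.mean()), 0.0)
        tests.append({"condition": cond, "t_stat": float(t), "df": len(vals) - 1,
                      "p": float(p), "mean_rate": float(vals.mean())})
    tests = pd.DataFrame(tests)

    anova = None
    if rates["condition"].nunique() >= 2:
        try:
            anova = condition_anova(rates.assign(block=0), coefficient="rate")
        except DataError:
            anova = None
    return MaladaptiveResult(rates=rates, tests=tests, anova=anova)


# ---------------------------------------------------------------------------
# Exploratory metrics
# ---------------------------------------------------------------------------

def exploratory_metrics(trials: pd.DataFrame, reversal_period: int = 25,
                        post_window: int = 10, persev_window: int = 5) -> pd.DataFrame:
    """Post-learning accuracy, perseveration errors, and post-error adjustment.

    Per subject x condition:

    - ``post_learning_acc``: high-probability choice rate over the last
      ``post_window`` trials of each contingency period (on trials where the
      symbol is shown); the window truncates, with a warning, in periods
      shorter than the window.
    - ``perseveration``: rate of choosing the immediately-previous
      high-probability symbol when it is shown together with the new
      high-probability symbol during the first ``persev_window`` trials
      after a reversal.
    - ``post_error_adjustment``: switch rate on trials following a
      non-reward (previous choice available again); ``overall_switch`` is
      the unconditional switch rate for reference.

    Metrics with no qualifying trials are reported as NaN (missing).
    """
    rows = []
    truncated = False
    for (subject, condition), sess in trials.groupby(["subject", "condition"], sort=True):
        sess = sess.reset_index(drop=True)
        block = sess["block"].to_numpy(dtype=np.int64)
        wtrial = sess["trial"].to_numpy(dtype=np.int64)
        s_left = sess["sym_left"].to_numpy(dtype=float)
        s_right = sess["sym_right"].to_numpy(dtype=float)
        chosen = sess["chosen"].to_numpy(dtype=float)
        outcome = sess["outcome"].to_numpy(dtype=float)
        lost = sess["lost"].to_numpy(dtype=bool)
        hp = sess["hp_symbol"].to_numpy(dtype=float)
        n = len(block)

        period = wtrial // reversal_period
        pos = wtrial % reversal_period
        # length of each period: full, except a possibly truncated block tail
        block_len = {b: int(wtrial[block == b].max()) + 1 for b in np.unique(block)}
        plen = np.minimum(reversal_period,
                          np.array([block_len[b] for b in block]) - period * reversal_period)
        if (plen < post_window).any():
            truncated = True

        on_screen = (hp == s_left) | (hp == s_right)
        usable = ~lost & ~np.isnan(chosen)

        late = usable & on_screen & (pos >= plen - post_window)
        post_learning = float(np.mean(chosen[late] == hp[late])) if late.any() else np.nan

        # previous high-probability symbol for perseveration scoring
        prev_hp = np.full(n, np.nan)
        for t in range(1, n):
            if block[t] == block[t - 1] and hp[t] != hp[t - 1]:
                start = t
                old = hp[t - 1]
                end = min(n, t + reversal_period)
                for u in range(start, end):
                    if block[u] != block[t]:
                        break
                    if hp[u] != hp[t]:
                        break
                    prev_hp[u] = old
        # perseveration is scored on conflict trials only: the old and the
        # new high-probability symbols shown together
        early = usable & (pos < persev_window) & (period > 0)
        persev_mask = (early & ((prev_hp == s_left) | (prev_hp == s_right))
                       & ((hp == s_left) | (hp == s_right)))
        perseveration = (float(np.mean(chosen[persev_mask] == prev_hp[persev_mask]))
                         if persev_mask.any() else np.nan)

        post_err, overall = [], []
        for t in range(n - 1):
            if block[t + 1] != block[t] or lost[t] or lost[t + 1]:
                continue
            if chosen[t] not in (s_left[t + 1], s_right[t + 1]):
                continue
            switch = chosen[t + 1] != chosen[t]
            overall.append(switch)
            if outcome[t] == 0:
                post_err.append(switch)
        rows.append({
            "subject": subject, "condition": condition,
            "post_learning_acc": post_learning,
            "perseveration": perseveration,
            "post_error_adjustment": float(np.mean(post_err)) if post_err else np.nan,
            "overall_switch": float(np.mean(overall)) if overall else np.nan,
        })
    if truncated:
        warnings.warn("post-learning window truncated in periods shorter than the window")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-group rank test
# ---------------------------------------------------------------------------

def rank_test_groups(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two independent groups.

    Uses exact enumeration when both groups are small (n <= 8, no ties) and
    the tie-corrected normal approximation otherwise. Returns the U
    statistic of ``group_a`` and the two-sided p value.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
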