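"""Propensity estimation, greedy caliper matching, and balance diagnostics.

Propensity scores come from a maximum-likelihood logistic regression of
treatment on the configured covariates.  Matching is 1:1 greedy nearest
neighbor on the logit of the score, without replacement, with a caliper of
``caliper_multiplier`` times the standard deviation of the pooled logit
scores; treated subjects are processed in a seed-shuffled order and distance
ties go to the lower comparator id.  Balance is summarized as standardized
mean differences before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import GROUP_TREATMENT


@dataclass
class PropensityModel:
    coefficients: pd.Series  # intercept + per-covariate
    standard_errors: pd.Series
    covariate_names: list
    subject_ids: np.ndarray
    treated: np.ndarray  # boolean, aligned with subject_ids
    scores: np.ndarray  # fitted P(treatment | x), in (0, 1)
    logits: np.ndarray
    converged: bool


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame  # treated_id, comparator_id, distance
    caliper_value: float
    n_unmatched_treated: int
    n_unmatched_comparator: int

    @property
    def matched_ids(self) -> np.ndarray:
        return np.concatenate(
            [self.pairs["treated_id"].to_numpy(), self.pairs["comparator_id"].to_numpy()]
        )


class SeparationError(RuntimeError):
    pass


def _separating_covariates(x: pd.DataFrame, y: np.ndarray) -> list:
    out = []
    for c in x.columns:
        t, u = x.loc[y, c], x.loc[~y, c]
        if t.min() > u.max() or u.min() > t.max():
            out.append(c)
    return out


def estimate_propensity(cohort: pd.DataFrame, covariate_names) -> PropensityModel:
    """Fit the treatment logit; constant covariates are dropped with a warning,
    perfect separation raises :class:`SeparationError` naming the covariate."""
    covariate_names = list(covariate_names)
    y = (cohort["group"] == GROUP_TREATMENT).to_numpy()
    if y.all() or not y.any():
        raise ValueError("need at least one subject in each group")
    x = cohort[covariate_names].astype(float).reset_index(drop=True)
    keep = [c for c in covariate_names if x[c].nunique() > 1]
    dropped = sorted(set(covariate_names) - set(keep))
    if dropped:
        warnings.warn(f"dropping constant covariates from the propensity model: {dropped}")
    x = x[keep]
    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y.astype(float), design).fit(disp=0, maxiter=200, tol=1e-10)
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as exc:
        culprits = _separating_covariates(x, y)
        raise SeparationError(
            f"perfect separation in the propensity model (covariates: {culprits or 'joint'})"
        ) from exc
    if np.abs(res.params).max() > 30:
        culprits = _separating_covariates(x, y)
        if culprits:
            raise SeparationError(
                f"perfect separation in the propensity model (covariates: {culprits})"
            )
    logits = np.asarray(design @ res.params, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    return PropensityModel(
        coefficients=res.params,
        standard_errors=res.bse,
        covariate_names=keep,
        subject_ids=cohort["patient_id"].to_numpy(),
        treated=y,
        scores=1.0 / (1.0 + np.exp(-logits)),
        logits=logits,
        converged=converged,
    )


def match_nearest_neighbor(
    model: PropensityModel, caliper_multiplier: float = 0.2, seed: int = 0
) -> MatchedCohort:
    """1:1 greedy nearest-neighbor caliper matching without replacement."""
    if caliper_multiplier <= 0:
        raise ValueError("caliper_multiplier must be positive")
    caliper = caliper_multiplier * float(np.std(model.logits, ddof=1))

    t_ids = model.subject_ids[model.treated]
    t_logit = model.logits[model.treated]
    c_ids = model.subject_ids[~model.treated]
    c_logit = model.logits[~model.treated]

    # comparators in (logit, id) order; removals tracked by path-compressed
    # skip pointers so nearest-alive lookups stay near O(1)
    order = np.lexsort((c_ids, c_logit))
    c_ids, c_logit = c_ids[order], c_logit[order]
    m = len(c_ids)
    alive = np.ones(m, dtype=bool)
    right = list(range(m + 1))  # right[i]: smallest alive index >= i (m = none)
    left = list(range(-1, m))  # left[i+1]: largest alive index <= i (-1 = none)

    def find_right(i):
        while i < m and right[i] != i:
            right[i] = right[right[i]]
            i = right[i]
        return i

    def find_left(i):
        while i >= 0 and left[i + 1] != i:
            left[i + 1] = left[left[i + 1] + 1]
            i = left[i + 1]
        return i

    rng = np.random.default_rng(seed)
    rows = []
    for k in rng.permutation(len(t_ids)):
        tl = t_logit[k]
        pos = int(np.searchsorted(c_logit, tl))
        li = find_left(pos - 1)
        ri = find_right(pos)
        cands = []
        if li >= 0:
            cands.append((abs(tl - c_logit[li]), li))
        if ri < m:
            cands.append((abs(tl - c_logit[ri]), ri))
        if not cands:
            continue
        best_d = min(d for d, _ in cands)
        if best_d > caliper:
            continue
        # collect every alive comparator at exactly best_d; tie -> lowest id
        tied = []
        for d, i in cands:
            if d == best_d:
                tied.append(i)
                # walk runs of equal logit adjacent to the candidate
                j = i - 1
                while j >= 0 and c_logit[j] == c_logit[i]:
                    if alive[j]:
                        tied.append(j)
                    j -= 1
                j = i + 1
                while j < m and c_logit[j] == c_logit[i]:
                    if alive[j]:
                        tied.append(j)
                    j += 1
        pick = min(tied, key=lambda i: c_ids[i])
        alive[pick] = False
        right[pick] = pick + 1
        left[pick + 1] = pick - 1
        rows.append((t_ids[k], c_ids[pick], best_d))

    pairs = pd.DataFrame(rows, columns=["treated_id", "comparator_id", "distance"])
    return MatchedCohort(
        pairs=pairs,
        caliper_value=caliper,
        n_unmatched_treated=len(t_ids) - len(pairs),
        n_unmatched_comparator=m - len(pairs),
    )


def balance_diagnostics(
    matched: MatchedCohort, cohort: pd.DataFrame, covariate_names
) -> pd.DataFrame:
    """Standardized mean differences per covariate, pre- and post-match.

    SMD = (mean_T - mean_C) / sqrt((var_T + var_C)/2); a zero pooled SD is
    reported as SMD 0 with ``zero_sd`` flagged.
    """
    if matched.pairs.empty:
        raise ValueError("empty matching: no balance to diagnose")

    def smds(frame: pd.DataFrame) -> list:
        t = frame[frame["group"] == GROUP_TREATMENT]
        c = frame[frame["group"] != GROUP_TREATMENT]
        out = []
        for cov in covariate_names:
            pooled = np.sqrt((t[cov].var(ddof=1) + c[cov].var(ddof=1)) / 2.0)
            if not np.isfinite(pooled) or pooled == 0.0:
                out.append((0.0, True))
            else:
                out.append(((t[cov].mean() - c[cov].mean()) / pooled, False))
        return out

    post = cohort[cohort["patient_id"].isin(matched.matched_ids)]
    before, after = smds(cohort), smds(post)
    return pd.DataFrame({
        "covariate": list(covariate_names),
        "smd_before": [b for b, _ in before],
        "smd_after": [a for a, _ in after],
        "zero_sd": [fb or fa for (_, fb), (_, fa) in zip(before, after)],
    })
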