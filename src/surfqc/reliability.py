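"""Inter-rater agreement: Spearman correlations, two-way agreement ICC, consensus flags.

The reliability statistic is the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(A,1): participants and raters are
both treated as random samples and systematic rater offsets count against
agreement. From the two-way ANOVA mean squares (MSR between participants,
MSC between raters, MSE residual), with n participants and k raters,

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

The average-measure variant ICC(A,k) is available for users whose unit of
analysis is the mean over their rater panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DegenerateInputError, IntegrityError


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman_rho(x, y, exact_p: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties, plus a p-value.

    The p-value uses the standard large-sample t approximation; for n <= 10
    ``exact_p=True`` computes the exact permutation p over all n! orderings.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise AlignmentError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise IntegrityError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if exact_p:
        if len(x) > 10:
            raise DegenerateInputError("exact permutation p only for n <= 10")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def pairwise_rater_matrix(matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Rater x rater Spearman matrix on pairwise-complete participants.

    Symmetric with unit diagonal; pairs sharing fewer than ``min_shared``
    participants are left NaN (flagged missing).
    """
    raters = list(matrix.columns)
    if len(raters) < 2:
        raise AlignmentError("need >= 2 raters")
    out = pd.DataFrame(np.eye(len(raters)), index=raters, columns=raters)
    for a, b in itertools.combinations(raters, 2):
        pair = matrix[[a, b]].dropna()
        if len(pair) < min_shared:
            rho = np.nan
        else:
            try:
                rho, _ = spearman_rho(pair[a], pair[b])
            except DegenerateInputError:
                rho = np.nan
        out.loc[a, b] = out.loc[b, a] = rho
    return out


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    value: float
    n_participants: int
    n_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    variant: str
    degenerate: bool


def icc_two_way_agreement(matrix: pd.DataFrame, average_measure: bool = False) -> ICCResult:
    """Two-way random-effects absolute-agreement ICC from a participants x raters grid.

    Default is the single-measure ICC(A,1); ``average_measure=True`` gives
    ICC(A,k). The matrix must be complete. Zero between-participant variance
    is reported with a degenerate flag rather than raised, since the value is
    still defined.
    """
    data = matrix.to_numpy(float)
    if np.isnan(data).any():
        raise IntegrityError("ICC requires a complete participants x raters matrix")
    n, k = data.shape
    if k < 2 or n < 3:
        raise AlignmentError("ICC needs >= 2 raters and >= 3 participants")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if average_measure:
        denom = msr + (msc - mse) / n
        variant = "ICC(A,k)"
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        variant = "ICC(A,1)"
    degenerate = msr <= mse or denom <= 0
    value = float((msr - mse) / denom) if denom != 0 else 0.0
    return ICCResult(
        value=value,
        n_participants=n,
        n_raters=k,
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        variant=variant,
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Consensus workflow
# ---------------------------------------------------------------------------


def consensus_flags(
    scores_a: pd.Series, scores_b: pd.Series, threshold: float = 1.0
) -> pd.DataFrame:
    """Participants whose two raters disagree by strictly more than ``threshold``.

    Flagged participants are the ones whose images get discussed to a
    consensus before rating continues; a discrepancy of exactly the threshold
    is not flagged (strict inequality).
    """
    a = pd.Series(scores_a)
    b = pd.Series(scores_b)
    if not a.index.equals(b.index):
        if len(a) == len(b) and set(a.index) == set(b.index):
            b = b.reindex(a.index)
        else:
            raise AlignmentError("score lists do not cover the same participants")
    disc = (a - b).abs()
    flagged = disc[disc > threshold]
    return pd.DataFrame(
        {
            "subject_id": flagged.index,
            "score_a": a.loc[flagged.index].to_numpy(),
            "score_b": b.loc[flagged.index].to_numpy(),
            "discrepancy": flagged.to_numpy(),
        }
    ).reset_index(drop=True)


def reliability_report(matrix: pd.DataFrame, consensus_threshold: float = 1.0) -> dict:
    """Bundle the pairwise Spearman matrix, ICC(A,1) and first-two-rater flags."""
    pw = pairwise_rater_matrix(matrix)
    complete = matrix.dropna()
    icc = icc_two_way_agreement(complete) if len(complete) >= 3 else None
    flags = None
    if matrix.shape[1] >= 2:
        a, b = matrix.columns[:2]
        pair = matrix[[a, b]].dropna()
        flags = consensus_flags(pair[a], pair[b], consensus_threshold)
    return {
        "pairwise_spearman": pw.to_dict(),
        "icc": None
        if icc is None
        else {
            "value": icc.value,
            "variant": icc.variant,
            "n_participants": icc.n_participants,
            "n_raters": icc.n_raters,
            "degenerate": icc.degenerate,
        },
        "consensus_flags": None if flags is None else flags.to_dict(orient="records"),
    }
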