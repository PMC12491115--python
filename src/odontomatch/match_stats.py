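"""Match/non-match decision statistics on RMS comparison tables.

The identification decision reduces to a single threshold on the RMS: pairs
below the cutoff are called matches.  On well-separated data the logistic
maximum-likelihood estimate diverges (perfect separation), so separation is
detected explicitly and the reported cutoff falls back to the midpoint
between the two classes' nearest values — a reproducible, honest behaviour
rather than a numerically unstable coefficient ratio.

Also provided: the Box-Cox profile-likelihood power selection used to
normalize RMS values before parametric modelling, and Bonferroni-adjusted
pairwise Welch comparisons of method means within matching / non-matching
strata.  Full mixed-effects modelling is intentionally out of scope: the CSV
record table is shaped so external statistics environments can fit it
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "CutoffResult",
    "BoxCoxResult",
    "fit_rms_cutoff",
    "classify_match",
    "boxcox_lambda",
    "pairwise_bonferroni",
]

#: default significance level for pairwise comparisons
ALPHA = 0.05


@dataclass
class CutoffResult:
    """Fitted RMS decision threshold (mm) and its training accuracy."""

    cutoff: float
    accuracy: float
    mode: str  # "midpoint" or "logistic"
    separable: bool


@dataclass
class BoxCoxResult:
    """Selected Box-Cox power and its profile log-likelihood."""

    lmbda: float
    log_likelihood: float
    grid: np.ndarray


def _split_classes(rms, is_match):
    rms = np.asarray(rms, float).ravel()
    is_match = np.asarray(is_match, bool).ravel()
    if rms.shape != is_match.shape:
        raise ValueError("rms and is_match must have equal lengths")
    m, n = rms[is_match], rms[~is_match]
    if len(m) == 0 or len(n) == 0:
        raise ValueError("both matching and non-matching values are required")
    return rms, is_match, m, n


def _accuracy_at(rms, is_match, cutoff) -> float:
    pred = rms < cutoff
    return float(np.mean(pred == is_match))


def _best_threshold(rms, is_match):
    """Accuracy-maximizing threshold; ties resolve to the smaller one."""
    values = np.unique(rms)
    # candidates: below the smallest value and midpoints between neighbours,
    # plus above the largest (predict-all-match)
    cand = np.concatenate([[values[0] - 1.0],
                           0.5 * (values[:-1] + values[1:]),
                           [values[-1] + 1.0]])
    accs = np.array([_accuracy_at(rms, is_match, c) for c in cand])
    best = int(np.argmax(accs))  # argmax takes the first (smallest) on ties
    return float(cand[best]), float(accs[best])


def fit_rms_cutoff(rms, is_match, mode: str = "midpoint") -> CutoffResult:
    """Fit the RMS decision threshold separating matches from non-matches.

    ``midpoint``: when the classes separate perfectly, the cutoff is the
    midpoint between the largest matching and smallest non-matching RMS;
    otherwise the accuracy-maximizing threshold.  ``logistic``: univariate
    logistic regression; under perfect separation (diverging coefficient) the
    result is flagged ``separable`` and the midpoint rule is reported instead,
    else the cutoff is the point of predicted probability 0.5.
    """
    if mode not in ("midpoint", "logistic"):
        raise ValueError("mode must be 'midpoint' or 'logistic'")
    rms, is_match, m, n = _split_classes(rms, is_match)
    separable = float(m.max()) < float(n.min())
    if separable:
        cutoff = 0.5 * (float(m.max()) + float(n.min()))
        return CutoffResult(cutoff, _accuracy_at(rms, is_match, cutoff),
                            mode, True)
    if mode == "midpoint":
        cutoff, acc = _best_threshold(rms, is_match)
        return CutoffResult(cutoff, acc, mode, False)
    # logistic fit on overlapping classes
    import statsmodels.api as sm
    X = sm.add_constant(rms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(is_match.astype(float), X).fit(disp=0, maxiter=200)
    b0, b1 = fit.params
    if not np.all(np.isfinite(fit.params)) or abs(b1) > 1e3 or b1 >= 0:
        # quasi-separation or a degenerate slope: fall back to the scan
        cutoff, acc = _best_threshold(rms, is_match)
        return CutoffResult(cutoff, acc, mode, False)
    cutoff = float(-b0 / b1)
    return CutoffResult(cutoff, _accuracy_at(rms, is_match, cutoff), mode, False)


def classify_match(rms: float, cutoff: float) -> str:
    """Classify one RMS value against a cutoff.

    A pair is a ``"match"`` iff ``rms < cutoff``; the boundary value counts
    as ``"non-match"`` (fail-safe toward non-identification).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if rms < 0:
        raise ValueError("rms must be >= 0")
    return "match" if rms < cutoff else "non-match"


def boxcox_lambda(x, grid_start: float = -3.0, grid_stop: float = 3.0,
                  grid_step: float = 0.01) -> BoxCoxResult:
    """Select the Box-Cox power by profile log-likelihood over a grid.

    The family is ``(x**λ − 1)/λ`` (``log x`` at λ=0); the profile
    log-likelihood includes the Jacobian term ``(λ−1)·Σ log x`` and is
    maximized over λ ∈ [-3, 3] in steps of 0.01 by default.
    """
    x = np.asarray(x, float).ravel()
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    grid = np.arange(grid_start, grid_stop + grid_step / 2, grid_step)
    llf = np.array([sstats.boxcox_llf(l, x) for l in grid])
    best = int(np.argmax(llf))
    return BoxCoxResult(float(grid[best]), float(llf[best]), grid)


def _sd_observations(table: pd.DataFrame) -> pd.DataFrame:
    """Per-pairing replicate SDs as observations (for the SD response)."""
    keys = ["participant_a", "participant_b", "arch", "method",
            "operator", "session", "is_match"]
    sd = (table.groupby(keys)["rms"]
                .agg(lambda v: v.std(ddof=1) if len(v) > 1 else np.nan)
                .rename("value").reset_index())
    return sd.dropna(subset=["value"])


def pairwise_bonferroni(table: pd.DataFrame, response: str = "rms") -> pd.DataFrame:
    """Pairwise method mean differences with Bonferroni-adjusted Welch tests.

    ``response`` is ``"rms"`` (the raw record RMS) or ``"sd"`` (per-pairing
    replicate standard deviations).  Comparisons are computed separately
    within the matching and non-matching strata; each raw p-value is
    multiplied by the number of pairwise comparisons in its stratum and
    capped at 1.
    """
    if response not in ("rms", "sd"):
        raise ValueError("response must be 'rms' or 'sd'")
    if "error" in table:
        table = table[table["error"].isna()]
    if response == "sd":
        obs = _sd_observations(table)
    else:
        obs = table.rename(columns={"rms": "value"})[
            ["method", "is_match", "value"]]
    methods = sorted(obs["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    rows = []
    for stratum in (True, False):
        sub = obs[obs["is_match"] == stratum]
        pairs = list(combinations(methods, 2))
        k = len(pairs)
        for a, b in pairs:
            va = sub.loc[sub["method"] == a, "value"].to_numpy()
            vb = sub.loc[sub["method"] == b, "value"].to_numpy()
            row = dict(is_match=stratum, method_a=a, method_b=b,
                       n_a=len(va), n_b=len(vb))
            if len(va) < 2 or len(vb) < 2:
                row.update(mean_diff=np.nan, t=np.nan, p_raw=np.nan,
                           p_adj=np.nan, error="insufficient observations")
            elif np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
                # identical constant samples: no difference, nothing to test
                row.update(mean_diff=0.0, t=0.0, p_raw=1.0, p_adj=1.0,
                           error=None)
            else:
                t, p = sstats.ttest_ind(va, vb, equal_var=False)
                row.update(mean_diff=float(va.mean() - vb.mean()),
                           t=float(t), p_raw=float(p),
                           p_adj=float(min(1.0, p * k)), error=None)
            rows.append(row)
    return pd.DataFrame(rows)
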