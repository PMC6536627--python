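"""Template-pattern classification of stress-responsive transcripts.

Within each strain, each transcript is fit against two predicted response
templates over the ordered treatment groups (CMS, CMS-R, NH-R):

* ``TRANSIENT`` — 0:1:0, expression responds only when an acute challenge
  follows chronic stress;
* ``SUSTAINED`` — 1:1:0, expression responds to chronic stress regardless
  of the acute challenge.

Down-regulation is the inverse pattern (1:0:1 / 0:0:1), which under the
single-indicator linear model used here is exactly the same fit with a
negated slope.  A transcript is called stress-responsive in a strain when
its best template fit reaches nominal significance, the Welch contrast
between NH-R and CMS-R is significant, and the linear-scale expression
change between those groups exceeds the fold-change threshold in the
direction of the fitted slope.  Benjamini–Hochberg q-values are reported
per strain for reference but do not gate the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import TEMPLATE_GROUPS

SHAPES = ("TRANSIENT", "SUSTAINED")

#: indicator value per template group, up-orientation
SHAPE_CODES = {"TRANSIENT": {"CMS": 0, "CMS-R": 1, "NH-R": 0},
               "SUSTAINED": {"CMS": 1, "CMS-R": 1, "NH-R": 0}}


@dataclass
class TemplateFit:
    """Result of one transcript-by-template linear-model fit."""

    beta: float
    t: float
    df: int
    p: float
    transcript: str | None = None
    strain: str | None = None
    shape: str | None = None
    q: float | None = None


@dataclass
class DirectionCounts:
    """Up/down counts for one strain with a 50:50 goodness-of-fit test."""

    strain: str
    n_up: int
    n_down: int
    chi2: float
    p: float


def encode_template(samples: pd.DataFrame, strain: str, shape: str) -> pd.Series:
    """Binary template indicator for one strain's non-NH samples.

    Returns a 0/1 Series indexed by sample id, ordered by treatment group
    (CMS, CMS-R, NH-R) and within group by appearance in ``samples``.
    The NH group takes no part in template fitting.

    Raises
    ------
    ValueError
        If the shape is unknown, or the strain is missing a template
        group or has fewer than two samples in one.
    """
    if shape not in SHAPE_CODES:
        raise ValueError(f"unknown template shape {shape!r}")
    sub = samples[samples["strain"] == strain]
    if sub.empty:
        raise ValueError(f"strain {strain!r} not present in sample table")
    ids: list[str] = []
    codes: list[int] = []
    for group in TEMPLATE_GROUPS:
        members = sub[sub["treatment"] == group]
        if len(members) < 2:
            raise ValueError(
                f"strain {strain!r} needs >= 2 samples in group {group!r}, "
                f"found {len(members)}"
            )
        ids.extend(members["sample_id"])
        codes.extend([SHAPE_CODES[shape][group]] * len(members))
    return pd.Series(codes, index=pd.Index(ids, name="sample_id"), name=shape)


def _fit_arrays(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Vectorised OLS of each row of Y on the binary indicator x.

    Equivalent to the pooled-variance two-sample t-test grouping each row
    by x (slope = mean difference, t identical).  Rows with zero total
    variance return beta 0, t 0, p 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.all(x == x[0]):
        raise ValueError("template indicator is constant; cannot fit")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    xc = x - x.mean()
    sxx = float(xc @ xc)
    beta = (Y @ xc) / sxx
    fitted_delta = beta[:, None] * xc[None, :]
    resid = (Y - Y.mean(axis=1, keepdims=True)) - fitted_delta
    rss = np.einsum("ij,ij->i", resid, resid)
    df = n - 2
    sigma2 = rss / df
    tot = np.einsum("ij,ij->i", Y - Y.mean(axis=1, keepdims=True),
                    Y - Y.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / sxx)
    flat = tot == 0.0
    beta = np.where(flat, 0.0, beta)
    t = np.where(flat, 0.0, t)
    # exact fit with non-zero slope: infinite t, p -> 0
    with np.errstate(invalid="ignore"):
        t = np.where((sigma2 == 0.0) & ~flat, np.sign(beta) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(flat, 1.0, p)
    return beta, t, df, p


def fit_template(y, x) -> TemplateFit:
    """Fit expression values to a binary template indicator by OLS.

    The two-sided t-test on the slope (df = n - 2) is numerically
    identical to a pooled-variance two-sample t-test grouping ``y`` by
    ``x``.  A zero-variance ``y`` returns beta 0, p 1 (non-responsive by
    convention); a constant ``x`` is a precondition error.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or y.size != x.size:
        raise ValueError("y and x must be 1-D of equal length")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    beta, t, df, p = _fit_arrays(y[None, :], x)
    return TemplateFit(beta=float(beta[0]), t=float(t[0]), df=df, p=float(p[0]))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_arrays(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t and two-sided p with degenerate-variance handling."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        t, p = np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)
    diff = A.mean(axis=1) - B.mean(axis=1)
    bad = ~np.isfinite(p)
    with np.errstate(invalid="ignore"):
        p = np.where(bad, np.where(diff == 0.0, 1.0, 0.0), p)
        t = np.where(bad, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    return t, p


def contrast_nhr_cmsr(y_nhr, y_cmsr) -> tuple[float, float]:
    """Welch contrast between the NH-R and CMS-R groups of one transcript.

    Returns ``(p, relative_change)`` where the relative change is on the
    linear scale: ``2**(mean_log2_CMSR - mean_log2_NHR) - 1``, so +1.0 is
    a doubling and -0.5 a halving.
    """
    y_nhr = np.asarray(y_nhr, dtype=float)
    y_cmsr = np.asarray(y_cmsr, dtype=float)
    if y_nhr.size < 2 or y_cmsr.size < 2:
        raise ValueError("need >= 2 values per group for the Welch contrast")
    _, p = _welch_arrays(y_cmsr[None, :], y_nhr[None, :])
    rel = 2.0 ** (y_cmsr.mean() - y_nhr.mean()) - 1.0
    return float(p[0]), float(rel)


def call_stress_transcripts(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 0.10,
) -> pd.DataFrame:
    """Call stress-responsive transcripts per strain.

    Parameters
    ----------
    matrix : DataFrame
        Log2 expression, transcripts x samples.
    samples : DataFrame
        Sample metadata with columns sample_id, strain, treatment; every
        matrix column must be present.
    alpha : float
        Nominal significance threshold for the template fit (<=) and the
        NH-R vs CMS-R Welch contrast (<).
    fc_threshold : float
        Linear-scale relative-change threshold, strict inequality.

    Returns
    -------
    DataFrame with one row per (transcript, strain): shape, direction,
    template_p, q (BH within strain), contrast_p, rel_change, passes.
    Both shapes are fit; the reported shape is the smaller template p,
    ties broken by larger absolute t, then TRANSIENT.
    """
    missing = set(matrix.columns) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"matrix columns missing from sample table: {sorted(missing)[:5]}")
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    frames = []
    for strain in pd.unique(samples["strain"]):
        x_by_shape = {shape: encode_template(samples, strain, shape) for shape in SHAPES}
        order = x_by_shape["TRANSIENT"].index
        Y = matrix.loc[:, order].to_numpy()
        beta_t, t_t, _, p_t = _fit_arrays(Y, x_by_shape["TRANSIENT"].to_numpy())
        beta_s, t_s, _, p_s = _fit_arrays(Y, x_by_shape["SUSTAINED"].to_numpy())
        pick_s = (p_s < p_t) | ((p_s == p_t) & (np.abs(t_s) > np.abs(t_t)))
        shape = np.where(pick_s, "SUSTAINED", "TRANSIENT")
        beta = np.where(pick_s, beta_s, beta_t)
        template_p = np.where(pick_s, p_s, p_t)
        direction = np.where(beta >= 0, "UP", "DOWN")

        nhr_cols = samples.loc[
            (samples["strain"] == strain) & (samples["treatment"] == "NH-R"), "sample_id"
        ]
        cmsr_cols = samples.loc[
            (samples["strain"] == strain) & (samples["treatment"] == "CMS-R"), "sample_id"
        ]
        A = matrix.loc[:, cmsr_cols].to_numpy()
        B = matrix.loc[:, nhr_cols].to_numpy()
        _, contrast_p = _welch_arrays(A, B)
        rel = 2.0 ** (A.mean(axis=1) - B.mean(axis=1)) - 1.0

        sign_ok = np.where(direction == "UP", rel > 0, rel < 0)
        passes = (
            (template_p <= alpha)
            & (contrast_p < alpha)
            & (np.abs(rel) > fc_threshold)
            & sign_ok
        )
        frames.append(
            pd.DataFrame(
                {
                    "transcript": matrix.index,
                    "strain": strain,
                    "shape": shape,
                    "direction": direction,
                    "template_p": template_p,
                    "q": bh_adjust(template_p),
                    "contrast_p": contrast_p,
                    "rel_change": rel,
                    "passes": passes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def direction_bias_test(calls: pd.DataFrame, strain: str) -> DirectionCounts:
    """Chi-square goodness-of-fit of a strain's up/down call split vs 50:50.

    The 1-df statistic is (n_up - n_down)^2 / (n_up + n_down) with a
    two-sided p from the chi-square upper tail.
    """
    sub = calls[(calls["strain"] == strain) & calls["passes"]]
    n_up = int((sub["direction"] == "UP").sum())
    n_down = int((sub["direction"] == "DOWN").sum())
    total = n_up + n_down
    if total == 0:
        raise ValueError(f"no passing calls for strain {strain!r}; test undefined")
    chi2 = (n_up - n_down) ** 2 / total
    p = float(stats.chi2.sf(chi2, df=1))
    return DirectionCounts(strain=strain, n_up=n_up, n_down=n_down, chi2=float(chi2), p=p)


def direction_counts_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Direction-bias test for every strain with at least one passing call."""
    rows = []
    for strain in pd.unique(calls["strain"]):
        sub = calls[(calls["strain"] == strain) & calls["passes"]]
        if sub.empty:
            continue
        r = direction_bias_test(calls, strain)
        rows.append({"strain": r.strain, "n_up": r.n_up, "n_down": r.n_down,
                     "chi2": r.chi2, "p": r.p})
    return pd.DataFrame(rows, columns=["strain", "n_up", "n_down", "chi2", "p"])
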