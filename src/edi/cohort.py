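"""Cohort-level analyses downstream of the EDI score.

Dichotomisation (EDI = 5 is "high", 1-4 "low"), Kaplan-Meier / log-rank
survival comparison, Cox proportional-hazards models, the three-level
EDI + TP53 prognostic index, Fisher's-exact copy-number enrichment, and a
Pearson expression screen with tail-area (Storey-type) q-values.

Survival machinery is delegated to lifelines (Efron handling of tied event
times); Fisher's exact test to scipy; Benjamini-Hochberg adjustment to
statsmodels.  The q-value estimator is implemented here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.interpolate import UnivariateSpline
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


def dichotomize_edi(scores) -> np.ndarray:
    """Map EDI scores to subtype labels: 5 -> "high", 1-4 -> "low"."""
    s = np.asarray(scores)
    if not np.isin(s, [1, 2, 3, 4, 5]).all():
        bad = s[~np.isin(s, [1, 2, 3, 4, 5])]
        raise ValueError(f"EDI scores must be integers 1..5 (got {bad[:5]!r})")
    return np.where(s == 5, "high", "low")


def km_logrank(times, events, groups) -> dict:
    """Kaplan-Meier curves per group and a log-rank test across groups.

    Empty groups are dropped with a warning.  With no events anywhere the
    curves are flat at 1 and the test is undefined (p = NaN, flagged).

    Returns a dict with ``curves`` (group -> survival-function DataFrame),
    ``p`` (log-rank), ``test_statistic`` and ``defined``.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(times, float),
            "event": np.asarray(events, int),
            "group": np.asarray(groups),
        }
    )
    sizes = df.groupby("group").size()
    empty = [g for g in sizes.index if sizes[g] == 0]
    if empty:
        warnings.warn(f"dropping empty group(s): {empty}")
        df = df[~df["group"].isin(empty)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least two non-empty groups")
    curves = {}
    for g, sub in df.groupby("group"):
        km = KaplanMeierFitter(label=str(g)).fit(sub["time"], sub["event"])
        curves[g] = km.survival_function_
    if df["event"].sum() == 0:
        return {
            "curves": curves,
            "p": float("nan"),
            "test_statistic": float("nan"),
            "defined": False,
        }
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return {
        "curves": curves,
        "p": float(res.p_value),
        "test_statistic": float(res.test_statistic),
        "defined": True,
    }


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "survival_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    Pass one covariate for a univariate model, several for a multivariate
    model.  Ties are handled by the Efron approximation.  Returns HR with
    95% CI and Wald p per covariate.

    Raises
    ------
    ValueError
        On rank-deficient design (e.g. duplicated covariates) or
        convergence failure (monotone likelihood / complete separation).
    """
    if not covariates:
        raise ValueError("need at least one covariate")
    cols = [duration_col, event_col, *covariates]
    df = cohort[cols].dropna()
    if df[event_col].sum() == 0:
        raise ValueError("no events in cohort; Cox model undefined")
    X = df[covariates].to_numpy(float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(covariates):
        raise ValueError(f"rank-deficient design for covariates {covariates}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    out = cph.summary[
        ["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].copy()
    out.columns = ["HR", "CI_lower", "CI_upper", "p"]
    out.index.name = "covariate"
    return out


def combine_edi_tp53(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add the three-level EDI + TP53 prognostic index.

    favorable  = EDI-low  and TP53 wild-type   (code 0)
    adverse    = EDI-high and TP53 mutant      (code 2)
    intermediate = all other combinations      (code 1)

    The ordinal code enters a Cox model as a single covariate
    (``combined_code``).  Rows with missing TP53 are excluded; the count
    is recorded in ``DataFrame.attrs["n_excluded_tp53"]``.
    """
    required = {"edi_group", "tp53"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort requires columns {sorted(required)}")
    df = cohort.copy()
    missing = df["tp53"].isna()
    df = df[~missing].copy()
    high = df["edi_group"].astype(str) == "high"
    mut = df["tp53"].astype(str) == "MUT"
    code = np.where(high & mut, 2, np.where(~high & ~mut, 0, 1))
    df["combined_group"] = np.array(["favorable", "intermediate", "adverse"])[code]
    df["combined_code"] = code
    df.attrs["n_excluded_tp53"] = int(missing.sum())
    return df


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums, under the hypergeometric null with fixed margins, the
    probabilities of all tables at most as probable as the observed one
    (the standard two-sided convention).
    """
    return float(fisher_exact(np.asarray(table))[1])


def fisher_enrichment(cna: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-gene Fisher's-exact enrichment of gains and losses in EDI-high.

    For each gene and each direction (gain: call > 0; loss: call < 0) a
    2x2 table of group (high/low) by aberration (present/absent) is tested
    two-sided.  Genes with no variation in a direction are reported with
    p = 1 and flagged.  Benjamini-Hochberg adjusted p-values are reported
    alongside the raw ones.

    Returns a DataFrame with one row per (gene, direction): counts a
    (high & aberrant), b (high & normal), c (low & aberrant), d (low &
    normal), ``p``, ``p_adj``, ``constant`` flag.
    """
    groups = np.asarray(groups)
    if groups.size != cna.shape[1]:
        raise ValueError(
            f"{cna.shape[1]} samples in matrix but {groups.size} group labels"
        )
    high = groups == "high"
    rows = []
    vals = cna.to_numpy()
    for direction, mask in (("gain", vals > 0), ("loss", vals < 0)):
        a = mask[:, high].sum(axis=1)
        c = mask[:, ~high].sum(axis=1)
        b = int(high.sum()) - a
        d = int((~high).sum()) - c
        for i, gene in enumerate(cna.index):
            table = [[a[i], b[i]], [c[i], d[i]]]
            constant = (a[i] + c[i] == 0) or (b[i] + d[i] == 0)
            p = 1.0 if constant else fisher_two_sided(table)
            rows.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "a": int(a[i]),
                    "b": int(b[i]),
                    "c": int(c[i]),
                    "d": int(d[i]),
                    "p": p,
                    "constant": constant,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def storey_qvalues(pvalues, lambdas=None) -> np.ndarray:
    """Tail-area false-discovery-rate q-values (Storey-type).

    The null proportion pi0 is estimated from the flat right tail of the
    p-value histogram on a lambda grid (0.05..0.95) smoothed with a cubic
    spline and evaluated at the largest lambda, then q_i = min over
    p_(j) >= p_(i) of pi0 * n * p_(j) / j.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if p.size < 100:
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > l).mean() / (1 - l) for l in lambdas])
        spline = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(np.clip(spline(lambdas.max()), 1e-8, 1.0))
    n = p.size
    order = np.argsort(p)
    ranked = pi0 * n * p[order] / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def expression_correlation(expr: pd.DataFrame, edi_scores) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with the EDI score.

    ``expr`` is genes x samples.  Constant genes are excluded (count in
    ``attrs["n_excluded_constant"]``).  Returns per-gene r, the two-sided
    correlation-test p, and a Storey-type q-value.
    """
    scores = np.asarray(edi_scores, float)
    if scores.size != expr.shape[1]:
        raise ValueError("sample count mismatch between expression and scores")
    if scores.size < 3:
        raise ValueError("need at least three samples")
    if np.std(scores) == 0:
        raise ValueError("EDI scores are constant; correlation undefined")
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    keep = sd > 0
    Xk = X[keep]
    xc = Xk - Xk.mean(axis=1, keepdims=True)
    yc = scores - scores.mean()
    r = (xc @ yc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(yc))
    r = np.clip(r, -1.0, 1.0)
    n = scores.size
    # two-sided p from the exact t transform of Pearson r
    from scipy.stats import t as t_dist

    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * t_dist.sf(np.abs(tstat), df=n - 2)
    out = pd.DataFrame(
        {"gene": expr.index[keep], "r": r, "p": p, "q": storey_qvalues(p)}
    ).set_index("gene")
    out.attrs["n_excluded_constant"] = int((~keep).sum())
    return out


def genomic_instability(segments: pd.DataFrame) -> float:
    """Fraction of the genome carrying a copy-number aberration.

    ``segments`` has one row per segment with columns ``length`` (> 0 in
    any consistent unit) and ``call`` (0 = neutral, non-zero = aberrant).
    """
    if not {"length", "call"} <= set(segments.columns):
        raise ValueError("segments require 'length' and 'call' columns")
    lengths = segments["length"].to_numpy(float)
    if (lengths < 0).any():
        raise ValueError("segment lengths must be non-negative")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total genome length must be positive")
    aberrant = lengths[segments["call"].to_numpy() != 0].sum()
    return float(aberrant / total)
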