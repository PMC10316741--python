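"""Differentially methylated probe (DMP) calling for one stage contrast.

A probe is a DMP when the group-mean beta difference against Normal
(delta beta) exceeds a magnitude threshold AND the Benjamini-Hochberg
adjusted two-sided Welch-t p-value clears an FDR level:

    hyper : delta_beta >  delta_thresh  and  adj_p < alpha
    hypo  : delta_beta < -delta_thresh  and  adj_p < alpha

Defaults delta_thresh = 0.1, alpha = 0.05.  Working on the beta scale, the
group-mean difference is what array pipelines report as the probe's
"fold change"; it lives in [-1, 1] and is directly interpretable as a
change in methylation fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, SampleSheet

__all__ = ["call_dmps", "bh_adjust", "DMP_COLUMNS"]

DMP_COLUMNS = ("probe_id", "contrast", "delta_beta", "stat", "p", "adj_p", "call")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    bm: BetaMatrix,
    sheet: SampleSheet,
    case_stage: str,
    ref_stage: str = "N",
    delta_thresh: float = 0.1,
    alpha: float = 0.05,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Per-probe case-vs-reference differential methylation.

    The matrix must be complete (run the imputation step first) and both
    groups need at least two samples.  p comes from a two-sided Welch
    two-sample t-test on beta values; adjustment is BH over all probes of
    the contrast.  A probe with zero variance in both groups gets p = 1
    when the means are equal (no evidence of difference, rather than NaN).

    Returns a DataFrame with columns ``probe_id, contrast, delta_beta,
    stat, p, adj_p, call`` (call in {"hyper", "hypo", "none"}).
    """
    case_ids = sheet.stage_samples(case_stage, tissue)
    ref_ids = sheet.stage_samples(ref_stage, tissue)
    case_ids = case_ids.intersection(bm.sample_ids)
    ref_ids = ref_ids.intersection(bm.sample_ids)
    if len(case_ids) < 2 or len(ref_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(case_ids)} {case_stage!r} "
            f"and {len(ref_ids)} {ref_stage!r}"
        )
    X_case = bm.values[case_ids].to_numpy(dtype=float)
    X_ref = bm.values[ref_ids].to_numpy(dtype=float)
    if np.isnan(X_case).any() or np.isnan(X_ref).any():
        raise ValueError("beta matrix has missing values; impute before DMP calling")

    delta = X_case.mean(axis=1) - X_ref.mean(axis=1)
    stat, p = stats.ttest_ind(X_case, X_ref, axis=1, equal_var=False)
    # both groups constant: Welch t is 0/0.  Equal means -> p = 1; unequal
    # means -> the difference is exact, p -> 0.
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(delta, 0.0)
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, 0.0, p)
        stat = np.where(degenerate, 0.0, stat)
    adj_p = bh_adjust(p)

    call = np.full(len(delta), "none", dtype=object)
    sig = adj_p < alpha
    call[sig & (delta > delta_thresh)] = "hyper"
    call[sig & (delta < -delta_thresh)] = "hypo"

    return pd.DataFrame(
        {
            "probe_id": bm.probe_ids.to_numpy(),
            "contrast": f"{case_stage}/{ref_stage}",
            "delta_beta": delta,
            "stat": stat,
            "p": p,
            "adj_p": adj_p,
            "call": call,
        }
    )
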