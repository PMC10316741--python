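"""Per-probe univariate survival screen and per-type fraction summaries.

Each probe's beta value enters a univariate Cox proportional-hazards model
as a continuous covariate; the screen keeps probes with likelihood-ratio
p below alpha (raw p — a screening step, not a discovery claim, so no
multiplicity correction).  The partial-likelihood Newton solve is
vectorized across probes (Breslow convention for tied event times), which
makes genome-scale screens cheap; it depends only on the rank order of
event times, so p-values are invariant to affine time rescaling.

The summary step reports, per trajectory type, the fraction of its probes
that pass the screen — under the null this sits near alpha for every type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, SampleSheet

__all__ = ["cox_univariate", "screen_probes", "fraction_survival_associated"]

_MAX_NEWTON = 50
_TOL = 1e-9


def _suffix_sums(w: np.ndarray, first_of_tie: np.ndarray) -> np.ndarray:
    """Risk-set sums per position: sum of w over samples with time >= t_i.

    ``w`` is (P, n) over samples sorted by ascending time; ties share the
    risk set of the first member of their tie group.
    """
    suffix = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    return suffix[:, first_of_tie]


def cox_univariate(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one univariate Cox model per row of ``X``.

    Returns (coef, p): the partial-likelihood MLE of the log hazard ratio
    per unit covariate and the likelihood-ratio test p-value against
    coef = 0.  Rows with no covariate variation among at-risk samples get
    coef 0 and p 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not event.any():
        raise ValueError("no events in the survival data")

    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    Xs = X[:, order]
    first_of_tie = np.searchsorted(t_s, t_s, side="left")
    ev = e_s.astype(bool)

    P, n = Xs.shape
    beta = np.zeros(P)

    def loglik_terms(b: np.ndarray):
        w = np.exp(b[:, None] * Xs)
        S0 = _suffix_sums(w, first_of_tie)
        S1 = _suffix_sums(w * Xs, first_of_tie)
        S2 = _suffix_sums(w * Xs * Xs, first_of_tie)
        ll = np.sum(b[:, None] * Xs[:, ev] - np.log(S0[:, ev]), axis=1)
        mean = S1 / S0
        U = np.sum(Xs[:, ev] - mean[:, ev], axis=1)
        I = np.sum(S2[:, ev] / S0[:, ev] - mean[:, ev] ** 2, axis=1)
        return ll, U, I

    ll0, U0, I0 = loglik_terms(beta)
    active = I0 > _TOL  # zero information: constant covariate among at-risk
    for _ in range(_MAX_NEWTON):
        ll, U, I = loglik_terms(beta)
        step = np.zeros(P)
        upd = active & (I > _TOL)
        step[upd] = U[upd] / I[upd]
        np.clip(step, -2.0, 2.0, out=step)  # damp early overshoot
        if np.max(np.abs(step)) < 1e-8:
            break
        beta = beta + step

    ll_hat, _, _ = loglik_terms(beta)
    lr = np.maximum(2.0 * (ll_hat - ll0), 0.0)
    p = stats.chi2.sf(lr, df=1)
    beta = np.where(active, beta, 0.0)
    p = np.where(active, p, 1.0)
    return beta, p


def screen_probes(
    bm: BetaMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
    min_events: int = 10,
) -> pd.DataFrame:
    """Univariate Cox screen of every probe against overall survival.

    Uses the samples with survival annotation (os_time/os_event).  Returns
    a DataFrame: probe_id, hazard_coef (log HR per unit beta), p,
    significant (raw p < alpha).
    """
    if "os_time" not in sheet.df.columns:
        raise ValueError("sample sheet carries no survival columns")
    surv = sheet.df.dropna(subset=["os_time", "os_event"])
    ids = surv.index.intersection(bm.sample_ids)
    if len(ids) == 0:
        raise ValueError("no overlap between beta matrix and survival samples")
    surv = surv.loc[ids]
    n_events = int(surv["os_event"].sum())
    if n_events == 0:
        raise ValueError("no events among survival samples")
    if n_events < min_events:
        raise ValueError(f"only {n_events} events; need >= {min_events} for the screen")

    X = bm.values[ids].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("beta matrix has missing values; impute before the screen")
    coef, p = cox_univariate(
        X, surv["os_time"].to_numpy(dtype=float), surv["os_event"].to_numpy(dtype=int)
    )
    return pd.DataFrame(
        {
            "probe_id": bm.probe_ids.to_numpy(),
            "hazard_coef": coef,
            "p": p,
            "significant": p < alpha,
        }
    )


def fraction_survival_associated(
    results: pd.DataFrame,
    calls: pd.DataFrame,
    subset_probe_ids=None,
) -> pd.DataFrame:
    """Fraction of each trajectory type's probes passing the survival screen.

    ``subset_probe_ids`` restricts the tally (e.g., to sites recurring in
    several tissues).  Types with no probes are reported with NaN fraction.

    Returns a DataFrame: type, n_probes, n_significant, fraction.
    """
    merged = calls.merge(results[["probe_id", "significant"]], on="probe_id", how="inner")
    if subset_probe_ids is not None:
        merged = merged[merged["probe_id"].isin(set(subset_probe_ids))]
    typed = merged.dropna(subset=["type"])
    rows = []
    for typ in range(1, 9):
        grp = typed[typed["type"] == typ]
        n = len(grp)
        n_sig = int(grp["significant"].sum())
        rows.append(
            {
                "type": typ,
                "n_probes": n,
                "n_significant": n_sig,
                "fraction": (n_sig / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["type", "n_probes", "n_significant", "fraction"])
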