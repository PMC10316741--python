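"""Probe QC, imputation, platform intersection and global methylation summaries.

Quality control here is missingness-based: probes measured in too few
samples are dropped, the remainder imputed.  Detection-p filtering and
probe-type bias correction belong to raw-intensity processing and are out
of scope for a pipeline that starts from a beta matrix; the normalization
hook offers ``none`` (default — every downstream statistic is a
within-probe contrast) and ``quantile``.

The global summary is aDNAme: a sample's mean beta over all retained
probes.  Group dispersion is the coefficient of variation of aDNAme within
a (tissue, stage) group, using the population (n-denominator) standard
deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import AUTOSOMES, BetaMatrix, ProbeManifest, SampleSheet

__all__ = [
    "filter_probes",
    "impute_missing",
    "intersect_platforms",
    "normalize_beta",
    "average_dname",
    "group_cv",
]


def filter_probes(bm: BetaMatrix, max_missing_frac: float = 0.2) -> BetaMatrix:
    """Drop probes whose fraction of missing samples exceeds ``max_missing_frac``.

    The boundary is inclusive on the keep side: a probe missing exactly
    20% of samples is retained; only strictly greater fractions go.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = bm.missing_fraction_per_probe()
    keep = frac[frac <= max_missing_frac].index
    if len(keep) == 0:
        warnings.warn("probe filter removed every probe", stacklevel=2)
    return BetaMatrix(bm.values.loc[keep])


def impute_missing(bm: BetaMatrix, method: str = "row_mean", k: int = 5) -> BetaMatrix:
    """Fill missing beta values.

    ``row_mean`` replaces each probe's missing entries with that probe's
    mean over observed samples.  ``knn`` finds, per missing cell, the k
    samples nearest in Euclidean distance over mutually observed probes
    that have a value at that probe, and averages them.  Observed entries
    are never altered; imputed values are clipped to [0, 1] (a no-op for
    both methods, kept as a guard).
    """
    vals = bm.values
    if not vals.isna().to_numpy().any():
        return bm
    if vals.isna().all(axis=1).any():
        bad = vals.index[vals.isna().all(axis=1)].tolist()[:5]
        raise ValueError(f"probes with no observed values cannot be imputed: {bad}")

    if method == "row_mean":
        filled = vals.T.fillna(vals.mean(axis=1)).T
    elif method == "knn":
        filled = _impute_knn(vals, k)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return BetaMatrix(filled.clip(0.0, 1.0))


def _impute_knn(vals: pd.DataFrame, k: int) -> pd.DataFrame:
    if k < 1:
        raise ValueError("k must be >= 1")
    X = vals.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    obs = ~np.isnan(X)
    # mean squared difference over mutually observed probes, per sample pair
    dist = np.full((n_samples, n_samples), np.inf)
    for a in range(n_samples):
        for b in range(n_samples):
            if a == b:
                continue
            shared = obs[:, a] & obs[:, b]
            if shared.any():
                d = X[shared, a] - X[shared, b]
                dist[a, b] = float(np.mean(d * d))
    out = X.copy()
    for p, s in zip(*np.where(~obs)):
        donors = np.where(obs[p])[0]
        order = donors[np.argsort(dist[s, donors], kind="stable")]
        nn = order[:k]
        out[p, s] = float(np.mean(X[p, nn]))
    return pd.DataFrame(out, index=vals.index, columns=vals.columns)


def intersect_platforms(bms: list[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict several beta matrices (e.g., 450K and EPIC cohorts) to the
    sorted intersection of their probe sets."""
    if not bms:
        raise ValueError("need at least one beta matrix")
    common = set(bms[0].probe_ids)
    for bm in bms[1:]:
        common &= set(bm.probe_ids)
    if not common:
        raise ValueError("platform probe sets have an empty intersection")
    shared = sorted(common)
    return [BetaMatrix(bm.values.loc[shared]) for bm in bms]


def normalize_beta(bm: BetaMatrix, method: str = "none") -> BetaMatrix:
    """Across-sample normalization hook.

    ``quantile`` maps every sample's sorted values onto the across-sample
    mean order statistics (classic quantile normalization; ties broken by
    stable input order, which makes the transform idempotent).
    """
    if method == "none":
        return bm
    if method != "quantile":
        raise ValueError(f"unknown normalization method {method!r}")
    X = bm.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile normalization needs a complete matrix; impute first")
    ref = np.sort(X, axis=0).mean(axis=1)
    ranks = np.argsort(np.argsort(X, axis=0, kind="stable"), axis=0, kind="stable")
    out = ref[ranks]
    return BetaMatrix(pd.DataFrame(out, index=bm.probe_ids, columns=bm.sample_ids))


def average_dname(
    bm: BetaMatrix,
    manifest: ProbeManifest | None = None,
    autosomes_only: bool = False,
) -> pd.DataFrame:
    """Per-sample aDNAme: mean beta over retained probes.

    With ``autosomes_only`` the mean is over autosomal probes (manifest
    required), excluding sex chromosomes whose methylation tracks sample
    sex rather than disease state.

    Returns a DataFrame indexed by sample id with one column ``adname``.
    """
    vals = bm.values
    if autosomes_only:
        if manifest is None:
            raise ValueError("autosomes_only requires a manifest")
        chrom = manifest.df.loc[vals.index.intersection(manifest.probe_ids), "chrom"]
        keep = chrom.index[chrom.isin(AUTOSOMES)]
        vals = vals.loc[keep]
    if vals.shape[0] == 0:
        raise ValueError("no probes retained for aDNAme computation")
    adname = vals.mean(axis=0, skipna=True)
    out = pd.DataFrame({"adname": adname})
    out.index.name = "sample_id"
    return out


def group_cv(summaries: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Coefficient of variation of aDNAme within each (tissue, stage) group.

    cv = population standard deviation / mean.  Groups with fewer than two
    samples are an error — a dispersion of one value is meaningless.

    Returns a DataFrame with columns tissue, stage, cv, n.
    """
    joined = summaries.join(sheet.df[["tissue", "stage"]], how="inner")
    if len(joined) < len(summaries):
        missing = summaries.index.difference(sheet.df.index).tolist()[:5]
        raise ValueError(f"samples absent from sample sheet: {missing}")
    rows = []
    for (tissue, stage), grp in joined.groupby(["tissue", "stage"], sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"group (tissue={tissue!r}, stage={stage!r}) has "
                f"{len(grp)} sample(s); need >= 2 for a CV"
            )
        a = grp["adname"].to_numpy(dtype=float)
        mean = float(a.mean())
        if mean == 0:
            raise ValueError(f"group (tissue={tissue!r}, stage={stage!r}) has zero mean")
        rows.append(
            {
                "tissue": tissue,
                "stage": stage,
                "cv": float(a.std(ddof=0)) / mean,
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "stage", "cv", "n"])
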