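"""Eight-type cross-stage methylation trajectory classification.

The two contrasts against Normal — precancer (P/N) and cancer (C/N) — are
combined per probe into one of eight trajectory types, anchored on the
probe being a DMP in precancer:

    P/N hyper:
      1 hyper-hyper   C/N hyper and delta_cp >  t   (keeps rising in tumour)
      2 hyper-similar C/N hyper and delta_cp <= t   (similar level kept)
      3 hyper-normal  C/N none                      (back to normal in tumour)
      4 hyper-hypo    C/N hypo                      (reversed in tumour)
    P/N hypo:
      5 hypo-hypo     C/N hypo  and delta_cp < -t   (keeps falling)
      6 hypo-similar  C/N hypo  and delta_cp >= -t
      7 hypo-normal   C/N none
      8 hypo-hyper    C/N hyper
    P/N none: no type (tumour-only changes are outside the scheme)

where delta_cp = mean beta(C) - mean beta(P) and t = 0.1 by default.
Types 1+2 form the shared-hypermethylation group (sHyperMethyl), 5+6 the
shared-hypomethylation group (sHypoMethyl); 3/7 are transient and 4/8
reversed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet, STAGES

__all__ = [
    "stage_mean_betas",
    "classify_eight_types",
    "summarize_type_fractions",
    "TYPE_GROUPS",
    "SHYPER_TYPES",
    "SHYPO_TYPES",
]

#: trajectory type -> grouping used throughout downstream analyses
TYPE_GROUPS = {
    1: "sHyperMethyl",
    2: "sHyperMethyl",
    3: "transient",
    4: "reversed",
    5: "sHypoMethyl",
    6: "sHypoMethyl",
    7: "transient",
    8: "reversed",
}
SHYPER_TYPES = (1, 2)
SHYPO_TYPES = (5, 6)


def stage_mean_betas(
    bm: BetaMatrix, sheet: SampleSheet, tissue: str | None = None
) -> pd.DataFrame:
    """Per-probe mean beta per stage (columns N, P, C where present)."""
    cols = {}
    for stage in STAGES:
        ids = sheet.stage_samples(stage, tissue).intersection(bm.sample_ids)
        if len(ids):
            cols[stage] = bm.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def classify_eight_types(
    dmp_pn: pd.DataFrame,
    dmp_cn: pd.DataFrame,
    delta_cp: pd.Series,
    delta_thresh: float = 0.1,
) -> pd.DataFrame:
    """Assign each probe a trajectory type from its P/N and C/N calls.

    ``dmp_pn`` and ``dmp_cn`` are DMP tables over the identical probe
    universe; ``delta_cp`` maps probe id to mean(C) - mean(P).  Every probe
    receives exactly one assignment (type 1-8 or <NA>), so the output is a
    partition of the universe.

    Returns a DataFrame with columns ``probe_id, type, group, delta_cp``.
    """
    pn = dmp_pn.set_index("probe_id")["call"]
    cn = dmp_cn.set_index("probe_id")["call"]
    if not pn.index.equals(cn.index):
        only_pn = pn.index.difference(cn.index).tolist()[:5]
        only_cn = cn.index.difference(pn.index).tolist()[:5]
        raise ValueError(
            "P/N and C/N contrasts must cover the identical probe universe; "
            f"only in P/N: {only_pn}, only in C/N: {only_cn}"
        )
    dcp = delta_cp.reindex(pn.index)
    if dcp.isna().any():
        missing = dcp.index[dcp.isna()].tolist()[:5]
        raise ValueError(f"delta_cp missing for probes: {missing}")

    pn_v = pn.to_numpy()
    cn_v = cn.to_numpy()
    d = dcp.to_numpy(dtype=float)
    t = np.zeros(len(pn_v), dtype=int)  # 0 = no type

    hyper = pn_v == "hyper"
    hypo = pn_v == "hypo"
    t[hyper & (cn_v == "hyper") & (d > delta_thresh)] = 1
    t[hyper & (cn_v == "hyper") & (d <= delta_thresh)] = 2
    t[hyper & (cn_v == "none")] = 3
    t[hyper & (cn_v == "hypo")] = 4
    t[hypo & (cn_v == "hypo") & (d < -delta_thresh)] = 5
    t[hypo & (cn_v == "hypo") & (d >= -delta_thresh)] = 6
    t[hypo & (cn_v == "none")] = 7
    t[hypo & (cn_v == "hyper")] = 8

    type_col = pd.array([v if v else pd.NA for v in t], dtype="Int64")
    group = np.array([TYPE_GROUPS.get(v, "none") for v in t], dtype=object)
    return pd.DataFrame(
        {
            "probe_id": pn.index.to_numpy(),
            "type": type_col,
            "group": group,
            "delta_cp": d,
        }
    )


def summarize_type_fractions(calls_by_tissue) -> pd.DataFrame:
    """Per-tissue counts and percentages of trajectory types 1-8.

    ``calls_by_tissue`` maps tissue label -> classification table (or is a
    single table, reported under tissue "all").  Percentages are over typed
    probes only and sum to 100 within a tissue.

    Returns a tidy DataFrame: tissue, type, count, pct.
    """
    if isinstance(calls_by_tissue, pd.DataFrame):
        calls_by_tissue = {"all": calls_by_tissue}
    rows = []
    for tissue, calls in calls_by_tissue.items():
        typed = calls["type"].dropna().astype(int)
        total = len(typed)
        if total == 0:
            raise ValueError(f"tissue {tissue!r} has no typed probes")
        counts = typed.value_counts()
        for typ in range(1, 9):
            n = int(counts.get(typ, 0))
            rows.append(
                {"tissue": tissue, "type": typ, "count": n, "pct": 100.0 * n / total}
            )
    return pd.DataFrame(rows, columns=["tissue", "type", "count", "pct"])
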