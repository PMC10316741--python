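"""Enrichment layers: chromosome permutation null, genomic features, gene sets.

Three views of where differential probes concentrate:

* **Chromosome** — Monte-Carlo resampling null: draw as many probes as were
  called (D) from the filtered universe (M), uniformly without replacement,
  many times; the empirical upper tail of each autosome's count gives the
  enrichment p.  The +1/(n_perm+1) pseudocount estimator is used, so an
  empirical p is never exactly zero.
* **Genomic feature / CGI relation** — exact hypergeometric tails of the
  probe-label 2x2 table per category, BH across categories.
* **Gene set** — one-sided hypergeometric over an explicit gene universe
  (the genes on the filtered array — the defensible background for array
  data), sets size-filtered within the universe, BH across sets.

On top of these sit the bidirectional-chaos flag (a pathway enriched for
both shared-hyper and shared-hypo genes within one tissue) and the
cross-tissue comparison of enriched pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AUTOSOMES, CGI_RELATIONS, GENE_FEATURES, GeneSetCollection, ProbeManifest
from .dmp import bh_adjust

__all__ = [
    "PermConfig",
    "hypergeom_tail",
    "chromosome_enrichment_perm",
    "feature_enrichment",
    "top_k_by_pn",
    "geneset_enrichment",
    "bidirectional_chaos",
    "cross_tissue_compare",
    "ENRICHMENT_COLUMNS",
]

ENRICHMENT_COLUMNS = (
    "category",
    "observed",
    "expected",
    "p_enrich",
    "p_deplete",
    "adj_p",
    "odds_ratio",
)


@dataclass(frozen=True)
class PermConfig:
    """Resampling-null configuration.

    n_perm replicates of a draw of ``draw_size`` probes from a universe of
    ``universe_size``; when the sizes are left None they are taken from the
    inputs, when given they are cross-checked against them.
    """

    n_perm: int = 10_000
    seed: int = 0
    universe_size: int | None = None
    draw_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.draw_size is not None and self.universe_size is not None:
            if not 0 < self.draw_size <= self.universe_size:
                raise ValueError("need 0 < draw_size <= universe_size")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities, both inclusive of ``k``.

    X ~ Hypergeom(universe N, category K, draw n); returns
    (P(X >= k), P(X <= k)).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if k > min(K, n) or k < max(0, n + K - N):
        raise ValueError(f"observed count k={k} impossible for (N={N}, K={K}, n={n})")
    p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_lower = float(stats.hypergeom.cdf(k, N, K, n))
    return p_upper, p_lower


def _odds_ratio(N: int, K: int, n: int, k: int) -> float:
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    if b == 0 or c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def chromosome_enrichment_perm(
    dmp_ids,
    universe_ids,
    manifest: ProbeManifest,
    cfg: PermConfig,
) -> pd.DataFrame:
    """Per-autosome DMP enrichment against a resampling null.

    Draws ``len(dmp_ids)`` probe ids uniformly without replacement from the
    universe, ``cfg.n_perm`` times, and compares each autosome's observed
    DMP count with the permuted counts.  Sex chromosomes are excluded from
    the categories (their methylation tracks sample sex); they still count
    toward the universe the draws come from.  Fixed seed gives bit-identical
    results.
    """
    universe = pd.Index(universe_ids)
    dmps = pd.Index(dmp_ids)
    if not dmps.isin(universe).all():
        extra = dmps[~dmps.isin(universe)].tolist()[:5]
        raise ValueError(f"DMP ids outside the universe: {extra}")
    unknown = universe.difference(manifest.probe_ids)
    if len(unknown):
        raise ValueError(f"universe probes missing from manifest: {unknown[:5].tolist()}")
    M, D = len(universe), len(dmps)
    if not 0 < D <= M:
        raise ValueError(f"need 0 < D <= M, got D={D}, M={M}")
    if cfg.universe_size is not None and cfg.universe_size != M:
        raise ValueError(f"cfg.universe_size={cfg.universe_size} but universe has {M}")
    if cfg.draw_size is not None and cfg.draw_size != D:
        raise ValueError(f"cfg.draw_size={cfg.draw_size} but {D} DMPs given")

    chrom = manifest.df.loc[universe, "chrom"]
    present = [c for c in AUTOSOMES if (chrom == c).any()]
    absent = [c for c in AUTOSOMES if c not in present]
    if absent:
        warnings.warn(f"autosome(s) absent from universe, dropped: {absent}", stacklevel=2)
    code_of = {c: i for i, c in enumerate(present)}
    codes = chrom.map(lambda c: code_of.get(c, -1)).to_numpy(dtype=np.int64)
    n_cat = len(present)

    observed = np.bincount(
        codes[universe.get_indexer(dmps)][codes[universe.get_indexer(dmps)] >= 0],
        minlength=n_cat,
    )

    rng = np.random.default_rng(cfg.seed)
    ge = np.zeros(n_cat, dtype=np.int64)  # replicates with count >= observed
    le = np.zeros(n_cat, dtype=np.int64)
    total = np.zeros(n_cat, dtype=np.float64)
    for _ in range(cfg.n_perm):
        draw = codes[rng.choice(M, size=D, replace=False)]
        counts = np.bincount(draw[draw >= 0], minlength=n_cat)
        ge += counts >= observed
        le += counts <= observed
        total += counts

    p_enrich = (1 + ge) / (cfg.n_perm + 1)
    p_deplete = (1 + le) / (cfg.n_perm + 1)
    expected = total / cfg.n_perm
    K_per = np.bincount(codes[codes >= 0], minlength=n_cat)
    odds = [_odds_ratio(M, int(K), D, int(k)) for K, k in zip(K_per, observed)]
    return pd.DataFrame(
        {
            "category": present,
            "observed": observed.astype(int),
            "expected": expected,
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
            "adj_p": bh_adjust(p_enrich),
            "odds_ratio": odds,
        }
    )


def feature_enrichment(
    dmp_ids,
    universe_ids,
    manifest: ProbeManifest,
    axis: str = "feature",
) -> pd.DataFrame:
    """Hypergeometric enrichment of DMPs over probe annotation categories.

    ``axis`` is "feature" (gene-model classes TSS200..IGR; a probe counts
    once in each distinct class it is annotated to) or "cgi" (Island /
    Shore / Shelf / OpenSea, one per probe).  Tails are exact; BH across
    categories.
    """
    if axis == "feature":
        vocab = sorted(GENE_FEATURES)
        membership = manifest.df["features"].map(frozenset)
    elif axis == "cgi":
        vocab = sorted(CGI_RELATIONS)
        membership = manifest.df["cgi"].map(lambda c: frozenset((c,)))
    else:
        raise ValueError(f"axis must be 'feature' or 'cgi', got {axis!r}")

    universe = pd.Index(universe_ids)
    dmps = pd.Index(dmp_ids)
    if not dmps.isin(universe).all():
        extra = dmps[~dmps.isin(universe)].tolist()[:5]
        raise ValueError(f"DMP ids outside the universe: {extra}")
    uni_m = membership.loc[universe]
    dmp_m = membership.loc[dmps]
    N, n = len(universe), len(dmps)

    rows = []
    for cat in vocab:
        K = int(sum(cat in m for m in uni_m))
        if K == 0:
            warnings.warn(f"category {cat!r} empty in universe, dropped", stacklevel=2)
            continue
        k = int(sum(cat in m for m in dmp_m))
        p_up, p_lo = hypergeom_tail(N, K, n, k)
        rows.append(
            {
                "category": cat,
                "observed": k,
                "expected": n * K / N,
                "p_enrich": p_up,
                "p_deplete": p_lo,
                "odds_ratio": _odds_ratio(N, K, n, k),
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_enrich"].to_numpy())
    return out[list(ENRICHMENT_COLUMNS)]


def top_k_by_pn(
    dmps_pn: pd.DataFrame,
    calls: pd.DataFrame,
    type_filter,
    k: int = 1000,
) -> list[str]:
    """Top-k probes of given trajectory type(s), ranked by P/N significance.

    Sort key: raw P/N p ascending, then |delta_beta| descending, then probe
    id — deterministic under ties.  Fewer than ``k`` candidates returns
    them all with a warning.
    """
    if isinstance(type_filter, int):
        type_filter = (type_filter,)
    wanted = calls.loc[calls["type"].isin(list(type_filter)), "probe_id"]
    pool = dmps_pn[dmps_pn["probe_id"].isin(set(wanted))].copy()
    pool["abs_delta"] = pool["delta_beta"].abs()
    pool = pool.sort_values(
        ["p", "abs_delta", "probe_id"], ascending=[True, False, True], kind="mergesort"
    )
    if len(pool) < k:
        warnings.warn(
            f"only {len(pool)} probes of type(s) {tuple(type_filter)} available "
            f"(requested {k})",
            stacklevel=2,
        )
    return pool["probe_id"].head(k).tolist()


def geneset_enrichment(
    query_genes,
    universe_genes,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """One-sided hypergeometric gene-set enrichment over an explicit universe.

    Per set: overlap of query with the set, drawn from (universe size,
    set size within universe, query size).  Sets whose within-universe size
    falls outside [min_size, max_size] are skipped.  Query genes outside
    the universe are reported and dropped.  BH across tested sets; ``alpha``
    is carried in the ``significant`` column for convenience.
    """
    universe = frozenset(universe_genes)
    query = frozenset(query_genes)
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe dropped: "
            f"{sorted(stray)[:5]}",
            stacklevel=2,
        )
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name in sets.names():
        members = sets[name] & universe
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        k = len(query & members)
        p_up, p_lo = hypergeom_tail(N, K, n, k)
        rows.append(
            {
                "category": name,
                "observed": k,
                "expected": n * K / N,
                "p_enrich": p_up,
                "p_deplete": p_lo,
                "odds_ratio": _odds_ratio(N, K, n, k),
            }
        )
    if not rows:
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS) + ["significant"])
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_enrich"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    return out[list(ENRICHMENT_COLUMNS) + ["significant"]]


def bidirectional_chaos(
    enr_hyper: pd.DataFrame,
    enr_hypo: pd.DataFrame,
    alpha: float = 0.05,
) -> set[str]:
    """Pathways enriched for BOTH shared-hyper and shared-hypo genes.

    Input: two enrichment tables from the same tissue, one from the
    sHyperMethyl gene query, one from sHypoMethyl.  A category is flagged
    when its BH-adjusted enrichment p is below ``alpha`` in both — the
    methylation of the pathway's genes is being pushed in both directions
    at once.
    """
    sig_hyper = set(enr_hyper.loc[enr_hyper["adj_p"] < alpha, "category"])
    sig_hypo = set(enr_hypo.loc[enr_hypo["adj_p"] < alpha, "category"])
    return sig_hyper & sig_hypo


def cross_tissue_compare(
    per_tissue_enrichments: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify enriched pathways by how they recur across tissues.

    ``per_tissue_enrichments`` maps (tissue, direction) — direction
    "hyper" or "hypo" — to an enrichment table.  Each significant
    (pathway, tissue, direction) entry is classed, in order of precedence:

    bidirectional-within-tissue  the same tissue is significant in the
                                 other direction too
    different-direction-shared   another tissue is significant in the
                                 opposite direction
    same-direction-shared        another tissue is significant in the
                                 same direction
    unique                       nowhere else

    Returns a tidy DataFrame: pathway, tissue, direction, class.
    """
    sig: set[tuple[str, str, str]] = set()
    for (tissue, direction), enr in per_tissue_enrichments.items():
        if direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
        for cat in enr.loc[enr["adj_p"] < alpha, "category"]:
            sig.add((cat, tissue, direction))

    rows = []
    for cat, tissue, direction in sorted(sig):
        other = "hypo" if direction == "hyper" else "hyper"
        if (cat, tissue, other) in sig:
            cls = "bidirectional-within-tissue"
        elif any(c == cat and t != tissue and d == other for c, t, d in sig):
            cls = "different-direction-shared"
        elif any(c == cat and t != tissue and d == direction for c, t, d in sig):
            cls = "same-direction-shared"
        else:
            cls = "unique"
        rows.append({"pathway": cat, "tissue": tissue, "direction": direction, "class": cls})
    return pd.DataFrame(rows, columns=["pathway", "tissue", "direction", "class"])
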