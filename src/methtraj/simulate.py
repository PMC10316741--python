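"""Ground-truthed synthetic three-stage methylation cohorts.

The generator emulates the study design every other module assumes: a
Normal / Precancer / Cancer cohort measured on a beta-value array, with a
known subset of probes planted to follow each of the eight cross-stage
trajectory types and everything else null.

Per probe and stage, beta values are drawn from Beta(mu*phi, (1-mu)*phi),
where mu is the tissue baseline plus the planted stage shift and phi the
concentration: beta-distributed noise keeps values in [0, 1] and carries
the mean-variance coupling real beta values show (variance
mu*(1-mu)/(phi+1), largest at intermediate methylation).  Defaults — 20
Normal, 20 Precancer, 40 Cancer samples (cancer arms of public cohorts
run larger), baseline 0.45 (bulk-tissue genome-wide average; 0.18 mimics
a hypomethylated cervix-like tissue), phi = 100, planted |delta beta| =
0.3 against a 0.1 calling threshold.

The manifest assigns probes to autosomes by (approximate length
proportional) weights, genes round-robin over a synthetic gene pool, and
features/CGI classes by fixed proportions.  Gene sets, an oncogene/TSG
census and exponential survival outcomes (log hazard linear in the
planted probes' beta) complete the inputs.  Identical config (including
seed) gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (
    AUTOSOMES,
    BetaMatrix,
    CensusTable,
    GeneSetCollection,
    ProbeManifest,
    SampleSheet,
)

__all__ = [
    "SimConfig",
    "SurvivalSimConfig",
    "default_effects",
    "expected_type",
    "simulate_dataset",
    "simulate_survival",
]

# relative autosome lengths (hg-style, coarse), used as default chrom weights
_AUTOSOME_WEIGHTS = np.array(
    [249, 243, 198, 190, 182, 171, 159, 145, 138, 134, 135, 133,
     114, 107, 102, 90, 83, 80, 59, 63, 48, 51],
    dtype=float,
)

_FEATURE_PROPS = {
    "TSS200": 0.10,
    "TSS1500": 0.10,
    "1stExon": 0.05,
    "5'UTR": 0.05,
    "Body": 0.45,
    "3'UTR": 0.05,
    "IGR": 0.20,
}
_CGI_PROPS = {"Island": 0.30, "Shore": 0.25, "Shelf": 0.10, "OpenSea": 0.35}


def default_effects(delta: float = 0.3) -> dict[int, tuple[float, float]]:
    """Per-type (shift in P, shift in C) relative to the Normal baseline.

    Anchored at |delta| = 0.3 — comfortably past the 0.1 calling
    threshold — with the C-stage continuation of types 1/5 overshooting by
    a further 0.15 so the tumour-vs-precancer gate (0.1) is cleanly met.
    """
    return {
        1: (delta, delta + 0.15),
        2: (delta, delta),
        3: (delta, 0.0),
        4: (delta, -delta),
        5: (-delta, -delta - 0.15),
        6: (-delta, -delta),
        7: (-delta, 0.0),
        8: (-delta, delta),
    }


def expected_type(d_pn: float, d_cn: float, thresh: float = 0.1) -> int | None:
    """Noiseless trajectory type implied by a pair of planted shifts."""
    pn = "hyper" if d_pn > thresh else "hypo" if d_pn < -thresh else "none"
    cn = "hyper" if d_cn > thresh else "hypo" if d_cn < -thresh else "none"
    dcp = d_cn - d_pn
    if pn == "none":
        return None
    if pn == "hyper":
        if cn == "hyper":
            return 1 if dcp > thresh else 2
        return 3 if cn == "none" else 4
    if cn == "hypo":
        return 5 if dcp < -thresh else 6
    return 7 if cn == "none" else 8


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Planted survival structure for the Cancer arm.

    ``n_probes`` null-type probes receive a log hazard-ratio ``coef`` per
    unit beta; event times are exponential with rate
    baseline_hazard * exp(sum coef * beta), censoring independent
    exponential calibrated to the target censoring fraction.

    Prognostic loci in patients vary far more across individuals than the
    assay noise around a common mean; ``heterogeneity`` is the half-width
    of the uniform spread of per-patient mean methylation at the planted
    probes in the Cancer arm (centred on the tissue baseline, so the
    probes stay null for the stage contrasts).  At 0 the planted probes
    carry only assay noise and a per-unit-beta hazard effect is
    undetectable by design.
    """

    n_probes: int = 0
    coef: float = 2.0
    baseline_hazard: float = 0.002  # events per day at eta = 0
    censoring_rate: float = 0.3
    heterogeneity: float = 0.45

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; identical configs give identical data."""

    seed: int = 0
    n_normal: int = 20
    n_precancer: int = 20
    n_cancer: int = 40
    n_probes: int = 2000
    planted: Mapping[int, int] = field(default_factory=dict)  # type -> count
    effects: Mapping[int, tuple[float, float]] | None = None
    baseline_mean: float = 0.45
    phi: float = 100.0
    missing_rate: float = 0.0
    chrom_weights: Mapping[str, float] | None = None
    probes_per_gene: int = 4
    n_gene_sets: int = 10
    gene_set_size: int = 20
    # set name -> (n genes from hyper-planted, n genes from hypo-planted)
    planted_sets: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    census_fraction: float = 0.2
    tissue: str = "synth"
    survival: SurvivalSimConfig | None = None
    delta_thresh: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.baseline_mean < 1:
            raise ValueError("baseline_mean must be in (0, 1)")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(self.planted.values()) > self.n_probes:
            raise ValueError("planted counts exceed n_probes")
        eff = self.type_effects()
        for typ, count in self.planted.items():
            if typ not in range(1, 9):
                raise ValueError(f"planted type must be 1..8, got {typ}")
            if count < 0:
                raise ValueError("planted counts must be nonnegative")
            d_pn, d_cn = eff[typ]
            for d in (d_pn, d_cn):
                mu = self.baseline_mean + d
                if not 0 < mu < 1:
                    raise ValueError(
                        f"type {typ}: planted shift {d:+.2f} pushes the stage mean "
                        f"to {mu:.2f}, outside (0, 1)"
                    )
            implied = expected_type(d_pn, d_cn, self.delta_thresh)
            if implied != typ:
                raise ValueError(
                    f"effect pair {d_pn:+.2f}/{d_cn:+.2f} implies type {implied}, "
                    f"not the requested type {typ}"
                )

    def type_effects(self) -> dict[int, tuple[float, float]]:
        return dict(self.effects) if self.effects is not None else default_effects()

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted" in raw:
            raw["planted"] = {int(k): int(v) for k, v in raw["planted"].items()}
        if raw.get("effects"):
            raw["effects"] = {
                int(k): (float(v[0]), float(v[1])) for k, v in raw["effects"].items()
            }
        if raw.get("planted_sets"):
            raw["planted_sets"] = {
                str(k): (int(v[0]), int(v[1])) for k, v in raw["planted_sets"].items()
            }
        if raw.get("survival") is not None:
            raw["survival"] = SurvivalSimConfig(**raw["survival"])
        return cls(**raw)


def _draw_betas(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.clip(mu, 0.01, 0.99)
    return rng.beta(mu * phi, (1.0 - mu) * phi)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeManifest, GeneSetCollection, CensusTable, pd.DataFrame]:
    """Generate one synthetic cohort plus its ground truth.

    Returns (beta matrix, sample sheet, manifest, gene sets, census,
    truth table).  The truth table is indexed by probe id with columns
    ``type`` (1-8, <NA> for null probes), ``d_pn``, ``d_cn``, ``gene``
    (first annotated gene, "" if intergenic) and ``survival_coef``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_probes = cfg.n_probes
    width = max(5, len(str(n_probes)))
    probe_ids = [f"cg{i:0{width}d}" for i in range(n_probes)]

    # --- planted type assignment, scattered over the probe universe
    eff = cfg.type_effects()
    types = np.zeros(n_probes, dtype=int)  # 0 = null
    perm = rng.permutation(n_probes)
    cursor = 0
    for typ in sorted(cfg.planted):
        count = cfg.planted[typ]
        types[perm[cursor : cursor + count]] = typ
        cursor += count

    d_pn = np.array([eff[t][0] if t else 0.0 for t in types])
    d_cn = np.array([eff[t][1] if t else 0.0 for t in types])

    # --- beta draws per stage
    base = cfg.baseline_mean
    stage_sizes = {"N": cfg.n_normal, "P": cfg.n_precancer, "C": cfg.n_cancer}
    shifts = {"N": np.zeros(n_probes), "P": d_pn, "C": d_cn}
    blocks, sample_ids, stages = [], [], []
    for stage in ("N", "P", "C"):
        n_s = stage_sizes[stage]
        mu = np.repeat((base + shifts[stage])[:, None], n_s, axis=1)
        blocks.append(_draw_betas(rng, mu, cfg.phi))
        sample_ids += [f"{cfg.tissue}_{stage}{i + 1:03d}" for i in range(n_s)]
        stages += [stage] * n_s
    X = np.concatenate(blocks, axis=1)

    # --- survival effects live on null probes so the trajectory and
    #     survival plantings stay orthogonal; planted probes get a
    #     heterogeneous per-patient methylation level in the Cancer arm
    surv_coef = np.zeros(n_probes)
    if cfg.survival is not None and cfg.survival.n_probes > 0:
        null_idx = np.flatnonzero(types == 0)
        if cfg.survival.n_probes > len(null_idx):
            raise ValueError("not enough null probes to carry survival effects")
        chosen = np.sort(rng.choice(null_idx, size=cfg.survival.n_probes, replace=False))
        surv_coef[chosen] = cfg.survival.coef
        h = cfg.survival.heterogeneity
        if h > 0:
            c_cols = np.arange(X.shape[1] - cfg.n_cancer, X.shape[1])
            lo, hi = max(0.01, base - h), min(0.99, base + h)
            mu_het = rng.uniform(lo, hi, size=(len(chosen), cfg.n_cancer))
            X[np.ix_(chosen, c_cols)] = _draw_betas(rng, mu_het, cfg.phi)

    if cfg.missing_rate > 0:
        mask = rng.random(X.shape) < cfg.missing_rate
        X = np.where(mask, np.nan, X)

    bm = BetaMatrix(pd.DataFrame(X, index=pd.Index(probe_ids, name="probe_id"),
                                 columns=sample_ids))
    sheet = SampleSheet(
        pd.DataFrame(
            {"tissue": cfg.tissue, "stage": stages},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- manifest
    weights = (
        np.array([cfg.chrom_weights.get(c, 0.0) for c in AUTOSOMES], dtype=float)
        if cfg.chrom_weights is not None
        else _AUTOSOME_WEIGHTS
    )
    weights = weights / weights.sum()
    chrom = rng.choice(np.array(AUTOSOMES), size=n_probes, p=weights)
    pos = rng.integers(1, 100_000_000, size=n_probes)
    feats = rng.choice(
        np.array(list(_FEATURE_PROPS)), size=n_probes, p=np.array(list(_FEATURE_PROPS.values()))
    )
    cgi = rng.choice(
        np.array(list(_CGI_PROPS)), size=n_probes, p=np.array(list(_CGI_PROPS.values()))
    )
    n_genes = max(1, -(-n_probes // cfg.probes_per_gene))
    gene_pool = [f"GENE{i:05d}" for i in range(n_genes)]
    genes_col, feats_col = [], []
    g = 0
    for i in range(n_probes):
        if feats[i] == "IGR":
            genes_col.append(())
            feats_col.append(("IGR",))
        else:
            genes_col.append((gene_pool[g % n_genes],))
            feats_col.append((str(feats[i]),))
            g += 1
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "genes": genes_col,
                "features": feats_col,
                "cgi": cgi,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # --- gene sets: planted ones draw from hyper/hypo-planted genes
    first_gene = np.array([g[0] if g else "" for g in genes_col], dtype=object)
    hyper_genes = sorted({g for g, t in zip(first_gene, types) if g and t in (1, 2)})
    hypo_genes = sorted({g for g, t in zip(first_gene, types) if g and t in (5, 6)})
    null_genes = sorted({g for g, t in zip(first_gene, types) if g and t == 0})
    sets: dict[str, frozenset[str]] = {}
    for name, (n_hyper, n_hypo) in cfg.planted_sets.items():
        if n_hyper > len(hyper_genes) or n_hypo > len(hypo_genes):
            raise ValueError(
                f"planted set {name!r} asks for more planted genes than exist"
            )
        members = list(rng.choice(hyper_genes, size=n_hyper, replace=False)) if n_hyper else []
        members += list(rng.choice(hypo_genes, size=n_hypo, replace=False)) if n_hypo else []
        filler = max(0, cfg.gene_set_size - len(members))
        members += list(rng.choice(null_genes, size=min(filler, len(null_genes)), replace=False))
        sets[name] = frozenset(members)
    for i in range(cfg.n_gene_sets):
        size = min(cfg.gene_set_size, n_genes)
        members = rng.choice(gene_pool, size=size, replace=False)
        sets[f"set{i + 1:03d}"] = frozenset(str(m) for m in members)
    genesets = GeneSetCollection(sets, {name: "simulated" for name in sets})

    # --- census: a deterministic-rate random subset of the gene pool
    n_census = int(round(cfg.census_fraction * n_genes))
    census_genes = sorted(rng.choice(gene_pool, size=n_census, replace=False))
    roles = rng.choice(
        np.array(["oncogene", "TSG", "both"]), size=n_census, p=np.array([0.45, 0.45, 0.10])
    )
    census = CensusTable(
        pd.DataFrame({"role": roles}, index=pd.Index(census_genes, name="gene"))
    )

    truth = pd.DataFrame(
        {
            "type": pd.array([t if t else pd.NA for t in types], dtype="Int64"),
            "d_pn": d_pn,
            "d_cn": d_cn,
            "gene": first_gene,
            "survival_coef": surv_coef,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    if cfg.survival is not None:
        sheet = simulate_survival(cfg, bm, sheet, truth)

    return bm, sheet, manifest, genesets, census, truth


def simulate_survival(
    cfg: SimConfig,
    bm: BetaMatrix,
    sheet: SampleSheet,
    truth: pd.DataFrame,
) -> SampleSheet:
    """Attach exponential survival outcomes to the Cancer-stage samples.

    Event rate per sample: baseline_hazard * exp(sum coef_j * beta_j);
    censoring is independent exponential with its rate set so the expected
    censored fraction matches the configured rate (0 disables censoring).
    A fresh stream seeded from cfg.seed keeps the draw deterministic.
    """
    scfg = cfg.survival
    if scfg is None:
        raise ValueError("config has no survival section")
    c_ids = sheet.stage_samples("C")
    if len(c_ids) == 0:
        raise ValueError("no Cancer-stage samples to attach survival to")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    coefs = truth["survival_coef"].to_numpy()
    Xc = bm.values[c_ids].to_numpy(dtype=float)
    Xc = np.nan_to_num(Xc, nan=cfg.baseline_mean)
    eta = coefs @ Xc
    rate = scfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if scfg.censoring_rate > 0:
        c = scfg.censoring_rate
        rate_cens = float(rate.mean()) * c / (1.0 - c)
        t_cens = rng.exponential(1.0 / rate_cens, size=len(c_ids))
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(len(c_ids), dtype=int)

    df = sheet.df.copy()
    df["os_time"] = np.nan
    df["os_event"] = np.nan
    df.loc[c_ids, "os_time"] = os_time
    df.loc[c_ids, "os_event"] = os_event
    return SampleSheet(df)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Same study conditions, different random stream."""
    return replace(cfg, seed=seed)
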