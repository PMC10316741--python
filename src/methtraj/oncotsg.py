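"""Mapping shared methylation changes onto oncogene/TSG gene models.

Probes carrying shared cross-stage changes (types 1/2 -> sHyperMethyl,
5/6 -> sHypoMethyl) are projected onto the gene models of census
oncogenes and tumour-suppressor genes, with manifest features collapsed
to three regions:

    TSS200, TSS1500   -> TSS   (promoter-proximal)
    5'UTR, 3'UTR      -> UTR
    Body, 1stExon     -> Body

Intergenic (IGR) probes yield no hits.  The cross-tissue step keeps
(gene, region, group) combinations recurring in at least ``min_tissues``
tissues — recurrent lesions are the ones least likely to be batch or
cohort artefacts.
"""

from __future__ import annotations

import pandas as pd

from .crossstage import SHYPER_TYPES, SHYPO_TYPES
from .io import CensusTable, ProbeManifest

__all__ = ["collapse_region", "map_probes_to_oncotsg", "common_across_tissues"]

_REGION_OF = {
    "TSS200": "TSS",
    "TSS1500": "TSS",
    "5'UTR": "UTR",
    "3'UTR": "UTR",
    "Body": "Body",
    "1stExon": "Body",
}


def collapse_region(feature: str) -> str | None:
    """Manifest feature -> coarse gene region (TSS/UTR/Body); IGR -> None."""
    return _REGION_OF.get(feature)


def map_probes_to_oncotsg(
    calls: pd.DataFrame,
    manifest: ProbeManifest,
    census: CensusTable,
    tissue: str = "all",
) -> pd.DataFrame:
    """One row per (gene, region, group) hit by shared-change probes.

    Only trajectory types 1/2/5/6 contribute (the shared groups); a probe
    annotated to several gene-region pairs contributes one hit per pair
    whose gene is in the census.  Census genes with no probe in the
    manifest are simply unrepresented.

    Returns a DataFrame: gene, role, region, tissue, group, n_probes,
    probe_ids (tuple).
    """
    shared = calls[calls["type"].isin(list(SHYPER_TYPES + SHYPO_TYPES))]
    census_genes = set(census.genes)
    acc: dict[tuple[str, str, str], list[str]] = {}
    for probe_id, typ in zip(shared["probe_id"], shared["type"]):
        if probe_id not in manifest.probe_ids:
            raise ValueError(f"probe {probe_id!r} missing from manifest")
        group = "sHyperMethyl" if typ in SHYPER_TYPES else "sHypoMethyl"
        for gene, feature in manifest.gene_feature_pairs(probe_id):
            region = collapse_region(feature)
            if region is None or gene not in census_genes:
                continue
            acc.setdefault((gene, region, group), []).append(probe_id)
    rows = [
        {
            "gene": gene,
            "role": census.role(gene),
            "region": region,
            "tissue": tissue,
            "group": group,
            "n_probes": len(sorted(set(probes))),
            "probe_ids": tuple(sorted(set(probes))),
        }
        for (gene, region, group), probes in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "role", "region", "tissue", "group", "n_probes", "probe_ids"],
    )


def common_across_tissues(
    hits_by_tissue: dict[str, pd.DataFrame],
    min_tissues: int = 2,
) -> pd.DataFrame:
    """(gene, region, group) combinations recurring in >= ``min_tissues`` tissues.

    Returns a DataFrame: gene, role, region, group, n_tissues, tissues
    (tuple, sorted).
    """
    if min_tissues < 1:
        raise ValueError("min_tissues must be >= 1")
    combined = []
    for tissue, hits in hits_by_tissue.items():
        h = hits.copy()
        h["tissue"] = tissue
        combined.append(h)
    if not combined:
        return pd.DataFrame(
            columns=["gene", "role", "region", "group", "n_tissues", "tissues"]
        )
    allhits = pd.concat(combined, ignore_index=True)
    rows = []
    for (gene, region, group), grp in allhits.groupby(["gene", "region", "group"], sort=True):
        tissues = tuple(sorted(grp["tissue"].unique()))
        if len(tissues) >= min_tissues:
            rows.append(
                {
                    "gene": gene,
                    "role": grp["role"].iloc[0],
                    "region": region,
                    "group": group,
                    "n_tissues": len(tissues),
                    "tissues": tissues,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "role", "region", "group", "n_tissues", "tissues"]
    )
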