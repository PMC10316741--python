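"""Readers/writers for the tables a methylation trajectory analysis touches.

All downstream modules consume the validated in-memory containers defined
here; no other module parses files.  Formats are deliberately plain:

* beta matrix       — delimited table, probes in rows, samples in columns
* probe manifest    — CSV: probe_id, chrom, pos, genes, feature, cgi
* sample sheet      — CSV: sample_id, tissue, stage[, os_time, os_event]
* gene sets         — standard GMT (name, description, tab-separated members)
* cancer gene census— CSV: gene, role

Manifest rows may carry several ";"-joined gene/feature annotations (a CpG
probe can sit in the UTR of one gene and the body of an overlapping one);
these are split and all kept.  Chromosome labels are normalized by stripping
a leading "chr".  Coordinates are 1-based point positions; array beta values
are strand-collapsed by the platform so no strand is tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BetaMatrix",
    "ProbeManifest",
    "SampleSheet",
    "GeneSetCollection",
    "CensusTable",
    "GENE_FEATURES",
    "CGI_RELATIONS",
    "STAGES",
    "CENSUS_ROLES",
    "AUTOSOMES",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_census",
    "write_census",
]

#: Gene-model feature classes used by Illumina array manifests.
GENE_FEATURES = frozenset(
    {"TSS200", "TSS1500", "1stExon", "5'UTR", "Body", "3'UTR", "IGR"}
)
#: Position of a probe relative to the nearest CpG island.
CGI_RELATIONS = frozenset({"Island", "Shore", "Shelf", "OpenSea"})
#: Disease stages: Normal tissue, Precancerous lesion, Cancer.
STAGES = ("N", "P", "C")
CENSUS_ROLES = frozenset({"oncogene", "TSG", "both"})
#: Chromosome labels accepted in manifests ("chr" prefixes are stripped).
AUTOSOMES = tuple(str(i) for i in range(1, 23))
_CHROMS = frozenset(AUTOSOMES) | {"X", "Y"}


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


def _check_unique(values: Iterable[str], what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class BetaMatrix:
    """Probe x sample matrix of methylation beta values in [0, 1].

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns; missing measurements are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def missing_fraction_per_probe(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)])


def _normalize_chrom(label: str) -> str:
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True)
class ProbeManifest:
    """Genomic and gene-model annotation per array probe.

    ``df`` is indexed by probe id with columns:

    chrom    normalized chromosome label ("1".."22", "X", "Y")
    pos      1-based genomic coordinate of the interrogated CpG
    genes    tuple of gene symbols (empty for intergenic probes)
    features tuple of gene-model features, parallel to ``genes`` for genic
             probes; a single entry (usually "IGR") for intergenic ones
    cgi      CpG-island relation
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "probe ids")
        bad_chrom = set(self.df["chrom"]) - _CHROMS
        if bad_chrom:
            raise FormatError(f"unknown chromosome labels: {sorted(bad_chrom)[:5]}")
        if (self.df["pos"] < 1).any():
            raise FormatError("positions must be >= 1")
        for pid, genes, feats in zip(self.df.index, self.df["genes"], self.df["features"]):
            bad = set(feats) - GENE_FEATURES
            if bad:
                raise FormatError(f"probe {pid!r}: unknown feature(s) {sorted(bad)}")
            if genes and len(feats) != len(genes):
                raise FormatError(
                    f"probe {pid!r}: {len(genes)} genes but {len(feats)} features"
                )
            if not genes and len(feats) != 1:
                raise FormatError(f"probe {pid!r}: intergenic probe needs one feature")
        bad_cgi = set(self.df["cgi"]) - CGI_RELATIONS
        if bad_cgi:
            raise FormatError(f"unknown CGI relation(s): {sorted(bad_cgi)[:5]}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def chrom(self) -> pd.Series:
        return self.df["chrom"]

    def gene_feature_pairs(self, probe_id: str) -> list[tuple[str, str]]:
        """(gene, feature) pairs for a probe; empty for intergenic probes."""
        row = self.df.loc[probe_id]
        return list(zip(row["genes"], row["features"]))

    def genes_for(self, probe_ids: Iterable[str]) -> set[str]:
        sub = self.df.loc[list(probe_ids), "genes"]
        out: set[str] = set()
        for genes in sub:
            out.update(genes)
        return out

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        return ProbeManifest(self.df.loc[list(probe_ids)])


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: tissue, stage, optional survival outcome.

    ``df`` is indexed by sample id with columns ``tissue``, ``stage``
    ("N"/"P"/"C") and optional ``os_time`` (days) / ``os_event`` (0/1).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample ids")
        bad = set(self.df["stage"]) - set(STAGES)
        if bad:
            raise FormatError(f"unknown stage label(s): {sorted(bad)}")
        has_time = "os_time" in self.df.columns
        has_event = "os_event" in self.df.columns
        if has_time != has_event:
            raise FormatError("os_time and os_event must be provided together")
        if has_time:
            t = self.df["os_time"]
            e = self.df["os_event"]
            if (t.notna() != e.notna()).any():
                raise FormatError("os_event present iff os_time present, per sample")
            if (t.dropna() < 0).any():
                raise FormatError("os_time must be nonnegative")
            if not e.dropna().isin([0, 1]).all():
                raise FormatError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def stage_samples(self, stage: str, tissue: str | None = None) -> pd.Index:
        mask = self.df["stage"] == stage
        if tissue is not None:
            mask &= self.df["tissue"] == tissue
        return self.df.index[mask]

    def has_survival(self) -> bool:
        return "os_time" in self.df.columns and self.df["os_time"].notna().any()


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (KEGG/GO style), as loaded from a GMT file."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class CensusTable:
    """Cancer gene census: gene symbol -> oncogene/TSG role."""

    df: pd.DataFrame  # indexed by gene, column "role"

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "census genes")
        bad = set(self.df["role"]) - CENSUS_ROLES
        if bad:
            raise FormatError(f"unknown census role(s): {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    def role(self, gene: str) -> str:
        return self.df.loc[gene, "role"]


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path: str, missing_token: str = "NA") -> BetaMatrix:
    """Read a probe x sample beta-value table (TSV or CSV).

    First column holds probe ids, header row holds sample ids; cells equal
    to ``missing_token`` become missing.  Values outside [0, 1], duplicate
    ids and non-numeric cells raise :class:`FormatError`.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
    )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in beta matrix: {exc}") from None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path: str, missing_token: str = "NA") -> None:
    bm.values.to_csv(path, sep=_sep_for(path), na_rep=missing_token)


_MANIFEST_COLS = ("probe_id", "chrom", "pos", "genes", "feature", "cgi")


def _require_cols(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {missing}")


def read_manifest(path: str) -> ProbeManifest:
    """Read a probe manifest CSV.

    ``genes`` and ``feature`` may hold ";"-joined lists (parallel order);
    an empty ``genes`` field marks an intergenic probe.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_cols(raw, _MANIFEST_COLS, "manifest")
    genes = [tuple(g for g in cell.split(";") if g) for cell in raw["genes"]]
    feats = [tuple(f for f in cell.split(";") if f) for cell in raw["feature"]]
    try:
        pos = raw["pos"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer position in manifest: {exc}") from None
    df = pd.DataFrame(
        {
            "chrom": [_normalize_chrom(c) for c in raw["chrom"]],
            "pos": pos.to_numpy(),
            "genes": genes,
            "features": feats,
            "cgi": raw["cgi"].to_numpy(),
        },
        index=pd.Index(raw["probe_id"], name="probe_id"),
    )
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str) -> None:
    df = manifest.df
    out = pd.DataFrame(
        {
            "probe_id": df.index,
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "genes": [";".join(g) for g in df["genes"]],
            "feature": [";".join(f) for f in df["features"]],
            "cgi": df["cgi"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def read_sample_sheet(path: str) -> SampleSheet:
    raw = pd.read_csv(path)
    _require_cols(raw, ("sample_id", "tissue", "stage"), "sample sheet")
    raw["sample_id"] = raw["sample_id"].astype(str)
    df = raw.set_index("sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    sheet.df.reset_index().to_csv(path, index=False)


def read_gmt(path: str) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: need name, description, members")
            name = parts[0]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_census(path: str) -> CensusTable:
    raw = pd.read_csv(path)
    _require_cols(raw, ("gene", "role"), "census table")
    df = raw.set_index("gene")[["role"]]
    return CensusTable(df)


def write_census(census: CensusTable, path: str) -> None:
    census.df.reset_index().to_csv(path, index=False)
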