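import numpy as np
import pandas as pd
import pytest

from methtraj.io import BetaMatrix, ProbeManifest, SampleSheet
from methtraj.simulate import SimConfig, simulate_dataset


def make_manifest(
    probe_ids,
    chroms=None,
    genes=None,
    features=None,
    cgi=None,
) -> ProbeManifest:
    """Hand-build a small manifest; scalars are broadcast."""
    n = len(probe_ids)
    chroms = chroms if chroms is not None else ["1"] * n
    genes = genes if genes is not None else [("GENE1",)] * n
    features = features if features is not None else [("Body",)] * n
    cgi = cgi if cgi is not None else ["OpenSea"] * n
    return ProbeManifest(
        pd.DataFrame(
            {
                "chrom": chroms,
                "pos": np.arange(1, n + 1) * 1000,
                "genes": genes,
                "features": features,
                "cgi": cgi,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )


def make_sheet(n_n=4, n_p=4, n_c=4, tissue="toy") -> SampleSheet:
    ids, stages = [], []
    for stage, n in (("N", n_n), ("P", n_p), ("C", n_c)):
        ids += [f"{stage}{i}" for i in range(n)]
        stages += [stage] * n
    return SampleSheet(
        pd.DataFrame(
            {"tissue": tissue, "stage": stages},
            index=pd.Index(ids, name="sample_id"),
        )
    )


def make_beta(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return BetaMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """One simulated cohort with 20 probes of each trajectory type planted."""
    cfg = SimConfig(seed=11, n_probes=1000, planted={t: 20 for t in range(1, 9)})
    return cfg, simulate_dataset(cfg)
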