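import numpy as np
import pandas as pd
import pytest

import geomxpurity as gp
from geomxpurity.signatures import aggregate_zscore


@pytest.fixture(scope="session")
def small_cohort():
    """Fast structural cohort (few patients, small panel)."""
    cfg = gp.SimConfig(
        n_patients=4,
        n_genes=660,
        n_negprobes=40,
        aois_per_tumor=2,
        cnv_window=25,
        seed=11,
    )
    return gp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """The hallmark-CNV recovery scenario: default panel, dosage 1.5x/0.5x,
    malignant AOIs at purity >= 0.6 plus a purity-0 contingent."""
    cfg = gp.SimConfig(seed=1, purity_grid=(0.0, 0.6, 0.8, 1.0))
    dataset, ann, sigs, truth = gp.simulate_cohort(cfg)
    norm, _ = gp.preprocess_dataset(dataset)
    sox2 = dataset.segment_aois("SOX2")
    iba1 = dataset.segment_aois("IBA1")
    profile = gp.compute_cnv_profile(
        norm, ann, reference_aois=iba1, query_aois=sox2,
        batch=dataset.aoi_meta["batch"],
    )
    calls = gp.score_and_call(profile)
    malignant = sigs.by_role("malignant_state")
    scores = aggregate_zscore(
        norm,
        {name: sigs[name] for name in malignant + ["oligodendrocyte", "TAM"]},
        population=sox2,
    ).scores
    return {
        "dataset": dataset,
        "annotation": ann,
        "signatures": sigs,
        "truth": truth,
        "norm": norm,
        "profile": profile,
        "cnv_calls": calls,
        "scores_sox2": scores,
        "malignant_sigs": malignant,
        "sox2": sox2,
        "iba1": iba1,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
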