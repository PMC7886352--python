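import logging

import numpy as np
import pytest

from labelkin import synthdata
from labelkin.labelmodel import BodyWaterParams

logging.getLogger("labelkin").setLevel(logging.WARNING)


@pytest.fixture
def bw_params() -> BodyWaterParams:
    return BodyWaterParams(f=0.019, delta=0.065, beta=0.0075, tau=42.0)


@pytest.fixture
def noisefree_patient():
    cfg = synthdata.patient_config(noise=synthdata.NoiseConfig(0.0, 0.0))
    return cfg, synthdata.generate_individual(cfg, seed=7, individual="P1")


@pytest.fixture
def noisy_patient():
    cfg = synthdata.patient_config()
    return cfg, synthdata.generate_individual(cfg, seed=7, individual="P1")


def subset_inputs(cfg, ds, subset):
    """Extract (scaled enrichment series, counts tuple, truth) for one
    subset of a generated individual, scaling by the true granulocyte
    curve maximum."""
    from labelkin.labelmodel import (
        EnrichmentSeries,
        granulocyte_max,
        granulocyte_scale,
        mono_label_fraction,
    )

    tb = np.asarray(cfg.schedule.blood_days, dtype=float)
    m = granulocyte_max(
        lambda t: mono_label_fraction(t, cfg.p_gran, cfg.body_water, cfg.c), tb
    )
    sub = ds.enrichment[ds.enrichment["compartment"] == subset]
    series = granulocyte_scale(
        m,
        EnrichmentSeries(
            ds.individual, subset,
            sub["time_days"].to_numpy(), sub["enrichment"].to_numpy(),
        ),
    )
    cnt = ds.counts[ds.counts["subset"] == subset]
    counts = (cnt["time_days"].to_numpy(), cnt["subset_count_per_ml"].to_numpy())
    return series, counts, m
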