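import numpy as np
import pytest

from perimir import MIR124_3P
from perimir.synthdata import (ImageGeom, QpcrConfig, Scenario,
                               TranscriptomeConfig)


@pytest.fixture
def mirna():
    return MIR124_3P


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_scene_scenario():
    """Tiny imaging scenario: 20 cells per subject, one group."""
    return Scenario(
        name="tiny",
        rng_seed=42,
        image_geom=ImageGeom(width_um=400.0, depth_um=300.0,
                             microns_per_pixel=2.0),
        groups=[{"group_label": "naive", "n_subjects": 2}],
        layer_effect=1.9,
        group_scale={"naive": 1.0},
        base_signal=0.25,
        signal_cv=0.15,
        n_cells_per_subject=20,
        cell_radius_um=8.0,
    )


@pytest.fixture
def toy_transcriptome_scenario():
    """10 genes, 4 seed-site targets, hand-countable DE overlap of 2 up."""
    return Scenario(
        name="toy",
        rng_seed=7,
        transcriptome=TranscriptomeConfig(
            n_genes=10, n_target_genes=4, n_up_sig=3, n_down_sig=2,
            n_up_targets=2, n_down_targets=1, utr_len=60),
    )


@pytest.fixture
def qpcr_scenario():
    def make(planted_fc, ct_sd=0.3, n=6, seed=3):
        return Scenario(
            name="q", rng_seed=seed,
            qpcr={"assay": QpcrConfig(n_case=n, n_control=n,
                                      planted_fc=planted_fc, ct_sd=ct_sd)},
        )
    return make
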