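import numpy as np
import pandas as pd
import pytest

from streamcsa.synthetic import OTUDesign, SurveyDesign, generate_otu_tables, generate_survey


@pytest.fixture(scope="session")
def default_survey():
    return generate_survey(SurveyDesign(seed=0))


@pytest.fixture(scope="session")
def noiseless_design():
    """All noise sources zeroed; injected effects kept."""
    return SurveyDesign(
        seed=5,
        residual_sd=0.0,
        site_sd=0.0,
        do_noise_sd=0.0,
        ts_reference_sd=0.0,
        mass_reference_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_otu_tables(default_survey):
    design = OTUDesign(
        n_taxa_pool=300,
        reads_per_sample=2000,
        upstream_richness_mean=80,
        upstream_richness_sd=8.0,
        seed=11,
    )
    bacteria = OTUDesign(
        n_taxa_pool=300,
        reads_per_sample=2000,
        upstream_richness_mean=90,
        upstream_richness_sd=8.0,
        downstream_richness_ratio=1.12,
        marker="16S-like",
        seed=12,
    )
    return generate_otu_tables(design, default_survey, bacteria_design=bacteria)


@pytest.fixture()
def measurement_fixture():
    """Three well-formed measurement rows."""
    return pd.DataFrame(
        {
            "site": ["S01", "S01", "S02"],
            "location": ["U1", "D", "U1"],
            "strip_id": ["a", "b", "c"],
            "do_stream_start": [10.0, 10.0, 9.5],
            "do_chamber_end": [8.0, 7.5, 8.0],
            "do_blank_end": [9.8, 9.8, 9.4],
            "chamber_volume_L": [0.5, 0.5, 0.5],
            "strip_mass_g": [0.5, 0.5, 0.5],
            "assay_duration_hr": [1.0, 1.0, 1.0],
            "ts_final_N": [70.0, 60.0, 80.0],
            "mass_final_g": [0.45, 0.42, 0.47],
            "incubation_days": [14, 14, 14],
        }
    )
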