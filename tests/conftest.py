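import numpy as np
import pandas as pd
import pytest

from neurometab.pipeline import PipelineConfig, run_all
from neurometab.synthetic import RawFeatureTable, SyntheticConfig, generate_dataset


def tiny_synthetic_config(seed: int = 1, **overrides) -> SyntheticConfig:
    """Small, fast configuration for generator-level unit tests."""
    params = dict(
        n_mci=20,
        n_control=25,
        grid_dims=(22, 22, 16),
        n_regions=2,
        region_size=25,
        n_features=300,
        n_signal_features_per_region=8,
        n_annotatable_background=30,
        n_decoy_compounds=40,
        n_pathways=8,
        planted_pathway_size=6,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(tiny_synthetic_config())


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline run at the standard synthetic conditions.

    Shared across recovery tests so the (multi-second) end-to-end run
    happens once per session.
    """
    cfg = PipelineConfig(seed=0, synthetic=SyntheticConfig(seed=0))
    return run_all(cfg)


def make_raw(
    intensities: np.ndarray,
    mz: np.ndarray | None = None,
    batches: np.ndarray | None = None,
) -> RawFeatureTable:
    """RawFeatureTable from a (features, samples, 3) array of replicates."""
    intensities = np.asarray(intensities, dtype=float)
    f, s, _ = intensities.shape
    return RawFeatureTable(
        mz=mz if mz is not None else np.linspace(100, 900, f),
        rt=np.linspace(30, 280, f),
        intensities=intensities,
        samples=[f"S{i + 1:03d}" for i in range(s)],
        sample_batches=batches if batches is not None else np.zeros(s, dtype=int),
        feature_ids=[f"F{i + 1:06d}" for i in range(f)],
    )


def make_meta(samples: list[str], diagnoses: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"diagnosis": diagnoses, "age": 65.0, "sex": "F", "batch": 0},
        index=pd.Index(samples, name="subject"),
    )
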