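import numpy as np
import pandas as pd
import pytest

from oratox.dossier import DESCRIPTOR_NAMES
from oratox.knn import knn_feature_column
from oratox.models import ModelingDataset
from oratox.synthetic import GeneratorConfig, generate_fingerprints, latent_toxicity


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Module-clustered dataset small enough for model-fitting tests."""
    return GeneratorConfig(
        seed=7, n_substances=240, n_modules=6,
        within_module_similarity=0.92, clustering_strength=1.0,
    )


@pytest.fixture(scope="session")
def small_substances(small_cfg):
    return generate_fingerprints(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_substances) -> ModelingDataset:
    """Descriptors + leave-self-out KNN column + latent toxicity labels."""
    F = np.array([s.fingerprint for s in small_substances])
    ids = [s.substance_id for s in small_substances]
    y, _ = latent_toxicity(small_cfg)
    X = pd.DataFrame([s.descriptors for s in small_substances])
    X = X[list(DESCRIPTOR_NAMES)]
    X["KNN"] = knn_feature_column(F, ids, y)["knn"].to_numpy()
    return ModelingDataset(ids=ids, X=X, y=y, fingerprints=F)
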