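import numpy as np
import pytest

from latentconn.autoencoder import EncoderSpec, make_splits, train
from latentconn.data import EdgeScaler, ParcelScheme, residualize_confounds
from latentconn.synthetic import SyntheticConfig, cohort_edge_tables, generate_cohort


@pytest.fixture(scope="session")
def rank5_edges():
    """Noiseless rank-5 edge data (15 parcels per hemisphere -> 105 edges)."""
    rng = np.random.default_rng(0)
    n, d, rank = 200, 105, 5
    loadings = rng.standard_normal((rank, d)) * 0.5 / np.sqrt(rank)
    scores = rng.standard_normal((n, rank))
    return 3.0 + scores @ loadings


@pytest.fixture(scope="session")
def small_trained_model(rank5_edges):
    """Small autoencoder trained on scaled rank-5 edges."""
    X = rank5_edges
    plan = make_splits(X.shape[0], n_repeats=1, seed=1)[0]
    scaler = EdgeScaler().fit(X[plan.train])
    spec = EncoderSpec(
        hidden_sizes=[64, 32],
        bottleneck=8,
        input_dropout=0.0,
        learning_rate=0.2,
        max_epochs=1500,
    )
    model = train(
        scaler.transform(X[plan.train]),
        scaler.transform(X[plan.validation]),
        spec,
        seed=2,
        scaler=scaler,
    )
    return model, plan, X


@pytest.fixture(scope="session")
def planted_cohort():
    """68-parcel cohort with a delta=0.5 shift in the default-mode block."""
    config = SyntheticConfig(
        n_autism=100,
        n_control=100,
        n_parcels=68,
        effect_blocks=[("default_mode", "default_mode", 0.5)],
        seed=42,
    )
    phenotype, matrices, truth = generate_cohort(config)
    scheme = ParcelScheme.default(68)
    left, right, combined = cohort_edge_tables(matrices, scheme)
    resid = {
        "L": residualize_confounds(left, phenotype),
        "R": residualize_confounds(right, phenotype),
    }
    return {
        "config": config,
        "phenotype": phenotype,
        "matrices": matrices,
        "truth": truth,
        "scheme": scheme,
        "combined": combined,
        "resid": resid,
    }
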