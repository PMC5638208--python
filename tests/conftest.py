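import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regulead.interactomes import Interactome, Regulon
from regulead.signatures import ExpressionMatrix, GeneSignature

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("regulead").setLevel(logging.ERROR)


def build_regulon(regulator, targets, modes, weights, source="synthetic"):
    table = pd.DataFrame(
        {"mode": np.asarray(modes, float), "weight": np.asarray(weights, float)},
        index=pd.Index(targets, name="target"),
    )
    return Regulon(regulator=regulator, table=table, source=source)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_interactome():
    """Two disjoint 12-target regulons plus one mixed-mode regulon."""
    genes = [f"G{i:03d}" for i in range(36)]
    regulons = {
        "RA": build_regulon("RA", genes[:12], [1] * 12, np.linspace(0.4, 1, 12)),
        "RB": build_regulon("RB", genes[12:24], [-1] * 12, np.ones(12)),
        "RC": build_regulon("RC", genes[24:36], [1] * 4 + [-1] * 4 + [0] * 4,
                            np.ones(12)),
    }
    return Interactome(name="toy", regulons=regulons, source="synthetic")


@pytest.fixture
def gaussian_signature(rng):
    values = pd.Series(rng.standard_normal(500),
                       index=[f"G{i:03d}" for i in range(500)])
    return GeneSignature(values=values, label="gauss")


@pytest.fixture
def expression_matrix(rng):
    genes = [f"G{i:03d}" for i in range(40)]
    samples = [f"S{i:02d}" for i in range(12)]
    data = pd.DataFrame(rng.standard_normal((40, 12)), index=genes, columns=samples)
    meta = pd.DataFrame(
        {"perturbation": ["p1"] * 6 + ["p2"] * 6,
         "replicate_group": ["r1"] * 3 + ["r2"] * 3 + ["r3"] * 3 + ["r4"] * 3,
         "plate": ["A"] * 6 + ["B"] * 6},
        index=samples,
    )
    return ExpressionMatrix(data=data, metadata=meta)
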