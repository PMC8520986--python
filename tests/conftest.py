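import numpy as np
import pytest

from qsarnet import ClassifierSpec, DescriptorMatrix, PropertyLabels


@pytest.fixture
def separable_xy():
    """Two well-separated Gaussian clusters in 2-D, n=40, labels by cluster."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(-3.0, 0.5, (20, 2)), rng.normal(3.0, 0.5, (20, 2))])
    ids = [f"c{i}" for i in range(40)]
    matrix = DescriptorMatrix(ids, ["d1", "d2"], X)
    labels = PropertyLabels(ids, "OB", ["-"] * 20 + ["+"] * 20)
    return matrix, labels


@pytest.fixture(params=["KNN", "SVM", "RF", "PLSDA", "EBPT"])
def any_spec(request):
    hp = {"KNN": {"k": 3}, "RF": {"n_trees": 30}, "EBPT": {"epochs": 200}}.get(request.param, {})
    return ClassifierSpec(request.param, hp, seed=0)
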