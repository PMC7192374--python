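import numpy as np
import pandas as pd
import pytest

from tnbcsubtype import (
    CentroidSet,
    ExpressionMatrix,
    Scale,
    SyntheticCohortSpec,
    classify_cohort,
    generate_centroids,
    generate_cohort,
)


def spearman_bruteforce(x, y):
    """Independent Spearman oracle: explicit average ranks + product-moment
    correlation of the ranks, in plain python arithmetic."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0  # average of 1-based positions i..j
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / (sxx * syy) ** 0.5


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data, scale=Scale.LINEAR)


@pytest.fixture
def small_centroids():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(20)]
    data = pd.DataFrame(
        rng.normal(size=(20, 3)), index=genes, columns=["BL1", "BL2", "M"]
    )
    im = pd.Series(rng.normal(size=20), index=genes)
    return CentroidSet(data, im_centroid=im, algorithm_label="test")


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticCohortSpec(seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    centroids = generate_centroids(default_spec)
    matrix, truth = generate_cohort(default_spec, centroids)
    return default_spec, centroids, matrix, truth


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    _, centroids, matrix, truth = default_cohort
    return classify_cohort(matrix, centroids)
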