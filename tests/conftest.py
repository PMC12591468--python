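import numpy as np
import pytest

from cytocomm import (
    ChannelPanel,
    GaussianComponent,
    GMParams,
    HypothesisModelSet,
)

PANEL6 = ChannelPanel()


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def univariate_model(mean: float, var: float = 1.0, rho: float = 1.0,
                     mean2: float | None = None, var2: float | None = None,
                     index: int = -1) -> GMParams:
    """Convenience builder for K=1 mixtures used across tests."""
    return GMParams(
        rho=rho,
        comp1=GaussianComponent([mean], [[var]]),
        comp2=GaussianComponent([mean if mean2 is None else mean2],
                                [[var if var2 is None else var2]]),
        hypothesis_index=index,
    )


def random_model_set(rng: np.random.Generator, M: int, K: int,
                     mean_scale: float = 1.5) -> HypothesisModelSet:
    """Random well-conditioned mixture hypotheses for oracle battles."""
    models = []
    for i in range(M):
        comps = []
        for _ in range(2):
            mean = mean_scale * rng.standard_normal(K)
            A = rng.standard_normal((K, K)) / np.sqrt(K)
            cov = A @ A.T + 0.3 * np.eye(K)
            comps.append(GaussianComponent(mean, cov))
        rho = float(rng.uniform(0.3, 0.7))
        models.append(GMParams(rho, comps[0], comps[1], hypothesis_index=i))
    return HypothesisModelSet(models)


@pytest.fixture
def write_csv(tmp_path):
    """Write a CSV from header + rows; returns the path."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = [",".join(header)]
        lines += [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
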