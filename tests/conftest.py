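import numpy as np
import pytest

from cvgsa import default_bounds, pipeline, samplers


@pytest.fixture(scope="session")
def nominal_waveform_1ch():
    from cvgsa import simulate

    return simulate("one_chamber")


@pytest.fixture(scope="session")
def nominal_waveform_2ch():
    from cvgsa import simulate

    return simulate("two_chamber")


@pytest.fixture(scope="session")
def sobol_bundle_1ch():
    """Continuous-waveform pick-freeze bundle, 1-chamber model, Sobol design,
    N=2000 at the default 0.5-1.5x bounds — the scaled replication condition
    shared by the acceptance-level checks (its discrete twin is a reduction)."""
    pf = samplers.pick_freeze_design("sobol", 2000, 9, seed=1,
                                     bounds=default_bounds("one_chamber"))
    bundle, _ = pipeline.evaluate_pick_freeze("one_chamber", pf, "continuous")
    return bundle


def ishigami(X: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
            + b * X[:, 2] ** 4 * np.sin(X[:, 0]))


def ishigami_total_indices(a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Closed-form total-order indices of the Ishigami function on U(-pi,pi)^3."""
    p4, p8 = np.pi**4, np.pi**8
    var = a**2 / 8 + b * p4 / 5 + b**2 * p8 / 18 + 0.5
    v1 = 0.5 * (1 + b * p4 / 5) ** 2
    v2 = a**2 / 8
    v13 = 8 * b**2 * p8 / 225
    return np.array([(v1 + v13) / var, v2 / var, v13 / var])
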