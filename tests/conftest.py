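import numpy as np
import pytest

from moescreen.classify import profile_chemical
from moescreen.records import ChemicalRecord
from moescreen.synthetic import PANEL, generate_bundle


@pytest.fixture(scope="session")
def panel_profiles():
    """Structural profiles for every template-panel exemplar."""
    out = {}
    for category, entries in PANEL.items():
        for smiles, kroes in entries:
            out[smiles] = (
                category,
                kroes,
                profile_chemical(ChemicalRecord(chem_id=smiles, smiles=smiles)),
            )
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-chemical TTC-consistent synthetic bundle (deterministic)."""
    return generate_bundle(40, seed=11, ttc_consistent=True, noael_n_range=(20, 40))


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)


def quantile_type2_oracle(values, p):
    """Independent brute-force type-2 quantile via the discontinuous CDF.

    Q(p) is the midpoint of inf{x : F(x) >= p} and inf{x : F(x) > p}
    evaluated on the sample's order statistics (the two coincide except when
    p sits exactly on a CDF jump).
    """
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def cdf(x):
        return sum(1 for v in xs if v <= x) / n

    lower = next(x for x in xs if cdf(x) >= p)
    above = [x for x in xs if cdf(x) > p]
    upper = above[0] if above else xs[-1]
    return 0.5 * (lower + upper)
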