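import pytest

from isletquant import BinningScheme, kansas_rat_2012


@pytest.fixture(scope="session")
def rat_model():
    """The built-in published rat diameter->cells cubic (20-350 um)."""
    return kansas_rat_2012()


@pytest.fixture(scope="session")
def conventional_scheme():
    """Six 50-um bins from 50 to 350 um with endpoint-mean factors."""
    return BinningScheme.conventional()


#: Conventional 50-um bin factors derived once by direct edge-cube averaging
#: ((lo^3 + hi^3) / (2 * 150^3)), frozen for regression testing.
CONVENTIONAL_FACTORS_3DP = (0.167, 0.648, 1.685, 3.500, 6.315, 10.352)
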