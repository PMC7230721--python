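import numpy as np
import pytest

from calorflex.gas_exchange_io import EpochSeries, GasExchangeTrace, GasSample


@pytest.fixture
def rng():
    return np.random.default_rng(20200423)


def build_trace(t, vo2, vco2, ve=None, duration_s=None, pid="T") -> GasExchangeTrace:
    """Construct a trace from parallel arrays (helper, not a fixture)."""
    t = np.asarray(t, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    ve = np.asarray(ve, dtype=float) if ve is not None else vo2 / 10.0
    samples = tuple(
        GasSample(t=a, vo2=b, vco2=c, ve=d) for a, b, c, d in zip(t, vo2, vco2, ve)
    )
    return GasExchangeTrace(
        participant_id=pid,
        samples=samples,
        duration_s=duration_s if duration_s is not None else float(t[-1]),
    )


def build_series(vo2, vco2, ve=None, epoch_s=30.0, missing=None) -> EpochSeries:
    """Construct an EpochSeries directly from per-epoch means."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    ve = np.asarray(ve, dtype=float) if ve is not None else vo2 / 10.0
    missing = (
        np.asarray(missing, dtype=bool)
        if missing is not None
        else np.zeros(len(vo2), dtype=bool)
    )
    return EpochSeries(
        epoch_s=epoch_s,
        vo2=vo2,
        vco2=vco2,
        ve=ve,
        rer=vco2 / vo2,
        missing=missing,
        n_samples=np.where(missing, 0, 1),
    )


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Small on-disk cohort + traces written once per session."""
    from calorflex.synthetic_data import make_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixture_suite(out, n=12, seed=7)
    return out, manifest
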