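import numpy as np
import pytest

import probepanel as pp


@pytest.fixture(scope="session")
def lib40():
    """The platform-scale library: 40 probes, 35-base barcodes, >=5 mismatches apart."""
    return pp.generate_barcode_library(40, 35, 5, seed=7)


@pytest.fixture(scope="session")
def lib5():
    return pp.generate_barcode_library(5, 20, 4, seed=3)


@pytest.fixture(scope="session")
def sim_params():
    return pp.SimulationParams(seed=1)


@pytest.fixture(scope="session")
def clean_params():
    """Error-free basecalls, no spurious blockades."""
    return pp.SimulationParams(
        seed=2, basecall_sub_rate_5p=0.0, basecall_sub_rate_3p=0.0,
        indel_rate=0.0, spurious_short_event_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_run(lib5, sim_params):
    """One small multiplexed trace with truth and reads (5 probes at 5 nM)."""
    mix = {p: 5.0 for p in lib5.probe_ids}
    trace, truth = pp.simulate_trace(lib5, mix, sim_params, n_events=150, trace_id="small")
    reads = pp.simulate_basecalls(truth, lib5, sim_params)
    return trace, truth, reads
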