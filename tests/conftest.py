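"""Shared fixtures.

The ``study`` / ``local_study`` fixtures run the full desk-scale protocol
(5 frequency configurations, 60 timings per state, coupling grid step 0.01)
once per session; the acceptance tests all read from them.  Seeds are fixed
constants chosen up front.
"""

from __future__ import annotations

import pytest

from critresp.connectome import generate_synthetic_connectome
from critresp.experiments import ProtocolConfig, run_global_protocol, run_local_protocol

CONN_SEED = 11
STUDY_SEED = 2026

STUDY_KW = dict(n_freq_configs=5, n_timings=60, dk=0.01, master_seed=STUDY_SEED)

#: Tiny-but-complete protocol settings for fast structural tests.
TINY_KW = dict(
    n_freq_configs=1,
    n_timings=2,
    n_baseline_iterations=2,
    dk=0.1,
    burn_in=2.0,
    record_len=4.0,
    master_seed=123,
)


@pytest.fixture(scope="session")
def conn82():
    return generate_synthetic_connectome(rng_seed=CONN_SEED)

@pytest.fixture(scope="session")
def small_conn():
    return generate_synthetic_connectome(n_nodes=12, edge_density=0.4, rng_seed=3)


@pytest.fixture(scope="session")
def study(conn82):
    cfg = ProtocolConfig(**STUDY_KW)
    return run_global_protocol(conn82, cfg)


@pytest.fixture(scope="session")
def local_study(conn82, study):
    cfg = ProtocolConfig(**STUDY_KW)
    return run_local_protocol(conn82, cfg, profile=study.profile)
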