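"""Shared fixtures: the expensive reference runs are computed once per session."""

import numpy as np
import pytest

import airwayrfa as a
from airwayrfa import experiments as exp


@pytest.fixture(scope="session")
def default_table():
    return a.default_table()


@pytest.fixture(scope="session")
def branched_reference_run(default_table):
    """Closed-loop temperature-controlled run on the 1 mm branched cast.

    Shared by the controller-regulation, safety-distance and lesion tests.
    """
    domain, tree = exp.reference_branched_domain(
        seed=0, depth=3, config={"sheath_length": 20.0})
    protocol = exp.reference_protocol(duration=300.0)
    result = a.run_ablation(domain, default_table, protocol)
    return {"domain": domain, "tree": tree, "protocol": protocol,
            "result": result}
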