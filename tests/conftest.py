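import numpy as np
import pandas as pd
import pytest

from efficacysim.agent import AgentConfig, BackgroundConfig, init_background
from efficacysim.memory import MemoryParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def background_store():
    """Default 2,100-chunk background memory (session-scoped, read-only)."""
    return init_background(BackgroundConfig(rng_seed=1), MemoryParams())


@pytest.fixture
def toy_log():
    """Three participants, hand-enumerable adherence log.

    p1 succeeds every exercise day; p2 alternates day success; p3 never
    succeeds.  Three goals per exercise day on days 1, 3, 5.
    """
    rows = []
    days = [1, 3, 5]
    success = {
        "p1": {1: [1, 1, 1], 3: [1, 0, 1], 5: [1, 1, 1]},
        "p2": {1: [1, 0, 0], 3: [0, 0, 0], 5: [1, 1, 0]},
        "p3": {1: [0, 0, 0], 3: [0, 0, 0], 5: [0, 0, 0]},
    }
    for pid in ("p1", "p2", "p3"):
        for d in days:
            for j in range(3):
                rows.append({"participant_id": pid, "day": d,
                             "exercise_id": f"e{j + 1}",
                             "success": success[pid][d][j],
                             "condition": "adaptive",
                             "difficulty": -0.5 + 0.1 * j})
    return pd.DataFrame(rows)
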