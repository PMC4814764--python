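import sys
from pathlib import Path

import numpy as np
import pytest

# allow `import oracles` from any test module
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tmp_events_csv(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "child_id,stream,start_s,end_s,category,level\n"
        "c01,gesture,12.0,15.0,representation,3\n"
        "c01,speech,13.0,20.0,description,4\n"
        "c01,gesture,20.0,22.0,emblem,\n"
        "c02,speech,0.0,5.0,explanation,7\n"
    )
    return path
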