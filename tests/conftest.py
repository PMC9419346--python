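import logging
from datetime import datetime

import numpy as np
import pytest

from chapchild import synthetic
from chapchild.io_formats import EpochLabelSeries

# the drop-remainder log lines are expected on synthetic day lengths
logging.getLogger("chapchild.preprocess").setLevel(logging.ERROR)

T0 = datetime(2022, 3, 1, 8, 0, 0)


@pytest.fixture(scope="session")
def tiny_study():
    """Three participants, one half-hour day each: fast full-stack fixture."""
    cfg = synthetic.SimConfig(
        n_participants=3, days_per_participant=1, day_wear_hours=0.5, seed=42
    )
    return synthetic.make_study(cfg)


def series(labels, epoch_s=10, start=T0, probs=None, source="activpal"):
    """Shorthand EpochLabelSeries constructor for label-pattern tests."""
    return EpochLabelSeries(
        start, epoch_s, np.array(list(labels), dtype=object), probs, source
    )


def expand(pattern: str):
    """'SSN' → ['SIT','SIT','NONSIT']; U → UNWORN."""
    m = {"S": "SIT", "N": "NONSIT", "U": "UNWORN"}
    return [m[c] for c in pattern]
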