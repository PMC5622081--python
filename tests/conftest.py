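import pandas as pd
import pytest

from segspeech import stimgen


@pytest.fixture(scope="session")
def l1():
    return stimgen.build_language(id="L1")


@pytest.fixture(scope="session")
def l2():
    return stimgen.build_language(id="L2")


@pytest.fixture(scope="session")
def l1_melodic(l1):
    return stimgen.assign_pitches(l1, "melodic")


@pytest.fixture(scope="session")
def l1_flat(l1):
    return stimgen.assign_pitches(l1, "flat")


@pytest.fixture(scope="session")
def learning_stream(l1_melodic):
    return stimgen.generate_learning_stream(l1_melodic, reps=50, seed=0)


@pytest.fixture(scope="session")
def test_stream(l1_melodic):
    return stimgen.generate_test_stream(l1_melodic, seed=0)


def make_amplitude_table(values, phase="learning"):
    """Build a tidy window-amplitude table from a nested dict
    subject -> condition -> cell -> channel -> amplitude (learning), with
    windows attached per phase."""
    rows = []
    for subject, conds in values.items():
        for condition, cells in conds.items():
            for cell, chans in cells.items():
                for (channel, win), amp in chans.items():
                    rows.append({
                        "subject": subject, "condition": condition,
                        "phase": phase, "cell": cell, "channel": channel,
                        "win_lo_ms": win[0], "win_hi_ms": win[1],
                        "amplitude_uv": amp,
                    })
    return pd.DataFrame(rows)
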