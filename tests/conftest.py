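import numpy as np
import pytest

import fieldsync as fs
from fieldsync._util import derive_seed


@pytest.fixture(scope="session")
def syn_spec():
    return fs.make_condition("synaptic_blockers")


@pytest.fixture(scope="session")
def short_recording(syn_spec):
    """120 s paired recording at 2 kHz (fast; below the sync minimum)."""
    return fs.simulate_recording(syn_spec, 120.0, seed=5, sampling_rate=2000.0)


@pytest.fixture(scope="session")
def full_recording(syn_spec):
    """600 s paired recording at the native 10 kHz."""
    return fs.simulate_recording(syn_spec, 600.0, seed=3)


def child_seed(parent, i):
    return derive_seed(parent, i)


def match_events(detected, truth, tol=0.3):
    """Greedy onset matching of detected vs ground-truth discharges.

    Returns (n_true_positive, n_detected, n_truth, duration_errors).
    """
    gto = truth["onset_s"].to_numpy()
    gtoff = truth["offset_s"].to_numpy()
    used = set()
    tp = 0
    errs = []
    for o, off in zip(detected["onset_s"], detected["offset_s"]):
        if len(gto) == 0:
            break
        j = int(np.argmin(np.abs(gto - o)))
        if abs(gto[j] - o) < tol and j not in used:
            used.add(j)
            tp += 1
            errs.append((off - o) - (gtoff[j] - gto[j]))
    return tp, len(detected), len(gto), np.asarray(errs)
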