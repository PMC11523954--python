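import numpy as np
import pytest

from pwlscore import SimulationConfig, simulate_cohort
from pwlscore.simulate import default_snp_mafs


@pytest.fixture(scope="session")
def small_cohort():
    """A modest signal-bearing cohort shared by structural tests."""
    beta = np.zeros(4 + 10 + 6)
    beta[4:7] = 1.2
    beta[14] = 1.0
    config = SimulationConfig(
        n_samples=200,
        n_binary_clinical=4,
        n_quant_clinical=10,
        snp_mafs=default_snp_mafs(6),
        effect_vector=beta,
        missing_rate=0.05,
        censor_rate=0.25,
        seed=11,
    )
    return simulate_cohort(config)


def brute_force_auc(y, scores):
    """Exhaustive pair counting; ties in score count one half."""
    y = np.asarray(y)
    scores = np.asarray(scores, float)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    num = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / (len(pos) * len(neg))


def brute_force_c(time, event, pred):
    """Exhaustive comparable-pair enumeration (pred: higher = longer survival).

    A pair is comparable when the earlier time is an event; equal times are
    comparable only when exactly one is an event (the event came first).
    Tied predictions count one half.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    pred = np.asarray(pred, float)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if event[i] + event[j] != 1:
                    continue
                first, other = (i, j) if event[i] else (j, i)
            else:
                first, other = (i, j) if time[i] < time[j] else (j, i)
                if not event[first]:
                    continue
            den += 1
            if pred[first] < pred[other]:
                num += 1
            elif pred[first] == pred[other]:
                num += 0.5
    if den == 0:
        return float("nan")
    return num / den
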