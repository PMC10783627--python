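import numpy as np
import pytest

from nocirig.signals import DetectionConfig, SignalTrace, StimulusEvent


@pytest.fixture
def default_cfg() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def pulse_stim() -> StimulusEvent:
    """100-ms blue pulse at 500 ms with a 1.4 s detection window."""
    return StimulusEvent("optogenetic", waveform="pulse", onset=500.0, intensity=5.0, cutoff=1400.0)


def make_trace(values, fs=1000.0, t0=0.0, units="mV") -> SignalTrace:
    return SignalTrace(np.asarray(values, dtype=float), fs=fs, t0=t0, units=units)


def brute_force_reflectance(trace, stim, cfg):
    """Independent sample-by-sample evaluation of the reflectance rule.

    Trailing mean computed by direct slice averaging, baseline by direct
    masking, runs scanned one sample at a time.  Deliberately slow and
    simple: the oracle for the vectorized and streaming detectors.
    """
    v = trace.values
    t = trace.times
    dt = trace.dt
    n = max(1, round(cfg.smooth_window * trace.fs / 1000.0))
    sm = np.array([v[max(0, k - n + 1): k + 1].mean() for k in range(len(v))])
    base_mask = (t >= stim.onset - cfg.baseline_window) & (t < stim.onset)
    base = sm[base_mask].mean()
    thr = base - cfg.reflectance_drop
    win = np.flatnonzero((t > stim.onset) & (t <= stim.onset + stim.cutoff))
    run_start = None
    run_len = 0
    for k in win:
        if sm[k] < thr:
            if run_len == 0:
                run_start = k
            run_len += 1
            if run_len * dt > cfg.persistence:
                return True, t[run_start] - stim.onset
        else:
            run_len = 0
            run_start = None
    return False, stim.cutoff
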