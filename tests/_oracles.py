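"""Independent brute-force reference implementations for oracle tests.

These re-derive detector outputs with plain per-second scans of the
stated rules and must stay independent of the package implementations
they check.
"""

import numpy as np


def naive_deltas(pressure):
    n = len(pressure)
    d = [0.0] * n
    for t in range(1, n):
        d[t] = sum(abs(float(pressure[t][i]) - float(pressure[t - 1][i]))
                   for i in range(8))
    return d


def naive_toss_scan(pressure, threshold, quiescence):
    """Per-second scan: open above threshold, close at the start of the
    first run of `quiescence` consecutive at-or-below seconds (else at
    stream end)."""
    d = naive_deltas(pressure)
    n = len(d)
    events = []
    t = 1
    while t < n:
        if d[t] > threshold:
            start = t
            end = n
            for tau in range(start + 1, n):
                if tau + quiescence <= n and all(
                        d[tau + k] <= threshold for k in range(quiescence)):
                    end = tau
                    break
            events.append((start, end))
            t = end + quiescence
        else:
            t += 1
    return events


def naive_snore_scan(sound, threshold, max_capture, rearm_delay):
    """Per-second scan of the capture rule: open strictly above threshold,
    close on fall-back or at the capture cap, re-arm after the delay."""
    n = len(sound)
    events = []
    armed_at = 0
    t = 0
    while t < n:
        if t >= armed_at and sound[t] > threshold:
            start = t
            end = start + 1
            while end < min(start + max_capture, n) and sound[end] > threshold:
                end += 1
            events.append((start, end))
            armed_at = end + rearm_delay
            t = max(end, armed_at)
        else:
            t += 1
    return events


def naive_roc_auc(scores, labels):
    """All-thresholds ROC enumeration + trapezoid, REM(1) positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels.sum()
    neg = len(labels) - pos
    points = {(0.0, 0.0), (1.0, 1.0)}
    for theta in np.unique(scores):
        pred = scores >= theta
        tpr = float(np.sum(pred & (labels == 1)) / pos)
        fpr = float(np.sum(pred & (labels == 0)) / neg)
        points.add((fpr, tpr))
    pts = sorted(points)
    return float(sum((b[0] - a[0]) * (a[1] + b[1]) / 2.0
                     for a, b in zip(pts, pts[1:])))


def random_pressure_stream(rng, n=600, burst_rate=0.01, amp=150.0):
    """Noise-floor pressure stream with random movement bursts."""
    base = rng.uniform(10, 40, size=8)
    p = base + rng.normal(0, 3.0, size=(n, 8))
    t = 0
    while t < n:
        if rng.random() < burst_rate:
            dur = int(rng.integers(1, 6))
            p[t:t + dur] += rng.uniform(0, amp, size=(min(dur, n - t), 8))
            t += dur
        t += 1
    return np.clip(p, 0, None)


def random_sound_stream(rng, n=600, burst_rate=0.05):
    """Quiet floor with supra-threshold bursts of varied length."""
    s = rng.normal(25.0, 1.0, size=n)
    t = 0
    while t < n:
        if rng.random() < burst_rate:
            dur = int(rng.integers(1, 20))
            s[t:t + dur] = rng.normal(40.0, 3.0, size=min(dur, n - t))
            t += dur
        t += 1
    return s
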