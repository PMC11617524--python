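"""Shared brute-force I-VT oracle: naive sample-by-sample velocity scan."""

import numpy as np


def brute_force_ivt(stream, thr_dps=30.0, min_ms=60.0, dist=1.0):
    t, p, v = stream.timestamps_ms, stream.points, stream.validity
    n = len(t)
    slow = []
    for i in range(n - 1):
        d = np.hypot(p[i + 1, 0] - p[i, 0], p[i + 1, 1] - p[i, 1])
        ang = np.degrees(2 * np.arctan2(d, 2 * dist))
        vel = ang / ((t[i + 1] - t[i]) / 1000.0)
        slow.append(vel < thr_dps and v[i] and v[i + 1])
    dt = np.median(np.diff(t)) if n > 1 else 20.0
    out = []
    i = 0
    while i < n - 1:
        if slow[i]:
            j = i
            while j < n - 1 and slow[j]:
                j += 1
            dur = (j - i + 1) * dt
            if dur >= min_ms:
                out.append((t[i], dur))
            i = j
        else:
            i += 1
    return out
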