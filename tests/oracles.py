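"""Independent brute-force oracles for the signal chain.

These evaluate the same definitions as the library — Butterworth difference
equations, rolling-window activity rule, trapezoid quadrature, percentile by
sort-and-interpolate — but sample-by-sample in plain Python loops, sharing
no code with the implementation paths they check.
"""

import numpy as np
from scipy.signal import butter, lfilter_zi


def lfilter_loop(b, a, x, zi=None):
    """Direct-form-II-transposed difference equation, one sample at a time."""
    b = np.asarray(b, float) / a[0]
    a = np.asarray(a, float) / a[0]
    nstate = max(len(a), len(b)) - 1
    z = np.zeros(nstate) if zi is None else np.array(zi, float)
    y = np.empty(len(x))
    for n, xn in enumerate(x):
        yn = b[0] * xn + z[0]
        for i in range(nstate - 1):
            z[i] = b[i + 1] * xn + z[i + 1] - a[i + 1] * yn
        z[nstate - 1] = b[nstate] * xn - a[nstate] * yn
        y[n] = yn
    return y


def filtfilt_loop(b, a, x):
    """Forward-backward filtering with odd edge extension, via loops."""
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        padlen = len(x) - 1
    left = 2 * x[0] - x[padlen:0:-1]
    right = 2 * x[-1] - x[-2:-padlen - 2:-1]
    ext = np.concatenate([left, x, right])
    zi = lfilter_zi(b, a)
    y = lfilter_loop(b, a, ext, zi=zi * ext[0])
    y = y[::-1]
    y = lfilter_loop(b, a, y, zi=zi * y[0])
    y = y[::-1]
    return y[padlen:len(y) - padlen]


def preprocess_loop(stream, cfg):
    """The full per-axis chain evaluated with the loop filters."""
    b_lo, a_lo = butter(cfg.lowpass_order, cfg.lowpass_cutoff_hz,
                        btype="lowpass", fs=stream.rate)
    b_hi, a_hi = butter(cfg.highpass_order, cfg.highpass_cutoff_hz,
                        btype="highpass", fs=stream.rate)
    filt = filtfilt_loop if cfg.zero_phase else lfilter_loop
    chans = []
    for arr in (stream.ax, stream.ay, stream.az):
        low = filt(b_lo, a_lo, np.asarray(arr, float))
        rect = np.abs(low)
        chans.append(filt(b_hi, a_hi, rect))
    out = np.empty(len(stream.ax))
    for i in range(len(out)):
        out[i] = np.sqrt(
            chans[0][i] ** 2 + chans[1][i] ** 2 + chans[2][i] ** 2
        )
    return out


def detect_active_loop(values, rate, cfg):
    """Evaluate every centered rolling window explicitly."""
    n = len(values)
    window = int(round(cfg.window_s * rate))
    half = window // 2
    active = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i - half + window, n)
        count = sum(1 for v in values[lo:hi] if v >= cfg.active_threshold_g)
        active[i] = count >= cfg.window_fraction * (hi - lo)
    intervals = []
    i = 0
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return intervals


def trapezoid_loop(values, start, end, rate):
    """Trapezoid sum over [start, end) with the right-boundary sample."""
    stop = min(end + 1, len(values))
    total = 0.0
    for i in range(start, stop - 1):
        total += 0.5 * (values[i] + values[i + 1]) / rate
    return total


def percentile_loop(values, q):
    """Sort-and-linearly-interpolate percentile."""
    s = sorted(values)
    pos = (len(s) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return s[lo] + (s[hi] - s[lo]) * (pos - lo)
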