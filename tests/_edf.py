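"""Minimal synthetic EDF writer, used only to construct read fixtures in tests.

Writes a single-record EDF file (16-bit samples, physical range +-1000) —
a synthetic stand-in for a recorded EEG file, not a general-purpose
exporter.
"""

import numpy as np


def write_edf(path, data: np.ndarray, fs: float, ch_names) -> None:
    n_ch, n_samp = data.shape
    dur = n_samp / fs
    pmin, pmax = -1000.0, 1000.0
    dmin, dmax = -32768, 32767
    hdr = b"0".ljust(8)
    hdr += b"synthetic patient".ljust(80)
    hdr += b"synthetic recording".ljust(80)
    hdr += b"01.01.20".ljust(8)
    hdr += b"00.00.00".ljust(8)
    hdr += str(256 + 256 * n_ch).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += b"1".ljust(8)
    hdr += f"{dur:g}".encode().ljust(8)
    hdr += str(n_ch).encode().ljust(4)
    fields = [
        (lambda c: ch_names[c], 16),
        (lambda c: "", 80),
        (lambda c: "uV", 8),
        (lambda c: f"{pmin:g}", 8),
        (lambda c: f"{pmax:g}", 8),
        (lambda c: str(dmin), 8),
        (lambda c: str(dmax), 8),
        (lambda c: "", 80),
        (lambda c: str(n_samp), 8),
        (lambda c: "", 32),
    ]
    for fn, width in fields:
        for c in range(n_ch):
            hdr += str(fn(c)).encode().ljust(width)
    scaled = np.clip(
        (data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin, dmin, dmax
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(scaled.tobytes())
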