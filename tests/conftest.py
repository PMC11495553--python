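"""Shared fixtures: tiny synthetic recordings and a minimal EDF writer."""

from __future__ import annotations

import numpy as np
import pytest

from rsbagging.eeg_io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """20-channel white-noise recording, 10 s at 250 Hz, average scale ~10 µV."""
    from rsbagging.eeg_io import DEFAULT_MONTAGE

    data = 10.0 * rng.standard_normal((20, 2500))
    return Recording(data, 250.0, list(DEFAULT_MONTAGE.labels), "noise")


def write_minimal_edf(path, data, fs, labels, phys_range=400.0):
    """Write a bare-bones EDF file: 1 s records, 16-bit samples.

    Quantization error is phys_range/65536 per sample.
    """
    n_ch, n_samp = data.shape
    spr = int(fs)
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "use a whole number of 1 s records"

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    header = b""
    header += pad("0", 8).encode()
    header += pad("synthetic patient", 80).encode()
    header += pad("synthetic recording", 80).encode()
    header += pad("01.01.24", 8).encode()
    header += pad("00.00.00", 8).encode()
    header += pad(256 * (1 + n_ch), 8).encode()
    header += pad("", 44).encode()
    header += pad(n_rec, 8).encode()
    header += pad("1", 8).encode()
    header += pad(n_ch, 4).encode()
    for lab in labels:
        header += pad(lab, 16).encode()
    header += pad("", 80).encode() * n_ch          # transducer
    header += pad("uV", 8).encode() * n_ch          # physical dimension
    header += pad(-phys_range / 2, 8).encode() * n_ch
    header += pad(phys_range / 2, 8).encode() * n_ch
    header += pad(-32768, 8).encode() * n_ch
    header += pad(32767, 8).encode() * n_ch
    header += pad("", 80).encode() * n_ch          # prefiltering
    header += pad(spr, 8).encode() * n_ch
    header += pad("", 32).encode() * n_ch

    scale = 65535.0 / phys_range
    digital = np.clip(np.round(data * scale), -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())


@pytest.fixture
def edf_writer():
    return write_minimal_edf
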