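"""Shared helpers for the test suite."""

import numpy as np

from fnirscreen.containers import HemoSeries, RawRecording

FS = 8.138
W = int(np.floor(10 * FS))  # samples per 10-s window


def make_series(hbo, fs=FS, filter_state="filtered"):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    return HemoSeries(
        subject_id="S",
        channel_ids=np.arange(1, hbo.shape[0] + 1),
        hbo=hbo,
        hbr=-0.4 * hbo,
        fs=fs,
        filter_state=filter_state,
    )


def make_recording(delta_od, layout, fs=FS):
    return RawRecording(subject_id="S", layout=layout, delta_od=delta_od, fs=fs)
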