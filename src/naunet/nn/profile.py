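"""Forward-pass cost recording for the static complexity profiler.

A :class:`Recorder` activated around a forward pass collects one entry per
tensor operation with the static quantities (kernel size, channel counts,
output spatial dims) needed to price it.  Because the networks are fully
convolutional, every per-layer cost scales exactly with the number of output
spatial positions, so a pass traced at a small size can be re-priced at any
larger size by scaling H and W (see naunet.complexity).
"""

from __future__ import annotations

from contextlib import contextmanager

from . import autograd


class Recorder:
    def __init__(self):
        self.entries = []

    def add(self, kind, **info):
        self.entries.append({"kind": kind, **info})


@contextmanager
def record():
    """Context manager that activates a fresh Recorder and yields it."""
    rec = Recorder()
    prev = autograd._RECORDER
    autograd._RECORDER = rec
    try:
        yield rec
    finally:
        autograd._RECORDER = prev
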