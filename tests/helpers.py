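"""Tiny builders shared across test modules."""

import numpy as np

from erpscreen.synthetic import ERPRecord

FS = 640.0


def make_record(signal, fs=FS, **overrides):
    fields = dict(
        subject_id="S1",
        group_label="control",
        modality="auditory",
        electrode="Cz",
        sampling_rate=fs,
        signal=np.asarray(signal, dtype=float),
        gender="F",
        first_child=False,
    )
    fields.update(overrides)
    return ERPRecord(**fields)
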