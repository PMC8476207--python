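"""Tiny trial constructors shared by behavior-related tests."""

import numpy as np

from pairedstim.synthetic import TrialRecord


def _trial(thumb_max, index_max):
    n = 20
    return TrialRecord(
        trial_id=0, epoch="task_before", instructed="thumb", success=True,
        completion_time=1.0,
        thumb_trace=np.linspace(0.0, thumb_max, n),
        index_trace=np.linspace(0.0, index_max, n),
    )


def success_trial():
    return _trial(9.0, 4.0)


def failure_trial():
    return _trial(9.0, 12.0)
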