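"""Detection verdict: is the classifier reliable enough to detect UPB patterns?

A subject's system is READY when the classification accuracy strictly exceeds
the threshold (default 80%); at exactly the threshold it is NOT_READY (the
criterion is "exceeds", documented as a strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_THRESHOLD = 0.80

READY_MESSAGE = "Ready to detect unplanned purchase patterns."
NOT_READY_MESSAGE = "Not able to detect unplanned purchase patterns."


@dataclass(frozen=True)
class Verdict:
    status: str  # "READY" | "NOT_READY"
    accuracy: float
    threshold: float
    message: str

    @property
    def ready(self) -> bool:
        return self.status == "READY"


def detection_verdict(accuracy: float, threshold: float = DEFAULT_THRESHOLD) -> Verdict:
    """Map a classification accuracy (fraction) to a READY/NOT_READY verdict."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be within [0, 1], got {accuracy}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be within [0, 1], got {threshold}")
    if accuracy > threshold:
        return Verdict("READY", accuracy, threshold, READY_MESSAGE)
    return Verdict("NOT_READY", accuracy, threshold, NOT_READY_MESSAGE)
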