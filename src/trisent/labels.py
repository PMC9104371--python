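"""Sentiment class labels shared across the pipeline.

The three ordinal classes are kept in score order (negative < neutral <
positive) everywhere: confusion matrices, threshold intervals and reports
all index classes in this order.
"""

NEGATIVE = "negative"
NEUTRAL = "neutral"
POSITIVE = "positive"

#: Canonical class order used for matrices and reports.
CLASSES: tuple[str, str, str] = (NEGATIVE, NEUTRAL, POSITIVE)

CLASS_INDEX = {label: i for i, label in enumerate(CLASSES)}


def validate_label(label: str) -> str:
    if label not in CLASS_INDEX:
        raise ValueError(f"unknown sentiment label {label!r}; expected one of {CLASSES}")
    return label
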