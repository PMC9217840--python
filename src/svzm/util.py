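"""Shared helpers for two-class label handling."""

from __future__ import annotations

import pandas as pd


def two_classes(labels) -> tuple[pd.Series, tuple]:
    """Validate a two-class label vector and fix the (positive, negative)
    class order.

    The positive class is ``"SVZ+"`` when present; otherwise the
    lexicographically larger label. Returns ``(labels_as_series,
    (pos_label, neg_label))``.
    """
    labels = pd.Series(labels)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two label classes, got {classes}")
    if "SVZ+" in classes:
        pos = "SVZ+"
    else:
        pos = classes[1]
    neg = classes[0] if pos == classes[1] else classes[1]
    return labels, (pos, neg)
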