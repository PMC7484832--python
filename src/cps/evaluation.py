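"""ROC-formalism scoring of predicted versus observed collisions.

A predicted collision that was physically observed is a true positive; a
prediction with no observed collision is a false positive (the
conservative direction); a missed collision is a false negative (the
dangerous direction).  Ratios with a zero denominator are reported as
``None`` rather than coerced to a number, so degenerate validation
campaigns fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ConfusionCounts", "score_outcomes", "metrics"]

_TRUTHY = {"yes", "y", "true", "1", "collision"}
_FALSY = {"no", "n", "false", "0", "clear"}


def _as_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _TRUTHY:
            return True
        if v in _FALSY:
            return False
    raise ValueError(f"cannot interpret outcome flag {value!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for key in ("tp", "fp", "tn", "fn"):
            v = getattr(self, key)
            if v != int(v) or v < 0:
                raise ValueError(f"{key} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, key, int(v))
        if self.total < 1:
            raise ValueError("at least one outcome is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def score_outcomes(pairs) -> ConfusionCounts:
    """Count (predicted, observed) outcome pairs into a confusion table.

    Flags may be booleans, 0/1, or yes/no strings.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("outcome list is empty")
    tp = fp = tn = fn = 0
    for predicted, observed in pairs:
        p, o = _as_flag(predicted), _as_flag(observed)
        if p and o:
            tp += 1
        elif p and not o:
            fp += 1
        elif not p and not o:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, PPV, NPV; ``None`` when undefined."""

    def ratio(num: int, den: int):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }
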