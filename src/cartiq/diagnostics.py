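"""Histology scoring, reference-interval diagnostics and test combination.

Conventions: a test is *positive* when the value reads as intact tissue
(inside the intact-group reference interval), and the ground truth label
*int* counts as the "true" class.  Sensitivity is therefore the fraction of
histologically intact samples reading positive, and specificity the
fraction of degenerative samples reading negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HistologyScore",
    "ReferenceInterval",
    "DiagnosticResult",
    "mankin_sum",
    "dichotomize",
    "interval_from_int",
    "classify",
    "sens_spec",
    "combine",
    "combine_many",
    "diagnose_cohort_table",
    "DEFAULT_COMBINATIONS",
    "SUBSCORE_RANGES",
    "OUT_OF_STUDY",
]

#: Inclusive ceilings of the four histological subscores.
SUBSCORE_RANGES = {
    "structure": (0, 6),
    "cellularity": (0, 3),
    "proteoglycan": (0, 4),
    "tidemark": (0, 1),
}

INT, DEG = "int", "deg"
POSITIVE, NEGATIVE = "positive", "negative"
OUT_OF_STUDY = "out-of-study"


@dataclass(frozen=True)
class HistologyScore:
    """The four histological subscores and their sum."""

    structure: int
    cellularity: int
    proteoglycan: int
    tidemark: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in SUBSCORE_RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise ValueError(f"subscore {name}={v!r} outside range [{lo}, {hi}]")

    @property
    def mss(self) -> int:
        return self.structure + self.cellularity + self.proteoglycan + self.tidemark


@dataclass(frozen=True)
class ReferenceInterval:
    """Closed reference interval for one parameter (or its relative change)."""

    parameter: str
    lower: float
    upper: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if not self.lower <= self.upper:
            raise ValueError("interval lower bound exceeds upper bound")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError("log-scale interval bounds must be positive")


@dataclass
class DiagnosticResult:
    """Sensitivity/specificity of one (possibly combined) test."""

    name: str
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0


def mankin_sum(
    structure: int, cellularity: int, proteoglycan: int, tidemark: int
) -> int:
    """Sum of the four histological subscores (0-14).

    Raises
    ------
    ValueError
        If any component is outside its stated range.
    """
    return HistologyScore(structure, cellularity, proteoglycan, tidemark).mss


def dichotomize(mss: int) -> str:
    """Map a histological sum score to a degeneration group.

    0-4 reads intact, 5-8 early degenerative.  Scores of 9-14 are valid sums
    but fall outside the studied spectrum and are labelled
    ``"out-of-study"`` rather than guessed into a group.
    """
    if not 0 <= mss <= 14:
        raise ValueError(f"sum score {mss} outside [0, 14]")
    if mss <= 4:
        return INT
    if mss <= 8:
        return DEG
    return OUT_OF_STUDY


def interval_from_int(values_int, scale: str = "linear") -> ReferenceInterval:
    """Reference interval (mean +/- SD) from the intact group's values.

    On the linear scale the bounds are ``mean -/+ SD``; on the log scale the
    mean and SD are taken on log-values and exponentiated back.

    Raises
    ------
    ValueError
        For fewer than two values, or non-positive values on the log scale.
    """
    x = np.asarray(values_int, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite values to build an interval")
    if scale == "log":
        if np.any(x <= 0):
            raise ValueError("log-scale interval requires positive values")
        m, s = float(np.mean(np.log(x))), float(np.std(np.log(x), ddof=1))
        lo, hi = float(np.exp(m - s)), float(np.exp(m + s))
    elif scale == "linear":
        m, s = float(np.mean(x)), float(np.std(x, ddof=1))
        lo, hi = m - s, m + s
    else:
        raise ValueError("scale must be 'linear' or 'log'")
    return ReferenceInterval(parameter="", lower=lo, upper=hi, scale=scale)


def classify(value: float, interval: ReferenceInterval) -> str | None:
    """Positive (reads intact) iff the value lies inside the closed interval.

    Undefined values (NaN) are unclassifiable and return None; callers must
    exclude them explicitly rather than defaulting either way.
    """
    if not np.isfinite(value):
        return None
    return POSITIVE if interval.lower <= value <= interval.upper else NEGATIVE


def sens_spec(predictions, truth, name: str = "") -> DiagnosticResult:
    """Sensitivity, specificity and 2x2 counts of one test.

    ``predictions`` holds positive/negative labels (None entries are
    excluded and counted); ``truth`` holds int/deg group labels.  A truth
    class with no classified members leaves its rate NaN.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    tp = fp = tn = fn = excluded = 0
    for pred, t in zip(predictions, truth):
        if pred is None:
            excluded += 1
            continue
        if t == INT:
            if pred == POSITIVE:
                tp += 1
            else:
                fn += 1
        elif t == DEG:
            if pred == NEGATIVE:
                tn += 1
            else:
                fp += 1
        else:
            raise ValueError(f"unknown truth label {t!r}")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return DiagnosticResult(
        name=name, sensitivity=sens, specificity=spec,
        tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=excluded,
    )


def combine(predictions_a, predictions_b, rule: str) -> list:
    """Combine two tests' labels under a believe-the-positive/-negative rule.

    ``believe_positive``: combined positive iff either component is positive
    (maximizes sensitivity).  ``believe_negative``: combined negative iff
    either component is negative (maximizes specificity).  None entries
    propagate: a pair with an unclassifiable member is unclassifiable.
    """
    if rule not in ("believe_positive", "believe_negative"):
        raise ValueError("rule must be 'believe_positive' or 'believe_negative'")
    if len(predictions_a) != len(predictions_b):
        raise ValueError("prediction vectors must have equal length")
    out = []
    for a, b in zip(predictions_a, predictions_b):
        if a is None or b is None:
            out.append(None)
        elif rule == "believe_positive":
            out.append(POSITIVE if POSITIVE in (a, b) else NEGATIVE)
        else:
            out.append(NEGATIVE if NEGATIVE in (a, b) else POSITIVE)
    return out


def combine_many(prediction_lists, rule: str) -> list:
    """Fold :func:`combine` over k >= 2 component tests."""
    if len(prediction_lists) < 2:
        raise ValueError("need at least two component tests")
    out = prediction_lists[0]
    for preds in prediction_lists[1:]:
        out = combine(out, preds, rule)
    return out


# Default combined panels evaluated by the cohort-level report: component
# test names plus the combination rule.  Singles use the unloaded ECS value
# ("T1") or a relative change ("T2* d5.0 delta").
DEFAULT_COMBINATIONS = (
    (("T2", "T2star_delta_d5.0"), "believe_positive"),
    (("T1rho", "T2star_delta_d5.0"), "believe_positive"),
    (("T2", "T2_delta_d2.5"), "believe_negative"),
    (("T1", "T2_delta_d2.5"), "believe_negative"),
)


def diagnose_cohort_table(table, scale: str = "log", combinations=DEFAULT_COMBINATIONS):
    """Reference-interval diagnostics over a tidy cohort table.

    Builds intact-group intervals for every parameter's unloaded ECS value
    and for its ECS relative changes, classifies every sample, and reports
    sensitivity/specificity for each single test and for the requested
    combined panels.  Relative-change intervals always use the linear scale
    (changes can be negative); unloaded values use ``scale``.

    Returns ``(intervals DataFrame, results DataFrame)``.
    """
    import pandas as pd

    sub = table[table["zone"] == "ECS"]
    truth_by_sample = (
        sub[["sample_id", "group"]].drop_duplicates().set_index("sample_id")["group"]
    )
    sample_ids = list(truth_by_sample.index)
    truth = [truth_by_sample[s] for s in sample_ids]

    def _values(parameter, displacement, column):
        s = sub[
            (sub["parameter"] == parameter) & (sub["displacement"] == displacement)
        ].set_index("sample_id")[column]
        return s.reindex(sample_ids)

    tests: dict[str, list] = {}
    interval_rows = []
    for param in sorted(sub["parameter"].unique()):
        specs = [(param, "d0", "mean", scale)]
        for disp in ("d2.5", "d5.0"):
            specs.append((f"{param}_delta_{disp}", disp, "delta_pct", "linear"))
        for name, disp, column, sc in specs:
            vals = _values(param, disp, column)
            ints = vals[[t == INT for t in truth]].dropna()
            if len(ints) < 2:
                continue
            interval = interval_from_int(ints.to_numpy(), scale=sc)
            interval = ReferenceInterval(name, interval.lower, interval.upper, sc)
            interval_rows.append(
                {
                    "test": name,
                    "lower": interval.lower,
                    "upper": interval.upper,
                    "scale": sc,
                }
            )
            tests[name] = [classify(v, interval) for v in vals.to_numpy()]

    result_rows = []
    for name, preds in tests.items():
        r = sens_spec(preds, truth, name=name)
        result_rows.append(
            {
                "test": name,
                "rule": "single",
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "n_excluded": r.n_excluded,
            }
        )
    for components, rule in combinations:
        if not all(c in tests for c in components):
            continue
        preds = combine_many([tests[c] for c in components], rule)
        r = sens_spec(preds, truth, name="+".join(components))
        result_rows.append(
            {
                "test": "+".join(components),
                "rule": rule,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "n_excluded": r.n_excluded,
            }
        )
    return pd.DataFrame(interval_rows), pd.DataFrame(result_rows)
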