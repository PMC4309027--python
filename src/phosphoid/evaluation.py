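"""Performance indexes and sequence/site-correctness checks.

Detection is evaluated per spectrum: a spectrum counts as predicted
phosphorylated when it passes the neutral-loss prescreen and its target
hit list is non-empty (``all_hits`` mode) or contains at least one
statistically significant entry (``significant`` mode).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, as in the printed tables."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The six detection indexes; undefined ratios are NaN."""

    sensitivity: float
    specificity: float
    accuracy: float
    fdr: float
    precision: float
    f_measure: float

    def rounded(self, ndigits: int = 3) -> "MetricSet":
        return MetricSet(
            *(round_half_away(v, ndigits) for v in (
                self.sensitivity, self.specificity, self.accuracy,
                self.fdr, self.precision, self.f_measure,
            ))
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "fdr": self.fdr,
            "precision": self.precision,
            "f_measure": self.f_measure,
        }


@dataclass(frozen=True)
class SpectrumPrediction:
    """Per-spectrum identification outcome used for the confusion table."""

    spectrum_id: str
    passed_nl: bool
    n_hits: int
    n_significant: int
    top_hit_phospho: bool = False  # only consulted under tp_rule="top_hit_phospho"


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator)", name)
        return math.nan
    return num / den


def confusion(
    predictions: Iterable[SpectrumPrediction],
    truth_labels: Mapping[str, bool],
    mode: str = "all_hits",
    tp_rule: str = "any_hit",
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN for phospho-spectrum detection.

    ``truth_labels`` maps spectrum_id to whether the spectrum comes from a
    phosphopeptide.  A positive prediction requires passing the
    neutral-loss check and a non-empty (mode ``all_hits``) or significant
    (mode ``significant``) target hit list.  With
    ``tp_rule="top_hit_phospho"`` the top-ranked hit must additionally be
    phosphorylated, the convention used for tools without a prescreen.
    """
    if mode not in ("all_hits", "significant"):
        raise ValueError("mode must be 'all_hits' or 'significant'")
    if tp_rule not in ("any_hit", "top_hit_phospho"):
        raise ValueError("tp_rule must be 'any_hit' or 'top_hit_phospho'")
    tp = fp = fn = tn = 0
    preds = list(predictions)
    pred_ids = {p.spectrum_id for p in preds}
    if pred_ids != set(truth_labels):
        missing = pred_ids.symmetric_difference(truth_labels)
        raise ValueError(f"prediction/truth spectrum IDs differ: {sorted(missing)[:5]}")
    for p in preds:
        n = p.n_hits if mode == "all_hits" else p.n_significant
        positive = p.passed_nl and n >= 1
        if tp_rule == "top_hit_phospho":
            positive = positive and p.top_hit_phospho
        truth = truth_labels[p.spectrum_id]
        if truth and positive:
            tp += 1
        elif truth:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy, FDR, precision, F-measure."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    acc = _ratio(tp + tn, counts.total, "accuracy")
    fdr = _ratio(fp, tp + fp, "FDR")
    prec = _ratio(tp, tp + fp, "precision")
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        logger.warning("F-measure undefined")
        f = math.nan
    else:
        f = 2 * prec * sens / (prec + sens)
    return MetricSet(sens, spec, acc, fdr, prec, f)


def sequence_site_check(
    hit_modseqs: Sequence[str], true_modseq: str
) -> tuple[bool, bool]:
    """Whether the hit list contains the right sequence / the right site.

    ``sequence_found`` ignores phospho placement (case-insensitive match
    of the plain sequence); ``site_correct`` requires the exact modified
    sequence, phospho residues lower-cased.
    """
    true_plain = true_modseq.upper()
    sequence_found = any(h.upper() == true_plain for h in hit_modseqs)
    site_correct = any(h == true_modseq for h in hit_modseqs)
    return sequence_found, site_correct
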