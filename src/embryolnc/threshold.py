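"""ROC-based optimal read-coverage threshold for assembled transcripts.

Assembled transcripts are labelled good/bad by how much of their
best-matching reference transcript's exonic length they recover (good at
recovery >= 0.75). Over the candidate threshold set T (the sorted unique
coverages plus a below-minimum sentinel), sensitivity(t) is the fraction of
good transcripts with coverage >= t and specificity(t) the fraction of bad
transcripts with coverage < t. The optimum minimises the squared distance to
the perfect-classifier corner,

    i* = argmin_i (1 - sensitivity_i)^2 + (1 - specificity_i)^2,
    t* = T[i*],

and the final filtering threshold is the mean of the coding and noncoding
optima. Ties in the distance are broken toward the smallest (most
permissive) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TranscriptModel, exonic_length, logger, merge_intervals

__all__ = [
    "ROCCurve",
    "ThresholdResult",
    "label_by_recovery",
    "roc_curve",
    "optimal_threshold",
    "combined_threshold",
]


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray


@dataclass(frozen=True)
class ThresholdResult:
    i_star: int
    t_star: float
    t_combined: float | None = None


def _overlap_bases(a: tuple[tuple[int, int], ...],
                   b: tuple[tuple[int, int], ...]) -> int:
    a, b = merge_intervals(a), merge_intervals(b)
    total, j = 0, 0
    for s, e in a:
        while j < len(b) and b[j][1] <= s:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            total += min(e, b[k][1]) - max(s, b[k][0])
            k += 1
    return total


def label_by_recovery(
    assembled: list[TranscriptModel],
    reference: list[TranscriptModel],
    coverage: pd.DataFrame,
    categories: dict[str, str] | None = None,
    min_recovery: float = 0.75,
) -> pd.DataFrame:
    """Label assembled transcripts good/bad by reference exonic recovery.

    For each assembled transcript, recovery against a reference transcript is
    (overlapping exonic bases) / (reference exonic length); the best-matching
    reference (max recovery) decides. Recovery >= ``min_recovery`` (boundary
    inclusive) is good. ``coverage`` maps transcript_id -> coverage;
    ``categories`` maps reference transcript ids to 'coding'/'noncoding'
    (default: all 'coding'). No-overlap transcripts are labelled bad.
    """
    cov = coverage.set_index("transcript_id")["coverage"]
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)

    rows = []
    for t in assembled:
        best_rec, best_ref = 0.0, None
        for r in by_chrom.get(t.chrom, []):
            if r.end <= t.start or r.start >= t.end:
                continue
            rec = _overlap_bases(t.exons, r.exons) / exonic_length(r.exons)
            if rec > best_rec:
                best_rec, best_ref = rec, r
        if best_ref is None:
            logger.info("transcript %s has no reference overlap; labelled bad",
                        t.transcript_id)
        label = "good" if best_rec >= min_recovery else "bad"
        category = "coding"
        if best_ref is not None and categories is not None:
            category = categories.get(best_ref.transcript_id, "coding")
        rows.append((t.transcript_id, float(cov[t.transcript_id]), label,
                     category, best_rec))
    return pd.DataFrame(rows, columns=["transcript_id", "coverage", "label",
                                       "category", "recovery"])


def roc_curve(data: pd.DataFrame) -> ROCCurve:
    """Empirical ROC over T = sorted unique coverages + below-min sentinel."""
    good = data.loc[data.label == "good", "coverage"].to_numpy(float)
    bad = data.loc[data.label == "bad", "coverage"].to_numpy(float)
    if len(good) == 0 or len(bad) == 0:
        raise ValueError("degenerate ROC: need at least one good and one bad")
    cov = np.concatenate([good, bad])
    uniq = np.unique(cov)
    # sentinels complete the curve: below-min reaches (1, 0), above-max (0, 1)
    T = np.concatenate([[uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]])
    sens = np.array([(good >= t).mean() for t in T])
    spec = np.array([(bad < t).mean() for t in T])
    return ROCCurve(thresholds=T, sensitivities=sens, specificities=spec)


def optimal_threshold(roc: ROCCurve) -> ThresholdResult:
    """Minimise (1-sens)^2 + (1-spec)^2; ties to the smallest threshold."""
    d2 = (1.0 - roc.sensitivities) ** 2 + (1.0 - roc.specificities) ** 2
    i_star = int(np.argmin(d2))  # first minimum = smallest threshold (T sorted)
    return ThresholdResult(i_star=i_star, t_star=float(roc.thresholds[i_star]))


def combined_threshold(coding: pd.DataFrame,
                       noncoding: pd.DataFrame) -> ThresholdResult:
    """Average of the per-category optimum thresholds."""
    tc = optimal_threshold(roc_curve(coding))
    tn = optimal_threshold(roc_curve(noncoding))
    return ThresholdResult(i_star=tc.i_star, t_star=tc.t_star,
                           t_combined=(tc.t_star + tn.t_star) / 2.0)
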