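"""Entropy-based temporal-specificity scoring and lncRNA/coding comparisons.

A gene's stage expression vector V (mean FPKM per stage) is normalized to a
density e with e_i = log10(v_i + 1) / sum_j log10(v_j + 1). The temporal
specificity against stage s is

    JS_sp(e | s) = 1 - JS_dist(e, e^s),

where e^s is the point-mass pattern on stage s and JS_dist is the
Jensen-Shannon distance, the square root of the Jensen-Shannon divergence

    JSD(p, q) = H((p + q) / 2) - (H(p) + H(q)) / 2

with base-2 entropy H, so scores live in [0, 1]. A gene's score is the
maximum over stages; genes above 0.5 are called temporally specific.
Class-level comparisons (lncRNA vs coding): KS test on maximal-score
distributions, Fisher exact on specific fractions, Mann-Whitney on
sample-pair Spearman correlations, and KS on maximal log10(FPKM+1)
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import logger

__all__ = [
    "SpecificityResult",
    "ClassComparison",
    "pool_stages",
    "normalize_density",
    "entropy",
    "js_divergence",
    "js_distance",
    "specificity_score",
    "specificity_table",
    "compare_classes",
    "sample_pair_spearman",
    "max_expression_distribution",
]

DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class SpecificityResult:
    gene_id: str
    js_sp_per_stage: np.ndarray
    max_score: float
    argmax_stage: int
    is_specific: bool


@dataclass
class ClassComparison:
    ks_stat: float
    ks_p: float
    fisher_odds: float
    fisher_p: float
    frac_specific_a: float
    frac_specific_b: float
    table: np.ndarray


def pool_stages(matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                stages: list[str] | None = None,
                method: str = "mean") -> pd.DataFrame:
    """Pool cells to per-stage expression: V_s = mean (or median) FPKM.

    Returns a genes x stages frame with stages in the given (or sheet) order.
    """
    if stages is None:
        stages = list(dict.fromkeys(sample_sheet.stage))
    agg = {"mean": np.mean, "median": np.median}[method]
    cols = {}
    for s in stages:
        cells = sample_sheet.loc[sample_sheet.stage == s, "cell_id"].tolist()
        if not cells:
            raise ValueError(f"stage {s!r} has no cells")
        cols[s] = matrix[cells].apply(agg, axis=1)
    return pd.DataFrame(cols, index=matrix.index)[stages]


def normalize_density(V: np.ndarray) -> tuple[np.ndarray, bool]:
    """log10(V+1) normalized to sum 1; (density, expressed) pair.

    All-zero vectors cannot be normalized and come back flagged unexpressed.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("negative expression values")
    logs = np.log10(V + 1.0)
    total = logs.sum()
    if total == 0.0:
        return np.zeros_like(logs), False
    return logs / total, True


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) = 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probabilities")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    p, q = np.asarray(p, float), np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("length mismatch between densities")
    return entropy((p + q) / 2.0) - (entropy(p) + entropy(q)) / 2.0


def js_distance(p: np.ndarray, q: np.ndarray, sqrt: bool = True) -> float:
    """Jensen-Shannon distance (root of the divergence; bits).

    ``sqrt=False`` returns the raw divergence instead of its metric root.
    """
    d = max(js_divergence(p, q), 0.0)
    return float(np.sqrt(d)) if sqrt else float(d)


def _per_stage_scores(density: np.ndarray, sqrt: bool = True) -> np.ndarray:
    n = len(density)
    scores = np.empty(n)
    h_e = entropy(density)
    for s in range(n):
        m = density / 2.0
        m = m.copy()
        m[s] += 0.5
        jsd = max(entropy(m) - h_e / 2.0, 0.0)   # H(e^s) = 0
        scores[s] = 1.0 - (np.sqrt(jsd) if sqrt else jsd)
    return scores


def specificity_score(density: np.ndarray, gene_id: str = "",
                      cutoff: float = DEFAULT_CUTOFF,
                      sqrt: bool = True) -> SpecificityResult:
    """Per-stage JS_sp scores, their maximum, and the argmax stage.

    Argmax ties resolve to the earliest stage. ``is_specific`` is
    max_score > cutoff.
    """
    scores = _per_stage_scores(np.asarray(density, float), sqrt=sqrt)
    arg = int(np.argmax(scores))
    mx = float(scores[arg])
    return SpecificityResult(gene_id=gene_id, js_sp_per_stage=scores,
                             max_score=mx, argmax_stage=arg,
                             is_specific=mx > cutoff)


def specificity_table(pooled: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF,
                      sqrt: bool = True) -> pd.DataFrame:
    """Score every expressed gene of a genes x stages pooled matrix.

    Unexpressed (all-zero) genes are excluded. Columns: per-stage scores,
    max_score, argmax_stage (stage name), is_specific.
    """
    stages = list(pooled.columns)
    rows, idx = [], []
    for gid, V in pooled.iterrows():
        density, expressed = normalize_density(V.to_numpy())
        if not expressed:
            continue
        r = specificity_score(density, gene_id=gid, cutoff=cutoff, sqrt=sqrt)
        rows.append(list(r.js_sp_per_stage)
                    + [r.max_score, stages[r.argmax_stage], r.is_specific])
        idx.append(gid)
    cols = [f"js_{s}" for s in stages] + ["max_score", "argmax_stage",
                                          "is_specific"]
    return pd.DataFrame(rows, index=pd.Index(idx, name="gene_id"), columns=cols)


def compare_classes(lnc_scores: pd.DataFrame, coding_scores: pd.DataFrame,
                    cutoff: float = DEFAULT_CUTOFF) -> ClassComparison:
    """KS on max-score distributions + Fisher exact on specific fractions."""
    if lnc_scores.empty or coding_scores.empty:
        raise ValueError("both classes must be non-empty")
    a, b = lnc_scores.max_score.to_numpy(), coding_scores.max_score.to_numpy()
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    table = np.array([
        [(a > cutoff).sum(), (a <= cutoff).sum()],
        [(b > cutoff).sum(), (b <= cutoff).sum()],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ClassComparison(ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
                           fisher_odds=float(odds), fisher_p=float(p),
                           frac_specific_a=table[0, 0] / table[0].sum(),
                           frac_specific_b=table[1, 0] / table[1].sum(),
                           table=table)


def sample_pair_spearman(matrix: pd.DataFrame, lnc_mask: pd.Series,
                         coding_mask: pd.Series | None = None) -> dict:
    """Spearman rho across all unordered sample pairs, per gene class.

    For each class, rows are restricted to class genes and rho is computed
    between every pair of sample columns; constant columns give undefined
    rho and those pairs are dropped. Returns the two rho distributions and a
    two-sided Mann-Whitney U comparison.
    """
    if coding_mask is None:
        coding_mask = ~lnc_mask

    def pair_rhos(sub: pd.DataFrame) -> np.ndarray:
        if sub.shape[0] < 3 or sub.shape[1] < 2:
            raise ValueError("need >=3 genes and >=2 samples per class")
        ranks = stats.rankdata(sub.to_numpy(), axis=0)
        sd = ranks.std(axis=0)
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(ranks, rowvar=False)
        iu = np.triu_indices_from(C, k=1)
        vals = C[iu]
        bad = (sd[iu[0]] == 0) | (sd[iu[1]] == 0)
        if bad.any():
            logger.info("dropping %d sample pairs with constant ranks", bad.sum())
        return vals[~bad & np.isfinite(vals)]

    rho_lnc = pair_rhos(matrix.loc[lnc_mask.reindex(matrix.index, fill_value=False)])
    rho_cod = pair_rhos(matrix.loc[coding_mask.reindex(matrix.index, fill_value=False)])
    mw = stats.mannwhitneyu(rho_lnc, rho_cod, alternative="two-sided")
    return {"rho_lnc": rho_lnc, "rho_coding": rho_cod,
            "u_stat": float(mw.statistic), "p": float(mw.pvalue)}


def max_expression_distribution(matrix: pd.DataFrame, lnc_mask: pd.Series,
                                coding_mask: pd.Series | None = None) -> dict:
    """Per-gene max of log10(FPKM+1) and a two-sided KS lnc-vs-coding test."""
    if coding_mask is None:
        coding_mask = ~lnc_mask
    mx = np.log10(matrix + 1.0).max(axis=1)
    a = mx[lnc_mask.reindex(matrix.index, fill_value=False)].to_numpy()
    b = mx[coding_mask.reindex(matrix.index, fill_value=False)].to_numpy()
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    return {"max_lnc": a, "max_coding": b,
            "ks_stat": float(ks.statistic), "p": float(ks.pvalue)}
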