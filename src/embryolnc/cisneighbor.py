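"""Neighboring-gene identification and cis-correlation analysis.

Two genes are neighbors when their gene bodies lie on the same chromosome
less than 10 kb apart (overlapping bodies count, gap 0). Orientation:
divergent pairs are head-to-head on opposite strands (left gene on '-',
right gene on '+'), convergent pairs tail-to-tail, unidirectional pairs on
the same strand. Pair co-expression is the Pearson correlation of the two
genes' density-normalized stage profiles; the null is a seeded sample of
random non-neighbor coding-coding pairs. A per-module neighbor-fraction
table tests whether coding genes in co-expression modules tend to be
lncRNA neighbors (one-sample t against 50%, equivalently a paired t on the
neighbor/non-neighbor split since rows sum to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import CODING, LNCRNA, GeneRecord, logger

__all__ = [
    "NeighborPair",
    "find_neighbors",
    "pair_correlation",
    "random_coding_pairs",
    "compare_pair_classes",
    "cohens_d",
    "neighbor_fraction_test",
]

MAX_GAP_DEFAULT = 10_000


@dataclass
class NeighborPair:
    gene_a: str
    gene_b: str
    gap_bp: int
    orientation: str    # divergent | unidirectional | convergent
    pair_class: str     # lnc_coding | coding_coding | lnc_lnc
    pearson_r: float | None = None
    p_value: float | None = None
    significant: bool | None = None


def _orientation(left: GeneRecord, right: GeneRecord) -> str:
    if left.strand == right.strand:
        return "unidirectional"
    # opposite strands: 5' ends adjacent (-| |+) = divergent, else convergent
    return "divergent" if (left.strand, right.strand) == ("-", "+") else "convergent"


def _pair_class(a: GeneRecord, b: GeneRecord) -> str:
    kinds = sorted((a.biotype, b.biotype))
    if kinds == [LNCRNA, LNCRNA]:
        return "lnc_lnc"
    if kinds == [CODING, CODING]:
        return "coding_coding"
    return "lnc_coding"


def find_neighbors(annotation: list[GeneRecord],
                   max_gap: int = MAX_GAP_DEFAULT) -> list[NeighborPair]:
    """All same-chromosome gene pairs with body gap strictly < max_gap.

    gap = max(0, later.start - earlier.end); overlapping bodies give gap 0.
    Genes without a usable strand are excluded with a log entry. Output is
    independent of input order (pairs sorted by position, gene_a left).
    """
    usable = []
    for g in annotation:
        if g.strand not in ("+", "-"):
            logger.warning("gene %s has no strand; excluded from neighbor scan",
                           g.gene_id)
            continue
        usable.append(g)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in usable:
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for i, left in enumerate(genes):
            for right in genes[i + 1:]:
                gap = max(0, right.start - left.end)
                if right.start - left.end >= max_gap:
                    break  # sorted by start: all later genes at least this far
                if gap < max_gap:
                    pairs.append(NeighborPair(
                        gene_a=left.gene_id, gene_b=right.gene_id, gap_bp=gap,
                        orientation=_orientation(left, right),
                        pair_class=_pair_class(left, right)))
    return pairs


def pair_correlation(pairs: list[NeighborPair], profiles: pd.DataFrame,
                     p_cutoff: float = 0.05) -> list[NeighborPair]:
    """Pearson r of the two density-normalized stage profiles per pair.

    All pairs are kept; ``significant`` flags p <= p_cutoff. Pairs with a
    constant profile (undefined r) get pearson_r=None and are excluded from
    distribution summaries downstream.
    """
    for p in pairs:
        if p.gene_a not in profiles.index or p.gene_b not in profiles.index:
            p.pearson_r = None
            continue
        x = profiles.loc[p.gene_a].to_numpy(float)
        y = profiles.loc[p.gene_b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.info("pair (%s, %s): constant profile, r undefined",
                        p.gene_a, p.gene_b)
            p.pearson_r = None
            continue
        r, pv = stats.pearsonr(x, y)
        p.pearson_r, p.p_value = float(r), float(pv)
        p.significant = pv <= p_cutoff
    return pairs


def random_coding_pairs(annotation: list[GeneRecord], n: int = 10_000,
                        seed: int = 0,
                        exclude: list[NeighborPair] | None = None
                        ) -> list[NeighborPair]:
    """Seeded sample of n distinct random coding-coding non-neighbor pairs.

    True neighbor pairs (``exclude``) are never sampled; if n exceeds the
    number of available distinct pairs the sample is capped with a warning.
    """
    coding = sorted(g.gene_id for g in annotation if g.biotype == CODING)
    if len(coding) < 2:
        raise ValueError("need >=2 coding genes for the random-pair null")
    banned = set()
    for p in exclude or []:
        banned.add(frozenset((p.gene_a, p.gene_b)))
    rng = np.random.default_rng(seed)
    n_total = len(coding) * (len(coding) - 1) // 2

    if n >= n_total:
        all_pairs = [pq for pq in combinations(coding, 2)
                     if frozenset(pq) not in banned]
        if n > len(all_pairs):
            logger.warning("requested %d random pairs but only %d exist; capped",
                           n, len(all_pairs))
        chosen = all_pairs
    else:
        chosen_set: set[frozenset] = set()
        chosen = []
        while len(chosen) < n:
            i, j = rng.integers(0, len(coding), size=2)
            if i == j:
                continue
            key = frozenset((coding[i], coding[j]))
            if key in banned or key in chosen_set:
                continue
            chosen_set.add(key)
            chosen.append(tuple(sorted((coding[i], coding[j]))))
    return [NeighborPair(gene_a=a, gene_b=b, gap_bp=-1, orientation="random",
                         pair_class="coding_coding") for a, b in chosen]


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled (n-1) standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                 / (nx + ny - 2))
    return float((x.mean() - y.mean()) / sp)


def _defined_r(pairs: list[NeighborPair]) -> np.ndarray:
    return np.array([p.pearson_r for p in pairs if p.pearson_r is not None])


def compare_pair_classes(lnc_pairs: list[NeighborPair],
                         null_pairs: list[NeighborPair]) -> dict:
    """Compare pair-correlation distributions: KS, Welch t, Cohen's d.

    Reported overall and separately for the unidirectional and divergent
    strata of the lncRNA-coding pairs (both against the same null).
    """
    out = {}
    null_r = _defined_r(null_pairs)
    for stratum in ("all", "unidirectional", "divergent"):
        sel = [p for p in lnc_pairs
               if stratum == "all" or p.orientation == stratum]
        r = _defined_r(sel)
        if len(r) < 3 or len(null_r) < 3:
            logger.warning("stratum %s skipped: <3 defined correlations", stratum)
            continue
        ks = stats.ks_2samp(r, null_r, alternative="two-sided")
        tt = stats.ttest_ind(r, null_r, equal_var=False)
        out[stratum] = {
            "n": len(r), "mean_r": float(r.mean()),
            "null_n": len(null_r), "null_mean_r": float(null_r.mean()),
            "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "t_stat": float(tt.statistic), "t_p": float(tt.pvalue),
            "cohens_d": cohens_d(r, null_r),
        }
    return out


def neighbor_fraction_test(modules: dict[str, set[str] | list[str]],
                           neighbor_map: dict[str, bool],
                           coding_genes: set[str] | None = None) -> dict:
    """Per-module % of coding genes that neighbor an lncRNA, plus a t-test.

    ``neighbor_map`` flags each coding gene as lncRNA-neighbor or not; genes
    absent from it count as non-neighbors. Modules without coding genes are
    excluded with a warning. The summary t is the one-sample t of the
    neighbor percentages against 50 (identical to the paired t on
    neighbor - non-neighbor differences because each row sums to 100).
    """
    rows = []
    for name in sorted(modules):
        members = set(modules[name])
        coding = members if coding_genes is None else members & coding_genes
        if not coding:
            logger.warning("module %s has no coding genes; excluded", name)
            continue
        n_nb = sum(bool(neighbor_map.get(g, False)) for g in coding)
        pct = 100.0 * n_nb / len(coding)
        rows.append((name, pct, 100.0 - pct))
    table = pd.DataFrame(rows, columns=["module", "pct_neighbor_coding",
                                        "pct_non_neighbor_coding"])
    if len(table) < 2:
        raise ValueError("need >=2 modules with coding genes")
    return summarize_neighbor_fractions(table)


def summarize_neighbor_fractions(table: pd.DataFrame) -> dict:
    """Mean/sd and one-sample t vs 50% over per-module neighbor percentages."""
    pct = table.pct_neighbor_coding.to_numpy(float)
    mean, sd = float(pct.mean()), float(pct.std(ddof=1))
    if sd == 0.0:
        logger.warning("zero variance across modules; t undefined")
        t_stat, p = (0.0 if mean == 50.0 else np.inf), np.nan
    else:
        res = stats.ttest_1samp(pct, 50.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
        # identical by construction: paired t on (neighbor - non-neighbor)/2
    return {"table": table, "mean": mean, "sd": sd, "t": t_stat, "p": p,
            "n_modules": len(pct)}
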