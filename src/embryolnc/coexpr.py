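"""Signed weighted co-expression network analysis.

Pipeline: select stage-specific genes (differential expression between
consecutive stages), build a signed adjacency a_ij = ((1 + cor_ij)/2)^beta
from the Pearson correlation of expression profiles, transform it to a
topological overlap matrix

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

cluster genes by average linkage on 1 - TOM, cut the tree into modules
(static cut at the modularity-maximising height followed by kME-based
rescue of unassigned genes), merge modules whose eigengenes correlate
above 0.85, and summarise each module by its eigengene (first principal
component, unit variance, sign fixed so member genes correlate positively).
Module membership kME_q(i) = cor(x_i, ME_q); genes with kME >= 0.9 in their
own module are intramodular hubs. Module-trait relations are eigengene
Pearson correlations against stage indicators and an ordinal time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import logger

__all__ = [
    "CoexpressionNetwork",
    "ModuleSet",
    "stage_specific_genes",
    "pick_soft_threshold",
    "build_network",
    "module_eigengene",
    "detect_modules",
    "stage_trait_table",
    "module_trait",
    "kme_and_hubs",
    "hub_edges",
    "filter_interactions",
]

GREY = "grey"
#: module label vocabulary, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    cor: np.ndarray
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def diss_tom(self) -> np.ndarray:
        return 1.0 - self.tom


@dataclass
class ModuleSet:
    assignment: pd.Series               # gene -> module label or 'grey'
    eigengenes: pd.DataFrame            # samples x modules
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_cor: pd.DataFrame | None = None
    trait_p: pd.DataFrame | None = None
    hubs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, label in self.assignment.items():
            if label != GREY:
                out.setdefault(label, []).append(gene)
        return out


# ---------------------------------------------------------------------------
# Stage-specific gene selection (generic consecutive-stage DE)
# ---------------------------------------------------------------------------

#: prior degrees of freedom for the variance moderation of the DE test
MODERATION_PRIOR_DF = 4.0


def _moderated_t_p(a: np.ndarray, b: np.ndarray,
                   d0: float = MODERATION_PRIOR_DF) -> np.ndarray:
    """Two-sided p of a pooled-variance t with variance shrunken toward the
    median per-gene variance (prior df d0); rescues the tiny-n comparisons
    where an unmoderated t has too few degrees of freedom to reach
    significance."""
    n1, n2 = a.shape[1], b.shape[1]
    df_res = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1)
          + (n2 - 1) * b.var(axis=1, ddof=1)) / df_res
    positive = s2[s2 > 0]
    s2_prior = float(np.median(positive)) if len(positive) else 0.0
    s2_mod = (d0 * s2_prior + df_res * s2) / (d0 + df_res)
    delta = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df=d0 + df_res)
    # fully degenerate genes (no variance anywhere): decide by the means
    degenerate = s2_mod == 0
    p = np.where(degenerate, np.where(np.isclose(delta, 0.0), 1.0, 0.0), p)
    return np.where(np.isnan(p), 1.0, p)


def stage_specific_genes(matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                         stages: list[str] | None = None,
                         lfc_cutoff: float = 1.0,
                         q_cutoff: float = 0.01) -> pd.DataFrame:
    """Moderated-t differential expression between consecutive stages.

    Tests are on log10(FPKM+1) per cell, with the per-gene variance
    shrunken toward the across-gene median (the standard small-sample
    moderation; some stages have only three cells). BH correction is
    applied across genes within each consecutive-stage comparison; the fold
    change is log2((mean2 + 1)/(mean1 + 1)) on stage-mean FPKM. A gene is
    stage-specific if any comparison has q < q_cutoff and |log2FC| >
    lfc_cutoff. Stage pairs where either stage has <2 cells are skipped.
    """
    from statsmodels.stats.multitest import multipletests

    if stages is None:
        stages = list(dict.fromkeys(sample_sheet.stage))
    rows = []
    for s1, s2 in zip(stages, stages[1:]):
        c1 = sample_sheet.loc[sample_sheet.stage == s1, "cell_id"].tolist()
        c2 = sample_sheet.loc[sample_sheet.stage == s2, "cell_id"].tolist()
        if len(c1) < 2 or len(c2) < 2:
            logger.warning("stage pair %s->%s skipped: <2 cells", s1, s2)
            continue
        a = np.log10(matrix[c1].to_numpy(float) + 1.0)
        b = np.log10(matrix[c2].to_numpy(float) + 1.0)
        p = _moderated_t_p(a, b)
        q = multipletests(p, method="fdr_bh")[1]
        m1 = matrix[c1].mean(axis=1).to_numpy(float)
        m2 = matrix[c2].mean(axis=1).to_numpy(float)
        lfc = np.log2((m2 + 1.0) / (m1 + 1.0))
        pair = f"{s1}->{s2}"
        for gid, pv, qv, fc in zip(matrix.index, p, q, lfc):
            rows.append((gid, pair, float(fc), float(pv), float(qv),
                         bool(qv < q_cutoff and abs(fc) > lfc_cutoff)))
    return pd.DataFrame(rows, columns=["gene_id", "stage_pair", "log2_fc",
                                       "p_value", "q_value",
                                       "is_stage_specific"])


def stage_specific_set(de: pd.DataFrame) -> list[str]:
    return sorted(de.loc[de.is_stage_specific, "gene_id"].unique())


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _signed_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression over degree bins."""
    k = np.asarray(k, float)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all degrees equal")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if len(kb) == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(len(kb) / len(k)))
    if len(xs) < 3:
        raise ValueError("too few occupied degree bins for a fit")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r ** 2)


def pick_soft_threshold(cor: np.ndarray,
                        candidate_betas=range(1, 21),
                        r2_target: float = 0.9,
                        beta_override: float | None = None,
                        fallback_beta: float = 5.0) -> tuple[float, pd.DataFrame]:
    """Smallest power giving approximate scale-free topology (R^2 >= target).

    Returns (beta, fit table). If no candidate reaches the target the best
    R^2 wins with a warning; if the fit is undefined (degenerate degrees)
    ``fallback_beta`` is returned. An explicit ``beta_override`` wins.
    """
    rows = []
    if beta_override is not None:
        return float(beta_override), pd.DataFrame(columns=["beta", "r2"])
    for b in candidate_betas:
        a = _signed_adjacency(cor, b)
        k = a.sum(axis=1) - 1.0
        try:
            r2 = scale_free_fit(k)
        except ValueError as err:
            logger.warning("beta=%s: %s; falling back to beta=%s",
                           b, err, fallback_beta)
            return float(fallback_beta), pd.DataFrame(rows, columns=["beta", "r2"])
        rows.append((float(b), r2))
        if r2 >= r2_target:
            return float(b), pd.DataFrame(rows, columns=["beta", "r2"])
    fits = pd.DataFrame(rows, columns=["beta", "r2"])
    best = fits.loc[fits.r2.idxmax()]
    logger.warning("no candidate beta reached R^2 >= %.2f; using beta=%g "
                   "(R^2=%.3f)", r2_target, best.beta, best.r2)
    return float(best.beta), fits


def build_network(expr: pd.DataFrame, beta: float = 5.0) -> CoexpressionNetwork:
    """Correlation -> signed adjacency -> TOM for a genes x samples matrix.

    ``expr`` rows are gene profiles (typically log10(FPKM+1) per cell).
    Constant rows make the correlation undefined and raise, naming the genes.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("need >=2 genes and >=3 samples")
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"constant expression rows: {bad}")
    cor = np.corrcoef(X)
    a = _signed_adjacency(cor, beta)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    L = a0 @ a0                                   # L_ij = sum_u a_iu a_uj, u != i,j
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a0) / denom
    np.fill_diagonal(tom, 1.0)
    return CoexpressionNetwork(genes=list(expr.index), cor=cor, beta=beta,
                               adjacency=a, tom=tom)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First PC of the standardized module expression, unit variance,
    sign fixed so the mean member correlation is positive."""
    X = expr.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    me = me / np.std(me, ddof=1)
    cors = np.array([np.corrcoef(Z[i], me)[0, 1] for i in range(Z.shape[0])])
    if np.nanmean(cors) < 0:
        me = -me
    return pd.Series(me, index=expr.columns)


def _weighted_modularity(adj0: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a weighted graph; unassigned (-1) = singletons."""
    two_m = adj0.sum()
    if two_m == 0:
        return 0.0
    deg = adj0.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        if lab == -1:
            continue
        idx = np.where(labels == lab)[0]
        q += adj0[np.ix_(idx, idx)].sum() / two_m - (deg[idx].sum() / two_m) ** 2
    return q


def detect_modules(network: CoexpressionNetwork, expr: pd.DataFrame,
                   min_module_size: int = 30, merge_cor: float = 0.85,
                   rescue_kme: float = 0.3,
                   n_cut_candidates: int = 40) -> ModuleSet:
    """Cluster on 1 - TOM and cut into modules.

    Average-linkage clustering; candidate static cut heights are quantiles
    of the merge heights, the one maximising the weighted modularity of the
    >=min_module_size branches wins. Unassigned genes are rescued into the
    module of their highest kME when that kME >= ``rescue_kme``, else stay
    grey. Modules whose eigengenes correlate above ``merge_cor`` are merged
    iteratively, then labelled by descending size from the color vocabulary.
    """
    genes = network.genes
    diss = np.maximum(network.diss_tom, 0.0)  # guard fp noise at TOM = 1
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    adj0 = network.adjacency.copy()
    np.fill_diagonal(adj0, 0.0)

    heights = np.unique(Z[:, 2])
    qs = np.linspace(0.05, 1.0, n_cut_candidates)
    candidates = np.unique(np.quantile(heights, qs))
    best_labels, best_q = None, -np.inf
    for h in candidates:
        flat = fcluster(Z, t=h, criterion="distance")
        labels = np.full(len(genes), -1)
        for lab in np.unique(flat):
            idx = np.where(flat == lab)[0]
            if len(idx) >= min_module_size:
                labels[idx] = lab
        if (labels == -1).all():
            continue
        q = _weighted_modularity(adj0, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    if best_labels is None:
        logger.warning("no branch reached min_module_size=%d; all genes grey",
                       min_module_size)
        return ModuleSet(assignment=pd.Series(GREY, index=genes),
                         eigengenes=pd.DataFrame(index=expr.columns))

    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes, best_labels):
        if lab != -1:
            groups.setdefault(int(lab), []).append(g)

    # kME rescue of unassigned genes (hybrid-like step)
    mes = {lab: module_eigengene(expr.loc[members])
           for lab, members in groups.items()}
    for g, lab in zip(genes, best_labels):
        if lab != -1:
            continue
        x = expr.loc[g].to_numpy(float)
        if x.std() == 0:
            continue
        kmes = {m: np.corrcoef(x, me)[0, 1] for m, me in mes.items()}
        best_m = max(kmes, key=kmes.get)
        if kmes[best_m] >= rescue_kme:
            groups[best_m].append(g)
    mes = {lab: module_eigengene(expr.loc[members])
           for lab, members in groups.items()}

    # iterative eigengene merging
    while len(groups) > 1:
        labs = sorted(groups)
        me_mat = np.array([mes[l].to_numpy() for l in labs])
        C = np.corrcoef(me_mat)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= merge_cor:
            break
        keep, drop = labs[i], labs[j]
        groups[keep] = groups[keep] + groups.pop(drop)
        mes.pop(drop)
        mes[keep] = module_eigengene(expr.loc[groups[keep]])

    # size-ordered color labels
    ordered = sorted(groups.values(), key=lambda m: (-len(m), sorted(m)[0]))
    assignment = pd.Series(GREY, index=genes, dtype=object)
    eig = {}
    for rank, members in enumerate(ordered):
        color = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                 else f"module{rank + 1}")
        assignment[members] = color
        eig[color] = module_eigengene(expr.loc[members])
    return ModuleSet(assignment=assignment,
                     eigengenes=pd.DataFrame(eig, index=expr.columns))


# ---------------------------------------------------------------------------
# Module-trait relations, kME, hubs
# ---------------------------------------------------------------------------

def stage_trait_table(sample_sheet: pd.DataFrame,
                      stages: list[str] | None = None) -> pd.DataFrame:
    """One-hot stage indicators plus an ordinal 'time' column (1..n)."""
    if stages is None:
        stages = list(dict.fromkeys(sample_sheet.stage))
    out = pd.DataFrame(index=sample_sheet.cell_id)
    stage_of = sample_sheet.set_index("cell_id").stage
    for s in stages:
        out[s] = (stage_of == s).astype(float)
    out["time"] = stage_of.map({s: i + 1 for i, s in enumerate(stages)}).astype(float)
    return out


def _cor_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait(modules: ModuleSet, traits: pd.DataFrame,
                 r_cutoff: float = 0.6, p_cutoff: float = 1e-4) -> ModuleSet:
    """Eigengene-trait Pearson correlations with Student-t p-values."""
    traits = traits.loc[modules.eigengenes.index]
    n = len(traits)
    cor = pd.DataFrame(index=modules.eigengenes.columns, columns=traits.columns,
                       dtype=float)
    pval = cor.copy()
    for trait in traits.columns:
        tv = traits[trait].to_numpy(float)
        if tv.std() == 0:
            logger.warning("trait %s has zero variance; skipped", trait)
            cor.drop(columns=[trait], inplace=True)
            pval.drop(columns=[trait], inplace=True)
            continue
        for mod in modules.eigengenes.columns:
            r = float(np.corrcoef(modules.eigengenes[mod].to_numpy(), tv)[0, 1])
            cor.loc[mod, trait] = r
            pval.loc[mod, trait] = _cor_p(r, n)
    modules.trait_cor, modules.trait_p = cor, pval
    return modules


def kme_and_hubs(expr: pd.DataFrame, modules: ModuleSet,
                 hub_kme: float = 0.9,
                 hub_p_max: float | None = None) -> ModuleSet:
    """kME_q(i) = cor(x_i, ME_q) for every gene x module; hub sets per module.

    Hubs are own-module genes with kME >= hub_kme (and correlation p below
    ``hub_p_max`` when given). Constant genes have undefined kME (NaN) and
    cannot be hubs.
    """
    n = expr.shape[1]
    kme = pd.DataFrame(index=expr.index, columns=modules.eigengenes.columns,
                       dtype=float)
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    for mod in modules.eigengenes.columns:
        me = modules.eigengenes[mod].to_numpy(float)
        with np.errstate(invalid="ignore"):
            r = ((X - X.mean(axis=1, keepdims=True)) @ (me - me.mean())
                 / (n * np.where(sd == 0, np.nan, sd) * me.std()))
        kme[mod] = r
    modules.kme = kme
    hubs: dict[str, list[str]] = {}
    for mod in modules.eigengenes.columns:
        members = [g for g in expr.index if modules.assignment.get(g) == mod]
        sel = []
        for g in members:
            r = kme.loc[g, mod]
            if np.isnan(r) or r < hub_kme:
                continue
            if hub_p_max is not None and _cor_p(float(r), n) >= hub_p_max:
                continue
            sel.append(g)
        hubs[mod] = sel
    modules.hubs = hubs
    return modules


def hub_edges(network: CoexpressionNetwork, hub_genes: list[str],
              weight_cutoff: float = 0.1) -> pd.DataFrame:
    """TOM edges among hub genes at weight >= cutoff; isolated hubs dropped."""
    idx = {g: i for i, g in enumerate(network.genes)}
    rows = []
    for i, a in enumerate(hub_genes):
        for b in hub_genes[i + 1:]:
            w = network.tom[idx[a], idx[b]]
            if w >= weight_cutoff:
                rows.append((a, b, float(w)))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def filter_interactions(table: pd.DataFrame, cutoff: float = -0.1) -> pd.DataFrame:
    """Keep predicted RNA-RNA interactions with ndG <= cutoff (inclusive)."""
    ndg = pd.to_numeric(table["ndG"], errors="coerce")
    bad = ndg.isna() & table["ndG"].notna() | table["ndG"].isna()
    if bad.any():
        row = int(np.where(bad)[0][0])
        raise ValueError(f"non-numeric ndG value at row {row}: "
                         f"{table['ndG'].iloc[row]!r}")
    return table.loc[ndg <= cutoff].copy()
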