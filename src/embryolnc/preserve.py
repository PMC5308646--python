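"""Cross-species module preservation and gene-set enrichment.

Preservation: map one species' genes onto the other through a strict
one-to-one ortholog table, restrict both module sets to the shared universe,
and score every module pair by the upper-tail hypergeometric probability of
their gene overlap, P(X >= n_overlap) with population |universe|, successes
|A| and draws |B|. Enrichment: the same upper-tail test of a module against
GMT-style gene sets, reported at p <= 0.05 and overlap >= 5 by default, with
BH q-values alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import logger

__all__ = [
    "map_orthologs",
    "hypergeom_overlap_p",
    "module_overlap",
    "read_gmt",
    "gene_set_enrichment",
]


def map_orthologs(genes: list[str] | set[str],
                  table: pd.DataFrame) -> tuple[dict[str, str], dict]:
    """Apply a strict one-to-one ortholog mapping.

    ``table`` has two columns (species A gene, species B gene). Any A or B
    gene appearing in more than one distinct pair is dropped as ambiguous,
    so the retained map is a bijection on its domain. Returns
    (mapping restricted to ``genes``, report with unmapped/ambiguous counts).
    """
    a_col, b_col = table.columns[:2]
    pairs = table[[a_col, b_col]].drop_duplicates()
    a_counts = pairs[a_col].value_counts()
    b_counts = pairs[b_col].value_counts()
    ok = pairs[(pairs[a_col].map(a_counts) == 1)
               & (pairs[b_col].map(b_counts) == 1)]
    n_ambiguous = len(pairs) - len(ok)
    full = dict(zip(ok[a_col], ok[b_col]))
    genes = list(genes)
    mapping = {g: full[g] for g in genes if g in full}
    report = {"n_input": len(genes), "n_mapped": len(mapping),
              "n_unmapped": len(genes) - len(mapping),
              "n_ambiguous_rows": int(n_ambiguous)}
    if n_ambiguous:
        logger.info("ortholog table: %d ambiguous (non 1:1) rows dropped",
                    n_ambiguous)
    return mapping, report


def hypergeom_overlap_p(n_overlap: int, n_a: int, n_b: int,
                        n_universe: int) -> float:
    """Upper-tail P(X >= n_overlap) for |A intersect B| under random draws."""
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


def module_overlap(modules_a: dict[str, set | list],
                   modules_b: dict[str, set | list],
                   universe: set[str]) -> pd.DataFrame:
    """Hypergeometric overlap of every (A-module, B-module) pair.

    Module gene sets are first restricted to the shared universe. Rows carry
    the overlap count, the upper-tail p, and -log10 p.
    """
    if not universe:
        raise ValueError("empty universe")
    rows = []
    for na in sorted(modules_a):
        A = set(modules_a[na]) & universe
        for nb in sorted(modules_b):
            B = set(modules_b[nb]) & universe
            k = len(A & B)
            p = hypergeom_overlap_p(k, len(A), len(B), len(universe))
            rows.append((na, nb, k, len(A), len(B), p, -np.log10(p)))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "n_overlap",
                                       "n_a", "n_b", "p", "neg_log10_p"])


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """GMT gene sets: term_id <tab> term_name <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = (parts[1], set(parts[2:]))
    return sets


def gene_set_enrichment(module_genes: set[str] | list[str],
                        universe: set[str],
                        gene_sets: dict[str, tuple[str, set[str]]],
                        p_cutoff: float = 0.05,
                        min_count: int = 5) -> pd.DataFrame:
    """Hypergeometric enrichment of a module against each gene set.

    Terms with no universe genes are skipped. Rows are filtered to overlap
    >= min_count and p <= p_cutoff; BH q-values (computed across all tested
    terms before filtering) are reported alongside the raw p.
    """
    from statsmodels.stats.multitest import multipletests

    module = set(module_genes) & universe
    rows = []
    for term_id in sorted(gene_sets):
        term_name, genes = gene_sets[term_id]
        in_universe = genes & universe
        if not in_universe:
            logger.info("term %s has no universe genes; skipped", term_id)
            continue
        k = len(module & in_universe)
        p = hypergeom_overlap_p(k, len(in_universe), len(module), len(universe))
        rows.append((term_id, term_name, k, len(in_universe), p))
    df = pd.DataFrame(rows, columns=["term_id", "term_name",
                                     "n_module_in_term", "n_universe_in_term",
                                     "p"])
    if df.empty:
        df["bh_q"] = []
        return df
    df["bh_q"] = multipletests(df.p, method="fdr_bh")[1]
    keep = (df.n_module_in_term >= min_count) & (df.p <= p_cutoff)
    return df.loc[keep].sort_values("p").reset_index(drop=True)
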