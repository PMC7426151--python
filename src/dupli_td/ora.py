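"""Hypergeometric over-representation analysis of gene sets against a term map."""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from .dge import adjust_pvalues
from .errors import InputError

__all__ = ["hypergeometric_ora", "read_term_map"]


def read_term_map(path) -> pd.DataFrame:
    """Two-column term -> gene TSV."""
    df = pd.read_csv(path, sep="\t", names=["term", "gene"], header=None, comment="#")
    first = df.iloc[0]
    if {str(first["term"]).lower(), str(first["gene"]).lower()} == {"term", "gene"}:
        df = df.iloc[1:].reset_index(drop=True)
    return df


def hypergeometric_ora(
    gene_set,
    term_map: pd.DataFrame,
    universe,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_set`` per term.

    Terms are intersected with the universe (by default the expressed genes,
    not all annotated ones). Columns: term, k (set ∩ term), K (term size in
    universe), n (set size), N (universe size), p, p_adj (BH), enriched
    (p_adj < p_cutoff). Sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    gene_set = set(gene_set) & universe
    n, N = len(gene_set), len(universe)
    rows = []
    for term, grp in term_map.groupby("term"):
        members = set(grp["gene"]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & gene_set)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
        return out
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="BH")
    out["enriched"] = out["p_adj"] < p_cutoff
    return out.sort_values(["p", "term"]).reset_index(drop=True)
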