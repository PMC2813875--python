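"""Over-representation of a gene list across functional categories.

For each category a 2x2 table is built within the background (the expressed
genes surviving the detection filter): membership in the query list crossed
with membership in the category.  Significance is the two-sided Fisher
exact test; Benjamini-Hochberg adjusted p-values are reported alongside the
raw ones because category counts vary with the annotation supplied.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_enrichment", "read_category_map", "read_gmt"]


def fisher_enrichment(
    query: set,
    background: set,
    categories: dict[str, set],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of ``query`` within ``background``.

    Parameters
    ----------
    query : set
        Genes of interest (e.g. the alternative-splicing transcript list);
        must be a subset of ``background``.
    background : set
        The analyzed universe (all expressed genes).
    categories : dict
        Category id -> gene set; genes outside the background are ignored.
    alpha : float
        Raw-p threshold for the ``significant`` flag (default 0.01).

    Returns a frame indexed by category with the 2x2 counts, odds ratio,
    raw p, BH-adjusted p and the significance flag, sorted by raw p.
    """
    query, background = set(query), set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"query contains {len(stray)} gene(s) outside the background, "
            f"e.g. {sorted(stray)[:3]}"
        )
    rows = []
    for cat, genes in categories.items():
        genes = set(genes) & background
        a = len(query & genes)            # query, in category
        b = len(query) - a                # query, outside
        c = len(genes) - a                # background-only, in category
        d = len(background) - len(query) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"category": cat, "q_in": a, "q_out": b, "bg_in": c, "bg_out": d,
             "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows).set_index("category")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] <= alpha
        out = out.sort_values(["p", "category"])
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out


def read_category_map(path, names_path=None) -> dict[str, set]:
    """Read a two-column TSV (category_id, gene_id) into a CategoryMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["category_id", "gene_id"]:
        raise ValueError(f"{path}: expected columns category_id, gene_id; got {cols}")
    out: dict[str, set] = {}
    for cat, sub in df.groupby("category_id"):
        out[cat] = set(sub["gene_id"])
    return out


def read_gmt(path) -> dict[str, set]:
    """Read GMT format: category <tab> description <tab> gene1 <tab> gene2..."""
    out: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_category_map(categories: dict[str, set], path) -> None:
    rows = [
        {"category_id": cat, "gene_id": g}
        for cat in sorted(categories)
        for g in sorted(categories[cat])
    ]
    pd.DataFrame(rows, columns=["category_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
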