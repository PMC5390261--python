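"""Category summaries, extreme-protein ranking and sample-correlation clustering.

The curated differential lists are annotated with cancer-related functional
categories (a data map, never inferred by the code), summarised as
per-category percentages, and ranked for the most extreme fold changes.
Sample similarity is assessed by Pearson correlation between the samples'
normalized spectral-count profiles, ordered by average-linkage hierarchical
clustering on the distance 1 - r for heat-map display.

The packaged fixture tables (`load_fixture_table`) transcribe the published
curated lists for the three compartments and both directions; they are
reporting inputs only and are never re-thresholded by the differential
criteria.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FIXTURE_TABLES",
    "load_fixture_table",
    "fixture_category_map",
    "load_category_map",
    "assign_categories",
    "category_distribution",
    "rank_extremes",
    "sample_correlation_matrix",
    "hierarchical_cluster",
    "export_gene_lists",
]

UNKNOWN_CATEGORY = "Unknown function"

#: (compartment, direction) -> packaged fixture file.
FIXTURE_TABLES = {
    ("cell", "down"): "cell_down.tsv",
    ("cell", "up"): "cell_up.tsv",
    ("secretome", "down"): "secretome_down.tsv",
    ("secretome", "up"): "secretome_up.tsv",
    ("xenograft", "down"): "xenograft_down.tsv",
    ("xenograft", "up"): "xenograft_up.tsv",
}


def load_fixture_table(compartment: str, direction: str) -> pd.DataFrame:
    """Load one packaged curated table (columns: category, gene, description,
    rsc) for a compartment ("cell", "secretome", "xenograft") and direction
    ("up", "down")."""
    try:
        name = FIXTURE_TABLES[(compartment, direction)]
    except KeyError:
        raise ValueError(f"no fixture table for {(compartment, direction)!r}") from None
    with resources.files("spcdelta.data").joinpath(name).open() as handle:
        table = pd.read_csv(handle, sep="\t")
    table["compartment"] = compartment
    table["direction"] = direction
    return table


def fixture_category_map() -> dict[str, str]:
    """Gene-symbol -> category map pooled over all packaged fixture tables.

    A gene listed in several compartments keeps its first (cell, secretome,
    xenograft order) assignment.
    """
    cmap: dict[str, str] = {}
    for (compartment, direction) in FIXTURE_TABLES:
        table = load_fixture_table(compartment, direction)
        for _, row in table.iterrows():
            cmap.setdefault(row["gene"], row["category"])
    return cmap


def load_category_map(path) -> dict[str, str]:
    """Read a two-column (identifier, category) TSV into a map."""
    frame = pd.read_csv(path, sep="\t")
    id_col, cat_col = frame.columns[:2]
    return dict(zip(frame[id_col].astype(str), frame[cat_col].astype(str)))


def assign_categories(table: pd.DataFrame, category_map: dict[str, str], key: str = "gene") -> pd.DataFrame:
    """Attach exactly one category per row; unmapped rows get "Unknown function"."""
    out = table.copy()
    out["category"] = [category_map.get(str(k), UNKNOWN_CATEGORY) for k in out[key]]
    return out


def category_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category counts and percentages (of the table's rows).

    Percentages are computed from the unrounded fractions, then rounded
    half-up to one decimal; they therefore sum to 100.0 only up to rounding
    slack (about +/-0.3 for tables of this size).
    """
    if table.empty:
        raise ValueError("cannot summarise an empty table")
    counts = table["category"].value_counts()
    total = int(counts.sum())
    pct = [
        float(Decimal(100 * c / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        for c in counts
    ]
    return pd.DataFrame(
        {"category": counts.index, "count": counts.to_numpy(), "percentage": pct}
    ).sort_values(["count", "category"], ascending=[False, True]).reset_index(drop=True)


def rank_extremes(table: pd.DataFrame, direction: str) -> tuple[str, float]:
    """The most extreme entry of a curated table: the minimum Rsc for a
    "down" table, the maximum for an "up" table.  Ties break by
    lexicographically smallest gene symbol."""
    if table.empty:
        raise ValueError("cannot rank an empty table")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    ordered = table.sort_values("gene", kind="mergesort")
    rsc = ordered["rsc"].to_numpy(dtype=float)
    idx = int(np.argmin(rsc)) if direction == "down" else int(np.argmax(rsc))
    row = ordered.iloc[idx]
    return str(row["gene"]), float(row["rsc"])


def sample_correlation_matrix(nspc: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between samples over their protein profiles.

    ``nspc`` has proteins as rows and samples as columns.  The result is
    symmetric with unit diagonal.  A zero-variance sample profile has no
    defined correlation and raises, naming the sample.
    """
    if nspc.shape[0] < 2 or nspc.shape[1] < 2:
        raise ValueError("need at least 2 proteins and 2 samples")
    variances = nspc.var(axis=0, ddof=0)
    flat = variances.index[variances == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance sample profile(s): {flat}")
    corr = np.corrcoef(nspc.to_numpy(), rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=nspc.columns, columns=nspc.columns)


def hierarchical_cluster(corr: pd.DataFrame):
    """Average-linkage clustering of samples on the distance 1 - r.

    Samples are pre-sorted by id so that scipy's deterministic tie handling
    yields a reproducible leaf order.  Returns (leaf order as sample ids,
    reordered correlation matrix, linkage matrix).
    """
    arr = corr.to_numpy()
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    order0 = sorted(corr.index)
    corr = corr.loc[order0, order0]
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    order = [order0[i] for i in leaves]
    return order, corr.loc[order, order], linkage


def export_gene_lists(tables: dict, outdir=None) -> dict:
    """Deduplicated, sorted gene-symbol lists per (compartment, direction),
    one symbol per line — ready for pasting into external network tools.

    ``tables`` maps (compartment, direction) to curated tables with a
    ``gene`` column.  When ``outdir`` is given, writes
    ``genes_<compartment>_<direction>.txt`` files there.
    """
    lists = {}
    for key, table in tables.items():
        genes = sorted(set(map(str, table["gene"]))) if len(table) else []
        lists[key] = genes
        if outdir is not None:
            compartment, direction = key
            path = f"{outdir}/genes_{compartment}_{direction}.txt"
            with open(path, "w") as handle:
                handle.write("\n".join(genes) + ("\n" if genes else ""))
    return lists
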