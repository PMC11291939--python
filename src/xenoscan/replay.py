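"""Deterministic recomputation of headline counts from a published call set.

When the authors' supplementary workbook of identified clusters and
xenologs is available locally (it is not shipped with this package: it is
a large binary spreadsheet distributed alongside the original study), the
bookkeeping of the pipeline can be replayed on it: total xenologs, subtree
and tree counts, the largest subtree, trees with a single focal subtree,
the concentration of xenologs in the top species, and the truncated
geometric ML parameter of the subtree-size sample.

Column names in published workbooks drift; the loader looks for the
conventional sheets ("Protein summary", "Cluster summary", "Organism
summary") and falls back to positional conventions.  All quantities are
recomputed from rows — nothing here is hard-coded.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import fit_geometric_ml


def _find_col(df: pd.DataFrame, *needles: str) -> str | None:
    for col in df.columns:
        name = str(col).lower()
        if all(n in name for n in needles):
            return col
    return None


def replay_supplementary(path: str | Path, size_window=(1, 12)) -> dict:
    """Recompute headline totals from a supplementary workbook.

    Returns a dict with: n_xenologs, n_subtrees, n_trees, n_fungal_xenologs,
    largest_subtree, single_subtree_trees, top5_species_fraction,
    geometric_p_ml.  Raises FileNotFoundError when the workbook is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary workbook not found at {path}; download the study's "
            "supplementary tables and pass their local path"
        )
    sheets = pd.read_excel(path, sheet_name=None)
    by_name = {str(k).strip().lower(): v for k, v in sheets.items()}
    prot = by_name.get("protein summary")
    clus = by_name.get("cluster summary")
    if prot is None or clus is None:
        raise ValueError(
            f"workbook lacks 'Protein summary'/'Cluster summary' sheets: "
            f"{sorted(by_name)}"
        )
    out: dict = {"n_xenologs": int(len(prot))}

    tree_col = _find_col(clus, "tree") or _find_col(clus, "cluster")
    size_col = _find_col(clus, "size") or _find_col(clus, "protein", "count")
    support_col = _find_col(clus, "support") or _find_col(clus, "class")
    supported = clus
    if support_col is not None:
        mask = (
            clus[support_col].astype(str).str.lower().str.contains("support")
            & ~clus[support_col].astype(str).str.lower().str.contains("weak|un")
        )
        if mask.any():
            supported = clus[mask]
    out["n_subtrees"] = int(len(supported))
    if tree_col is not None:
        trees = supported[tree_col]
        out["n_trees"] = int(trees.nunique())
        counts = trees.value_counts()
        out["single_subtree_trees"] = int((counts == 1).sum())
    if size_col is not None:
        sizes = pd.to_numeric(supported[size_col], errors="coerce").dropna()
        out["n_fungal_xenologs"] = int(sizes.sum())
        out["largest_subtree"] = int(sizes.max())
        windowed = sizes[(sizes >= size_window[0]) & (sizes <= size_window[1])]
        fit = fit_geometric_ml(
            windowed.astype(int).tolist(), support=size_window, truncated=True
        )
        out["geometric_p_ml"] = float(fit.parameter)
    species_col = _find_col(prot, "taxid") or _find_col(prot, "species") or _find_col(
        prot, "organism"
    )
    if species_col is not None:
        frac = prot[species_col].value_counts(normalize=True)
        out["top5_species_fraction"] = float(frac.iloc[:5].sum())
    return out
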