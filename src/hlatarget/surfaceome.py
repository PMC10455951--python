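"""Cell-surface proteome analysis: shared-core computation across cell
lines, transmembrane-helix filtering, intensity ranking and surface-marker
annotation.

Surface capture by glycoprotein biotinylation enriches, but does not
guarantee, plasma-membrane proteins; the predicted transmembrane-helix
count (three or more) is used as an orthogonal membrane filter, and the
shared core across lines is ranked by mean log-transformed intensity to
nominate broadly expressed targets.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LfqMatrix, TmPrediction

__all__ = [
    "detection_sets",
    "shared_core",
    "tm_filter",
    "rank_surface",
]


def detection_sets(matrix: LfqMatrix, min_replicates: int = 1) -> dict[str, set[str]]:
    """Proteins detected per cell line (group), at >= min_replicates valid values."""
    out = {}
    for line, samples in matrix.group_samples().items():
        valid = matrix.data[samples].notna().sum(axis=1)
        out[line] = set(valid.index[valid >= min_replicates])
    return out


def shared_core(sets: Iterable[set[str] | frozenset[str]]) -> set[str]:
    """Exact intersection of per-line protein sets."""
    sets = [set(s) for s in sets]
    if not sets:
        raise ValueError("need at least one set")
    core = sets[0].copy()
    for s in sets[1:]:
        core &= s
    return core


def tm_filter(
    predictions: Sequence[TmPrediction] | Mapping[str, int],
    proteins: Iterable[str],
    min_helices: int = 3,
    missing: str = "error",
) -> list[str]:
    """Keep proteins whose predicted transmembrane-helix count is >= min_helices.

    ``missing`` selects the policy for proteins without a prediction:
    "error" raises, "drop" removes them.
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-prediction policy {missing!r}")
    table = (
        {p.protein: p.pred_hel for p in predictions}
        if not isinstance(predictions, Mapping)
        else dict(predictions)
    )
    retained = []
    for acc in proteins:
        if acc not in table:
            if missing == "error":
                raise KeyError(f"no transmembrane prediction for {acc!r}")
            continue
        if table[acc] >= min_helices:
            retained.append(acc)
    return retained


def rank_surface(
    proteins: Iterable[str],
    log_matrix: LfqMatrix,
    k: int = 50,
    cspa: set[str] | frozenset[str] | None = None,
    gene_symbols: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Top-k proteins by mean log-transformed intensity, with marker flags.

    Ties in mean intensity break by accession lexicographic order. Flags:
    ``cspa`` membership of a curated surface-protein list; ``cd_marker``
    and ``slc_family`` from gene-symbol prefixes (CD<number>, SLC...) when a
    symbol mapping is supplied.
    """
    if not log_matrix.log_scale:
        raise ValueError("rank_surface expects a log-scale matrix")
    proteins = sorted(set(proteins) & set(log_matrix.proteins))
    if not proteins:
        raise ValueError("no queried protein is present in the matrix")
    if k > len(proteins):
        warnings.warn(
            f"k={k} exceeds the {len(proteins)} available proteins; returning all"
        )
    means = log_matrix.data.loc[proteins].mean(axis=1)
    out = pd.DataFrame({"mean_log_intensity": means})
    out.index.name = "protein"
    # stable sort on a lexicographically pre-sorted index => deterministic ties
    out = out.sort_index().sort_values(
        "mean_log_intensity", ascending=False, kind="stable"
    )
    out = out.head(min(k, len(out)))
    symbols = gene_symbols or {}

    def _symbol(acc: str) -> str:
        return symbols.get(acc, acc)

    out["gene_symbol"] = [_symbol(a) for a in out.index]
    out["cspa"] = [a in (cspa or set()) for a in out.index]
    out["cd_marker"] = [
        s.startswith("CD") and len(s) > 2 and s[2].isdigit() for s in out["gene_symbol"]
    ]
    out["slc_family"] = [s.startswith("SLC") for s in out["gene_symbol"]]
    return out
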