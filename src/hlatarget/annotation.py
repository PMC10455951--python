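"""Cross-referencing the retained peptidome against reference databases,
shared/unique set structure across samples, conserved-peptide heatmap
inputs, and hypergeometric term enrichment.

Peptide-level databases (tumor-antigen and epitope collections) match on
exact sequence; protein-level databases (tissue atlases, surface-protein
and druggable-target lists) match when *any* source protein of the peptide
is a member.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import RetainedPeptide
from .io import AnnotationDb

__all__ = [
    "AnnotatedPeptide",
    "annotate",
    "set_intersections",
    "top_shared_matrix",
    "enrich_terms",
    "zscore_rows",
]


@dataclass
class AnnotatedPeptide:
    """A retained peptide with database flags and an optional restriction."""

    sequence: str
    proteins: frozenset[str]
    restriction: tuple[str, str] | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    sample_log2_intensity: dict[str, float] = field(default_factory=dict)


def annotate(
    entries: Sequence[RetainedPeptide],
    databases: Sequence[AnnotationDb],
    restrictions: Mapping[str, tuple[str, str] | None] | None = None,
) -> tuple[list[AnnotatedPeptide], dict[str, int]]:
    """Flag every peptide against every database.

    Returns the annotated entries plus per-database overlap counts; the
    extra key ``"multi"`` counts peptides flagged by more than one
    database.
    """
    annotated: list[AnnotatedPeptide] = []
    counts = {db.name: 0 for db in databases}
    n_multi = 0
    for entry in entries:
        flags = {}
        for db in databases:
            if db.kind == "peptide":
                hit = entry.sequence in db.members
            else:  # protein-level: any source accession
                hit = any(p in db.members for p in entry.proteins)
            flags[db.name] = hit
            if hit:
                counts[db.name] += 1
        if sum(flags.values()) > 1:
            n_multi += 1
        annotated.append(
            AnnotatedPeptide(
                sequence=entry.sequence,
                proteins=entry.proteins,
                restriction=(restrictions or {}).get(entry.sequence),
                flags=flags,
                sample_log2_intensity={
                    s: float(np.log2(v)) for s, v in entry.sample_intensity.items() if v > 0
                },
            )
        )
    counts["multi"] = n_multi
    return annotated, counts


def set_intersections(
    sets: Mapping[str, set[str] | frozenset[str]],
) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts over all 2^k - 1 set combinations.

    Each element is counted in exactly one combination — the one naming
    precisely the sets that contain it — so the counts sum to the union
    size (the tabular content of an UpSet plot).
    """
    if not sets:
        raise ValueError("need at least one set")
    if len(sets) > 12:
        raise ValueError("more than 12 sets is not supported")
    names = list(sets)
    counts: dict[tuple[str, ...], int] = {
        combo: 0
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    universe = set().union(*sets.values())
    for element in universe:
        combo = tuple(n for n in names if element in sets[n])
        counts[combo] += 1
    return counts


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-score with sample SD (n-1); constant rows map to zeros."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    z = np.nan_to_num(z, nan=0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def top_shared_matrix(
    log2_matrix: pd.DataFrame, k: int = 40
) -> tuple[pd.DataFrame, int]:
    """Row-Z-scored heatmap input for the top-k fully shared peptides.

    ``log2_matrix`` holds log2 intensities of peptides observed in every
    sample (rows = peptides). Rows are ordered by descending mean log2
    intensity before Z-scoring. Returns (matrix, shortfall): when fewer
    than k rows exist all are returned and the shortfall is reported.
    """
    order = log2_matrix.mean(axis=1).sort_values(ascending=False).index
    shortfall = max(0, k - len(order))
    if shortfall:
        warnings.warn(
            f"only {len(order)} shared peptides available for top-{k} selection"
        )
    top = log2_matrix.loc[order[: min(k, len(order))]]
    return zscore_rows(top), shortfall


def enrich_terms(
    query: set[str] | frozenset[str],
    terms: Mapping[str, set[str] | frozenset[str]],
    background: set[str] | frozenset[str],
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Right-sided hypergeometric enrichment of a protein set per term.

    p = P(X >= x) with X hypergeometric(N = |background|, K = term size in
    background, n = |query|). Adjustment is plain Bonferroni across tested
    terms by default, Holm step-down via ``method="holm"``. Terms with no
    background members are skipped with a warning.
    """
    if not set(query) <= set(background):
        raise ValueError("query must be a subset of the background")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown correction method {method!r}")
    rows = []
    for name, members in terms.items():
        K = len(set(members) & set(background))
        if K == 0:
            warnings.warn(f"term {name!r} has no background members; skipped")
            continue
        x = len(set(members) & set(query))
        p = float(stats.hypergeom.sf(x - 1, len(background), K, len(query)))
        rows.append({"term": name, "n_term": K, "n_hits": x, "p_value": min(1.0, p)})
    out = pd.DataFrame(rows, columns=["term", "n_term", "n_hits", "p_value"])
    m = len(out)
    if m == 0:
        out["p_adjusted"] = []
        return out
    if method == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * m)
    else:
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="holm")[1]
    return out
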