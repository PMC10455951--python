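"""Length distributions, binding-motif analysis and HLA-restriction calls.

Motif structure is summarised as a position frequency matrix (PFM) and
compared against a reference repertoire as a percentage-point difference
per (position, residue) cell — the quantity a sequence-logo difference
plot displays — with an exact binomial test per cell, Bonferroni-corrected.

Restriction of peptides captured with a pan-class-I antibody is assigned
from predictor percent ranks: strong binder (SB) at rank <= 0.5, weak
binder (WB) at 0.5 < rank <= 2.0, non-binder (NB) otherwise; a peptide goes
to the allotype with the lowest rank.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AMINO_ACIDS

__all__ = [
    "SB_MAX_RANK",
    "WB_MAX_RANK",
    "length_distribution",
    "build_pfm",
    "icelogo_diff",
    "categorize_rank",
    "assign_restriction",
    "pssm_score",
    "percent_rank_surrogate",
]

SB_MAX_RANK = 0.5
WB_MAX_RANK = 2.0


def length_distribution(
    peptides: Iterable[str], length_min: int = 8, length_max: int = 12
) -> tuple[dict[int, int], dict[int, float]]:
    """Counts and fractions per length over the allowed window.

    Raises on out-of-window peptides (the filter ladder should already
    have enforced the window). An empty input yields zero counts and an
    empty fraction mapping.
    """
    counts = {length: 0 for length in range(length_min, length_max + 1)}
    total = 0
    for pep in peptides:
        if len(pep) not in counts:
            raise ValueError(f"peptide {pep!r} outside length {length_min}-{length_max}")
        counts[len(pep)] += 1
        total += 1
    if total == 0:
        return counts, {}
    return counts, {length: c / total for length, c in counts.items()}


def build_pfm(peptides: Sequence[str], pseudocount: float = 0.0) -> pd.DataFrame:
    """Position frequency matrix for peptides of one length.

    Rows are 1-based positions, columns the 20 residues. With pseudocount
    c each cell is (count + c) / (n + 20c), so columns remain stochastic.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not peptides:
        raise ValueError("need at least one peptide")
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise ValueError("peptides must share one length")
    counts = np.zeros((length, 20))
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for pep in peptides:
        for pos, aa in enumerate(pep):
            counts[pos, idx[aa]] += 1
    freqs = (counts + pseudocount) / (len(peptides) + 20 * pseudocount)
    return pd.DataFrame(
        freqs, index=pd.RangeIndex(1, length + 1, name="position"), columns=list(AMINO_ACIDS)
    )


def icelogo_diff(
    observed_pfm: pd.DataFrame,
    reference_pfm: pd.DataFrame,
    n_observed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentage-point motif difference with per-cell binomial tests.

    For every (position, residue) cell: difference = (observed -
    reference) * 100; a two-sided exact binomial test of the observed
    count against the reference frequency, Bonferroni-corrected across all
    cells, flags ``significant``; ``enriched`` marks a positive
    difference. Cells flagged both significant and enriched are the motif's
    anchor residues.
    """
    if observed_pfm.shape != reference_pfm.shape:
        raise ValueError("observed and reference matrices differ in shape")
    if n_observed < 1:
        raise ValueError("n_observed must be >= 1")
    n_cells = observed_pfm.size
    rows = []
    for pos in observed_pfm.index:
        for aa in observed_pfm.columns:
            obs = float(observed_pfm.loc[pos, aa])
            ref = float(reference_pfm.loc[pos, aa])
            k = int(round(obs * n_observed))
            p = stats.binomtest(
                k, n_observed, float(np.clip(ref, 1e-12, 1 - 1e-12)),
                alternative="two-sided",
            ).pvalue
            rows.append(
                {
                    "position": pos,
                    "residue": aa,
                    "observed": obs,
                    "reference": ref,
                    "diff_pct": (obs - ref) * 100.0,
                    "p_value": p,
                    "p_bonferroni": min(1.0, p * n_cells),
                }
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] <= alpha
    out["enriched"] = out["diff_pct"] > 0
    return out


def categorize_rank(percent_rank: float) -> str:
    """SB / WB / NB category of a percent rank.

    The boundaries are inclusive on the strong side: rank 0.5 is SB,
    rank 2.0 is WB (predictor convention for "rank <= threshold").
    """
    if percent_rank < 0:
        raise ValueError("percent rank must be >= 0")
    if percent_rank <= SB_MAX_RANK:
        return "SB"
    if percent_rank <= WB_MAX_RANK:
        return "WB"
    return "NB"


def assign_restriction(
    ranks: Mapping[str, float], sb_only: bool = False
) -> tuple[str, str] | None:
    """Best-allele restriction call from per-allotype percent ranks.

    The allotype with the minimum rank wins, ties broken by allele-name
    lexicographic order. Returns None (unassigned) when the winning rank
    is a non-binder, or — with ``sb_only`` — anything weaker than SB.
    """
    if not ranks:
        raise ValueError("need at least one allele rank")
    allele = min(sorted(ranks), key=lambda a: ranks[a])
    category = categorize_rank(ranks[allele])
    if category == "NB" or (sb_only and category != "SB"):
        return None
    return allele, category


def pssm_score(peptide: str, pfm: pd.DataFrame, pseudofreq: float = 1e-4) -> float:
    """Log-odds of a peptide under a PFM against a uniform background."""
    if len(peptide) != len(pfm.index):
        raise ValueError("peptide length does not match the matrix")
    score = 0.0
    for pos, aa in zip(pfm.index, peptide):
        score += np.log((pfm.loc[pos, aa] + pseudofreq) / (1.0 / 20.0))
    return float(score)


def percent_rank_surrogate(
    peptides: Sequence[str],
    pfm: pd.DataFrame,
    n_background: int = 10000,
    seed: int = 0,
) -> dict[str, float]:
    """Percent ranks from a PSSM against a random-peptide background.

    The rank of a peptide is the percentage of random same-length peptides
    scoring at least as well — an in-package surrogate with the same
    lower-is-stronger semantics as an external binding predictor, meant
    for running the pipeline without one (not a replacement for a trained
    model on real data).
    """
    rng = np.random.default_rng(seed)
    length = len(pfm.index)
    aa = np.array(list(AMINO_ACIDS))
    background = ["".join(rng.choice(aa, size=length)) for _ in range(n_background)]
    bg_scores = np.sort([pssm_score(p, pfm) for p in background])
    out = {}
    for pep in peptides:
        s = pssm_score(pep, pfm)
        n_ge = len(bg_scores) - int(np.searchsorted(bg_scores, s, side="left"))
        out[pep] = 100.0 * n_ge / n_background
    return out
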