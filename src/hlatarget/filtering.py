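"""The PSM filtering ladder: raw search output to a non-redundant 8-12-mer
HLA class I peptide repertoire.

Steps run in a fixed order: FDR cutoff on target-decoy q-values, then
removal of decoys, spiked retention-time calibrants, blank-detected
sequences and modified PSMs, then a length window, and finally
sequence-level deduplication keeping the best-scoring PSM while merging
per-sample intensities. The retained *set* is order-invariant (each step is
a predicate on the row); only the per-step removal counts depend on the
order, which is reported so counts always conserve the input size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import PsmRecord

__all__ = [
    "FilterConfig",
    "FilterReport",
    "RetainedPeptide",
    "estimate_q_values",
    "apply_filter_ladder",
    "peptides_per_protein",
]


@dataclass
class FilterConfig:
    """Parameters of the filtering ladder.

    The FDR cutoff applies at PSM level to target-decoy q-values (the
    simplest published estimator; proprietary search-engine FDR machinery
    is out of scope).
    """

    fdr_cutoff: float = 0.05
    length_min: int = 8
    length_max: int = 12
    drop_modified: bool = True
    blank_peptides: frozenset[str] = frozenset()
    irt_peptides: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_cutoff <= 1.0:
            raise ValueError("fdr_cutoff must be in (0, 1]")
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        self.blank_peptides = frozenset(self.blank_peptides)
        self.irt_peptides = frozenset(self.irt_peptides)


@dataclass
class RetainedPeptide:
    """One non-redundant retained sequence with merged evidence."""

    sequence: str
    score: float
    q_value: float | None
    proteins: frozenset[str]
    samples: frozenset[str]
    sample_intensity: dict[str, float] = field(default_factory=dict)


@dataclass
class FilterReport:
    """Per-step removal counts plus the retained peptide entries.

    Invariant: ``n_input == n_retained + sum(removed.values())``.
    ``per_sample_counts`` gives per-sample unique-sequence tallies (a
    sequence seen in two samples counts once in each).
    """

    n_input: int
    removed: dict[str, int]
    n_retained: int
    retained: list[RetainedPeptide]
    per_sample_counts: dict[str, int]


def estimate_q_values(
    scores: Sequence[float], decoy_flags: Sequence[bool]
) -> np.ndarray:
    """Target-decoy q-values: monotonized #decoys>=s / max(1, #targets>=s).

    The q-value of a PSM is the minimum estimated FDR over all score
    thresholds at which it would be accepted; it is non-increasing in
    score and clipped to <= 1.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(decoy_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and decoy_flags must have equal length")
    if not flags.any():
        raise ValueError("q-value estimation needs at least one decoy")
    if flags.all():
        raise ValueError("q-value estimation needs at least one target")
    order = np.argsort(-scores, kind="stable")
    n_decoy = np.cumsum(flags[order])
    n_target = np.cumsum(~flags[order])
    fdr = n_decoy / np.maximum(1, n_target)
    # ties share the FDR at the last PSM with the same score
    sorted_scores = scores[order]
    last_of_tie = np.concatenate([sorted_scores[1:] != sorted_scores[:-1], [True]])
    for i in range(len(fdr) - 2, -1, -1):
        if not last_of_tie[i]:
            fdr[i] = fdr[i + 1]
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def apply_filter_ladder(
    psms: Sequence[PsmRecord], config: FilterConfig
) -> FilterReport:
    """Run the fixed-order ladder and report counts at every step."""
    removed = {
        "above_fdr": 0,
        "decoy": 0,
        "irt": 0,
        "blank": 0,
        "modified": 0,
        "length": 0,
        "duplicate": 0,
    }
    if not psms:
        return FilterReport(0, removed, 0, [], {})

    q_values = [p.q_value for p in psms]
    if any(q is None for q in q_values):
        q_values = estimate_q_values(
            [p.score for p in psms], [p.is_decoy for p in psms]
        ).tolist()

    surviving: list[tuple[PsmRecord, float]] = []
    for psm, q in zip(psms, q_values):
        if q > config.fdr_cutoff:
            removed["above_fdr"] += 1
        elif psm.is_decoy:
            removed["decoy"] += 1
        elif psm.sequence in config.irt_peptides:
            removed["irt"] += 1
        elif psm.sequence in config.blank_peptides:
            removed["blank"] += 1
        elif config.drop_modified and psm.modifications:
            removed["modified"] += 1
        elif not config.length_min <= len(psm.sequence) <= config.length_max:
            removed["length"] += 1
        else:
            surviving.append((psm, q))

    by_seq: dict[str, RetainedPeptide] = {}
    for psm, q in surviving:
        entry = by_seq.get(psm.sequence)
        if entry is None:
            by_seq[psm.sequence] = RetainedPeptide(
                sequence=psm.sequence,
                score=psm.score,
                q_value=q,
                proteins=frozenset(psm.proteins),
                samples=frozenset([psm.sample]),
                sample_intensity=(
                    {psm.sample: psm.intensity} if psm.intensity is not None else {}
                ),
            )
        else:
            removed["duplicate"] += 1
            if psm.score > entry.score:
                entry.score, entry.q_value = psm.score, q
            entry.proteins = entry.proteins | frozenset(psm.proteins)
            entry.samples = entry.samples | {psm.sample}
            if psm.intensity is not None:
                prev = entry.sample_intensity.get(psm.sample)
                entry.sample_intensity[psm.sample] = (
                    psm.intensity if prev is None else max(prev, psm.intensity)
                )

    per_sample: Counter[str] = Counter()
    for entry in by_seq.values():
        for s in entry.samples:
            per_sample[s] += 1

    retained = list(by_seq.values())
    return FilterReport(
        n_input=len(psms),
        removed=removed,
        n_retained=len(retained),
        retained=retained,
        per_sample_counts=dict(per_sample),
    )


def peptides_per_protein(
    retained: Iterable[RetainedPeptide],
) -> tuple[dict[str, int], float]:
    """Peptide count per source protein and the single-peptide fraction.

    A peptide mapping to several proteins counts once for each of them.
    The second return value is the fraction of proteins contributing
    exactly one peptide.
    """
    counts: Counter[str] = Counter()
    for entry in retained:
        for prot in entry.proteins:
            counts[prot] += 1
    if not counts:
        return {}, float("nan")
    singletons = sum(1 for c in counts.values() if c == 1)
    return dict(counts), singletons / len(counts)
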