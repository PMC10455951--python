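"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and a seed, so each
downstream stage can be exercised against known ground truth: planted HLA
binding motifs, PSM contamination of every class the filter ladder
removes, paired endogenous/synthetic-standard fragment spectra, and LFQ
matrices with group effects and intensity-dependent (missing-not-at-random)
dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, AnnotationDb, LfqMatrix, PsmRecord, Spectrum, TmPrediction
from .spectra import precursor_mz, theoretical_fragments

__all__ = [
    "MotifModel",
    "SimTruth",
    "IRT_PEPTIDES",
    "make_motif_model",
    "sample_peptides",
    "make_psm_dataset",
    "simulate_spectrum_pair",
    "simulate_lfq_experiment",
    "make_annotation_fixtures",
    "predict_tm_helices",
    "make_tm_predictions",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Eleven synthetic stand-ins for spiked retention-time calibration
#: peptides. Sequences are arbitrary tryptic-looking inventions, not any
#: commercial calibration kit.
IRT_PEPTIDES: tuple[str, ...] = (
    "AGDVLESLYK",
    "DGTWNDLAYR",
    "EVLTGSPLYK",
    "FNDATSLGVR",
    "GSIEHVDTLK",
    "HTAVDGNSLR",
    "LDNSVETGYK",
    "NVGSEADTLR",
    "SGDYLTNAVK",
    "TPEVDGLSYR",
    "VANDLTEGSK",
)


@dataclass(frozen=True)
class MotifModel:
    """Per-position residue frequencies for one HLA allotype and length."""

    allele: str
    length: int
    position_freqs: np.ndarray  # (length, 20), rows sum to 1
    anchor_positions: frozenset[int]
    anchor_spec: tuple[tuple[int, tuple[str, ...], float], ...] = ()

    def __post_init__(self) -> None:
        freqs = np.asarray(self.position_freqs, dtype=float)
        if freqs.shape != (self.length, 20):
            raise ValueError("position_freqs must be (length, 20)")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's frequencies must sum to 1")
        object.__setattr__(self, "position_freqs", freqs)


@dataclass
class SimTruth:
    """Ground-truth bookkeeping emitted alongside every synthetic dataset."""

    psm_labels: list[str] = field(default_factory=list)
    peptide_allele: dict[str, str] = field(default_factory=dict)
    de_proteins: frozenset[str] = frozenset()
    de_effects: dict[str, float] = field(default_factory=dict)
    db_members: dict[str, frozenset[str]] = field(default_factory=dict)
    seed: int | None = None


def make_motif_model(
    allele: str,
    anchors: Mapping[int, tuple[Sequence[str], float]],
    length: int = 9,
) -> MotifModel:
    """Build a motif model from an anchor definition.

    ``anchors`` maps a 1-based position to (residues, total anchor
    probability); the probability is split equally among the listed
    residues, with the remainder spread uniformly over the other residues.
    Non-anchor positions are uniform over the 20-letter alphabet.
    """
    freqs = np.full((length, 20), 1.0 / 20.0)
    for pos, (residues, prob) in anchors.items():
        if not 0.0 < prob <= 1.0:
            raise ValueError(f"anchor probability {prob} outside (0, 1]")
        if not 1 <= pos <= length:
            raise ValueError(f"anchor position {pos} outside 1..{length}")
        row = np.full(20, (1.0 - prob) / (20 - len(residues)))
        for r in residues:
            row[_AA_INDEX[r]] = prob / len(residues)
        freqs[pos - 1] = row
    spec = tuple(
        (pos, tuple(res), prob) for pos, (res, prob) in sorted(anchors.items())
    )
    return MotifModel(
        allele=allele,
        length=length,
        position_freqs=freqs,
        anchor_positions=frozenset(anchors),
        anchor_spec=spec,
    )


def _freqs_for_length(model: MotifModel, length: int) -> np.ndarray:
    """Map a model onto another peptide length.

    Internal anchors keep their index; an anchor at the model's C-terminal
    position maps to the new C-terminus. Non-anchor positions are uniform.
    """
    if length == model.length:
        return model.position_freqs
    freqs = np.full((length, 20), 1.0 / 20.0)
    for pos in model.anchor_positions:
        new_pos = length if pos == model.length else pos
        if 1 <= new_pos <= length:
            freqs[new_pos - 1] = model.position_freqs[pos - 1]
    return freqs


def sample_peptides(
    model: MotifModel,
    n: int,
    length_dist: Mapping[int, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw peptides letter-by-letter from the motif model.

    ``length_dist`` gives probabilities over lengths 8-12 (default: all
    peptides at the model's own length). The canonical class I repertoire
    shape used throughout the test scenarios is
    ``{9: 0.65, 10: 0.2, 11: 0.1, 8: 0.03, 12: 0.02}``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if length_dist is None:
        length_dist = {model.length: 1.0}
    lengths = sorted(length_dist)
    probs = np.array([length_dist[l] for l in lengths], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError("length distribution must sum to 1")
    drawn = rng.choice(lengths, size=n, p=probs)
    aa = np.array(list(AMINO_ACIDS))
    peptides = []
    for length in drawn:
        freqs = _freqs_for_length(model, int(length))
        letters = [
            aa[rng.choice(20, p=freqs[i])] for i in range(int(length))
        ]
        peptides.append("".join(letters))
    return peptides


def _shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    letters = list(seq)
    rng.shuffle(letters)
    return "".join(letters)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_psm_dataset(
    true_peptides: Sequence[str],
    n_decoy: int = 0,
    n_irt: int = 0,
    n_blank: int = 0,
    n_modified: int = 0,
    score_true: tuple[float, float] = (60.0, 10.0),
    score_decoy: tuple[float, float] = (40.0, 10.0),
    samples: Sequence[str] = ("sample1",),
    antibody: str = "pan-classI",
    proteins_per_peptide: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> tuple[list[PsmRecord], frozenset[str], SimTruth]:
    """Assemble a contaminated PSM table with per-row truth labels.

    True PSMs get scores from ``score_true`` (mean, sd); contaminants of
    every class the filter ladder removes are appended: decoys (shuffled
    true sequences under DECOY_ accessions), spiked retention-time
    calibrants, blank-detected peptides (returned also as the blank set),
    and modified duplicates of true PSMs. Scores of true PSMs are
    stochastically larger than decoy scores.
    """
    for name, k in (("n_decoy", n_decoy), ("n_irt", n_irt), ("n_modified", n_modified)):
        if name != "n_irt" and k > len(true_peptides):
            raise ValueError(f"{name}={k} exceeds number of true peptides")
    if n_irt > len(IRT_PEPTIDES):
        raise ValueError(f"n_irt={n_irt} exceeds the {len(IRT_PEPTIDES)}-member iRT list")
    rng = np.random.default_rng(seed)
    records: list[PsmRecord] = []
    labels: list[str] = []

    def _mk(seq, score, *, decoy=False, mods=(), prots=None, sample=None):
        return PsmRecord(
            sequence=seq,
            modifications=list(mods),
            score=float(score),
            is_decoy=decoy,
            sample=sample if sample is not None else samples[int(rng.integers(len(samples)))],
            antibody=antibody,
            rt_min=float(np.round(rng.uniform(10.0, 110.0), 3)),
            intensity=float(np.round(np.exp(rng.normal(16.0, 1.5)), 1)),
            proteins=list(prots) if prots is not None else [],
        )

    for pep in true_peptides:
        prots = (
            list(proteins_per_peptide.get(pep, [f"PROT_{pep[:4]}"]))
            if proteins_per_peptide is not None
            else [f"PROT_{pep[:4]}"]
        )
        records.append(_mk(pep, rng.normal(*score_true), prots=prots))
        labels.append("true")

    decoy_src = rng.choice(len(true_peptides), size=n_decoy, replace=False) if n_decoy else []
    for idx in decoy_src:
        seq = _shuffle_sequence(true_peptides[int(idx)], rng)
        records.append(
            _mk(seq, rng.normal(*score_decoy), decoy=True, prots=[f"DECOY_PROT_{int(idx)}"])
        )
        labels.append("decoy")

    for pep in list(IRT_PEPTIDES)[:n_irt]:
        records.append(_mk(pep, rng.normal(*score_true), prots=["IRT_STANDARD"]))
        labels.append("irt")

    blank_set = set()
    for _ in range(n_blank):
        seq = _random_peptide(rng, int(rng.integers(8, 13)))
        while seq in set(true_peptides) | blank_set:
            seq = _random_peptide(rng, int(rng.integers(8, 13)))
        blank_set.add(seq)
        records.append(_mk(seq, rng.normal(*score_true), prots=[f"PROT_{seq[:4]}"]))
        labels.append("blank")

    mod_src = rng.choice(len(true_peptides), size=n_modified, replace=False) if n_modified else []
    for idx in mod_src:
        base = records[int(idx)]
        pos = int(rng.integers(1, len(base.sequence) + 1))
        records.append(
            _mk(
                base.sequence,
                rng.normal(*score_true),
                mods=[(pos, "Oxidation")],
                prots=base.proteins,
                sample=base.sample,
            )
        )
        labels.append("modified")

    truth = SimTruth(psm_labels=labels, seed=seed)
    return records, frozenset(blank_set), truth


def simulate_spectrum_pair(
    peptide: str,
    noise_cv: float = 0.1,
    rt_shift_min: float = 0.0,
    n_noise_peaks: int = 0,
    rt_base_min: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> tuple[Spectrum, Spectrum]:
    """An endogenous / synthetic-standard spectrum pair for one peptide.

    Both spectra contain every singly charged b/y ion. Base fragment
    intensities are drawn log-normal (sigma = 1) once per pair, then each
    spectrum perturbs them independently with multiplicative log-normal
    noise of coefficient of variation ``noise_cv``; uniform random noise
    peaks are added on top. Retention times differ by ``rt_shift_min``.
    """
    if not 8 <= len(peptide) <= 12:
        raise ValueError("peptide length must be 8-12")
    rng = np.random.default_rng(seed)
    frags = theoretical_fragments(peptide, max_charge=1)
    mzs = np.array([f.mz for f in frags])
    base = np.exp(rng.normal(0.0, 1.0, size=len(frags))) * 1e4
    sigma = np.sqrt(np.log1p(noise_cv**2))

    def _one(title: str, rt: float) -> Spectrum:
        inten = base * np.exp(rng.normal(0.0, sigma, size=len(frags))) if sigma > 0 else base.copy()
        mz_all, int_all = list(mzs), list(inten)
        for _ in range(n_noise_peaks):
            mz_all.append(rng.uniform(100.0, 1500.0))
            int_all.append(np.exp(rng.normal(0.0, 1.0)) * 1e3)
        return Spectrum(
            title=title,
            precursor_mz=precursor_mz(peptide, charge=2),
            precursor_charge=2,
            rt_min=rt,
            peaks=np.column_stack([mz_all, int_all]),
        )

    endo = _one(f"{peptide}_endogenous", rt_base_min)
    synth = _one(f"{peptide}_synthetic", rt_base_min + rt_shift_min)
    return endo, synth


def simulate_lfq_experiment(
    n_proteins: int = 2000,
    n_per_group: int = 3,
    frac_de: float = 0.05,
    log2_effect: float = 2.0,
    within_sd: float = 0.5,
    baseline_mean: float = 24.0,
    baseline_sd: float = 2.5,
    dropout_midpoint: float = 21.0,
    dropout_steepness: float = 1.5,
    groups: tuple[str, str] = ("DIPG-like", "PB-like"),
    seed: int = 0,
) -> tuple[LfqMatrix, SimTruth]:
    """Two-group LFQ matrix with planted effects and MNAR dropout.

    Exactly ``round(frac_de * n_proteins)`` proteins are shifted by
    ``log2_effect`` (log2 units) in the first group. Dropout is
    missing-not-at-random: the probability that a measurement is missing
    follows a logistic curve decreasing in log2 intensity, with 50%
    dropout at ``dropout_midpoint`` and slope ``dropout_steepness``.
    Returned intensities are raw (linear) scale.
    """
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must be in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    mu = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    n_de = int(round(frac_de * n_proteins))
    de_idx = rng.choice(n_proteins, size=n_de, replace=False)
    effect = np.zeros(n_proteins)
    effect[de_idx] = log2_effect

    cols = [f"{groups[0]}_{i+1}" for i in range(n_per_group)] + [
        f"{groups[1]}_{i+1}" for i in range(n_per_group)
    ]
    log2x = np.empty((n_proteins, 2 * n_per_group))
    log2x[:, :n_per_group] = (
        mu[:, None] + effect[:, None] + rng.normal(0.0, within_sd, (n_proteins, n_per_group))
    )
    log2x[:, n_per_group:] = mu[:, None] + rng.normal(
        0.0, within_sd, (n_proteins, n_per_group)
    )
    from scipy.special import expit

    p_miss = expit(-dropout_steepness * (log2x - dropout_midpoint))
    missing = rng.random(log2x.shape) < p_miss
    raw = np.power(2.0, log2x)
    raw[missing] = np.nan

    data = pd.DataFrame(raw, index=proteins, columns=cols)
    group_map = {c: (groups[0] if i < n_per_group else groups[1]) for i, c in enumerate(cols)}
    truth = SimTruth(
        de_proteins=frozenset(proteins[int(i)] for i in de_idx),
        de_effects={proteins[int(i)]: log2_effect for i in de_idx},
        seed=seed,
    )
    return LfqMatrix(data, group_map, log_scale=False), truth


# default database kinds used across the pipeline
DB_KINDS = {
    "HBPA": "protein",
    "TANTIGEN": "peptide",
    "CTA": "peptide",
    "IEDB": "peptide",
    "CSPA": "protein",
    "DRUGGABLE": "protein",
}


def make_annotation_fixtures(
    peptides: Sequence[str],
    proteins: Sequence[str],
    overlap_fractions: Mapping[str, float],
    n_distractors: int = 20,
    kinds: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[list[AnnotationDb], SimTruth]:
    """Reference databases overlapping the universe by stated fractions.

    Each database receives ``round(fraction * universe size)`` members from
    the matching universe (peptide or protein, per its kind) plus
    distractor members absent from the universe.
    """
    kinds = dict(DB_KINDS if kinds is None else kinds)
    rng = np.random.default_rng(seed)
    dbs: list[AnnotationDb] = []
    truth_members: dict[str, frozenset[str]] = {}
    for name, frac in overlap_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"overlap fraction for {name} outside [0, 1]")
        kind = kinds.get(name, "peptide")
        universe = list(peptides) if kind == "peptide" else list(proteins)
        k = int(round(frac * len(universe)))
        hits = set(rng.choice(universe, size=k, replace=False)) if k else set()
        distractors = set()
        while len(distractors) < n_distractors:
            cand = (
                _random_peptide(rng, 9)
                if kind == "peptide"
                else f"X{rng.integers(10**5, 10**6)}"
            )
            if cand not in set(universe):
                distractors.add(cand)
        dbs.append(AnnotationDb(name=name, kind=kind, members=frozenset(hits | distractors)))
        truth_members[name] = frozenset(hits)
    return dbs, SimTruth(db_members=truth_members, seed=seed)


# Kyte-Doolittle hydropathy (trivial stand-in for a real TM-topology model)
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def predict_tm_helices(sequence: str, window: int = 19, threshold: float = 1.6) -> int:
    """Count non-overlapping hydrophobic windows (hydropathy-window stand-in).

    A deliberately simple surrogate for a transmembrane-topology predictor:
    scans with a Kyte-Doolittle window and counts disjoint stretches whose
    mean hydropathy exceeds ``threshold``. Useful only for generating test
    fixtures, not for real topology prediction.
    """
    if len(sequence) < window:
        return 0
    scores = np.convolve(
        [_KD[a] for a in sequence], np.ones(window) / window, mode="valid"
    )
    count, i = 0, 0
    while i < len(scores):
        if scores[i] > threshold:
            count += 1
            i += window  # skip past this helix
        else:
            i += 1
    return count


def make_tm_predictions(
    sequences: Mapping[str, str], window: int = 19, threshold: float = 1.6
) -> list[TmPrediction]:
    return [
        TmPrediction(protein=acc, pred_hel=predict_tm_helices(seq, window, threshold))
        for acc, seq in sequences.items()
    ]

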