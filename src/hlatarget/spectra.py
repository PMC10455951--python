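"""Fragment-mass computation and endogenous-vs-synthetic spectral validation.

Candidate peptide identifications are confirmed by acquiring a synthetic
standard of the same sequence and checking that the two fragmentation
patterns agree: theoretical b/y ions are matched into both spectra within a
fragment tolerance, and the Pearson correlation of the paired intensity
vectors (the quantity a mirror plot visualises) is compared against a
threshold, optionally together with a retention-time window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AMINO_ACIDS, Spectrum

__all__ = [
    "FragmentIon",
    "ValidationResult",
    "ZeroVarianceError",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "PROTON_MASS",
    "WATER_MASS",
    "neutral_mass",
    "precursor_mz",
    "theoretical_fragments",
    "match_intensity_vectors",
    "mirror_pearson",
    "validate_pair",
]

# Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863


class ZeroVarianceError(ValueError):
    """Correlation is undefined because an intensity vector is constant."""


@dataclass(frozen=True)
class FragmentIon:
    """One backbone fragment: series 'b' (N-terminal) or 'y' (C-terminal)."""

    series: str
    index: int
    charge: int
    mz: float


@dataclass
class ValidationResult:
    """Outcome of one endogenous/synthetic pair comparison."""

    peptide: str
    pearson_r: float
    rt_endogenous_min: float
    rt_synthetic_min: float
    n_matched_fragments: int
    decision: bool


def _residue_masses(peptide: str) -> np.ndarray:
    try:
        return np.array([MONOISOTOPIC_RESIDUE_MASSES[a] for a in peptide])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from None


def neutral_mass(peptide: str) -> float:
    """Neutral monoisotopic mass: residue masses plus one water."""
    return float(_residue_masses(peptide).sum() + WATER_MASS)


def precursor_mz(peptide: str, charge: int = 1) -> float:
    """m/z of [M + zH]^z+."""
    return (neutral_mass(peptide) + charge * PROTON_MASS) / charge


def theoretical_fragments(peptide: str, max_charge: int = 1) -> list[FragmentIon]:
    """All b/y ions of a peptide up to ``max_charge``.

    b_i is the N-terminal prefix of i residues plus a proton; y_i is the
    C-terminal suffix of i residues plus water plus a proton. A peptide of
    length L yields exactly 2(L-1) ions per charge state.
    """
    if set(peptide) - set(AMINO_ACIDS):
        raise ValueError(f"non-standard residues in {peptide!r}")
    masses = _residue_masses(peptide)
    prefix = np.cumsum(masses)[:-1]          # b1 .. b(L-1)
    suffix = np.cumsum(masses[::-1])[:-1]    # y1 .. y(L-1)
    frags: list[FragmentIon] = []
    for z in range(1, max_charge + 1):
        for i, m in enumerate(prefix, start=1):
            frags.append(FragmentIon("b", i, z, (m + z * PROTON_MASS) / z))
        for i, m in enumerate(suffix, start=1):
            frags.append(
                FragmentIon("y", i, z, (m + WATER_MASS + z * PROTON_MASS) / z)
            )
    return frags


def match_intensity_vectors(
    spectrum_a: Spectrum,
    spectrum_b: Spectrum,
    fragments: list[FragmentIon],
    tol_da: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity of the nearest peak within +-tol_da of each fragment.

    Both output vectors are indexed by the fragment list; a fragment with
    no peak inside the window contributes zero. When two peaks fall inside
    the window the nearer one (in m/z) wins.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")

    def _vector(spec: Spectrum) -> np.ndarray:
        mz = spec.peaks[:, 0]
        inten = spec.peaks[:, 1]
        out = np.zeros(len(fragments))
        for k, frag in enumerate(fragments):
            if mz.size == 0:
                continue
            j = int(np.argmin(np.abs(mz - frag.mz)))
            if abs(mz[j] - frag.mz) <= tol_da:
                out[k] = inten[j]
        return out

    return _vector(spectrum_a), _vector(spectrum_b)


def mirror_pearson(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Pearson product-moment correlation of two matched intensity vectors."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired intensities")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("constant intensity vector; correlation undefined")
    if np.array_equal(a, b):
        return 1.0
    return float(stats.pearsonr(a, b).statistic)


def validate_pair(
    endogenous: Spectrum,
    synthetic: Spectrum,
    peptide: str,
    r_min: float = 0.9,
    rt_window_min: float = 3.0,
    rt_rule_enabled: bool = False,
    tol_da: float = 0.02,
    max_charge: int = 1,
) -> ValidationResult:
    """Apply the pass/fail rule to one endogenous/synthetic spectrum pair.

    The default rule is R >= r_min alone; enabling the retention-time rule
    additionally requires |RT_endogenous - RT_synthetic| <= rt_window_min.
    """
    frags = theoretical_fragments(peptide, max_charge=max_charge)
    va, vb = match_intensity_vectors(endogenous, synthetic, frags, tol_da=tol_da)
    r = mirror_pearson(va, vb)
    n_matched = int(np.sum((va > 0) & (vb > 0)))
    decision = r >= r_min
    if rt_rule_enabled:
        decision = decision and abs(endogenous.rt_min - synthetic.rt_min) <= rt_window_min
    return ValidationResult(
        peptide=peptide,
        pearson_r=r,
        rt_endogenous_min=endogenous.rt_min,
        rt_synthetic_min=synthetic.rt_min,
        n_matched_fragments=n_matched,
        decision=bool(decision),
    )
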