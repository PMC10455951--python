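"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated with a header row. Canonical column
names are defined here; foreign exports (search-engine or predictor
dialects) are mapped in through a ``dialect`` argument, a mapping from
canonical name to the column name found in the file.

Conventions fixed package-wide:

* retention time is minutes everywhere in memory;
* modifications are encoded ``"pos|Name"`` (1-based residue index),
  semicolon-joined when a PSM carries several;
* decoy status, when the table has no explicit column, is inferred from a
  configurable accession prefix (default ``"DECOY_"``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "FormatError",
    "PsmRecord",
    "Spectrum",
    "BindingRank",
    "AnnotationDb",
    "LfqMatrix",
    "TmPrediction",
    "parse_psm_table",
    "write_psm_table",
    "parse_mgf",
    "write_mgf",
    "parse_rank_table",
    "write_rank_table",
    "parse_named_list",
    "write_named_list",
    "parse_fasta",
    "write_fasta",
    "parse_tm_table",
    "write_tm_table",
    "parse_lfq_matrix",
    "write_lfq_matrix",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PsmRecord:
    """One peptide-spectrum match.

    ``score`` is a search-engine score, unitless, higher is better.
    ``antibody`` records the capture reagent (pan-class-I vs
    allotype-specific immunoprecipitation).
    """

    sequence: str
    modifications: list[tuple[int, str]] = field(default_factory=list)
    score: float = 0.0
    q_value: float | None = None
    is_decoy: bool = False
    sample: str = ""
    antibody: str = ""
    rt_min: float | None = None
    intensity: float | None = None
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("PSM sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"sequence contains non-standard residues: {sorted(bad)}")
        for pos, name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            if not name:
                raise ValueError("modification name must be non-empty")
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class Spectrum:
    """A fragment spectrum: precursor, retention time and a peak list.

    Peaks are stored as a float array of shape (n, 2), columns (m/z,
    intensity), sorted ascending by m/z.
    """

    title: str
    precursor_mz: float
    precursor_charge: int
    rt_min: float
    peaks: np.ndarray

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        order = np.argsort(peaks[:, 0], kind="stable")
        peaks = peaks[order]
        if peaks.size and peaks[:, 0].min() <= 0:
            raise ValueError("peak m/z values must be strictly positive")
        if peaks.size and peaks[:, 1].min() < 0:
            raise ValueError("peak intensities must be >= 0")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be a positive integer")
        self.peaks = peaks

    def __eq__(self, other: object) -> bool:  # array field needs care
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.title == other.title
            and np.isclose(self.precursor_mz, other.precursor_mz)
            and self.precursor_charge == other.precursor_charge
            and np.isclose(self.rt_min, other.rt_min)
            and self.peaks.shape == other.peaks.shape
            and np.allclose(self.peaks, other.peaks)
        )


@dataclass(frozen=True)
class BindingRank:
    """Predicted percent rank of a peptide against one HLA allotype.

    Percent rank is the percentile of the predicted binding score against a
    random-peptide background; lower is stronger.
    """

    peptide: str
    allele: str
    percent_rank: float

    def __post_init__(self) -> None:
        if self.percent_rank < 0:
            raise ValueError("percent rank must be >= 0")


@dataclass
class AnnotationDb:
    """A named reference list of peptides or protein accessions."""

    name: str
    kind: str  # "peptide" or "protein"
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in ("peptide", "protein"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not self.members:
            raise ValueError(f"annotation database {self.name!r} is empty")
        self.members = frozenset(self.members)


@dataclass
class TmPrediction:
    """Predicted transmembrane-helix count for one protein."""

    protein: str
    pred_hel: int

    def __post_init__(self) -> None:
        if self.pred_hel < 0:
            raise ValueError("pred_hel must be >= 0")


class LfqMatrix:
    """Protein-by-sample label-free quantification intensities.

    Wraps a pandas DataFrame (rows = protein accessions, columns = sample
    labels) plus a sample-to-group mapping. ``log_scale`` tracks whether
    values are raw areas (must be positive where present) or log2.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        groups: Mapping[str, str],
        log_scale: bool = False,
    ) -> None:
        missing = [s for s in data.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        if not log_scale:
            vals = data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise ValueError("raw intensities must be > 0 where present")
        self.data = data.astype(float)
        self.groups = {s: groups[s] for s in data.columns}
        self.log_scale = bool(log_scale)

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def group_samples(self) -> dict[str, list[str]]:
        """Samples per group, groups in first-appearance order."""
        out: dict[str, list[str]] = {}
        for s, g in self.groups.items():
            out.setdefault(g, []).append(s)
        return out

    def copy(self) -> "LfqMatrix":
        return LfqMatrix(self.data.copy(), dict(self.groups), self.log_scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LfqMatrix):
            return NotImplemented
        return (
            self.groups == other.groups
            and self.log_scale == other.log_scale
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(
                self.data.to_numpy(), other.data.to_numpy(), equal_nan=True
            )
        )


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

PSM_COLUMNS = [
    "sequence",
    "modifications",
    "score",
    "q_value",
    "is_decoy",
    "sample",
    "antibody",
    "rt_min",
    "intensity",
    "proteins",
]

_REQUIRED_PSM = ("sequence", "score", "sample")


def format_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{pos}|{name}" for pos, name in mods)


def parse_modifications(text: str, row: int | None = None) -> list[tuple[int, str]]:
    """Parse ``"4|Oxidation;7|Phospho"`` into [(4, "Oxidation"), ...]."""
    if not text or not text.strip():
        return []
    out = []
    for token in text.split(";"):
        parts = token.split("|")
        if len(parts) != 2 or not parts[0].strip():
            where = f" (row {row})" if row is not None else ""
            raise FormatError(f"malformed modification string {token!r}{where}")
        try:
            pos = int(parts[0])
        except ValueError as exc:
            where = f" (row {row})" if row is not None else ""
            raise FormatError(
                f"non-integer modification position in {token!r}{where}"
            ) from exc
        out.append((pos, parts[1].strip()))
    return out


def _remap(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def parse_psm_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    decoy_prefix: str = "DECOY_",
) -> list[PsmRecord]:
    """Read a tab-separated PSM table into records, order-preserving.

    ``dialect`` maps canonical column names to the file's column names.
    When the file has no ``is_decoy`` column the decoy flag is inferred
    from ``decoy_prefix`` on any source-protein accession.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = _remap(df, dialect)
    for col in _REQUIRED_PSM:
        if col not in df.columns:
            raise FormatError(f"PSM table missing required column {col!r}")
    records: list[PsmRecord] = []
    has_decoy_col = "is_decoy" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = dict(zip(df.columns, row))
        proteins = [p for p in d.get("proteins", "").split(";") if p]
        if has_decoy_col:
            is_decoy = d["is_decoy"].strip().lower() in ("1", "true", "yes")
        else:
            is_decoy = any(p.startswith(decoy_prefix) for p in proteins)
        try:
            records.append(
                PsmRecord(
                    sequence=d["sequence"].strip(),
                    modifications=parse_modifications(d.get("modifications", ""), i),
                    score=float(d["score"]),
                    q_value=float(d["q_value"]) if d.get("q_value", "") else None,
                    is_decoy=is_decoy,
                    sample=d["sample"].strip(),
                    antibody=d.get("antibody", "").strip(),
                    rt_min=float(d["rt_min"]) if d.get("rt_min", "") else None,
                    intensity=float(d["intensity"]) if d.get("intensity", "") else None,
                    proteins=proteins,
                )
            )
        except (ValueError, KeyError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"malformed PSM row {i}: {exc}") from exc
    return records


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sequence": r.sequence,
                "modifications": format_modifications(r.modifications),
                "score": repr(r.score),
                "q_value": "" if r.q_value is None else repr(r.q_value),
                "is_decoy": str(r.is_decoy).lower(),
                "sample": r.sample,
                "antibody": r.antibody,
                "rt_min": "" if r.rt_min is None else repr(r.rt_min),
                "intensity": "" if r.intensity is None else repr(r.intensity),
                "proteins": ";".join(r.proteins),
            }
        )
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MGF spectra
# ---------------------------------------------------------------------------


def parse_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file; retention time is converted to minutes."""
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                params = entry["params"]
                if "rtinminutes" in params:
                    rt = float(params["rtinminutes"])
                elif "rtinseconds" in params:
                    rt = float(params["rtinseconds"]) / 60.0
                else:
                    rt = 0.0
                charge = int(params["charge"][0]) if "charge" in params else 1
                peaks = np.column_stack(
                    [entry["m/z array"], entry["intensity array"]]
                )
                spectra.append(
                    Spectrum(
                        title=str(params.get("title", "")),
                        precursor_mz=float(params["pepmass"][0]),
                        precursor_charge=charge,
                        rt_min=rt,
                        peaks=peaks,
                    )
                )
    except FormatError:
        raise
    except Exception as exc:  # pyteomics raises assorted errors on bad input
        raise FormatError(f"malformed MGF {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
                "params": {
                    "title": s.title,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                    "rtinseconds": repr(s.rt_min * 60.0),
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# binding-rank tables
# ---------------------------------------------------------------------------

_RANK_ALIASES = {
    "peptide": ("peptide", "Peptide"),
    "allele": ("allele", "MHC", "HLA", "Allele"),
    "percent_rank": ("percent_rank", "%Rank", "%Rank_EL", "Rank", "rank"),
}


def parse_rank_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[BindingRank]:
    """Read a (peptide, allele, percent-rank) table.

    NetMHCpan-style column names (``%Rank``, ``MHC``) are recognised
    without an explicit dialect. Duplicate (peptide, allele) rows collapse
    to the minimum rank.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = _remap(df, dialect)
    for canon, aliases in _RANK_ALIASES.items():
        if canon not in df.columns:
            hit = next((a for a in aliases if a in df.columns), None)
            if hit is None:
                raise FormatError(f"rank table missing column {canon!r}")
            df = df.rename(columns={hit: canon})
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            rank = float(d["percent_rank"])
        except ValueError as exc:
            raise FormatError(f"non-numeric rank at row {i}") from exc
        if rank < 0:
            raise FormatError(f"negative percent rank at row {i}")
        key = (d["peptide"].strip(), d["allele"].strip())
        if key not in best:
            order.append(key)
            best[key] = rank
        else:
            best[key] = min(best[key], rank)
    return [BindingRank(p, a, best[(p, a)]) for p, a in order]


def write_rank_table(ranks: Iterable[BindingRank], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"peptide": r.peptide, "allele": r.allele, "percent_rank": repr(r.percent_rank)}
            for r in ranks
        ],
        columns=["peptide", "allele", "percent_rank"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation lists, FASTA, TM tables
# ---------------------------------------------------------------------------


def parse_named_list(path: str | Path, name: str, kind: str) -> AnnotationDb:
    """Read a one-member-per-line list; blank lines and ``#`` comments skipped."""
    members = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            members.add(line)
    if not members:
        raise FormatError(f"annotation list {path} is empty")
    return AnnotationDb(name=name, kind=kind, members=frozenset(members))


def write_named_list(db: AnnotationDb, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(db.members)) + "\n")


def _primary_accession(header_id: str) -> str:
    # UniProt convention: sp|P04637|P53_HUMAN -> P04637
    parts = header_id.split("|")
    return parts[1] if len(parts) >= 2 and parts[1] else parts[0]


def parse_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to {primary accession: sequence}."""
    return {
        _primary_accession(rec.id): str(rec.seq)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def parse_tm_table(path: str | Path) -> list[TmPrediction]:
    """Read TMHMM-style summary lines; ``PredHel=N`` is the payload."""
    preds = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        hel = None
        for tok in fields:
            if tok.startswith("PredHel="):
                try:
                    hel = int(tok.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"bad PredHel token at line {i}") from exc
        if hel is None:
            raise FormatError(f"no PredHel= token at line {i}")
        preds.append(TmPrediction(protein=fields[0], pred_hel=hel))
    return preds


def write_tm_table(preds: Iterable[TmPrediction], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{p.protein}\tPredHel={p.pred_hel}\n" for p in preds)
    )


# ---------------------------------------------------------------------------
# LFQ matrices
# ---------------------------------------------------------------------------


def parse_lfq_matrix(
    matrix_path: str | Path,
    groups_path: str | Path,
    log_scale: bool = False,
) -> LfqMatrix:
    """Read a protein-by-sample intensity matrix plus a sample→group map.

    The matrix file has a ``protein`` first column and one column per
    sample; empty cells are missing values. The groups file has columns
    ``sample`` and ``group``.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col="protein")
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in gdf.columns:
            raise FormatError(f"groups file missing column {col!r}")
    groups = dict(zip(gdf["sample"], gdf["group"]))
    return LfqMatrix(df, groups, log_scale=log_scale)


def write_lfq_matrix(
    matrix: LfqMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    out = matrix.data.copy()
    out.index.name = "protein"
    out.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": list(matrix.groups), "group": list(matrix.groups.values())}
    ).to_csv(groups_path, sep="\t", index=False)
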