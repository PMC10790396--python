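"""Readers and writers for the tabular and sequence formats the KiP pipeline touches.

The pipeline consumes Skyline-style transition chromatogram reports (long CSV),
PSM archive tables (TSV), gene-by-sample protein quantification matrices (TSV)
and protein sequence FASTA files.  Everything is validated on the way in:
readers reject rows that violate the domain invariants rather than silently
coercing them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import parser as _parser

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

# Cleave C-terminal to K/R unless the next residue is proline.
TRYPSIN_RULE = r"[KR](?!P)"


class FormatError(ValueError):
    """A file does not have the expected columns or structure."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionTrace:
    """One fragment ion's retention-time/intensity chromatogram.

    The atomic input of PRM quantification: a single transition (product ion)
    of one peptide precursor in one sample, sampled over the scheduled
    retention-time window.  Times are minutes, strictly increasing; intensities
    are finite and non-negative.
    """

    sample_id: str
    peptide: str
    charge: int
    fragment_label: str
    times: np.ndarray
    intensities: np.ndarray
    is_heavy: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if not re.fullmatch(r"[A-Z]{5,40}", self.peptide):
            raise ValidationError(
                f"peptide {self.peptide!r} must be 5-40 upper-case residues"
            )
        if self.charge < 1:
            raise ValidationError(f"charge must be positive, got {self.charge}")
        if t.size != y.size or t.size < 2:
            raise ValidationError(
                f"trace {self.key()} needs >=2 aligned (time, intensity) points"
            )
        if not np.all(np.diff(t) > 0):
            raise ValidationError(f"times not strictly increasing for trace {self.key()}")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValidationError(f"intensities must be finite and >= 0 for {self.key()}")

    def key(self) -> tuple[str, str, int, str, bool]:
        return (self.sample_id, self.peptide, self.charge, self.fragment_label, self.is_heavy)


@dataclass(frozen=True)
class PsmRecord:
    """Per-peptide evidence summarised from a search-engine PSM archive."""

    peptide: str
    gene_ids: frozenset[str]
    psm_count: int
    modified_psm_count: int
    best_ion_score: float
    missed_cleavages: int
    is_subpeptide_of_miscleaved: bool
    shared_with_mouse: bool
    covers_all_isoforms: bool
    q_value: float

    def __post_init__(self) -> None:
        if self.modified_psm_count > self.psm_count:
            raise ValidationError(
                f"peptide {self.peptide}: modified_psm_count "
                f"{self.modified_psm_count} > psm_count {self.psm_count}"
            )
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(f"peptide {self.peptide}: q_value {self.q_value} not in [0,1]")
        if self.psm_count < 0 or self.missed_cleavages < 0:
            raise ValidationError(f"peptide {self.peptide}: negative count field")

    @property
    def modified_fraction(self) -> float:
        return self.modified_psm_count / self.psm_count if self.psm_count else 0.0


@dataclass
class ProteinQuantMatrix:
    """Gene-by-sample abundance matrix on a flagged (linear or log2) scale.

    Missing values (gene not identified in a sample) are NaN and mean
    *absence*, never zero.
    """

    data: pd.DataFrame  # index = genes, columns = samples
    scale: str = "linear"  # "linear" | "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.scale == "linear":
            vals = self.data.to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] < 0):
                raise ValidationError("negative values in a linear-scale matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(self.data.copy(), self.scale)

    def equals(self, other: "ProteinQuantMatrix", rtol: float = 1e-12) -> bool:
        if self.scale != other.scale:
            return False
        if self.genes != other.genes or self.samples != other.samples:
            return False
        a = self.data.to_numpy(dtype=float)
        b = other.data.to_numpy(dtype=float)
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=0.0, equal_nan=True)
        return bool(np.all(close | both_nan))


@dataclass
class FastaDb:
    """Protein sequences keyed by accession, with an accession->gene map."""

    sequences: dict[str, str] = field(default_factory=dict)
    gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, seq in self.sequences.items():
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValidationError(f"{acc}: non-canonical residues {sorted(bad)}")

    def sequence_for_gene(self, gene: str) -> str | None:
        for acc, g in self.gene_map.items():
            if g == gene:
                return self.sequences.get(acc)
        return None


# ---------------------------------------------------------------------------
# Transition reports
# ---------------------------------------------------------------------------

#: Default column dialect mirroring common Skyline long-format export headers.
DEFAULT_TRANSITION_DIALECT: dict[str, str] = {
    "sample": "Replicate",
    "peptide": "Peptide Sequence",
    "charge": "Precursor Charge",
    "fragment": "Fragment Ion",
    "time": "Retention Time",
    "intensity": "Intensity",
    "heavy": "Isotope Label Type",
}


def read_transition_report(
    path, dialect: Mapping[str, str] | None = None
) -> list[TransitionTrace]:
    """Read a long-format transition chromatogram CSV into traces.

    One row per (trace, time point); rows are grouped into one
    :class:`TransitionTrace` per (sample, peptide, charge, fragment, label)
    and sorted by retention time.  ``dialect`` maps the logical column names
    (sample, peptide, charge, fragment, time, intensity, heavy) to the
    headers actually present in the file.
    """
    cols = dict(DEFAULT_TRANSITION_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    traces: list[TransitionTrace] = []
    keycols = [cols["sample"], cols["peptide"], cols["charge"], cols["fragment"], cols["heavy"]]
    for (sample, pep, charge, frag, label), grp in df.groupby(keycols, sort=True):
        grp = grp.sort_values(cols["time"])
        is_heavy = str(label).strip().lower() in ("heavy", "true", "1")
        t = grp[cols["time"]].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"non-monotone retention times for trace "
                f"({sample}, {pep}, {frag}, {'heavy' if is_heavy else 'light'})"
            )
        traces.append(
            TransitionTrace(
                sample_id=str(sample),
                peptide=str(pep),
                charge=int(charge),
                fragment_label=str(frag),
                times=t,
                intensities=grp[cols["intensity"]].to_numpy(dtype=float),
                is_heavy=is_heavy,
            )
        )
    return traces


def write_transition_report(
    traces: Iterable[TransitionTrace], path, dialect: Mapping[str, str] | None = None
) -> None:
    """Write traces back to the long CSV format ``read_transition_report`` reads."""
    cols = dict(DEFAULT_TRANSITION_DIALECT)
    if dialect:
        cols.update(dialect)
    rows = []
    for tr in traces:
        for t, y in zip(tr.times, tr.intensities):
            rows.append(
                {
                    cols["sample"]: tr.sample_id,
                    cols["peptide"]: tr.peptide,
                    cols["charge"]: tr.charge,
                    cols["fragment"]: tr.fragment_label,
                    cols["time"]: t,
                    cols["intensity"]: y,
                    cols["heavy"]: "heavy" if tr.is_heavy else "light",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PSM archive tables
# ---------------------------------------------------------------------------

_PSM_COLUMNS = [
    "peptide",
    "gene_ids",
    "psm_count",
    "modified_psm_count",
    "best_ion_score",
    "missed_cleavages",
    "is_subpeptide_of_miscleaved",
    "shared_with_mouse",
    "covers_all_isoforms",
    "q_value",
]


def read_psm_table(path, fdr: float = 0.05) -> list[PsmRecord]:
    """Read a PSM archive TSV, dropping records above the FDR cut-off.

    Records with q_value > ``fdr`` (default 5% FDR) are dropped and the
    number dropped is logged.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty PSM table", path)
        return []
    records: list[PsmRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        if float(row["q_value"]) > fdr:
            n_dropped += 1
            continue
        genes = frozenset(str(row["gene_ids"]).split(";")) if str(row["gene_ids"]) else frozenset()
        records.append(
            PsmRecord(
                peptide=str(row["peptide"]),
                gene_ids=genes,
                psm_count=int(row["psm_count"]),
                modified_psm_count=int(row["modified_psm_count"]),
                best_ion_score=float(row["best_ion_score"]),
                missed_cleavages=int(row["missed_cleavages"]),
                is_subpeptide_of_miscleaved=bool(row["is_subpeptide_of_miscleaved"]),
                shared_with_mouse=bool(row["shared_with_mouse"]),
                covers_all_isoforms=bool(row["covers_all_isoforms"]),
                q_value=float(row["q_value"]),
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d record(s) above %.0f%% FDR", path, n_dropped, fdr * 100)
    return records


def write_psm_table(records: Iterable[PsmRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "peptide": r.peptide,
                "gene_ids": ";".join(sorted(r.gene_ids)),
                "psm_count": r.psm_count,
                "modified_psm_count": r.modified_psm_count,
                "best_ion_score": r.best_ion_score,
                "missed_cleavages": r.missed_cleavages,
                "is_subpeptide_of_miscleaved": r.is_subpeptide_of_miscleaved,
                "shared_with_mouse": r.shared_with_mouse,
                "covers_all_isoforms": r.covers_all_isoforms,
                "q_value": r.q_value,
            }
        )
    pd.DataFrame(rows, columns=_PSM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# In-silico digestion (iBAQ denominator)
# ---------------------------------------------------------------------------


def tryptic_digest(
    sequence: str, min_len: int = 7, max_len: int = 30, *, return_peptides: bool = False
):
    """Count theoretical fully-tryptic peptides of a protein sequence.

    Cleaves C-terminal to K/R except before proline, with zero missed
    cleavages, and counts distinct peptides with ``min_len <= length <=
    max_len``.  The default 7-30 residue bounds are the usual convention for
    iBAQ denominators (peptides a mass spectrometer plausibly observes).
    """
    if not sequence:
        raise ValueError("empty sequence")
    peptides = _parser.cleave(sequence.upper(), TRYPSIN_RULE, missed_cleavages=0)
    kept = {p for p in peptides if min_len <= len(p) <= max_len}
    if return_peptides:
        return kept
    return len(kept)


# ---------------------------------------------------------------------------
# Quant matrices
# ---------------------------------------------------------------------------


def write_quant_matrix(matrix: ProteinQuantMatrix, path) -> None:
    """Write a quant matrix as TSV: genes as rows, samples as columns.

    The scale is recorded in a leading ``# scale=`` comment line.  Missing
    values are written as empty cells (absence, not zero); the round trip
    through :func:`read_quant_matrix` reproduces the matrix.
    """
    # __post_init__ enforces label uniqueness; revalidate in case data mutated
    ProteinQuantMatrix(matrix.data, matrix.scale)
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene", na_rep="")


def read_quant_matrix(path) -> ProteinQuantMatrix:
    """Read back a TSV written by :func:`write_quant_matrix`."""
    scale = "linear"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"scale=(\w+)", first)
            if m:
                scale = m.group(1)
            df = pd.read_csv(fh, sep="\t", index_col="gene")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="gene")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ProteinQuantMatrix(df.astype(float), scale)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_GN_RE = re.compile(r"\bGN=(\S+)")


def read_fasta(path) -> FastaDb:
    """Read protein sequences; gene symbols from UniProt ``GN=`` tags or headers.

    Headers of the form ``>sp|ACC|NAME GN=GENE`` map ACC -> GENE; bare
    ``>NAME`` headers use the first token as both accession and gene.
    """
    sequences: dict[str, str] = {}
    gene_map: dict[str, str] = {}
    for header, seq in _fasta.read(str(path)):
        parts = header.split("|")
        acc = parts[1] if len(parts) >= 2 else header.split()[0]
        m = _GN_RE.search(header)
        gene = m.group(1) if m else acc
        sequences[acc] = seq.upper()
        gene_map[acc] = gene
    return FastaDb(sequences=sequences, gene_map=gene_map)


def write_fasta(db: FastaDb, path) -> None:
    with open(path, "w") as fh:
        for acc, seq in db.sequences.items():
            gene = db.gene_map.get(acc, acc)
            fh.write(f">sp|{acc}|{acc}_SYN GN={gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
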