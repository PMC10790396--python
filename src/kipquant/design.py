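"""PRM peptide-panel design: candidate filtering and response-curve evaluation.

Candidates per gene come from a PSM archive.  Peptides are excluded for hard
defects (poor ion score, frequent modification, missed cleavage, being a
subpeptide of a miscleaved form, shared sequence across gene products),
deprioritised for soft ones (shared with mouse, not covering all isoforms),
ranked by PSM count, shortlisted, then judged on dilution response curves:
a panel peptide must show a proportional (through-origin) response to input
amount, a narrow symmetrical peak, and no non-specific interfering peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import PsmRecord, TransitionTrace
from .quant import PeakBoundary, detect_boundaries, integrate_area

# rule codes
LOW_SCORE = "low_score"
MODIFIED_FRACTION = "modified_fraction"
MISSED_CLEAVAGE = "missed_cleavage"
SUBPEPTIDE = "subpeptide_of_miscleaved"
SHARED_GENE = "shared_gene"
MOUSE_SHARED = "mouse_shared"
NOT_ALL_ISOFORMS = "not_all_isoforms"


@dataclass
class SelectionCriteria:
    """Thresholds and sizes for candidate selection.

    Hard-exclusion thresholds quantify the archive rules (ion score < 20,
    >10% modified PSMs, missed cleavage); soft rules only deprioritise.
    """

    min_ion_score: float = 20.0
    max_modified_fraction: float = 0.10
    allow_missed_cleavage: bool = False
    exclude_subpeptides_of_miscleaved: bool = True
    exclude_shared_genes: bool = True
    deprioritize_mouse_shared: bool = True
    shortlist_size: tuple[int, int] = (3, 6)
    final_size: tuple[int, int] = (2, 4)
    min_linearity_r2: float = 0.95
    symmetry_bounds: tuple[float, float] = (0.67, 1.5)
    interference_frac: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_modified_fraction <= 1.0:
            raise ValueError("max_modified_fraction must be in [0,1]")
        for rng in (self.shortlist_size, self.final_size):
            if rng[0] < 1 or rng[1] < rng[0]:
                raise ValueError(f"empty size range {rng}")


@dataclass
class CandidateVerdict:
    peptide: str
    status: str  # excluded | deprioritized | shortlisted | final
    reasons: list[str] = field(default_factory=list)
    rank: int = 0
    psm_count: int = 0

    def __post_init__(self) -> None:
        if self.status == "excluded" and not self.reasons:
            raise ValueError(f"{self.peptide}: excluded verdict needs >= 1 reason")


@dataclass
class ResponseAssessment:
    """Dilution response-curve evaluation for one peptide."""

    peptide: str
    linearity_r2: float
    symmetry: float  # left/right half-area ratio at apex (nan if no traces)
    interference_flag: bool
    passed: bool


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------


def filter_candidates(
    records: Sequence[PsmRecord],
    criteria: SelectionCriteria | None = None,
) -> list[CandidateVerdict]:
    """Apply exclusion/deprioritisation rules and shortlist the best candidates.

    All rules are applied to every record and reasons accumulate, so the
    exclusion status is independent of rule ordering.  Survivors are ranked
    by PSM count descending (ties on peptide); deprioritised peptides fill
    shortlist slots only when fewer non-deprioritised candidates exist than
    the shortlist can hold.
    """
    crit = criteria or SelectionCriteria()
    if not records:
        return []

    verdicts: list[CandidateVerdict] = []
    for rec in records:
        reasons: list[str] = []
        if rec.best_ion_score < crit.min_ion_score:
            reasons.append(LOW_SCORE)
        if rec.modified_fraction > crit.max_modified_fraction:
            reasons.append(MODIFIED_FRACTION)
        if rec.missed_cleavages > 0 and not crit.allow_missed_cleavage:
            reasons.append(MISSED_CLEAVAGE)
        if rec.is_subpeptide_of_miscleaved and crit.exclude_subpeptides_of_miscleaved:
            reasons.append(SUBPEPTIDE)
        if len(rec.gene_ids) > 1 and crit.exclude_shared_genes:
            reasons.append(SHARED_GENE)

        soft: list[str] = []
        if rec.shared_with_mouse and crit.deprioritize_mouse_shared:
            soft.append(MOUSE_SHARED)
        if not rec.covers_all_isoforms:
            soft.append(NOT_ALL_ISOFORMS)

        if reasons:
            status = "excluded"
        elif soft:
            status = "deprioritized"
        else:
            status = "viable"
        verdicts.append(
            CandidateVerdict(
                peptide=rec.peptide, status=status, reasons=reasons + soft,
                psm_count=rec.psm_count,
            )
        )

    order = sorted(
        (v for v in verdicts if v.status != "excluded"),
        key=lambda v: (-v.psm_count, v.peptide),
    )
    for i, v in enumerate(order, start=1):
        v.rank = i

    capacity = crit.shortlist_size[1]
    primary = [v for v in order if v.status == "viable"]
    deprior = [v for v in order if v.status == "deprioritized"]
    shortlist = primary[:capacity]
    if len(shortlist) < capacity:
        shortlist += deprior[: capacity - len(shortlist)]
    for v in shortlist:
        v.status = "shortlisted"
    # viable candidates that did not rank high enough keep status "viable"
    return verdicts


# ---------------------------------------------------------------------------
# Response-curve evaluation
# ---------------------------------------------------------------------------


def evaluate_response(
    peptide: str,
    inputs_ug: Sequence[float],
    areas: Sequence[float],
    traces: Sequence[TransitionTrace] | None = None,
    criteria: SelectionCriteria | None = None,
) -> ResponseAssessment:
    """Judge a candidate peptide on its dilution response and peak shape.

    ``linearity_r2`` is the R-squared of the zero-intercept fit of area
    against input amount (computed against the mean-model total sum of
    squares, so saturating curves score well below 1).  When representative
    traces are supplied, peak symmetry (left/right half-area ratio at the
    apex) and interference (any in-window local maximum outside the
    integration boundary above 20% of the apex) are evaluated too.
    """
    crit = criteria or SelectionCriteria()
    x = np.asarray(inputs_ug, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 matched (input, area) levels")

    slope = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)

    symmetry = float("nan")
    symmetric = True
    interference = False
    if traces:
        boundary = detect_boundaries(traces, boundary_frac=DEFAULT_BOUNDARY_FRAC_FOR_SHAPE)
        if boundary is None:
            symmetric = False
        else:
            total = np.sum([tr.intensities for tr in traces], axis=0)
            t = traces[0].times
            apex_idx = int(np.argmax(total))
            apex_rt = float(t[apex_idx])
            left = integrate_area(
                _summed_trace(traces), PeakBoundary(boundary.start_rt, max(apex_rt, boundary.start_rt + 1e-9))
            )
            right = integrate_area(
                _summed_trace(traces), PeakBoundary(min(apex_rt, boundary.end_rt - 1e-9), boundary.end_rt)
            )
            symmetry = left / right if right > 0 else float("inf")
            symmetric = crit.symmetry_bounds[0] <= symmetry <= crit.symmetry_bounds[1]

            peaks, _ = find_peaks(total, height=crit.interference_frac * total[apex_idx])
            for idx in peaks:
                if not boundary.start_rt <= t[idx] <= boundary.end_rt:
                    interference = True
                    break

    passed = (r2 >= crit.min_linearity_r2) and symmetric and not interference
    return ResponseAssessment(
        peptide=peptide, linearity_r2=r2, symmetry=symmetry,
        interference_flag=interference, passed=passed,
    )


DEFAULT_BOUNDARY_FRAC_FOR_SHAPE = 0.05


def _summed_trace(traces: Sequence[TransitionTrace]) -> TransitionTrace:
    total = np.sum([tr.intensities for tr in traces], axis=0)
    first = traces[0]
    return TransitionTrace(
        sample_id=first.sample_id, peptide=first.peptide, charge=first.charge,
        fragment_label="sum", times=first.times, intensities=total,
        is_heavy=first.is_heavy,
    )


# ---------------------------------------------------------------------------
# Final panel
# ---------------------------------------------------------------------------


def final_panel(
    verdicts_by_gene: Mapping[str, Sequence[CandidateVerdict]],
    assessments: Mapping[str, ResponseAssessment],
    criteria: SelectionCriteria | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pick the final 2-4 peptides per gene from shortlisted, passing candidates.

    Passing peptides are ranked by (linearity R2 desc, PSM count desc); the
    top ``final_size`` upper bound are retained.  Genes with zero passing
    peptides are returned in the shortfall list and omitted from the panel.
    """
    crit = criteria or SelectionCriteria()
    rows = []
    shortfall: list[str] = []
    for gene, verdicts in verdicts_by_gene.items():
        passing = []
        for v in verdicts:
            if v.status != "shortlisted":
                continue
            a = assessments.get(v.peptide)
            if a is not None and a.passed:
                passing.append((v, a))
        if not passing:
            shortfall.append(gene)
            continue
        passing.sort(key=lambda va: (-va[1].linearity_r2, -va[0].psm_count, va[0].peptide))
        for rank, (v, a) in enumerate(passing[: crit.final_size[1]], start=1):
            rows.append(
                {
                    "gene": gene,
                    "peptide": v.peptide,
                    "rank": rank,
                    "psm_count": v.psm_count,
                    "r2": a.linearity_r2,
                    "reasons": ";".join(v.reasons),
                }
            )
    panel = pd.DataFrame(rows, columns=["gene", "peptide", "rank", "psm_count", "r2", "reasons"])
    return panel, sorted(shortfall)
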