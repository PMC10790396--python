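"""Internal-standard-triggered PRM (IS-PRM / SureQuant-style) acquisition logic.

A spiked heavy isotope-labelled peptide is watched for in survey scans; when
its precursor matches the inclusion list within a tight ppm tolerance, a heavy
MS2 scan is taken and pseudo-spectrally matched against the peptide's defined
product-ion list.  Only when at least four listed product ions are found does
the instrument trigger a quantitative MS2 scan of the endogenous (light)
peptide at a fixed mass offset.  This module replays that event loop
deterministically over a recorded spectra stream and TIC-normalises the
resulting light-peptide quantities.

The scheduler is event-driven over the supplied survey scans; instrument
internals (AGC, injection time, resolution) are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: SILAC-style label masses (Da): 13C6,15N2-lysine and 13C6,15N4-arginine.
LABEL_MASS_K = 8.014199
LABEL_MASS_R = 10.008269

DEFAULT_PRECURSOR_TOL_PPM = 3.0
DEFAULT_PRODUCT_TOL_PPM = 10.0
MIN_PRODUCT_MATCHES = 4


@dataclass(frozen=True)
class InclusionEntry:
    """One heavy internal-standard target on the inclusion list.

    ``mass_offset_mz`` is the (negative) m/z shift from the heavy standard to
    the endogenous light peptide: light m/z = heavy m/z + mass_offset_mz.
    """

    peptide: str
    heavy_mz: float
    charge: int
    product_ion_mzs: tuple[float, ...]
    mass_offset_mz: float
    rt_window: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if len(self.product_ion_mzs) < MIN_PRODUCT_MATCHES:
            raise ValueError(
                f"{self.peptide}: inclusion entry needs >= {MIN_PRODUCT_MATCHES} "
                "product ions or the trigger rule can never fire"
            )
        if self.mass_offset_mz >= 0:
            raise ValueError(f"{self.peptide}: mass_offset_mz must be negative (heavy > light)")

    def light_product_mzs(self) -> tuple[float, ...]:
        # C-terminal label: every singly charged y ion shifts by the full
        # label mass = -mass_offset_mz * precursor charge.
        shift = self.mass_offset_mz * self.charge
        return tuple(mz + shift for mz in self.product_ion_mzs)


@dataclass(frozen=True)
class Precursor:
    """A precursor ion observed in a survey scan, with the product spectra an
    MS2 at its m/z (heavy) or at the offset m/z (light) would record."""

    mz: float
    intensity: float
    heavy_products: tuple[tuple[float, float], ...] = ()  # (mz, intensity)
    light_products: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class SurveyScan:
    time: float  # minutes
    precursors: tuple[Precursor, ...] = ()


@dataclass
class SpectraStream:
    """Time-ordered survey scans plus per-sample total ion current."""

    scans: list[SurveyScan] = field(default_factory=list)
    tic: float = 1.0


@dataclass(frozen=True)
class ScanEvent:
    time: float
    kind: str  # "survey" | "heavy_ms2" | "light_ms2"
    peptide: str | None = None
    matched_product_count: int = 0
    triggered: bool = False
    light_intensity: float = 0.0


@dataclass
class AcquisitionLog:
    events: list[ScanEvent] = field(default_factory=list)

    def validate(self) -> None:
        """Assert that no light scan occurs without a preceding satisfied trigger."""
        armed: set[str] = set()
        for ev in self.events:
            if ev.kind == "heavy_ms2" and ev.triggered:
                armed.add(ev.peptide)
            elif ev.kind == "light_ms2":
                if ev.peptide not in armed:
                    raise AssertionError(
                        f"light MS2 for {ev.peptide} at t={ev.time} without satisfied trigger"
                    )
                armed.discard(ev.peptide)

    def light_events(self) -> list[ScanEvent]:
        return [e for e in self.events if e.kind == "light_ms2"]


# ---------------------------------------------------------------------------
# Matching primitives
# ---------------------------------------------------------------------------


def ppm_match(observed_mz: float, target_mz: float, tol_ppm: float) -> bool:
    """True iff |observed - target| / target * 1e6 <= tol_ppm."""
    if observed_mz <= 0 or target_mz <= 0:
        raise ValueError("m/z values must be positive")
    return abs(observed_mz - target_mz) / target_mz * 1e6 <= tol_ppm


def survey_select(
    scan: SurveyScan,
    inclusion: Sequence[InclusionEntry],
    tol_ppm: float = 10.0,
    intensity_min: float = 1e5,
    max_ions: int = 70,
) -> list[tuple[Precursor, InclusionEntry]]:
    """Pick precursors to isolate from a survey scan.

    Precursors matching any inclusion entry within ``tol_ppm`` with intensity
    at or above ``intensity_min``, capped at ``max_ions`` by descending
    intensity.
    """
    hits: list[tuple[Precursor, InclusionEntry]] = []
    for prec in scan.precursors:
        if prec.intensity < intensity_min:
            continue
        for entry in inclusion:
            if entry.rt_window[0] <= scan.time <= entry.rt_window[1] and ppm_match(
                prec.mz, entry.heavy_mz, tol_ppm
            ):
                hits.append((prec, entry))
                break
    hits.sort(key=lambda pe: -pe[0].intensity)
    return hits[:max_ions]


def pseudo_spectral_match(
    heavy_ms2: Iterable[tuple[float, float]],
    entry: InclusionEntry,
    tol_ppm: float = DEFAULT_PRODUCT_TOL_PPM,
) -> tuple[int, bool]:
    """Count listed product ions present in a heavy MS2 scan; trigger iff >= 4.

    Each listed product ion counts at most once even if several peaks fall
    within tolerance.
    """
    peaks = [mz for mz, _ in heavy_ms2]
    matched = 0
    for target in entry.product_ion_mzs:
        if any(ppm_match(mz, target, tol_ppm) for mz in peaks):
            matched += 1
    return matched, matched >= MIN_PRODUCT_MATCHES


# ---------------------------------------------------------------------------
# Acquisition loop
# ---------------------------------------------------------------------------


def run_acquisition(
    stream: SpectraStream,
    inclusion: Sequence[InclusionEntry],
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    product_tol_ppm: float = DEFAULT_PRODUCT_TOL_PPM,
    intensity_min: float = 1e5,
    max_ions: int = 70,
    once_per_elution: bool = True,
) -> tuple[AcquisitionLog, dict[str, float]]:
    """Replay the IS-PRM event loop over a recorded stream.

    survey -> heavy precursor match (tight ppm) -> heavy MS2 ->
    pseudo-spectral match -> (if >= 4 listed ions) light MS2 at
    heavy m/z + mass offset.  The light quantity for a peptide is the summed
    intensity of its matched light product ions over all triggered light
    scans.  With ``once_per_elution`` (default), a target that has fired is
    not re-isolated until its precursor drops out of the survey selection,
    so each contiguous elution yields one quantitative light scan.
    Returns the full decision log and per-peptide light quantities.
    """
    times = [s.time for s in stream.scans]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("spectra stream is not time-ordered")

    log = AcquisitionLog()
    quantities: dict[str, float] = {e.peptide: 0.0 for e in inclusion}
    suppressed: set[str] = set()

    for scan in stream.scans:
        log.events.append(ScanEvent(time=scan.time, kind="survey"))
        selected = survey_select(
            scan, inclusion, tol_ppm=precursor_tol_ppm,
            intensity_min=intensity_min, max_ions=max_ions,
        )
        present = {entry.peptide for _, entry in selected}
        suppressed &= present  # elution ended -> re-arm
        for prec, entry in selected:
            if entry.peptide in suppressed:
                continue
            matched, triggered = pseudo_spectral_match(
                prec.heavy_products, entry, tol_ppm=product_tol_ppm
            )
            log.events.append(
                ScanEvent(
                    time=scan.time,
                    kind="heavy_ms2",
                    peptide=entry.peptide,
                    matched_product_count=matched,
                    triggered=triggered,
                )
            )
            if not triggered:
                continue
            light_targets = entry.light_product_mzs()
            light_sum = 0.0
            n_light = 0
            for mz, inten in prec.light_products:
                if any(ppm_match(mz, t, product_tol_ppm) for t in light_targets):
                    light_sum += inten
                    n_light += 1
            log.events.append(
                ScanEvent(
                    time=scan.time,
                    kind="light_ms2",
                    peptide=entry.peptide,
                    matched_product_count=n_light,
                    triggered=True,
                    light_intensity=light_sum,
                )
            )
            quantities[entry.peptide] += light_sum
            if once_per_elution:
                suppressed.add(entry.peptide)

    log.validate()
    return log, quantities


def tic_normalize(
    light_quantities: dict[str, dict[str, float]] | "pd.DataFrame",
    tic: dict[str, float],
    rescale_to_mean: bool = False,
) -> "pd.DataFrame":
    """Normalise per-sample quantities to total ion current.

    ``light_quantities`` maps sample -> {peptide: quantity} (or an equivalent
    peptides x samples DataFrame); each sample's values are divided by its
    TIC, a proxy for total peptide input.  Plain division keeps the transform
    invariant to a joint rescaling of intensities and TIC; set
    ``rescale_to_mean`` to multiply back by the mean TIC when magnitudes
    comparable to raw intensities are wanted (gives up that invariance).
    """
    import pandas as pd

    if not isinstance(light_quantities, pd.DataFrame):
        df = pd.DataFrame(light_quantities)
    else:
        df = light_quantities.copy()
    missing = [s for s in df.columns if s not in tic]
    if missing:
        raise ValueError(f"no TIC for sample(s) {missing}")
    tics = np.array([float(tic[s]) for s in df.columns])
    if np.any(tics <= 0):
        raise ValueError("TIC must be > 0 for every sample")
    out = df / tics
    if rescale_to_mean:
        out = out * tics.mean()
    return out
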