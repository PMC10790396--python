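"""Seeded generators for every input the KiP pipeline consumes.

Each generator is a pure function of its spec (same seed, same output) and
returns the planted ground truth alongside the data, so downstream recovery
tests never need to peek at generator internals.  The generators emulate:

* Gaussian transition chromatograms with additive noise and optional
  interference peaks, plus heavy/light twin traces at the SILAC label offset;
* dilution series with linear and saturating (Michaelis-like) kinases;
* serial-depletion experiments with a constant per-round binding fraction
  (geometric capture decay);
* two-subtype cohorts with planted log2 fold changes, multiplicative
  lognormal technical noise at a stated CV, technical replicates and
  missing-completely-at-random dropout;
* IS-PRM spectra streams with jittered heavy precursors, complete product-ion
  sets for true targets, crippled (<=3 ion) sets for decoys, and light twins
  only for endogenous-present targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _mass

from .io import FastaDb, ProteinQuantMatrix, PsmRecord, TransitionTrace
from .surequant import (
    LABEL_MASS_K,
    LABEL_MASS_R,
    InclusionEntry,
    Precursor,
    SpectraStream,
    SurveyScan,
)

_AMINO = "ACDEFGHILMNPQSTVWY"  # K/R reserved for the tryptic C-terminus


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class ChromSpec:
    """Design of a synthetic transition-chromatogram experiment."""

    n_peptides: int = 1
    transitions_per_peptide: int = 8
    apex_rt: Sequence[float] | None = None  # minutes, one per peptide
    peak_sigma: float = 0.05  # minutes
    sampling_interval: float = 0.01  # minutes
    rt_window: float = 4.0  # scheduled window width, minutes
    true_transition_areas: np.ndarray | None = None  # (n_peptides, transitions)
    noise_sd: float = 0.0
    interference: list[tuple] | None = None  # (peptide_idx, offset_min, amplitude[, transition_idx])
    heavy_pairs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_interval >= self.peak_sigma:
            raise ValueError(
                f"sampling_interval {self.sampling_interval} >= peak_sigma "
                f"{self.peak_sigma}: peaks would be undersampled"
            )
        if self.rt_window < 8 * self.peak_sigma:
            raise ValueError("rt_window must contain apex +/- 4 sigma")
        if self.true_transition_areas is not None and np.any(
            np.asarray(self.true_transition_areas) <= 0
        ):
            raise ValueError("true areas must be > 0")


@dataclass
class CohortSpec:
    """Design of a two-subtype cohort with planted differential kinases."""

    n_basal: int = 8
    n_luminal: int = 8
    n_kinases: int = 100
    n_differential: int = 36
    log2_effect: float = 2.0
    n_up_basal: int | None = None  # default: half of n_differential (rounded up)
    abundance_meanlog: float = 14.0
    abundance_sdlog: float = 2.0
    technical_cv: float = 0.10
    technical_replicates: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_differential > self.n_kinases:
            raise ValueError("n_differential exceeds n_kinases")
        if self.technical_cv < 0:
            raise ValueError("technical_cv must be >= 0")
        if self.n_basal < 2 or self.n_luminal < 2:
            raise ValueError("need >= 2 samples per subtype for downstream t-tests")


@dataclass
class DepletionSpec:
    """Serial-depletion design: rebinding the supernatant of a pulldown.

    A constant fraction ``binding_fraction`` of each kinase binds in every
    round, so the bound amount decays geometrically across rounds.  A kinase
    is "identified" in a round when its bound abundance reaches
    ``detection_floor``.
    """

    n_kinases: int = 300
    binding_fraction: float = 0.7
    n_rounds: int = 3  # original + two depletions
    detection_floor: float = 7e4
    abundance_meanlog: float = 14.0
    abundance_sdlog: float = 2.5
    noise_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.binding_fraction < 1.0:
            raise ValueError("binding_fraction must be in (0, 1)")
        if self.n_rounds < 1 or self.n_kinases < 1:
            raise ValueError("n_rounds and n_kinases must be >= 1")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def random_tryptic_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 15) -> str:
    """A random fully-tryptic peptide: internal residues without K/R, C-terminal K or R."""
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(list(_AMINO), size=n - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def gen_fasta(genes: Sequence[str], seed: int = 0, min_len: int = 150, max_len: int = 450) -> FastaDb:
    """Random protein sequences, one accession per gene (for digest/iBAQ tests)."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    sequences, gene_map = {}, {}
    for i, gene in enumerate(genes):
        n = int(rng.integers(min_len, max_len + 1))
        acc = f"SYN{i:05d}"
        sequences[acc] = "".join(rng.choice(alphabet, size=n))
        gene_map[acc] = gene
    return FastaDb(sequences=sequences, gene_map=gene_map)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------


def _gaussian(t: np.ndarray, apex: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


def gen_chromatograms(spec: ChromSpec) -> tuple[list[TransitionTrace], pd.DataFrame]:
    """Generate Gaussian transition traces with planted areas.

    Each trace is a Gaussian centred on the peptide apex whose *analytic*
    area equals its planted true area, plus i.i.d. additive noise (clipped at
    zero).  Interference entries add an extra Gaussian peak offset in RT.
    When ``heavy_pairs`` is set, an identical heavy-labelled twin trace is
    emitted for every transition.  Returns the traces and a truth table of
    planted areas.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.apex_rt is not None:
        apexes = np.asarray(spec.apex_rt, dtype=float)
        if apexes.size != spec.n_peptides:
            raise ValueError("apex_rt length must equal n_peptides")
    else:
        apexes = rng.uniform(5.0, 60.0, size=spec.n_peptides)

    if spec.true_transition_areas is not None:
        areas = np.asarray(spec.true_transition_areas, dtype=float).reshape(
            spec.n_peptides, spec.transitions_per_peptide
        )
    else:
        areas = np.exp(rng.normal(math.log(1e5), 0.8,
                                  size=(spec.n_peptides, spec.transitions_per_peptide)))

    interference = spec.interference or []
    traces: list[TransitionTrace] = []
    truth_rows = []
    for p in range(spec.n_peptides):
        # deterministic sequence of valid residues, unique per peptide index
        peptide = "SYNTH" + "".join("ACDEFGHILMN"[int(d)] for d in f"{p:04d}") + "K"
        half = spec.rt_window / 2.0
        t = np.arange(apexes[p] - half, apexes[p] + half + 1e-12, spec.sampling_interval)
        for j in range(spec.transitions_per_peptide):
            y = _gaussian(t, apexes[p], spec.peak_sigma, areas[p, j])
            for entry in interference:
                pi, offset, amplitude = entry[0], entry[1], entry[2]
                which = entry[3] if len(entry) > 3 else None
                if pi == p and (which is None or which == j):
                    y = y + amplitude * np.exp(
                        -0.5 * ((t - (apexes[p] + offset)) / spec.peak_sigma) ** 2
                    )
            if spec.noise_sd > 0:
                y = y + rng.normal(0.0, spec.noise_sd, size=t.size)
            y = np.clip(y, 0.0, None)
            frag = f"y{j + 3}+"
            traces.append(
                TransitionTrace(
                    sample_id="sim",
                    peptide=peptide,
                    charge=2,
                    fragment_label=frag,
                    times=t,
                    intensities=y,
                    is_heavy=False,
                )
            )
            if spec.heavy_pairs:
                traces.append(
                    TransitionTrace(
                        sample_id="sim",
                        peptide=peptide,
                        charge=2,
                        fragment_label=frag,
                        times=t,
                        intensities=y.copy(),
                        is_heavy=True,
                    )
                )
            truth_rows.append(
                {"peptide": peptide, "fragment": frag, "true_area": areas[p, j],
                 "apex_rt": apexes[p]}
            )
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------


def gen_dilution_series(
    inputs_ug: Sequence[float],
    n_genes: int = 20,
    saturating_genes: Mapping[str, float] | None = None,
    coeff_meanlog: float = 10.0,
    coeff_sdlog: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[ProteinQuantMatrix, pd.DataFrame]:
    """Gene-level areas across a lysate dilution series, with planted truth.

    Linear genes scale proportionally to input; saturating genes (mapping
    gene -> half-saturation constant K, in ug) follow area ~ input/(input+K),
    emulating the saturation seen for highly abundant kinases such as CDK4
    and PRKDC.  Columns are input amounts as strings.
    """
    inputs = [float(x) for x in inputs_ug]
    if any(x <= 0 for x in inputs):
        raise ValueError("input amounts must be positive")
    rng = np.random.default_rng(seed)
    saturating = dict(saturating_genes or {})
    genes = [f"KIN{i:04d}" for i in range(n_genes)]
    for g in saturating:
        if g not in genes:
            genes.append(g)
    coeffs = np.exp(rng.normal(coeff_meanlog, coeff_sdlog, size=len(genes)))

    values = np.empty((len(genes), len(inputs)))
    truth_rows = []
    for i, g in enumerate(genes):
        if g in saturating:
            K = float(saturating[g])
            resp = np.array([x / (x + K) for x in inputs])
            kind = "saturating"
        else:
            K = np.nan
            resp = np.array(inputs)
            kind = "linear"
        values[i] = coeffs[i] * resp
        truth_rows.append({"gene": g, "kind": kind, "coefficient": coeffs[i], "K": K})
    values = values * _lognormal_factor(rng, noise_cv, values.shape)

    df = pd.DataFrame(values, index=genes, columns=[str(x) for x in inputs])
    return ProteinQuantMatrix(df, "linear"), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Serial depletion
# ---------------------------------------------------------------------------


def gen_depletion_series(spec: DepletionSpec) -> tuple[ProteinQuantMatrix, pd.DataFrame]:
    """Bound-kinase abundance across serial depletion rounds (rounds as samples).

    Round-k bound abundance of a kinase with total amount A is
    ``A * f * (1-f)**k`` for binding fraction f; values below the detection
    floor are missing ("not identified").
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"KIN{i:04d}" for i in range(spec.n_kinases)]
    A = np.exp(rng.normal(spec.abundance_meanlog, spec.abundance_sdlog, size=spec.n_kinases))
    f = spec.binding_fraction

    cols = {}
    for k in range(spec.n_rounds):
        bound = A * f * (1.0 - f) ** k
        bound = bound * _lognormal_factor(rng, spec.noise_cv, bound.shape)
        bound[bound < spec.detection_floor] = np.nan
        cols[f"round{k}"] = bound
    df = pd.DataFrame(cols, index=genes)
    truth = pd.DataFrame({"gene": genes, "total_abundance": A})
    return ProteinQuantMatrix(df, "linear"), truth


# ---------------------------------------------------------------------------
# Two-subtype cohort
# ---------------------------------------------------------------------------


def gen_cohort_matrix(
    spec: CohortSpec,
) -> tuple[ProteinQuantMatrix, dict[str, str], pd.DataFrame]:
    """Linear-scale kinase matrix for a basal-vs-luminal cohort with planted truth.

    Within a subtype, a gene's biological value is constant across samples;
    replicate observations are that value times mean-one lognormal technical
    noise at the stated CV.  Differential genes carry the planted log2 effect
    on the elevated subtype.  Returns (matrix with one column per technical
    replicate, replicate map column -> biological sample, truth table).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"KIN{i:04d}" for i in range(spec.n_kinases)]
    base = np.exp(rng.normal(spec.abundance_meanlog, spec.abundance_sdlog, size=spec.n_kinases))

    diff_idx = rng.choice(spec.n_kinases, size=spec.n_differential, replace=False)
    n_up_basal = (
        spec.n_up_basal if spec.n_up_basal is not None else (spec.n_differential + 1) // 2
    )
    if not 0 <= n_up_basal <= spec.n_differential:
        raise ValueError("n_up_basal out of range")
    up_basal = set(diff_idx[:n_up_basal])
    up_luminal = set(diff_idx[n_up_basal:])

    bio_samples = [f"B{i + 1:02d}" for i in range(spec.n_basal)] + [
        f"L{i + 1:02d}" for i in range(spec.n_luminal)
    ]
    subtype = {s: ("basal" if s.startswith("B") else "luminal") for s in bio_samples}

    effect = 2.0 ** spec.log2_effect
    cols: dict[str, np.ndarray] = {}
    replicate_map: dict[str, str] = {}
    for s in bio_samples:
        mean_vec = base.copy()
        for i in range(spec.n_kinases):
            if (i in up_basal and subtype[s] == "basal") or (
                i in up_luminal and subtype[s] == "luminal"
            ):
                mean_vec[i] = mean_vec[i] * effect
        for r in range(spec.technical_replicates):
            col = f"{s}_r{r + 1}"
            replicate_map[col] = s
            cols[col] = mean_vec * _lognormal_factor(rng, spec.technical_cv, spec.n_kinases)

    df = pd.DataFrame(cols, index=genes)
    if spec.missing_rate > 0:
        mask = rng.random(df.shape) < spec.missing_rate
        df = df.mask(mask)

    direction = []
    for i in range(spec.n_kinases):
        if i in up_basal:
            direction.append("up_basal")
        elif i in up_luminal:
            direction.append("up_luminal")
        else:
            direction.append("none")
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_differential": [d != "none" for d in direction],
            "direction": direction,
            "log2_effect": [spec.log2_effect if d != "none" else 0.0 for d in direction],
        }
    )
    return ProteinQuantMatrix(df, "linear"), replicate_map, truth


def gen_replicate_run(
    n_peptides: int = 80,
    n_replicates: int = 18,
    technical_cv: float = 0.10,
    abundance_meanlog: float = 14.0,
    abundance_sdlog: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated injections of one pooled sample: peptides x replicates, linear scale.

    Emulates the precision experiment used to establish assay CV (a pooled
    lysate run many times); each replicate is the peptide's true quantity
    times lognormal technical noise at the stated CV.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(abundance_meanlog, abundance_sdlog, size=n_peptides))
    vals = base[:, None] * _lognormal_factor(rng, technical_cv, (n_peptides, n_replicates))
    return pd.DataFrame(
        vals,
        index=[f"PEP{i:03d}" for i in range(n_peptides)],
        columns=[f"rep{j + 1:02d}" for j in range(n_replicates)],
    )


# ---------------------------------------------------------------------------
# IS-PRM stream
# ---------------------------------------------------------------------------


def _peptide_mzs(peptide: str, charge: int = 2, n_products: int = 6):
    """Light/heavy precursor m/z and matched light/heavy singly-charged y-ion m/z."""
    label = LABEL_MASS_K if peptide.endswith("K") else LABEL_MASS_R
    light_mz = _mass.fast_mass(peptide, ion_type="M", charge=charge)
    heavy_mz = light_mz + label / charge
    # y ions from y3 upward; C-terminal label shifts every y ion by the label mass
    light_y = []
    for k in range(3, len(peptide)):
        light_y.append(_mass.fast_mass(peptide[-k:], ion_type="y", charge=1))
        if len(light_y) == n_products:
            break
    heavy_y = [mz + label for mz in light_y]
    return light_mz, heavy_mz, light_y, heavy_y, label


def gen_isprm_stream(
    n_targets: int,
    endogenous_present: Iterable[int] | None = None,
    ppm_jitter_sd: float = 0.0,
    decoy_rate: float = 0.0,
    seed: int = 0,
    charge: int = 2,
    gradient_min: float = 10.0,
    cycle_time_min: float = 0.02,
    elution_sigma_min: float = 0.08,
    heavy_peak_intensity: float = 5e6,
) -> tuple[SpectraStream, list[InclusionEntry], pd.DataFrame]:
    """Simulate survey scans for an IS-PRM run with planted truth.

    Targets elute as Gaussian profiles over the gradient; every survey scan
    during a target's elution contains its heavy precursor with m/z jittered
    at ``ppm_jitter_sd`` ppm.  True targets carry their full 6-ion product
    set; decoys emit only 3 of the 6 listed ions (so the n>=4 trigger rule can
    never fire on them).  Light twin products appear only for targets in
    ``endogenous_present`` (indices; None means all non-decoy targets).
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    while len(peptides) < n_targets:
        p = random_tryptic_peptide(rng, 9, 14)
        if p not in peptides:
            peptides.append(p)

    is_decoy = rng.random(n_targets) < decoy_rate
    if endogenous_present is None:
        endo = {i for i in range(n_targets) if not is_decoy[i]}
    else:
        endo = set(endogenous_present)
    apexes = rng.uniform(1.0, gradient_min - 1.0, size=n_targets)
    light_abundance = np.exp(rng.normal(12.0, 1.0, size=n_targets))

    entries: list[InclusionEntry] = []
    per_target = []
    for i, pep in enumerate(peptides):
        light_mz, heavy_mz, light_y, heavy_y, label = _peptide_mzs(pep, charge)
        frac = rng.dirichlet(np.ones(len(heavy_y)))  # relative product intensities
        emitted = sorted(rng.choice(len(heavy_y), size=3, replace=False)) if is_decoy[i] else list(
            range(len(heavy_y))
        )
        entries.append(
            InclusionEntry(
                peptide=pep,
                heavy_mz=heavy_mz,
                charge=charge,
                product_ion_mzs=tuple(heavy_y),
                mass_offset_mz=-label / charge,
                rt_window=(apexes[i] - 2.0, apexes[i] + 2.0),
            )
        )
        per_target.append(
            {
                "heavy_mz": heavy_mz,
                "light_y": light_y,
                "heavy_y": heavy_y,
                "frac": frac,
                "emitted": emitted,
            }
        )

    scan_times = np.arange(0.0, gradient_min, cycle_time_min)
    scans: list[SurveyScan] = []
    tic = 0.0
    for t in scan_times:
        precursors = []
        for i in range(n_targets):
            z = (t - apexes[i]) / elution_sigma_min
            if abs(z) > 4.0:
                continue
            bell = math.exp(-0.5 * z * z)
            inten = heavy_peak_intensity * bell
            jitter = 1.0 + rng.normal(0.0, ppm_jitter_sd) * 1e-6 if ppm_jitter_sd > 0 else 1.0
            info = per_target[i]
            heavy_products = tuple(
                (info["heavy_y"][j], inten * info["frac"][j]) for j in info["emitted"]
            )
            light_products = ()
            if i in endo:
                light_inten = light_abundance[i] * bell
                light_products = tuple(
                    (info["light_y"][j], light_inten * info["frac"][j])
                    for j in range(len(info["light_y"]))
                )
            precursors.append(
                Precursor(
                    mz=info["heavy_mz"] * jitter,
                    intensity=inten,
                    heavy_products=heavy_products,
                    light_products=light_products,
                )
            )
            tic += inten
        scans.append(SurveyScan(time=float(t), precursors=tuple(precursors)))

    truth = pd.DataFrame(
        {
            "peptide": peptides,
            "is_decoy": is_decoy,
            "endogenous_present": [i in endo for i in range(n_targets)],
            "apex_rt": apexes,
            "light_abundance": light_abundance,
        }
    )
    return SpectraStream(scans=scans, tic=max(tic, 1.0)), entries, truth


# ---------------------------------------------------------------------------
# PSM archive / assay-design inputs
# ---------------------------------------------------------------------------

_DEFECTS = ("low_score", "modified", "miscleaved", "subpeptide", "shared_gene", "mouse_shared")


def gen_assay_candidates(
    n_genes: int = 10,
    good_per_gene: int = 3,
    bad_per_gene: int = 4,
    inputs_ug: Sequence[float] = (12.5, 25.0, 50.0, 100.0),
    response_noise_cv: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, list[PsmRecord]], dict[str, tuple[list[float], list[float]]], pd.DataFrame]:
    """PSM archive plus dilution response curves with planted good candidates.

    Good peptides have clean PSM evidence (high ion score, low modification
    fraction, no missed cleavage, unshared) and linear dilution responses;
    bad peptides each carry one planted defect (PSM-level or a saturating
    response).  Returns (records per gene, peptide -> (inputs, areas), truth).
    """
    rng = np.random.default_rng(seed)
    records: dict[str, list[PsmRecord]] = {}
    responses: dict[str, tuple[list[float], list[float]]] = {}
    truth_rows = []
    inputs = [float(x) for x in inputs_ug]
    seen: set[str] = set()

    def fresh_peptide() -> str:
        while True:
            p = random_tryptic_peptide(rng, 9, 16)
            if p not in seen:
                seen.add(p)
                return p

    for g in range(n_genes):
        gene = f"KIN{g:04d}"
        recs: list[PsmRecord] = []
        for _ in range(good_per_gene):
            pep = fresh_peptide()
            psm = int(rng.integers(50, 500))
            recs.append(
                PsmRecord(
                    peptide=pep, gene_ids=frozenset({gene}), psm_count=psm,
                    modified_psm_count=int(psm * rng.uniform(0.0, 0.05)),
                    best_ion_score=float(rng.uniform(35, 90)), missed_cleavages=0,
                    is_subpeptide_of_miscleaved=False, shared_with_mouse=False,
                    covers_all_isoforms=True, q_value=0.01,
                )
            )
            coeff = float(np.exp(rng.normal(8.0, 0.5)))
            areas = [coeff * x for x in inputs]
            areas = list(np.array(areas) * _lognormal_factor(rng, response_noise_cv, len(areas)))
            responses[pep] = (inputs, areas)
            truth_rows.append({"gene": gene, "peptide": pep, "planted": "good", "defect": ""})
        for b in range(bad_per_gene):
            pep = fresh_peptide()
            defect = _DEFECTS[int(rng.integers(0, len(_DEFECTS)))]
            psm = int(rng.integers(20, 200))
            kw = dict(
                peptide=pep, gene_ids=frozenset({gene}), psm_count=psm,
                modified_psm_count=int(psm * 0.02), best_ion_score=float(rng.uniform(35, 90)),
                missed_cleavages=0, is_subpeptide_of_miscleaved=False,
                shared_with_mouse=False, covers_all_isoforms=True, q_value=0.01,
            )
            if defect == "low_score":
                kw["best_ion_score"] = float(rng.uniform(5, 19.5))
            elif defect == "modified":
                kw["modified_psm_count"] = int(psm * rng.uniform(0.15, 0.5))
            elif defect == "miscleaved":
                kw["missed_cleavages"] = 1
            elif defect == "subpeptide":
                kw["is_subpeptide_of_miscleaved"] = True
            elif defect == "shared_gene":
                kw["gene_ids"] = frozenset({gene, f"KIN{(g + 1) % n_genes:04d}"})
            elif defect == "mouse_shared":
                kw["shared_with_mouse"] = True
            recs.append(PsmRecord(**kw))
            coeff = float(np.exp(rng.normal(8.0, 0.5)))
            if defect == "mouse_shared":
                # deprioritized but technically sound: give it a bad (saturating)
                # response so it cannot displace planted good peptides downstream
                areas = [coeff * x / (x + 25.0) for x in inputs]
            else:
                areas = [coeff * x for x in inputs]
            responses[pep] = (inputs, list(areas))
            truth_rows.append({"gene": gene, "peptide": pep, "planted": "bad", "defect": defect})
        records[gene] = recs

    return records, responses, pd.DataFrame(truth_rows)
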