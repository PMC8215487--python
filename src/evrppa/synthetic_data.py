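"""Synthetic spot-level RPPA data with the statistical structure of a serum-EV study.

The generator emulates the geometry and signal composition of an antibody
microarray experiment on extracellular-vesicle lysates: each sample is printed
in triplicate spots at two total-protein concentrations, probed one antibody
per slide, accompanied by a secondary-antibody-only negative-control slide and
a total-protein (Sypro) stain channel.  The signal model is

    raw = (baseline * effect(group, antibody) * loading(sample)
           * conc_scaling * lognormal_noise) + assay_background + local_background

where ``assay_background`` is the antibody-independent secondary-antibody
signal also measured on the negative-control slide, and ``loading`` is a
per-sample total-protein multiplier shared across antibodies so that Sypro
normalization can cancel it.  All randomness flows from a single integer seed;
per-call sub-seeds are derived deterministically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPOT_COLUMNS = [
    "slide_id",
    "channel",
    "antibody_id",
    "sample_id",
    "print_conc_mg_ml",
    "replicate_idx",
    "raw_intensity",
    "local_background",
]

CHANNEL_ANTIBODY = "antibody"
CHANNEL_TOTAL_PROTEIN = "total_protein"
CHANNEL_NEGATIVE_CONTROL = "negative_control"


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return np.exp(rng.normal(-sigma2 / 2.0, sigma, size=size))


@dataclass(frozen=True)
class AssayLayout:
    """Printed-slide geometry: which endpoints, samples, replicates and dilutions exist."""

    antibodies: tuple[str, ...]
    samples: tuple[str, ...]
    replicates_per_spot: int = 3
    print_concentrations: tuple[float, ...] = (0.5, 0.125)
    reference_curve_points: int = 10
    has_negative_control_slide: bool = True
    has_total_protein_channel: bool = True

    def __post_init__(self):
        object.__setattr__(self, "antibodies", tuple(self.antibodies))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "print_concentrations", tuple(self.print_concentrations))
        if not self.antibodies:
            raise ValueError("AssayLayout.antibodies is empty")
        if not self.samples:
            raise ValueError("AssayLayout.samples is empty")
        if self.replicates_per_spot < 1:
            raise ValueError("replicates_per_spot must be >= 1")
        if any(c <= 0 for c in self.print_concentrations):
            raise ValueError("print_concentrations must all be > 0")
        if self.reference_curve_points < 2:
            raise ValueError("reference_curve_points must be >= 2")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and the multiplicative effect structure programmed into it.

    ``effects`` maps ``(antibody_id, group)`` to a fold-change relative to the
    baseline intensity; unlisted pairs default to 1.0.  ``noise_cv`` is the
    coefficient of variation of the per-spot multiplicative log-normal noise;
    ``loading_cv`` the CV of the per-sample total-protein loading multiplier.
    """

    groups: dict[str, int]
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.15
    baseline_intensity: float = 1000.0
    seed: int = 0
    loading_cv: float = 0.1
    assay_background: float = 50.0
    local_background: float = 20.0
    sypro_baseline: float = 5000.0

    def __post_init__(self):
        if any(n < 0 for n in self.groups.values()):
            raise ValueError("group sample counts must be >= 0")
        if self.noise_cv < 0 or self.loading_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if any(e <= 0 for e in self.effects.values()):
            raise ValueError("effect sizes must be > 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")

    def sample_ids(self) -> list[tuple[str, str]]:
        """Deterministic (sample_id, group) pairs, e.g. PCa_01 ... PCa_12."""
        out = []
        for group in self.groups:
            for i in range(self.groups[group]):
                out.append((f"{group}_{i + 1:02d}", group))
        return out


@dataclass(frozen=True)
class MixtureSpec:
    """Two-source EV mixture series: positive-source fractions in percent."""

    fractions: tuple[float, ...]
    positive_level: float
    negative_level: float
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fractions", tuple(self.fractions))
        if any(f < 0 or f > 100 for f in self.fractions):
            raise ValueError("mixture fractions must lie in [0, 100]")
        if self.positive_level < 0 or self.negative_level < 0:
            raise ValueError("mixture levels must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class ReferenceCurveData:
    """A dilution series of a synthetic peptide: known amounts (pg) with replicate intensities."""

    analyte: str
    amounts: tuple[float, ...]
    intensities: tuple[tuple[float, ...], ...]  # replicate A.U. per amount

    def __post_init__(self):
        object.__setattr__(self, "amounts", tuple(self.amounts))
        object.__setattr__(
            self, "intensities", tuple(tuple(row) for row in self.intensities)
        )
        if any(a <= 0 for a in self.amounts):
            raise ValueError("reference-curve amounts must be strictly positive")
        if len(set(self.amounts)) < 2:
            raise ValueError("reference curve needs at least 2 distinct amounts")
        if len(self.amounts) != len(self.intensities):
            raise ValueError("amounts and intensities length mismatch")


def _sub_seed(seed: int, tag: str) -> np.random.Generator:
    # stable across processes (unlike builtin hash)
    tag_int = zlib.crc32(tag.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag_int]))


def generate_slide(layout: AssayLayout, cohort: CohortSpec) -> pd.DataFrame:
    """Generate a full spot table for one assay run.

    One row per (sample x antibody x replicate x print concentration) in the
    antibody channel, plus matched total-protein spots and a negative-control
    slide of identical geometry with antibody-independent background signal.
    Deterministic for a fixed ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    samples = cohort.sample_ids()
    if not samples:
        raise ValueError("CohortSpec.groups yields no samples")

    conc_ref = max(layout.print_concentrations)
    loadings = {
        sid: f
        for (sid, _), f in zip(
            samples, _lognormal_factors(rng, cohort.loading_cv, len(samples))
        )
    }

    rows: list[tuple] = []
    n_rep = layout.replicates_per_spot

    for ab in layout.antibodies:
        slide = f"slide_{ab}"
        for sid, group in samples:
            effect = cohort.effects.get((ab, group), 1.0)
            signal = cohort.baseline_intensity * effect * loadings[sid]
            for conc in layout.print_concentrations:
                scale = conc / conc_ref
                noise = _lognormal_factors(rng, cohort.noise_cv, n_rep)
                bg_noise = _lognormal_factors(rng, cohort.noise_cv, n_rep)
                for r in range(n_rep):
                    raw = (
                        signal * scale * noise[r]
                        + cohort.assay_background * bg_noise[r]
                        + cohort.local_background
                    )
                    rows.append(
                        (slide, CHANNEL_ANTIBODY, ab, sid, conc, r + 1, raw,
                         cohort.local_background)
                    )

    if layout.has_total_protein_channel:
        for sid, group in samples:
            for conc in layout.print_concentrations:
                scale = conc / conc_ref
                noise = _lognormal_factors(rng, cohort.noise_cv, n_rep)
                for r in range(n_rep):
                    raw = (
                        cohort.sypro_baseline * loadings[sid] * scale * noise[r]
                        + cohort.local_background
                    )
                    rows.append(
                        ("slide_sypro", CHANNEL_TOTAL_PROTEIN, "Sypro", sid, conc,
                         r + 1, raw, cohort.local_background)
                    )

    if layout.has_negative_control_slide:
        for sid, group in samples:
            for conc in layout.print_concentrations:
                noise = _lognormal_factors(rng, cohort.noise_cv, n_rep)
                for r in range(n_rep):
                    raw = cohort.assay_background * noise[r] + cohort.local_background
                    rows.append(
                        ("slide_negctrl", CHANNEL_NEGATIVE_CONTROL, "none", sid, conc,
                         r + 1, raw, cohort.local_background)
                    )

    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def generate_annotation(
    cohort: CohortSpec,
    recurrent_fraction: dict[str, float] | None = None,
    psa_ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Clinical annotation table matched to a cohort's sample ids.

    PSA ranges default to group-typical values (healthy-like groups low, tumour
    groups spanning the 4-10 ng/mL gray zone and above); Gleason/pTNM are drawn
    uniformly from the declared categories for tumour groups and left missing
    otherwise.  ``recurrent_fraction`` maps group -> probability of recurrence.
    """
    rng = _sub_seed(cohort.seed, "annotation")
    psa_defaults = {"HD": (0.2, 3.0), "Hyper": (2.0, 12.0), "DF": (0.05, 1.0)}
    gleasons = ["6", "7(3+4)", "7(4+3)", "8", "9"]
    ptnms = ["T1c", "T2a", "T2b", "T2c", "T3a", "T3b"]
    rows = []
    for sid, group in cohort.sample_ids():
        lo, hi = (psa_ranges or {}).get(group, psa_defaults.get(group, (2.0, 30.0)))
        psa = round(float(rng.uniform(lo, hi)), 2)
        tumour = group not in psa_defaults
        gleason = str(rng.choice(gleasons)) if tumour else ""
        ptnm = str(rng.choice(ptnms)) if tumour else ""
        p_rec = (recurrent_fraction or {}).get(group)
        if p_rec is None:
            rec = ""
        else:
            rec = int(rng.random() < p_rec)
        followup = round(float(rng.uniform(1.0, 15.0)), 1)
        rows.append((sid, group, psa, gleason, ptnm, rec, followup))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "psa_ng_ml", "gleason", "ptnm",
            "recurrent", "followup_years",
        ],
    )


def generate_mixture_series(spec: MixtureSpec, layout: AssayLayout) -> pd.DataFrame:
    """Spot table for a positive/negative EV mixture series.

    Expected intensity at fraction f is
    ``negative_level + (positive_level - negative_level) * f / 100``
    with multiplicative log-normal noise; one pseudo-sample per fraction,
    printed at the layout's replicate count and highest concentration.
    """
    rng = np.random.default_rng(spec.seed)
    conc = max(layout.print_concentrations)
    n_rep = layout.replicates_per_spot
    rows = []
    for f in spec.fractions:
        expected = spec.negative_level + (spec.positive_level - spec.negative_level) * f / 100.0
        noise = _lognormal_factors(rng, spec.noise_cv, n_rep)
        for r in range(n_rep):
            rows.append(
                ("slide_mixture", CHANNEL_ANTIBODY, "mixture_target",
                 f"frac_{f:g}", conc, r + 1, expected * noise[r], 0.0)
            )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def mixture_table_to_series(table: pd.DataFrame) -> tuple[list[float], list[list[float]]]:
    """Extract (fractions, replicate intensities per fraction) from a mixture spot table."""
    fracs, reps = [], []
    for sid, grp in table.groupby("sample_id", sort=False):
        fracs.append(float(sid.split("_", 1)[1]))
        reps.append([r - b for r, b in zip(grp["raw_intensity"], grp["local_background"])])
    order = np.argsort(fracs)
    return [fracs[i] for i in order], [reps[i] for i in order]


def generate_reference_curve(
    analyte: str,
    amounts,
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> ReferenceCurveData:
    """Synthetic-peptide dilution curve with log10-linear signal.

    ``log10(intensity) = intercept + slope * log10(amount) + N(0, noise_sd)``;
    amounts in pg, intensities in A.U.  Deterministic per seed.
    """
    amounts = [float(a) for a in amounts]
    if any(a <= 0 for a in amounts):
        raise ValueError("amounts must be strictly positive (log undefined otherwise)")
    if len(set(amounts)) < 2:
        raise ValueError("need at least 2 distinct amounts")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    intensities = []
    for a in amounts:
        log_mu = intercept + slope * np.log10(a)
        eps = rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.zeros(replicates)
        intensities.append(tuple(float(10.0 ** (log_mu + e)) for e in eps))
    return ReferenceCurveData(analyte=analyte, amounts=tuple(amounts), intensities=tuple(intensities))


# ---------------------------------------------------------------------------
# Study presets mirroring the three cohort designs

PIVOTAL_ENDPOINTS = tuple(
    ["ERG", "PD-L1", "Survivin", "Integrin-b5", "IL-6", "SPARC"]
    + [f"EP{i:02d}" for i in range(1, 32)]
)

PROGNOSTIC_ENDPOINTS = (
    "c-Myc_pT58_S62", "SHC_pY317", "Wnt5a_b", "c-RAF_pS338", "TGF-beta",
)


def pivotal_cohort(seed: int = 0, noise_cv: float = 0.15) -> tuple[AssayLayout, CohortSpec]:
    """Pivotal design: 16 healthy donors vs 12 tumours, 37 endpoints, six of them
    programmed with a 2-fold tumour effect."""
    effects = {(ep, "PCa"): 2.0 for ep in PIVOTAL_ENDPOINTS[:6]}
    cohort = CohortSpec(
        groups={"HD": 16, "PCa": 12}, effects=effects, noise_cv=noise_cv, seed=seed
    )
    layout = AssayLayout(
        antibodies=PIVOTAL_ENDPOINTS,
        samples=tuple(s for s, _ in cohort.sample_ids()),
    )
    return layout, cohort


def training_cohort(seed: int = 0, noise_cv: float = 0.15) -> tuple[AssayLayout, CohortSpec]:
    """Training design: HD/Hyper/DF/PCa groups with diagnostic effects on a
    small marker panel (group sizes 18/41/44/57)."""
    endpoints = ("c-Myc_pT58_S62", "TSC2_pY1571", "TGF-beta", "b-Catenin_pT41_S45",
                 "SPARC", "PD-L1", "Survivin") + tuple(f"EP{i:02d}" for i in range(1, 21))
    effects = {
        ("c-Myc_pT58_S62", "PCa"): 0.5,   # lower in tumours
        ("TSC2_pY1571", "PCa"): 2.0,      # higher in tumours
        ("TGF-beta", "PCa"): 1.8,
        ("b-Catenin_pT41_S45", "PCa"): 1.6,
        ("SPARC", "PCa"): 1.8,
        ("PD-L1", "PCa"): 1.5,
        ("PD-L1", "Hyper"): 1.5,
        ("Survivin", "PCa"): 1.5,
        ("Survivin", "Hyper"): 1.5,
    }
    cohort = CohortSpec(
        groups={"HD": 18, "Hyper": 41, "DF": 44, "PCa": 57},
        effects=effects, noise_cv=noise_cv, seed=seed,
    )
    layout = AssayLayout(
        antibodies=endpoints, samples=tuple(s for s, _ in cohort.sample_ids())
    )
    return layout, cohort


def risk_cohort(seed: int = 0, noise_cv: float = 0.2) -> tuple[AssayLayout, CohortSpec]:
    """Risk-assessment design: non-recurrent primaries vs grouped recurrent and
    advanced tumours (11 vs 7+6), with 2-fold effects on the five prognostic
    endpoints in the recurrent/advanced groups."""
    endpoints = PROGNOSTIC_ENDPOINTS + tuple(f"EP{i:02d}" for i in range(1, 16))
    effects = {}
    for ep in PROGNOSTIC_ENDPOINTS:
        effects[(ep, "Recurrent")] = 2.0
        effects[(ep, "Advanced")] = 2.0
    cohort = CohortSpec(
        groups={"NonRecurrent": 11, "Recurrent": 7, "Advanced": 6},
        effects=effects, noise_cv=noise_cv, seed=seed,
    )
    layout = AssayLayout(
        antibodies=endpoints, samples=tuple(s for s, _ in cohort.sample_ids())
    )
    return layout, cohort
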