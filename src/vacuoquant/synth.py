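"""Synthetic cohorts, flow-cytometry samples and single-cell image pairs.

CLN3 disease (juvenile neuronal ceroid lipofuscinosis) presents as a
phenotypic spectrum — from a retina-only disease through protracted forms to
the classical childhood-onset neurodegenerative disease — and the fraction of
vacuolated blood lymphocytes tracks that severity.  Patient material is not
publicly available, so this module emulates the three measurement modalities
the analysis stages consume:

* **Smear cohorts** — repeated blood-smear counts per patient (three
  independent observers, 100 lymphocytes each, vacuoles per cell in at most
  20 vacuolated cells), with per-patient random intercepts/age-slopes on the
  logit scale and per-observer counting noise.
* **Flow samples** — per-event marker intensities (CD3, CD4, CD8, CD20,
  CD56, LAMP-1, perforin) on an arbitrary log scale, with NK cells acting as
  the dual LAMP-1/perforin internal positive control and a class- and
  subset-dependent fraction of "affected" (LAMP-1 high, perforin low) cells.
* **Cell images** — two-channel 8-bit single-cell frames (surface CD4 for
  segmentation, intracellular LAMP-1 for quantification) in which vacuoles
  are rendered as bright LAMP-1 rings, mirroring LAMP-1 residing on vacuole
  membranes.

Every generator records its ground truth (true vacuolated fraction, true
subset and affected labels, true mask and mean LAMP-1), so downstream stages
can be tested as parameter-recovery problems.

Class-level defaults follow the published severity strata: vacuolization is
rare in controls (~1-3 % of lymphocytes, 1-5 small vacuoles), intermediate in
protracted disease (median ~8 %, ~8 vacuoles/cell, range 3-12) and abundant
in classical disease (median ~30 %, range ~11-69 %, 6-18 vacuoles/cell,
median 10).  The retina-only phenotype is near-control in T cells but shows a
markedly elevated B-cell LAMP-1 signal.  The default fixed age slope is zero:
severity strata, not age, drive the vacuolization level.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SeverityClass",
    "CohortConfig",
    "PatientRecord",
    "CellImagePair",
    "ImageParams",
    "FlowEvent",
    "generate_cohort",
    "generate_flow_sample",
    "generate_cell_image",
    "expected_affected_fraction",
    "peaked_pmf",
    "SUBSET_PROPORTIONS",
]


class SeverityClass(str, enum.Enum):
    """CLN3 severity strata, ordered from unaffected to most severe.

    ``ordinal_rank`` encodes the clinical ordering used by monotonicity
    checks: control < carrier < retina_only < protracted < delayed_classical
    < classical.
    """

    CONTROL = "control"
    CARRIER = "carrier"
    RETINA_ONLY = "retina_only"
    PROTRACTED = "protracted"
    DELAYED_CLASSICAL = "delayed_classical"
    CLASSICAL = "classical"

    @property
    def ordinal_rank(self) -> int:
        return _ORDINAL_RANK[self]

    @classmethod
    def from_label(cls, label: "SeverityClass | str") -> "SeverityClass":
        if isinstance(label, SeverityClass):
            return label
        try:
            return cls(str(label))
        except ValueError:
            raise ValueError(f"unknown severity class: {label!r}") from None


_ORDINAL_RANK = {c: i for i, c in enumerate(SeverityClass)}


def peaked_pmf(lo: int, mode: int, hi: int) -> dict[int, float]:
    """Discrete unimodal pmf on ``lo..hi`` with weights 1/(1+|k-mode|).

    Used for vacuoles-per-cell distributions: it reproduces a stated
    median/mode with hard range limits without assuming a parametric family.
    """
    if not lo <= mode <= hi:
        raise ValueError("need lo <= mode <= hi")
    support = np.arange(lo, hi + 1)
    w = 1.0 / (1.0 + np.abs(support - mode))
    w /= w.sum()
    return dict(zip(support.tolist(), w.tolist()))


# Per-class defaults. Vacuolated fractions use the reported medians
# (controls 1-3 %, protracted median 8 %, classical median 30 %); carriers sit
# just above controls, the retina-only phenotype within the control range on
# smears, and delayed-classical between protracted and classical.
DEFAULT_VAC_FRACTION: dict[SeverityClass, float] = {
    SeverityClass.CONTROL: 0.02,
    SeverityClass.CARRIER: 0.03,
    SeverityClass.RETINA_ONLY: 0.03,
    SeverityClass.PROTRACTED: 0.08,
    SeverityClass.DELAYED_CLASSICAL: 0.15,
    SeverityClass.CLASSICAL: 0.30,
}

DEFAULT_VACUOLE_PMF: dict[SeverityClass, dict[int, float]] = {
    SeverityClass.CONTROL: peaked_pmf(1, 2, 5),
    SeverityClass.CARRIER: peaked_pmf(1, 2, 5),
    SeverityClass.RETINA_ONLY: peaked_pmf(1, 2, 5),
    SeverityClass.PROTRACTED: peaked_pmf(3, 8, 12),
    SeverityClass.DELAYED_CLASSICAL: peaked_pmf(4, 9, 14),
    SeverityClass.CLASSICAL: peaked_pmf(6, 10, 18),
}

# Additive shifts (logit scale) applied to the baseline affected fraction per
# lymphocyte subset. T-cell involvement scales with severity; the retina-only
# phenotype instead shows its signal almost exclusively in the B (CD20)
# compartment.
DEFAULT_LAMP_SHIFT: dict[SeverityClass, dict[str, float]] = {
    SeverityClass.CONTROL: {"T4": 0.0, "T8": 0.0, "B": 0.0},
    SeverityClass.CARRIER: {"T4": 0.3, "T8": 0.3, "B": 0.3},
    SeverityClass.RETINA_ONLY: {"T4": 0.3, "T8": 0.3, "B": 4.5},
    SeverityClass.PROTRACTED: {"T4": 2.5, "T8": 2.5, "B": 1.5},
    SeverityClass.DELAYED_CLASSICAL: {"T4": 3.2, "T8": 3.2, "B": 2.0},
    SeverityClass.CLASSICAL: {"T4": 4.0, "T8": 4.0, "B": 2.5},
}

# Representative genotype strings per stratum (two truncating alleles for
# classical disease, truncating + mild missense for delayed classical, at
# least one mild missense for protracted, two particularly mild missense
# alleles for retina-only disease).
GENOTYPE_BY_CLASS: dict[SeverityClass, str] = {
    SeverityClass.CONTROL: "wild-type/wild-type",
    SeverityClass.CARRIER: "1kb-del/wild-type",
    SeverityClass.RETINA_ONLY: "c.1213C>T/c.1213C>T",
    SeverityClass.PROTRACTED: "c.139T>C/c.1000C>T",
    SeverityClass.DELAYED_CLASSICAL: "1kb-del/c.1000C>T",
    SeverityClass.CLASSICAL: "1kb-del/1kb-del",
}

DEFAULT_N_PATIENTS: dict[SeverityClass, int] = {
    SeverityClass.CONTROL: 8,
    SeverityClass.CARRIER: 3,
    SeverityClass.RETINA_ONLY: 2,
    SeverityClass.PROTRACTED: 3,
    SeverityClass.DELAYED_CLASSICAL: 2,
    SeverityClass.CLASSICAL: 10,
}

#: Flow subset mixing proportions (events, not sorted cells).
SUBSET_PROPORTIONS: dict[str, float] = {
    "T4": 0.40,
    "T8": 0.25,
    "B": 0.15,
    "NK": 0.10,
    "other": 0.10,
}

# Log-scale fluorescence model (arbitrary decades). Populations are well
# separated by construction: 12 sigma between negative and positive marker
# modes, so 1-D thresholds recover subsets essentially without error.
MARKER_NEG = (0.8, 0.2)
MARKER_POS = (3.2, 0.2)
LAMP_NEG = (1.0, 0.3)
LAMP_AFFECTED = (3.4, 0.2)
PERFORIN_POS = (3.2, 0.2)
NK_LEVEL = 3.2          # shared LAMP-1/perforin elevation of NK cells
NK_SHARED_SD = 0.25     # common granule-content factor (correlates the two)
NK_LOCAL_SD = 0.05
T8_ACTIVATED_FRACTION = 0.05  # cytotoxically activated: LAMP-1+ AND perforin+

MARKER_CHANNELS = ("CD3", "CD4", "CD8", "CD20", "CD56")
ALL_CHANNELS = MARKER_CHANNELS + ("LAMP1", "PERFORIN")

# Which surface markers are positive per true subset.
_POSITIVE_MARKERS = {
    "B": ("CD20",),
    "T4": ("CD3", "CD4"),
    "T8": ("CD3", "CD8"),
    "NK": ("CD56",),
    "other": (),
}


def _normalize_class_map(m: Mapping) -> dict[SeverityClass, object]:
    return {SeverityClass.from_label(k): v for k, v in m.items()}


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort.

    Random effects act on the logit of the per-sample vacuolated fraction:
    ``p(patient, age) = expit(logit(class_mean) + b0 + (b1 + age_slope_true) * age)``
    with ``b0 ~ N(0, random_intercept_sd)`` and ``b1 ~ N(0, random_slope_sd)``
    drawn once per patient.  Each of ``n_observers`` observers applies an
    additional additive logit shift ``N(0, observer_sd)`` before binomial
    counting of ``n_cells_counted`` lymphocytes.  When all three SDs are zero
    the generator collapses to its analytic expectation and emits exact
    (rounded) expected counts instead of binomial draws.
    """

    n_patients_per_class: dict = field(
        default_factory=lambda: dict(DEFAULT_N_PATIENTS)
    )
    samples_per_patient: tuple[int, int] = (2, 5)
    age_range_years: tuple[float, float] = (4.0, 25.0)
    vac_fraction_by_class: dict = field(
        default_factory=lambda: dict(DEFAULT_VAC_FRACTION)
    )
    vacuoles_per_cell_dist_by_class: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VACUOLE_PMF.items()}
    )
    lamp_shift_by_class_and_subset: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LAMP_SHIFT.items()}
    )
    affected_baseline: float = 0.02
    random_intercept_sd: float = 0.25
    random_slope_sd: float = 0.01
    observer_sd: float = 0.15
    age_slope_true: float = 0.0
    n_cells_counted: int = 100
    n_observers: int = 3
    seed: int = 0

    def normalized(self) -> "CohortConfig":
        """Return a copy with all class keys coerced to :class:`SeverityClass`."""
        return dataclasses.replace(
            self,
            n_patients_per_class=_normalize_class_map(self.n_patients_per_class),
            vac_fraction_by_class=_normalize_class_map(self.vac_fraction_by_class),
            vacuoles_per_cell_dist_by_class={
                SeverityClass.from_label(k): {int(a): float(b) for a, b in v.items()}
                for k, v in self.vacuoles_per_cell_dist_by_class.items()
            },
            lamp_shift_by_class_and_subset={
                SeverityClass.from_label(k): dict(v)
                for k, v in self.lamp_shift_by_class_and_subset.items()
            },
            samples_per_patient=tuple(self.samples_per_patient),
            age_range_years=tuple(self.age_range_years),
        )

    def validate(self) -> None:
        if not self.n_patients_per_class:
            raise ValueError("n_patients_per_class is empty")
        for sd_name in ("random_intercept_sd", "random_slope_sd", "observer_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        for cls, p in self.vac_fraction_by_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"vac_fraction for {cls} outside [0, 1]: {p}")
        if not 0.0 <= self.affected_baseline <= 1.0:
            raise ValueError("affected_baseline outside [0, 1]")
        lo, hi = self.samples_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("invalid samples_per_patient range")
        if self.n_cells_counted < 1 or self.n_observers < 1:
            raise ValueError("n_cells_counted and n_observers must be >= 1")

    @property
    def zero_noise(self) -> bool:
        return (
            self.random_intercept_sd == 0
            and self.random_slope_sd == 0
            and self.observer_sd == 0
        )


@dataclass
class PatientRecord:
    """One synthetic patient with the random effects drawn for them."""

    patient_id: str
    severity_class: SeverityClass
    genotype_string: str
    random_intercept: float
    random_slope: float
    sample_ages: list[float]


@dataclass
class FlowEvent:
    """One flow-cytometry event: seven channel intensities plus ground truth."""

    cd3: float
    cd4: float
    cd8: float
    cd20: float
    cd56: float
    lamp1: float
    perforin: float
    true_subset: str
    true_affected: bool


@dataclass
class ImageParams:
    """Rendering parameters for synthetic two-channel single-cell frames."""

    background: float = 20.0
    cell_cd4_intensity: float = 180.0
    lamp1_background: float = 10.0
    cytoplasm_lamp1_by_class: dict = field(
        default_factory=lambda: {
            SeverityClass.CONTROL: 40.0,
            SeverityClass.CARRIER: 45.0,
            SeverityClass.RETINA_ONLY: 50.0,
            SeverityClass.PROTRACTED: 60.0,
            SeverityClass.DELAYED_CLASSICAL: 65.0,
            SeverityClass.CLASSICAL: 70.0,
        }
    )
    ring_intensity: float = 200.0
    vacuole_radius: float = 3.0
    ring_width: float = 1.5
    noise_sd: float = 6.0
    cell_radius_frac: float = 0.32
    center_jitter: float = 2.0


@dataclass
class CellImagePair:
    """Two-channel 8-bit single-cell image with generator ground truth."""

    cd4_channel: np.ndarray
    lamp1_channel: np.ndarray
    true_mask: np.ndarray
    true_mean_lamp1: float
    cell_id: str
    class_label: SeverityClass


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[PatientRecord]]:
    """Generate a longitudinal smear-count cohort.

    Returns a table with one row per (patient, sampling age, observer) and the
    list of :class:`PatientRecord` holding the drawn random effects.  Columns:
    ``patient_id, class, genotype, age_years, observer_id, n_counted,
    n_vacuolated, vacuole_counts`` (semicolon-joined, at most 20 entries — the
    per-observer cap on vacuolated cells examined in detail).
    """
    config = config.normalized()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo_s, hi_s = config.samples_per_patient
    lo_a, hi_a = config.age_range_years

    patients: list[PatientRecord] = []
    rows: list[dict] = []
    pid = 0
    for cls in SeverityClass:  # fixed iteration order for determinism
        n_pat = int(config.n_patients_per_class.get(cls, 0))
        if n_pat == 0:
            continue
        if cls not in config.vac_fraction_by_class:
            raise ValueError(f"no vac_fraction configured for class {cls.value}")
        class_mean = float(config.vac_fraction_by_class[cls])
        pmf = config.vacuoles_per_cell_dist_by_class[cls]
        vac_values = np.array(sorted(pmf))
        vac_probs = np.array([pmf[v] for v in vac_values], dtype=float)
        vac_probs = vac_probs / vac_probs.sum()
        for _ in range(n_pat):
            pid += 1
            patient_id = f"P{pid:03d}"
            b0 = rng.normal(0.0, config.random_intercept_sd)
            b1 = rng.normal(0.0, config.random_slope_sd)
            n_samples = int(rng.integers(lo_s, hi_s + 1))
            ages = np.sort(rng.uniform(lo_a, hi_a, size=n_samples))
            patients.append(
                PatientRecord(
                    patient_id=patient_id,
                    severity_class=cls,
                    genotype_string=GENOTYPE_BY_CLASS[cls],
                    random_intercept=float(b0),
                    random_slope=float(b1),
                    sample_ages=[float(a) for a in ages],
                )
            )
            for age in ages:
                eta = logit(class_mean) + b0 + (b1 + config.age_slope_true) * age
                p_true = float(expit(eta))
                for obs_id in range(1, config.n_observers + 1):
                    p_obs = float(expit(eta + rng.normal(0.0, config.observer_sd)))
                    if config.zero_noise:
                        n_vac = int(round(p_obs * config.n_cells_counted))
                    else:
                        n_vac = int(rng.binomial(config.n_cells_counted, p_obs))
                    n_detail = min(20, n_vac)
                    counts = rng.choice(vac_values, size=n_detail, p=vac_probs)
                    rows.append(
                        {
                            "patient_id": patient_id,
                            "class": cls.value,
                            "genotype": GENOTYPE_BY_CLASS[cls],
                            "age_years": float(age),
                            "observer_id": obs_id,
                            "n_counted": config.n_cells_counted,
                            "n_vacuolated": n_vac,
                            "vacuole_counts": ";".join(
                                str(int(c)) for c in counts
                            ),
                        }
                    )
    return pd.DataFrame(rows), patients


def expected_affected_fraction(
    class_label: SeverityClass | str,
    subset: str,
    config: CohortConfig | None = None,
    logit_offset: float = 0.0,
) -> float:
    """Expected affected (LAMP-1+ perforin-) fraction for a class and subset.

    ``expit(logit(baseline) + shift[class][subset] + logit_offset)`` — the
    mixture weight the flow generator uses, exposed so recovery tests can
    compare estimates against the exact generator truth.
    """
    cls = SeverityClass.from_label(class_label)
    config = (config or CohortConfig()).normalized()
    if subset in ("NK", "other"):
        return 0.0
    shift = config.lamp_shift_by_class_and_subset[cls][subset]
    return float(expit(logit(config.affected_baseline) + shift + logit_offset))


def generate_flow_sample(
    class_label: SeverityClass | str,
    n_events: int,
    config: CohortConfig | None = None,
    seed: int | None = None,
    affected_logit_offset: float = 0.0,
    subset_proportions: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Generate one flow-cytometry sample as a per-event table.

    Columns: the seven channels ``CD3 CD4 CD8 CD20 CD56 LAMP1 PERFORIN``
    (log-scale arbitrary units) plus ground truth ``true_subset`` and
    ``true_affected``.  NK events always draw elevated LAMP-1 *and* perforin
    from a shared granule-content factor (the internal positive control); a
    small fraction of CD8 T cells is rendered cytotoxically activated (both
    markers high) and is *not* counted as affected.  ``affected_logit_offset``
    shifts the affected-mixture weight on the logit scale, e.g. to inject a
    patient-level random effect.
    """
    cls = SeverityClass.from_label(class_label)
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    config = (config or CohortConfig()).normalized()
    props = dict(subset_proportions or SUBSET_PROPORTIONS)
    names = list(props)
    p = np.array([props[k] for k in names], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("invalid subset proportions")
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    subset = rng.choice(names, size=n_events, p=p)
    data = {ch: np.empty(n_events) for ch in ALL_CHANNELS}
    affected = np.zeros(n_events, dtype=bool)

    for name in names:
        m = subset == name
        n = int(m.sum())
        if n == 0:
            continue
        pos = _POSITIVE_MARKERS.get(name, ())
        for ch in MARKER_CHANNELS:
            mu, sd = MARKER_POS if ch in pos else MARKER_NEG
            data[ch][m] = rng.normal(mu, sd, size=n)
        if name == "NK":
            e = rng.normal(0.0, NK_SHARED_SD, size=n)
            data["LAMP1"][m] = NK_LEVEL + e + rng.normal(0, NK_LOCAL_SD, size=n)
            data["PERFORIN"][m] = NK_LEVEL + e + rng.normal(0, NK_LOCAL_SD, size=n)
        else:
            pi = expected_affected_fraction(
                cls, name, config, logit_offset=affected_logit_offset
            )
            aff = rng.random(n) < pi
            lamp = np.where(
                aff,
                rng.normal(*LAMP_AFFECTED, size=n),
                rng.normal(*LAMP_NEG, size=n),
            )
            perf = rng.normal(*MARKER_NEG, size=n)
            if name == "T8":
                act = (~aff) & (rng.random(n) < T8_ACTIVATED_FRACTION)
                lamp = np.where(act, rng.normal(*LAMP_AFFECTED, size=n), lamp)
                perf = np.where(act, rng.normal(*PERFORIN_POS, size=n), perf)
            data["LAMP1"][m] = lamp
            data["PERFORIN"][m] = perf
            idx = np.flatnonzero(m)
            affected[idx[aff]] = True

    out = pd.DataFrame(data)
    out["true_subset"] = subset
    out["true_affected"] = affected
    return out


def generate_cell_image(
    class_label: SeverityClass | str,
    n_vacuoles: int,
    image_size: tuple[int, int] = (64, 64),
    seed: int | None = None,
    params: ImageParams | None = None,
    cell_id: str | None = None,
) -> CellImagePair:
    """Render one two-channel 8-bit single-cell frame with ground truth.

    The CD4 channel is a bright disk (the cell) on a dark background; the
    LAMP-1 channel is a diffuse cytoplasmic signal whose baseline rises with
    severity class, plus ``n_vacuoles`` bright rings at vacuole perimeters
    (LAMP-1 sits on the vacuole membrane, so vacuoles appear as annuli, not
    filled disks).  ``true_mean_lamp1`` is the mean of the *noise-free* LAMP-1
    signal over the true mask.

    Raises ``ValueError`` if the requested vacuoles cannot be placed inside
    the cell disk.
    """
    cls = SeverityClass.from_label(class_label)
    if n_vacuoles < 0:
        raise ValueError("n_vacuoles must be >= 0")
    h, w = image_size
    if h < 32 or w < 32:
        raise ValueError("image_size must be at least 32x32")
    params = params or ImageParams()
    rng = np.random.default_rng(seed)

    radius = params.cell_radius_frac * min(h, w)
    cy = h / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    cx = w / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    mask = dist <= radius

    cyto = {SeverityClass.from_label(k): v
            for k, v in params.cytoplasm_lamp1_by_class.items()}[cls]
    cd4_clean = np.where(mask, params.cell_cd4_intensity, params.background)
    lamp_clean = np.where(mask, cyto, params.lamp1_background)

    if n_vacuoles > 0:
        r_vac = params.vacuole_radius
        max_center_r = radius - r_vac - params.ring_width / 2.0 - 1.0
        if max_center_r <= 0:
            raise ValueError(
                f"vacuole radius {r_vac} does not fit inside cell radius {radius:.1f}"
            )
        centers: list[tuple[float, float]] = []
        for _ in range(n_vacuoles):
            placed = False
            for _attempt in range(200):
                rr = max_center_r * np.sqrt(rng.random())
                th = rng.uniform(0, 2 * np.pi)
                vy, vx = cy + rr * np.sin(th), cx + rr * np.cos(th)
                if all(np.hypot(vy - oy, vx - ox) >= 1.8 * r_vac
                       for oy, ox in centers):
                    centers.append((vy, vx))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place {n_vacuoles} vacuoles of radius {r_vac} "
                    f"inside a cell of radius {radius:.1f}"
                )
        for vy, vx in centers:
            d = np.hypot(yy - vy, xx - vx)
            ring = np.abs(d - r_vac) <= params.ring_width / 2.0
            lamp_clean = np.where(ring & mask, params.ring_intensity, lamp_clean)

    true_mean = float(lamp_clean[mask].mean())

    def _noisy(clean: np.ndarray) -> np.ndarray:
        img = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return CellImagePair(
        cd4_channel=_noisy(cd4_clean),
        lamp1_channel=_noisy(lamp_clean),
        true_mask=mask,
        true_mean_lamp1=true_mean,
        cell_id=cell_id or f"{cls.value}_cell",
        class_label=cls,
    )
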