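"""Synthetic inputs: DCE phantoms with known kinetic truth, vessel
cross-sections with known areas, and a small-cohort patient table.

No patient data ship with this package; every analysis input is generated
here, fully seeded. The phantom is a forward model of the acquisition: a
multi-flip-angle SPGR block at the region's true T1, then a dynamic SPGR
series whose concentration curves come from the extended Tofts model
driven by the population input function, with optional additive Gaussian
noise at a stated SNR (baseline signal / noise SD). The cohort generator
reproduces the study's printed group sizes, risk-factor counts, and
stage-by-stenosis distribution exactly; continuous fields (age, Ktrans)
are drawn from truncated normal distributions with the printed group
means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data import AIF, DynamicSeries, VFASeries
from .kinetics import AIFParams, population_aif, tofts_forward
from .protocol import ScanProtocol
from .relaxometry import spgr_signal, spgr_signal_from_r1

__all__ = [
    "RegionTruth",
    "PhantomTruth",
    "Phantom",
    "default_phantom_truth",
    "generate_phantom",
    "generate_vessel_sections",
    "CohortConfig",
    "GroupConfig",
    "generate_cohort",
    "SINUS_LABEL",
]

SINUS_LABEL = 99


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth tissue properties for one phantom region."""

    label: int
    name: str
    t1_ms: float
    ktrans: float  # 1/min
    ve: float
    vp: float
    m0: float = 1000.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0:
            raise ValueError("t1_ms must be positive")
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        if self.ktrans > 0 and not 0.0 < self.ve <= 1.0:
            raise ValueError("ve must lie in (0, 1] when ktrans > 0")
        if not 0.0 <= self.vp <= 1.0:
            raise ValueError("vp must lie in [0, 1]")
        if self.ve + self.vp > 1.0:
            raise ValueError("ve + vp must not exceed 1")


@dataclass(frozen=True)
class PhantomTruth:
    """Collection of region truths; labels must be unique."""

    regions: tuple[RegionTruth, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if SINUS_LABEL in labels:
            raise ValueError(f"label {SINUS_LABEL} is reserved for the sinus")

    def by_label(self) -> dict[int, RegionTruth]:
        return {r.label: r for r in self.regions}


def default_phantom_truth() -> PhantomTruth:
    """Lesion / mirror / background regions at the study's group-mean
    permeabilities: a leaky acute lesion (Ktrans 0.098 /min), its
    contralateral mirror (0.003 /min) and non-enhancing background."""
    return PhantomTruth(
        regions=(
            RegionTruth(1, "lesion", 1000.0, 0.098, 0.2, 0.02),
            RegionTruth(2, "mirror", 1000.0, 0.003, 0.2, 0.02),
            RegionTruth(3, "background", 900.0, 0.0, 0.2, 0.0),
        )
    )


@dataclass
class Phantom:
    """A generated phantom plus its generating ground truth."""

    vfa: VFASeries
    dynamic: DynamicSeries
    labels: np.ndarray
    sinus_mask: np.ndarray
    truth: PhantomTruth
    protocol: ScanProtocol
    aif_truth: AIF  # plasma curve used to generate the data
    conc_truth: dict  # label -> noiseless tissue concentration curve (mM)
    seed: int
    snr: float | None

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _default_labels(grid_shape, truth: PhantomTruth, include_sinus: bool) -> np.ndarray:
    """Partition the grid into near-equal strips along axis 0, one per
    region (sinus last)."""
    n_parts = len(truth.regions) + (1 if include_sinus else 0)
    if grid_shape[0] < n_parts:
        raise ValueError(f"grid axis 0 too small for {n_parts} regions")
    labels = np.zeros(grid_shape, dtype=int)
    edges = np.linspace(0, grid_shape[0], n_parts + 1).astype(int)
    parts = [r.label for r in truth.regions] + ([SINUS_LABEL] if include_sinus else [])
    for lab, lo, hi in zip(parts, edges[:-1], edges[1:]):
        labels[lo:hi] = lab
    return labels


def generate_phantom(
    seed: int,
    protocol: ScanProtocol | None = None,
    truth: PhantomTruth | None = None,
    grid_shape: tuple[int, ...] = (32, 32, 4),
    labels: np.ndarray | None = None,
    snr: float | None = None,
    include_sinus: bool = True,
    sinus_t1_ms: float = 1700.0,
    sinus_m0: float = 1000.0,
    aif_params: AIFParams | None = None,
) -> Phantom:
    """Generate a VFA + dynamic SPGR phantom with known kinetic truth.

    Each labeled region carries a :class:`RegionTruth`; its dynamic signal
    is the SPGR forward model of R1(t) = 1/T1 + r1*C(t) with C(t) from the
    extended Tofts model under the population plasma input. The sinus
    region carries the whole-blood curve, i.e. the plasma curve scaled by
    (1 - hematocrit). ``snr=None`` means noiseless; otherwise additive
    Gaussian noise with SD = (mean baseline dynamic signal) / snr is added
    to both series. Identical seeds give bit-identical output.
    """
    protocol = protocol or ScanProtocol()
    truth = truth or default_phantom_truth()
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noiseless)")
    if labels is None:
        labels = _default_labels(grid_shape, truth, include_sinus)
    else:
        labels = np.asarray(labels)
        grid_shape = labels.shape
    by_label = truth.by_label()
    present = set(np.unique(labels).tolist())
    allowed = set(by_label) | ({SINUS_LABEL} if include_sinus else set())
    unknown = present - allowed
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} have no truth record")

    times = protocol.times
    aif = population_aif(times, aif_params)
    n_ang = len(protocol.flip_angles)
    angles = np.asarray(protocol.flip_angles, dtype=float)

    vfa = np.zeros(grid_shape + (n_ang,))
    dyn = np.zeros(grid_shape + (protocol.n_dynamics,))
    conc_truth: dict[int, np.ndarray] = {}

    for lab in sorted(present):
        mask = labels == lab
        if lab == SINUS_LABEL:
            t1, m0 = sinus_t1_ms, sinus_m0
            conc = aif.cp * (1.0 - protocol.hematocrit)
        else:
            r = by_label[lab]
            t1, m0 = r.t1_ms, r.m0
            conc = tofts_forward(r.ktrans, r.ve, r.vp, aif)
        conc_truth[lab] = conc
        vfa[mask] = spgr_signal(m0, t1, angles, protocol.tr)
        r1_t = 1000.0 / t1 + protocol.relaxivity_r1 * conc
        dyn[mask] = spgr_signal_from_r1(m0, r1_t, protocol.flip_angle_dynamic, protocol.tr)

    if snr is not None:
        rng = np.random.default_rng(seed)
        baseline = dyn[..., : max(protocol.n_baseline, 1)]
        sd = float(np.mean(baseline)) / snr
        dyn = dyn + rng.normal(0.0, sd, size=dyn.shape)
        vfa = vfa + rng.normal(0.0, sd, size=vfa.shape)

    return Phantom(
        vfa=VFASeries(vfa, angles, protocol.tr),
        dynamic=DynamicSeries(dyn, times, protocol),
        labels=labels,
        sinus_mask=labels == SINUS_LABEL,
        truth=truth,
        protocol=protocol,
        aif_truth=aif,
        conc_truth=conc_truth,
        seed=seed,
        snr=snr,
    )


# ---------------------------------------------------------------------------
# vessel cross-sections
# ---------------------------------------------------------------------------

def generate_vessel_sections(
    seed: int,
    specs,
    pixel_spacing: float,
    shape: tuple[int, int] | None = None,
):
    """Render annular vessel cross-sections with known areas.

    ``specs`` is a sequence of (lumen_area, vessel_area) pairs in mm^2.
    Each section is a label image (0 background, 1 lumen, 2 wall) built by
    assigning the N pixels closest to the (slightly jittered) center to
    the lumen and the next ring of pixels to the wall, so pixel-count
    areas match the request to within one pixel's area by construction.

    Returns (list of 2D int images, truth DataFrame).
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    rng = np.random.default_rng(seed)
    px_area = pixel_spacing**2
    images, rows = [], []
    for i, (la, va) in enumerate(specs):
        if la < 0 or va < la:
            raise ValueError(f"section {i}: need vessel area >= lumen area >= 0")
        n_lumen = int(round(la / px_area))
        n_vessel = int(round(va / px_area))
        if shape is None:
            r_px = np.sqrt(max(n_vessel, 1) / np.pi)
            side = int(2 * np.ceil(r_px)) + 5
            shp = (side, side)
        else:
            shp = shape
            if n_vessel > shp[0] * shp[1]:
                raise ValueError(f"section {i}: image shape too small")
        cy = (shp[0] - 1) / 2 + rng.uniform(-0.3, 0.3)
        cx = (shp[1] - 1) / 2 + rng.uniform(-0.3, 0.3)
        yy, xx = np.mgrid[0 : shp[0], 0 : shp[1]]
        dist = (yy - cy) ** 2 + (xx - cx) ** 2
        order = np.argsort(dist.ravel(), kind="stable")
        img = np.zeros(shp, dtype=np.int16).ravel()
        img[order[:n_lumen]] = 1
        img[order[n_lumen:n_vessel]] = 2
        img = img.reshape(shp)
        images.append(img)
        rows.append(
            {
                "section_id": i,
                "la_requested": la,
                "va_requested": va,
                "la_rendered": n_lumen * px_area,
                "va_rendered": n_vessel * px_area,
                "wa_rendered": (n_vessel - n_lumen) * px_area,
            }
        )
    return images, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

AETIOLOGIES = ("vasculitis", "atherosclerosis", "moyamoya")
STAGES = ("acute_subacute", "chronic", "none")
FLAG_COLUMNS = (
    "smoking",
    "drinking",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "infection_immune_positive",
)


@dataclass(frozen=True)
class GroupConfig:
    """Per-aetiology group configuration (counts are exact, not rates)."""

    name: str
    n: int
    n_male: int
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    n_age_ge_55: int
    flag_counts: dict  # column -> count of True

    def __post_init__(self) -> None:
        if not 0 <= self.n_male <= self.n:
            raise ValueError(f"{self.name}: n_male out of range")
        if not 0 <= self.n_age_ge_55 <= self.n:
            raise ValueError(f"{self.name}: n_age_ge_55 out of range")
        for col, k in self.flag_counts.items():
            if not 0 <= k <= self.n:
                raise ValueError(f"{self.name}: flag count {col}={k} exceeds group size {self.n}")


# (extent, stenosis category, infarct stage, count) cells of the
# stage-by-stenosis distribution for the vasculitis group
_TABLE_CELLS = (
    ("focal", "mild", "acute_subacute", 2),
    ("focal", "mod_severe", "chronic", 1),
    ("focal", "mod_severe", "none", 2),
    ("segmental", "mod_severe", "acute_subacute", 2),
    ("segmental", "mod_severe", "chronic", 2),
    ("segmental", "mod_severe", "none", 4),
    ("segmental", "occlusion", "acute_subacute", 2),
    ("full_length", "mod_severe", "acute_subacute", 1),
    ("full_length", "mod_severe", "none", 1),
    ("full_length", "occlusion", "acute_subacute", 3),
    ("full_length", "occlusion", "none", 3),
)

# lesion / mirror / follow-up Ktrans (mean, sd) in 1/min by infarct stage;
# follow-up n = how many patients were re-measured at 6 months
_KTRANS_BY_STAGE = {
    "acute_subacute": {"lesion": (0.098, 0.038), "mirror": (0.003, 0.001),
                       "followup": (0.039, 0.014), "followup_n": 10},
    "chronic": {"lesion": (0.044, 0.012), "mirror": (0.003, 0.001),
                "followup": (0.018, 0.009), "followup_n": 2},
    "none": {"lesion": (0.007, 0.001), "mirror": (0.006, 0.002),
             "followup": (0.006, 0.001), "followup_n": 4},
}


def _default_groups() -> tuple[GroupConfig, ...]:
    return (
        GroupConfig(
            "vasculitis", 23, 16, 37.7, 10.2, (16.0, 58.0), 1,
            {"smoking": 15, "drinking": 7, "hypertension": 8, "diabetes": 3,
             "hyperlipidemia": 4, "infection_immune_positive": 18},
        ),
        GroupConfig(
            "atherosclerosis", 10, 6, 50.0, 10.4, (33.0, 68.0), 4,
            {"smoking": 2, "drinking": 3, "hypertension": 7, "diabetes": 4,
             "hyperlipidemia": 5, "infection_immune_positive": 1},
        ),
        GroupConfig(
            "moyamoya", 3, 2, 26.7, 5.0, (21.0, 31.0), 0,
            {"smoking": 1, "drinking": 1, "hypertension": 0, "diabetes": 0,
             "hyperlipidemia": 0, "infection_immune_positive": 0},
        ),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort; defaults reproduce the
    study's printed counts exactly."""

    groups: tuple[GroupConfig, ...] = field(default_factory=_default_groups)
    table_cells: tuple = _TABLE_CELLS
    ktrans_by_stage: dict = field(default_factory=lambda: dict(_KTRANS_BY_STAGE))

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        vasc = next((g for g in self.groups if g.name == "vasculitis"), None)
        if vasc is not None and sum(c for *_, c in self.table_cells) != vasc.n:
            raise ValueError("stage-by-stenosis cells must sum to the vasculitis group size")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(seed: int, config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the patient-level cohort table.

    Count-level fields (group sizes, sex, risk flags, the over-55 count,
    the stage-by-stenosis cells) match the configuration exactly for every
    seed; only the continuous draws (age within its stratum, Ktrans)
    depend on the random state. Identical seed and config give an
    identical table.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    frames = []
    pid = 0
    for g in config.groups:
        rows = {
            "patient_id": [f"P{pid + i + 1:03d}" for i in range(g.n)],
            "aetiology": [g.name] * g.n,
        }
        pid += g.n
        # sex: exact counts, seeded placement
        sex = np.array(["F"] * g.n, dtype=object)
        sex[rng.permutation(g.n)[: g.n_male]] = "M"
        rows["sex"] = sex
        # age: draw within the <55 / >=55 strata so the over-55 count is exact
        lo, hi = g.age_range
        age = np.empty(g.n)
        old_idx = rng.permutation(g.n)[: g.n_age_ge_55]
        young = np.setdiff1d(np.arange(g.n), old_idx)
        if g.n_age_ge_55:
            age[old_idx] = _trunc_normal(rng, g.age_mean, g.age_sd, 55.0, hi, g.n_age_ge_55)
        age[young] = _trunc_normal(
            rng, g.age_mean, g.age_sd, lo, min(hi, 54.9), young.size
        )
        rows["age"] = np.round(age, 1)
        # boolean risk flags: exact counts, independently seeded placement
        for col in FLAG_COLUMNS:
            flag = np.zeros(g.n, dtype=bool)
            k = g.flag_counts.get(col, 0)
            flag[rng.permutation(g.n)[:k]] = True
            rows[col] = flag
        frames.append(pd.DataFrame(rows))
    cohort = pd.concat(frames, ignore_index=True)

    # stage / stenosis assignment
    stage = np.array(["none"] * len(cohort), dtype=object)
    extent = np.array([None] * len(cohort), dtype=object)
    grade = np.array([None] * len(cohort), dtype=object)
    vasc_idx = cohort.index[cohort["aetiology"] == "vasculitis"].to_numpy()
    assignment = []
    for ext, cat, stg, count in config.table_cells:
        assignment += [(ext, cat, stg)] * count
    order = rng.permutation(len(vasc_idx))
    for slot, (ext, cat, stg) in zip(vasc_idx[order], assignment):
        stage[slot] = stg
        extent[slot] = ext
        grade[slot] = (
            cat if cat in ("mild", "occlusion") else rng.choice(["moderate", "severe"])
        )
    # stenosis for the non-vasculitis groups is not tabulated in the study;
    # draw plausible moderate-severe patterns
    other_idx = cohort.index[cohort["aetiology"] != "vasculitis"].to_numpy()
    extent[other_idx] = rng.choice(["focal", "segmental", "full_length"], size=other_idx.size)
    grade[other_idx] = rng.choice(["moderate", "severe"], size=other_idx.size)
    cohort["infarct_stage"] = stage
    cohort["lesion_extent"] = extent
    cohort["stenosis_grade"] = grade

    # Ktrans draws: truncated normals (lower bound 0) at the group summaries
    k_lesion = np.empty(len(cohort))
    k_mirror = np.empty(len(cohort))
    k_follow = np.full(len(cohort), np.nan)
    for stg, params in config.ktrans_by_stage.items():
        idx = vasc_idx[stage[vasc_idx] == stg]
        m, s = params["lesion"]
        k_lesion[idx] = _trunc_normal(rng, m, s, 0.0, np.inf, idx.size)
        m, s = params["mirror"]
        k_mirror[idx] = _trunc_normal(rng, m, s, 0.0, np.inf, idx.size)
        n_fu = min(params.get("followup_n", 0), idx.size)
        fu_idx = rng.permutation(idx)[:n_fu]
        m, s = params["followup"]
        k_follow[fu_idx] = _trunc_normal(rng, m, s, 0.0, np.inf, n_fu)
    # non-vasculitis patients: permeability in the unremarkable range
    k_lesion[other_idx] = _trunc_normal(rng, 0.007, 0.002, 0.0, np.inf, other_idx.size)
    k_mirror[other_idx] = _trunc_normal(rng, 0.003, 0.001, 0.0, np.inf, other_idx.size)
    cohort["ktrans_lesion"] = k_lesion
    cohort["ktrans_mirror"] = k_mirror
    cohort["ktrans_followup"] = k_follow
    return cohort
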