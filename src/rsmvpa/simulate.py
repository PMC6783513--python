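"""Synthetic resting-state cohorts with a recoverable group effect.

The generator emulates a two-group (patient / control) resting-state fMRI
study already in a common space: each subject is a 4D grid of voxel time
series organised into disjoint cuboid "regions".  Every region carries one
latent AR(1) signal shared by its voxels plus independent voxel noise, which
gives high within-region and near-zero between-region correlation.  In
patients an extra latent per (effect-region, partner-region) pair couples
the designated effect region to a fixed set of partner regions, so the
effect region's voxel-wise functional connectivity strength (FCS) rises
strictly above the control expectation while each partner gains only one
coupled pair.  Clinical questionnaire scores are linked linearly to the
subject's realised coupling amplitude, so correlation analyses downstream
have a known ground truth.

Voxels outside every region are written as zeros (background air); the
gray-matter probability map exceeds the masking threshold exactly on the
union of regions, so no analysis stage reads them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import BOLDSeries, default_affine, save_volume

__all__ = [
    "ScoreLink",
    "SimulationConfig",
    "default_region_layout",
    "coupling_amplitude",
    "simulate_subject",
    "simulate_cohort",
    "region_masks",
    "summarize_manifest",
]

PATIENT = "patient"
CONTROL = "control"

#: (patient intercept, control intercept, slope per unit coupling, noise sd)
#: Intercepts follow the questionnaire means of typical primary-insomnia
#: case-control cohorts (ISI ~19 vs ~5, PSQI ~12 vs ~6, SAS ~50 vs ~40,
#: SDS ~55 vs ~40).
DEFAULT_SCORE_LINKS = {
    "ISI": (19.3, 5.4, 1.0, 2.5),
    "PSQI": (12.5, 5.8, 1.0, 2.5),
    "SAS": (50.3, 39.7, 2.0, 6.0),
    "SDS": (55.2, 40.4, 2.0, 6.0),
}


@dataclass(frozen=True)
class ScoreLink:
    """Linear link from a subject's realised coupling to a clinical score."""

    patient_intercept: float
    control_intercept: float
    slope: float
    noise_sd: float


def default_region_layout(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    region_shape: tuple[int, int, int] = (3, 3, 3),
    gap: int = 1,
) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Place ``n_regions`` disjoint cuboid blocks on a regular lattice.

    Blocks of ``region_shape`` voxels are laid out with ``gap`` empty voxels
    between them, starting at offset ``gap`` along each axis, filled in
    C order.  Returns a list of (corner, shape) pairs.
    """
    stride = tuple(s + gap for s in region_shape)
    slots_per_axis = tuple(
        (g - gap) // st for g, st in zip(grid_shape, stride)
    )
    capacity = int(np.prod(slots_per_axis))
    if n_regions > capacity:
        raise ValueError(
            f"cannot place {n_regions} regions of shape {region_shape} on grid "
            f"{grid_shape} (capacity {capacity})"
        )
    layout = []
    for flat in range(n_regions):
        idx = np.unravel_index(flat, slots_per_axis)
        corner = tuple(gap + i * st for i, st in zip(idx, stride))
        layout.append((corner, tuple(region_shape)))
    return layout


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow a 1.5 T resting-state protocol (240 volumes at
    TR = 2.5 s, 3 mm isotropic voxels) with a 38-patient / 44-control
    cohort; the grid is a small 24-cube so a full cohort simulates in
    seconds.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    tr_s: float = 2.5
    n_per_group: tuple[int, int] = (38, 44)  # (patients, controls)
    n_regions: int = 27
    region_shape: tuple[int, int, int] = (3, 3, 3)
    regions: list[tuple[tuple[int, int, int], tuple[int, int, int]]] | None = None
    effect_region: int = 0
    coupled_regions: tuple[int, ...] = (1, 2, 3)
    effect_strength: float = 0.8
    coupling_jitter_sd: float = 0.15
    ar1_coef: float = 0.4
    noise_sd: float = 1.0
    score_links: dict[str, ScoreLink] = field(
        default_factory=lambda: {
            name: ScoreLink(*vals) for name, vals in DEFAULT_SCORE_LINKS.items()
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions is None:
            self.regions = default_region_layout(
                self.grid_shape, self.n_regions, self.region_shape
            )
        else:
            self.regions = [
                (tuple(c), tuple(s)) for c, s in self.regions
            ]
            self.n_regions = len(self.regions)
        if not 0 <= self.effect_region < self.n_regions:
            raise ValueError(
                f"effect_region {self.effect_region} outside region list "
                f"(n_regions={self.n_regions})"
            )
        for p in self.coupled_regions:
            if not 0 <= p < self.n_regions or p == self.effect_region:
                raise ValueError(f"invalid coupled region index {p}")
        if not 0.0 <= self.effect_strength < 1.0:
            raise ValueError("effect_strength must lie in [0, 1)")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self._check_regions_disjoint()

    def _check_regions_disjoint(self) -> None:
        occupancy = np.zeros(self.grid_shape, dtype=np.int32)
        for corner, shape in self.regions:
            sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
            if any(c < 0 or c + s > g for c, s, g in zip(corner, shape, self.grid_shape)):
                raise ValueError(f"region {corner}+{shape} leaves the grid")
            occupancy[sl] += 1
        if occupancy.max() > 1:
            raise ValueError("regions overlap")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def region_masks(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(gray_mask, parcellation) for a config.

    The boolean gray mask is the union of regions; the parcellation labels
    region ``i`` with integer ``i + 1`` (0 = background).
    """
    parc = np.zeros(config.grid_shape, dtype=np.int16)
    for i, (corner, shape) in enumerate(config.regions):
        sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
        parc[sl] = i + 1
    return parc > 0, parc


def coupling_amplitude(config: SimulationConfig) -> float:
    """Latent amplitude ``a`` such that one coupled pair of voxels has
    correlation ``effect_strength`` in the two-region model
    ``a^2 / (1 + a^2 + noise_sd^2) = effect_strength``."""
    rho = config.effect_strength
    if rho == 0.0:
        return 0.0
    return float(np.sqrt(rho * (1.0 + config.noise_sd**2) / (1.0 - rho)))


def _ar1(rng: np.random.Generator, phi: float, n: int, size: int) -> np.ndarray:
    """``size`` independent AR(1) series of length ``n`` with unit marginal
    variance: x_t = phi x_{t-1} + sqrt(1 - phi^2) e_t, x_0 ~ N(0, 1)."""
    e = rng.standard_normal((size, n))
    x = np.empty((size, n))
    x[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + c * e[:, t]
    return x


def _motion_params(rng: np.random.Generator, n: int) -> np.ndarray:
    """Six small smooth random walks (3 translations mm, 3 rotations deg)."""
    steps = rng.standard_normal((n, 6)) * 0.01
    walk = np.cumsum(steps, axis=0)
    # light smoothing so the walk resembles slow head drift
    kernel = np.ones(5) / 5.0
    return np.apply_along_axis(lambda m: np.convolve(m, kernel, mode="same"), 0, walk)


def simulate_subject(
    config: SimulationConfig, group: str, rng: np.random.Generator
) -> tuple[BOLDSeries, np.ndarray, dict[str, float]]:
    """Draw one subject: BOLD series, 6-column motion, clinical scores.

    The control branch consumes the identical random stream as the patient
    branch (coupling latents are drawn but enter with amplitude zero), so at
    ``effect_strength = 0`` seed-matched patients and controls are
    bit-identical — the exchangeability-under-null guarantee.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
    n_t = config.n_timepoints
    phi = config.ar1_coef

    region_latents = _ar1(rng, phi, n_t, config.n_regions)
    pair_latents = _ar1(rng, phi, n_t, len(config.coupled_regions))
    jitter = max(0.0, 1.0 + config.coupling_jitter_sd * rng.standard_normal())
    amp = coupling_amplitude(config)
    coupling = amp * jitter if group == PATIENT else 0.0

    data = np.zeros((*config.grid_shape, n_t))
    for i, (corner, shape) in enumerate(config.regions):
        sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
        n_vox = int(np.prod(shape))
        signal = region_latents[i]
        if i == config.effect_region:
            signal = signal + coupling * pair_latents.sum(axis=0)
        elif i in config.coupled_regions:
            p = config.coupled_regions.index(i)
            signal = signal + coupling * pair_latents[p]
        noise = rng.standard_normal((n_vox, n_t)) * config.noise_sd
        data[sl] = (signal[None, :] + noise).reshape(*shape, n_t)

    motion = _motion_params(rng, n_t)

    scores: dict[str, float] = {}
    for name, link in config.score_links.items():
        intercept = link.patient_intercept if group == PATIENT else link.control_intercept
        scores[name] = intercept + link.slope * coupling + link.noise_sd * rng.standard_normal()
    scores["realized_coupling"] = coupling

    # demographics matched across groups; sleep-architecture fields follow
    # typical severity distributions for patients and healthy values otherwise
    scores["age"] = float(np.clip(40.0 + 9.4 * rng.standard_normal(), 20, 60))
    scores["sex"] = int(rng.random() < (16 / 38 if group == PATIENT else 11 / 44))
    scores["education"] = float(np.clip(8.0 + 4.0 * rng.standard_normal(), 0, 22))
    if group == PATIENT:
        scores["duration"] = float(np.exp(rng.normal(np.log(24.0), 1.0)))
        scores["total_sleep_time"] = float(np.clip(rng.normal(360.0, 45.0), 180, 480))
        scores["SOL"] = float(np.clip(rng.normal(47.0, 29.0), 0, None))
        scores["WASO"] = float(np.clip(rng.normal(60.0, 45.0), 0, None))
    else:
        scores["duration"] = 0.0
        scores["total_sleep_time"] = float(np.clip(rng.normal(450.0, 30.0), 360, 540))
        scores["SOL"] = float(np.clip(rng.normal(10.0, 5.0), 0, None))
        scores["WASO"] = float(np.clip(rng.normal(10.0, 8.0), 0, None))

    series = BOLDSeries(data=data, affine=config.affine, tr_s=config.tr_s)
    return series, motion, scores


MANIFEST_COLUMNS = [
    "id", "path", "motion_path", "group", "age", "sex", "education",
    "ISI", "PSQI", "SAS", "SDS",
    "duration", "total_sleep_time", "SOL", "WASO", "realized_coupling",
]


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, list[BOLDSeries], list[np.ndarray]]:
    """Simulate the full two-group cohort.

    Returns the manifest plus the in-memory series and motion arrays (in
    manifest row order: patients first).  If ``out_dir`` is given, also
    writes one 4D NIfTI and one whitespace-delimited motion file per
    subject, the gray-matter probability map, the integer parcellation, the
    manifest TSV and the config JSON.

    Reproducibility: the whole cohort is a pure function of ``config.seed``.
    """
    n_pat, n_con = config.n_per_group
    groups = [PATIENT] * n_pat + [CONTROL] * n_con
    seq = np.random.SeedSequence(config.seed)
    child_seeds = seq.spawn(len(groups))

    gray_mask, parc = region_masks(config)

    rows = []
    all_series: list[BOLDSeries] = []
    all_motion: list[np.ndarray] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for i, (group, child) in enumerate(zip(groups, child_seeds)):
        rng = np.random.default_rng(child)
        series, motion, scores = simulate_subject(config, group, rng)
        sid = f"sub-{i + 1:03d}"
        path = motion_path = ""
        if out is not None:
            path = str(out / f"{sid}_bold.nii.gz")
            motion_path = str(out / f"{sid}_motion.txt")
            series.save(path)
            np.savetxt(motion_path, motion, fmt="%.6f")
        rows.append({"id": sid, "path": path, "motion_path": motion_path,
                     "group": group, **{k: scores[k] for k in MANIFEST_COLUMNS[4:]}})
        all_series.append(series)
        all_motion.append(motion)

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["id"].duplicated().any():
        raise RuntimeError("duplicate subject ids")

    if out is not None:
        gm_prob = np.where(gray_mask, 0.9, 0.0)
        save_volume(gm_prob, config.affine, out / "gm_prob.nii.gz")
        save_volume(parc, config.affine, out / "parcellation.nii.gz", dtype=np.int16)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        (out / "config.json").write_text(config.to_json())

    return manifest, all_series, all_motion


def summarize_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Table-style cohort summary: per-group mean +/- sd of demographics and
    questionnaire scores with Wilcoxon rank-sum p values (chi-squared for
    sex).  A descriptive utility, not an analysis endpoint."""
    from scipy import stats

    groups = sorted(manifest["group"].unique())
    rows = []
    for col in ["age", "education", "ISI", "PSQI", "SAS", "SDS", "duration"]:
        if col not in manifest.columns:
            continue
        by = [manifest.loc[manifest["group"] == g, col].dropna() for g in groups]
        row = {"variable": col}
        for g, vals in zip(groups, by):
            row[g] = f"{vals.mean():.2f} ± {vals.std():.2f}"
        if len(by) == 2 and all(len(v) > 0 for v in by):
            row["p"] = float(stats.ranksums(by[0], by[1]).pvalue)
        rows.append(row)
    if "sex" in manifest.columns and len(groups) == 2:
        tab = pd.crosstab(manifest["group"], manifest["sex"])
        row = {"variable": "sex (M/F)"}
        for g in groups:
            row[g] = f"{tab.loc[g].get(1, 0)}/{tab.loc[g].get(0, 0)}"
        if tab.shape == (2, 2):
            row["p"] = float(stats.chi2_contingency(tab.to_numpy()).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
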