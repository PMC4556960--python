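"""Seeded synthetic resting-state cohorts with planted connectivity structure.

The generator emits 4D BOLD-like volumes in which designated "hub" regions
carry shared band-limited latent signals, so that every planted pairwise
correlation has a closed form that downstream code can be tested against.

Signal model
------------
Every voxel time series is a unit-variance mixture

    v(t) = sum_k sqrt(c_k) * z_k(t) + sqrt(1 - sum_k c_k) * eta(t)

where the z_k are independent, unit-variance, band-limited latent signals
shared between voxels, eta is the voxel's private (also band-limited) noise,
and the couplings c_k lie in [0, 1] with sum_k c_k <= 1 per voxel.  Two
voxels that share latent k with couplings c and c' then have correlation
exactly sqrt(c * c') (summed over shared latents): a coupling IS the planted
correlation between two equally-coupled voxels.  Because variance is pinned
to one, changing one coupling (e.g. a group-specific multiplier) cannot
perturb unrelated correlations through variance inflation.

Each hub owns one "local" latent shared by all voxels of its region
(seed voxel plus voxels within ``region_radius_mm``).  Each coupled hub
pair owns two "pair" latents, assigned to region voxels by the parity of
i+j+k (a 3D checkerboard): on a 3 mm grid the only voxel pairs within the
3 mm local radius are face neighbours, which always have opposite parity,
so distant (pair) coupling never contributes to local correlations.

All latents and noise are band-limited strictly inside the analysis
passband (default 0.015-0.075 Hz), so the bandpass stage of preprocessing
preserves the planted correlation structure and is variance-neutral.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .images import BoldImage, FcdPipeError, MotionTrace

GROUPS = ("control", "nonHE", "MHE")
ROLES = ("cortical", "subcortical")


@dataclass(frozen=True)
class Hub:
    """A planted hub: seed voxel index triple and a role tag."""

    seed: tuple[int, int, int]
    role: str  # 'cortical' or 'subcortical'

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FcdPipeError(f"hub role must be one of {ROLES}, got {self.role!r}")


@dataclass
class ConnectivitySpec:
    """Geometry and planted-correlation parameters of a synthetic scan.

    ``local_coupling`` may be a scalar (all hubs) or a per-hub sequence;
    ``distant_coupling`` likewise per hub pair.  ``hub_pairs`` lists index
    pairs into ``hub_seeds``; both hubs of a pair must share a role, and
    their seeds must be farther apart than ``distant_radius_mm`` whenever
    the pair's coupling is nonzero (otherwise the planted effect would fall
    into the distance band excluded from both local and distant maps).
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    n_volumes: int = 250
    tr_s: float = 2.0
    hub_seeds: list[Hub] = field(default_factory=list)
    hub_pairs: list[tuple[int, int]] = field(default_factory=list)
    local_coupling: float | list[float] = 0.5
    distant_coupling: float | list[float] = 0.35
    noise_sd: float = 1.0
    region_radius_mm: float = 3.0
    distant_radius_mm: float = 25.0
    latent_band_hz: tuple[float, float] = (0.015, 0.075)
    motion_walk_sd_mm: float = 0.02
    motion_walk_sd_deg: float = 0.02
    motion_spike_rate: float = 0.01
    motion_spike_mm: float = 0.4

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise FcdPipeError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_volumes < 2:
            raise FcdPipeError("n_volumes must be >= 2")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0 or self.noise_sd <= 0:
            raise FcdPipeError("voxel_size_mm, tr_s and noise_sd must be positive")
        for h in self.hub_seeds:
            if any(not (0 <= h.seed[a] < self.grid_shape[a]) for a in range(3)):
                raise FcdPipeError(f"hub seed {h.seed} lies outside grid {self.grid_shape}")
        for i, j in self.hub_pairs:
            if not (0 <= i < len(self.hub_seeds) and 0 <= j < len(self.hub_seeds)):
                raise FcdPipeError(f"hub pair ({i}, {j}) indexes outside hub_seeds")
            if self.hub_seeds[i].role != self.hub_seeds[j].role:
                raise FcdPipeError("hubs of a coupled pair must share a role tag")
        for c in np.atleast_1d(self.local_couplings()):
            if not 0 <= c <= 1:
                raise FcdPipeError(f"local coupling {c} outside [0, 1]")
        for c in np.atleast_1d(self.distant_couplings()):
            if not 0 <= c <= 1:
                raise FcdPipeError(f"distant coupling {c} outside [0, 1]")
        lo, hi = self.latent_band_hz
        if not (0 <= lo < hi <= 0.5 / self.tr_s):
            raise FcdPipeError("latent band must satisfy 0 <= low < high <= Nyquist")

    def local_couplings(self) -> np.ndarray:
        c = self.local_coupling
        if np.isscalar(c):
            return np.full(len(self.hub_seeds), float(c))
        c = np.asarray(c, float)
        if len(c) != len(self.hub_seeds):
            raise FcdPipeError("per-hub local_coupling length mismatch")
        return c

    def distant_couplings(self) -> np.ndarray:
        c = self.distant_coupling
        if np.isscalar(c):
            return np.full(len(self.hub_pairs), float(c))
        c = np.asarray(c, float)
        if len(c) != len(self.hub_pairs):
            raise FcdPipeError("per-pair distant_coupling length mismatch")
        return c

    def region_members(self, hub_index: int) -> list[tuple[int, int, int]]:
        """Voxels within region_radius_mm of the hub seed (incl. the seed)."""
        seed = np.array(self.hub_seeds[hub_index].seed)
        r_vox = self.region_radius_mm / self.voxel_size_mm
        reach = int(np.floor(r_vox))
        members = []
        for off in itertools.product(range(-reach, reach + 1), repeat=3):
            if np.dot(off, off) > r_vox * r_vox + 1e-12:
                continue
            v = seed + off
            if all(0 <= v[a] < self.grid_shape[a] for a in range(3)):
                members.append(tuple(int(x) for x in v))
        return members


@dataclass
class GroupEffects:
    """Group-specific multipliers applied to planted couplings.

    Both patient groups share a local-coupling multiplier (the cirrhosis
    effect); only the MHE group additionally rescales distant couplings,
    with opposite directions for cortical (decrease) and subcortical
    (increase) hub pairs.
    """

    group: str = "control"
    local_coupling_multiplier: float = 1.0
    distant_cortical_multiplier: float = 1.0
    distant_subcortical_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FcdPipeError(f"group must be one of {GROUPS}")
        mults = (self.local_coupling_multiplier, self.distant_cortical_multiplier,
                 self.distant_subcortical_multiplier)
        if any(m < 0 for m in mults):
            raise FcdPipeError("multipliers must be >= 0")
        if self.group == "control" and any(m != 1.0 for m in mults):
            raise FcdPipeError("control multipliers must all equal 1")

    def distant_multiplier(self, role: str) -> float:
        return (self.distant_cortical_multiplier if role == "cortical"
                else self.distant_subcortical_multiplier)


# --------------------------------------------------------------------------
# coupling bookkeeping

def _coupling_map(spec: ConnectivitySpec, effects: GroupEffects) -> dict:
    """Map voxel -> {latent id -> coupling c} after applying group effects.

    Latent ids: ('local', hub_index) and ('pair', pair_index, parity).
    """
    out: dict[tuple[int, int, int], dict[tuple, float]] = {}
    local_c = spec.local_couplings() * effects.local_coupling_multiplier
    for h, hub in enumerate(spec.hub_seeds):
        c = float(local_c[h])
        if not 0 <= c <= 1:
            raise FcdPipeError(f"effective local coupling {c} outside [0, 1] for hub {h}")
        if c == 0:
            continue
        for v in spec.region_members(h):
            out.setdefault(v, {})[("local", h)] = c
    dist_c = spec.distant_couplings()
    for p, (i, j) in enumerate(spec.hub_pairs):
        role = spec.hub_seeds[i].role
        c = float(dist_c[p]) * effects.distant_multiplier(role)
        if not 0 <= c <= 1:
            raise FcdPipeError(f"effective distant coupling {c} outside [0, 1] for pair {p}")
        if c == 0:
            continue
        d_mm = np.linalg.norm(
            (np.array(spec.hub_seeds[i].seed) - np.array(spec.hub_seeds[j].seed))
            * spec.voxel_size_mm
        )
        if d_mm <= spec.distant_radius_mm:
            raise FcdPipeError(
                f"hub pair {p} seeds are {d_mm:.1f} mm apart but a distant effect "
                f"is requested; pairs must exceed {spec.distant_radius_mm} mm so the "
                "planted correlations do not fall in the excluded gap band"
            )
        for h in (i, j):
            for v in spec.region_members(h):
                parity = (v[0] + v[1] + v[2]) % 2
                out.setdefault(v, {})[("pair", p, parity)] = c
    for v, cs in out.items():
        if sum(cs.values()) > 1 + 1e-12:
            raise FcdPipeError(
                f"total coupling {sum(cs.values()):.3f} at voxel {v} exceeds 1; "
                "reduce couplings or multipliers"
            )
    return out


def expected_correlation(
    spec: ConnectivitySpec, effects: GroupEffects,
    voxel_a: tuple[int, int, int], voxel_b: tuple[int, int, int],
) -> float:
    """Closed-form planted correlation between two voxels' time series.

    Equals sum over shared latents of sqrt(c_a * c_b); 0 for voxels with no
    shared latent.  This is exact for the mixture model (unit variances).
    """
    cmap = _coupling_map(spec, effects)
    ca = cmap.get(tuple(voxel_a), {})
    cb = cmap.get(tuple(voxel_b), {})
    return float(sum(np.sqrt(ca[k] * cb[k]) for k in ca.keys() & cb.keys()))


# --------------------------------------------------------------------------
# signal generation

def _bandlimit_unit(x: np.ndarray, tr_s: float, band: tuple[float, float]) -> np.ndarray:
    """Restrict each row of x to the band (rFFT boxcar) and standardize to
    zero mean, unit variance."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not keep.any():
        raise FcdPipeError(f"no DFT bins inside band {band} at n={n}, TR={tr_s}")
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0
    y = np.fft.irfft(spec, n=n, axis=-1)
    y -= y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise FcdPipeError("degenerate band-limited series (zero variance)")
    return y / sd


def simulate_motion(spec: ConnectivitySpec, seed) -> MotionTrace:
    """Random-walk motion parameters with occasional spikes."""
    rng = np.random.default_rng(seed)
    t = spec.n_volumes
    trans = np.cumsum(rng.normal(0, spec.motion_walk_sd_mm, (t, 3)), axis=0)
    rot = np.cumsum(rng.normal(0, spec.motion_walk_sd_deg, (t, 3)), axis=0)
    spikes = rng.random(t) < spec.motion_spike_rate
    for idx in np.nonzero(spikes)[0]:
        axis = rng.integers(0, 3)
        sign = 1 if rng.random() < 0.5 else -1
        trans[idx, axis] += sign * spec.motion_spike_mm
    return MotionTrace(trans, rot)


def simulate_subject_bold(
    spec: ConnectivitySpec, effects: GroupEffects, seed,
) -> tuple[BoldImage, MotionTrace]:
    """Generate one subject's 4D volume and motion trace, deterministically.

    The same (spec, effects, seed) always yields bit-identical output.
    """
    ss = np.random.SeedSequence(seed)
    bold_ss, motion_ss = ss.spawn(2)
    rng = np.random.default_rng(bold_ss)

    cmap = _coupling_map(spec, effects)
    latent_ids = sorted({k for cs in cmap.values() for k in cs}, key=repr)
    t = spec.n_volumes

    latents = {}
    for lid in latent_ids:
        z = rng.standard_normal((1, t))
        latents[lid] = _bandlimit_unit(z, spec.tr_s, spec.latent_band_hz)[0]

    shape = spec.grid_shape
    n_vox = int(np.prod(shape))
    noise = rng.standard_normal((n_vox, t))
    noise = _bandlimit_unit(noise, spec.tr_s, spec.latent_band_hz)
    data = noise.reshape(shape + (t,))

    for v, cs in cmap.items():
        total_c = sum(cs.values())
        series = np.sqrt(max(0.0, 1.0 - total_c)) * data[v]
        for lid, c in cs.items():
            series = series + np.sqrt(c) * latents[lid]
        data[v] = series
    data *= spec.noise_sd

    bold = BoldImage(
        data=data, voxel_size_mm=(spec.voxel_size_mm,) * 3, tr_s=spec.tr_s,
        brain_mask=np.ones(shape, dtype=bool),
        provenance=[f"synthesized(seed={seed})"],
    )
    return bold, simulate_motion(spec, motion_ss)


# --------------------------------------------------------------------------
# cohorts

@dataclass
class PhenotypeParams:
    """Normal-distribution parameters for one group's phenotype columns."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    male_fraction: float
    nct_a_mean: float
    nct_a_sd: float
    dst_mean: float
    dst_sd: float
    ammonia_mean: float | None = None
    ammonia_sd: float | None = None

    def __post_init__(self) -> None:
        sds = [self.age_sd, self.education_sd, self.nct_a_sd, self.dst_sd]
        if self.ammonia_sd is not None:
            sds.append(self.ammonia_sd)
        if any(s <= 0 for s in sds):
            raise FcdPipeError("phenotype SDs must be positive")
        if not 0 <= self.male_fraction <= 1:
            raise FcdPipeError("male_fraction must lie in [0, 1]")


#: Published cohort summaries used as generator defaults (healthy controls
#: and cirrhotic patients; both patient groups draw from the patient row).
CONTROL_PHENOTYPES = PhenotypeParams(
    age_mean=47.43, age_sd=10.09, education_mean=10.97, education_sd=3.18,
    male_fraction=72 / 103, nct_a_mean=44.06, nct_a_sd=10.66,
    dst_mean=46.83, dst_sd=12.51,
)
PATIENT_PHENOTYPES = PhenotypeParams(
    age_mean=47.99, age_sd=10.27, education_mean=10.45, education_sd=3.11,
    male_fraction=81 / 103, nct_a_mean=54.38, nct_a_sd=20.02,
    dst_mean=35.52, dst_sd=11.80, ammonia_mean=53.34, ammonia_sd=34.34,
)

DEFAULT_PHENOTYPES = {
    "control": CONTROL_PHENOTYPES,
    "nonHE": PATIENT_PHENOTYPES,
    "MHE": PATIENT_PHENOTYPES,
}


@dataclass
class SubjectRecord:
    """One phenotype row of a cohort."""

    subject_id: str
    group: str
    age_y: float
    sex: str  # 'M' or 'F'
    education_y: float
    nct_a_s: float
    dst_score: float
    ammonia_umol_l: float | None = None
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0
    n_motion_spikes: int = 0
    included: bool = True

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FcdPipeError(f"group must be one of {GROUPS}")
        if self.sex not in ("M", "F"):
            raise FcdPipeError("sex must be 'M' or 'F'")
        if self.age_y < 0 or self.education_y < 0:
            raise FcdPipeError("age and education must be nonnegative")


def default_hub_layout(grid_shape, voxel_size_mm: float = 3.0, margin: int = 1):
    """Six hubs: one subcortical and one cortical coupled pair on opposite
    space diagonals (guaranteeing >25 mm seed separation on desk-scale
    grids) plus two uncoupled cortical hubs at opposite face centers
    (away from grid corners, so their regions are not clipped)."""
    hi = tuple(s - 1 - margin for s in grid_shape)
    lo = (margin,) * 3
    mid = tuple(s // 2 for s in grid_shape)
    hubs = [
        Hub((lo[0], lo[1], lo[2]), "subcortical"),
        Hub((hi[0], hi[1], hi[2]), "subcortical"),
        Hub((hi[0], lo[1], lo[2]), "cortical"),
        Hub((lo[0], hi[1], hi[2]), "cortical"),
        Hub((mid[0], mid[1], lo[2]), "cortical"),
        Hub((mid[0], mid[1], hi[2]), "cortical"),
    ]
    pairs = [(0, 1), (2, 3)]
    return hubs, pairs


@dataclass
class CohortConfig:
    """Everything needed to draw a cohort: group sizes, scan spec, group
    effects, and per-group phenotype distributions."""

    group_sizes: dict = field(default_factory=lambda: {"control": 8, "nonHE": 8, "MHE": 8})
    spec: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    effects: dict = field(default_factory=lambda: {g: GroupEffects(group=g) for g in GROUPS})
    phenotypes: dict = field(default_factory=lambda: dict(DEFAULT_PHENOTYPES))

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise FcdPipeError(f"unknown group {g!r}")
            if n < 2:
                raise FcdPipeError(f"group {g} needs >= 2 subjects, got {n}")


class Cohort:
    """A drawn cohort: eager phenotype records and motion traces, lazy BOLD.

    BOLD volumes are regenerated deterministically from per-subject seeds on
    each access, so arbitrarily large cohorts never need to fit in memory.
    """

    def __init__(self, config: CohortConfig, seed):
        from .preprocess import count_motion_spikes, motion_excluded

        self.config = config
        self.seed = seed
        root = np.random.SeedSequence(seed)
        groups = [g for g in GROUPS if g in config.group_sizes]
        n_total = sum(config.group_sizes[g] for g in groups)
        # one uint32 stream seed per subject for BOLD+motion, one for phenotypes
        state = root.generate_state(n_total + 1, dtype=np.uint32) & 0x7FFFFFFF
        pheno_rng = np.random.default_rng(int(state[-1]))

        self.records: list[SubjectRecord] = []
        self._subject_seeds: list[int] = []
        self.motion: list[MotionTrace] = []
        idx = 0
        for g in groups:
            params = config.phenotypes[g]
            for _ in range(config.group_sizes[g]):
                sid = f"sub-{idx + 1:03d}"
                subject_seed = int(state[idx])
                self._subject_seeds.append(subject_seed)
                _, motion_ss = np.random.SeedSequence(subject_seed).spawn(2)
                trace = simulate_motion(config.spec, motion_ss)
                amm = (
                    float(pheno_rng.normal(params.ammonia_mean, params.ammonia_sd))
                    if params.ammonia_mean is not None else None
                )
                rec = SubjectRecord(
                    subject_id=sid, group=g,
                    age_y=max(18.0, float(pheno_rng.normal(params.age_mean, params.age_sd))),
                    sex="M" if pheno_rng.random() < params.male_fraction else "F",
                    education_y=max(0.0, float(pheno_rng.normal(params.education_mean,
                                                                params.education_sd))),
                    nct_a_s=float(pheno_rng.normal(params.nct_a_mean, params.nct_a_sd)),
                    dst_score=float(pheno_rng.normal(params.dst_mean, params.dst_sd)),
                    ammonia_umol_l=amm,
                    max_translation_mm=float(np.abs(trace.translations_mm).max()),
                    max_rotation_deg=float(np.abs(trace.rotations_deg).max()),
                    n_motion_spikes=count_motion_spikes(trace, 0.5),
                    included=not motion_excluded(trace),
                )
                self.records.append(rec)
                self.motion.append(trace)
                idx += 1

    def __len__(self) -> int:
        return len(self.records)

    def bold(self, i: int) -> BoldImage:
        """Regenerate subject i's BOLD volume (deterministic)."""
        rec = self.records[i]
        effects = self.config.effects[rec.group]
        bold, _ = simulate_subject_bold(self.config.spec, effects, self._subject_seeds[i])
        return bold

    def phenotype_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id, "group": r.group, "age": r.age_y,
                "sex": r.sex, "education": r.education_y, "nct_a": r.nct_a_s,
                "dst": r.dst_score,
                "ammonia": r.ammonia_umol_l if r.ammonia_umol_l is not None else np.nan,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir, write_bold: bool = True) -> None:
        """Write phenotype TSV, motion TSVs, and (optionally) NIfTI volumes."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.phenotype_frame().to_csv(
            out / "participants.tsv", sep="\t", index=False, float_format="%.4f"
        )
        for i, rec in enumerate(self.records):
            self.motion[i].to_tsv(out / f"{rec.subject_id}_motion.tsv")
            if write_bold:
                self.bold(i).save(out / f"{rec.subject_id}_bold.nii.gz")
        if write_bold and self.records:
            self.bold(0).save(out / "template_bold.nii.gz",
                              mask_path=out / "brain_mask.nii.gz")


def simulate_cohort(config: CohortConfig, seed, out_dir=None) -> Cohort:
    """Draw a cohort; optionally write TSV/NIfTI fixtures to out_dir."""
    cohort = Cohort(config, seed)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


# --------------------------------------------------------------------------
# psychometric classification

@dataclass(frozen=True)
class ControlNorms:
    """Age-matched control means and SDs for the two psychometric tests."""

    nct_a_mean: float
    nct_a_sd: float
    dst_mean: float
    dst_sd: float

    def __post_init__(self) -> None:
        if self.nct_a_sd <= 0 or self.dst_sd <= 0:
            raise FcdPipeError("control SDs must be positive")


def classify_mhe(nct_a: float, dst: float, norms: ControlNorms) -> bool:
    """Minimal-HE call: abnormal (> 2 SD beyond the control mean, in the
    impaired direction) on at least one test.

    NCT-A is a completion time (larger = worse), so impairment is
    nct_a > mean + 2 SD; DST is a score (larger = better), so impairment is
    dst < mean - 2 SD.  Both inequalities are strict.
    """
    if nct_a is None or dst is None or np.isnan(nct_a) or np.isnan(dst):
        raise FcdPipeError("classify_mhe requires both NCT-A and DST scores")
    slow = nct_a > norms.nct_a_mean + 2 * norms.nct_a_sd
    low = dst < norms.dst_mean - 2 * norms.dst_sd
    return bool(slow or low)
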