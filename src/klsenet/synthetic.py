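"""Phantom atlases and age-parameterized synthetic PET cohorts.

Real normalized FDG-uptake volumes are not publicly distributable, so this
module generates phantom data with the statistical structure the KLSE
pipeline assumes: a 100-parcel atlas grouped into 8 intrinsic functional
networks, and per-subject voxel intensity volumes whose *inter-parcel mean
dispersion* grows with age in designated networks.  Growing dispersion
means growing pairwise Kullback-Leibler divergence between parcel intensity
distributions, hence falling KLS connectivity strength - the generative
mechanism behind an aging metabolic network.

Generative model for a subject of age ``a``:

    voxel values of parcel p  ~  Normal(mu_p, sigma_p) truncated at 0
    mu_p = 1 + delta_p * s_g(a) * exp(eps)

where ``delta_p`` is the parcel's fixed offset from the global mean uptake,
``s_g(a)`` is the per-network dispersion scale (constant, linear or
quadratic in age) and ``eps ~ Normal(0, subject_sd)`` is a subject- and
network-level scatter (inter-subject variability of the regional uptake
pattern; regional rather than global, since a global factor would largely
be absorbed by grey-matter normalization).  After generation the volume is
recentred so the mean over labelled voxels equals 1, mimicking
grey-matter-normalized uptake.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas
from .exceptions import CapacityError, InputError

__all__ = [
    "DEFAULT_NETWORK_SIZES",
    "AFFECTED_NETWORKS",
    "NULL_NETWORKS",
    "PhantomSpec",
    "AgeEffect",
    "AgeEffectModel",
    "SyntheticSubject",
    "build_phantom_atlas",
    "sample_cohort_ages",
    "simulate_subject",
    "simulate_cohort",
    "analytic_kls_gaussian",
    "aging_effect_model",
    "null_effect_model",
]

#: Parcel counts of the 8 intrinsic functional networks of the 100-parcel
#: functional cortical parcellation (frontoparietal + 7 subnetworks).
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "visual": 13,
    "somatomotor": 14,
    "dorsal_attention": 13,
    "ventral_attention": 14,
    "limbic": 5,
    "control": 16,
    "default_mode": 21,
    "frontoparietal": 4,
}

#: Networks carrying an age effect in the default aging scenario.
AFFECTED_NETWORKS = ("default_mode", "control", "dorsal_attention", "ventral_attention", "frontoparietal")
#: Networks left age-flat in the default aging scenario.
NULL_NETWORKS = ("somatomotor", "limbic", "visual")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a phantom atlas.

    ``base_mean_sd`` is the standard deviation of the per-parcel offsets
    delta_p (drawn once, deterministically, from ``seed``); ``base_sd`` is
    the within-parcel voxel standard deviation sigma_p.  Explicit per-parcel
    arrays may be supplied instead via ``base_mean``/``base_sd_per_parcel``.
    """

    volume_shape: tuple[int, int, int] = (44, 44, 44)
    parcel_voxel_count: int = 800
    network_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_NETWORK_SIZES))
    base_mean_sd: float = 0.05
    base_sd: float = 0.10
    base_mean: np.ndarray | None = None
    base_sd_per_parcel: np.ndarray | None = None
    min_voxels: int = 800
    seed: int = 0

    @property
    def n_parcels(self) -> int:
        return int(sum(self.network_sizes.values()))


@dataclass(frozen=True)
class AgeEffect:
    """Dispersion scale s(age) = a + b*age + c*age^2 for one network."""

    kind: str = "none"  # none | linear | quadratic
    a: float = 1.0
    b: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "quadratic"):
            raise InputError(f"unknown effect kind {self.kind!r}")
        if self.kind == "none" and (self.b != 0.0 or self.c != 0.0):
            raise InputError("effect kind 'none' requires b = c = 0")
        if self.kind == "linear" and self.c != 0.0:
            raise InputError("linear effect requires c = 0")

    def scale(self, age: float) -> float:
        return self.a + self.b * age + self.c * age * age


@dataclass(frozen=True)
class AgeEffectModel:
    """Per-network age effects plus the subject-level noise model.

    ``subject_sd`` is the sd of the lognormal subject factor exp(eps)
    applied to the dispersion scale; one independent factor is drawn per
    functional network of each subject.
    """

    effects: dict[str, AgeEffect] = field(default_factory=dict)
    subject_sd: float = 0.12

    def effect_for(self, network: str) -> AgeEffect:
        return self.effects.get(network, AgeEffect())


@dataclass
class SyntheticSubject:
    subject_id: str
    age: float
    volume: np.ndarray


def aging_effect_model(
    kind: str = "linear",
    growth: float = 0.5,
    affected: tuple[str, ...] = AFFECTED_NETWORKS,
    subject_sd: float = 0.12,
    vertex: float = 45.0,
) -> AgeEffectModel:
    """Aging scenario for the designated networks.

    ``kind="linear"``: the dispersion scale grows linearly from 1.0 at age
    20 to 1 + ``growth`` at age 80, so KLS strength declines monotonically.
    ``kind="quadratic"``: s(age) = 1 + c*(age - vertex)^2 with the minimum
    at mid-life (``vertex``, default 45 y) and s(80) = 1 + ``growth`` -
    strength then follows an inverted U peaking in middle age with an
    accelerating late-life decline, the trajectory quadratic age models
    describe.  Networks not listed in ``affected`` stay flat.
    """
    if kind == "linear":
        b = growth / 60.0
        eff = AgeEffect("linear", a=1.0 - 20.0 * b, b=b)
    elif kind == "quadratic":
        c = growth / (80.0 - vertex) ** 2
        eff = AgeEffect("quadratic", a=1.0 + c * vertex**2, b=-2.0 * c * vertex, c=c)
    else:
        raise InputError(f"unknown scenario kind {kind!r}")
    return AgeEffectModel({n: eff for n in affected}, subject_sd=subject_sd)


def null_effect_model(subject_sd: float = 0.12) -> AgeEffectModel:
    """All networks age-flat (type-I-error scenario)."""
    return AgeEffectModel({}, subject_sd=subject_sd)


def build_phantom_atlas(spec: PhantomSpec | None = None) -> ParcellationAtlas:
    """Lay out ``n_parcels`` contiguous blocks of equal voxel count.

    Parcels are flat contiguous runs in a rectangular volume - the KLSE
    connectivity math never uses spatial adjacency, so no anatomical
    geometry is emulated.  Labels are 1..N; remaining voxels are background.
    """
    spec = spec or PhantomSpec()
    n_parcels = spec.n_parcels
    n_vox = int(np.prod(spec.volume_shape))
    needed = n_parcels * spec.parcel_voxel_count
    if needed > n_vox:
        raise CapacityError(
            f"volume {spec.volume_shape} has {n_vox} voxels; "
            f"{n_parcels} parcels x {spec.parcel_voxel_count} voxels need {needed}"
        )
    if spec.parcel_voxel_count < spec.min_voxels:
        raise InputError(
            f"parcel_voxel_count {spec.parcel_voxel_count} below min_voxels {spec.min_voxels}"
        )
    flat = np.zeros(n_vox, dtype=np.int32)
    for p in range(n_parcels):
        start = p * spec.parcel_voxel_count
        flat[start : start + spec.parcel_voxel_count] = p + 1

    rng = np.random.default_rng(spec.seed)
    if spec.base_mean is not None:
        delta = np.asarray(spec.base_mean, dtype=float)
        if len(delta) != n_parcels:
            raise InputError("base_mean length must equal parcel count")
    else:
        delta = rng.normal(0.0, spec.base_mean_sd, n_parcels)
    if spec.base_sd_per_parcel is not None:
        sigma = np.asarray(spec.base_sd_per_parcel, dtype=float)
        if len(sigma) != n_parcels:
            raise InputError("base_sd_per_parcel length must equal parcel count")
    else:
        sigma = np.full(n_parcels, float(spec.base_sd))
    if np.any(sigma <= 0):
        raise InputError("base_sd must be positive")

    rows = []
    pid = 1
    for network, size in spec.network_sizes.items():
        for k in range(size):
            rows.append(
                {
                    "parcel_id": pid,
                    "parcel_name": f"{network}_{k + 1:02d}",
                    "network": network,
                    "base_mean": delta[pid - 1],
                    "base_sd": sigma[pid - 1],
                }
            )
            pid += 1
    parcels = pd.DataFrame(rows)
    return ParcellationAtlas(flat.reshape(spec.volume_shape), parcels)


def sample_cohort_ages(n: int, age_range: tuple[float, float] = (20.0, 82.0), seed: int = 0) -> np.ndarray:
    """Draw ``n`` ages uniformly over ``age_range`` (reproducible)."""
    lo, hi = float(age_range[0]), float(age_range[1])
    if n < 1:
        raise InputError("n must be >= 1")
    if hi < lo:
        raise InputError(f"empty age range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, n)


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at 0 by re-draw (no point mass at 0)."""
    x = rng.normal(mu, sd, size)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = x < 0
    return x


def simulate_subject(
    atlas: ParcellationAtlas,
    age: float,
    effects: AgeEffectModel,
    seed: int,
    subject_id: str = "sub-000",
) -> SyntheticSubject:
    """Generate one subject's intensity volume.

    Requires a phantom atlas whose parcel table carries ``base_mean`` and
    ``base_sd``.  The output volume has global mean 1 over labelled voxels.
    """
    for col in ("base_mean", "base_sd"):
        if col not in atlas.parcels.columns:
            raise InputError(f"atlas parcel table lacks generative column {col!r}")
    if (atlas.parcels["base_sd"] <= 0).any():
        raise InputError("base_sd must be positive for every parcel")

    rng = np.random.default_rng(seed)
    networks = list(dict.fromkeys(atlas.parcels["network"]))
    if effects.subject_sd > 0:
        eps = rng.normal(0.0, effects.subject_sd, len(networks))
    else:
        eps = np.zeros(len(networks))
    net_factor = dict(zip(networks, np.exp(eps)))

    vol = np.zeros(atlas.labels.shape, dtype=float)
    flat = atlas.labels.ravel()
    out = vol.ravel()
    for row in atlas.parcels.itertuples(index=False):
        s = effects.effect_for(row.network).scale(age)
        mu = 1.0 + row.base_mean * s * net_factor[row.network]
        idx = np.flatnonzero(flat == row.parcel_id)
        out[idx] = _truncated_normal(rng, mu, row.base_sd, idx.size)
    labelled = flat > 0
    m = out[labelled].mean()
    if m <= 0:
        raise InputError("degenerate subject volume (nonpositive mean)")
    out[labelled] /= m
    return SyntheticSubject(subject_id, float(age), vol)


def simulate_cohort(
    atlas: ParcellationAtlas,
    effects: AgeEffectModel,
    n_subjects: int = 67,
    age_range: tuple[float, float] = (20.0, 82.0),
    seed: int = 0,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Simulate a cohort; returns subjects plus a cohort table.

    The cohort table has columns ``subject_id, age, seed`` where ``seed`` is
    the per-subject generator seed derived deterministically from the cohort
    seed.  The age stream and the per-subject noise streams are spawned as
    independent child sequences of the cohort seed so they share no
    initialization entropy.
    """
    age_ss, subj_ss = np.random.SeedSequence(seed).spawn(2)
    ages = sample_cohort_ages(n_subjects, age_range, int(age_ss.generate_state(1)[0] % (2**31)))
    child_seeds = subj_ss.generate_state(n_subjects) % (2**31)
    subjects = []
    rows = []
    for i, (age, s) in enumerate(zip(ages, child_seeds)):
        sid = f"sub-{i + 1:03d}"
        subjects.append(simulate_subject(atlas, age, effects, int(s), subject_id=sid))
        rows.append({"subject_id": sid, "age": float(age), "seed": int(s)})
    return subjects, pd.DataFrame(rows)


def analytic_kls_gaussian(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Closed-form KLS between two Gaussians (test oracle).

    KL(P||Q) = ln(s2/s1) + (s1^2 + (m1-m2)^2) / (2 s2^2) - 1/2 for normals;
    the similarity is exp(-(KL(P||Q) + KL(Q||P))).  For equal sds this
    reduces to exp(-(dmu/sd)^2).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("standard deviations must be positive")
    d2 = (mu1 - mu2) ** 2
    kl_pq = np.log(sd2 / sd1) + (sd1**2 + d2) / (2.0 * sd2**2) - 0.5
    kl_qp = np.log(sd1 / sd2) + (sd2**2 + d2) / (2.0 * sd1**2) - 0.5
    return float(np.exp(-(kl_pq + kl_qp)))
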