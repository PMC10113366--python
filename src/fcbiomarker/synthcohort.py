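"""Synthetic cohorts for the StD-classifier pipeline.

Real resting-state cohorts for subthreshold depression (StD) are not openly
deposited, so this module generates cohorts with the statistical structure the
downstream analysis assumes: two groups (StD / healthy controls) whose
inter-regional coupling differs on a small, known set of edges, nuisance
covariates (age, sex) that shift other edges, BDI-II item scores consistent
with the group definitions (StD total >= 13, HC total < 8), and an EROS
reward-responsiveness score negatively coupled to the BDI anhedonic subscore.

Two generation routes are provided:

* :func:`generate_fc_dataset` draws per-subject Fisher-z FC vectors directly
  around the group means — the fast route for exercising the classifier.
* :func:`generate_timeseries` synthesises per-subject ROI time series as an
  AR(1)-filtered multivariate Gaussian whose stationary correlation matrix is
  the (SPD-projected) subject target, plus additive confound components and a
  head-motion trace with step-like spikes — the route that exercises the full
  preprocessing chain.

Ground truth (which edges discriminate, and by how much) is returned alongside
so recovery can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import FCDataset, edge_id, n_edges

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "CohortError",
    "generate_cohort",
    "generate_fc_dataset",
    "generate_timeseries",
    "nearest_spd",
    "ANHEDONIA_ITEMS",
]

# BDI-II anhedonic subscore items (1-based, as printed on the inventory):
# #4 loss of pleasure, #12 loss of interest, #15 loss of energy, #21 loss of
# sex drive.
ANHEDONIA_ITEMS = (4, 12, 15, 21)


class CohortError(ValueError):
    """Raised when a cohort specification or generation step is invalid."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the training cohort the classifier was designed around:
    30 StD subjects vs 61 healthy controls, 137 cortical/subcortical regions
    (9316 edges), late-adolescent ages, BDI-II bands of 16.8 +/- 3.5 (StD) and
    3.0 +/- 1.9 (HC), and an anhedonia–EROS coupling of -0.5.

    ``discriminative_edges`` lists (i, j, delta_z): the StD-minus-HC group
    difference in Fisher-z coupling on edge (i, j).  ``nuisance_effects``
    lists ((i, j), covariate, slope): a per-unit shift of that edge's z value
    with the named covariate ("age" in years about the cohort centre, or
    "sex" coded male=+0.5 / female=-0.5).
    """

    n_std: int = 30
    n_hc: int = 61
    n_regions: int = 137
    n_frames: int = 240
    tr: float = 2.5
    discriminative_edges: list = field(default_factory=list)
    nuisance_effects: list = field(default_factory=list)
    ar_coef: float = 0.3
    motion_spike_rate: float = 0.0
    motion_spike_mm: float = 1.0
    seed: int = 0
    # second-order structure
    base_z_sd: float = 0.10      # spread of the shared baseline coupling (z)
    # subject-level heterogeneity of edge coupling (z scale), on top of the
    # Fisher-z sampling noise ~1/sqrt(n_frames - 3) that the correlation
    # estimation itself contributes in either generation route; 0.2 makes a
    # printed-table-sized group gap (dz ~ 0.21) a d ~ 1 effect, the regime in
    # which only the strongest single edge clears a Bonferroni t test
    subject_z_sd: float = 0.20
    confound_scale: float = 0.0  # loading of tissue confound signals on regions
    # clinical-score model
    bdi_mean_std: float = 16.8
    bdi_sd_std: float = 3.5
    bdi_mean_hc: float = 3.0
    bdi_sd_hc: float = 1.9
    anhedonia_loading: float = 2.5   # extra allocation weight of anhedonic items in StD
    eros_anhedonia_rho: float = -0.5
    p_male_std: float = 19 / 30
    p_male_hc: float = 32 / 61

    def validate(self) -> None:
        if self.n_std < 1 or self.n_hc < 1:
            raise CohortError("n_std and n_hc must be positive")
        if self.n_regions < 3:
            raise CohortError(f"n_regions must be >= 3, got {self.n_regions}")
        if self.tr <= 0:
            raise CohortError(f"tr must be positive, got {self.tr}")
        if self.n_frames < 8:
            raise CohortError(f"n_frames must be >= 8, got {self.n_frames}")
        if not (0.0 <= self.ar_coef < 1.0):
            raise CohortError(f"ar_coef must lie in [0, 1), got {self.ar_coef}")
        if not (0.0 <= self.motion_spike_rate <= 1.0):
            raise CohortError("motion_spike_rate must lie in [0, 1]")
        if not (-1.0 < self.eros_anhedonia_rho < 1.0):
            raise CohortError("eros_anhedonia_rho must lie in (-1, 1)")
        for i, j, dz in self.discriminative_edges:
            if not (0 <= i < j < self.n_regions):
                raise CohortError(
                    f"discriminative_edges: pair ({i}, {j}) must satisfy i < j < n_regions"
                )
            # baseline z is ~0, so |dz|/2 plus jitter must keep r inside (-1, 1);
            # atanh headroom makes any finite dz valid, but reject absurd values.
            if abs(dz) > 4.0:
                raise CohortError(f"discriminative_edges: |delta_z| = {abs(dz)} too large")
        for (i, j), cov, slope in self.nuisance_effects:
            if not (0 <= i < j < self.n_regions):
                raise CohortError(f"nuisance_effects: pair ({i}, {j}) out of range")
            if cov not in ("age", "sex"):
                raise CohortError(f"nuisance_effects: unknown covariate {cov!r}")


@dataclass
class SubjectRecord:
    """Metadata for one synthetic participant."""

    subject_id: str
    group: str                 # "StD" or "HC"
    age: int
    sex: str                   # "male" or "female"
    bdi_total: int
    bdi_items: list            # 21 integers, each 0..3
    eros: int                  # 10..40
    cohort: str = "training"   # "training" or "test"

    def __post_init__(self) -> None:
        if self.group not in ("StD", "HC"):
            raise CohortError(f"{self.subject_id}: unknown group {self.group!r}")
        if len(self.bdi_items) != 21 or any(not (0 <= v <= 3) for v in self.bdi_items):
            raise CohortError(f"{self.subject_id}: bdi_items must be 21 values in 0..3")
        if self.bdi_total != sum(self.bdi_items):
            raise CohortError(f"{self.subject_id}: bdi_total != sum(bdi_items)")
        if self.group == "StD" and self.bdi_total < 13:
            raise CohortError(f"{self.subject_id}: StD requires BDI-II >= 13")
        if self.group == "HC" and self.bdi_total >= 8:
            raise CohortError(f"{self.subject_id}: HC requires BDI-II < 8")
        if not (10 <= self.eros <= 40):
            raise CohortError(f"{self.subject_id}: EROS must lie in 10..40")

    @property
    def bdi_anhedonia(self) -> int:
        return sum(self.bdi_items[k - 1] for k in ANHEDONIA_ITEMS)


@dataclass
class GroundTruth:
    """What the generator injected, for recovery scoring."""

    discriminative_edge_ids: np.ndarray     # canonical edge ids
    z_mean_std: np.ndarray                  # (E,) group-mean Fisher z, StD
    z_mean_hc: np.ndarray                   # (E,) group-mean Fisher z, HC
    nuisance_map: dict                      # edge id -> list of (covariate, slope)


# ---------------------------------------------------------------------------
# metadata generation
# ---------------------------------------------------------------------------

def _sample_bdi_total(rng: np.random.Generator, group: str, spec: CohortSpec) -> int:
    if group == "StD":
        lo, hi, mu, sd = 13, 63, spec.bdi_mean_std, spec.bdi_sd_std
    else:
        lo, hi, mu, sd = 0, 7, spec.bdi_mean_hc, spec.bdi_sd_hc
    for _ in range(1000):
        t = int(round(rng.normal(mu, sd)))
        if lo <= t <= hi:
            return t
    return int(np.clip(round(mu), lo, hi))


def _allocate_items(rng: np.random.Generator, total: int, loading: float) -> list:
    """Distribute ``total`` points over 21 items capped at 3 each.

    Anhedonic items receive ``loading``-fold allocation weight, so higher
    loading concentrates depressive burden on anhedonia.
    """
    items = np.zeros(21, dtype=int)
    weights = np.ones(21)
    for k in ANHEDONIA_ITEMS:
        weights[k - 1] = loading
    for _ in range(total):
        open_items = np.flatnonzero(items < 3)
        w = weights[open_items]
        pick = rng.choice(open_items, p=w / w.sum())
        items[pick] += 1
    return items.tolist()


def generate_cohort(spec: CohortSpec, cohort: str = "training"):
    """Generate subject metadata and the edge-level ground truth.

    Returns ``(records, truth)``.  Deterministic given ``spec.seed``: group
    sizes, the BDI group bands, and the anhedonia–EROS coupling all follow
    the spec.  EROS scores are produced from a latent Gaussian coupled to the
    (standardised) anhedonic subscore at correlation ``eros_anhedonia_rho``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))

    groups = ["StD"] * spec.n_std + ["HC"] * spec.n_hc
    records: list[SubjectRecord] = []
    raw = []
    for idx, group in enumerate(groups):
        total = _sample_bdi_total(rng, group, spec)
        loading = spec.anhedonia_loading if group == "StD" else 1.0
        items = _allocate_items(rng, total, loading)
        age = int(rng.choice([18, 19]))
        p_male = spec.p_male_std if group == "StD" else spec.p_male_hc
        sex = "male" if rng.random() < p_male else "female"
        raw.append((idx, group, age, sex, total, items))

    # EROS: couple to the anhedonic subscore at the requested correlation.
    anh = np.array([sum(items[k - 1] for k in ANHEDONIA_ITEMS) for *_, items in raw], float)
    sd = anh.std()
    anh_std = (anh - anh.mean()) / sd if sd > 0 else np.zeros_like(anh)
    rho = spec.eros_anhedonia_rho
    latent = rho * anh_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(raw))
    eros = np.clip(np.round(25.0 + 6.0 * latent), 10, 40).astype(int)

    for (idx, group, age, sex, total, items), e in zip(raw, eros):
        records.append(
            SubjectRecord(
                subject_id=f"S{idx:04d}",
                group=group,
                age=age,
                sex=sex,
                bdi_total=total,
                bdi_items=items,
                eros=int(e),
                cohort=cohort,
            )
        )

    truth = _make_ground_truth(spec)
    return records, truth


def _make_ground_truth(spec: CohortSpec) -> GroundTruth:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    E = n_edges(spec.n_regions)
    base_z = rng.normal(0.0, spec.base_z_sd, size=E)
    z_std = base_z.copy()
    z_hc = base_z.copy()
    ids = []
    for i, j, dz in spec.discriminative_edges:
        e = edge_id(i, j, spec.n_regions)
        ids.append(e)
        z_std[e] = base_z[e] + dz / 2.0
        z_hc[e] = base_z[e] - dz / 2.0
    nuis: dict[int, list] = {}
    for (i, j), cov, slope in spec.nuisance_effects:
        e = edge_id(i, j, spec.n_regions)
        nuis.setdefault(e, []).append((cov, slope))
    return GroundTruth(
        discriminative_edge_ids=np.array(sorted(ids), dtype=int),
        z_mean_std=z_std,
        z_mean_hc=z_hc,
        nuisance_map=nuis,
    )


def _covariate_value(record: SubjectRecord, cov: str) -> float:
    if cov == "age":
        return record.age - 18.5
    if cov == "sex":
        return 0.5 if record.sex == "male" else -0.5
    raise CohortError(f"unknown covariate {cov!r}")


def _subject_z(record: SubjectRecord, spec: CohortSpec, truth: GroundTruth,
               rng: np.random.Generator) -> np.ndarray:
    """Subject-level target Fisher-z vector: group mean + nuisance shifts + jitter."""
    z = (truth.z_mean_std if record.group == "StD" else truth.z_mean_hc).copy()
    for e, effects in truth.nuisance_map.items():
        for cov, slope in effects:
            z[e] += slope * _covariate_value(record, cov)
    z += rng.normal(0.0, spec.subject_z_sd, size=z.shape)
    return z


def generate_fc_dataset(spec: CohortSpec, cohort: str = "training"):
    """Draw per-subject Fisher-z FC vectors directly (no time-series stage).

    Returns ``(dataset, records, truth)``.  Each subject's edge vector is the
    group mean plus nuisance-covariate shifts plus subject heterogeneity
    (``subject_z_sd``) plus the Fisher-z sampling noise 1/sqrt(n_frames - 3)
    that estimating a correlation from ``n_frames`` frames would contribute —
    the marginal structure the full time-series route produces, without
    simulating the series.
    """
    records, truth = generate_cohort(spec, cohort=cohort)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    sampling_sd = 1.0 / np.sqrt(max(spec.n_frames - 3, 1))
    X = np.stack([_subject_z(r, spec, truth, rng) for r in records])
    X = X + sampling_sd * rng.standard_normal(X.shape)
    ds = FCDataset(
        X=X,
        y=np.array([1 if r.group == "StD" else 0 for r in records]),
        age=np.array([float(r.age) for r in records]),
        sex=np.array([1.0 if r.sex == "male" else 0.0 for r in records]),
        subject_ids=[r.subject_id for r in records],
        n_regions=spec.n_regions,
        scale="fisher_z",
    )
    return ds, records, truth


# ---------------------------------------------------------------------------
# SPD projection
# ---------------------------------------------------------------------------

def nearest_spd(matrix: np.ndarray, floor: float = 1e-6,
                unit_diag: bool | None = None) -> np.ndarray:
    """Project a symmetric matrix to the symmetric positive-definite cone.

    Eigenvalues below ``floor`` are clipped up to it; for correlation matrices
    (``unit_diag`` True, or auto-detected from the input diagonal) the unit
    diagonal is restored after clipping, iterating the two steps until the
    smallest eigenvalue respects the floor.  An input that is already SPD is
    returned unchanged.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"nearest_spd requires a square matrix, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("nearest_spd requires a symmetric matrix")
    if unit_diag is None:
        unit_diag = bool(np.allclose(np.diag(A), 1.0, atol=1e-12))

    B = (A + A.T) / 2.0
    for _ in range(100):
        w, V = np.linalg.eigh(B)
        if w[0] >= floor * (1.0 - 1e-9):
            return B
        B = (V * np.maximum(w, floor)) @ V.T
        B = (B + B.T) / 2.0
        if unit_diag:
            d = np.sqrt(np.diag(B))
            B = B / np.outer(d, d)
            np.fill_diagonal(B, 1.0)
    w = np.linalg.eigvalsh(B)
    if w[0] < floor * 0.5:
        raise CohortError("SPD projection failed to converge")
    return B


# ---------------------------------------------------------------------------
# time-series generation
# ---------------------------------------------------------------------------

def _target_correlation(record: SubjectRecord, spec: CohortSpec, truth: GroundTruth,
                        rng: np.random.Generator) -> np.ndarray:
    R = spec.n_regions
    z = _subject_z(record, spec, truth, rng)
    C = np.eye(R)
    iu = np.triu_indices(R, k=1)
    r = np.tanh(z)
    C[iu] = r
    C[(iu[1], iu[0])] = r
    return nearest_spd(C, unit_diag=True)


def generate_timeseries(record: SubjectRecord, spec: CohortSpec, truth: GroundTruth):
    """Synthesise one subject's ROI time series, motion trace and confounds.

    The series is a stationary AR(1) process (coefficient ``spec.ar_coef``)
    whose cross-region correlation matrix equals the subject's SPD-projected
    target.  Tissue confound signals (white matter, CSF, global) load on all
    regions with weight ``spec.confound_scale``.  Head motion is a step
    process: zero except at spike frames, where a translation step of
    ``motion_spike_mm`` occurs (so framewise displacement is exactly the step
    magnitude at that frame and zero elsewhere).  Spike frames also receive a
    burst artifact in the signal.

    Returns ``(data, motion, confounds)`` where ``data`` is frames × regions,
    ``motion`` is frames × 6 (translations mm, rotations rad) and
    ``confounds`` is frames × 3.  Deterministic given the spec seed and the
    numeric part of the subject id.
    """
    idx = int("".join(ch for ch in record.subject_id if ch.isdigit()) or 0)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404, idx]))

    R, T, phi = spec.n_regions, spec.n_frames, spec.ar_coef
    C = _target_correlation(record, spec, truth, rng)
    L = np.linalg.cholesky(C)

    # unit-variance AR(1) innovations, identical filter in every region so the
    # imposed cross-correlation is preserved
    e = rng.standard_normal((T, R))
    s = np.empty_like(e)
    s[0] = e[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        s[t] = phi * s[t - 1] + scale * e[t]
    data = s @ L.T

    # tissue confounds: smooth AR(1) nuisance signals added to every region
    ec = rng.standard_normal((T, 3))
    conf = np.empty_like(ec)
    conf[0] = ec[0]
    for t in range(1, T):
        conf[t] = 0.8 * conf[t - 1] + np.sqrt(1 - 0.8**2) * ec[t]
    if spec.confound_scale > 0:
        load = spec.confound_scale * rng.standard_normal((3, R))
        data = data + conf @ load

    # motion: step process, spikes from frame 1 on (frame 0 is the reference)
    motion = np.zeros((T, 6))
    if spec.motion_spike_rate > 0:
        spikes = np.flatnonzero(rng.random(T - 1) < spec.motion_spike_rate) + 1
        pos = 0.0
        step_signs = rng.choice([-1.0, 1.0], size=spikes.size)
        for t, sgn in zip(spikes, step_signs):
            pos += sgn * spec.motion_spike_mm
            motion[t:, 0] = pos
            data[t] += spec.motion_spike_mm * rng.standard_normal(R)
    return data, motion, conf
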