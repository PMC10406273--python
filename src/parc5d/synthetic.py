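"""Seeded synthetic resting-state fMRI studies with known ground truth.

Emulates preprocessed 4D scans built from K overlapping brain networks
grouped into up to seven functional domains (SM, DMN, AU, CC, VI, SC, CB).
Each network is an anisotropic Gaussian blob whose centre and log-width
follow a smooth Ornstein-Uhlenbeck random walk over time (voxel-level
spatial dynamics) and whose amplitude is modulated by a temporally
smoothed, domain-correlated timecourse (temporal coupling).  The scan is
the amplitude-weighted sum of the network maps plus i.i.d. Gaussian noise.

Group structure is injectable: patients can carry per-network amplitude
scalings, per-network spatial-jitter scalings, and per-domain-pair shifts
of timecourse correlation.  Every quantity is reproducible bit-for-bit
from the study seed.

Networks in the same domain are placed with nearby centres and share a
latent temporal driver, so the domain-block structure seen in functional
network connectivity matrices emerges both spatially (overlap) and
temporally (correlation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import save_nifti, write_manifest

DOMAIN_NAMES = ("SM", "DMN", "AU", "CC", "VI", "SC", "CB")

# Network counts per domain for the full 53-network layout.
_FULL_DOMAIN_SIZES = {"SC": 5, "AU": 2, "SM": 9, "VI": 9, "CC": 17,
                      "DMN": 7, "CB": 4}

__all__ = [
    "DOMAIN_NAMES", "SyntheticStudyConfig", "NetworkTemplate",
    "GroundTruthSubject", "make_network_templates", "simulate_timecourses",
    "render_subject", "observed_score_maps", "make_group_study",
    "simulate_study", "study_mask",
]


def _default_domains(k: int) -> dict[str, tuple[int, ...]]:
    if k == 53:
        sizes = [_FULL_DOMAIN_SIZES[d] for d in DOMAIN_NAMES]
    else:
        # spread networks over domains round-robin, keeping pairs together
        n_dom = min(max(k // 2, 1), len(DOMAIN_NAMES))
        sizes = [0] * n_dom
        for i in range(k):
            sizes[i % n_dom] += 1
    domains, nid = {}, 1
    for name, size in zip(DOMAIN_NAMES, sizes):
        if size:
            domains[name] = tuple(range(nid, nid + size))
            nid += size
    return domains


@dataclass
class SyntheticStudyConfig:
    """Full specification of a synthetic two-group study.

    Effects dictionaries apply to the patient group only:
    ``amplitude_effect`` maps network id -> amplitude multiplier,
    ``deviation_effect`` maps network id -> spatial-jitter multiplier,
    ``coupling_effect`` maps a (domain, domain) pair -> additive shift of
    the between-domain timecourse correlation.
    """

    grid_dims: tuple[int, int, int] = (53, 63, 52)
    n_networks: int = 53
    domains: dict[str, tuple[int, ...]] | None = None
    n_timepoints: int = 150
    n_control: int = 10
    n_patient: int = 10
    noise_sd: float = 0.1
    amplitude_effect: dict[int, float] = field(default_factory=dict)
    deviation_effect: dict[int, float] = field(default_factory=dict)
    coupling_effect: dict[tuple[str, str], float] = field(
        default_factory=dict)
    jitter_sd: float = 0.75          # voxels, stationary sd of centre walk
    jitter_smooth: float = 0.8       # OU autoregression of the walk
    width_jitter_sd: float = 0.05    # stationary sd of the log-width walk
    within_corr: float = 0.45        # timecourse correlation inside a domain
    cross_corr: float = 0.0          # baseline correlation across domains
    tc_smooth: float = 0.6           # AR(1) coefficient of the timecourses
    amp_base: float = 0.55
    amp_depth: float = 0.2
    base_width: float = 3.0          # voxels, mean Gaussian sigma
    domain_spread: float = 1.5       # voxels, centre scatter inside a domain
    domain_separation: float | None = None  # anchor spacing, voxels
    map_bias_sd: float = 0.08        # per-subject map estimation bias
    map_noise_sd: float = 0.05       # per-(voxel, t) map estimation noise
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.domains is None:
            self.domains = _default_domains(self.n_networks)
        k = self.n_networks
        members = sorted(itertools.chain.from_iterable(self.domains.values()))
        if members != list(range(1, k + 1)):
            raise ValueError(
                f"domains must partition networks 1..{k}, got {members}")
        if any(d not in DOMAIN_NAMES for d in self.domains):
            raise ValueError(f"domain names must be among {DOMAIN_NAMES}")
        if min(self.grid_dims) < 1 or k < 1 or self.n_timepoints < 1:
            raise ValueError("grid dims, network and timepoint counts must "
                             "be positive")
        if self.n_control < 1 or self.n_patient < 1:
            raise ValueError("subject counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for r in (self.within_corr, self.cross_corr):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation target {r} outside (-1, 1)")

    # ------------------------------------------------------------------
    # presets (reduced problem sizes for tests and desk-scale runs)
    @classmethod
    def small(cls, **kw) -> "SyntheticStudyConfig":
        """8 networks in 4 domains on a 24x28x24 grid."""
        defaults = dict(
            grid_dims=(24, 28, 24), n_networks=8,
            domains={"SM": (1, 2), "DMN": (3, 4), "VI": (5, 6),
                     "CB": (7, 8)},
            n_timepoints=100, base_width=2.6, domain_spread=1.3,
            domain_separation=5.0, amp_base=0.5, amp_depth=0.4,
            jitter_sd=0.5, tc_smooth=0.5)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def effect_study(cls, **kw) -> "SyntheticStudyConfig":
        """Two-group study with all three injectable effects switched on:
        amplitude x1.3 and halved spatial jitter on network 5 (VI domain),
        and a +0.4 shift of the SM-DMN timecourse coupling in patients.
        The map-level effects sit outside the coupled domains so each can
        be assessed without contaminating the other."""
        defaults = dict(
            n_timepoints=150, n_control=20, n_patient=20,
            amplitude_effect={5: 1.3}, deviation_effect={5: 0.5},
            coupling_effect={("SM", "DMN"): 0.4})
        defaults.update(kw)
        return cls.small(**defaults)

    @classmethod
    def tiny(cls, **kw) -> "SyntheticStudyConfig":
        """4 networks in 2 domains on a 16^3 grid (model-training scale)."""
        defaults = dict(
            grid_dims=(16, 16, 16), n_networks=4,
            domains={"SM": (1, 2), "DMN": (3, 4)},
            n_timepoints=8, n_control=2, n_patient=2,
            base_width=1.8, domain_spread=1.2, jitter_sd=0.4,
            noise_sd=0.05)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def null_calibration(cls, **kw) -> "SyntheticStudyConfig":
        """Homogeneous null study for type-I-error calibration.

        Spatial dynamics are switched off and amplitude modulation kept
        shallow so that, within the analysis mask, the across-subject
        variability of the observed maps is dominated by independent
        per-voxel estimation noise -- the regime in which per-voxel test
        statistics are approximately independent and the binomial
        reference band for the rejection rate applies.
        """
        defaults = dict(
            n_timepoints=50, n_control=20, n_patient=20,
            jitter_sd=0.0, amp_depth=0.02, map_bias_sd=0.1)
        defaults.update(kw)
        return cls.small(**defaults)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["coupling_effect"] = {f"{a}-{b}": v for (a, b), v
                                in self.coupling_effect.items()}
        return d


@dataclass
class NetworkTemplate:
    """Static spatial prior of one network: unit-peak Gaussian blob."""

    network_id: int
    domain: str
    centers: list[tuple[int, int, int]]
    widths: np.ndarray          # per-axis sigma, voxels
    base_map: np.ndarray        # 3D, values in [0, 1], max 1 at center

    @property
    def center(self) -> tuple[int, int, int]:
        return self.centers[0]


@dataclass
class GroundTruthSubject:
    """Noise-free ideal of one subject: per-network 4D score maps in
    [0, 1] and the T x K amplitude timecourse matrix."""

    subject_id: str
    group: str
    subject_index: int
    score_maps: list[np.ndarray]      # K arrays (X, Y, Z, T)
    timecourses: np.ndarray           # (T, K)


# ---------------------------------------------------------------------------
# deterministic seeding helpers

_GROUP_CODE = {"control": 1, "patient": 2}


def _rng(cfg: SyntheticStudyConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *key]))


def _check_group(group: str):
    if group not in _GROUP_CODE:
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")


# ---------------------------------------------------------------------------
# templates

def _gaussian_blob(grid, center, widths) -> np.ndarray:
    axes = [np.exp(-0.5 * ((np.arange(n) - c) / s) ** 2)
            for n, c, s in zip(grid, center, widths)]
    return np.einsum("i,j,k->ijk", *axes).astype(np.float32)


def _farthest_point_anchors(candidates: np.ndarray, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point choice of n anchors among candidate sites."""
    first = rng.integers(len(candidates))
    chosen = [candidates[first]]
    for _ in range(n - 1):
        d = np.min(
            [np.linalg.norm(candidates - c, axis=1) for c in chosen], axis=0)
        chosen.append(candidates[int(np.argmax(d))])
    return np.array(chosen, dtype=float)


def make_network_templates(cfg: SyntheticStudyConfig
                           ) -> list[NetworkTemplate]:
    """Place one Gaussian blob per network so that same-domain networks
    sit nearer each other than cross-domain ones (deterministic in the
    study seed)."""
    rng = _rng(cfg, 0x7E)
    grid = np.array(cfg.grid_dims)
    margin = max(2.0, 1.5 * cfg.base_width)
    lo, hi = np.full(3, margin), grid - 1 - margin
    if np.any(hi <= lo):
        raise ValueError(
            f"grid {cfg.grid_dims} too small for blobs of width "
            f"{cfg.base_width} (needs every dim > {2 * margin + 1:.0f})")
    spacing = cfg.domain_separation or max(2.0, 2 * cfg.base_width)
    n_steps = np.maximum(((hi - lo) // spacing).astype(int), 1) + 1
    axes = [np.linspace(l, h, int(s)) for l, h, s in zip(lo, hi, n_steps)]
    candidates = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    n_dom = len(cfg.domains)
    if len(candidates) < n_dom:
        raise ValueError(
            f"grid {cfg.grid_dims} admits only {len(candidates)} well-"
            f"separated blob sites but {n_dom} domains are requested")
    if cfg.domain_separation is None:
        anchors = _farthest_point_anchors(candidates, n_dom, rng)
    else:
        # compact layout at the requested spacing: lattice sites nearest
        # the grid centre, so neighbouring domains' blob tails overlap
        order = np.argsort(np.linalg.norm(candidates - grid / 2.0, axis=1))
        anchors = candidates[order[:n_dom]]
    templates = [None] * cfg.n_networks
    for anchor, (domain, members) in zip(anchors, cfg.domains.items()):
        for nid in members:
            center = anchor + rng.normal(0, cfg.domain_spread, 3)
            center = np.clip(np.round(center), lo, hi).astype(int)
            widths = cfg.base_width * rng.uniform(0.8, 1.2, 3)
            base = _gaussian_blob(cfg.grid_dims, center, widths)
            templates[nid - 1] = NetworkTemplate(
                network_id=nid, domain=domain,
                centers=[tuple(int(c) for c in center)],
                widths=widths, base_map=base)
    return templates


def study_mask(templates, level: float = 0.1) -> np.ndarray:
    """Union of template supports at the given fraction of peak value."""
    mask = np.zeros(templates[0].base_map.shape, dtype=bool)
    for t in templates:
        mask |= t.base_map > level
    return mask


# ---------------------------------------------------------------------------
# timecourses

def _target_correlation(cfg: SyntheticStudyConfig, group: str) -> np.ndarray:
    k = cfg.n_networks
    r = np.full((k, k), cfg.cross_corr)
    for _, members in cfg.domains.items():
        for a in members:
            for b in members:
                r[a - 1, b - 1] = cfg.within_corr
    if group == "patient":
        for (da, db), delta in cfg.coupling_effect.items():
            for a in cfg.domains.get(da, ()):
                for b in cfg.domains.get(db, ()):
                    r[a - 1, b - 1] += delta
                    r[b - 1, a - 1] += delta
    np.fill_diagonal(r, 1.0)
    off = r[~np.eye(k, dtype=bool)]
    if off.size and (off.min() <= -1.0 or off.max() >= 1.0):
        raise ValueError(
            f"target correlations must lie in (-1, 1); got range "
            f"[{off.min():.3f}, {off.max():.3f}]")
    return r


def simulate_timecourses(cfg: SyntheticStudyConfig, group: str,
                         subject_index: int = 0) -> np.ndarray:
    """T x K unit-variance timecourses: temporally smoothed (AR(1)) and
    correlated across networks according to the domain structure (plus any
    patient coupling effects)."""
    _check_group(group)
    t_len, k = cfg.n_timepoints, cfg.n_networks
    r = _target_correlation(cfg, group)
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "target correlation matrix is not positive definite; reduce "
            "within_corr/coupling_effect") from exc
    rng = _rng(cfg, 0x7C, _GROUP_CODE[group], subject_index)
    phi = cfg.tc_smooth
    z = np.empty((t_len, k))
    z[0] = rng.standard_normal(k)
    innov = rng.standard_normal((t_len - 1, k)) if t_len > 1 else None
    scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, t_len):
        z[t] = phi * z[t - 1] + scale * innov[t - 1]
    return z @ chol.T


# ---------------------------------------------------------------------------
# subjects

def _ou_path(rng, t_len, sd, smooth) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck walk, sd given, AR coefficient smooth."""
    x = np.empty(t_len)
    x[0] = rng.standard_normal()
    scale = np.sqrt(1.0 - smooth ** 2)
    for t in range(1, t_len):
        x[t] = smooth * x[t - 1] + scale * rng.standard_normal()
    return sd * x


def render_subject(templates, cfg: SyntheticStudyConfig, group: str,
                   subject_index: int):
    """Render one subject: the noisy 4D scan plus its noise-free ground
    truth (per-network score maps and timecourses)."""
    _check_group(group)
    if len(templates) != cfg.n_networks:
        raise ValueError("template list does not match config network count")
    t_len, k = cfg.n_timepoints, cfg.n_networks
    tc = simulate_timecourses(cfg, group, subject_index)
    rng = _rng(cfg, 0x5B, _GROUP_CODE[group], subject_index)
    amps = np.clip(cfg.amp_base + cfg.amp_depth * tc, 0.0, 1.0)
    if group == "patient":
        for nid, mult in cfg.amplitude_effect.items():
            amps[:, nid - 1] = np.clip(amps[:, nid - 1] * mult, 0.0, 1.0)
    grid = cfg.grid_dims
    volume = np.zeros(grid + (t_len,), dtype=np.float32)
    score_maps = []
    for tpl in templates:
        nid = tpl.network_id
        jit = cfg.jitter_sd
        if group == "patient":
            jit *= cfg.deviation_effect.get(nid, 1.0)
        off = np.stack([_ou_path(rng, t_len, jit, cfg.jitter_smooth)
                        for _ in range(3)], axis=1)
        lw = _ou_path(rng, t_len, cfg.width_jitter_sd, cfg.jitter_smooth)
        if group == "patient":
            lw = lw * cfg.deviation_effect.get(nid, 1.0)
        center = np.array(tpl.center, dtype=float)
        widths_t = tpl.widths[None, :] * np.exp(lw)[:, None]   # (T, 3)
        axes = []
        for ax in range(3):
            coords = np.arange(grid[ax])[None, :]
            c = (center[ax] + off[:, ax])[:, None]
            s = widths_t[:, ax][:, None]
            axes.append(np.exp(-0.5 * ((coords - c) / s) ** 2))
        omega = np.einsum("ti,tj,tk,t->ijkt", axes[0], axes[1], axes[2],
                          amps[:, nid - 1], optimize=True).astype(np.float32)
        score_maps.append(omega)
        volume += omega
    if cfg.noise_sd > 0:
        volume += rng.normal(0.0, cfg.noise_sd,
                             volume.shape).astype(np.float32)
    prefix = "C" if group == "control" else "P"
    subject = GroundTruthSubject(
        subject_id=f"{prefix}{subject_index + 1:03d}", group=group,
        subject_index=subject_index, score_maps=score_maps, timecourses=tc)
    return volume, subject


def observed_score_maps(subject: GroundTruthSubject,
                        cfg: SyntheticStudyConfig) -> list[np.ndarray]:
    """Ground-truth maps degraded by an estimation-error model: a
    per-subject time-constant voxel bias plus per-(voxel, t) noise.

    Emulates imperfect model predictions so group statistics can be
    exercised without a training run.  The error is left additive and
    symmetric (no re-projection onto [0, 1]): clipping would concentrate
    low-signal voxels at the boundary and distort the sampling
    distributions the downstream tests assume.
    """
    rng = _rng(cfg, 0x0B5, _GROUP_CODE[subject.group], subject.subject_index)
    out = []
    for omega in subject.score_maps:
        grid_t = omega.shape
        bias = rng.normal(0.0, cfg.map_bias_sd, grid_t[:3]).astype(np.float32)
        obs = omega + bias[..., None]
        if cfg.map_noise_sd > 0:
            obs = obs + rng.normal(0.0, cfg.map_noise_sd,
                                   grid_t).astype(np.float32)
        out.append(obs)
    return out


def simulate_study(cfg: SyntheticStudyConfig, templates=None):
    """Yield (volume, GroundTruthSubject) for every subject, controls
    first.  Generation is streamed so large studies need not fit in
    memory at once."""
    if templates is None:
        templates = make_network_templates(cfg)
    for group, count in (("control", cfg.n_control),
                         ("patient", cfg.n_patient)):
        for idx in range(count):
            yield render_subject(templates, cfg, group, idx)


def make_group_study(cfg: SyntheticStudyConfig, out_dir):
    """Write a full study to disk: per-subject 4D scans, per-network
    ground-truth 4D maps, and a manifest CSV (subject_id, group, path).

    Returns (manifest_path, templates).
    """
    out_dir = Path(out_dir)
    templates = make_network_templates(cfg)
    rows = []
    for volume, subject in simulate_study(cfg, templates):
        vol_path = out_dir / "fmri" / f"{subject.subject_id}.nii.gz"
        save_nifti(volume, vol_path, cfg.voxel_size)
        truth_dir = out_dir / "truth" / subject.subject_id
        for k, omega in enumerate(subject.score_maps, start=1):
            save_nifti(omega, truth_dir / f"net_{k:02d}.nii.gz",
                       cfg.voxel_size)
        np.savetxt(truth_dir / "timecourses.csv", subject.timecourses,
                   delimiter=",")
        rows.append((subject.subject_id, subject.group, str(vol_path)))
    manifest = write_manifest(rows, out_dir / "manifest.csv")
    return manifest, templates
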