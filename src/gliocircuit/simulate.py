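"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* trial-structured multichannel ECoG — 1/f background, line components at 50
  and 79 Hz, and a band-limited high-gamma carrier whose envelope power is
  multiplied by planted condition factors, so the true percentage signal
  change has the closed form (factor - 1) * 100;
* 4-D BOLD volumes whose voxels load on K latent network time courses with
  additive Gaussian noise, plus a tumour mask partially coupled to chosen
  networks (population tumour-voxel/network correlation is
  w / sqrt(w^2 + sigma^2) for unit-variance courses);
* a patient cohort table generated from linear models with known
  coefficients, with realistic missingness in the follow-up scores.

Every generator is a pure function of its spec and seed.  A unit icosphere
with contiguous random parcels stands in for the registration sphere and the
canonical 7-network parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sps

from .errors import RangeError
from .recording import EcogRecording, make_channel_table, make_marker_table
from .surface import SurfaceMesh

# ---------------------------------------------------------------------------
# noise primitives


def powerlaw_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise by spectral shaping of white noise."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(spec, n=n)
    return x / max(x.std(), 1e-30)


def bandlimited_noise(n: int, fs: float, band, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band``."""
    sos = sps.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / max(x.std(), 1e-30)


# ---------------------------------------------------------------------------
# ECoG


def _default_trial_plan() -> list:
    # one long rest baseline, then alternating counting trials (2-5 repeats
    # per condition in the intraoperative protocol; 3 is typical)
    return [("rest", 120.0, 1), ("easy", 20.0, 3), ("hard", 20.0, 3)]


@dataclass
class EcogSimSpec:
    """Specification of a synthetic intraoperative ECoG session.

    ``easy_vs_rest`` and ``hard_vs_easy`` are multiplicative factors on the
    high-gamma carrier *power* (scalar, or one value per channel); the planted
    PSC of each contrast is therefore (factor - 1) * 100 exactly.
    """

    n_strips: int = 1
    electrodes_per_strip: int = 4
    fs: float = 10_000.0
    trial_plan: list = field(default_factory=_default_trial_plan)
    easy_vs_rest: float | np.ndarray = 1.0
    hard_vs_easy: float | np.ndarray = 1.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 20.0       # uV RMS broadband background
    carrier_band: tuple = (70.0, 250.0)
    carrier_amplitude: float = 10.0     # uV RMS high-gamma carrier
    line_amplitudes: dict = field(default_factory=lambda: {50.0: 8.0, 79.0: 3.0})
    gap_s: float = 2.0
    pad_s: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.electrodes_per_strip < 2 or self.n_strips < 1:
            raise ValueError("need >= 1 strip with >= 2 electrodes each")
        for cond, dur, rep in self.trial_plan:
            if dur <= 0 or rep < 1:
                raise ValueError(f"trial plan entry ({cond}) needs duration > 0, repeats >= 1")
        n_ch = self.n_strips * self.electrodes_per_strip
        for name in ("easy_vs_rest", "hard_vs_easy"):
            f = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n_ch,))
            if np.any(f <= 0):
                raise ValueError(f"{name} factors must be positive")
            setattr(self, name, f.copy())

    @property
    def n_channels(self) -> int:
        return self.n_strips * self.electrodes_per_strip


def _expand_trial_plan(spec: EcogSimSpec):
    """Flatten the plan into per-trial (condition, onset_s, offset_s)."""
    trials = []
    t = spec.pad_s
    for cond, dur, rep in spec.trial_plan:
        for _ in range(rep):
            trials.append((cond, t, t + dur))
            t += dur + spec.gap_s
    total_s = t - spec.gap_s + spec.pad_s
    return trials, total_s


def simulate_ecog(spec: EcogSimSpec) -> tuple[EcogRecording, pd.DataFrame]:
    """Generate a recording and the per-channel ground-truth PSC table."""
    rng = np.random.default_rng(spec.rng_seed)
    trials, total_s = _expand_trial_plan(spec)
    n = int(round(total_s * spec.fs))
    t = np.arange(n) / spec.fs

    # power factor of each condition relative to rest, per channel
    cond_factor = {
        "rest": np.ones(spec.n_channels),
        "easy": spec.easy_vs_rest,
        "hard": spec.easy_vs_rest * spec.hard_vs_easy,
    }
    envelope = np.ones((spec.n_channels, n))
    onsets, offsets, conds, ids = [], [], [], []
    for i, (cond, a_s, b_s) in enumerate(trials):
        a, b = int(round(a_s * spec.fs)), int(round(b_s * spec.fs))
        envelope[:, a:b] = np.sqrt(cond_factor[cond])[:, None]
        onsets.append(a)
        offsets.append(b)
        conds.append(cond)
        ids.append(f"t{i:02d}")

    data = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        x = spec.noise_amplitude * powerlaw_noise(n, spec.noise_exponent, rng)
        carrier = bandlimited_noise(n, spec.fs, spec.carrier_band, rng)
        x = x + spec.carrier_amplitude * envelope[c] * carrier
        for f0, amp in spec.line_amplitudes.items():
            x = x + amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        data[c] = x

    strip_ids = [f"strip{s + 1}" for s in range(spec.n_strips)
                 for _ in range(spec.electrodes_per_strip)]
    channel_ids = [f"s{s + 1}e{e + 1}" for s in range(spec.n_strips)
                   for e in range(spec.electrodes_per_strip)]
    rec = EcogRecording(
        data=data,
        fs=spec.fs,
        channels=make_channel_table(channel_ids, strip_ids),
        markers=make_marker_table(ids, conds, onsets, offsets),
        provenance=["simulate_ecog"],
    )
    truth = pd.DataFrame(
        {
            "channel_id": channel_ids,
            "strip_id": strip_ids,
            "psc_easy_gt_rest": (spec.easy_vs_rest - 1.0) * 100.0,
            "psc_hard_gt_easy": (spec.hard_vs_easy - 1.0) * 100.0,
        }
    )
    return rec, truth


# ---------------------------------------------------------------------------
# BOLD


@dataclass
class BoldSimSpec:
    """Specification of a synthetic resting-state BOLD session.

    Voxels inside each network support load with weight 1 on that network's
    latent course; tumour voxels load on networks with ``tumour_coupling``
    weights in [0, 1]; everything else in the parenchyma is pure noise.
    """

    shape: tuple = (20, 20, 20)
    voxel_size_mm: float = 2.0
    tr_s: float = 1.06
    n_volumes: int = 200
    n_networks: int = 7
    network_radius_vox: float = 3.0
    course_sd: float = 1.0
    noise_sd: float = 1.0
    tumour_centre_vox: tuple | None = None
    tumour_radius_vox: float = 2.5
    tumour_coupling: dict = field(default_factory=lambda: {1: 0.6})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 4:
            raise ValueError("need at least 4 volumes")
        for k, w in self.tumour_coupling.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"coupling weight for network {k} must lie in [0, 1]")
            if not (1 <= k <= self.n_networks):
                raise ValueError(f"coupling names unknown network {k}")


def _sphere_mask(shape, centre, radius) -> np.ndarray:
    grids = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return d2 <= radius**2


def _fibonacci_directions(k: int) -> np.ndarray:
    i = np.arange(k)
    phi = np.arccos(1 - 2 * (i + 0.5) / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def simulate_bold(spec: BoldSimSpec):
    """Generate ``(bold4d, masks, affine, ground_truth)``.

    ``masks`` maps ``network_1..network_K``, ``tumour`` and ``parenchyma`` to
    boolean arrays; ``ground_truth`` lists each tumour voxel's population
    correlation with each network course.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape)
    centre = (np.array(shape) - 1) / 2.0
    brain_r = min(shape) * 0.45
    parenchyma = _sphere_mask(shape, centre, brain_r)

    # disjoint network supports: spheres around points spread inside the brain
    dirs = _fibonacci_directions(spec.n_networks)
    net_centres = centre[None, :] + dirs * brain_r * 0.55
    masks = {}
    claimed = np.zeros(shape, dtype=bool)
    for k in range(spec.n_networks):
        m = _sphere_mask(shape, net_centres[k], spec.network_radius_vox) & parenchyma & ~claimed
        masks[f"network_{k + 1}"] = m
        claimed |= m

    tumour_centre = (
        np.asarray(spec.tumour_centre_vox, dtype=float)
        if spec.tumour_centre_vox is not None
        else net_centres[0] + np.array([spec.network_radius_vox + spec.tumour_radius_vox, 0, 0])
    )
    if np.any(tumour_centre < 0) or np.any(tumour_centre > np.array(shape) - 1):
        raise RangeError(f"tumour centre {tuple(tumour_centre)} outside grid {shape}")
    tumour = _sphere_mask(shape, tumour_centre, spec.tumour_radius_vox)
    if not tumour.any():
        raise RangeError("tumour mask is empty")
    masks["tumour"] = tumour
    masks["parenchyma"] = parenchyma | tumour

    courses = rng.standard_normal((spec.n_networks, spec.n_volumes)) * spec.course_sd
    bold = np.zeros(shape + (spec.n_volumes,))
    noise = rng.standard_normal(bold.shape) * spec.noise_sd
    bold[masks["parenchyma"]] += noise[masks["parenchyma"]]
    for k in range(spec.n_networks):
        bold[masks[f"network_{k + 1}"]] += courses[k]

    weights = np.zeros(spec.n_networks)
    for k, w in spec.tumour_coupling.items():
        weights[k - 1] = w
    tumour_signal = weights @ courses
    # tumour voxels not already carrying a network course get coupling + noise
    tumour_only = tumour & ~claimed
    bold[tumour_only] += tumour_signal

    ijk = np.argwhere(tumour)
    var_total = float(weights @ weights) * spec.course_sd**2 + spec.noise_sd**2
    rows = []
    for k in range(spec.n_networks):
        pop_r = np.where(
            [bool(claimed[tuple(v)]) for v in ijk],
            np.nan,  # voxels inside a network support carry that course, not the coupling
            weights[k] * spec.course_sd**2 / max(np.sqrt(var_total) * spec.course_sd, 1e-30),
        )
        for v, r in zip(ijk, pop_r):
            rows.append({"i": v[0], "j": v[1], "k": v[2],
                         "network": k + 1, "population_r": r})
    truth = pd.DataFrame(rows)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -centre * spec.voxel_size_mm
    return bold, masks, affine, truth


# ---------------------------------------------------------------------------
# sphere mesh and parcellation


def make_icosphere(subdivisions: int) -> SurfaceMesh:
    """Unit sphere by repeated subdivision of an icosahedron.

    Vertex count is 10 * 4**s + 2.
    """
    import trimesh

    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def make_parcellation(mesh: SurfaceMesh, n_parcels: int, rng_seed: int = 0) -> np.ndarray:
    """Contiguous random parcels 1..K by nearest-seed-vertex assignment.

    Chord distance on the unit sphere orders points exactly like geodesic
    distance, so each Voronoi cell is geodesically convex and hence contiguous
    on the mesh graph.
    """
    if not 1 <= n_parcels <= mesh.n_vertices:
        raise ValueError("need 1 <= K <= number of vertices")
    rng = np.random.default_rng(rng_seed)
    seeds = rng.choice(mesh.n_vertices, size=n_parcels, replace=False)
    d2 = ((mesh.vertices[:, None, :] - mesh.vertices[seeds][None, :, :]) ** 2).sum(-1)
    return np.argmin(d2, axis=1).astype(np.int64) + 1


# ---------------------------------------------------------------------------
# electrode-level cross-modal feature rows


def simulate_electrode_features(
    n_participants: int = 8,
    electrodes_per_participant: int = 5,
    networks=("VN", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN"),
    contrasts=("hard_gt_easy", "easy_gt_rest"),
    slopes: dict | None = None,
    participant_sd: float = 20.0,
    fc_sd: float = 0.3,
    noise_sd: float = 10.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Electrode rows (participant, electrode, contrast, network, psc, fc)
    with planted PSC-on-connectivity slopes.

    ``slopes`` maps (contrast, network) to the true fixed-effect slope
    (default: 2.0 for the attention network in the hard-vs-easy contrast,
    0 elsewhere); each participant contributes a random PSC intercept.
    """
    slopes = slopes if slopes is not None else {("hard_gt_easy", "DAN"): 2.0}
    rng = np.random.default_rng(rng_seed)
    rows = []
    for p in range(n_participants):
        intercept = rng.normal(0.0, participant_sd)
        for e in range(electrodes_per_participant):
            fc = {n: rng.normal(0.0, fc_sd) for n in networks}
            for contrast in contrasts:
                # one PSC per (electrode, contrast), shared across network rows
                psc = (
                    intercept
                    + sum(slopes.get((contrast, n), 0.0) * fc[n] for n in networks)
                    + rng.normal(0.0, noise_sd)
                )
                for n in networks:
                    rows.append(
                        {
                            "participant": f"P{p + 1:02d}",
                            "electrode": f"E{e + 1:02d}",
                            "contrast": contrast,
                            "network": n,
                            "psc": psc,
                            "fc": fc[n],
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSimSpec:
    """Specification of a synthetic patient cohort.

    Continuous predictors enter the outcome model z-scored (sample mean/sd),
    so ``outcome_coefs`` are planted on the standardized scale that the
    model-fitting layer reports.  Follow-up scores are healthy-control
    Z-normalised by construction (unit-scale residuals around the planted
    linear predictor).
    """

    n_patients: int = 17
    conn_base: float = 0.10
    conn_sd: float = 0.08
    location_shift: dict = field(
        default_factory=lambda: {"frontal": 0.0, "insula": 0.10, "temporal": -0.02}
    )
    outcome_coefs: dict = field(
        default_factory=lambda: {
            "connectivity": 1.10,
            "preop": 0.14,
            "location[insula]": -0.36,
            "location[temporal]": 0.75,
            "hemisphere[right]": -0.27,
            "timepoint[month3]": 0.10,
            "timepoint[postop]": -0.41,
            "age": 0.07,
            "gender[male]": 0.06,
        }
    )
    outcome_intercept: float = 0.0
    residual_sd: float = 0.5
    missing_followup_frac: float = 0.12
    timepoint_probs: dict = field(
        default_factory=lambda: {"post-op": 0.2, "month 3": 0.3, "month 12": 0.5}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        n_predictors = len(self.outcome_coefs)
        if self.n_patients < n_predictors + 2:
            raise ValueError(
                f"n_patients={self.n_patients} too small for {n_predictors} predictors"
            )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """One row per patient with planted regression structure.

    The planted coefficients are recorded in ``df.attrs['planted']``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients
    locations = rng.choice(list(spec.location_shift), size=n)
    hemisphere = rng.choice(["left", "right"], size=n)
    gender = rng.choice(["female", "male"], size=n)
    antiseizure = rng.choice(["no", "yes"], size=n)
    age = np.clip(rng.normal(40.0, 12.0, size=n), 18.0, 80.0)
    overlap = rng.integers(0, 40, size=n)
    shift = np.array([spec.location_shift[l] for l in locations])
    conn = spec.conn_base + shift + rng.normal(0.0, spec.conn_sd, size=n)
    preop = rng.normal(0.0, 1.0, size=n)
    timepoint = rng.choice(
        list(spec.timepoint_probs), size=n, p=list(spec.timepoint_probs.values())
    )

    c = spec.outcome_coefs
    lin = (
        spec.outcome_intercept
        + c.get("connectivity", 0.0) * _zscore(conn)
        + c.get("preop", 0.0) * _zscore(preop)
        + c.get("age", 0.0) * _zscore(age)
        + c.get("location[insula]", 0.0) * (locations == "insula")
        + c.get("location[temporal]", 0.0) * (locations == "temporal")
        + c.get("hemisphere[right]", 0.0) * (hemisphere == "right")
        + c.get("gender[male]", 0.0) * (gender == "male")
        + c.get("timepoint[month3]", 0.0) * (timepoint == "month 3")
        + c.get("timepoint[postop]", 0.0) * (timepoint == "post-op")
    )
    followup = lin + rng.normal(0.0, spec.residual_sd, size=n)
    missing = rng.random(n) < spec.missing_followup_frac
    followup = np.where(missing, np.nan, followup)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in range(n)],
            "tumour_network_connectivity": conn,
            "location": locations,
            "hemisphere": hemisphere,
            "overlap_with_network": overlap,
            "antiseizure": antiseizure,
            "age": age,
            "gender": gender,
            "preop_score": preop,
            "followup_score": followup,
            "latest_timepoint": timepoint,
        }
    )
    df.attrs["planted"] = {"outcome_coefs": dict(c),
                           "location_shift": dict(spec.location_shift),
                           "residual_sd": spec.residual_sd}
    return df
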