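"""Synthetic two-group resting-state cohort with known timescale structure.

Every voxel time series is a stationary AR(1) process whose coefficient is
set by the voxel's parcel and the subject's group, optionally perturbed per
subject.  The AR(1) coefficient ``phi`` maps to a generative timescale

    tau = TR * phi / (1 - phi)   [seconds]

which is exactly the TR-scaled sum of the theoretical autocorrelation
function over positive lags — i.e. the population value of the ACF-AUC
timescale statistic the pipeline estimates.  The cohort plants a mediation
chain on the subject-level generative timescales:

    GMV_AG   = intercept + gmv_int_coupling * tau_AG + noise
    tau_DMN  = base(group) + a_gen * (tau_AG deviation) + noise
    MMSE     = base + b_gen * tau_DMN + cprime_gen * tau_AG + noise

so that the downstream mediation suite has a known truth to recover: with
``cprime_gen = 0`` the chain GMV -> AG timescale -> DMN timescale -> MMSE is
a complete mediation.  Confound signals (slow sinusoidal "motion", low-pass
filtered "white matter" and "CSF" noise) are mixed into in-brain voxels so
the confound-regression stage has real work to do; background voxels are
pure white noise.

All randomness descends from ``CohortSpec.seed``; per-subject streams are
derived by stable hashing (CRC-32) of the subject id, so any single
subject's images can be regenerated lazily and independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .core import AtlasGeometry, Bold4D, Parcellation, SubjectRecord

CONFOUND_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "wm", "csf")

#: AR(1) coefficients per (parcel, group).  The AG carries the planted
#: group deficit (0.8 vs 0.5, i.e. generative timescales 8.8 s vs 2.2 s at
#: TR = 2.2 s); the DMN core and SMG are mildly shortened in AD; the six
#: control networks are group-neutral.
DEFAULT_PHI: dict[str, dict[str, float]] = {
    "DMN-core": {"CN": 0.70, "AD": 0.60},
    "AG": {"CN": 0.80, "AD": 0.50},
    "SMG": {"CN": 0.75, "AD": 0.60},
    "frontoparietal": {"CN": 0.50, "AD": 0.50},
    "DAN": {"CN": 0.50, "AD": 0.50},
    "VAN": {"CN": 0.50, "AD": 0.50},
    "limbic": {"CN": 0.50, "AD": 0.50},
    "somatomotor": {"CN": 0.50, "AD": 0.50},
    "visual": {"CN": 0.50, "AD": 0.50},
}

#: Box layout (half-open voxel ranges per axis) of the toy atlas on the
#: default 20 x 20 x 12 grid.  Parcels are separated by background so that
#: smoothing and clustering cannot bleed across them.
DEFAULT_LAYOUT: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = {
    "DMN-core": ((2, 8), (2, 8), (2, 8)),
    "AG": ((10, 14), (2, 6), (2, 5)),
    "SMG": ((10, 14), (7, 11), (2, 5)),
    "frontoparietal": ((15, 19), (2, 6), (2, 5)),
    "DAN": ((15, 19), (7, 11), (2, 5)),
    "VAN": ((15, 19), (12, 16), (2, 5)),
    "limbic": ((2, 6), (10, 14), (2, 5)),
    "somatomotor": ((2, 6), (15, 19), (2, 5)),
    "visual": ((8, 12), (15, 19), (2, 5)),
}

DEFAULT_NETWORKS: dict[str, str] = {
    "DMN-core": "DMN",
    "AG": "DMN",  # the AG and SMG parcels belong to the DMN
    "SMG": "DMN",
    "frontoparietal": "frontoparietal",
    "DAN": "DAN",
    "VAN": "VAN",
    "limbic": "limbic",
    "somatomotor": "somatomotor",
    "visual": "visual",
}

DEFAULT_GRID = (20, 20, 12)
DEFAULT_VOXEL_MM = (4.0, 4.0, 4.0)

# Centering constants for the generated MMSE (kept fixed so phenotypes are a
# pure function of the spec): reference generative timescales near the
# between-group midpoints, and a base score in the clinically typical range.
MMSE_BASE = 26.0
TAU_REF_DMN_S = 4.2
TAU_REF_AG_S = 5.5
GMV_INTERCEPT = 10.0


def phi_to_tau(phi: float, tr_s: float) -> float:
    """Generative timescale (s) of an AR(1) coefficient: TR * phi / (1 - phi)."""
    return tr_s * phi / (1.0 - phi)


def tau_to_phi(tau_s: float, tr_s: float) -> float:
    return tau_s / (tau_s + tr_s)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; every artifact is a pure
    function of this object (the seed included)."""

    n_cn: int = 30
    n_ad: int = 30
    n_timepoints: int = 160  # retained volumes, after the lead-in discard
    tr_s: float = 2.2
    n_discard: int = 5
    phi_by_region_and_group: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PHI.items()}
    )
    noise_sd: float = 1.0
    gmv_int_coupling: float = 1.0
    a_gen: float = 0.8
    b_gen: float = 0.6
    cprime_gen: float = 0.0
    confound_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"motion": 0.5, "wm": 0.5, "csf": 0.5}
    )
    tau_sd_s: float = 1.5  # between-subject sd of the AG generative timescale
    dmn_tau_sd_s: float = 0.5  # residual sd of the DMN generative timescale
    gmv_noise_sd: float = 0.5
    mmse_noise_sd: float = 1.0
    attention_coupling: float = 0.7  # digit span loading on the DMN timescale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cn < 1 or self.n_ad < 1 or self.n_timepoints < 1:
            raise ValueError("subject and timepoint counts must be >= 1")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")
        if not (self.tr_s > 0):
            raise ValueError("tr_s must be positive")
        for region, by_group in self.phi_by_region_and_group.items():
            for group, phi in by_group.items():
                if not abs(phi) < 1:
                    raise ValueError(f"|phi| must be < 1 for ({region!r}, {group!r}), got {phi}")

    def phi_for(self, region: str, group: str) -> float:
        try:
            return float(self.phi_by_region_and_group[region][group])
        except KeyError:
            raise KeyError(
                f"no AR(1) coefficient for parcel {region!r} in group {group!r}"
            ) from None

    @classmethod
    def null(cls, phi: float = 0.6, **kw) -> "CohortSpec":
        """A no-effect cohort: identical phi in both groups everywhere and
        all planted couplings zero.  Used for calibration checks."""
        flat = {region: {"CN": phi, "AD": phi} for region in DEFAULT_PHI}
        kw.setdefault("phi_by_region_and_group", flat)
        return cls(
            gmv_int_coupling=0.0, a_gen=0.0, b_gen=0.0, cprime_gen=0.0,
            attention_coupling=0.0, **kw,
        )


# ---------------------------------------------------------------------------
# Atlas construction


def default_geometry() -> AtlasGeometry:
    origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(DEFAULT_GRID, DEFAULT_VOXEL_MM))
    return AtlasGeometry(DEFAULT_GRID, DEFAULT_VOXEL_MM, origin)


def make_toy_atlas(
    geometry: AtlasGeometry,
    layout: Mapping[str, tuple],
    networks: Optional[Mapping[str, str]] = None,
) -> Parcellation:
    """Build a box-parcel atlas from ``layout`` (name -> half-open voxel
    ranges per axis).  Boxes must be pairwise disjoint and inside the grid.

    ``networks`` assigns each parcel to a functional network; by default the
    DMN-core/AG/SMG parcels map to "DMN" and every other parcel is its own
    network.
    """
    dims = geometry.grid_dims
    labels = np.zeros(dims, dtype=np.int32)
    owner: dict[str, str] = {}
    label_names: dict[int, str] = {}
    for i, (name, box) in enumerate(layout.items(), start=1):
        (x0, x1), (y0, y1), (z0, z1) = box
        if not (0 <= x0 < x1 <= dims[0] and 0 <= y0 < y1 <= dims[1] and 0 <= z0 < z1 <= dims[2]):
            raise ValueError(f"parcel {name!r} box {box} falls outside the {dims} grid")
        region = labels[x0:x1, y0:y1, z0:z1]
        if np.any(region != 0):
            clash = label_names[int(region[region != 0].flat[0])]
            raise ValueError(f"parcels {clash!r} and {name!r} overlap")
        labels[x0:x1, y0:y1, z0:z1] = i
        label_names[i] = name
        owner[name] = name
    if networks is None:
        networks = {
            name: (DEFAULT_NETWORKS.get(name, name)) for name in layout
        }
    return Parcellation(labels=labels, label_names=label_names,
                        network_of=dict(networks), geometry=geometry)


def default_toy_atlas() -> Parcellation:
    return make_toy_atlas(default_geometry(), DEFAULT_LAYOUT, DEFAULT_NETWORKS)


# ---------------------------------------------------------------------------
# AR(1) simulation


def simulate_ar1(phi: float, n: int, sd: float, seed) -> np.ndarray:
    """Draw one stationary AR(1) series x_t = phi x_{t-1} + eps_t.

    The first sample is drawn from the stationary distribution
    N(0, sd^2 / (1 - phi^2)), so the whole series is strictly stationary.
    ``seed`` may be an int or a numpy Generator.
    """
    if not abs(phi) < 1:
        raise ValueError(f"AR(1) requires |phi| < 1 for stationarity, got {phi}")
    if n < 2:
        raise ValueError("need n >= 2")
    if not (sd > 0):
        raise ValueError("sd must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _ar1_block(rng, phi, n, sd, 1)[0]


def _ar1_block(rng: np.random.Generator, phi: float, n: int, sd: float, rows: int) -> np.ndarray:
    """(rows, n) independent stationary AR(1) draws sharing one phi."""
    e = rng.standard_normal((rows, n)) * sd
    e[:, 0] = rng.standard_normal(rows) * sd / np.sqrt(1.0 - phi * phi)
    # lfilter realizes x_t = phi x_{t-1} + e_t with x_0 = e_0 (the
    # stationary draw placed in the first innovation slot).
    return lfilter([1.0], [1.0, -phi], e, axis=1)


# ---------------------------------------------------------------------------
# Confound signals


def _gen_confounds(rng: np.random.Generator, n: int, tr_s: float) -> pd.DataFrame:
    """Per-volume nuisance table: slow sinusoidal motion drifts plus
    low-frequency WM/CSF noise.  Draw order is fixed so that the table can
    be replayed independently of the voxel simulation."""
    t = np.arange(n) * tr_s
    cols: dict[str, np.ndarray] = {}
    for name in CONFOUND_COLUMNS[:6]:
        amp = rng.uniform(0.05, 0.30) if name.startswith("trans") else rng.uniform(0.001, 0.006)
        period = rng.uniform(60.0, 200.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        jitter = rng.standard_normal(n) * 0.02 * amp
        cols[name] = amp * np.sin(2 * np.pi * t / period + phase) + jitter
    for name in ("wm", "csf"):
        raw = gaussian_filter1d(rng.standard_normal(n), sigma=6.0)
        cols[name] = (raw - raw.mean()) / raw.std()
    return pd.DataFrame(cols, columns=list(CONFOUND_COLUMNS))


def _zscore_cols(df: pd.DataFrame) -> np.ndarray:
    arr = df.to_numpy(dtype=float).T  # (8, T)
    arr = arr - arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return arr / sd


# ---------------------------------------------------------------------------
# Subject-level simulation


def simulate_subject_bold(
    spec: CohortSpec,
    atlas: Parcellation,
    subject: SubjectRecord,
    seed,
    tau_by_parcel: Optional[Mapping[str, float]] = None,
) -> tuple[Bold4D, pd.DataFrame]:
    """Simulate one subject's 4D BOLD volume plus its confound table.

    The returned volume includes ``spec.n_discard`` lead-in volumes that the
    preprocessing stage is expected to drop; the confound table covers only
    the retained volumes.  ``tau_by_parcel`` overrides the group-level AR(1)
    coefficient of named parcels with a subject-specific generative
    timescale (seconds), which is how the cohort generator injects
    between-subject variation into the AG and DMN core.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = spec.n_timepoints + spec.n_discard
    conf_full = _gen_confounds(rng, n_total, spec.tr_s)

    dims = atlas.geometry.grid_dims
    vol = np.empty(dims + (n_total,), dtype=float)
    # background: pure white noise
    bg = ~atlas.brain_mask
    vol[bg] = rng.standard_normal((int(bg.sum()), n_total)) * spec.noise_sd

    tau_by_parcel = dict(tau_by_parcel or {})
    for lab in sorted(atlas.label_names):
        name = atlas.label_names[lab]
        if name in tau_by_parcel:
            phi = tau_to_phi(float(tau_by_parcel[name]), spec.tr_s)
        else:
            phi = spec.phi_for(name, subject.group)
        mask = atlas.labels == lab
        vol[mask] = _ar1_block(rng, phi, n_total, spec.noise_sd, int(mask.sum()))

    # confound leakage into in-brain voxels: random per-voxel loadings on
    # the z-scored confound columns, scaled by the configured amplitudes
    amps = np.array(
        [spec.confound_amplitudes.get("motion", 0.0)] * 6
        + [spec.confound_amplitudes.get("wm", 0.0),
           spec.confound_amplitudes.get("csf", 0.0)]
    )
    brain = atlas.brain_mask
    n_brain = int(brain.sum())
    loadings = rng.normal(1.0, 0.3, size=(n_brain, len(CONFOUND_COLUMNS)))
    if np.any(amps > 0):
        signals = _zscore_cols(conf_full)  # (8, T)
        vol[brain] += (loadings * amps) @ signals

    bold = Bold4D(values=vol, tr_s=spec.tr_s, geometry=atlas.geometry)
    confounds = conf_full.iloc[spec.n_discard:].reset_index(drop=True)
    return bold, confounds


def _subject_seed(spec_seed: int, subject_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(spec_seed), zlib.crc32(subject_id.encode())])


def subject_confounds(spec: CohortSpec, subject_id: str) -> pd.DataFrame:
    """Replay only the confound table of a subject (retained volumes)."""
    rng = np.random.default_rng(_subject_seed(spec.seed, subject_id).spawn(1)[0])
    conf = _gen_confounds(rng, spec.n_timepoints + spec.n_discard, spec.tr_s)
    return conf.iloc[spec.n_discard:].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort-level simulation

BATTERY_TESTS = ("digit_span", "tmt_a", "digit_symbol", "tmt_b",
                 "logical_memory", "boston_naming", "category_fluency")


@dataclass
class Cohort:
    """A simulated cohort.  Images are regenerated lazily per subject from
    the spec seed, so holding a cohort costs only its phenotype tables."""

    spec: CohortSpec
    atlas: Parcellation
    subjects: list[SubjectRecord]
    truth: pd.DataFrame  # subject, group, tau_ag_s, tau_dmn_s (generative)

    def bold_for(self, subject_id: str) -> tuple[Bold4D, pd.DataFrame]:
        subject = self.subject(subject_id)
        row = self.truth.loc[self.truth["subject"] == subject_id].iloc[0]
        taus = {"AG": float(row["tau_ag_s"]), "DMN-core": float(row["tau_dmn_s"])}
        rng = np.random.default_rng(_subject_seed(self.spec.seed, subject_id).spawn(1)[0])
        return simulate_subject_bold(self.spec, self.atlas, subject, rng, tau_by_parcel=taus)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(f"unknown subject {subject_id!r}")

    @property
    def phenotypes(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject": s.id, "group": s.group, "age": s.age, "sex": s.sex,
                "mmse": s.mmse, "mean_motion_mm": s.mean_motion_mm,
                "gmv_AG": s.roi_gmv.get("AG", np.nan),
                "gmv_SMG": s.roi_gmv.get("SMG", np.nan),
            }
            for test in BATTERY_TESTS:
                row[test] = (s.battery or {}).get(test, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec, atlas: Optional[Parcellation] = None) -> Cohort:
    """Generate the phenotype side of a cohort and plant the mediation chain.

    AD subjects receive the shorter-timescale AR(1) coefficients of
    ``spec.phi_by_region_and_group``; subject-level AG and DMN-core
    generative timescales vary around the group values and drive GMV and
    MMSE as documented in the module docstring.  Images are lazy (see
    :meth:`Cohort.bold_for`).
    """
    if atlas is None:
        atlas = default_toy_atlas()
    tr = spec.tr_s
    subjects: list[SubjectRecord] = []
    truth_rows = []
    ids = [f"CN{i:03d}" for i in range(1, spec.n_cn + 1)] + \
          [f"AD{i:03d}" for i in range(1, spec.n_ad + 1)]
    groups = ["CN"] * spec.n_cn + ["AD"] * spec.n_ad
    for sid, group in zip(ids, groups):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), zlib.crc32(sid.encode()), 7])
        )
        tau_ag_base = phi_to_tau(spec.phi_for("AG", group), tr)
        tau_dmn_base = phi_to_tau(spec.phi_for("DMN-core", group), tr)
        delta = rng.normal(0.0, spec.tau_sd_s)
        tau_ag = float(np.clip(tau_ag_base + delta, 0.3, 60.0))
        tau_dmn = float(np.clip(
            tau_dmn_base + spec.a_gen * delta + rng.normal(0.0, spec.dmn_tau_sd_s),
            0.3, 60.0,
        ))
        gmv_ag = GMV_INTERCEPT + spec.gmv_int_coupling * tau_ag + rng.normal(0.0, spec.gmv_noise_sd)
        tau_smg = phi_to_tau(spec.phi_for("SMG", group), tr)
        gmv_smg = GMV_INTERCEPT + spec.gmv_int_coupling * tau_smg + rng.normal(0.0, spec.gmv_noise_sd)
        mmse_raw = (MMSE_BASE
                    + spec.b_gen * (tau_dmn - TAU_REF_DMN_S)
                    + spec.cprime_gen * (tau_ag - TAU_REF_AG_S)
                    + rng.normal(0.0, spec.mmse_noise_sd))
        mmse = int(np.clip(np.rint(mmse_raw), 0, 30))
        age = float(np.clip(rng.normal(74.0 if group == "AD" else 72.0, 6.0), 55.0, 95.0))
        sex = "F" if rng.random() < 0.5 else "M"
        battery = {
            "digit_span": float(10.0 + spec.attention_coupling * (tau_dmn - TAU_REF_DMN_S)
                                + rng.normal(0.0, 1.0)),
            "tmt_a": float(np.clip(45.0 + rng.normal(0.0, 10.0), 5.0, 300.0)),
            "digit_symbol": float(40.0 + rng.normal(0.0, 8.0)),
            "tmt_b": float(np.clip(110.0 + rng.normal(0.0, 25.0), 10.0, 400.0)),
            "logical_memory": float(10.0 + rng.normal(0.0, 3.0)),
            "boston_naming": float(50.0 + rng.normal(0.0, 5.0)),
            "category_fluency": float(18.0 + rng.normal(0.0, 4.0)),
        }
        conf = subject_confounds(spec, sid)
        trans = conf[["trans_x", "trans_y", "trans_z"]].to_numpy()
        mean_motion = float(np.mean(np.linalg.norm(trans, axis=1)))
        subjects.append(SubjectRecord(
            id=sid, group=group, age=age, sex=sex, mmse=mmse,
            roi_gmv={"AG": float(gmv_ag), "SMG": float(gmv_smg)},
            mean_motion_mm=mean_motion, battery=battery,
        ))
        truth_rows.append({"subject": sid, "group": group,
                           "tau_ag_s": tau_ag, "tau_dmn_s": tau_dmn})
    return Cohort(spec=spec, atlas=atlas, subjects=subjects,
                  truth=pd.DataFrame(truth_rows))


def null_cohort_spec(seed: int, **kw) -> CohortSpec:
    """Convenience wrapper for :meth:`CohortSpec.null` with a seed."""
    return replace(CohortSpec.null(**kw), seed=seed)
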