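"""Synthetic cohorts with known distributional ground truth.

Everything the downstream pipeline consumes can be generated here: degree
sequences drawn directly from the discrete candidate laws (the precise test
path for the fitting machinery), voxel time series with community structure
and per-voxel "hubness" (a stand-in for cleaned, band-limited resting-state
series), and a demographic/cognition table mirroring a two-group
HC-vs-aMCI study design.

Degree-sequence sampling uses inverse-CDF lookup on a pmf table built from
the *same* discretization the fitting module uses, truncated where the
cumulative mass exceeds ``1 - 1e-9`` (bounded memory, negligible bias).

The time-series generator emulates a grey-matter slab on a 3-mm lattice:
voxel i carries ``x_i(t) = sqrt(c_i)*s_g(i)(t) + sqrt(1-c_i)*eps_i(t)``
with one shared signal s per community (atlas label) and coupling c_i — the
voxel's hubness — drawn from a configurable distribution.  Voxels with high
coupling correlate strongly with many community members and so acquire high
degree after thresholding.  Communities are spatially interdigitated
(random label assignment) so the short-distance exclusion rule does not
remove within-community edges wholesale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import heavytail

logger = logging.getLogger(__name__)

NETWORKS = ("V", "SM", "DA", "VA", "Lim", "FP", "DM")
WHOLE_BRAIN = "whole_brain"

_TAIL_MASS = 1e-9
_MAX_TABLE = 1 << 23

#: Per-network baseline Weibull shape for the degrees-mode generator.  All
#: lie in (0, 1) — between power-law-like and exponential behavior, the
#: regime reported for voxelwise functional networks.
DEFAULT_BETA0 = {
    WHOLE_BRAIN: 0.60, "V": 0.65, "SM": 0.62, "DA": 0.58, "VA": 0.55,
    "Lim": 0.52, "FP": 0.63, "DM": 0.68,
}
DEFAULT_LAMBDA = 0.1
#: Within-group SD of the per-subject Weibull shape.
DEFAULT_BETA_SD = 0.05
#: Degrees sampled per network in degrees mode (whole brain larger, as a
#: whole-brain sequence pools every voxel).
DEFAULT_N_DEGREES = {WHOLE_BRAIN: 600, **{k: 150 for k in NETWORKS}}


@dataclass
class SyntheticScene:
    """Per-subject voxel time series on a 3-mm lattice.

    ``series`` is (n_voxels, n_timepoints); ``coords`` are voxel centers in
    mm; ``atlas`` holds subnetwork labels 0-7 (0 = unassigned).
    """

    series: np.ndarray
    coords: np.ndarray
    atlas: np.ndarray
    grid_spacing: float = 3.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.atlas = np.asarray(self.atlas, dtype=int)
        if self.series.ndim != 2 or self.series.shape[0] < 2:
            raise ValueError("series must be (n_voxels >= 2, n_timepoints)")
        if self.coords.shape != (self.series.shape[0], 3):
            raise ValueError("coords must be (n_voxels, 3)")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("voxel coordinates must be unique")
        if self.atlas.shape != (self.series.shape[0],):
            raise ValueError("atlas must be (n_voxels,)")
        if self.atlas.min() < 0 or self.atlas.max() > 7:
            raise ValueError("atlas labels must lie in 0..7")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains missing values")

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass
class GroundTruth:
    """Generative parameters stored with every synthetic dataset, for
    parameter-recovery tests."""

    model: str
    params: dict
    group_effect: float
    cognition_slope: float
    seed: int
    subject_params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# discrete-law samplers
# ---------------------------------------------------------------------------


def _pmf_table(model: str, params: Mapping[str, float], xmin: int) -> np.ndarray:
    """Cumulative pmf table from xmin up to the value where the survival
    mass drops below _TAIL_MASS (capped at _MAX_TABLE entries)."""
    lo, size = xmin, 1024
    chunks = []
    while True:
        k = np.arange(lo, lo + size)
        chunks.append(heavytail.discrete_pmf(model, params, k, xmin))
        lo += size
        surv = heavytail.model_survival(model, params, np.array([lo]), xmin)[0]
        if surv < _TAIL_MASS or (lo - xmin) >= _MAX_TABLE:
            if (lo - xmin) >= _MAX_TABLE and surv >= _TAIL_MASS:
                logger.warning(
                    "pmf table for %s capped at %d entries with tail mass %.3g",
                    model, _MAX_TABLE, surv)
            break
        size = min(size * 2, _MAX_TABLE - (lo - xmin))
    return np.cumsum(np.concatenate(chunks))


def _check_sample_args(n: int, xmin: int) -> None:
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")


def sample_discrete_weibull(beta: float, lam: float, n: int, xmin: int = 1,
                            seed=None) -> np.ndarray:
    """Sample n integers >= xmin from the rounding-discretized Weibull law
    (same discretization as the fitting module).

    Because the discrete law is the rounding of a continuous one, sampling
    draws from the continuous Weibull truncated to ``x >= xmin - 1/2`` by
    inverse CDF and rounds to the nearest integer — exact and O(n).
    """
    if beta <= 0 or lam <= 0:
        raise ValueError("beta and lam must be positive")
    _check_sample_args(n, xmin)
    rng = np.random.default_rng(seed)
    x0 = xmin - 0.5
    u = rng.random(n)
    # survival ratio S(x)/S(x0) = u  =>  x = ((lam*x0**beta - log u)/lam)**(1/beta)
    x = ((lam * x0**beta - np.log1p(-u)) / lam) ** (1.0 / beta)
    return np.maximum(np.rint(x).astype(np.int64), xmin)


def sample_discrete_powerlaw(alpha: float, n: int, xmin: int = 1,
                             seed=None) -> np.ndarray:
    """Sample n integers >= xmin from the zeta-normalized discrete power law,
    by inverse-CDF lookup on a pmf table truncated where the cumulative mass
    exceeds 1 - 1e-9 (bounded memory, negligible bias)."""
    if alpha <= 1:
        raise ValueError("power law requires alpha > 1 (non-normalizable otherwise)")
    _check_sample_args(n, xmin)
    cdf = _pmf_table("powerlaw", {"alpha": alpha}, xmin)
    rng = np.random.default_rng(seed)
    u = rng.random(n) * cdf[-1]
    return (xmin + np.searchsorted(cdf, u, side="left")).astype(np.int64)


def sample_discrete_truncated_powerlaw(alpha: float, lam: float, n: int,
                                       xmin: int = 1, seed=None) -> np.ndarray:
    """Sample n integers >= xmin from the rounding-discretized power law
    with exponential cutoff.

    Continuous draws come from rejection sampling with the pure truncated
    power law as proposal (acceptance probability exp(-lam*(x - x0)), which
    is near 1 for the small-x region carrying most of the mass); rounding
    the accepted draws gives the discrete law exactly.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if alpha <= 1:
        raise ValueError("truncated-power-law sampler requires alpha > 1 "
                         "(proposal law must be normalizable)")
    _check_sample_args(n, xmin)
    rng = np.random.default_rng(seed)
    x0 = xmin - 0.5
    out = np.empty(0)
    while out.size < n:
        m = max(2 * (n - out.size), 1024)
        x = x0 * rng.random(m) ** (-1.0 / (alpha - 1.0))
        accept = rng.random(m) < np.exp(-lam * (x - x0))
        out = np.concatenate([out, x[accept]])
    x = out[:n]
    return np.maximum(np.rint(x).astype(np.int64), xmin)


# ---------------------------------------------------------------------------
# time-series scenes
# ---------------------------------------------------------------------------


def _resolve_hubness(hubness_dist) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Accept a callable(rng, size), ('beta', a, b) or ('point', c)."""
    if callable(hubness_dist):
        return hubness_dist
    kind = hubness_dist[0]
    if kind == "beta":
        a, b = hubness_dist[1], hubness_dist[2]
        return lambda rng, size: rng.beta(a, b, size)
    if kind == "point":
        c = float(hubness_dist[1])
        if not 0.0 <= c <= 1.0:
            raise ValueError("point-mass hubness must lie in [0, 1]")
        return lambda rng, size: np.full(size, c)
    raise ValueError(f"unknown hubness spec {hubness_dist!r}")


def _lattice_coords(n_voxels: int, spacing: float) -> np.ndarray:
    """Flat two-layer slab: maximizes in-plane extent so the short-distance
    exclusion leaves most voxel pairs eligible."""
    nz = 2 if n_voxels >= 100 else 1
    nx = int(np.ceil(np.sqrt(n_voxels / nz)))
    ny = int(np.ceil(n_voxels / (nx * nz)))
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])[:n_voxels]
    return pts.astype(float) * spacing


def generate_timeseries(n_voxels: int, n_timepoints: int,
                        hubness_dist=("beta", 2.0, 5.0),
                        seed=None, n_communities: int = 7,
                        grid_spacing: float = 3.0) -> SyntheticScene:
    """Generate one subject's voxel time series with community structure.

    Each voxel mixes a shared community signal with private noise according
    to its hubness coupling c_i; the expected correlation of two voxels in
    the same community is sqrt(c_i * c_j), so hubness governs degree.
    """
    if n_voxels < 50:
        raise ValueError("need n_voxels >= 50")
    if n_timepoints < 100:
        raise ValueError("need n_timepoints >= 100")
    if not 1 <= n_communities <= 7:
        raise ValueError("n_communities must lie in 1..7")
    rng = np.random.default_rng(seed)
    draw = _resolve_hubness(hubness_dist)
    c = np.clip(np.asarray(draw(rng, n_voxels), dtype=float), 0.0, 1.0)
    if np.all(c == 0):
        logger.warning("degenerate hubness: all couplings are 0; the network "
                       "will be empty at any positive threshold")
    atlas = rng.integers(1, n_communities + 1, size=n_voxels)
    signals = rng.standard_normal((n_communities + 1, n_timepoints))
    noise = rng.standard_normal((n_voxels, n_timepoints))
    series = (np.sqrt(c)[:, None] * signals[atlas]
              + np.sqrt(1.0 - c)[:, None] * noise)
    return SyntheticScene(series=series, coords=_lattice_coords(n_voxels, grid_spacing),
                          atlas=atlas, grid_spacing=grid_spacing)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Demographic templates per group: (age mean, age sd), male fraction,
#: (education mean, sd) — a two-group elderly design where the patient
#: group runs older, as is typical of aMCI samples.
_DEMO = {
    "HC": {"age": (70.3, 7.0), "male_frac": 13 / 41, "edu": (4.3, 0.9)},
    "aMCI": {"age": (74.8, 5.7), "male_frac": 13 / 30, "edu": (4.2, 1.1)},
}
#: Cognition generator: baseline score, group offset for aMCI, small
#: negative age slope, residual noise SD (score points), and the spread
#: between the two screening instruments.
_COG = {"base": 27.0, "amci_offset": -2.8, "age_slope": -0.05, "noise_sd": 1.5,
        "instrument_gap": 1.4, "instrument_noise": 0.75}
#: Hubness Beta parameters per group for timeseries mode; the aMCI setting
#: puts more mass on extreme couplings (more hubs, heavier degree tail,
#: hence a lower fitted Weibull shape).
DEFAULT_HUBNESS = {"HC": ("beta", 2.0, 5.0), "aMCI": ("beta", 1.5, 4.0)}


def _demographics(records_rng: np.random.Generator, group: str, idx: int) -> dict:
    d = _DEMO[group]
    age = float(np.clip(records_rng.normal(*d["age"]), 55.0, 85.0))
    gender = "M" if records_rng.random() < d["male_frac"] else "F"
    edu = float(np.clip(records_rng.normal(*d["edu"]), 0.0, 22.0))
    return {"subject_id": f"{group.lower()}{idx:03d}", "group": group,
            "age": round(age, 1), "gender": gender, "education": round(edu, 1)}


def generate_cohort(n_hc: int = 41, n_amci: int = 30,
                    delta_beta: float = 0.1, cognition_slope: float = 20.0,
                    seed=None, mode: str = "degrees",
                    beta0: Mapping[str, float] | None = None,
                    lam: float = DEFAULT_LAMBDA,
                    beta_sd: float = DEFAULT_BETA_SD,
                    n_degrees: Mapping[str, int] | None = None,
                    n_voxels: int = 400, n_timepoints: int = 240,
                    hubness: Mapping[str, tuple] | None = None,
                    ) -> tuple[pd.DataFrame, dict, GroundTruth]:
    """Generate a two-group cohort with known ground truth.

    mode="degrees" (default, the precise test path): each subject's degree
    sequence per network is drawn directly from a discrete Weibull whose
    shape is ``beta0[network] - delta_beta*[aMCI] + N(0, beta_sd)``.  The
    second element returned maps subject_id -> network -> degree array.

    mode="timeseries": each subject gets a :class:`SyntheticScene` whose
    hubness distribution is shifted for the aMCI group (delta_beta is then
    only approximately realized through the hubness shift).  The second
    element maps subject_id -> SyntheticScene.

    Cognitive ability couples linearly to the subject's whole-brain Weibull
    shape (slope ``cognition_slope`` score points per unit shape) plus
    covariate terms and Gaussian noise; MMSE and MoCA are emitted so their
    mean recovers it, clipped to [0, 30].
    """
    if n_hc < 2 or n_amci < 2:
        raise ValueError("need at least 2 subjects per group")
    if mode not in ("degrees", "timeseries"):
        raise ValueError("mode must be 'degrees' or 'timeseries'")
    beta0 = dict(DEFAULT_BETA0 if beta0 is None else beta0)
    n_degrees = dict(DEFAULT_N_DEGREES if n_degrees is None else n_degrees)
    hubness = dict(DEFAULT_HUBNESS if hubness is None else hubness)
    root = np.random.SeedSequence(seed)
    rec_rng = np.random.default_rng(root.spawn(1)[0])
    data_seeds = root.spawn(n_hc + n_amci)

    groups = ["HC"] * n_hc + ["aMCI"] * n_amci
    records, payload, subj_betas = [], {}, {}
    for idx, (group, sseq) in enumerate(zip(groups, data_seeds)):
        rec = _demographics(rec_rng, group, idx)
        sid = rec["subject_id"]
        srng = np.random.default_rng(sseq)
        shift = delta_beta if group == "aMCI" else 0.0
        betas = {net: float(np.clip(b0 - shift + rec_rng.normal(0.0, beta_sd),
                                    0.05, 3.0))
                 for net, b0 in beta0.items()}
        subj_betas[sid] = betas
        if mode == "degrees":
            payload[sid] = {net: sample_discrete_weibull(b, lam, n_degrees[net],
                                                         xmin=1, seed=srng)
                            for net, b in betas.items()}
        else:
            payload[sid] = generate_timeseries(n_voxels, n_timepoints,
                                               hubness_dist=hubness[group],
                                               seed=srng)
        # cognition linearly coupled to the subject's whole-brain shape
        ability = (_COG["base"]
                   + cognition_slope * (betas[WHOLE_BRAIN] - beta0[WHOLE_BRAIN])
                   + (_COG["amci_offset"] if group == "aMCI" else 0.0)
                   + _COG["age_slope"] * (rec["age"] - 70.0)
                   + rec_rng.normal(0.0, _COG["noise_sd"]))
        g = _COG["instrument_gap"]
        sdi = _COG["instrument_noise"]
        rec["mmse"] = float(np.clip(round(ability + g + rec_rng.normal(0, sdi)), 0, 30))
        rec["moca"] = float(np.clip(round(ability - g + rec_rng.normal(0, sdi)), 0, 30))
        records.append(rec)

    truth = GroundTruth(
        model="weibull",
        params={"beta0": beta0, "lam": lam, "beta_sd": beta_sd,
                "cognition": dict(_COG), "mode": mode},
        group_effect=delta_beta,
        cognition_slope=cognition_slope,
        seed=-1 if seed is None else int(seed),
        subject_params=subj_betas,
    )
    return pd.DataFrame(records), payload, truth


def cohort_to_csv(records: pd.DataFrame, path) -> None:
    cols = ["subject_id", "group", "age", "gender", "education", "mmse", "moca"]
    records[cols].to_csv(path, index=False)


def cognitive_ability(records: pd.DataFrame) -> pd.Series:
    """Cognitive ability = mean of the two 30-point screening scores."""
    return (records["mmse"] + records["moca"]) / 2.0
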