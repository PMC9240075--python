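"""Stochastic single-cell simulator of clonal hematopoiesis with superimposed
integration sites (IS).

The model tracks a pool of stem cells partitioned into clones.  Each cell
divides with a logistically regulated probability ``p(t) = p_max * (1 -
N_total/K)`` per unit time and leaves the observed pool (differentiates) with
a clone-specific probability ``r_c`` drawn once per clone from N(d, delta^2)
truncated at 0.  A larger spread ``delta`` of differentiation rates
accelerates clonal dominance: slow-differentiating clones progressively take
over the pool.

Each clone carries Poisson(lambda) integration sites, every one of which is
an exact copy of the clone's cell-count trajectory.  Measurement noise is
multiplicative per IS and measurement (g ~ N(1, sigma^2)); clonal
variability (the differing contribution of a clone to different
hematopoietic compartments) is multiplicative per clone and measurement
(f ~ N(1, nu^2)).  Observed values are the column-normalized relative
abundances, so the ground-truth IS-to-clone map is known exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import AbundanceMatrix, ReadCountMatrix, SampleMeta

__all__ = [
    "SimulationConfig",
    "CloneTrajectories",
    "ISMap",
    "SimulationResult",
    "simulate_clonal_dynamics",
    "assign_integration_sites",
    "superimpose_is",
    "apply_noise",
    "simulate",
    "noise_interval_halfwidth",
    "MixFixture",
    "make_mix_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated clone-tracking experiment.

    Rates are per unit time; the integrator picks a step ``dt`` small enough
    that per-step event probabilities stay below 0.1 unless ``dt`` is given
    explicitly.
    """

    n_clones: int = 100
    cells_per_clone: int = 100
    d: float = 0.1           #: mean differentiation rate
    delta: float = 0.0025    #: SD of the clone-wise differentiation rate
    p_max: float = 0.2       #: maximal proliferation rate
    K: int | None = None     #: carrying capacity; default 1.5x initial cells
    t_end: float = 750.0
    n_measurements: int = 8
    lam: float = 5.0         #: mean IS per clone (vector copy number)
    sigma: float = 0.04      #: measurement-noise SD
    nu: float = 0.0          #: clonal-variability SD
    seed: int = 0
    dt: float | None = None  #: integrator step; None = auto

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.cells_per_clone < 1:
            raise ValueError("n_clones and cells_per_clone must be positive")
        for name in ("d", "delta", "p_max", "sigma", "nu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n_measurements < 2:
            raise ValueError("need at least 2 measurements")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")

    @property
    def initial_cells(self) -> int:
        return self.n_clones * self.cells_per_clone

    @property
    def carrying_capacity(self) -> int:
        return self.K if self.K is not None else int(round(1.5 * self.initial_cells))

    def resolve_dt(self) -> float:
        """Step size keeping per-cell event probabilities small."""
        if self.dt is not None:
            return self.dt
        max_rate = max(self.p_max, self.d + 5.0 * self.delta, 1e-12)
        return min(1.0, 0.1 / max_rate)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class CloneTrajectories:
    """Per-clone cell counts N_c(t) on the measurement grid."""

    clone_ids: list[str]
    times: np.ndarray
    sizes: np.ndarray  # int, shape (n_clones, n_measurements)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{t:g}" for t in self.times]
        return pd.DataFrame(self.sizes, index=self.clone_ids, columns=cols)


@dataclass
class ISMap:
    """Ground-truth assignment of every IS to its clone."""

    clone_of: dict[str, str]  # is_id -> clone_id

    @property
    def is_ids(self) -> list[str]:
        return list(self.clone_of)

    def labels_for(self, is_ids: Sequence[str]) -> list[str]:
        return [self.clone_of[i] for i in is_ids]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"clone_id": pd.Series(self.clone_of)})
        df.index.name = "is_id"
        return df


@dataclass
class SimulationResult:
    """Everything one simulated experiment produced, ground truth included."""

    config: SimulationConfig
    trajectories: CloneTrajectories
    is_map: ISMap
    observed: AbundanceMatrix  # noisy, column-normalized relative abundances
    raw_is: pd.DataFrame       # noise-free IS copy-count matrix


def _measurement_grid(config: SimulationConfig) -> np.ndarray:
    """Equally spaced measurement times on (0, t_end]."""
    n = config.n_measurements
    return config.t_end * np.arange(1, n + 1) / n


def simulate_clonal_dynamics(config: SimulationConfig,
                             rng: np.random.Generator | None = None
                             ) -> CloneTrajectories:
    """Run the per-cell birth/differentiation process for all clones.

    Within one step of length dt each cell divides with probability
    ``p(t)*dt``, differentiates (leaves the pool) with probability
    ``r_c*dt``, or stays — sampled as a multinomial per clone.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.resolve_dt()
    r = rng.normal(config.d, config.delta, size=config.n_clones)
    r = np.maximum(r, 0.0)  # rates truncated at zero
    if config.p_max * dt > 1 or np.max(r) * dt > 1:
        raise ValueError("event probability exceeds 1; use a smaller dt")
    K = float(config.carrying_capacity)
    n_steps = int(math.ceil(config.t_end / dt))
    times = _measurement_grid(config)
    # map each measurement time to the step after which it is recorded
    record_at = np.minimum(np.round(times / dt).astype(int), n_steps)

    N = np.full(config.n_clones, config.cells_per_clone, dtype=np.int64)
    out = np.zeros((config.n_clones, len(times)), dtype=np.int64)
    rec = {}
    for step_idx, t_idx in zip(record_at, range(len(times))):
        rec.setdefault(int(step_idx), []).append(t_idx)
    for j in rec.get(0, []):  # degenerate: measurement at t ~ 0
        out[:, j] = N
    for step in range(1, n_steps + 1):
        p = max(0.0, config.p_max * (1.0 - N.sum() / K))
        p_div = min(1.0, p * dt)
        p_diff = r * dt
        if p_div + np.max(p_diff) > 1:
            raise ValueError("event probability exceeds 1; use a smaller dt")
        n_div = rng.binomial(N, p_div)
        remaining = N - n_div
        # conditional probability of differentiating given no division
        cond = np.where(p_div < 1.0, p_diff / (1.0 - p_div), 0.0)
        n_diff = rng.binomial(remaining, cond)
        N = N + n_div - n_diff
        for j in rec.get(step, []):
            out[:, j] = N
    clone_ids = [f"clone{c:03d}" for c in range(config.n_clones)]
    return CloneTrajectories(clone_ids, times, out)


def assign_integration_sites(clone_ids: Sequence[str], lam: float,
                             rng: np.random.Generator) -> ISMap:
    """Draw Poisson(lam) integration sites for every clone.

    Clones drawing zero IS remain in the dynamics but contribute no
    observable IS (they mimic untransduced cells in a real graft).
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    counts = rng.poisson(lam, size=len(clone_ids))
    clone_of: dict[str, str] = {}
    serial = 0
    for cid, m in zip(clone_ids, counts):
        for _ in range(int(m)):
            clone_of[f"is{serial:05d}"] = cid
            serial += 1
    return ISMap(clone_of)


def superimpose_is(traj: CloneTrajectories, is_map: ISMap) -> pd.DataFrame:
    """Copy each clone's trajectory onto each of its IS (noise-free)."""
    index = {cid: i for i, cid in enumerate(traj.clone_ids)}
    for iid, cid in is_map.clone_of.items():
        if cid not in index:
            raise ValueError(f"IS {iid!r} maps to unknown clone {cid!r}")
    rows = [traj.sizes[index[is_map.clone_of[iid]]] for iid in is_map.is_ids]
    cols = [f"m{j + 1:02d}" for j in range(len(traj.times))]
    return pd.DataFrame(
        np.asarray(rows, dtype=float), index=is_map.is_ids, columns=cols
    )


def apply_noise(raw: pd.DataFrame, is_map: ISMap, sigma: float, nu: float,
                rng: np.random.Generator,
                samples: Sequence[SampleMeta] | None = None) -> AbundanceMatrix:
    """Apply measurement noise and clonal variability, then normalize.

    Per IS and measurement: g ~ N(1, sigma^2); per clone and measurement:
    f ~ N(1, nu^2).  Negative products are truncated to 0 and every column is
    divided by its total.
    """
    if sigma < 0 or nu < 0:
        raise ValueError("sigma and nu must be >= 0")
    vals = raw.to_numpy(dtype=float)
    g = rng.normal(1.0, sigma, size=vals.shape) if sigma > 0 else np.ones(vals.shape)
    clones = sorted({is_map.clone_of[i] for i in raw.index})
    clone_pos = {c: i for i, c in enumerate(clones)}
    f_clone = (rng.normal(1.0, nu, size=(len(clones), vals.shape[1]))
               if nu > 0 else np.ones((len(clones), vals.shape[1])))
    f = f_clone[[clone_pos[is_map.clone_of[i]] for i in raw.index], :]
    noisy = np.maximum(f * g * vals, 0.0)
    totals = noisy.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if len(zero):
        raise ValueError(
            f"column {raw.columns[zero[0]]!r} is all zero after noise truncation"
        )
    rel = pd.DataFrame(noisy / totals, index=raw.index, columns=raw.columns)
    meta = list(samples) if samples else []
    return AbundanceMatrix(rel, meta)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Full generative run: dynamics -> IS map -> superposition -> noise."""
    rng = np.random.default_rng(config.seed)
    traj = simulate_clonal_dynamics(config, rng)
    is_map = assign_integration_sites(traj.clone_ids, config.lam, rng)
    if not is_map.clone_of:
        raise ValueError("no integration sites drawn; increase lam or n_clones")
    raw = superimpose_is(traj, is_map)
    samples = [
        SampleMeta(f"m{j + 1:02d}", float(t)) for j, t in enumerate(traj.times)
    ]
    observed = apply_noise(raw, is_map, config.sigma, config.nu, rng, samples)
    return SimulationResult(config, traj, is_map, observed, raw)


def noise_interval_halfwidth(sigma: float, level: float = 0.95) -> float:
    """Half-width of the central ``level`` interval of g ~ N(1, sigma^2),
    as a fraction of the true value (e.g. 0.0784 for sigma = 0.04)."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return z * sigma


# ---------------------------------------------------------------------------
# In-vitro-style clone-mix fixture
# ---------------------------------------------------------------------------

#: Cell-fraction of each foreground clone (rows) in the seven mixes (cols).
#: Chosen so the four clones have mutually distinct profiles; the remainder
#: of each mix (14-57% of cells) is the transduced background line.
MIX_PROPORTIONS = pd.DataFrame(
    {
        "mix1": [0.30, 0.10, 0.25, 0.20],
        "mix2": [0.05, 0.40, 0.08, 0.15],
        "mix3": [0.10, 0.05, 0.45, 0.10],
        "mix4": [0.02, 0.25, 0.05, 0.50],
        "mix5": [0.20, 0.03, 0.15, 0.05],
        "mix6": [0.01, 0.15, 0.30, 0.40],
        "mix7": [0.08, 0.30, 0.02, 0.25],
    },
    index=["ID27", "ID30", "ID37", "ID46"],
)

#: Number of IS carried by each foreground clone.
MIX_IS_COUNTS = {"ID27": 1, "ID30": 4, "ID37": 6, "ID46": 10}


@dataclass
class MixFixture:
    """Synthetic analog of the in vitro clone-mix validation assay."""

    counts: ReadCountMatrix
    truth: ISMap
    proportions: pd.DataFrame  # clone cell fractions incl. background row


def make_mix_fixture(seed: int = 0, read_depth: int = 1_000_000,
                     read_noise_sd: float = 0.04,
                     n_background_clones: int = 120,
                     background_vcn: float = 1.8) -> MixFixture:
    """Generate the 4-clone / 7-mix validation dataset.

    Four foreground clones carry 1/4/6/10 IS and are mixed at known,
    per-mix cell fractions; a polyclonal transduced background (mean vector
    copy number ~1.8) fills the remainder of each mix.  Read counts get
    multiplicative noise g ~ N(1, read_noise_sd^2) per IS and mix.  The
    proportions are this package's own design (synthetic), not measured ones.
    """
    rng = np.random.default_rng(seed)
    mixes = list(MIX_PROPORTIONS.columns)
    fg = MIX_PROPORTIONS.copy()
    bg_total = 1.0 - fg.sum(axis=0)  # cell fraction of the background line

    # background clone cell fractions: fairly even (concentrated Dirichlet)
    bg_weights = rng.dirichlet(np.full(n_background_clones, 5.0))
    bg_is_counts = rng.poisson(background_vcn, size=n_background_clones)

    clone_of: dict[str, str] = {}
    rows = []
    row_ids = []
    for cid in fg.index:
        for j in range(MIX_IS_COUNTS[cid]):
            iid = f"{cid}_is{j + 1:02d}"
            clone_of[iid] = cid
            rows.append(fg.loc[cid].to_numpy())
            row_ids.append(iid)
    for b in range(n_background_clones):
        cid = f"bg{b:03d}"
        cell_frac = bg_weights[b] * bg_total.to_numpy()
        for j in range(int(bg_is_counts[b])):
            iid = f"{cid}_is{j + 1:02d}"
            clone_of[iid] = cid
            rows.append(cell_frac)
            row_ids.append(iid)

    cell_frac = np.asarray(rows)  # each IS at its clone's cell fraction
    g = rng.normal(1.0, read_noise_sd, size=cell_frac.shape)
    noisy = np.maximum(cell_frac * g, 0.0)
    share = noisy / noisy.sum(axis=0)
    counts = np.round(share * read_depth).astype(np.int64)
    df = pd.DataFrame(counts, index=row_ids, columns=mixes)
    samples = [SampleMeta(m, float(i), "mix") for i, m in enumerate(mixes)]
    proportions = pd.concat(
        [fg, bg_total.rename("background").to_frame().T]
    )
    return MixFixture(ReadCountMatrix(df, samples), ISMap(clone_of), proportions)
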