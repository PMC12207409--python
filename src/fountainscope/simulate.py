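"""Stochastic 1D loop-extrusion simulator with oriented CTCF-like barriers.

A chromosome is a lattice of ``n_bins`` sites. Cohesin-like extruders carry
two legs; both legs step outward each time step unless stalled by an oriented
barrier or by another extruder's leg (legs block, no bypass — the cohesin
"traffic jam" premise). A bound extruder unloads with probability
``release_rate`` per step (the WAPL-activity proxy) or via a small
WAPL-independent ``turnover_rate`` (cohesin synthesis/degradation exchange),
and immediately attempts to re-load at a site drawn from
``loading_profile``, so occupancy stays at steady state. Contacts between the two leg positions are accumulated over
all post-burn-in steps and combined with a power-law background.

Barrier orientation convention: motifs point toward the loop interior. A
"+" barrier stalls the *leftward*-moving leg arriving from its right; a "−"
barrier stalls the *rightward*-moving leg arriving from its left. A
convergent pair is therefore ("+" upstream, "−" downstream) and traps a loop
loaded between the two, reproducing the CTCF convergence rule.

Acute-depletion conditions map onto single parameters (presets):
RAD21-off ``n_cohesins=0``; WAPL-off ``release_rate=0``; CTCF-off
``stall_probability=0``; WAPL/CTCF-off both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix

__all__ = [
    "SimParams",
    "ExtrusionResult",
    "simulate_extrusion_map",
    "run_extrusion",
    "convergent_pair",
    "preset_params",
    "PRESETS",
]


@dataclass
class SimParams:
    """Parameters of the 1D loop-extrusion simulation.

    ``loading_profile`` must be non-negative and sum to 1 (within 1e-9);
    use :meth:`normalized_loading` to build one from raw weights.
    """

    n_bins: int
    binsize: int
    loading_profile: np.ndarray
    n_cohesins: int
    release_rate: float
    turnover_rate: float = 0.0
    barriers: list[tuple[int, str, float]] = field(default_factory=list)
    extrusion_speed: int = 1
    n_steps: int = 1000
    n_ensembles: int = 1
    contact_capture_radius: int = 0
    burn_in_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.loading_profile = np.asarray(self.loading_profile, dtype=float)
        if self.loading_profile.shape != (self.n_bins,):
            raise ValueError("loading_profile length must equal n_bins")
        if np.any(self.loading_profile < 0):
            raise ValueError("loading_profile must be non-negative")
        if abs(self.loading_profile.sum() - 1.0) > 1e-9:
            raise ValueError("loading_profile must sum to 1 (within 1e-9)")
        if not 0.0 <= self.release_rate <= 1.0:
            raise ValueError("release_rate must be in [0, 1]")
        if not 0.0 <= self.turnover_rate <= 1.0:
            raise ValueError("turnover_rate must be in [0, 1]")
        if self.n_cohesins > self.n_bins // 2:
            raise ValueError("lattice overfull: n_cohesins > n_bins/2")
        if self.n_steps <= 0:
            raise ValueError("zero-length simulation: n_steps must be > 0")
        for pos, orient, p in self.barriers:
            if not 0 <= pos < self.n_bins:
                raise ValueError(f"barrier position {pos} outside [0, {self.n_bins})")
            if orient not in ("+", "-"):
                raise ValueError(f"barrier orientation must be '+' or '-', got {orient!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("stall_probability must be in [0, 1]")

    @staticmethod
    def normalized_loading(weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=float)
        s = w.sum()
        if s <= 0:
            raise ValueError("loading weights must have positive sum")
        return w / s


def convergent_pair(
    left: int, right: int, stall_probability: float = 1.0
) -> list[tuple[int, str, float]]:
    """Barrier pair that traps a loop loaded between ``left`` and ``right``."""
    return [(left, "+", stall_probability), (right, "-", stall_probability)]


@dataclass
class ExtrusionResult:
    """Simulator output: contact map plus extruded-loop-size diagnostics."""

    matrix: ContactMatrix
    mean_loop_size_bp: float
    loop_sizes_bp: np.ndarray  # per-ensemble mean |leg1 - leg2| at capture
    raw_contacts: np.ndarray  # extruder-only contact counts (lattice)
    trajectory: list | None = None  # optional per-step (left, right, bound)


def _simulate_ensemble(params: SimParams, rng: np.random.Generator, record=None):
    """One independent chain; returns (contact counts, sum |r-l|, n captures).

    ``record``, if a list, receives per-step snapshots (left, right, bound)
    for invariant checking on small lattices."""
    n = params.n_bins
    speed = params.extrusion_speed
    # per-site stall probability for legs moving left (-) / right (+)
    stall_left = np.zeros(n)
    stall_right = np.zeros(n)
    for pos, orient, p in params.barriers:
        if orient == "+":
            stall_left[pos] = max(stall_left[pos], p)
        else:
            stall_right[pos] = max(stall_right[pos], p)

    occupied = np.zeros(n, dtype=bool)
    left = np.full(params.n_cohesins, -1, dtype=np.int64)
    right = np.full(params.n_cohesins, -1, dtype=np.int64)
    bound = np.zeros(params.n_cohesins, dtype=bool)
    cdf = np.cumsum(params.loading_profile)

    def try_load(k: int) -> None:
        for _ in range(10):  # rejection sampling against occupancy
            b = int(np.searchsorted(cdf, rng.random()))
            if not occupied[b]:
                left[k] = right[k] = b
                occupied[b] = True
                bound[k] = True
                return

    def unload(k: int) -> None:
        occupied[left[k]] = False
        occupied[right[k]] = False
        bound[k] = False
        left[k] = right[k] = -1

    def step_leg(pos: int, other: int, direction: int) -> int:
        """Advance one leg up to ``speed`` sites; stop at occupied sites,
        lattice edges, or (stochastically) at oriented barriers."""
        stall = stall_left if direction < 0 else stall_right
        cur = pos
        for _ in range(speed):
            nxt = cur + direction
            if nxt < 0 or nxt >= n:
                break
            if occupied[nxt]:
                break
            if stall[nxt] > 0 and rng.random() < stall[nxt]:
                # blocked at the barrier this step; retries next step, so the
                # dwell time at a barrier is geometric with mean 1/(1-p)
                break
            if cur != other:
                occupied[cur] = False
            cur = nxt
            occupied[cur] = True
        return cur

    contacts = np.zeros((n, n))
    burn_in = int(params.burn_in_fraction * params.n_steps)
    size_sum = 0.0
    size_n = 0
    r = params.contact_capture_radius

    for k in range(params.n_cohesins):
        try_load(k)

    order = np.arange(params.n_cohesins)
    for step in range(params.n_steps):
        rng.shuffle(order)
        for k in order:
            if not bound[k]:
                try_load(k)
                continue
            p_off = 1.0 - (1.0 - params.release_rate) * (1.0 - params.turnover_rate)
            if p_off > 0 and rng.random() < p_off:
                unload(k)
                try_load(k)
                continue
            left[k] = step_leg(left[k], right[k], -1)
            right[k] = step_leg(right[k], left[k], +1)
        if record is not None:
            record.append((left.copy(), right.copy(), bound.copy()))
        if step >= burn_in:
            for k in range(params.n_cohesins):
                if not bound[k]:
                    continue
                l, rg = left[k], right[k]
                size_sum += rg - l
                size_n += 1
                if r == 0:
                    contacts[l, rg] += 1
                else:
                    lo1, hi1 = max(0, l - r), min(n, l + r + 1)
                    lo2, hi2 = max(0, rg - r), min(n, rg + r + 1)
                    contacts[lo1:hi1, lo2:hi2] += 1
    return contacts, size_sum, size_n


def run_extrusion(
    params: SimParams,
    rng: np.random.Generator | None = None,
    record_trajectory: bool = False,
) -> ExtrusionResult:
    """Run ``n_ensembles`` independent chains and pool their contacts.

    The returned matrix holds raw extruder contact counts only (no
    background); use :func:`simulate_extrusion_map` for an analysis-ready
    map. With ``record_trajectory`` the result carries per-step
    (left, right, bound) snapshots for invariant checking (small runs only).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_bins
    total = np.zeros((n, n))
    sizes = []
    trajectory: list | None = [] if record_trajectory else None
    for _ in range(params.n_ensembles):
        contacts, ssum, snum = _simulate_ensemble(params, rng, record=trajectory)
        total += contacts
        sizes.append(params.binsize * ssum / snum if snum else np.nan)
    total = total + total.T  # symmetrize (legs stored as l <= r)
    np.fill_diagonal(total, np.diagonal(total) / 2)
    sizes = np.asarray(sizes)
    mean_size = float(np.nanmean(sizes)) if np.any(np.isfinite(sizes)) else np.nan
    cmat = ContactMatrix({"chrSim": total.copy()}, params.binsize)
    res = ExtrusionResult(cmat, mean_size, sizes, total)
    res.trajectory = trajectory
    return res


def simulate_extrusion_map(
    params: SimParams,
    background_exponent: float = -1.0,
    background_weight: float | None = None,
    rng: np.random.Generator | None = None,
) -> ExtrusionResult:
    """Extruder contacts added onto a power-law distance-decay background.

    ``background_weight`` scales the background so that its total mass equals
    ``background_weight`` times the extruder contact mass (default 1.0; with
    no extruders the background alone is returned, amplitude 1 at the
    diagonal). The result's per-diagonal means follow the pure power law
    when ``n_cohesins == 0``.
    """
    res = run_extrusion(params, rng=rng)
    n = params.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    bg = (1.0 + d).astype(float) ** background_exponent
    ext = res.raw_contacts
    ext_mass = ext.sum()
    if ext_mass > 0:
        w = 1.0 if background_weight is None else background_weight
        bg = bg * (w * ext_mass / bg.sum())
    combined = bg + ext
    res.matrix = ContactMatrix({"chrSim": combined}, params.binsize)
    return res


def _default_barriers(n_bins: int, stall: float, spacing: int = 40) -> list:
    """Mixed-orientation barrier layout: convergent pairs at regular spacing
    with alternating singleton barriers between them."""
    barriers = []
    pattern = ["+", "-", "+", "+", "-", "-"]
    pos = spacing
    i = 0
    while pos < n_bins - spacing:
        barriers.append((pos, pattern[i % len(pattern)], stall))
        pos += spacing
        i += 1
    return barriers


def _fountain_loading(n_bins: int, bases: list[int], focal_weight: float = 0.3) -> np.ndarray:
    """Uniform loading plus focal mass concentrated at designated bases."""
    w = np.ones(n_bins) * (1 - focal_weight) / n_bins
    for b in bases:
        w[b] += focal_weight / len(bases)
    return w / w.sum()


PRESETS = ("untreated", "wapl_off", "ctcf_off", "wapl_ctcf_off", "rad21_off")


def preset_params(
    name: str,
    seed: int = 0,
    n_bins: int = 600,
    binsize: int = 10_000,
    n_steps: int = 600,
    n_ensembles: int = 1,
    fountain_bases: list[int] | None = None,
    barrier_spacing: int = 30,
) -> SimParams:
    """Degron-condition presets mapped to single simulator parameters.

    Baseline (untreated): release_rate 0.15 per step (extruder lifetime
    ~7 steps, so extruded loops stay small), absorbing barriers
    (stall 1.0) every ``barrier_spacing`` bins, one extruder per 100 bins
    (occupancy sparse enough that the packing limit does not bind before
    barriers do), loading 50% uniform / 50% focal at the designated
    fountain bases. WAPL-off sets release_rate to 0 (loops grow until a
    barrier stops them), CTCF-off sets stall to 0, WAPL/CTCF-off both
    (loops grow until extruders jam against each other), RAD21-off removes
    all extruders.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    if fountain_bases is None:
        fountain_bases = [n_bins // 4, n_bins // 2, 3 * n_bins // 4]
    release = 0.15
    turnover = 0.01  # cohesin synthesis/degradation exchange, WAPL-independent
    stall = 1.0
    n_coh = max(1, n_bins // 100)
    if name in ("wapl_off", "wapl_ctcf_off"):
        release = 0.0
    if name in ("ctcf_off", "wapl_ctcf_off"):
        stall = 0.0
    if name == "rad21_off":
        n_coh = 0
    barriers = _default_barriers(n_bins, stall, spacing=barrier_spacing) if stall > 0 else []
    return SimParams(
        n_bins=n_bins,
        binsize=binsize,
        loading_profile=_fountain_loading(n_bins, fountain_bases, focal_weight=0.5),
        n_cohesins=n_coh,
        release_rate=release,
        turnover_rate=turnover,
        barriers=barriers,
        extrusion_speed=1,
        n_steps=n_steps,
        n_ensembles=n_ensembles,
        contact_capture_radius=0,
        seed=seed,
    )
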