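"""Synthetic denatured-Fab electrospray runs with known ground truth.

The generator emulates the signal structure the pipeline assumes: several
co-eluting 45–52 kDa species, each ionized into a charge-state envelope
(truncated discrete Gaussian over charges, default 22+–42+ centred at 32),
eluting as a Gaussian chromatographic peak, rendered on a uniform profile
m/z grid with peak FWHM = m/z divided by the instrument resolving power.
An optional broad Gaussian baseline hump (default centred at 1500 Th,
FWHM 800 Th) stands in for the elevated unresolved background observed in
the 1000–2000 m/z range of serum runs, and additive half-normal noise per
grid point models detector noise.  Everything is deterministic given the
seed.

What this generator does *not* emulate: isotope fine structure, adducts,
chromatographic tailing, in-source fragmentation and intensity-dependent
(shot) noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .clones import Clone, ClonalProfile
from .io import PipelineConfig, Run, Spectrum, mz_grid
from .preprocess import FWHM_TO_SIGMA

__all__ = [
    "SimulatedClone",
    "SimulationParams",
    "make_repertoire",
    "render_run",
    "ground_truth_table",
    "noisy_profile",
]


@dataclass(frozen=True)
class SimulatedClone:
    """Ground truth for one synthetic Fab species."""

    true_mass: float            # Da
    rt_center: float            # minutes
    rt_sigma: float             # minutes
    abundance: float            # arbitrary units (apex-height scale)
    charge_center: float = 32.0
    charge_sigma: float = 4.0
    charge_lo: int = 22
    charge_hi: int = 42

    def validate(self) -> None:
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be > 0")
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.charge_lo > self.charge_hi:
            raise ValueError("charge_lo must be <= charge_hi")

    def charge_weights(self) -> tuple[np.ndarray, np.ndarray]:
        z = np.arange(self.charge_lo, self.charge_hi + 1)
        w = np.exp(-0.5 * ((z - self.charge_center) / self.charge_sigma) ** 2)
        return z, w / w.sum()


@dataclass(frozen=True)
class SimulationParams:
    """The stated world of a synthetic run.

    Defaults follow the published acquisition: scans at 1 Hz over a
    10–50 min elution region, masses uniform in the 45–52 kDa window.
    Elution width (``rt_sigma`` 0.1 min) and the abundance span (two orders
    of magnitude, log-uniform) are stated assumptions — the source data do
    not quantify them.  Baseline amplitude and noise sigma default to zero
    and are set explicitly per scenario.
    """

    n_clones: int = 50
    seed: int = 0
    mass_low: float = 45000.0
    mass_high: float = 52000.0
    abundance_low: float = 1e5
    abundance_high: float = 1e7
    rt_start: float = 10.0              # minutes
    rt_end: float = 50.0
    rt_sigma: float = 0.1               # minutes
    charge_center: float = 32.0
    charge_sigma: float = 4.0
    charge_lo: int = 22
    charge_hi: int = 42
    baseline_amplitude: float = 0.0
    baseline_center: float = 1500.0     # Th
    baseline_fwhm: float = 800.0        # Th
    noise_sigma: float = 0.0
    scan_rate_hz: float = 1.0
    min_mass_gap_ppm: float = 0.0       # enforce pairwise true-mass spacing

    def validate(self) -> None:
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.scan_rate_hz <= 0:
            raise ValueError("scan_rate_hz must be > 0")
        if not self.mass_low < self.mass_high:
            raise ValueError("mass window is empty")
        if not self.rt_start < self.rt_end:
            raise ValueError("rt window is empty")


def make_repertoire(params: SimulationParams) -> list[SimulatedClone]:
    """Draw a synthetic repertoire: uniform masses, log-uniform abundances.

    With ``min_mass_gap_ppm > 0``, masses are drawn by rejection so that
    every pairwise gap exceeds the requested relative spacing (useful for
    recall scoring where clones must be resolvable).  Deterministic given
    the seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    masses: list[float] = []
    attempts = 0
    while len(masses) < params.n_clones:
        m = float(rng.uniform(params.mass_low, params.mass_high))
        if params.min_mass_gap_ppm > 0 and any(
            abs(m - other) / other * 1e6 <= params.min_mass_gap_ppm for other in masses
        ):
            attempts += 1
            if attempts > 10000 * max(params.n_clones, 1):
                raise ValueError("cannot satisfy min_mass_gap_ppm in the mass window")
            continue
        masses.append(m)
    log_lo, log_hi = math.log(params.abundance_low), math.log(params.abundance_high)
    abundances = np.exp(rng.uniform(log_lo, log_hi, size=params.n_clones))
    rts = rng.uniform(params.rt_start, params.rt_end, size=params.n_clones)
    return [
        SimulatedClone(
            true_mass=masses[i],
            rt_center=float(rts[i]),
            rt_sigma=params.rt_sigma,
            abundance=float(abundances[i]),
            charge_center=params.charge_center,
            charge_sigma=params.charge_sigma,
            charge_lo=params.charge_lo,
            charge_hi=params.charge_hi,
        )
        for i in range(params.n_clones)
    ]


def _scan_times(params: SimulationParams) -> np.ndarray:
    n_scans = int(round((params.rt_end - params.rt_start) * 60.0 * params.scan_rate_hz))
    dt_min = 1.0 / (params.scan_rate_hz * 60.0)
    return params.rt_start + dt_min * np.arange(n_scans)


def render_run(repertoire: list[SimulatedClone], params: SimulationParams,
               config: PipelineConfig | None = None) -> Run:
    """Render a repertoire into a profile-mode MS1 run.

    Each clone contributes, at scan time ``t``, a charge-state envelope of
    Gaussian peaks at ``(M + z*m_p)/z`` with FWHM ``mz/R`` and height
    ``abundance * w(z) * exp(-(t - rt_center)^2 / (2 rt_sigma^2))``.
    A clone whose entire envelope falls outside the rendered m/z range is
    skipped with a warning.
    """
    params.validate()
    if config is None:
        config = PipelineConfig()
    grid = mz_grid(config)
    dmz = config.mz_spacing
    times = _scan_times(params)
    rng = np.random.default_rng(params.seed)

    # precompute each clone's noiseless envelope on the grid (height scale 1)
    envelopes: list[tuple[SimulatedClone, np.ndarray]] = []
    for clone in repertoire:
        clone.validate()
        zs, ws = clone.charge_weights()
        env = np.zeros_like(grid)
        any_inside = False
        for z, w in zip(zs, ws):
            mu = (clone.true_mass + z * config.proton_mass) / z
            if mu < config.mz_low or mu > config.mz_high:
                continue
            any_inside = True
            sigma = (mu / config.instrument_resolving_power) / FWHM_TO_SIGMA
            lo = np.searchsorted(grid, mu - 6 * sigma)
            hi = np.searchsorted(grid, mu + 6 * sigma)
            seg = grid[lo:hi]
            env[lo:hi] += w * np.exp(-0.5 * ((seg - mu) / sigma) ** 2)
        if not any_inside:
            warnings.warn(
                f"clone at {clone.true_mass:.1f} Da: entire charge envelope falls "
                f"outside [{config.mz_low}, {config.mz_high}] Th; skipped",
                stacklevel=2,
            )
            continue
        envelopes.append((clone, env))

    baseline = np.zeros_like(grid)
    if params.baseline_amplitude > 0:
        bsig = params.baseline_fwhm / FWHM_TO_SIGMA
        baseline = params.baseline_amplitude * np.exp(
            -0.5 * ((grid - params.baseline_center) / bsig) ** 2
        )

    scans: list[Spectrum] = []
    for t in times:
        intensity = baseline.copy()
        for clone, env in envelopes:
            rt_w = math.exp(-0.5 * ((t - clone.rt_center) / clone.rt_sigma) ** 2)
            if rt_w < 1e-8:
                continue
            intensity += clone.abundance * rt_w * env
        if params.noise_sigma > 0:
            intensity += np.abs(rng.normal(0.0, params.noise_sigma, grid.size))
        scans.append(Spectrum(rt=float(t), mz=grid, intensity=intensity))
    return Run(run_id=f"sim-seed{params.seed}", scans=scans,
               mz_low=config.mz_low, mz_high=config.mz_high,
               scan_rate_hz=params.scan_rate_hz)


def ground_truth_table(repertoire: list[SimulatedClone],
                       params: SimulationParams | None = None,
                       sample_id: str = "truth") -> ClonalProfile:
    """Clonal profile of the simulated ground truth.

    With ``params`` given, each clone's intensity is its total rendered
    intensity (abundance times the summed elution weight over scan times);
    without, the abundance itself is used — the two differ by a factor that
    is constant across clones fully eluting inside the scan window.
    """
    clones: list[Clone] = []
    times = _scan_times(params) if params is not None else None
    entries = []
    for sim in repertoire:
        if times is not None:
            rt_w = np.exp(-0.5 * ((times - sim.rt_center) / sim.rt_sigma) ** 2).sum()
            intensity = sim.abundance * float(rt_w)
        else:
            intensity = sim.abundance
        entries.append((sim, intensity))
    entries.sort(key=lambda e: (-e[1], e[0].true_mass))
    for i, (sim, intensity) in enumerate(entries):
        clones.append(Clone(clone_id=i + 1, mass=sim.true_mass, rt=sim.rt_center,
                            intensity=intensity, n_slices=1))
    return ClonalProfile(sample_id=sample_id, clones=clones)


def noisy_profile(repertoire: list[SimulatedClone], seed: int,
                  mass_sigma_ppm: float = 5.0,
                  intensity_cv: float = 0.3,
                  sample_id: str = "replicate") -> ClonalProfile:
    """A clone-level observation model: the ground-truth profile perturbed
    by Gaussian mass error (ppm scale, matching the pipeline's measured
    mass accuracy) and log-normal intensity variation (technical-replicate
    scale).  Used for desk-scale similarity experiments where rendering and
    re-profiling hundreds of full runs would be prohibitive.
    """
    rng = np.random.default_rng(seed)
    clones: list[Clone] = []
    perturbed = []
    for sim in repertoire:
        mass = sim.true_mass * (1.0 + rng.normal(0.0, mass_sigma_ppm * 1e-6))
        intensity = sim.abundance * math.exp(rng.normal(0.0, intensity_cv))
        perturbed.append((mass, sim.rt_center, intensity))
    perturbed.sort(key=lambda e: (-e[2], e[0]))
    for i, (mass, rt, intensity) in enumerate(perturbed):
        clones.append(Clone(clone_id=i + 1, mass=mass, rt=rt,
                            intensity=intensity, n_slices=1))
    return ClonalProfile(sample_id=sample_id, clones=clones)
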