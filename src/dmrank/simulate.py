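"""Synthetic 450k-like methylation datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a bimodal baseline of mostly-unmethylated and mostly-methylated probes,
a probe-level random effect shared across samples whose correlation
decays exponentially with genomic distance (this is what makes
neighbouring probe p-values spatially correlated), independent
measurement noise per sample, and optional spiked regions where one
group's betas are shifted by a fixed delta.  Everything is simulated on
the beta scale and truncated to [0, 1], so spiked deltas read directly
as methylation-fraction changes.

It does not emulate Infinium probe-type chemistry, dye bias or raw
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DetectionMatrix, MethylationDataset, Region, RegionSet

__all__ = ["SimulationConfig", "SpikeSpec", "SyntheticTruth", "simulate_dataset",
           "spiked_config"]


@dataclass(frozen=True)
class SpikeSpec:
    """A differential region planted by the simulator."""

    region: Region
    group: str  # group whose betas are shifted
    delta_beta: float  # shift, positive = higher methylation in `group`


@dataclass
class SimulationConfig:
    """Generator parameters; the seed is mandatory for reproducibility.

    Defaults describe a desk-scale 450k-like design: 2000 probes on two
    chromosomes, spacing a few hundred bp, two groups of eight samples,
    a 50/50 mixture of low (Beta(2, 10)) and high (Beta(10, 2))
    methylation modes, probe random effects with sd 0.05 decaying over
    500 bp, and per-sample noise sd 0.05.
    """

    seed: int
    n_probes: int = 2000
    n_chroms: int = 2
    mean_spacing_bp: float = 400.0
    min_spacing_bp: int = 20
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"case": 8, "control": 8}
    )
    low_mode: tuple[float, float] = (2.0, 10.0)  # Beta(a, b) of unmethylated mode
    high_mode: tuple[float, float] = (10.0, 2.0)
    high_fraction: float = 0.5
    probe_effect_sd: float = 0.05
    correlation_length_bp: float = 500.0
    noise_sd: float = 0.05
    spikes: list[SpikeSpec] = field(default_factory=list)
    detection_fail_rate: float = 0.0


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    spikes: list[SpikeSpec]

    @property
    def regions(self) -> RegionSet:
        return RegionSet([s.region for s in self.spikes])


def _simulate_positions(cfg: SimulationConfig, rng: np.random.Generator):
    """Probe coordinates: cumulative spacing draws split over chromosomes."""
    per_chrom = np.array_split(np.arange(cfg.n_probes), cfg.n_chroms)
    chrom, pos = [], []
    for c, idx in enumerate(per_chrom, start=1):
        spacing = cfg.min_spacing_bp + rng.exponential(
            cfg.mean_spacing_bp - cfg.min_spacing_bp, size=len(idx)
        ).astype(np.int64)
        p = np.cumsum(spacing)
        chrom.extend([f"chr{c}"] * len(idx))
        pos.extend(p.tolist())
    return np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64)


def _spatial_effect(
    pos: np.ndarray, chrom: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Probe-level random effect with exp(-d/L) correlation.

    Built as an Ornstein–Uhlenbeck walk along each chromosome:
    e_i = rho_i e_{i-1} + sqrt(1 - rho_i^2) eta_i with
    rho_i = exp(-d_i / L), which gives exactly exponential-decay
    autocorrelation in genomic distance.
    """
    eff = np.empty(len(pos))
    for c in np.unique(chrom.astype(str)):
        sel = np.where(chrom.astype(str) == c)[0]
        eta = rng.standard_normal(len(sel))
        e = np.empty(len(sel))
        e[0] = eta[0]
        rho = np.exp(-np.diff(pos[sel]) / cfg.correlation_length_bp)
        for i in range(1, len(sel)):
            e[i] = rho[i - 1] * e[i - 1] + np.sqrt(1 - rho[i - 1] ** 2) * eta[i]
        eff[sel] = e
    return cfg.probe_effect_sd * eff


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[MethylationDataset, DetectionMatrix, SyntheticTruth]:
    """Generate a dataset, detection matrix and ground truth from a config."""
    for spike in cfg.spikes:
        if spike.group not in cfg.group_sizes:
            raise ValueError(f"spiked group {spike.group!r} not in group_sizes")
        if abs(spike.delta_beta) > 1:
            raise ValueError(f"infeasible delta {spike.delta_beta}")
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _simulate_positions(cfg, rng)
    n = cfg.n_probes

    is_high = rng.random(n) < cfg.high_fraction
    # inside a spiked region the baseline mode must leave room for the
    # shift (hypermethylation starts from the unmethylated mode and vice
    # versa), otherwise truncation would shrink the planted delta
    for spike in cfg.spikes:
        in_region = (
            (chrom.astype(str) == spike.region.chrom)
            & (pos >= spike.region.start)
            & (pos < spike.region.end)
        )
        is_high[in_region] = spike.delta_beta < 0
    baseline = np.where(
        is_high,
        rng.beta(*cfg.high_mode, size=n),
        rng.beta(*cfg.low_mode, size=n),
    )
    baseline = baseline + _spatial_effect(pos, chrom, cfg, rng)

    samples, group_of = [], {}
    for g in sorted(cfg.group_sizes):
        for i in range(cfg.group_sizes[g]):
            s = f"{g}_{i + 1}"
            samples.append(s)
            group_of[s] = g

    beta = baseline[:, None] + rng.normal(0, cfg.noise_sd, size=(n, len(samples)))
    for spike in cfg.spikes:
        in_region = (
            (chrom.astype(str) == spike.region.chrom)
            & (pos >= spike.region.start)
            & (pos < spike.region.end)
        )
        cols = [j for j, s in enumerate(samples) if group_of[s] == spike.group]
        beta[np.ix_(np.where(in_region)[0], cols)] += spike.delta_beta
    beta = np.clip(beta, 0.0, 1.0)

    probe_ids = np.asarray([f"cg{i:08d}" for i in range(n)], dtype=object)
    ds = MethylationDataset(
        probe_ids=probe_ids, chrom=chrom, pos=pos, beta=beta,
        samples=samples, groups=group_of,
    )

    det = rng.uniform(0, 1e-3, size=(n, len(samples)))
    if cfg.detection_fail_rate > 0:
        fail = rng.random((n, len(samples))) < cfg.detection_fail_rate
        det[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))
    detection = DetectionMatrix(
        probe_ids=probe_ids.copy(), samples=list(samples), detection_p=det
    )
    return ds, detection, SyntheticTruth(spikes=list(cfg.spikes))


def spiked_config(
    seed: int,
    n_spikes: int = 10,
    delta_beta: float = 0.25,
    spike_group: str = "case",
    probes_per_spike: int = 5,
    **overrides,
) -> SimulationConfig:
    """A config with ``n_spikes`` planted regions on simulated coordinates.

    Positions are drawn first (with the same seed and draw order as
    ``simulate_dataset``), then every k-th run of ``probes_per_spike``
    consecutive probes is wrapped in a spiked region, evenly spread over
    the genome.  The returned config reproduces those coordinates
    exactly when passed to ``simulate_dataset``.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _simulate_positions(cfg, rng)
    stride = cfg.n_probes // n_spikes
    spikes = []
    for k in range(n_spikes):
        i0 = k * stride
        i1 = i0 + probes_per_spike - 1
        if chrom[i1] != chrom[i0]:  # do not straddle a chromosome break
            i0 = i1 = i0 + probes_per_spike
            i1 = i0 + probes_per_spike - 1
        region = Region(
            str(chrom[i0]), int(pos[i0]) - 1, int(pos[i1]) + 1, f"spike_{k + 1}"
        )
        spikes.append(SpikeSpec(region=region, group=spike_group, delta_beta=delta_beta))
    cfg.spikes = spikes
    return cfg
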