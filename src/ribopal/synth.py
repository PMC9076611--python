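"""Seeded generators for synthetic pipeline inputs.

Every downstream stage of the analysis is exercised on synthetic data with
the statistical structure the real experiments produce:

* per-nucleotide mutation/read count tables for the four MaP conditions
  (PAL = photoaffinity labeled, PRE = pre-photolyzed-reagent control,
  UV = irradiation-only control, NUL = untreated),
* dose-response tables for saturation-binding fits,
* single-molecule time-lapse intensity traces under burst/dark-gap
  illumination with exponential signal loss (dissociation + photobleaching).

All generators are deterministic for a fixed seed and carry their
configuration alongside the data they emit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("PAL", "PRE", "UV", "NUL")

__all__ = [
    "CONDITIONS",
    "CountSimConfig",
    "CountSimResult",
    "IlluminationSchedule",
    "TraceSet",
    "gen_count_tables",
    "gen_dose_response",
    "gen_exponential_lifetimes",
    "gen_timelapse_traces",
]


@dataclass(frozen=True)
class CountSimConfig:
    """Configuration of a synthetic MaP count-table experiment.

    Parameters
    ----------
    n_positions:
        Number of nucleotides in the transcript (1-based coordinates).
    depth_median, depth_sigma, depth_floor:
        Read depth C per (position, condition, replicate) is drawn lognormal
        with the given median and log-sd, then clipped from below at
        ``depth_floor``. Defaults emulate deep rRNA coverage in which
        essentially every nucleotide exceeds 10,000 reads.
    background_rate_mean, background_rate_shape:
        Per-nucleotide basal mutation rate is Beta distributed with the given
        mean; ``background_rate_shape`` is the first Beta shape parameter
        (larger = tighter around the mean). Default mean 0.2% is a typical
        MaP background.
    planted_sites:
        ``(position, fold_change)`` pairs: labeled sites whose mutation rate
        is elevated ``fold_change``-fold in the PAL condition only.
    native_mod_sites:
        ``(position, rate)`` pairs: natively modified nucleotides mutating at
        ``rate`` in all four conditions (observed range 0.28-1.0).
    uv_sites:
        ``(position, rate)`` pairs: UV-crosslink artifacts mutating at
        ``rate`` in PAL, PRE and UV but not NUL (observed range 0.018-0.099).
    excluded_regions:
        ``(start, end)`` inclusive position ranges forced to near-zero depth
        (strong secondary structure dropping coverage).
    """

    n_positions: int = 6000
    depth_median: float = 1.2e5
    depth_sigma: float = 0.5
    depth_floor: int = 10_000
    background_rate_mean: float = 0.002
    background_rate_shape: float = 10.0
    planted_sites: tuple[tuple[int, float], ...] = ()
    native_mod_sites: tuple[tuple[int, float], ...] = ()
    uv_sites: tuple[tuple[int, float], ...] = ()
    excluded_regions: tuple[tuple[int, int], ...] = ()
    replicates: int = 2
    transcript_id: str = "18S"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        planted = [p for p, _ in self.planted_sites]
        native = [p for p, _ in self.native_mod_sites]
        uv = [p for p, _ in self.uv_sites]
        everything = planted + native + uv
        if len(set(everything)) != len(everything):
            raise ValueError("planted, native and uv positions must be mutually disjoint")
        for pos in everything:
            if not 1 <= pos <= self.n_positions:
                raise ValueError(f"site position {pos} outside [1, {self.n_positions}]")
        for _, fc in self.planted_sites:
            if fc <= 1:
                raise ValueError("planted fold_change must be > 1")
        for _, r in list(self.native_mod_sites) + list(self.uv_sites):
            if not 0 <= r <= 1:
                raise ValueError("site rates must lie in [0, 1]")


@dataclass
class CountSimResult:
    """Counts plus ground truth and a config echo for provenance."""

    counts: pd.DataFrame
    truth: pd.DataFrame
    config: CountSimConfig

    def config_dict(self) -> dict:
        return dataclasses.asdict(self.config)


def _excluded_mask(config: CountSimConfig) -> np.ndarray:
    mask = np.zeros(config.n_positions, dtype=bool)
    for start, end in config.excluded_regions:
        mask[start - 1 : end] = True
    return mask


def gen_count_tables(config: CountSimConfig) -> CountSimResult:
    """Simulate per-nucleotide mutation counts across PAL/PRE/UV/NUL.

    For each position the basal rate is drawn once from the background Beta
    law and then modified per condition: planted sites are scaled by their
    fold change in PAL only, native modifications replace the rate in all
    conditions, UV-crosslink sites replace it in PAL/PRE/UV. Depth C is
    drawn per (position, condition, replicate); mutation counts are
    Binomial(C, rate).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_positions
    positions = np.arange(1, n + 1)

    a = config.background_rate_shape
    b = a * (1.0 - config.background_rate_mean) / config.background_rate_mean
    background = rng.beta(a, b, size=n)

    # per-condition true rate matrix, (n_positions, 4)
    rates = np.tile(background[:, None], (1, len(CONDITIONS)))
    category = np.full(n, "background", dtype=object)
    for pos, fc in config.planted_sites:
        rates[pos - 1, CONDITIONS.index("PAL")] = min(background[pos - 1] * fc, 1.0)
        category[pos - 1] = "planted"
    for pos, rate in config.native_mod_sites:
        rates[pos - 1, :] = rate
        category[pos - 1] = "native_mod"
    for pos, rate in config.uv_sites:
        for cond in ("PAL", "PRE", "UV"):
            rates[pos - 1, CONDITIONS.index(cond)] = rate
        category[pos - 1] = "uv_artifact"
    excluded = _excluded_mask(config)
    category[excluded] = "excluded"

    ref_base = rng.choice(list("ACGU"), size=n)

    frames = []
    for rep in range(1, config.replicates + 1):
        for ci, cond in enumerate(CONDITIONS):
            depth = rng.lognormal(np.log(config.depth_median), config.depth_sigma, size=n)
            depth = np.maximum(depth, config.depth_floor).astype(np.int64)
            # excluded regions: coverage collapse well below any floor
            depth[excluded] = rng.integers(0, 50, size=int(excluded.sum()))
            muts = rng.binomial(depth, rates[:, ci])
            frames.append(
                pd.DataFrame(
                    {
                        "transcript": config.transcript_id,
                        "position": positions,
                        "ref_base": ref_base,
                        "condition": cond,
                        "replicate": rep,
                        "reads": depth,
                        "mutations": muts,
                    }
                )
            )
    counts = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "transcript": config.transcript_id,
            "position": positions,
            "category": category,
            **{f"rate_{c}": rates[:, i] for i, c in enumerate(CONDITIONS)},
        }
    )
    return CountSimResult(counts=counts, truth=truth, config=config)


def gen_dose_response(
    model_kind: str,
    params: dict,
    concentrations,
    noise_sd: float = 0.05,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a saturation (dose-response) table.

    ``signal = model(conc) * (1 + eps)`` with ``eps ~ N(0, noise_sd)``,
    clipped at zero. Columns: concentration_uM, signal, replicate.
    """
    from ribopal.binding import eval_model

    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        mean = eval_model(model_kind, params, conc)
        signal = mean * (1.0 + noise_sd * rng.standard_normal(conc.size))
        rows.append(
            pd.DataFrame(
                {
                    "concentration_uM": conc,
                    "signal": np.clip(signal, 0.0, None),
                    "replicate": rep,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class IlluminationSchedule:
    """Time-lapse illumination: bursts of frames separated by dark gaps.

    Defaults follow the recording protocol used throughout: bursts of 20
    frames at 100 ms intervals, 24 s dark gaps, 22.7 min total, with factor
    injection ~3 s into the recording.
    """

    burst_frames: int = 20
    frame_interval: float = 0.1
    dark_gap: float = 24.0
    total_duration: float = 1362.0
    injection_time: float = 3.0

    def __post_init__(self) -> None:
        if self.burst_frames < 1:
            raise ValueError("burst_frames must be >= 1")
        if not self.total_duration > self.injection_time >= 0:
            raise ValueError("require total_duration > injection_time >= 0")

    def frame_times(self) -> np.ndarray:
        """Illuminated frame times in seconds from recording start."""
        cycle = self.burst_frames * self.frame_interval + self.dark_gap
        n_cycles = int(np.ceil(self.total_duration / cycle))
        starts = np.arange(n_cycles) * cycle
        offsets = np.arange(self.burst_frames) * self.frame_interval
        times = (starts[:, None] + offsets[None, :]).ravel()
        return times[times < self.total_duration]


@dataclass
class TraceSet:
    """A bundle of intensity traces sampled on a common illumination grid.

    ``intensities`` has shape (n_traces, n_frames); ``times_s`` gives the
    illuminated frame times. ``truth`` records the underlying loss time of
    each trace for generator-vs-pipeline comparisons.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    injection_time: float
    truth: pd.DataFrame
    channel: str = "peptide"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: trace_id, frame_index, time_s, channel, intensity."""
        n_traces, n_frames = self.intensities.shape
        return pd.DataFrame(
            {
                "trace_id": np.repeat(np.arange(n_traces), n_frames),
                "frame_index": np.tile(np.arange(n_frames), n_traces),
                "time_s": np.tile(self.times_s, n_traces),
                "channel": self.channel,
                "intensity": self.intensities.ravel(),
            }
        )


def gen_timelapse_traces(
    k_release: float,
    k_pb: float,
    schedule: IlluminationSchedule,
    n_traces: int,
    seed: int = 0,
    noise_sd: float = 0.05,
    on_level: float = 1.0,
    channel: str = "peptide",
) -> TraceSet:
    """Simulate single-step-loss fluorescence traces.

    Signal loss (dissociation or photobleaching) occurs at hazard
    ``k_release + k_pb`` (per minute) in real elapsed time, starting at the
    injection time. Intensity is two-level -- ``on_level`` before the loss,
    zero after -- with additive Gaussian read noise, observed only at
    illuminated frames. Traces without a loss before the end of recording
    are censored.
    """
    if k_release < 0 or k_pb < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    times = schedule.frame_times()
    hazard = k_release + k_pb  # per minute
    if hazard > 0:
        wait_s = rng.exponential(60.0 / hazard, size=n_traces)
    else:
        wait_s = np.full(n_traces, np.inf)
    loss_s = schedule.injection_time + wait_s
    censored = loss_s >= schedule.total_duration

    high = times[None, :] < loss_s[:, None]
    intens = np.where(high, on_level, 0.0)
    intens = intens + noise_sd * on_level * rng.standard_normal(intens.shape)
    truth = pd.DataFrame(
        {
            "trace_id": np.arange(n_traces),
            "loss_time_s": loss_s,
            "lifetime_min": np.where(
                censored,
                (schedule.total_duration - schedule.injection_time) / 60.0,
                wait_s / 60.0,
            ),
            "censored": censored,
        }
    )
    return TraceSet(
        times_s=times,
        intensities=intens,
        injection_time=schedule.injection_time,
        truth=truth,
        channel=channel,
    )


def gen_exponential_lifetimes(
    k_loss: float,
    observation_min: float,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential lifetimes (minutes) censored at the observation span.

    Lifetime-level shortcut for pipeline studies that do not need the
    trace-rendering layer; the censoring convention matches
    :func:`gen_timelapse_traces`.
    """
    rng = np.random.default_rng(seed)
    if k_loss > 0:
        t = rng.exponential(1.0 / k_loss, size=n)
    else:
        t = np.full(n, np.inf)
    censored = t >= observation_min
    return pd.DataFrame(
        {
            "lifetime_min": np.where(censored, observation_min, t),
            "censored": censored,
        }
    )
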