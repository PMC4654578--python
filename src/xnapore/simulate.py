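"""Synthetic squiggle generation: enzyme stepping, trace rendering, acquisition.

Emulates the features of enzyme-stepped nanopore recordings that matter for
the downstream analysis: millisecond-scale discrete levels with exponential
dwell times, occasional backward motion (a previously seen level re-emitted
before the enzyme resumes), skipped levels, Gaussian amplitude noise at the
acquisition rate, and the acquisition chain of 50 kHz sampling downsampled
by block averaging to 5 kHz.

Hel308-mode step sequences are traversed in reverse sequence order, since
the helicase walks 3'->5' while the series is stored 5'->3'; downstream
consensus re-orients tracks with
:func:`xnapore.align.orient_for_sequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kmer_model import ENZYME_MODES, PHI29, StepSequence
from .levels import LevelSequence, MeasuredLevel

FORWARD = "forward"
BACKSTEP = "backstep"
SKIP = "skip"


@dataclass
class SimulationConfig:
    """Knobs of the stepping + acquisition model.

    dwell_mean
        Mean level dwell in seconds (exponential by default; a log-normal
        alternative with the same mean is available via ``dwell_distribution``
        for heavy-tailed dwells).
    backstep_prob
        Per forward step, probability that the previous level is re-emitted
        (one-level retraction) before the walk resumes.
    skip_prob
        Per advance, probability of jumping two levels so one level is never
        emitted.
    noise_sd_raw
        Gaussian current noise (pA) at the acquisition rate; block averaging
        by ``downsample_factor`` shrinks it by its square root.
    """

    dwell_mean: float = 0.05
    backstep_prob: float = 0.05
    skip_prob: float = 0.02
    noise_sd_raw: float = 3.2
    sample_rate: float = 50_000.0
    downsample_factor: int = 10
    seed: int = 0
    enzyme_mode: str = PHI29
    dwell_distribution: str = "exponential"  # or "lognormal"
    lognormal_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("backstep_prob", "skip_prob"):
            p = getattr(self, name)
            if not 0 <= p < 1:
                raise ValueError(f"{name} must be in [0, 1), got {p}")
        if self.dwell_mean <= 0:
            raise ValueError(f"dwell_mean must be positive, got {self.dwell_mean}")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.sample_rate % self.downsample_factor:
            raise ValueError(
                f"sample_rate {self.sample_rate} not divisible by "
                f"downsample_factor {self.downsample_factor}"
            )
        if self.enzyme_mode not in ENZYME_MODES:
            raise ValueError(f"unknown enzyme_mode {self.enzyme_mode!r}")
        if self.dwell_distribution not in ("exponential", "lognormal"):
            raise ValueError(f"unknown dwell_distribution {self.dwell_distribution!r}")


@dataclass
class SteppedPath:
    """Realized enzyme walk: emitted temporal level indices, move labels, dwells."""

    level_indices: list[int]   # 1-based indices into the temporal level order
    moves: list[str]           # forward | backstep | skip per emission
    dwells: list[float]        # seconds per emission
    n_levels: int

    def __post_init__(self) -> None:
        if not self.level_indices:
            raise ValueError("empty path")
        if self.level_indices[0] != 1 or self.level_indices[-1] != self.n_levels:
            raise ValueError("path must start at level 1 and end at the final level")


@dataclass
class SignalTrace:
    """Sampled current, with ground-truth annotations when simulated.

    ``annotations`` has one row per emitted level: the sample index where it
    starts (``change_point_sample``), the true temporal level index, and the
    move label.
    """

    sample_rate: float
    samples: np.ndarray
    annotations: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def to_tsv(self, path, annotation_path=None) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_rate_hz={self.sample_rate!r}\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"#{key}={val!r}\n")
            fh.write("current_pA\n")
            np.savetxt(fh, self.samples, fmt="%.6f")
        if annotation_path is not None and self.annotations is not None:
            self.annotations.to_csv(annotation_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, annotation_path=None) -> "SignalTrace":
        meta: dict[str, str] = {}
        vals: list[float] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                elif line == "current_pA":
                    continue
                else:
                    try:
                        vals.append(float(line))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: malformed sample at line {lineno}: {line!r}"
                        ) from exc
        if "sample_rate_hz" not in meta:
            raise ValueError(f"{path}: missing #sample_rate_hz= header")
        sample_rate = float(meta.pop("sample_rate_hz"))
        ann = None
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t")
        return cls(sample_rate, np.array(vals), ann, meta)


def _draw_dwells(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    if config.dwell_distribution == "exponential":
        return rng.exponential(config.dwell_mean, size=n)
    # log-normal with the same mean: mean = exp(mu + sigma^2/2)
    sigma = config.lognormal_sigma
    mu = np.log(config.dwell_mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size=n)


def simulate_stepping(steps: StepSequence, config: SimulationConfig) -> SteppedPath:
    """Walk the level series with backsteps and skips; draw per-emission dwells.

    After each forward arrival (beyond the first level), a Bernoulli
    ``backstep_prob`` event re-emits the previous level and then re-emits the
    current one.  Each advance is a two-level skip with probability
    ``skip_prob`` (one level is then never emitted).  The walk always begins
    at temporal level 1 and ends at the last level.
    """
    n = len(steps)
    if n == 0:
        raise ValueError("empty step sequence")
    rng = np.random.default_rng(config.seed)
    indices = [1]
    moves = [FORWARD]
    pos = 1
    while pos < n:
        if pos + 2 <= n and rng.random() < config.skip_prob:
            pos += 2
            indices.append(pos)
            moves.append(SKIP)
        else:
            pos += 1
            indices.append(pos)
            moves.append(FORWARD)
            if pos > 1 and rng.random() < config.backstep_prob:
                indices.extend([pos - 1, pos])
                moves.extend([BACKSTEP, FORWARD])
    dwells = _draw_dwells(rng, len(indices), config)
    return SteppedPath(indices, moves, list(dwells), n)


def render_trace(
    path: SteppedPath, steps: StepSequence, config: SimulationConfig
) -> SignalTrace:
    """Render a path as a noisy piecewise-constant trace at the acquisition rate.

    Each emission holds its level current for its dwell (quantized to whole
    samples, minimum one sample); independent Gaussian noise of sd
    ``noise_sd_raw`` is added.  Annotations record the true segment starts.
    """
    temporal = steps.temporal_currents()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    seg_lengths = [
        max(1, int(round(d * config.sample_rate))) for d in path.dwells
    ]
    ideal = np.concatenate(
        [np.full(m, temporal[i - 1]) for i, m in zip(path.level_indices, seg_lengths)]
    )
    noise = rng.normal(0.0, config.noise_sd_raw, size=len(ideal)) \
        if config.noise_sd_raw > 0 else 0.0
    starts = np.concatenate([[0], np.cumsum(seg_lengths)[:-1]])
    ann = pd.DataFrame(
        {
            "change_point_sample": starts.astype(int),
            "level_index": path.level_indices,
            "move": path.moves,
        }
    )
    meta = {
        "seed": config.seed,
        "enzyme_mode": steps.enzyme_mode,
        "sequence_id": steps.sequence_id,
        "noise_sd_raw": config.noise_sd_raw,
        "voltage_mV": 180,  # recorded as metadata only; not part of the model
    }
    return SignalTrace(config.sample_rate, ideal + noise, ann, meta)


def downsample_by_averaging(trace: SignalTrace, factor: int) -> SignalTrace:
    """Replace non-overlapping blocks of ``factor`` samples by their mean.

    The sample rate divides by ``factor``; a trailing partial block is
    truncated; annotation sample indices are remapped by integer division.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return trace
    n = (len(trace.samples) // factor) * factor
    down = trace.samples[:n].reshape(-1, factor).mean(axis=1)
    ann = None
    if trace.annotations is not None:
        ann = trace.annotations.copy()
        ann["change_point_sample"] = ann["change_point_sample"] // factor
    meta = dict(trace.metadata)
    meta["downsample_factor"] = factor
    return SignalTrace(trace.sample_rate / factor, down, ann, meta)


def simulate_read(steps: StepSequence, config: SimulationConfig) -> SignalTrace:
    """Full acquisition chain: step, render at 50 kHz, downsample to 5 kHz."""
    path = simulate_stepping(steps, config)
    raw = render_trace(path, steps, config)
    return downsample_by_averaging(raw, config.downsample_factor)


def simulate_level_read(
    steps: StepSequence,
    config: SimulationConfig,
    emission_sd: float = 1.5,
) -> LevelSequence:
    """Generate a measured-level read directly, without sample-level rendering.

    The stepping model (backsteps, skips, dwells) is identical to
    :func:`simulate_stepping`; each emission's measured mean is its level
    current plus Gaussian noise of sd ``emission_sd``.  Useful for ensemble
    studies of consensus and difference statistics where the segmentation
    stage is not under test.
    """
    path = simulate_stepping(steps, config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    temporal = steps.temporal_currents()
    rate = config.sample_rate / config.downsample_factor
    levels = []
    start = 0
    for idx, dwell in zip(path.level_indices, path.dwells):
        n_samp = max(1, int(round(dwell * rate)))
        levels.append(
            MeasuredLevel(
                mean=float(temporal[idx - 1] + rng.normal(0.0, emission_sd)),
                sd=emission_sd,
                duration=n_samp / rate,
                start_sample=start,
            )
        )
        start += n_samp
    return LevelSequence(levels, rate, trace_id=f"{steps.sequence_id}:{config.seed}",
                         metadata={"tier": "level", "emission_sd": emission_sd})


def config_with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
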