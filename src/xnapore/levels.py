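"""Containers for measured current levels extracted from a trace."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MeasuredLevel:
    """One quasi-constant current segment of a squiggle."""

    mean: float        # pA
    sd: float          # pA, within-segment
    duration: float    # seconds
    start_sample: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")


@dataclass
class LevelSequence:
    """Time-ordered measured levels from one read.

    Levels are contiguous: each begins at the sample where the previous one
    ends, so the durations partition the trace exactly.
    """

    levels: list[MeasuredLevel]
    sample_rate: float
    trace_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        starts = [lv.start_sample for lv in self.levels]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("level start samples must be strictly increasing")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def means(self) -> np.ndarray:
        return np.array([lv.mean for lv in self.levels])

    @property
    def durations(self) -> np.ndarray:
        return np.array([lv.duration for lv in self.levels])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_rate_hz={self.sample_rate!r}\n")
            fh.write(f"#trace_id={self.trace_id}\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"#{key}={val!r}\n")
            fh.write("level_index\tmean_pA\tsd_pA\tduration_s\tstart_sample\n")
            for i, lv in enumerate(self.levels, start=1):
                fh.write(
                    f"{i}\t{float(lv.mean)!r}\t{float(lv.sd)!r}\t"
                    f"{float(lv.duration)!r}\t{int(lv.start_sample)}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "LevelSequence":
        meta: dict[str, str] = {}
        with open(path) as fh:
            rows = []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                elif line and not line.startswith("level_index"):
                    rows.append(line.split("\t"))
        sample_rate = float(meta.pop("sample_rate_hz"))
        trace_id = meta.pop("trace_id", "")
        levels = [
            MeasuredLevel(float(m), float(s), float(d), int(ss))
            for _, m, s, d, ss in rows
        ]
        return cls(levels, sample_rate, trace_id, meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_index": np.arange(1, len(self) + 1),
                "mean_pA": [lv.mean for lv in self.levels],
                "sd_pA": [lv.sd for lv in self.levels],
                "duration_s": [lv.duration for lv in self.levels],
                "start_sample": [lv.start_sample for lv in self.levels],
            }
        )
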