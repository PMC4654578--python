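"""Dynamic-programming alignment of measured levels to an ideal reference,
and combination of many aligned reads into a consensus of current levels.

A read's measured level means are aligned globally to the reference level
currents under a Gaussian emission model with a single global ``emission_sd``
and additive move penalties (log-units):

=============  ======================================================
move           reference index change
=============  ======================================================
step           +1 (normal enzyme advance)
skip           +2 (one reference level never emitted)
stay_backstep  0 or -1 (repeated level from backward motion)
spurious       none (measured level matches no reference level)
=============  ======================================================

The alignment must start by emitting reference level 1 and end with the last
assigned index equal to the final reference level.  Traceback is
deterministic: ties prefer step over skip over stay_backstep over spurious.

Consensus statistics per reference index are computed by first averaging the
(possibly repeated) matched means within each read, then taking the mean,
standard deviation and standard error (sd / sqrt(N)) across reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_model import HEL308, StepSequence
from .levels import LevelSequence

NEG_INF = -np.inf

#: default move penalties, log-units
DEFAULT_MOVE_PENALTIES = {
    "step": 0.0,
    "stay_backstep": -3.0,
    "skip": -4.0,
    "spurious": -5.0,
}

# move codes in tie-break priority order (first wins)
_STEP, _SKIP, _STAY, _BACK, _SPUR = range(5)
_MOVE_LABEL = {_STEP: "step", _SKIP: "skip", _STAY: "stay_backstep",
               _BACK: "stay_backstep", _SPUR: "spurious"}
_DELTA = {_STEP: 1, _SKIP: 2, _STAY: 0, _BACK: -1, _SPUR: 0}


@dataclass
class AlignmentResult:
    """Per-measured-level reference assignment and the total DP score."""

    assignments: list[tuple[int | None, str]]  # (ref index or None, move label)
    score: float
    n_reference: int

    def matched_by_ref(self, means: np.ndarray) -> dict[int, list[float]]:
        """Measured means grouped by assigned reference index."""
        out: dict[int, list[float]] = {}
        for (ref, _), m in zip(self.assignments, means):
            if ref is not None:
                out.setdefault(ref, []).append(float(m))
        return out


def gaussian_loglik(x: np.ndarray, mu: np.ndarray, sd: float) -> np.ndarray:
    """Log-density matrix of measured means under reference currents."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    z = (x[:, None] - mu[None, :]) / sd
    return -0.5 * z**2 - np.log(sd * np.sqrt(2 * np.pi))


def align_levels(
    read: LevelSequence,
    reference: StepSequence | np.ndarray,
    emission_sd: float = 1.5,
    move_penalties: dict[str, float] | None = None,
) -> AlignmentResult:
    """Globally align a read's levels to reference currents (temporal order).

    ``reference`` may be a :class:`StepSequence` (its temporal level order is
    used) or a plain array of currents already in temporal order.
    """
    if move_penalties is None:
        move_penalties = DEFAULT_MOVE_PENALTIES
    pen = {**DEFAULT_MOVE_PENALTIES, **move_penalties}
    ref = (reference.temporal_currents()
           if isinstance(reference, StepSequence) else np.asarray(reference, float))
    n = len(read)
    m = len(ref)
    if n == 0 or m == 0:
        raise ValueError("read and reference must both be non-empty")

    emit = gaussian_loglik(read.means, ref, emission_sd)  # (n, m)

    # dp[p] after consuming i read levels, p = last assigned reference index
    dp = np.full(m + 1, NEG_INF)
    dp[0] = 0.0
    back = np.zeros((n, m + 1), dtype=np.int8)
    cand = np.empty((5, m + 1))
    for i in range(n):
        e = emit[i]
        cand[:] = NEG_INF
        # step: p-1 -> p
        cand[_STEP, 1:] = dp[:-1] + e + pen["step"]
        # skip: p-2 -> p, source index >= 1
        if m >= 3:
            cand[_SKIP, 3:] = dp[1:-2] + e[2:] + pen["skip"]
        # stay: p -> p, p >= 1
        cand[_STAY, 1:] = dp[1:] + e + pen["stay_backstep"]
        # backstep: p+1 -> p, p >= 1
        cand[_BACK, 1:m] = dp[2:] + e[: m - 1] + pen["stay_backstep"]
        # spurious: p -> p, no emission
        cand[_SPUR, :] = dp + pen["spurious"]
        choice = np.argmax(cand, axis=0)  # first max wins -> priority order
        back[i] = choice
        dp = cand[choice, np.arange(m + 1)]

    score = dp[m]
    if not np.isfinite(score):
        raise ValueError("no legal alignment (read too short for reference?)")

    # traceback
    assignments: list[tuple[int | None, str]] = []
    p = m
    for i in range(n - 1, -1, -1):
        code = int(back[i, p])
        if code == _SPUR:
            assignments.append((None, "spurious"))
        else:
            assignments.append((p, _MOVE_LABEL[code]))
        p -= _DELTA[code]
    assignments.reverse()
    return AlignmentResult(assignments, float(score), m)


@dataclass
class ConsensusTrack:
    """Per-reference-index statistics across an ensemble of aligned reads.

    ``orientation`` is ``"time"`` for tracks indexed in temporal level order
    and ``"sequence"`` once re-ordered 5'->3' (see
    :func:`orient_for_sequence`).  Indices with no coverage carry
    ``n_reads = 0`` and NaN statistics.
    """

    mean: np.ndarray
    sd: np.ndarray          # across-read standard deviation
    se: np.ndarray          # sd / sqrt(n_reads)
    n_reads: np.ndarray
    enzyme_mode: str
    sequence_id: str = ""
    orientation: str = "time"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mean)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#enzyme_mode={self.enzyme_mode}\n")
            fh.write(f"#sequence_id={self.sequence_id}\n")
            fh.write(f"#orientation={self.orientation}\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"#{key}={val!r}\n")
            fh.write("level_index\tconsensus_mean_pA\tsd_pA\tse_pA\tn_reads\n")
            for i in range(len(self)):
                fh.write(
                    f"{i + 1}\t{float(self.mean[i])!r}\t{float(self.sd[i])!r}\t"
                    f"{float(self.se[i])!r}\t{int(self.n_reads[i])}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ConsensusTrack":
        meta: dict[str, str] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                elif line and not line.startswith("level_index"):
                    rows.append(line.split("\t"))
        arr = np.array([[float(v) for v in r[1:]] for r in rows])
        return cls(
            mean=arr[:, 0], sd=arr[:, 1], se=arr[:, 2],
            n_reads=arr[:, 3].astype(int),
            enzyme_mode=meta.pop("enzyme_mode"),
            sequence_id=meta.pop("sequence_id", ""),
            orientation=meta.pop("orientation", "time"),
            metadata=meta,
        )


def build_consensus(
    alignments: list[AlignmentResult],
    reads: list[LevelSequence],
    reference: StepSequence,
    min_score: float | None = None,
) -> ConsensusTrack:
    """Combine aligned reads into a consensus track (temporal order).

    Within each read, repeated visits to a reference index (backsteps) are
    averaged first; across reads the consensus mean, SD and SE are computed.
    Reads whose alignment score falls below ``min_score`` are rejected.
    """
    if len(alignments) != len(reads) or not reads:
        raise ValueError("need matching, non-empty alignments and reads")
    m = alignments[0].n_reference
    if any(a.n_reference != m for a in alignments):
        raise ValueError("alignments refer to different references")
    per_ref: list[list[float]] = [[] for _ in range(m)]
    n_used = 0
    for aln, read in zip(alignments, reads):
        if min_score is not None and aln.score < min_score:
            continue
        n_used += 1
        for ref, means in aln.matched_by_ref(read.means).items():
            per_ref[ref - 1].append(float(np.mean(means)))
    if n_used == 0:
        raise ValueError("all reads rejected by min_score")
    mean = np.full(m, np.nan)
    sd = np.full(m, np.nan)
    se = np.full(m, np.nan)
    n = np.zeros(m, dtype=int)
    for j, vals in enumerate(per_ref):
        n[j] = len(vals)
        if vals:
            mean[j] = np.mean(vals)
            sd[j] = np.std(vals, ddof=1) if len(vals) > 1 else 0.0
            se[j] = sd[j] / np.sqrt(len(vals))
    return ConsensusTrack(
        mean, sd, se, n, reference.enzyme_mode, reference.sequence_id,
        orientation="time", metadata={"n_reads_used": n_used},
    )


def orient_for_sequence(track: ConsensusTrack) -> ConsensusTrack:
    """Re-order a Hel308 track so indices run 5'->3'; phi29 tracks unchanged.

    Applying the function twice returns the original track.
    """
    if track.enzyme_mode != HEL308:
        return track
    flip = {"time": "sequence", "sequence": "time"}
    return ConsensusTrack(
        track.mean[::-1].copy(), track.sd[::-1].copy(), track.se[::-1].copy(),
        track.n_reads[::-1].copy(), track.enzyme_mode, track.sequence_id,
        orientation=flip[track.orientation], metadata=dict(track.metadata),
    )
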