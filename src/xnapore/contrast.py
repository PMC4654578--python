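"""Substitution detection by consensus differencing, and single-read calls.

The central object is :class:`SubstitutionContrast`, a model over two read
ensembles — a variant arm whose template carries one or more substitutions
(typically the unnatural bases Z/dNaM or Q/d5SICS) and a control arm with
natural bases at those sites.  :meth:`SubstitutionContrast.fit` aligns every
read to its ideal reference, builds the per-arm consensus of current levels,
subtracts control from variant with standard-error propagation, and calls
the contiguous runs of significant difference.  The returned
:class:`ContrastResults` carries the difference track (delta, SE, z),
region calls, a ``summary()`` table, plotting, and per-read classification.

Consensus overlays quote the across-read SD (single-read separability);
difference tracks quote the SE of the mean, and z = delta / SE(delta) with
SE(delta) = sqrt(SE_variant^2 + SE_control^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (AlignmentResult, ConsensusTrack, align_levels,
                    build_consensus, gaussian_loglik, orient_for_sequence)
from .kmer_model import (HEL308, PHI29, KmerCurrentTable, StepSequence,
                         affected_level_range, ideal_level_series)
from .levels import LevelSequence
from .sequences import ExtendedSequence


@dataclass
class DifferenceTrack:
    """Variant-minus-control difference per reference level (5'->3')."""

    level_index: np.ndarray      # 1-based, sequence order
    offset: np.ndarray | None    # index relative to the substitution (0 = first affected level)
    delta: np.ndarray            # pA
    se_delta: np.ndarray         # pA, sqrt(se_v^2 + se_c^2)
    z: np.ndarray
    enzyme_mode: str
    substitution_position: int | None = None

    def __len__(self) -> int:
        return len(self.delta)

    def to_frame(self) -> pd.DataFrame:
        d = {"level_index": self.level_index}
        if self.offset is not None:
            d["offset"] = self.offset
        d.update(delta_pA=self.delta, se_pA=self.se_delta, z=self.z)
        return pd.DataFrame(d)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#enzyme_mode={self.enzyme_mode}\n")
            fh.write(f"#substitution_position={self.substitution_position}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of consecutive significant difference levels."""

    start_index: int    # inclusive, sequence-order level index
    end_index: int      # inclusive
    peak_delta: float   # signed delta of largest magnitude, pA
    sign_profile: str   # e.g. "++++" or "+-+-"

    @property
    def n_levels(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class ReadClassification:
    """Single-read call at a known substitution site."""

    log_likelihood_ratio: float   # unnatural minus natural, log-units
    label: str                    # "unnatural" | "natural" | "ambiguous"
    margin: float                 # |LLR|
    window: tuple[int, int]


def difference_track(
    variant: ConsensusTrack,
    control: ConsensusTrack,
    substitution_position: int | None = None,
    k: int | None = None,
    seq_length: int | None = None,
) -> DifferenceTrack:
    """Subtract control consensus from variant consensus, propagating SE.

    Both tracks must share enzyme mode and length and be oriented 5'->3'
    (Hel308 tracks must have been passed through ``orient_for_sequence``).
    When ``substitution_position`` (and ``k``, ``seq_length``) are given,
    levels are additionally labeled with offsets such that the first level
    whose window covers the substituted position is offset 0.
    """
    if variant.enzyme_mode != control.enzyme_mode:
        raise ValueError("enzyme_mode mismatch between arms")
    if len(variant) != len(control):
        raise ValueError(f"length mismatch: {len(variant)} vs {len(control)}")
    for tr, name in ((variant, "variant"), (control, "control")):
        if tr.enzyme_mode == HEL308 and tr.orientation != "sequence":
            raise ValueError(
                f"{name} Hel308 track must be oriented 5'->3' before differencing"
            )
    delta = variant.mean - control.mean
    se = np.sqrt(variant.se**2 + control.se**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, np.nan)
    both = (variant.n_reads >= 1) & (control.n_reads >= 1)
    delta = np.where(both, delta, np.nan)
    z = np.where(both, z, np.nan)
    idx = np.arange(1, len(delta) + 1)
    offset = None
    if substitution_position is not None:
        if k is None or seq_length is None:
            raise ValueError("offset labeling needs k and seq_length")
        lo, _ = affected_level_range(substitution_position, k, seq_length,
                                     variant.enzyme_mode)
        offset = idx - lo
    return DifferenceTrack(idx, offset, delta, se, z, variant.enzyme_mode,
                           substitution_position)


def call_affected_regions(
    diff: DifferenceTrack, z_min: float = 3.0, min_run: int = 2
) -> list[RegionCall]:
    """Maximal runs of >= ``min_run`` consecutive levels with |z| >= ``z_min``."""
    if len(diff) == 0:
        raise ValueError("empty difference track")
    sig = np.isfinite(diff.z) & (np.abs(diff.z) >= z_min)
    regions: list[RegionCall] = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                d = diff.delta[i : j + 1]
                peak = d[np.argmax(np.abs(d))]
                signs = "".join("+" if x >= 0 else "-" for x in d)
                regions.append(
                    RegionCall(int(diff.level_index[i]), int(diff.level_index[j]),
                               float(peak), signs)
                )
            i = j + 1
        else:
            i += 1
    return regions


def _window_matches(
    aln: AlignmentResult, means: np.ndarray, window: tuple[int, int]
) -> list[tuple[int, float]]:
    """(reference index, measured mean) pairs matched inside the window."""
    lo, hi = window
    return [
        (ref_idx, float(m))
        for (ref_idx, _), m in zip(aln.assignments, means)
        if ref_idx is not None and lo <= ref_idx <= hi
    ]


def classify_single_read(
    read: LevelSequence,
    ref_natural: StepSequence,
    ref_unnatural: StepSequence,
    window: tuple[int, int],
    emission_sd: float = 1.5,
    ambiguity_margin: float = 2.0,
    move_penalties: dict[str, float] | None = None,
) -> ReadClassification:
    """Call one read natural vs unnatural at a known site.

    The read is aligned to each reference and the better-scoring alignment
    fixes which measured levels sit inside ``window`` (a range of temporal
    reference indices, inclusive).  The log-likelihood ratio then evaluates
    those same measured means under the two references' window currents:

        LLR = sum_j [ log N(m_j | unnatural_j, sd) - log N(m_j | natural_j, sd) ]

    so it is additive over window levels and unaffected by how the losing
    alignment disposes of mismatching levels.  The label follows the LLR
    sign, with ``|LLR| < ambiguity_margin`` called ambiguous.
    """
    if len(ref_natural) != len(ref_unnatural):
        raise ValueError("references must have equal length")
    aln_nat = align_levels(read, ref_natural, emission_sd, move_penalties)
    aln_unn = align_levels(read, ref_unnatural, emission_sd, move_penalties)
    best = aln_unn if aln_unn.score > aln_nat.score else aln_nat
    matches = _window_matches(best, read.means, window)
    if not matches:
        other = aln_nat if best is aln_unn else aln_unn
        matches = _window_matches(other, read.means, window)
    if not matches:
        raise ValueError("no read levels matched inside the window")
    cur_nat = ref_natural.temporal_currents()
    cur_unn = ref_unnatural.temporal_currents()
    llr = sum(
        float(gaussian_loglik(m, cur_unn[j - 1], emission_sd)[0, 0])
        - float(gaussian_loglik(m, cur_nat[j - 1], emission_sd)[0, 0])
        for j, m in matches
    )
    if abs(llr) < ambiguity_margin:
        label = "ambiguous"
    else:
        label = "unnatural" if llr > 0 else "natural"
    return ReadClassification(float(llr), label, abs(float(llr)), tuple(window))


class SubstitutionContrast:
    """Model of a variant-vs-control nanopore level contrast.

    Parameters
    ----------
    variant_reads, control_reads : list of LevelSequence
        Measured level sequences (temporal order) for each arm.
    reference_variant, reference_control : StepSequence
        Ideal level series of the two templates under the same k-mer table
        and enzyme mode.
    substitution_positions : list of int, optional
        1-based template positions where the arms differ; inferred from the
        references' template sequences when built via :meth:`from_sequences`.
    emission_sd : float
        Gaussian emission sd (pA) used for alignment and classification.
    """

    def __init__(
        self,
        variant_reads: list[LevelSequence],
        control_reads: list[LevelSequence],
        reference_variant: StepSequence,
        reference_control: StepSequence,
        substitution_positions: list[int] | None = None,
        emission_sd: float = 1.5,
        move_penalties: dict[str, float] | None = None,
        min_score: float | None = None,
    ) -> None:
        if reference_variant.enzyme_mode != reference_control.enzyme_mode:
            raise ValueError("references must share enzyme_mode")
        if len(reference_variant) != len(reference_control):
            raise ValueError("references must have equal length")
        if not variant_reads or not control_reads:
            raise ValueError("both arms need at least one read")
        self.variant_reads = variant_reads
        self.control_reads = control_reads
        self.reference_variant = reference_variant
        self.reference_control = reference_control
        self.substitution_positions = substitution_positions
        self.emission_sd = emission_sd
        self.move_penalties = move_penalties
        self.min_score = min_score
        self.seq_length = len(reference_variant) + reference_variant.k - 1 \
            if reference_variant.enzyme_mode == PHI29 \
            else (len(reference_variant) + 1) // 2 + reference_variant.k - 1

    @classmethod
    def from_sequences(
        cls,
        variant_seq: ExtendedSequence,
        control_seq: ExtendedSequence,
        table: KmerCurrentTable,
        variant_reads: list[LevelSequence],
        control_reads: list[LevelSequence],
        enzyme_mode: str = PHI29,
        **kwargs,
    ) -> "SubstitutionContrast":
        """Build the model from the two templates and a k-mer table."""
        if len(variant_seq) != len(control_seq):
            raise ValueError("templates must have equal length")
        subs = [
            i + 1
            for i, (a, b) in enumerate(zip(variant_seq.residues,
                                           control_seq.residues))
            if a != b
        ]
        return cls(
            variant_reads, control_reads,
            ideal_level_series(variant_seq, table, enzyme_mode),
            ideal_level_series(control_seq, table, enzyme_mode),
            substitution_positions=subs, **kwargs,
        )

    def _align_arm(self, reads, reference):
        return [
            align_levels(r, reference, self.emission_sd, self.move_penalties)
            for r in reads
        ]

    def fit(self, z_min: float = 3.0, min_run: int = 2) -> "ContrastResults":
        """Align, build per-arm consensus, difference, and call regions."""
        aln_v = self._align_arm(self.variant_reads, self.reference_variant)
        aln_c = self._align_arm(self.control_reads, self.reference_control)
        cons_v = orient_for_sequence(
            build_consensus(aln_v, self.variant_reads, self.reference_variant,
                            self.min_score))
        cons_c = orient_for_sequence(
            build_consensus(aln_c, self.control_reads, self.reference_control,
                            self.min_score))
        sub0 = (self.substitution_positions[0]
                if self.substitution_positions else None)
        diff = difference_track(
            cons_v, cons_c,
            substitution_position=sub0,
            k=self.reference_variant.k,
            seq_length=self.seq_length,
        )
        regions = call_affected_regions(diff, z_min=z_min, min_run=min_run)
        return ContrastResults(self, cons_v, cons_c, diff, regions,
                               z_min=z_min, min_run=min_run)

    def default_window(self, substitution_position: int | None = None) -> tuple[int, int]:
        """Temporal-index window of levels affected by a substitution."""
        pos = substitution_position or (
            self.substitution_positions[0] if self.substitution_positions else None)
        if pos is None:
            raise ValueError("no substitution position known")
        ref = self.reference_variant
        lo, hi = affected_level_range(pos, ref.k, self.seq_length, ref.enzyme_mode)
        if ref.enzyme_mode == HEL308:  # sequence -> temporal indices
            m = len(ref)
            lo, hi = m + 1 - hi, m + 1 - lo
        return lo, hi


@dataclass
class ContrastResults:
    """Fitted contrast: consensus tracks, difference track, region calls."""

    model: SubstitutionContrast
    consensus_variant: ConsensusTrack
    consensus_control: ConsensusTrack
    difference: DifferenceTrack
    regions: list[RegionCall]
    z_min: float = 3.0
    min_run: int = 2
    _classifications: list[ReadClassification] | None = field(
        default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = self.difference.to_frame()
        df["variant_mean_pA"] = self.consensus_variant.mean
        df["variant_sd_pA"] = self.consensus_variant.sd
        df["control_mean_pA"] = self.consensus_control.mean
        df["control_sd_pA"] = self.consensus_control.sd
        return df

    def classify_reads(
        self,
        window: tuple[int, int] | None = None,
        ambiguity_margin: float = 2.0,
    ) -> list[ReadClassification]:
        """Classify every variant-arm read at the (known) substitution site."""
        m = self.model
        if window is None:
            window = m.default_window()
        out = [
            classify_single_read(
                r, m.reference_control, m.reference_variant, window,
                m.emission_sd, ambiguity_margin, m.move_penalties)
            for r in m.variant_reads
        ]
        self._classifications = out
        return out

    def summary(self) -> str:
        m = self.model
        lines = [
            "Substitution contrast (variant - control)",
            "=" * 57,
            f"enzyme mode:        {m.reference_variant.enzyme_mode}",
            f"reference levels:   {len(m.reference_variant)}",
            f"reads (variant):    {len(m.variant_reads)}",
            f"reads (control):    {len(m.control_reads)}",
            f"substitutions at:   {m.substitution_positions}",
            f"significance rule:  |z| >= {self.z_min}, run >= {self.min_run}",
            "-" * 57,
            f"region calls:       {len(self.regions)}",
        ]
        for r in self.regions:
            lines.append(
                f"  levels {r.start_index}-{r.end_index} "
                f"({r.n_levels} levels, peak delta {r.peak_delta:+.1f} pA, "
                f"signs {r.sign_profile})"
            )
        sig = self.to_frame()
        sig = sig[np.abs(sig["z"]) >= self.z_min]
        if len(sig):
            lines.append("-" * 57)
            lines.append("significant levels:")
            lines.append(
                sig[["level_index", "delta_pA", "se_pA", "z"]]
                .to_string(index=False,
                           float_format=lambda v: f"{v:.2f}")
            )
        if self._classifications is not None:
            labels = [c.label for c in self._classifications]
            lines.append("-" * 57)
            lines.append(
                "single-read calls (variant arm): "
                + ", ".join(f"{lab}={labels.count(lab)}"
                            for lab in ("unnatural", "natural", "ambiguous"))
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Consensus overlay (SD bars) above the difference track (SE bars)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
        else:
            axes = ax
        x = self.difference.level_index
        axes[0].errorbar(x, self.consensus_variant.mean,
                         yerr=self.consensus_variant.sd, fmt="o-", color="red",
                         label=f"variant (N={len(self.model.variant_reads)})")
        axes[0].errorbar(x, self.consensus_control.mean,
                         yerr=self.consensus_control.sd, fmt="o-", color="black",
                         label=f"control (N={len(self.model.control_reads)})")
        axes[0].set_ylabel("current (pA)")
        axes[0].legend()
        axes[1].errorbar(x, self.difference.delta, yerr=self.difference.se_delta,
                         fmt="o-", color="tab:blue")
        axes[1].axhline(0, color="gray", lw=0.8)
        for r in self.regions:
            axes[1].axvspan(r.start_index - 0.5, r.end_index + 0.5,
                            color="orange", alpha=0.2)
        axes[1].set_xlabel("level index (5'->3')")
        axes[1].set_ylabel("delta (pA)")
        return axes
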