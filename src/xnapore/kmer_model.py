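"""Six-letter k-mer pore model and ideal level series.

The residual ion current of a nanopore read reports the ~k nucleotides
sitting in the pore constriction (k = 4 for MspA).  This module maps every
k-mer over the six-letter alphabet {A,C,G,T,Z,Q} to a mean blockade current
and converts a sequence into the ideal, noise-free series of current levels
an enzyme-stepped read would visit:

* phi29 forced-unzipping mode: one full-nucleotide step per level, giving
  L - k + 1 levels for a length-L template;
* Hel308 mode: the helicase advances in two sub-steps per nucleotide, so
  half-step levels are interleaved between the full-step levels, giving
  2(L - k + 1) - 1 levels.

Half-step currents are modelled as the arithmetic mean of the two flanking
full-step currents — the simplest model consistent with a single
substitution perturbing 2k + 1 consecutive half-step levels.

No attempt is made to reproduce physically measured pA values (which depend
on salt conditions and pore mutant); the synthetic table only reproduces the
*structure* of the problem: 6^k distinguishable-or-not levels, a large
positive current offset for d5SICS (Q), and mixed-sign offsets for dNaM (Z).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np

from .sequences import ExtendedSequence, TABLE_ALPHABET

NATURAL = "ACGT"

PHI29 = "phi29"
HEL308 = "hel308"
ENZYME_MODES = (PHI29, HEL308)


def all_kmers(k: int, alphabet: str = TABLE_ALPHABET) -> list[str]:
    """All k-mers over ``alphabet`` in lexicographic order."""
    return ["".join(p) for p in itertools.product(sorted(alphabet), repeat=k)]


@dataclass
class KmerCurrentTable:
    """Complete map from k-mers over {A,C,G,T,Z,Q} to mean current (pA).

    ``abasic_current`` is a constant override used whenever a window covers
    an abasic (X) residue; X does not participate in the 6^k table.
    """

    k: int
    entries: dict[str, float]
    abasic_current: float = 60.0
    current_range: tuple[float, float] = (15.0, 65.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        expected = set(all_kmers(self.k))
        got = set(self.entries)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise ValueError(
                f"table is not a complete 6^{self.k} map "
                f"({len(got)} entries; missing e.g. {missing}, extra e.g. {extra})"
            )
        vals = np.fromiter(self.entries.values(), dtype=float)
        lo, hi = self.current_range
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite current in table")
        if vals.min() < lo - 1e-9 or vals.max() > hi + 1e-9:
            raise ValueError(
                f"currents outside configured range {self.current_range}: "
                f"[{vals.min():.3f}, {vals.max():.3f}]"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def current(self, kmer: str) -> float:
        """Current of one window; any X in the window takes the abasic override."""
        if "X" in kmer:
            return self.abasic_current
        return self.entries[kmer]

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the table with metadata headers, rows lexicographic by k-mer."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            fh.write(f"#abasic_pA={float(self.abasic_current)!r}\n")
            fh.write(
                f"#range_pA={float(self.current_range[0])!r},"
                f"{float(self.current_range[1])!r}\n"
            )
            for key, val in sorted(self.provenance.items()):
                fh.write(f"#{key}={val!r}\n")
            fh.write("kmer\tcurrent_pA\n")
            for kmer in sorted(self.entries):
                fh.write(f"{kmer}\t{float(self.entries[kmer])!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerCurrentTable":
        meta: dict[str, str] = {}
        entries: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    meta[key] = val
                    continue
                if line.startswith("kmer\t"):
                    continue
                kmer, _, cur = line.partition("\t")
                entries[kmer] = float(cur)
        k = int(meta.pop("k"))
        abasic = float(meta.pop("abasic_pA"))
        lo, hi = (float(x) for x in meta.pop("range_pA").split(","))
        return cls(k=k, entries=entries, abasic_current=abasic,
                   current_range=(lo, hi), provenance=meta)


def generate_synthetic_table(
    seed: int,
    k: int = 4,
    base_range: tuple[float, float] = (15.0, 65.0),
    q_offset: float = 15.0,
    z_offsets: tuple[float, float] = (5.0, 15.0),
    abasic_current: float = 60.0,
) -> KmerCurrentTable:
    """Generate a seeded, complete 6^k current table.

    Natural (ACGT-only) k-mers draw their mean current uniformly from
    ``base_range``.  Every Q in a window adds ``q_offset`` pA relative to the
    window's Q->C homolog, emulating the consistently large current increase
    of d5SICS.  Windows containing Z are shifted by a context-dependent
    offset with magnitude drawn from ``z_offsets`` and random sign, emulating
    dNaM's mixed-sign current change.  Identical seed and parameters yield a
    byte-identical table.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lo, hi = base_range
    if not lo < hi:
        raise ValueError(f"base_range must be non-degenerate, got {base_range}")
    if q_offset <= 0:
        raise ValueError(f"q_offset must be positive, got {q_offset}")
    zlo, zhi = z_offsets
    if not 0 <= zlo <= zhi:
        raise ValueError(f"invalid z_offsets {z_offsets}")

    rng = np.random.default_rng(seed)
    nat_kmers = all_kmers(k, NATURAL)
    base = dict(zip(nat_kmers, rng.uniform(lo, hi, size=len(nat_kmers))))

    # one signed shift per Z-containing context (Q already collapsed to C),
    # so that a window and its Q->C homolog share the same Z contribution
    z_contexts = [w for w in all_kmers(k, NATURAL + "Z") if "Z" in w]
    mags = rng.uniform(zlo, zhi, size=len(z_contexts))
    signs = rng.choice([-1.0, 1.0], size=len(z_contexts))
    zshift = dict(zip(z_contexts, mags * signs))

    entries: dict[str, float] = {}
    for w in all_kmers(k):
        zctx = w.replace("Q", "C")
        nat = zctx.replace("Z", "C")
        entries[w] = (
            base[nat]
            + w.count("Q") * q_offset
            + (zshift[zctx] if "Z" in zctx else 0.0)
        )

    current_range = (lo - k * zhi, hi + k * q_offset + k * zhi)
    prov = {
        "seed": seed, "base_range": base_range, "q_offset": q_offset,
        "z_offsets": z_offsets,
    }
    return KmerCurrentTable(
        k=k, entries=entries, abasic_current=abasic_current,
        current_range=current_range, provenance=prov,
    )


@dataclass
class StepSequence:
    """Ideal (noise-free) level series for one template in one enzyme mode.

    Levels are stored in 5'->3' sequence order: entry ``i`` (1-based) of a
    phi29 series carries the current of the window at template positions
    ``i .. i+k-1``.  Hel308 series interleave half-step levels between full
    steps (full, half, full, ...).  Hel308 *temporal* order is the reverse of
    sequence order (the helicase walks 3'->5' on the strand read 5'->3' by
    the pore); :meth:`temporal_currents` gives time order for simulation.
    """

    currents: np.ndarray                 # pA, sequence order
    phases: tuple[str, ...]              # "full" | "half"
    covered: tuple[tuple[int, int], ...] # inclusive 1-based template span
    enzyme_mode: str
    k: int
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.enzyme_mode not in ENZYME_MODES:
            raise ValueError(f"unknown enzyme_mode {self.enzyme_mode!r}")
        self.currents = np.asarray(self.currents, dtype=float)

    def __len__(self) -> int:
        return len(self.currents)

    @property
    def n_levels(self) -> int:
        return len(self.currents)

    def temporal_currents(self) -> np.ndarray:
        """Level currents in the order they appear in time in a raw trace."""
        if self.enzyme_mode == HEL308:
            return self.currents[::-1]
        return self.currents

    def temporal_to_sequence_index(self, idx: int) -> int:
        """Map a 1-based temporal level index to its sequence-order index."""
        if self.enzyme_mode == HEL308:
            return len(self) + 1 - idx
        return idx


def ideal_level_series(
    seq: ExtendedSequence, table: KmerCurrentTable, enzyme_mode: str = PHI29
) -> StepSequence:
    """Convert a sequence to its ideal level series under ``table``.

    phi29: one level per window, ``L - k + 1`` levels.  hel308: full levels
    as for phi29 with interpolated half levels between consecutive fulls,
    ``2(L - k + 1) - 1`` levels.
    """
    k = table.k
    L = len(seq)
    if L < k:
        raise ValueError(
            f"sequence {seq.id!r} (length {L}) shorter than window k={k}"
        )
    full = np.array([table.current(w) for w in seq.kmers(k)])
    spans = [(i, i + k - 1) for i in range(1, L - k + 2)]
    if enzyme_mode == PHI29:
        return StepSequence(full, ("full",) * len(full), tuple(spans),
                            PHI29, k, seq.id)
    if enzyme_mode != HEL308:
        raise ValueError(f"unknown enzyme_mode {enzyme_mode!r}")
    n = len(full)
    currents = np.empty(2 * n - 1)
    currents[0::2] = full
    currents[1::2] = 0.5 * (full[:-1] + full[1:])
    phases: list[str] = []
    covered: list[tuple[int, int]] = []
    for i in range(n):
        phases.append("full")
        covered.append(spans[i])
        if i < n - 1:
            phases.append("half")
            covered.append((spans[i][0], spans[i + 1][1]))
    return StepSequence(currents, tuple(phases), tuple(covered), HEL308, k, seq.id)


def diff_ideal(
    series_a: StepSequence, series_b: StepSequence
) -> list[tuple[int, float]]:
    """Index-aligned elementwise difference a - b of two ideal series."""
    if series_a.enzyme_mode != series_b.enzyme_mode:
        raise ValueError(
            f"enzyme_mode mismatch: {series_a.enzyme_mode} vs {series_b.enzyme_mode}"
        )
    if len(series_a) != len(series_b):
        raise ValueError(f"length mismatch: {len(series_a)} vs {len(series_b)}")
    delta = series_a.currents - series_b.currents
    return [(i + 1, float(d)) for i, d in enumerate(delta)]


def affected_level_range(
    substitution_position: int, k: int, seq_length: int, enzyme_mode: str = PHI29
) -> tuple[int, int]:
    """Inclusive 1-based range of level indices whose window covers a
    substituted template position.

    phi29: the windows covering position p are levels max(1, p-k+1) .. min(n, p)
    with n = L - k + 1 (k levels for an interior site).  hel308: the affected
    full levels plus every flanking half level, 2k + 1 entries for an
    interior site.
    """
    n = seq_length - k + 1
    lo = max(1, substitution_position - k + 1)
    hi = min(n, substitution_position)
    if lo > hi:
        raise ValueError(
            f"position {substitution_position} not covered by any window "
            f"(length {seq_length}, k={k})"
        )
    if enzyme_mode == PHI29:
        return lo, hi
    if enzyme_mode == HEL308:
        return max(1, 2 * lo - 2), min(2 * n - 1, 2 * hi)
    raise ValueError(f"unknown enzyme_mode {enzyme_mode!r}")
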