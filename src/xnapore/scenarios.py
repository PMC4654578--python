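"""End-to-end synthetic experiment designs and the pipeline that runs them.

A :class:`Scenario` bundles everything one nanopore contrast experiment
needs: a variant/control template pair, the substitutions separating them,
an enzyme mode, per-arm read counts, k-mer table parameters, and a master
seed.  :func:`build_scenario` materializes it as a self-contained directory
(table TSV, FASTA pair, per-read signal + annotation TSVs, manifest JSON)
that every downstream stage can consume with no external data;
:func:`run_scenario_pipeline` runs detection, alignment, consensus and the
substitution contrast over such a bundle.

Shipped designs mirror the study layouts: the eight single-substitution
panels (Q or Z replacing each natural base at the same interior position of
an identical 30-mer context), the two-site Z+Q strand against its
all-cytosine control (41 vs 19 reads, phi29), and the Hel308 replica of the
two-site contrast (48 vs 49 reads).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .contrast import ContrastResults, SubstitutionContrast
from .detect import detect_levels
from .kmer_model import (HEL308, PHI29, KmerCurrentTable,
                         generate_synthetic_table, ideal_level_series)
from .sequences import ExtendedSequence, parse_extended_fasta, write_extended_fasta
from .simulate import (SignalTrace, SimulationConfig, config_with_seed,
                       simulate_read)

# 30-mer context used by every shipped design; substituted sites sit well
# inside the sensing window's reach from both ends.
CONTEXT_30 = "GATTACAGTCCATGCAGGTCAATCGCTTGA"


@dataclass
class Scenario:
    """One contrast experiment design."""

    name: str
    variant: ExtendedSequence
    control: ExtendedSequence
    substitutions: list[tuple[int, str, str]]  # (position, variant_sym, control_sym)
    enzyme_mode: str = PHI29
    n_variant: int = 41
    n_control: int = 19
    seed: int = 20150
    table_params: dict = field(default_factory=dict)  # kwargs to generate_synthetic_table
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if len(self.variant) != len(self.control):
            raise ValueError("variant and control must have equal length")
        if self.n_variant < 1 or self.n_control < 1:
            raise ValueError("read counts must be >= 1")
        for pos, var_sym, ctrl_sym in self.substitutions:
            if var_sym == ctrl_sym:
                raise ValueError(
                    f"substitution at {pos}: variant symbol equals control symbol"
                )
            if self.variant[pos] != var_sym or self.control[pos] != ctrl_sym:
                raise ValueError(f"substitution at {pos} inconsistent with templates")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.variant.residues,
                                           self.control.residues))
            if a != b
        ]
        declared = sorted(p for p, _, _ in self.substitutions)
        if diffs != declared:
            raise ValueError(
                f"templates differ at {diffs} but substitutions declare {declared}"
            )

    def make_table(self) -> KmerCurrentTable:
        params = dict(seed=self.seed, **self.table_params)
        return generate_synthetic_table(**params)


def _context_with(symbol: str, position: int = 15,
                  seq_id: str = "s") -> ExtendedSequence:
    base = ExtendedSequence(seq_id, CONTEXT_30)
    return base.substitute(position, symbol)


def builtin_scenario(name: str, seed: int = 20150,
                     n_variant: int | None = None,
                     n_control: int | None = None) -> Scenario:
    """Construct one of the shipped designs by name.

    Names: ``q_for_a`` .. ``q_for_t``, ``z_for_a`` .. ``z_for_t``,
    ``zq_vs_control_a``, ``hel308_replica``.
    """
    kw: dict = {}
    if name in {f"{u}_for_{b}" for u in "qz" for b in "acgt"}:
        unnatural, natural = name[0].upper(), name[-1].upper()
        scen = Scenario(
            name=name,
            variant=_context_with(unnatural, seq_id=f"ctx_{unnatural}"),
            control=_context_with(natural, seq_id=f"ctx_{natural}"),
            substitutions=[(15, unnatural, natural)],
            enzyme_mode=PHI29, seed=seed, **kw,
        )
    elif name == "zq_vs_control_a":
        ctrl = ExtendedSequence("control_A", CONTEXT_30)  # C at 11 and 20
        var = ctrl.substitute(11, "Z").substitute(20, "Q")
        var = ExtendedSequence("seq_ZQ", var.residues)
        scen = Scenario(
            name=name, variant=var, control=ctrl,
            substitutions=[(11, "Z", "C"), (20, "Q", "C")],
            enzyme_mode=PHI29, n_variant=41, n_control=19, seed=seed,
        )
    elif name == "hel308_replica":
        base = builtin_scenario("zq_vs_control_a", seed=seed)
        scen = replace(
            base, name=name, enzyme_mode=HEL308, n_variant=48, n_control=49,
            sim=replace(base.sim, enzyme_mode=HEL308),
        )
    else:
        raise ValueError(f"unknown scenario {name!r}")
    if n_variant is not None:
        scen = replace(scen, n_variant=n_variant)
    if n_control is not None:
        scen = replace(scen, n_control=n_control)
    return scen


BUILTIN_SCENARIOS = tuple(
    [f"{u}_for_{b}" for u in "qz" for b in "acgt"]
    + ["zq_vs_control_a", "hel308_replica"]
)


def _arm_seeds(master_seed: int, arm: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([master_seed, arm])
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_arm(
    scenario: Scenario, table: KmerCurrentTable, arm: str
) -> list[SignalTrace]:
    """Simulate all downsampled reads for one arm ('variant' or 'control')."""
    seq = scenario.variant if arm == "variant" else scenario.control
    n = scenario.n_variant if arm == "variant" else scenario.n_control
    steps = ideal_level_series(seq, table, scenario.enzyme_mode)
    cfg = replace(scenario.sim, enzyme_mode=scenario.enzyme_mode)
    seeds = _arm_seeds(scenario.seed, 0 if arm == "variant" else 1, n)
    return [simulate_read(steps, config_with_seed(cfg, s)) for s in seeds]


def build_scenario(scenario: Scenario, outdir) -> Path:
    """Materialize a scenario as a self-contained bundle directory."""
    out = Path(outdir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    table = scenario.make_table()
    table.to_tsv(out / "table.tsv")
    write_extended_fasta([scenario.variant, scenario.control],
                         str(out / "sequences.fasta"))
    files: dict[str, list[dict]] = {"variant": [], "control": []}
    for arm in ("variant", "control"):
        for i, trace in enumerate(simulate_arm(scenario, table, arm)):
            sig = f"reads/{arm}_{i:03d}.signal.tsv"
            ann = f"reads/{arm}_{i:03d}.annot.tsv"
            trace.to_tsv(out / sig, out / ann)
            files[arm].append({"signal": sig, "annotations": ann})
    manifest = {
        "name": scenario.name,
        "enzyme_mode": scenario.enzyme_mode,
        "seed": scenario.seed,
        "substitutions": [list(s) for s in scenario.substitutions],
        "variant_id": scenario.variant.id,
        "control_id": scenario.control.id,
        "n_variant": scenario.n_variant,
        "n_control": scenario.n_control,
        "table": "table.tsv",
        "sequences": "sequences.fasta",
        "reads": files,
        "sim_config": asdict(scenario.sim),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def load_bundle(bundle_dir) -> dict:
    """Load a bundle directory back into in-memory objects."""
    bundle = Path(bundle_dir)
    with open(bundle / "manifest.json") as fh:
        manifest = json.load(fh)
    table = KmerCurrentTable.from_tsv(bundle / manifest["table"])
    seqs = {s.id: s for s in
            parse_extended_fasta(open(bundle / manifest["sequences"]))}
    reads = {
        arm: [
            SignalTrace.from_tsv(bundle / f["signal"], bundle / f["annotations"])
            for f in manifest["reads"][arm]
        ]
        for arm in ("variant", "control")
    }
    return {"manifest": manifest, "table": table, "sequences": seqs,
            "traces": reads}


def run_scenario_pipeline(
    bundle_dir,
    t_threshold: float = 4.5,
    min_duration: float = 0.001,
    merge_delta: float = 0.4,
    emission_sd: float = 1.5,
    z_min: float = 3.0,
    min_run: int = 2,
) -> ContrastResults:
    """Detect levels, align, build consensus and fit the contrast for a bundle."""
    data = load_bundle(bundle_dir)
    man = data["manifest"]
    variant_seq = data["sequences"][man["variant_id"]]
    control_seq = data["sequences"][man["control_id"]]
    level_reads = {
        arm: [detect_levels(tr, t_threshold, min_duration, merge_delta)
              for tr in data["traces"][arm]]
        for arm in ("variant", "control")
    }
    model = SubstitutionContrast.from_sequences(
        variant_seq, control_seq, data["table"],
        level_reads["variant"], level_reads["control"],
        enzyme_mode=man["enzyme_mode"], emission_sd=emission_sd,
    )
    return model.fit(z_min=z_min, min_run=min_run)
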