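"""Synthetic hairpin (ox)BS data generator.

Forward-simulates dyad populations under the replication/maintenance/
de novo/hydroxylation dynamics, pushes them through the BS or oxBS
conversion chemistry with configurable error rates, and emits paired
hairpin FASTQ reads carrying the linker with its controls and a degenerate
UMI, plus ground-truth tables.  Every stage of the analysis pipeline can be
exercised offline against known truth.

Defaults emulate the mouse ESC serum-to-2i demethylation study design:
four observation days (0, 1, 3, 6) at a 12 h cell cycle, molecules drawn
iid from the population marginal (each sequenced molecule samples one
cell), and per-dyad independence within a molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .align import MethylationCall
from .conversion import EmissionParameters
from .model import (
    CountData,
    DivisionSchedule,
    EnzymeEfficiencies,
    STATES,
    STATE_PAIRS,
    _broadcast_efficiencies,
    _check_distribution,
    _propagate,
    emission_matrix,
)
from .reference import HairpinReference

_UMI_BASES = np.array(list("ATG"))
_ACGT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    reference: HairpinReference
    efficiencies: EnzymeEfficiencies | np.ndarray
    initial_distribution: np.ndarray
    schedule: DivisionSchedule
    emissions: dict[str, EmissionParameters]
    n_molecules: int = 1000  # per time point and treatment
    pcr_duplication_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    noncpg_methylation: float = 0.0
    read_length: int | None = None  # default: full molecule, fully overlapping mates
    common_dyad_state: bool = False  # tie all dyads of a molecule to one state
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory: simulations must be reproducible")
        for name in ("pcr_duplication_rate", "sequencing_error_rate", "noncpg_methylation"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")
        self.initial_distribution = _check_distribution(self.initial_distribution)

    def efficiency_array(self) -> np.ndarray:
        return _broadcast_efficiencies(self.efficiencies, self.schedule.n_intervals)

    def echo(self, path: str | Path) -> Path:
        """Write the resolved configuration (including the seed) as YAML."""
        eff = self.efficiency_array()
        payload = {
            "amplicon_id": self.reference.amplicon_id,
            "n_dyads": self.reference.n_dyads,
            "efficiencies": {
                "mu": eff[:, 0].tolist(),
                "delta": eff[:, 1].tolist(),
                "eta": eff[:, 2].tolist(),
            },
            "initial_distribution": dict(zip(STATES, self.initial_distribution.tolist())),
            "schedule": {
                "days": list(self.schedule.days),
                "divisions": list(self.schedule.divisions),
            },
            "emissions": {
                tr: {
                    "p_t_given_c": em.p_t_given_c,
                    "p_t_given_5mc": em.p_t_given_5mc,
                    "p_t_given_5hmc": em.p_t_given_5hmc,
                }
                for tr, em in self.emissions.items()
            },
            "n_molecules": self.n_molecules,
            "pcr_duplication_rate": self.pcr_duplication_rate,
            "sequencing_error_rate": self.sequencing_error_rate,
            "noncpg_methylation": self.noncpg_methylation,
            "common_dyad_state": self.common_dyad_state,
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


def population_distributions(config: SimulationConfig) -> np.ndarray:
    """(n_times, 9) population state distribution at each observation day."""
    return _propagate(
        config.efficiency_array(), config.initial_distribution, config.schedule
    )


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Draw hidden dyad states per molecule for each observation time.

    Returns one (n_molecules, n_dyads) integer state array per time point;
    molecules are iid samples from the propagated population marginal, with
    dyads independent within a molecule unless ``common_dyad_state``.
    """
    rng = rng or np.random.default_rng(config.seed)
    dists = population_distributions(config)
    n, d = config.n_molecules, config.reference.n_dyads
    out = []
    for t in range(config.schedule.n_times):
        if config.common_dyad_state:
            states = rng.choice(9, size=(n, 1), p=dists[t])
            states = np.repeat(states, d, axis=1)
        else:
            states = rng.choice(9, size=(n, d), p=dists[t])
        out.append(states)
    return out


def apply_chemistry(
    states: np.ndarray,
    treatment: str,
    params: EmissionParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convert hidden states into read classes (0=CC, 1=CT, 2=TC, 3=TT).

    Each strand is read T with the treatment's per-base probability; the
    linker controls elsewhere use the same parameters, so a round trip
    through the conversion QC recovers the configured rates.
    """
    pt_top = np.empty(9)
    pt_bot = np.empty(9)
    for i, (a, b) in enumerate(STATE_PAIRS):
        pt_top[i] = params.p_t(a)
        pt_bot[i] = params.p_t(b)
    top_t = rng.random(states.shape) < pt_top[states]
    bot_t = rng.random(states.shape) < pt_bot[states]
    return (top_t.astype(int) << 1) | bot_t.astype(int)


def simulate_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CountData:
    """Aggregated CC/CT/TC/TT counts per time and treatment.

    The BS and oxBS aliquots sample distinct molecules (different cells), as
    in the split-reaction design.
    """
    rng = rng or np.random.default_rng(config.seed)
    counts = {tr: np.zeros((config.schedule.n_times, 4), dtype=int) for tr in config.emissions}
    for tr, params in config.emissions.items():
        states_per_time = simulate_population(config, rng)
        for t, states in enumerate(states_per_time):
            classes = apply_chemistry(states, tr, params, rng)
            counts[tr][t] = np.bincount(classes.ravel(), minlength=4)
    return CountData(counts=counts)


def visible_class(state: int, treatment: str) -> str:
    """Dyad class a perfect, error-free read of this state would show.

    Under BS both m and h strands read C (modified); under oxBS only m does.
    """
    visible = ("m", "h") if treatment == "BS" else ("m",)
    a, b = STATE_PAIRS[state]
    top, bot = a in visible, b in visible
    if top and bot:
        return "both"
    if top:
        return "hemi_top"
    if bot:
        return "hemi_bottom"
    return "unmod"


@dataclass
class SimulatedMolecule:
    molecule_id: str
    sample: str
    day: float
    treatment: str
    umi: str
    states: tuple[int, ...]
    n_copies: int


@dataclass
class SimulatedDataset:
    fastq_pairs: dict[str, tuple[Path, Path]]  # sample -> (R1, R2)
    ground_truth: Path
    config_echo: Path
    molecules: list[SimulatedMolecule] = field(repr=False, default_factory=list)


def _molecule_sequence(
    ref: HairpinReference,
    states: np.ndarray,
    classes: np.ndarray,
    umi: str,
    params: EmissionParameters,
    noncpg_methylation: float,
    rng: np.random.Generator,
) -> str:
    """Sequence of one converted hairpin molecule in composite orientation."""
    seq = list(ref.composite_seq())
    # UMI slots
    for pos, base in zip(ref.umi_composite_positions, umi):
        seq[pos] = base
    # linker controls convert per their carried modification
    role_base = {"unmodC": "u", "5mC": "m", "5hmC": "h"}
    control_pos = ref.control_composite_positions
    for pos, role in control_pos.items():
        seq[pos] = "T" if rng.random() < params.p_t(role_base[role]) else "C"
    # dyad cytosines follow the drawn read classes (bit 1 = top strand T)
    for d, p in enumerate(ref.dyad_positions):
        c = classes[d]
        seq[ref.top_dyad_position(p)] = "T" if (c >> 1) & 1 else "C"
        seq[ref.bottom_dyad_position(p)] = "T" if c & 1 else "C"
    # remaining cytosines (nonCpG genomic + non-control linker) are
    # unmethylated except for an optional nonCpG methylation rate
    dyad_pos = {ref.top_dyad_position(p) for p in ref.dyad_positions} | {
        ref.bottom_dyad_position(p) for p in ref.dyad_positions
    }
    for pos, base in enumerate(seq):
        if base != "C" or pos in dyad_pos or pos in control_pos:
            continue
        methylated = (
            pos < ref.linker_offset or pos >= ref.bottom_offset
        ) and rng.random() < noncpg_methylation
        p_t = params.p_t("m") if methylated else params.p_t("u")
        seq[pos] = "T" if rng.random() < p_t else "C"
    return "".join(seq)


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.where(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def emit_fastq(
    config: SimulationConfig, out_dir: str | Path
) -> SimulatedDataset:
    """Write paired FASTQ per (day, treatment) sample plus ground truth.

    Read 1 covers the molecule from the top-arm end, read 2 (reverse
    complemented, as sequenced) from the bottom-arm end; with the default
    read length the mates fully overlap.  PCR clones replicate a molecule
    with its UMI (copy number geometric with mean 1/(1 - duplication rate));
    uniform substitution errors are applied after conversion, per copy.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = config.read_length or len(ref)
    if not 0 < L <= len(ref):
        raise ValueError(f"read_length must be in (0, {len(ref)}]")

    fastq_pairs: dict[str, tuple[Path, Path]] = {}
    molecules: list[SimulatedMolecule] = []
    gt_path = out_dir / "ground_truth.tsv"
    from .reference import reverse_complement

    with open(gt_path, "w") as gt:
        gt.write("sample\tmolecule_id\tday\ttreatment\tumi\tn_copies\tstates\n")
        for treatment, params in config.emissions.items():
            states_per_time = simulate_population(config, rng)
            for t, day in enumerate(config.schedule.days):
                sample = f"{ref.amplicon_id}_{treatment}_d{day:g}"
                r1_path = out_dir / f"{sample}_R1.fastq"
                r2_path = out_dir / f"{sample}_R2.fastq"
                states = states_per_time[t]
                classes = apply_chemistry(states, treatment, params, rng)
                with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
                    for m in range(config.n_molecules):
                        umi = "".join(
                            rng.choice(_UMI_BASES, size=len(ref.umi_composite_positions))
                        )
                        mol_id = f"{sample}:{m:06d}"
                        seq = _molecule_sequence(
                            ref, states[m], classes[m], umi, params,
                            config.noncpg_methylation, rng,
                        )
                        if config.pcr_duplication_rate > 0:
                            n_copies = int(rng.geometric(1.0 - config.pcr_duplication_rate))
                        else:
                            n_copies = 1
                        for c in range(n_copies):
                            r1 = _sequencing_errors(seq[:L], config.sequencing_error_rate, rng)
                            r2 = _sequencing_errors(
                                reverse_complement(seq[-L:]), config.sequencing_error_rate, rng
                            )
                            rid = f"{mol_id}:{c}"
                            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")
                        state_str = ",".join(STATES[s] for s in states[m])
                        gt.write(
                            f"{sample}\t{mol_id}\t{day:g}\t{treatment}\t{umi}\t{n_copies}\t{state_str}\n"
                        )
                        molecules.append(
                            SimulatedMolecule(
                                mol_id, sample, day, treatment, umi,
                                tuple(int(s) for s in states[m]), n_copies,
                            )
                        )
                fastq_pairs[sample] = (r1_path, r2_path)

    echo = config.echo(out_dir / "config_echo.yaml")
    return SimulatedDataset(
        fastq_pairs=fastq_pairs, ground_truth=gt_path, config_echo=echo, molecules=molecules
    )


def simulate_linker_reads(
    n_reads: int,
    treatment: str,
    params: EmissionParameters,
    rng: np.random.Generator,
    ref: HairpinReference | None = None,
) -> list[MethylationCall]:
    """Linker-control calls of ``n_reads`` simulated reads.

    Each read covers every control cytosine once and shows T with the
    treatment's per-base probability -- the minimal input for the
    conversion-rate analysis.
    """
    role_base = {"unmodC": "u", "5mC": "m", "5hmC": "h"}
    if ref is not None:
        positions = sorted(ref.control_composite_positions.items())
    else:
        positions = [(0, "unmodC"), (1, "5mC"), (2, "5hmC")]
    calls: list[MethylationCall] = []
    for pos, role in positions:
        p_t = params.p_t(role_base[role])
        is_t = rng.random(n_reads) < p_t
        for flag in is_t:
            observed = "T" if flag else "C"
            calls.append(
                MethylationCall(
                    position=pos,
                    strand="top",
                    context=f"linker_{role}",
                    observed=observed,
                    state="unmodified" if flag else "modified",
                )
            )
    return calls
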