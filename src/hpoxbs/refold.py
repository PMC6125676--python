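"""Restoration of double-strand information.

After alignment each molecule carries one methylation call per strand per
CpG dyad.  Refolding pairs those calls into dyad classes (modified on both
strands, hemimethylated on the top or bottom strand, unmodified, or not
analysable), collapses PCR clones that share a UMI, and summarises class
frequencies per dyad.  Pattern maps follow the conventional colouring:
red = both strands modified, dark green = top only, light green = bottom
only, blue = unmodified, white = not analysable.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .align import AlignedRead, MethylationCall, call_methylation, extract_umi
from .reference import HairpinReference

BOTH = "both"
HEMI_TOP = "hemi_top"
HEMI_BOTTOM = "hemi_bottom"
UNMOD = "unmod"
UNKNOWN = "unknown"

DYAD_CLASSES = (BOTH, HEMI_TOP, HEMI_BOTTOM, UNMOD, UNKNOWN)
ANALYSABLE_CLASSES = (BOTH, HEMI_TOP, HEMI_BOTTOM, UNMOD)

#: pattern-map palette (RGB)
CLASS_COLORS = {
    BOTH: (200, 30, 30),
    HEMI_TOP: (20, 110, 20),
    HEMI_BOTTOM: (140, 220, 140),
    UNMOD: (40, 70, 200),
    UNKNOWN: (255, 255, 255),
}

_CLASS_CODE = {BOTH: "B", HEMI_TOP: "T", HEMI_BOTTOM: "L", UNMOD: "U", UNKNOWN: "."}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}


@dataclass
class DyadPattern:
    """Per-dyad class vector of one (deduplicated) molecule."""

    molecule_id: str
    treatment: str
    classes: tuple[str, ...]
    umi: str | None = None
    noncpg_rate: float | None = None
    source_read_count: int = 1

    def __post_init__(self) -> None:
        for c in self.classes:
            if c not in DYAD_CLASSES:
                raise ValueError(f"unknown dyad class {c!r}")
        if self.source_read_count < 1:
            raise ValueError("source_read_count must be >= 1")

    def class_string(self) -> str:
        return "".join(_CLASS_CODE[c] for c in self.classes)


@dataclass
class PatternSummary:
    """Class frequencies among analysable molecules, per dyad and averaged."""

    n_molecules: int
    coverage: np.ndarray  # analysable molecules per dyad
    class_freq: pd.DataFrame  # index = dyad, columns = 4 analysable classes
    mean_class_freq: dict[str, float] = field(default_factory=dict)
    uncovered_dyads: tuple[int, ...] = ()

    @property
    def mean_modification_level(self) -> float:
        """Mean fraction of modified strands: both counts twice, hemi once."""
        return (
            self.mean_class_freq[BOTH]
            + 0.5 * (self.mean_class_freq[HEMI_TOP] + self.mean_class_freq[HEMI_BOTTOM])
        )


def refold_states(top_state: str, bottom_state: str) -> str:
    """Combine per-strand call states into a dyad class."""
    if top_state == "unknown" or bottom_state == "unknown":
        return UNKNOWN
    if top_state == "modified":
        return BOTH if bottom_state == "modified" else HEMI_TOP
    return HEMI_BOTTOM if bottom_state == "modified" else UNMOD


def refold(
    top_calls: list[MethylationCall],
    bottom_calls: list[MethylationCall],
    ref: HairpinReference,
    *,
    molecule_id: str = "molecule",
    treatment: str = "BS",
    umi: str | None = None,
    noncpg_rate: float | None = None,
) -> DyadPattern:
    """Pair the top- and bottom-strand CpG calls of one molecule into its
    dyad class vector.  Dyads missing a call on either strand are unknown."""
    by_dyad_top = {c.dyad_index: c.state for c in top_calls if c.context == "CpG"}
    by_dyad_bot = {c.dyad_index: c.state for c in bottom_calls if c.context == "CpG"}
    classes = tuple(
        refold_states(
            by_dyad_top.get(d, "unknown"), by_dyad_bot.get(d, "unknown")
        )
        for d in range(ref.n_dyads)
    )
    return DyadPattern(
        molecule_id=molecule_id,
        treatment=treatment,
        classes=classes,
        umi=umi,
        noncpg_rate=noncpg_rate,
    )


def pattern_from_read(
    aligned: AlignedRead, ref: HairpinReference, treatment: str | None = None
) -> DyadPattern:
    """Convenience: methylation-call and refold one aligned molecule."""
    calls = call_methylation(aligned, ref, contexts=("CpG", "nonCpG"))
    cpg = [c for c in calls if c.context == "CpG"]
    noncpg = [c for c in calls if c.context == "nonCpG" and c.state != "unknown"]
    rate = (
        sum(c.state == "modified" for c in noncpg) / len(noncpg) if noncpg else None
    )
    return refold(
        [c for c in cpg if c.strand == "top"],
        [c for c in cpg if c.strand == "bottom"],
        ref,
        molecule_id=aligned.read_id,
        treatment=treatment or aligned.treatment,
        umi=extract_umi(aligned, ref),
        noncpg_rate=rate,
    )


def dedup_umis(patterns: list[DyadPattern]) -> list[DyadPattern]:
    """Collapse PCR clones sharing a UMI into one consensus molecule.

    Consensus is per-dyad majority over the clone group (positions fail
    independently); a tied majority becomes unknown.  Reads without a UMI
    pass through uncollapsed.  Output order: UMI groups by first appearance,
    then UMI-less reads.
    """
    groups: dict[str, list[DyadPattern]] = defaultdict(list)
    order: list[str] = []
    no_umi: list[DyadPattern] = []
    for p in patterns:
        if p.umi is None:
            no_umi.append(p)
        else:
            if p.umi not in groups:
                order.append(p.umi)
            groups[p.umi].append(p)

    out: list[DyadPattern] = []
    for umi in order:
        members = groups[umi]
        if len(members) == 1:
            out.append(replace(members[0], source_read_count=sum(m.source_read_count for m in members)))
            continue
        n_dyads = len(members[0].classes)
        consensus = []
        for d in range(n_dyads):
            votes = Counter(m.classes[d] for m in members)
            (top_class, top_n), *rest = votes.most_common()
            if rest and rest[0][1] == top_n:
                consensus.append(UNKNOWN)
            else:
                consensus.append(top_class)
        rates = [m.noncpg_rate for m in members if m.noncpg_rate is not None]
        out.append(
            DyadPattern(
                molecule_id=members[0].molecule_id,
                treatment=members[0].treatment,
                classes=tuple(consensus),
                umi=umi,
                noncpg_rate=float(np.mean(rates)) if rates else None,
                source_read_count=sum(m.source_read_count for m in members),
            )
        )
    out.extend(no_umi)
    return out


def umi_collision_probability(n_molecules: int, umi_length: int) -> float:
    """Birthday-bound probability that >=2 of ``n_molecules`` share a UMI
    (3 legal bases per degenerate slot)."""
    k = 3**umi_length
    n = n_molecules
    if n > k:
        return 1.0
    # 1 - prod (1 - i/k), in log space for stability
    return float(1.0 - np.exp(np.sum(np.log1p(-np.arange(n) / k))))


def summarize(patterns: list[DyadPattern]) -> PatternSummary:
    """Per-dyad class frequencies over analysable molecules; the amplicon
    mean averages the per-dyad frequencies over dyads with coverage."""
    if not patterns:
        raise ValueError("no patterns to summarise")
    n_dyads = len(patterns[0].classes)
    counts = np.zeros((n_dyads, len(ANALYSABLE_CLASSES)))
    for p in patterns:
        for d, c in enumerate(p.classes):
            if c != UNKNOWN:
                counts[d, ANALYSABLE_CLASSES.index(c)] += 1
    coverage = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / coverage[:, None]
    uncovered = tuple(int(d) for d in np.where(coverage == 0)[0])
    if uncovered:
        warnings.warn(f"dyads with zero analysable molecules: {uncovered}", stacklevel=2)
    df = pd.DataFrame(freq, columns=list(ANALYSABLE_CLASSES))
    covered = coverage > 0
    mean = {
        c: float(np.mean(df.loc[covered, c])) if covered.any() else float("nan")
        for c in ANALYSABLE_CLASSES
    }
    return PatternSummary(
        n_molecules=len(patterns),
        coverage=coverage,
        class_freq=df,
        mean_class_freq=mean,
        uncovered_dyads=uncovered,
    )


def _blend(color_a, color_b, frac_a):
    return tuple(int(round(frac_a * a + (1 - frac_a) * b)) for a, b in zip(color_a, color_b))


def write_pattern_map(
    patterns: list[DyadPattern], path: str | Path, cell_size: int = 6
) -> Path:
    """Render the per-molecule dyad-class matrix as a PNG.

    One row per molecule, one column per dyad, preceded by a mean column
    (red/blue blend of the molecule's modified-strand fraction over its
    analysable dyads) and a 1-cell white separator.
    """
    if not patterns:
        raise ValueError("cannot render a pattern map from zero molecules")
    n_dyads = len(patterns[0].classes)
    n_cols = n_dyads + 2
    img = Image.new("RGB", (n_cols * cell_size, len(patterns) * cell_size), "white")
    px = img.load()
    for r, p in enumerate(patterns):
        strands_mod = strands_tot = 0
        for c in p.classes:
            if c == UNKNOWN:
                continue
            strands_tot += 2
            strands_mod += {BOTH: 2, HEMI_TOP: 1, HEMI_BOTTOM: 1, UNMOD: 0}[c]
        mean_color = (
            _blend(CLASS_COLORS[BOTH], CLASS_COLORS[UNMOD], strands_mod / strands_tot)
            if strands_tot
            else CLASS_COLORS[UNKNOWN]
        )
        row_colors = [mean_color, (255, 255, 255)] + [CLASS_COLORS[c] for c in p.classes]
        for col, color in enumerate(row_colors):
            for dy in range(cell_size):
                for dx in range(cell_size):
                    px[col * cell_size + dx, r * cell_size + dy] = color
    path = Path(path)
    img.save(path, format="PNG")
    return path


def molecule_table(patterns: list[DyadPattern]) -> pd.DataFrame:
    rows = [
        {
            "molecule_id": p.molecule_id,
            "treatment": p.treatment,
            "umi": p.umi if p.umi is not None else "",
            "source_read_count": p.source_read_count,
            "noncpg_rate": "" if p.noncpg_rate is None else f"{p.noncpg_rate:.6g}",
            "classes": p.class_string(),
        }
        for p in patterns
    ]
    return pd.DataFrame(rows)


def parse_class_string(s: str) -> tuple[str, ...]:
    return tuple(_CODE_CLASS[c] for c in s)


def write_tables(
    samples: dict[str, list[DyadPattern]],
    path_prefix: str | Path,
) -> list[Path]:
    """Write one per-molecule TSV per sample plus a cross-sample summary TSV.

    Schema (stable): per-molecule columns molecule_id / treatment / umi /
    source_read_count / noncpg_rate / classes (B=both, T=hemi-top,
    L=hemi-bottom, U=unmodified, .=unknown); summary has one row per sample
    with molecule count and mean class frequencies.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary_rows = []
    for sample, patterns in samples.items():
        per_mol = prefix.parent / f"{prefix.name}.{sample}.molecules.tsv"
        molecule_table(patterns).to_csv(per_mol, sep="\t", index=False)
        written.append(per_mol)
        s = summarize(patterns)
        row = {"sample": sample, "n_molecules": s.n_molecules}
        row.update({f"freq_{c}": f"{s.mean_class_freq[c]:.6g}" for c in ANALYSABLE_CLASSES})
        row["mean_modification_level"] = f"{s.mean_modification_level:.6g}"
        summary_rows.append(row)
    summary_path = prefix.parent / f"{prefix.name}.summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
    written.append(summary_path)
    return written
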