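"""Bisulfite-aware alignment of hairpin read pairs and methylation calling.

Reads from a bisulfite-treated hairpin molecule carry C->T conversions, so a
read T opposite a reference C is conversion-eligible and must not be scored
as a mismatch, while the reverse (read C opposite reference T) is a genuine
error.  This asymmetry is expressed through an asymmetric substitution
matrix fed to Biopython's ``PairwiseAligner`` in semi-global mode (the read
may cover only part of the composite reference without end-gap penalty).
Degenerate UMI slots (reference ``D``) accept A/T/G neutrally and penalise C.

Mates are aligned separately (mate 2 reverse-complemented first, which also
folds the G->A appearance of conversions on the opposite PCR strand back
into C->T space) and merged per reference position by quality-weighted
majority; disagreeing ties become N.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Align
from Bio.Align import substitution_matrices

from .reference import HairpinReference, reverse_complement

#: identity thresholds for keeping a read, by analysis context
IDENTITY_THRESHOLDS = {"single_copy": 0.9, "repetitive": 0.8}
LINKER_IDENTITY_THRESHOLD = 0.6

#: below this many aligned columns or this identity a read is unalignable
MIN_ALIGNED_COLUMNS = 20
MIN_IDENTITY = 0.3

_ALPHABET = "ACGTDN"

GAP = "-"


def _scoring_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 1.0 if a == b else -1.0
    # bisulfite conversion is one-directional: ref C may appear as read T
    m["C", "T"] = 1.0
    m["T", "C"] = -1.0
    # D = A/T/G UMI slot: neutral for the three legal bases, C is an error
    for b in "ATG":
        m["D", b] = 0.0
    m["D", "C"] = -1.0
    m["D", "D"] = 0.0
    # N is uninformative on either side
    for b in _ALPHABET:
        m["N", b] = 0.0
        m[b, "N"] = 0.0
    return m


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _scoring_matrix()
    aligner.mode = "global"
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -2.0
    # free end gaps on the reference: reads may cover a sub-interval
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class FastqRead:
    read_id: str
    seq: str
    quals: list[int]

    def reverse_complement(self) -> "FastqRead":
        return FastqRead(self.read_id, reverse_complement(self.seq), self.quals[::-1])


@dataclass
class AlignedRead:
    """One (merged) molecule aligned to the composite reference.

    ``aligned_bases`` maps composite positions to the observed base; a
    reference position deleted in the read maps to ``-``.
    """

    read_id: str
    treatment: str
    aligned_bases: dict[int, str]
    identity: float
    arms_covered: frozenset[str]
    quals: dict[int, int] = field(default_factory=dict, repr=False)
    alignable: bool = True


@dataclass(frozen=True)
class MethylationCall:
    position: int
    strand: str  # top | bottom
    context: str  # CpG | nonCpG | linker_unmodC | linker_5mC | linker_5hmC
    observed: str  # C | T | other
    state: str  # modified | unmodified | unknown
    dyad_index: int | None = None


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Plain or gzipped FASTQ; raises ValueError on malformed records."""
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record near {header.strip()!r} in {path}")
            yield FastqRead(
                header[1:].split()[0],
                seq.upper(),
                [ord(c) - 33 for c in qual],
            )


def _bases_match(ref_base: str, read_base: str) -> bool:
    if read_base in (GAP, "N"):
        return False
    if ref_base == "N":
        return True
    if read_base == ref_base:
        return True
    if ref_base == "C" and read_base == "T":
        return True  # conversion-eligible
    if ref_base == "D" and read_base in "ATG":
        return True
    return False


def _align_single(read: FastqRead, ref_seq: str) -> tuple[dict[int, str], dict[int, int]]:
    """Align one read; return per-reference-position base and quality maps."""
    alignments = _ALIGNER.align(ref_seq, read.seq)
    aln = alignments[0]
    blocks_t, blocks_q = aln.aligned
    bases: dict[int, str] = {}
    quals: dict[int, int] = {}
    prev_t_end: int | None = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            for p in range(prev_t_end, t0):  # reference bases deleted in read
                bases[p] = GAP
                quals[p] = 0
        for off in range(t1 - t0):
            bases[t0 + off] = read.seq[q0 + off]
            quals[t0 + off] = read.quals[q0 + off]
        prev_t_end = t1
    return bases, quals


def _merge_mates(
    b1: dict[int, str], q1: dict[int, int], b2: dict[int, str], q2: dict[int, int]
) -> tuple[dict[int, str], dict[int, int]]:
    merged: dict[int, str] = {}
    quals: dict[int, int] = {}
    for pos in set(b1) | set(b2):
        if pos not in b2:
            merged[pos], quals[pos] = b1[pos], q1[pos]
        elif pos not in b1:
            merged[pos], quals[pos] = b2[pos], q2[pos]
        elif b1[pos] == b2[pos]:
            merged[pos], quals[pos] = b1[pos], q1[pos] + q2[pos]
        elif q1[pos] > q2[pos]:
            merged[pos], quals[pos] = b1[pos], q1[pos]
        elif q2[pos] > q1[pos]:
            merged[pos], quals[pos] = b2[pos], q2[pos]
        else:
            merged[pos], quals[pos] = "N", 0  # quality tie with disagreement
    return merged, quals


def sequence_identity(
    aligned: AlignedRead | dict[int, str],
    ref: HairpinReference,
    region: str | None = None,
) -> float:
    """Fraction of matching aligned columns.

    C<->T at conversion-eligible positions and D vs A/T/G count as matches;
    gaps and N count as mismatches.  ``region`` restricts the computation to
    ``top`` / ``linker`` / ``bottom`` (the linker-only variant backs the
    relaxed 0.6 filter of the conversion-rate analysis).
    Raises ValueError when no columns are aligned.
    """
    bases = aligned.aligned_bases if isinstance(aligned, AlignedRead) else aligned
    ref_seq = ref.alignment_reference()
    n = matches = 0
    for pos, read_base in bases.items():
        if region is not None and ref.region_of(pos) != region:
            continue
        n += 1
        if _bases_match(ref_seq[pos], read_base):
            matches += 1
    if n == 0:
        raise ValueError("no aligned columns" + (f" in region {region!r}" if region else ""))
    return matches / n


def _arms_covered(bases: dict[int, str], ref: HairpinReference, min_frac: float = 0.8) -> frozenset[str]:
    spans = {
        "top": range(0, ref.linker_offset),
        "linker": range(ref.linker_offset, ref.bottom_offset),
        "bottom": range(ref.bottom_offset, len(ref)),
    }
    covered = set()
    for arm, span in spans.items():
        n_cov = sum(1 for p in span if bases.get(p, GAP) != GAP)
        if n_cov >= min_frac * len(span):
            covered.add(arm)
    return frozenset(covered)


def align_read_pair(
    read1: FastqRead,
    read2: FastqRead | None,
    ref: HairpinReference,
    treatment: str = "BS",
) -> AlignedRead:
    """Semi-global bisulfite-aware alignment of a (possibly overlapping)
    mate pair against the composite reference.

    Mate 2 is reverse-complemented into reference orientation before
    alignment; overlapping positions are resolved by quality-weighted
    majority with ties becoming N.  Reads with fewer than
    ``MIN_ALIGNED_COLUMNS`` columns or identity below ``MIN_IDENTITY`` are
    flagged unalignable.
    """
    ref_seq = ref.alignment_reference()
    b1, q1 = _align_single(read1, ref_seq)
    if read2 is not None:
        b2, q2 = _align_single(read2.reverse_complement(), ref_seq)
        bases, quals = _merge_mates(b1, q1, b2, q2)
    else:
        bases, quals = b1, q1
    out = AlignedRead(
        read_id=read1.read_id,
        treatment=treatment,
        aligned_bases=bases,
        identity=0.0,
        arms_covered=_arms_covered(bases, ref),
        quals=quals,
    )
    if len(bases) < MIN_ALIGNED_COLUMNS:
        out.alignable = False
        return out
    out.identity = sequence_identity(out, ref)
    if out.identity < MIN_IDENTITY:
        out.alignable = False
    return out


def passes_identity_filter(
    aligned: AlignedRead, ref: HairpinReference, mode: str = "cpg"
) -> bool:
    """Published retention thresholds: 0.9 single-copy / 0.8 repetitive for
    genomic analyses, 0.6 on the linker alone for conversion-rate analysis
    (the degenerate UMI loop depresses whole-read identity)."""
    if not aligned.alignable:
        return False
    if mode == "linker":
        try:
            return sequence_identity(aligned, ref, region="linker") >= LINKER_IDENTITY_THRESHOLD
        except ValueError:
            return False
    return aligned.identity >= IDENTITY_THRESHOLDS[ref.repeat_class]


def _state_from_base(base: str | None) -> tuple[str, str]:
    if base == "C":
        return "C", "modified"
    if base == "T":
        return "T", "unmodified"
    return "other", "unknown"


def call_methylation(
    aligned: AlignedRead,
    ref: HairpinReference,
    contexts: Iterable[str] = ("CpG", "linker"),
) -> list[MethylationCall]:
    """Per-cytosine calls for the requested context set.

    CpG calls are emitted per strand per dyad; nonCpG calls exclude dyad
    positions; linker controls are called through the SNP mechanism (the
    observed base, C or T, at the annotated control cytosines).
    """
    contexts = set(contexts)
    calls: list[MethylationCall] = []
    bases = aligned.aligned_bases
    if "CpG" in contexts:
        for d, p in enumerate(ref.dyad_positions):
            for strand, pos in (
                ("top", ref.top_dyad_position(p)),
                ("bottom", ref.bottom_dyad_position(p)),
            ):
                observed, state = _state_from_base(bases.get(pos))
                calls.append(MethylationCall(pos, strand, "CpG", observed, state, d))
    if "nonCpG" in contexts:
        dyad_pos = {ref.top_dyad_position(p) for p in ref.dyad_positions} | {
            ref.bottom_dyad_position(p) for p in ref.dyad_positions
        }
        for pos, strand in ref.genomic_c_positions().items():
            if pos in dyad_pos:
                continue
            observed, state = _state_from_base(bases.get(pos))
            calls.append(MethylationCall(pos, strand, "nonCpG", observed, state))
    if "linker" in contexts:
        for pos, role in sorted(ref.control_composite_positions.items()):
            observed, state = _state_from_base(bases.get(pos))
            calls.append(MethylationCall(pos, "top", f"linker_{role}", observed, state))
    return calls


def extract_umi(aligned: AlignedRead, ref: HairpinReference) -> str | None:
    """Concatenated bases at the UMI slots, reference order; ``None`` when
    any slot is uncovered, deleted or ambiguous (N)."""
    out = []
    for pos in ref.umi_composite_positions:
        base = aligned.aligned_bases.get(pos)
        if base is None or base in (GAP, "N"):
            return None
        out.append(base)
    return "".join(out)
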