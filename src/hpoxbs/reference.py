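"""Hairpin amplicon references.

A hairpin bisulfite amplicon is a single covalently closed molecule: the
Watson ("top") arm of the locus, the synthetic hairpin linker, and the Crick
("bottom") arm read back in the opposite direction.  After bisulfite (or
oxidative bisulfite) treatment and PCR the molecule is sequenced as one
continuous strand, so a read reports both strands of every CpG dyad at once.

Coordinates are 0-based, half-open, in composite-reference space
(top arm, then linker, then the reversed bottom arm).  CpG dyads are indexed
by the offset of the top-strand cytosine.  The bottom arm is stored in Watson
coordinates: position ``i`` of ``bottom_seq`` is the Crick base paired with
position ``i`` of ``top_seq``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTDN", "TGCAHN")  # H unused; D handled separately

#: linker control roles -> the modification carried by that cytosine
CONTROL_ROLES = ("unmodC", "5mC", "5hmC")

_VALID_GENOMIC = set("ACGTN")
_VALID_LINKER = set("ACGTDN")


def complement(seq: str) -> str:
    """Base-wise complement (no reversal) of an ACGTN sequence."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class LinkerSpec:
    """Hairpin linker sequence with annotated control and UMI positions.

    ``seq`` is given 5'->3' in the orientation it appears in the sequenced
    molecule, over the alphabet ACGTD where ``D`` marks a degenerate UMI slot
    (A, T or G -- D excludes C so UMI bases are immune to bisulfite
    conversion).  ``controls`` maps linker-local offsets to one of
    ``unmodC`` / ``5mC`` / ``5hmC``; each such position must hold a C.
    """

    seq: str
    controls: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID_LINKER
        if bad:
            raise ValueError(f"linker contains invalid characters: {sorted(bad)}")
        for pos, role in self.controls.items():
            if role not in CONTROL_ROLES:
                raise ValueError(f"unknown control role {role!r} at linker position {pos}")
            if not 0 <= pos < len(self.seq):
                raise ValueError(f"control position {pos} outside linker")
            if self.seq[pos] != "C":
                raise ValueError(
                    f"control position {pos} must be a C (found {self.seq[pos]!r})"
                )

    @property
    def umi_positions(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.seq) if b == "D")


@dataclass(frozen=True)
class HairpinReference:
    """Composite reference for one hairpin amplicon.

    Attributes
    ----------
    top_seq : Watson arm, 5'->3'.
    bottom_seq : Crick arm in Watson coordinates (``bottom_seq[i]`` pairs
        ``top_seq[i]``); the composite stores ``reverse(bottom_seq)`` so the
        whole reference reads in sequencing orientation.
    linker : the hairpin linker specification.
    dyad_positions : top-strand offsets of the CpG dyads.
    repeat_class : ``single_copy`` or ``repetitive`` (sets the identity
        filter threshold downstream).
    """

    amplicon_id: str
    top_seq: str
    bottom_seq: str
    linker: LinkerSpec
    dyad_positions: tuple[int, ...]
    repeat_class: str = "single_copy"
    snp_positions: tuple[int, ...] = ()
    restriction_overhang: str = ""

    # -- layout ---------------------------------------------------------
    @property
    def arm_length(self) -> int:
        return len(self.top_seq)

    @property
    def linker_offset(self) -> int:
        return len(self.top_seq)

    @property
    def bottom_offset(self) -> int:
        return len(self.top_seq) + len(self.linker.seq)

    def __len__(self) -> int:
        return 2 * len(self.top_seq) + len(self.linker.seq)

    @property
    def n_dyads(self) -> int:
        return len(self.dyad_positions)

    # -- coordinate maps ------------------------------------------------
    def top_dyad_position(self, p: int) -> int:
        """Composite offset of the top-strand C of the dyad at top offset p."""
        return p

    def bottom_dyad_position(self, p: int) -> int:
        """Composite offset of the bottom-strand C of the dyad at top offset p.

        The Crick cytosine pairs the top-strand G at ``p + 1``; the bottom arm
        is reversed in the composite.
        """
        return self.bottom_offset + (self.arm_length - 1 - (p + 1))

    @property
    def umi_composite_positions(self) -> tuple[int, ...]:
        off = self.linker_offset
        return tuple(off + i for i in self.linker.umi_positions)

    @property
    def control_composite_positions(self) -> dict[int, str]:
        """Map composite offset -> control role for the linker controls."""
        off = self.linker_offset
        return {off + i: role for i, role in self.linker.controls.items()}

    def region_of(self, pos: int) -> str:
        if pos < self.linker_offset:
            return "top"
        if pos < self.bottom_offset:
            return "linker"
        return "bottom"

    # -- sequences ------------------------------------------------------
    def composite_seq(self) -> str:
        """Unconverted composite: top + linker + reverse(bottom)."""
        return self.top_seq + self.linker.seq + self.bottom_seq[::-1]

    def alignment_reference(self) -> str:
        """Composite used for bisulfite-aware alignment and calling.

        Linker cytosines are replaced by T except at control positions, which
        stay C so their C/T state can be called like a SNP.  Genomic arms are
        left unconverted: the asymmetric scoring treats read T opposite
        reference C as a match, so methylated and converted reads both align.
        """
        link = list(self.linker.seq)
        for i, b in enumerate(link):
            if b == "C" and i not in self.linker.controls:
                link[i] = "T"
        return self.top_seq + "".join(link) + self.bottom_seq[::-1]

    def genomic_c_positions(self) -> dict[int, str]:
        """Composite offsets of genomic (non-linker) cytosines -> strand.

        Covers both arms; the bottom arm's cytosines appear as C in the
        composite because the composite stores Crick bases directly.
        """
        out: dict[int, str] = {}
        for i, b in enumerate(self.top_seq):
            if b == "C":
                out[i] = "top"
        for j, b in enumerate(self.bottom_seq[::-1]):
            if b == "C":
                out[self.bottom_offset + j] = "bottom"
        return out

    # -- persistence ----------------------------------------------------
    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.fasta`` (composite) and ``<prefix>.annot.tsv``."""
        prefix = Path(prefix)
        fasta = prefix.with_suffix(".fasta")
        annot = prefix.with_suffix(".annot.tsv")
        with open(fasta, "w") as fh:
            fh.write(f">{self.amplicon_id}\n")
            seq = self.composite_seq()
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        with open(annot, "w") as fh:
            fh.write(f"# amplicon_id={self.amplicon_id}\n")
            fh.write(f"# top_len={self.arm_length}\n")
            fh.write(f"# linker_len={len(self.linker.seq)}\n")
            fh.write(f"# repeat_class={self.repeat_class}\n")
            fh.write(f"# restriction_overhang={self.restriction_overhang}\n")
            fh.write("position\trole\n")
            rows: list[tuple[int, str]] = []
            rows += [(p, "dyad") for p in self.dyad_positions]
            rows += [
                (self.linker_offset + i, role)
                for i, role in self.linker.controls.items()
            ]
            rows += [(p, "UMI") for p in self.umi_composite_positions]
            rows += [(p, "SNP") for p in self.snp_positions]
            for pos, role in sorted(rows):
                fh.write(f"{pos}\t{role}\n")
        return fasta, annot

    @classmethod
    def load(cls, fasta: str | Path, annot: str | Path) -> "HairpinReference":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(fasta), "fasta"))
        seq = str(record.seq).upper()
        meta: dict[str, str] = {}
        dyads: list[int] = []
        controls: dict[int, str] = {}
        snps: list[int] = []
        with open(annot) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                    continue
                if not line or line.startswith("position"):
                    continue
                pos_s, role = line.split("\t")
                pos = int(pos_s)
                if role == "dyad":
                    dyads.append(pos)
                elif role in CONTROL_ROLES:
                    controls[pos] = role
                elif role == "SNP":
                    snps.append(pos)
                # UMI positions are recovered from the D letters below
        top_len = int(meta["top_len"])
        linker_len = int(meta["linker_len"])
        top = seq[:top_len]
        linker_seq = seq[top_len : top_len + linker_len]
        bottom = seq[top_len + linker_len :][::-1]
        linker = LinkerSpec(
            seq=linker_seq,
            controls={p - top_len: r for p, r in controls.items()},
        )
        return cls(
            amplicon_id=meta.get("amplicon_id", record.id),
            top_seq=top,
            bottom_seq=bottom,
            linker=linker,
            dyad_positions=tuple(sorted(dyads)),
            repeat_class=meta.get("repeat_class", "single_copy"),
            snp_positions=tuple(sorted(snps)),
            restriction_overhang=meta.get("restriction_overhang", ""),
        )


def find_dyads(top_seq: str, bottom_seq: str) -> tuple[int, ...]:
    """Top offsets p where top has CpG and the bottom arm carries the
    complementary CpG (bottom in Watson coordinates: G at p, C at p+1)."""
    out = []
    for p in range(len(top_seq) - 1):
        if (
            top_seq[p : p + 2] == "CG"
            and bottom_seq[p] == "G"
            and bottom_seq[p + 1] == "C"
        ):
            out.append(p)
    return tuple(out)


def build_reference(
    top_seq: str,
    bottom_arm_seq: str | None,
    linker_spec: LinkerSpec,
    repeat_class: str = "single_copy",
    *,
    amplicon_id: str = "amplicon",
    snp_positions: tuple[int, ...] = (),
    restriction_overhang: str = "",
) -> HairpinReference:
    """Assemble and validate a composite hairpin reference.

    ``bottom_arm_seq`` is the Crick arm in Watson coordinates; pass ``None``
    to derive it as the complement of the top arm.  Arms must be
    complementary except at declared SNP positions.  A CpG inside the
    restriction overhang triggers a warning (the cut site would be
    methylation-sensitive).
    """
    top_seq = top_seq.upper()
    if bottom_arm_seq is None:
        bottom_arm_seq = complement(top_seq)
    bottom_arm_seq = bottom_arm_seq.upper()

    if len(top_seq) != len(bottom_arm_seq):
        raise ValueError(
            f"arm length mismatch: top {len(top_seq)} vs bottom {len(bottom_arm_seq)}"
        )
    for seq, name in ((top_seq, "top"), (bottom_arm_seq, "bottom")):
        bad = set(seq) - _VALID_GENOMIC
        if bad:
            raise ValueError(f"{name} arm contains invalid characters: {sorted(bad)}")
    mismatches = [
        i
        for i in range(len(top_seq))
        if i not in snp_positions
        and "N" not in (top_seq[i], bottom_arm_seq[i])
        and bottom_arm_seq[i] != complement(top_seq[i])
    ]
    if mismatches:
        raise ValueError(
            "arms are not complementary at positions "
            f"{mismatches[:10]}{'...' if len(mismatches) > 10 else ''}; "
            "declare SNP positions or fix the sequences"
        )
    if repeat_class not in ("single_copy", "repetitive"):
        raise ValueError(f"unknown repeat_class {repeat_class!r}")
    if "CG" in restriction_overhang.upper():
        warnings.warn(
            "restriction overhang contains a CpG; the cut may be blocked or "
            "biased by methylation at that site",
            stacklevel=2,
        )
    dyads = find_dyads(top_seq, bottom_arm_seq)
    return HairpinReference(
        amplicon_id=amplicon_id,
        top_seq=top_seq,
        bottom_seq=bottom_arm_seq,
        linker=linker_spec,
        dyad_positions=dyads,
        repeat_class=repeat_class,
        snp_positions=tuple(snp_positions),
        restriction_overhang=restriction_overhang.upper(),
    )
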