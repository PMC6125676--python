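"""Published reference values and default study conditions.

The conversion-rate tables below are the linker-control measurements reported
for the eight mouse amplicons of the ESC demethylation panel (three single
copy loci and five retrotransposon families), one table per treatment.  Each
value is the probability that the named control cytosine is read as T after
the treatment: for the unmodified C control this is the intended conversion,
for the 5mC and 5hmC controls under BS it is an unwanted error, and for the
5hmC control under oxBS it is again the intended conversion.
"""

from __future__ import annotations

import numpy as np

from .reference import HairpinReference, LinkerSpec, build_reference

AMPLICONS = ("Afp", "IAP", "L1mdA", "L1mdT", "mSat", "MuERVL", "Ttc25", "Zim3")

#: measured read-T probability per control, BS treatment, by amplicon
BS_CONVERSION_RATES = {
    "C": dict(zip(AMPLICONS, (0.996, 0.999, 0.995, 0.993, 0.996, 0.993, 0.994, 0.995))),
    "5mC": dict(zip(AMPLICONS, (0.0674, 0.0628, 0.084, 0.088, 0.0685, 0.0819, 0.0813, 0.0763))),
    "5hmC": dict(zip(AMPLICONS, (0.0765, 0.0721, 0.0736, 0.0703, 0.0642, 0.0662, 0.0785, 0.0696))),
}

#: measured read-T probability per control, oxBS treatment, by amplicon
OXBS_CONVERSION_RATES = {
    "C": dict(zip(AMPLICONS, (0.996, 0.999, 0.996, 0.994, 0.997, 0.997, 0.996, 0.996))),
    "5mC": dict(zip(AMPLICONS, (0.0636, 0.0900, 0.0795, 0.0758, 0.0685, 0.0808, 0.1078, 0.0773))),
    "5hmC": dict(zip(AMPLICONS, (0.920, 0.9095, 0.909, 0.9323, 0.93693, 0.922, 0.942, 0.9315))),
}

#: observation days and cumulative cell divisions (mouse ESC cycle ~12 h:
#: day0 -> 0, day1 -> 2, day3 -> 6, day6 -> 12 divisions)
DEFAULT_SCHEDULE_DAYS = (0, 1, 3, 6)
DEFAULT_SCHEDULE_DIVISIONS = (0, 2, 6, 12)

#: serum/LIF-like initial dyad-state distribution used by the simulator:
#: heavily methylated, mostly symmetric, with a small hydroxylated fraction.
#: Order: uu, um, mu, mm, uh, hu, mh, hm, hh.
DEFAULT_INIT_DISTRIBUTION = np.array(
    [0.15, 0.03, 0.03, 0.72, 0.01, 0.01, 0.02, 0.02, 0.01]
)


def default_linker(umi_length: int = 5) -> LinkerSpec:
    """A hairpin linker carrying one unmodified-C, one 5mC and one 5hmC
    control plus a degenerate (D = A/T/G) UMI loop.

    Layout: stem with the unmodified control / 5mC control / UMI loop /
    5hmC control / stem.  Control positions are chosen outside CpG context.
    """
    left = "GCGATCATCA"  # C controls below are placed explicitly
    #            unmodC at index 10, 5mC at 14
    core = "C" + "TAG" + "C" + "AT"
    umi = "D" * umi_length
    #            5hmC control 2 bases after the UMI loop
    right = "TA" + "C" + "AGATTGGC"
    seq = left + core + umi + right
    controls = {
        len(left): "unmodC",
        len(left) + 4: "5mC",
        len(left) + len(core) + umi_length + 2: "5hmC",
    }
    return LinkerSpec(seq=seq, controls=controls)


def demo_reference(
    arm_length: int = 48, umi_length: int = 5, amplicon_id: str = "demo"
) -> HairpinReference:
    """A small single-copy amplicon with four CpG dyads for demos and tests."""
    top = (
        "ATTGGACGTTAGGATCACGTTAGATTGACGATTAGGATTACGTTAGGA"
    )
    assert len(top) == 48
    top = top[:arm_length]
    return build_reference(
        top,
        None,
        default_linker(umi_length),
        "single_copy",
        amplicon_id=amplicon_id,
        restriction_overhang="TA",
    )


def mean_oxbs_5hmc_rate() -> float:
    """Panel-mean oxBS 5hmC conversion probability (the headline ~93%)."""
    return float(np.mean(list(OXBS_CONVERSION_RATES["5hmC"].values())))
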