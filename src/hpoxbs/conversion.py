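"""Linker-control conversion rates and the treatment emission model.

The hairpin linker carries cytosines of known modification state (unmodified
C, 5mC, 5hmC).  For each treatment the conversion rate of a control is the
fraction of reads showing T at that position:

    conversion rate = (number of T at the C position) / (reads at the C position)

All three rates are oriented in the T-direction (probability of reading T),
so whether a given rate is an intended conversion or an error depends only
on which base the chemistry should produce: BS should convert C fully and
leave 5mC/5hmC untouched; oxBS should additionally convert 5hmC.  The six
measured rates become the emission parameters of the observation model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import MethylationCall

TREATMENTS = ("BS", "oxBS")
CONTROLS = ("unmodC", "5mC", "5hmC")

#: controls with fewer observations than this fall back to pooled rates
DEFAULT_MIN_CONTROL_COVERAGE = 200


def conversion_rate(n_t: int, n_total: int) -> float:
    """Exact T fraction at a control cytosine; undefined at zero coverage."""
    if not 0 <= n_t <= n_total:
        raise ValueError(f"invalid counts: n_t={n_t}, n_total={n_total}")
    if n_total == 0:
        raise ValueError("conversion rate undefined at zero coverage")
    return n_t / n_total


@dataclass(frozen=True)
class ConversionRates:
    """Measured per-treatment conversion of the three linker controls."""

    treatment: str
    counts: dict[str, tuple[int, int]]  # control -> (n_T, n_total)
    amplicon_id: str | None = None

    def rate(self, control: str) -> float | None:
        n_t, n_total = self.counts.get(control, (0, 0))
        if n_total == 0:
            return None
        return conversion_rate(n_t, n_total)

    @property
    def rate_c(self) -> float | None:
        return self.rate("unmodC")

    @property
    def rate_5mc(self) -> float | None:
        return self.rate("5mC")

    @property
    def rate_5hmc(self) -> float | None:
        return self.rate("5hmC")


@dataclass(frozen=True)
class EmissionParameters:
    """Read-T probabilities per true base for one treatment."""

    p_t_given_c: float
    p_t_given_5mc: float
    p_t_given_5hmc: float

    def __post_init__(self) -> None:
        for name, v in (
            ("p_t_given_c", self.p_t_given_c),
            ("p_t_given_5mc", self.p_t_given_5mc),
            ("p_t_given_5hmc", self.p_t_given_5hmc),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def p_t(self, true_base: str) -> float:
        return {"u": self.p_t_given_c, "m": self.p_t_given_5mc, "h": self.p_t_given_5hmc}[
            true_base
        ]


#: error-free chemistry: BS converts only C; oxBS converts C and 5hmC
IDEAL_BS = EmissionParameters(1.0, 0.0, 0.0)
IDEAL_OXBS = EmissionParameters(1.0, 0.0, 1.0)


def linker_control_rates(
    calls: list[MethylationCall],
    treatment: str,
    amplicon_id: str | None = None,
) -> ConversionRates:
    """Tally T/total at the linker control positions.

    Expects calls from reads passing the relaxed (0.6) linker identity
    filter; non-C/T observations are not informative and are excluded from
    the denominator.
    """
    counts = {c: [0, 0] for c in CONTROLS}
    for call in calls:
        if not call.context.startswith("linker_"):
            continue
        control = call.context.removeprefix("linker_")
        if call.observed not in ("C", "T"):
            continue
        counts[control][1] += 1
        if call.observed == "T":
            counts[control][0] += 1
    return ConversionRates(
        treatment=treatment,
        counts={c: (n_t, n) for c, (n_t, n) in counts.items()},
        amplicon_id=amplicon_id,
    )


def pool_rates(per_amplicon: list[ConversionRates]) -> ConversionRates:
    """Sum control counts across amplicons of one treatment."""
    if not per_amplicon:
        raise ValueError("nothing to pool")
    treatments = {r.treatment for r in per_amplicon}
    if len(treatments) != 1:
        raise ValueError(f"cannot pool across treatments: {sorted(treatments)}")
    counts = {}
    for c in CONTROLS:
        counts[c] = (
            sum(r.counts.get(c, (0, 0))[0] for r in per_amplicon),
            sum(r.counts.get(c, (0, 0))[1] for r in per_amplicon),
        )
    return ConversionRates(treatment=per_amplicon[0].treatment, counts=counts)


def effective_rates(
    own: ConversionRates,
    pooled: ConversionRates | None = None,
    min_coverage: int = DEFAULT_MIN_CONTROL_COVERAGE,
) -> dict[str, float]:
    """Per-amplicon rates where coverage allows, pooled fallback otherwise.

    Raises ValueError if a control is unmeasured in both sources.
    """
    out: dict[str, float] = {}
    for c in CONTROLS:
        n = own.counts.get(c, (0, 0))[1]
        if n >= min_coverage or (pooled is None and n > 0):
            out[c] = own.rate(c)  # type: ignore[assignment]
        elif pooled is not None and pooled.counts.get(c, (0, 0))[1] > 0:
            out[c] = pooled.rate(c)  # type: ignore[assignment]
        else:
            raise ValueError(
                f"control {c!r} has no usable coverage (own n={n}, no pooled fallback)"
            )
    return out


def derive_emission_parameters(
    bs_rates: ConversionRates | dict[str, float],
    oxbs_rates: ConversionRates | dict[str, float],
) -> dict[str, EmissionParameters]:
    """Turn measured control rates into the two treatment emission channels."""

    def as_params(rates) -> EmissionParameters:
        if isinstance(rates, ConversionRates):
            vals = {c: rates.rate(c) for c in CONTROLS}
            missing = [c for c, v in vals.items() if v is None]
            if missing:
                raise ValueError(f"controls without coverage: {missing}")
            rates = vals
        return EmissionParameters(rates["unmodC"], rates["5mC"], rates["5hmC"])

    return {"BS": as_params(bs_rates), "oxBS": as_params(oxbs_rates)}


def qc_report(
    per_amplicon: dict[str, ConversionRates], treatment: str
) -> pd.DataFrame:
    """Rate table, rows C / 5mC / 5hmC, one column per amplicon."""
    row_labels = {"unmodC": "C", "5mC": "5mC", "5hmC": "5hmC"}
    data = {}
    for amp, rates in per_amplicon.items():
        if rates.treatment != treatment:
            raise ValueError(f"{amp}: treatment {rates.treatment} != {treatment}")
        data[amp] = [rates.rate(c) for c in CONTROLS]
    return pd.DataFrame(data, index=[row_labels[c] for c in CONTROLS])


def write_qc_report(
    per_amplicon: dict[str, ConversionRates], treatment: str, path: str | Path
) -> Path:
    path = Path(path)
    qc_report(per_amplicon, treatment).to_csv(path, sep="\t", float_format="%.6g")
    return path
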