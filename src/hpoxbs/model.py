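"""Replication-driven dyad-state model and likelihood-based estimation.

A CpG dyad occupies one of nine hidden states, the ordered pairs over
{u, m, h} (u = unmodified C, m = 5mC, h = 5hmC) for the top and bottom
strand.  Each cell division applies, in order:

1. replication — one strand is retained uniformly at random, the new
   strand starts fully unmodified;
2. maintenance — a new-strand position opposite an m template becomes m
   with probability mu (Dnmt1 recognises hemimethylated CpGs with a 5mC
   template; an h template confers no maintenance);
3. de novo — every strand still u becomes m with probability delta,
   independently per strand (Dnmt3a/b);
4. hydroxylation — every m strand becomes h with probability eta (Tet).

The composition is a 9x9 row-stochastic matrix applied to the population
state distribution.  Two treatment-specific observation channels (BS and
oxBS) map hidden states to the four read classes CC/CT/TC/TT via measured
per-base read-T probabilities; both channels share the hidden chain and the
joint multinomial likelihood is maximised over per-interval (or constant)
efficiencies and the initial distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .conversion import EmissionParameters

#: hidden-state alphabet, fixed enumeration order
STATES = ("uu", "um", "mu", "mm", "uh", "hu", "mh", "hm", "hh")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_LETTERS = "umh"

#: observed read classes: first letter = top-strand base at the dyad
READ_CLASSES = ("CC", "CT", "TC", "TT")

#: the (top, bottom) letter pair of each state
STATE_PAIRS = tuple((s[0], s[1]) for s in STATES)

_BOUNDARY_EPS = 1e-3


@dataclass(frozen=True)
class EnzymeEfficiencies:
    """Per-division event probabilities.

    mu : maintenance methylation at a hemimethylated dyad with an m template
    delta : de novo methylation per unmethylated strand
    eta : hydroxylation per methylated strand
    """

    mu: float
    delta: float
    eta: float

    def __post_init__(self) -> None:
        for name, v in (("mu", self.mu), ("delta", self.delta), ("eta", self.eta)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def total_hemi_activity(self) -> float:
        """Combined methylation probability on a hemimethylated substrate:
        maintenance, or de novo where maintenance failed."""
        return self.mu + (1.0 - self.mu) * self.delta

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.delta, self.eta])


@dataclass(frozen=True)
class DivisionSchedule:
    """Observation times (days) and cumulative divisions elapsed by each."""

    days: tuple[float, ...]
    divisions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.divisions):
            raise ValueError("days and divisions must have equal length")
        if any(int(d) != d or d < 0 for d in self.divisions):
            raise ValueError("divisions must be nonnegative integers")
        if any(b < a for a, b in zip(self.divisions, self.divisions[1:])):
            raise ValueError("cumulative divisions must be nondecreasing")

    @property
    def n_times(self) -> int:
        return len(self.days)

    @property
    def n_intervals(self) -> int:
        return max(0, len(self.days) - 1)

    @property
    def interval_divisions(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.divisions, self.divisions[1:]))


def _check_distribution(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (9,):
        raise ValueError(f"state distribution must have 9 entries, got {dist.shape}")
    if np.any(dist < -1e-9) or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("state distribution must be nonnegative and sum to 1")
    return dist


def _old_strand_channel(letter: str, delta: float, eta: float) -> np.ndarray:
    """Post-division marginal of a template (old) strand over (u, m, h)."""
    if letter == "u":
        return np.array([(1 - delta), delta * (1 - eta), delta * eta])
    if letter == "m":
        return np.array([0.0, 1 - eta, eta])
    return np.array([0.0, 0.0, 1.0])  # h is terminal in this model


def _new_strand_channel(template: str, mu: float, delta: float, eta: float) -> np.ndarray:
    """Post-division marginal of the newly synthesised strand over (u, m, h).

    Maintenance applies only against an m template; a strand left u after
    maintenance is still a de novo substrate.
    """
    q = mu + (1 - mu) * delta if template == "m" else delta
    return np.array([1 - q, q * (1 - eta), q * eta])


def transition_matrix(eff: EnzymeEfficiencies) -> np.ndarray:
    """9x9 row-stochastic one-division transition matrix."""
    mu, delta, eta = eff.mu, eff.delta, eff.eta
    old = {x: _old_strand_channel(x, delta, eta) for x in _LETTERS}
    new = {x: _new_strand_channel(x, mu, delta, eta) for x in _LETTERS}
    T = np.zeros((9, 9))
    for i, (a, b) in enumerate(STATE_PAIRS):
        # retained strand chosen uniformly: top template (prob 1/2) keeps a,
        # bottom template keeps b; the complementary strand is resynthesised
        top_kept = 0.5 * np.outer(old[a], new[a])  # rows: top', cols: bottom'
        bottom_kept = 0.5 * np.outer(new[b], old[b])
        joint = top_kept + bottom_kept
        for j, (ta, tb) in enumerate(STATE_PAIRS):
            T[i, j] = joint[_LETTERS.index(ta), _LETTERS.index(tb)]
    return T


def division_step(dist: np.ndarray, eff: EnzymeEfficiencies) -> np.ndarray:
    """Propagate a population state distribution through one division."""
    return _check_distribution(dist) @ transition_matrix(eff)


def emission_matrix(params: EmissionParameters) -> np.ndarray:
    """9x4 row-stochastic matrix over CC/CT/TC/TT for one treatment.

    Strands are read independently: P(T | strand) depends only on the true
    base (u/m/h) through the measured conversion probabilities.
    """
    E = np.zeros((9, 4))
    for i, (a, b) in enumerate(STATE_PAIRS):
        pt_top, pt_bot = params.p_t(a), params.p_t(b)
        E[i] = [
            (1 - pt_top) * (1 - pt_bot),
            (1 - pt_top) * pt_bot,
            pt_top * (1 - pt_bot),
            pt_top * pt_bot,
        ]
    return E


@dataclass
class CountData:
    """Observed read-class counts per time point and treatment.

    ``counts[treatment]`` is an (n_times, 4) integer array over
    CC/CT/TC/TT, aggregated over dyads (the default fitting granularity)
    or restricted to one dyad.
    """

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = set()
        for tr, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[1] != 4 or np.any(arr < 0):
                raise ValueError(f"{tr}: counts must be a nonnegative (n_times, 4) array")
            self.counts[tr] = arr
            shapes.add(arr.shape[0])
        if len(shapes) != 1:
            raise ValueError("treatments disagree on the number of time points")

    @property
    def n_times(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    def to_tsv(self, path: str | Path, days: tuple[float, ...] | None = None) -> Path:
        rows = []
        for tr, arr in self.counts.items():
            for t in range(arr.shape[0]):
                row = {"time": days[t] if days is not None else t, "treatment": tr}
                row.update(dict(zip(READ_CLASSES, arr[t].tolist())))
                rows.append(row)
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> tuple["CountData", tuple[float, ...]]:
        df = pd.read_csv(path, sep="\t")
        days = tuple(sorted(df["time"].unique()))
        counts = {}
        for tr, sub in df.groupby("treatment"):
            sub = sub.set_index("time").reindex(days)
            counts[str(tr)] = sub[list(READ_CLASSES)].to_numpy(dtype=int)
        return cls(counts=counts), days


def observed_counts_from_patterns(patterns) -> np.ndarray:
    """Aggregate dyad classes of refolded molecules into CC/CT/TC/TT counts.

    A modified strand reads C, an unmodified strand reads T; unknown dyads
    are dropped.
    """
    from .refold import BOTH, HEMI_BOTTOM, HEMI_TOP, UNMOD

    mapping = {BOTH: 0, HEMI_TOP: 1, HEMI_BOTTOM: 2, UNMOD: 3}
    out = np.zeros(4, dtype=int)
    for p in patterns:
        for c in p.classes:
            if c in mapping:
                out[mapping[c]] += 1
    return out


def _propagate(
    efficiencies: np.ndarray, init: np.ndarray, schedule: DivisionSchedule
) -> np.ndarray:
    """Distributions at every observation time; efficiencies is (n_intervals, 3)."""
    dists = np.empty((schedule.n_times, 9))
    dists[0] = init
    d = init
    for i, k in enumerate(schedule.interval_divisions):
        T = transition_matrix(EnzymeEfficiencies(*efficiencies[i]))
        d = d @ np.linalg.matrix_power(T, k)
        dists[i + 1] = d
    return dists


def _broadcast_efficiencies(
    efficiencies, n_intervals: int
) -> np.ndarray:
    if isinstance(efficiencies, EnzymeEfficiencies):
        arr = np.tile(efficiencies.as_array(), (n_intervals, 1))
    else:
        arr = np.atleast_2d(np.asarray(efficiencies, dtype=float))
        if arr.shape == (1, 3) and n_intervals > 1:
            arr = np.tile(arr, (n_intervals, 1))
    if arr.shape != (n_intervals, 3):
        raise ValueError(f"expected ({n_intervals}, 3) efficiencies, got {arr.shape}")
    return arr


def log_likelihood(
    efficiencies,
    init: np.ndarray,
    schedule: DivisionSchedule,
    emissions: dict[str, EmissionParameters],
    counts: CountData,
) -> float:
    """Joint multinomial log-likelihood of both treatment channels.

    The BS and oxBS aliquots sample the same hidden population, so the
    distribution at each observation time is shared and the treatment
    likelihoods add.  A read class with zero model probability but nonzero
    count yields -inf (reported, not raised).
    """
    if counts.n_times != schedule.n_times:
        raise ValueError("counts and schedule disagree on the number of time points")
    init = _check_distribution(init)
    eff = _broadcast_efficiencies(efficiencies, schedule.n_intervals)
    dists = _propagate(eff, init, schedule)
    E = {tr: emission_matrix(emissions[tr]) for tr in counts.counts}
    ll = 0.0
    for tr, arr in counts.counts.items():
        probs = dists @ E[tr]  # (n_times, 4)
        mask = arr > 0
        if np.any(probs[mask] <= 0.0):
            return float("-inf")
        ll += float(np.sum(arr[mask] * np.log(probs[mask])))
    return ll


@dataclass
class FitResult:
    """Maximum-likelihood fit of efficiencies and state distributions."""

    efficiencies: np.ndarray  # (n_intervals, 3) columns mu, delta, eta; empty if none
    mode: str  # per_interval | constant | init_only
    initial_distribution: np.ndarray  # (9,)
    fitted_distributions: np.ndarray  # (n_times, 9)
    log_likelihood: float
    schedule: DivisionSchedule
    n_starts: int
    start_logliks: list[float]
    converged: bool
    boundary_flags: list[str] = field(default_factory=list)
    bootstrap_intervals: dict[str, tuple[float, float]] | None = None
    seed: int | None = None

    def efficiency(self, interval: int = 0) -> EnzymeEfficiencies:
        return EnzymeEfficiencies(*self.efficiencies[interval])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "states": list(STATES),
            "efficiency_columns": ["mu", "delta", "eta"],
            "efficiencies": self.efficiencies.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "fitted_distributions": self.fitted_distributions.tolist(),
            "log_likelihood": self.log_likelihood,
            "schedule": {"days": list(self.schedule.days), "divisions": list(self.schedule.divisions)},
            "n_starts": self.n_starts,
            "converged": self.converged,
            "boundary_flags": self.boundary_flags,
            "bootstrap_intervals": self.bootstrap_intervals,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _softmax9(z8: np.ndarray) -> np.ndarray:
    z = np.concatenate([z8, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _pack_init(dist: np.ndarray) -> np.ndarray:
    p = np.clip(dist, 1e-9, None)
    return np.log(p[:8] / p[8])


def fit(
    counts: CountData,
    schedule: DivisionSchedule,
    emissions: dict[str, EmissionParameters],
    *,
    mode: str = "per_interval",
    n_starts: int = 20,
    seed: int = 0,
    initial_distribution: np.ndarray | None = None,
    n_bootstrap: int = 0,
    tol: float = 1e-8,
    _z0: np.ndarray | None = None,
) -> FitResult:
    """Maximise the joint BS/oxBS likelihood.

    Efficiencies are piecewise-constant per inter-observation interval
    (``mode='per_interval'``) or shared across intervals
    (``mode='constant'``); with a single observation time only the initial
    distribution is estimated.  Efficiencies are logit-parameterised and the
    initial distribution lives on the 8-parameter softmax simplex; the
    optimiser is L-BFGS-B with seeded multi-starts.  Pass
    ``initial_distribution`` to hold the starting distribution fixed.
    Optional ``n_bootstrap`` multinomial resamples give percentile
    intervals for the efficiencies.
    """
    rng = np.random.default_rng(seed)
    n_int = schedule.n_intervals
    if n_int == 0:
        mode = "init_only"
    if mode not in ("per_interval", "constant", "init_only"):
        raise ValueError(f"unknown fitting mode {mode!r}")
    n_eff_blocks = {"per_interval": n_int, "constant": 1, "init_only": 0}[mode]
    fit_init = initial_distribution is None
    fixed_init = None if fit_init else _check_distribution(initial_distribution)

    def unpack(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eff_block = expit(z[: 3 * n_eff_blocks]).reshape(n_eff_blocks, 3)
        if mode == "constant" and n_int > 1:
            eff = np.tile(eff_block, (n_int, 1))
        else:
            eff = eff_block
        init = _softmax9(z[3 * n_eff_blocks :]) if fit_init else fixed_init
        return eff, init

    def objective(z: np.ndarray) -> float:
        eff, init = unpack(z)
        if n_int == 0:
            dists = init[None, :]
            ll = 0.0
            for tr, arr in counts.counts.items():
                probs = dists @ emission_matrix(emissions[tr])
                mask = arr > 0
                if np.any(probs[mask] <= 0):
                    return 1e12
                ll += float(np.sum(arr[mask] * np.log(probs[mask])))
        else:
            ll = log_likelihood(eff, init, schedule, emissions, counts)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    n_params = 3 * n_eff_blocks + (8 if fit_init else 0)
    if n_params == 0:
        raise ValueError("nothing to fit: no intervals and a fixed initial distribution")

    starts = [np.zeros(n_params) if _z0 is None else np.asarray(_z0, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        z = np.empty(n_params)
        z[: 3 * n_eff_blocks] = rng.normal(0.0, 2.0, size=3 * n_eff_blocks)
        if fit_init:
            z[3 * n_eff_blocks :] = rng.normal(0.0, 1.5, size=8)
        starts.append(z)

    results = []
    for z0 in starts:
        res = minimize(objective, z0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 2000})
        results.append(res)
    logliks = [-r.fun for r in results]
    best = results[int(np.argmax(logliks))]
    eff, init = unpack(best.x)
    dists = _propagate(eff, init, schedule) if n_int else init[None, :]

    flags = []
    for i in range(eff.shape[0]):
        for j, name in enumerate(("mu", "delta", "eta")):
            if eff[i, j] < _BOUNDARY_EPS or eff[i, j] > 1 - _BOUNDARY_EPS:
                flags.append(f"{name}[{i}]={eff[i, j]:.4g} at boundary")
    converged = bool(best.success) or np.isfinite(best.fun)
    if not any(np.isfinite(ll) for ll in logliks):
        raise RuntimeError(f"no start converged to a finite likelihood: {results[0].message}")

    boot_iv = None
    if n_bootstrap > 0 and n_eff_blocks > 0:
        boot = _bootstrap_efficiencies(
            counts, schedule, emissions, mode, n_bootstrap, rng, best.x, n_eff_blocks, fit_init, fixed_init, tol
        )
        boot_iv = boot

    return FitResult(
        efficiencies=eff if n_int else np.empty((0, 3)),
        mode=mode,
        initial_distribution=init,
        fitted_distributions=dists,
        log_likelihood=float(-best.fun),
        schedule=schedule,
        n_starts=len(starts),
        start_logliks=[float(v) for v in logliks],
        converged=converged,
        boundary_flags=flags,
        bootstrap_intervals=boot_iv,
        seed=seed,
    )


def _bootstrap_efficiencies(
    counts, schedule, emissions, mode, n_bootstrap, rng, z_best, n_eff_blocks, fit_init, fixed_init, tol
):
    """Percentile 90% intervals from multinomial resamples, warm-started at
    the point estimate."""
    samples = []
    for _ in range(n_bootstrap):
        resampled = {}
        for tr, arr in counts.counts.items():
            new = np.empty_like(arr)
            for t in range(arr.shape[0]):
                n = int(arr[t].sum())
                p = arr[t] / n if n else np.full(4, 0.25)
                new[t] = rng.multinomial(n, p)
            resampled[tr] = new
        sub = fit(
            CountData(counts=resampled),
            schedule,
            emissions,
            mode=mode,
            n_starts=1,
            seed=int(rng.integers(2**31 - 1)),
            initial_distribution=None if fit_init else fixed_init,
            tol=tol,
            _z0=z_best,  # warm start at the point estimate
        )
        samples.append(sub.efficiencies[0] if mode == "constant" else sub.efficiencies.ravel())
    samples = np.array(samples)
    names = ["mu", "delta", "eta"]
    out = {}
    for j in range(samples.shape[1]):
        name = names[j % 3] + (f"[{j // 3}]" if samples.shape[1] > 3 else "")
        lo, hi = np.percentile(samples[:, j], [5, 95])
        out[name] = (float(lo), float(hi))
    return out


def hydroxylation_summary(dist_or_fit, t: int | None = None) -> dict[str, float]:
    """Aggregate a state distribution into 5hmC pairing classes.

    Returns the probabilities of h paired with u (uh + hu), with m
    (mh + hm) and symmetric h (hh), the per-strand resolved variants, and
    the strand-level total 5hmC (fraction of strands carrying h).
    """
    if isinstance(dist_or_fit, FitResult):
        dist = dist_or_fit.fitted_distributions[t if t is not None else -1]
    else:
        dist = _check_distribution(dist_or_fit)
    p = {s: dist[i] for i, s in enumerate(STATES)}
    return {
        "h_with_u": p["uh"] + p["hu"],
        "h_with_m": p["mh"] + p["hm"],
        "h_symmetric": p["hh"],
        "top_strand_h": p["hu"] + p["hm"] + p["hh"],
        "bottom_strand_h": p["uh"] + p["mh"] + p["hh"],
        "total_5hmc_per_strand": (p["uh"] + p["hu"] + p["mh"] + p["hm"] + 2 * p["hh"]) / 2,
    }


def strand_levels(dist: np.ndarray) -> dict[str, float]:
    """Strand-level 5mC and 5hmC fractions of a state distribution."""
    dist = _check_distribution(dist)
    m = h = 0.0
    for i, (a, b) in enumerate(STATE_PAIRS):
        m += dist[i] * ((a == "m") + (b == "m")) / 2
        h += dist[i] * ((a == "h") + (b == "h")) / 2
    return {"5mC": m, "5hmC": h}


def naive_5hmc(bs_summary, oxbs_summary) -> dict[str, float]:
    """Subtraction estimator of 5hmC from BS and oxBS pattern summaries.

    Total 5hmC = mean modification level(BS) - mean modification level(oxBS);
    the same subtraction per dyad class (both / hemi top / hemi bottom)
    approximates the 5hmC pairing distribution.  Negative values are
    reported as-is with a warning -- they arise from sampling different
    cells in the two aliquots and from conversion errors, which is exactly
    the bias the model-based estimator corrects.
    """
    from .refold import BOTH, HEMI_BOTTOM, HEMI_TOP

    if len(bs_summary.class_freq) != len(oxbs_summary.class_freq):
        raise ValueError("BS and oxBS summaries cover different dyad sets")
    out = {
        "total_5hmc": bs_summary.mean_modification_level
        - oxbs_summary.mean_modification_level
    }
    for cls in (BOTH, HEMI_TOP, HEMI_BOTTOM):
        out[cls] = bs_summary.mean_class_freq[cls] - oxbs_summary.mean_class_freq[cls]
    negative = [k for k, v in out.items() if v < 0]
    if negative:
        warnings.warn(
            f"naive subtraction produced negative 5hmC estimates for {negative} "
            "(sampling noise and conversion errors); values reported unclipped",
            stacklevel=2,
        )
    return out
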