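"""Piecewise-stationary symmetric n-island demographies.

A demography is a symmetric island model with ``n`` demes whose common
migration rate (and, in the general model, relative deme size) is constant
within each of ``c = gamma + 1`` time components delimited by ``gamma``
event times.  Times are expressed in units of ``2N`` generations; migration
rates are the total rate ``M`` received by one island; deme sizes are
relative to the reference deme size ``N``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
import numpy as np

__all__ = [
    "IslandDemography",
    "ScaledDemography",
    "Bounds",
    "ValueSets",
    "validate_demography",
    "sample_continuous",
    "sample_discrete",
    "read_scenario_json",
    "write_scenario_json",
]


@dataclass(frozen=True)
class IslandDemography:
    """One piecewise-stationary symmetric n-island history.

    Parameters
    ----------
    n : int
        Number of islands (demes), at least 2.
    event_times : tuple of float
        The ``gamma`` times of demographic events, in units of 2N
        generations, expected strictly increasing and positive.
    migration_rates : tuple of float
        ``gamma + 1`` values, the total migration rate received by one
        island within each component.
    deme_sizes : tuple of float
        ``gamma + 1`` relative deme sizes; defaults to all ones.
    """

    n: int
    event_times: tuple = ()
    migration_rates: tuple = (1.0,)
    deme_sizes: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "event_times", tuple(float(t) for t in self.event_times))
        object.__setattr__(
            self, "migration_rates", tuple(float(m) for m in self.migration_rates)
        )
        sizes = self.deme_sizes
        if sizes is None:
            sizes = (1.0,) * len(self.migration_rates)
        object.__setattr__(self, "deme_sizes", tuple(float(s) for s in sizes))
        if len(self.migration_rates) != len(self.event_times) + 1:
            raise ValueError(
                f"need gamma+1={len(self.event_times) + 1} migration rates, "
                f"got {len(self.migration_rates)}"
            )
        if len(self.deme_sizes) != len(self.migration_rates):
            raise ValueError("deme_sizes and migration_rates must have equal length")

    @property
    def gamma(self) -> int:
        """Number of demographic events."""
        return len(self.event_times)

    @property
    def n_components(self) -> int:
        """Number of components c = gamma + 1."""
        return self.gamma + 1


@dataclass(frozen=True)
class ScaledDemography:
    """An :class:`IslandDemography` plus a reference deme size ``N``.

    ``N`` is the number of haploid genes corresponding to a relative deme
    size of 1; it converts model time (2N generations) into generations and
    dimensionless IICR values into effective sizes.
    """

    N: float
    base: IslandDemography

    def __post_init__(self):
        if not self.N > 0:
            raise ValueError("reference size N must be positive")


def _interval(pair) -> tuple:
    lo, hi = float(pair[0]), float(pair[1])
    if lo > hi:
        raise ValueError(f"invalid interval [{lo}, {hi}]")
    return (lo, hi)


@dataclass(frozen=True)
class Bounds:
    """Closed per-parameter intervals delimiting a parameter space.

    ``t_ranges``, ``m_ranges`` and ``s_ranges`` are per-index intervals
    (``gamma`` of them for times, ``gamma + 1`` for rates and sizes).
    Setting every ``s_range`` to ``(1, 1)`` fixes deme sizes, which reduces
    the free parameters to ``2 * gamma + 2``.
    """

    n_range: tuple
    t_ranges: tuple
    m_ranges: tuple
    s_ranges: tuple
    N_range: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "n_range", _interval(self.n_range))
        object.__setattr__(self, "t_ranges", tuple(_interval(p) for p in self.t_ranges))
        object.__setattr__(self, "m_ranges", tuple(_interval(p) for p in self.m_ranges))
        object.__setattr__(self, "s_ranges", tuple(_interval(p) for p in self.s_ranges))
        if self.N_range is not None:
            object.__setattr__(self, "N_range", _interval(self.N_range))
        if self.n_range[0] < 2:
            raise ValueError("n_min must be at least 2")
        if len(self.m_ranges) != len(self.t_ranges) + 1:
            raise ValueError("need gamma+1 M ranges for gamma t ranges")
        if len(self.s_ranges) != len(self.m_ranges):
            raise ValueError("need as many s ranges as M ranges")
        for name, ranges in (("t", self.t_ranges), ("M", self.m_ranges), ("s", self.s_ranges)):
            for lo, hi in ranges:
                if lo <= 0:
                    raise ValueError(f"{name} lower bounds must be strictly positive")
        if self.N_range is not None and self.N_range[0] <= 0:
            raise ValueError("N lower bound must be strictly positive")

    @property
    def gamma(self) -> int:
        return len(self.t_ranges)

    @classmethod
    def uniform(
        cls,
        gamma: int,
        n=(2, 50),
        t=(0.1, 50.0),
        M=(0.05, 50.0),
        s=(1.0, 1.0),
        N=None,
    ) -> "Bounds":
        """Build bounds repeating one interval per parameter family."""
        return cls(
            n_range=n,
            t_ranges=(tuple(t),) * gamma,
            m_ranges=(tuple(M),) * (gamma + 1),
            s_ranges=(tuple(s),) * (gamma + 1),
            N_range=N,
        )


def validate_demography(d: IslandDemography, b: Bounds) -> list:
    """Return a list of constraint violations of ``d`` against ``b``.

    An empty list means ``d`` lies inside the parameter space delimited by
    ``b``.  Violations are descriptions, not exceptions: samplers and
    optimizers treat them as data.
    """
    out = []
    if d.gamma != b.gamma:
        out.append(f"gamma mismatch: demography has {d.gamma}, bounds have {b.gamma}")
        return out
    n_min, n_max = b.n_range
    if d.n < 2 or d.n < n_min:
        out.append("n below n_min")
    elif d.n > n_max:
        out.append("n above n_max")
    times = d.event_times
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        out.append("event_times not increasing")
    for i, (t, (lo, hi)) in enumerate(zip(times, b.t_ranges)):
        if t <= 0:
            out.append(f"t_{i + 1} not positive")
        elif not lo <= t <= hi:
            out.append(f"t_{i + 1}={t} outside [{lo}, {hi}]")
    for i, (m, (lo, hi)) in enumerate(zip(d.migration_rates, b.m_ranges)):
        if m <= 0:
            out.append(f"M_{i} not positive")
        elif not lo <= m <= hi:
            out.append(f"M_{i}={m} outside [{lo}, {hi}]")
    for i, (s, (lo, hi)) in enumerate(zip(d.deme_sizes, b.s_ranges)):
        if s <= 0:
            out.append(f"s_{i} not positive")
        elif not lo <= s <= hi:
            out.append(f"s_{i}={s} outside [{lo}, {hi}]")
    return out


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))


def sample_continuous(b: Bounds, gamma: int, L: int, seed) -> list:
    """Draw ``L`` independent scenarios from the continuous prior.

    ``n`` is discrete-uniform on its integer range; each event time is
    log-uniform (base 10) in its interval, with the joint draw sorted
    ascending afterwards; migration rates and deme sizes are uniform.  Each
    scenario consumes its own deterministic RNG stream, so lists are
    reproducible and extendable under a fixed seed.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    if gamma != b.gamma:
        raise ValueError("bounds gamma does not match requested gamma")
    streams = np.random.SeedSequence(seed).spawn(L)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        n = int(rng.integers(int(b.n_range[0]), int(b.n_range[1]) + 1))
        times = sorted(_loguniform(rng, lo, hi) for lo, hi in b.t_ranges)
        Ms = [rng.uniform(lo, hi) for lo, hi in b.m_ranges]
        ss_sizes = [rng.uniform(lo, hi) for lo, hi in b.s_ranges]
        out.append(
            IslandDemography(
                n=n,
                event_times=tuple(times),
                migration_rates=tuple(Ms),
                deme_sizes=tuple(ss_sizes),
            )
        )
    return out


@dataclass(frozen=True)
class ValueSets:
    """Finite per-parameter value sets for discrete scenario sampling.

    Defaults are the validation grid: a coarse lattice of island counts,
    event times and migration rates with deme sizes pinned to 1.
    """

    n: tuple = (2, 5, 10, 15, 20)
    t: tuple = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    M: tuple = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    s: tuple = (1.0,)

    def hull(self, gamma: int) -> Bounds:
        """Smallest axis-aligned :class:`Bounds` containing the sets."""
        return Bounds.uniform(
            gamma,
            n=(min(self.n), max(self.n)),
            t=(min(self.t), max(self.t)),
            M=(min(self.M), max(self.M)),
            s=(min(self.s), max(self.s)),
        )


def _admissible(times: tuple, Ms: tuple) -> bool:
    # reject tied event times (zero-length components) and equal migration
    # rates in two consecutive components
    if any(b <= a for a, b in zip(times, times[1:])):
        return False
    if any(m2 == m1 for m1, m2 in zip(Ms, Ms[1:])):
        return False
    return True


def sample_discrete(value_sets: ValueSets, gamma: int, L: int, seed) -> list:
    """Draw ``L`` distinct scenarios from the Cartesian product of value sets.

    Tuples are drawn uniformly without replacement; event times are sorted
    after drawing; tuples with equal migration rates in two consecutive
    components, or with tied event times, are rejected and redrawn.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    rng = np.random.default_rng(seed)
    n_set = tuple(value_sets.n)
    t_set = tuple(sorted(float(t) for t in value_sets.t))
    m_set = tuple(float(m) for m in value_sets.M)
    s_set = tuple(float(s) for s in value_sets.s)
    if len(s_set) != 1:
        raise ValueError("discrete sampling supports a single deme-size value only")

    # canonical admissible scenarios: sorted distinct time combinations x
    # ordered M tuples without consecutive repeats
    time_combos = list(itertools.combinations(t_set, gamma))
    m_tuples = [
        ms for ms in itertools.product(m_set, repeat=gamma + 1) if _admissible((), ms)
    ]
    total = len(n_set) * len(time_combos) * len(m_tuples)
    if L > total:
        raise ValueError(
            f"requested {L} scenarios but only {total} admissible tuples exist"
        )
    idx = rng.choice(total, size=L, replace=False)
    out = []
    for k in idx:
        k = int(k)
        i_n, rem = divmod(k, len(time_combos) * len(m_tuples))
        i_t, i_m = divmod(rem, len(m_tuples))
        out.append(
            IslandDemography(
                n=int(n_set[i_n]),
                event_times=time_combos[i_t],
                migration_rates=m_tuples[i_m],
                deme_sizes=s_set * (gamma + 1),
            )
        )
    return out


def write_scenario_json(d, path) -> None:
    """Write a demography (scaled or not) to a JSON scenario file."""
    if isinstance(d, ScaledDemography):
        base, N = d.base, d.N
    else:
        base, N = d, None
    payload = {
        "n": base.n,
        "event_times": list(base.event_times),
        "migration_rates": list(base.migration_rates),
        "deme_sizes": list(base.deme_sizes),
    }
    if N is not None:
        payload["N"] = N
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_scenario_json(path):
    """Read a scenario file; returns Scaled- or IslandDemography."""
    with open(path) as fh:
        payload = json.load(fh)
    base = IslandDemography(
        n=int(payload["n"]),
        event_times=tuple(payload["event_times"]),
        migration_rates=tuple(payload["migration_rates"]),
        deme_sizes=tuple(payload.get("deme_sizes") or ()) or None,
    )
    if "N" in payload:
        return ScaledDemography(N=float(payload["N"]), base=base)
    return base
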