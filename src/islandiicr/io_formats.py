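"""Readers and writers binding the engine to the outside world.

Covers the Li & Durbin PSMC text output (the real-data entry point), its
conversion to a scaled stepwise IICR, emission of ``ms`` commands for the
simulation loop, connectivity-graph TSV export, and TSV/JSON round trips
for stepwise curves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import IslandDemography, ScaledDemography
from .iicr import StepwiseIICR

__all__ = [
    "PsmcOutput",
    "ScalingConstants",
    "read_psmc",
    "write_psmc",
    "scale_psmc",
    "ms_command",
    "export_connectivity_graph",
    "read_connectivity_graph",
    "write_iicr_tsv",
    "read_iicr_tsv",
    "write_iicr_json",
    "read_iicr_json",
]


@dataclass(frozen=True)
class PsmcOutput:
    """The last (converged) iteration of a PSMC run.

    ``theta0`` and ``rho0`` come from the final TR line; ``intervals`` are
    the ``(t_k, lambda_k)`` pairs of the final RS lines with ``t_k`` in
    units of 2N0 and ``lambda_k`` the relative size; ``pattern`` is the
    ``-p`` string when present.
    """

    theta0: float
    rho0: float
    intervals: tuple
    pattern: str = None

    def __post_init__(self):
        ts = [t for t, _ in self.intervals]
        lams = [lam for _, lam in self.intervals]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("PSMC interval times must be nondecreasing")
        if any(lam <= 0 for lam in lams):
            raise ValueError("PSMC lambda values must be positive")


@dataclass(frozen=True)
class ScalingConstants:
    """Constants converting PSMC units to generations and gene copies."""

    mu: float = 1.25e-8
    bin_size: int = 100
    generation_time: float = 25.0

    def __post_init__(self):
        if self.mu <= 0 or self.bin_size <= 0 or self.generation_time <= 0:
            raise ValueError("all scaling constants must be positive")


def read_psmc(path) -> PsmcOutput:
    """Parse a ``.psmc`` file, keeping only the final RD block."""
    blocks = []
    current = None
    pattern = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tag, _, rest = line.partition("\t")
            if tag == "RD":
                current = {"TR": None, "RS": []}
                blocks.append(current)
            elif tag == "PA":
                parts = rest.split()
                if parts:
                    pattern = parts[0]
            elif tag == "TR":
                if current is None:
                    raise ValueError(f"{path}: TR before any RD block (line {lineno})")
                try:
                    theta0, rho0 = (float(x) for x in rest.split())
                except ValueError as exc:
                    raise ValueError(f"{path}: bad TR line {lineno}: {line!r}") from exc
                current["TR"] = (theta0, rho0)
            elif tag == "RS":
                if current is None:
                    raise ValueError(f"{path}: RS before any RD block (line {lineno})")
                parts = rest.split()
                try:
                    t_k, lam_k = float(parts[1]), float(parts[2])
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}: bad RS line {lineno}: {line!r}") from exc
                current["RS"].append((t_k, lam_k))
    if not blocks:
        raise ValueError(f"{path}: no RD blocks found")
    last = blocks[-1]
    if last["TR"] is None or not last["RS"]:
        raise ValueError(f"{path}: final RD block is truncated")
    return PsmcOutput(
        theta0=last["TR"][0],
        rho0=last["TR"][1],
        intervals=tuple(last["RS"]),
        pattern=pattern,
    )


def write_psmc(p: PsmcOutput, path) -> None:
    """Write a minimal single-block PSMC file (test fixtures, round trips)."""
    with open(path, "w") as fh:
        if p.pattern:
            fh.write(f"PA\t{p.pattern}\n")
        fh.write("RD\t0\n")
        fh.write(f"TR\t{p.theta0:.6f}\t{p.rho0:.6f}\n")
        for k, (t_k, lam_k) in enumerate(p.intervals):
            fh.write(f"RS\t{k}\t{t_k:.6f}\t{lam_k:.6f}\t0\t0\t0\n")
        fh.write("//\n")


def scale_psmc(p: PsmcOutput, k: ScalingConstants = None):
    """Convert PSMC output into a scaled stepwise IICR plus ``N0``.

    ``N0 = theta0 / (4 mu s)`` with ``s`` the bin size; times become
    ``2 N0 t_k`` generations and values ``N0 lambda_k`` gene copies.  The
    final (unbounded) PSMC interval is closed by extending the last grid
    edge geometrically, so the curve is directly usable as a fitting
    target.
    """
    k = k or ScalingConstants()
    if p.theta0 <= 0:
        raise ValueError("theta0 must be positive")
    N0 = p.theta0 / (4.0 * k.mu * k.bin_size)
    ts = np.array([t for t, _ in p.intervals]) * 2.0 * N0
    lams = np.array([lam for _, lam in p.intervals])
    values = lams * N0
    if ts[0] != 0.0:
        raise ValueError("expected the first PSMC interval to start at t=0")
    if len(ts) < 3:
        raise ValueError("need at least three PSMC intervals")
    last_edge = ts[-1] * (ts[-1] / ts[-2])
    grid = np.concatenate([ts, [last_edge]])
    return StepwiseIICR(grid=grid, values=values, scaled=True), N0


def _fmt(x: float) -> str:
    """Compact number formatting for command strings."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def ms_command(
    d: ScaledDemography,
    nreps: int,
    seq_len: int,
    mu: float = 1.25e-8,
    rho_ratio: float = 5.0,
) -> str:
    """Emit the ``ms`` command simulating sequences under ``d``.

    ``theta = 4 mu L N`` and ``rho = theta / rho_ratio`` (5 by default).
    ms measures time in units of 4N generations while the model uses 2N,
    so every event time is divided by 2.  The island total migration rate
    ``M`` equals ms's ``-I``/``-eM`` parameter ``4 N m`` directly: from the
    structured-coalescent limit ``2 N m = M / 2``.
    """
    base = d.base
    theta = 4.0 * mu * seq_len * d.N
    rho = theta / rho_ratio
    zeros = " ".join(["0"] * (base.n - 1))
    parts = [
        f"ms 2 {nreps} -t {_fmt(theta)} -r {_fmt(rho)} {seq_len} -p 8",
        f"-I {base.n} 2 {zeros} {_fmt(base.migration_rates[0])}",
    ]
    for t_i, M_i in zip(base.event_times, base.migration_rates[1:]):
        parts.append(f"-eM {_fmt(t_i / 2.0)} {_fmt(M_i)}")
    return " ".join(parts)


def export_connectivity_graph(demographies, path) -> None:
    """Write the step functions t -> M(t) of one or more histories as TSV.

    Rows are ``(scenario_id, t_left, t_right, M)`` with ``inf`` closing the
    last component — ready for any plotting tool.
    """
    if isinstance(demographies, (IslandDemography, ScaledDemography)):
        demographies = [demographies]
    rows = []
    for sid, d in enumerate(demographies):
        base = d.base if isinstance(d, ScaledDemography) else d
        edges = [0.0, *base.event_times, math.inf]
        for left, right, M in zip(edges, edges[1:], base.migration_rates):
            rows.append((sid, left, right, M))
    df = pd.DataFrame(rows, columns=["scenario_id", "t_left", "t_right", "M"])
    df.to_csv(path, sep="\t", index=False)


def read_connectivity_graph(path) -> list:
    """Rebuild :class:`IslandDemography` step functions from a graph TSV.

    The deme count is not stored in the graph, so returned histories carry
    the placeholder ``n=2``; only times and rates are meaningful.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, group in df.groupby("scenario_id", sort=True):
        group = group.sort_values("t_left")
        times = tuple(group["t_left"].to_numpy()[1:])
        rates = tuple(group["M"].to_numpy())
        out.append(IslandDemography(n=2, event_times=times, migration_rates=rates))
    return out


# ---------------------------------------------------------------------------
# stepwise-curve serialization


def write_iicr_tsv(curve: StepwiseIICR, path) -> None:
    df = pd.DataFrame(
        {
            "time_left": curve.grid[:-1],
            "time_right": curve.grid[1:],
            "iicr": curve.values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_iicr_tsv(path, scaled: bool = False) -> StepwiseIICR:
    df = pd.read_csv(path, sep="\t")
    grid = np.concatenate([df["time_left"].to_numpy()[:1], df["time_right"].to_numpy()])
    return StepwiseIICR(grid=grid, values=df["iicr"].to_numpy(), scaled=scaled)


def write_iicr_json(curve: StepwiseIICR, path) -> None:
    payload = {
        "grid": list(curve.grid),
        "values": list(curve.values),
        "scaled": curve.scaled,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_iicr_json(path) -> StepwiseIICR:
    with open(path) as fh:
        payload = json.load(fh)
    return StepwiseIICR(
        grid=np.asarray(payload["grid"]),
        values=np.asarray(payload["values"]),
        scaled=bool(payload.get("scaled", False)),
    )
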