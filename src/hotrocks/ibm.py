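"""Individual-based simulation of size-structured crab demography.

A 100 × 20 grid of rock cells represents the shore: the lower 10 rows are
the mid-intertidal zone (MIZ), the upper 10 the high-intertidal zone
(HIZ).  Each simulated day every cell is assigned a temperature drawn at
random from the pool of observed (or synthetic) daily maximum
temperatures for its zone on that calendar day ± 1 day, with multiple
years combined.  1000 crabs (4–21 mm carapace width, 250 per demographic
size bin) carry size-dependent escape temperatures and heat tolerances;
each day a crab whose rock reaches its heat tolerance dies with
probability ``p_die``, and one whose rock reaches its escape temperature
moves (with probability ``p_move``) to random adjacent rocks until it
finds one below its escape threshold.  A null variant gives every crab
the population-mean thresholds, removing size dependence.

Within a day rock temperatures are fixed; movement uses the 8-cell
neighbourhood with edges clamped (no wraparound); crabs do not interact
and any number may share a cell.  Dead crabs are not replaced — the model
tracks how thermal mortality and avoidance reshape an initial cohort's
size structure across zones over one year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hotrocks.demography import BIN_LABELS, assign_size_bin, bin_spans
from hotrocks.thermal_traits import TraitCoefficients, ctmax_of_size, tesc_of_size

__all__ = [
    "SimConfig",
    "Population",
    "SimResult",
    "TemperaturePool",
    "build_temperature_pools",
    "init_population",
    "step_day",
    "run_replicates",
]

_ALLOWED_PROBS = "probabilities must lie in [0, 1]"


@dataclass(frozen=True)
class SimConfig:
    """Parameterization of one simulation setting."""

    p_move: float = 0.8
    p_die: float = 0.8
    n_crabs: int = 1000
    n_cols: int = 100
    n_rows: int = 20
    n_days: int | None = None  # None = every day the pools cover
    n_reps: int = 50
    seed: int = 0
    null_model: bool = False
    max_moves_per_day: int = 50
    cw_range: tuple[float, float] = (4.0, 21.0)

    def __post_init__(self):
        if not (0.0 <= self.p_move <= 1.0 and 0.0 <= self.p_die <= 1.0):
            raise ValueError(_ALLOWED_PROBS)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must be at least 2x2 for adjacency")
        if self.n_rows % 2 != 0:
            raise ValueError("n_rows must be even (half MIZ, half HIZ)")

    @classmethod
    def from_config(cls, block: dict, seed: int = 0) -> "SimConfig":
        return cls(
            p_move=float(block["p_move"]),
            p_die=float(block["p_die"]),
            n_crabs=int(block["n_crabs"]),
            n_cols=int(block["n_cols"]),
            n_rows=int(block["n_rows"]),
            n_days=(None if block.get("n_days") is None else int(block["n_days"])),
            n_reps=int(block["n_reps"]),
            seed=seed,
            null_model=bool(block.get("null_model", False)),
            max_moves_per_day=int(block.get("max_moves_per_day", 50)),
            cw_range=tuple(block.get("cw_range_mm", (4.0, 21.0))),
        )


class TemperaturePool:
    """Zone × day-of-year pools of daily maximum temperatures.

    ``pool(zone, doy)`` returns the multiset of daily maxima observed in
    that zone on calendar days ``doy − 1 .. doy + 1`` (wrapping across the
    year boundary; the same calendar day of different years is combined).
    """

    def __init__(self, pools: dict[tuple[str, int], np.ndarray]):
        self._pools = pools

    def __call__(self, zone: str, doy: int) -> np.ndarray:
        key = (zone, int(doy))
        if key not in self._pools or len(self._pools[key]) == 0:
            raise KeyError(f"no temperatures pooled for zone {zone}, day {doy}")
        return self._pools[key]

    def covered_days(self, zones=("MIZ", "HIZ")) -> list[int]:
        """Days-of-year with a non-empty pool in every requested zone."""
        days = None
        for zone in zones:
            zdays = {d for (z, d), v in self._pools.items() if z == zone and len(v)}
            days = zdays if days is None else days & zdays
        return sorted(days or [])


def build_temperature_pools(summaries: pd.DataFrame) -> TemperaturePool:
    """Build ±1-day temperature pools from zone-labelled daily summaries
    (columns ``zone, date, t_max``)."""
    if "zone" not in summaries.columns:
        raise ValueError("summaries must carry a 'zone' column")
    doy = pd.DatetimeIndex(summaries["date"]).dayofyear.to_numpy()
    doy = np.minimum(doy, 365)  # fold leap day into day 365
    zones = summaries["zone"].to_numpy()
    tmax = summaries["t_max"].to_numpy(dtype=float)
    pools: dict[tuple[str, int], list] = {}
    for z, d, t in zip(zones, doy, tmax):
        for offset in (-1, 0, 1):
            dd = (d - 1 + offset) % 365 + 1
            pools.setdefault((z, int(dd)), []).append(t)
    return TemperaturePool({k: np.asarray(v) for k, v in pools.items()})


@dataclass
class Population:
    """Vectorized crab state (one entry per individual)."""

    cw: np.ndarray  # carapace width, mm
    t_esc: np.ndarray
    ct_max: np.ndarray
    col: np.ndarray
    row: np.ndarray
    alive: np.ndarray
    moves_today: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.moves_today is None:
            self.moves_today = np.zeros(len(self.cw), dtype=int)

    def __len__(self) -> int:
        return len(self.cw)


def crab_zones(pop: Population, n_rows: int) -> np.ndarray:
    """Zone label per crab: rows in the upper half of the grid are HIZ."""
    return np.where(pop.row >= n_rows // 2, "HIZ", "MIZ")


def init_population(
    n: int = 1000,
    seed: int = 0,
    *,
    config: SimConfig | None = None,
    coeffs: TraitCoefficients = TraitCoefficients(),
    rng: np.random.Generator | None = None,
) -> Population:
    """Seed a population: equal numbers per size bin, widths uniform
    within each bin's span intersected with the 4–21 mm range, positions
    uniform over the grid, thresholds from the size functions (or the
    population-mean constants under the null model)."""
    config = config or SimConfig()
    if n < 4 or n % 4 != 0:
        raise ValueError("n must be a positive multiple of 4 (equal bins)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    spans = bin_spans(*config.cw_range)
    per_bin = n // 4
    cw = np.concatenate(
        [rng.uniform(lo, hi, size=per_bin) for lo, hi in spans.values()]
    )
    if config.null_model:
        t_esc = np.full(n, coeffs.mean_tesc)
        ct_max = np.full(n, coeffs.mean_ctmax)
    else:
        t_esc = tesc_of_size(cw, coeffs)
        ct_max = ctmax_of_size(cw, coeffs)
    col = rng.integers(0, config.n_cols, size=n)
    row = rng.integers(0, config.n_rows, size=n)
    return Population(
        cw=cw, t_esc=t_esc, ct_max=ct_max,
        col=col, row=row, alive=np.ones(n, dtype=bool),
    )


_NEIGHBOR_OFFSETS = np.array(
    [(dc, dr) for dc in (-1, 0, 1) for dr in (-1, 0, 1) if (dc, dr) != (0, 0)]
)


def _draw_grid(pool: TemperaturePool, doy: int, config: SimConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Assign every cell a temperature from its zone's ±1-day pool."""
    grid = np.empty((config.n_rows, config.n_cols))
    half = config.n_rows // 2
    for zone, rows in (("MIZ", slice(0, half)), ("HIZ", slice(half, None))):
        values = pool(zone, doy)
        grid[rows] = rng.choice(values, size=(half, config.n_cols), replace=True)
    return grid


def step_day(
    pop: Population,
    pool: TemperaturePool,
    doy: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the population one day in place; returns the day's cell
    temperature grid.

    Per crab: a mortality check (die with ``p_die`` where the cell is at
    or above its heat tolerance) precedes the escape check; escapers
    relocate (gated once per day by ``p_move``) through random adjacent
    cells, with mortality re-checked at every visited cell, until they
    find a cell below their escape temperature or exhaust
    ``max_moves_per_day``.
    """
    grid = _draw_grid(pool, doy, config, rng)
    pop.moves_today[:] = 0
    alive = pop.alive
    temp_here = grid[pop.row, pop.col]

    # mortality at the home cell
    at_risk = alive & (temp_here >= pop.ct_max)
    dies = at_risk & (rng.random(len(pop)) < config.p_die)
    pop.alive[dies] = False

    # escape gating: one p_move draw per crab per day
    hot = pop.alive & (temp_here >= pop.t_esc)
    moving = hot & (rng.random(len(pop)) < config.p_move)

    for _ in range(config.max_moves_per_day):
        idx = np.flatnonzero(moving)
        if idx.size == 0:
            break
        hops = _NEIGHBOR_OFFSETS[rng.integers(0, 8, size=idx.size)]
        new_col = np.clip(pop.col[idx] + hops[:, 0], 0, config.n_cols - 1)
        new_row = np.clip(pop.row[idx] + hops[:, 1], 0, config.n_rows - 1)
        pop.col[idx] = new_col
        pop.row[idx] = new_row
        pop.moves_today[idx] += 1
        temp_new = grid[new_row, new_col]
        # mortality re-check at the visited cell
        lethal = temp_new >= pop.ct_max[idx]
        dies = lethal & (rng.random(idx.size) < config.p_die)
        pop.alive[idx[dies]] = False
        # stop moving if dead or below the escape threshold
        settled = temp_new < pop.t_esc[idx]
        moving[idx[dies]] = False
        moving[idx[settled & ~dies]] = False
    return grid


@dataclass(frozen=True)
class SimResult:
    """Replicate-level and aggregated size-structure output."""

    final_counts: pd.DataFrame  # rep, zone, bin, count, proportion
    summary: pd.DataFrame  # zone, bin, mean/sd of proportion and count
    config: SimConfig
    max_moves_hits: int  # crab-days that exhausted max_moves_per_day


def _final_counts(pop: Population, config: SimConfig, rep: int) -> pd.DataFrame:
    zones = crab_zones(pop, config.n_rows)
    bins = assign_size_bin(pop.cw)
    rows = []
    for zone in ("MIZ", "HIZ"):
        in_zone = pop.alive & (zones == zone)
        total = int(in_zone.sum())
        for label in BIN_LABELS:
            count = int((in_zone & (bins == label)).sum())
            rows.append(
                {
                    "rep": rep,
                    "zone": zone,
                    "bin": label,
                    "count": count,
                    "proportion": count / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_replicates(
    config: SimConfig,
    pools: TemperaturePool,
    coeffs: TraitCoefficients = TraitCoefficients(),
) -> SimResult:
    """Run ``config.n_reps`` independent one-year simulations and
    aggregate final-day per-zone size-bin proportions.

    Replicates use independent child streams spawned from the master
    seed, so results are reproducible and order-independent.
    """
    days = pools.covered_days()
    if not days:
        raise ValueError("temperature pools cover no simulatable days")
    if config.n_days is not None:
        days = days[: config.n_days]
    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    reps = []
    max_moves_hits = 0
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pop = init_population(
            config.n_crabs, config=config, coeffs=coeffs, rng=rng
        )
        for doy in days:
            step_day(pop, pools, doy, config, rng)
            max_moves_hits += int(
                np.sum(pop.moves_today >= config.max_moves_per_day)
            )
        reps.append(_final_counts(pop, config, rep))
    final = pd.concat(reps, ignore_index=True)
    summary = (
        final.groupby(["zone", "bin"], observed=True)
        .agg(
            mean_proportion=("proportion", "mean"),
            sd_proportion=("proportion", "std"),
            mean_count=("count", "mean"),
            sd_count=("count", "std"),
        )
        .reset_index()
    )
    return SimResult(final, summary, config, max_moves_hits)
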