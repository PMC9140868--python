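"""Agarose-gel band migration and resolvability.

Migration follows the familiar log-linear size law: at gel concentration g
(% agarose), run time t (minutes) and voltage gradient V (V/cm), a fragment
of length L bp travels

    d(L) = t * V * exp(alpha(g) - beta(g) * ln L)   [mm]

i.e. d ∝ t·V·L^(-beta(g)), strictly decreasing in L and linear in t by
construction. beta grows with gel concentration (denser gels sieve small
fragments harder), alpha sets the overall scale. Two bands are called
*separated* when their migration distances differ by at least two band
half-widths (2·band_sigma); pairs with 0 < |Δd| < 2·band_sigma are a third
state, *indistinct* — visibly one smeared band, the way a few-bp length
polymorphism looks on a standard gel.

The default calibration (alpha, beta per standard gel percentage, sigma =
0.5 mm, 5 V/cm) was fit once to the behaviour of the marker panel on 1-3%
gels — an 11 bp difference near 370 bp separable only at 3%, a 43 bp
difference near 500 bp separable at 2% after 60 but not 10 minutes, and a
413 bp difference at 923/510 bp separable at 1% within 10 minutes — and is
shipped frozen. No reptation physics, no band-intensity modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

MIN_LENGTH = 50  # bp floor below which the model is not calibrated
STANDARD_GEL_PCTS = (1.0, 2.0, 3.0)
DEFAULT_TIME_MIN = 60.0

#: Frozen default mobility calibration per standard gel percentage.
DEFAULT_ALPHA = {
    1.0: math.log(11.0 / 3.0),
    2.0: math.log(35.0 / 3.0),
    3.0: math.log(400.0 / 3.0),
}
DEFAULT_BETA = {1.0: 0.6, 2.0: 0.9, 3.0: 1.2}


def _interp(table: Mapping[float, float], g: float) -> float:
    xs = sorted(table)
    if g <= xs[0]:
        return table[xs[0]]
    if g >= xs[-1]:
        return table[xs[-1]]
    for lo, hi in zip(xs, xs[1:]):
        if lo <= g <= hi:
            w = (g - lo) / (hi - lo)
            return (1 - w) * table[lo] + w * table[hi]
    raise AssertionError


@dataclass(frozen=True)
class GelConfig:
    """Agarose gel run configuration and mobility calibration."""

    gel_pct: float = 2.0
    voltage_gradient: float = 5.0  # V/cm
    band_sigma: float = 0.5  # mm, band half-width
    alpha_table: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta_table: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_BETA))

    def __post_init__(self) -> None:
        if self.gel_pct <= 0:
            raise ValueError("gel_pct must be positive")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        betas = [self.beta_table[k] for k in sorted(self.beta_table)]
        if any(b <= 0 for b in betas) or any(b2 < b1 for b1, b2 in zip(betas, betas[1:])):
            raise ValueError("beta must be positive and non-decreasing in gel percentage")

    @property
    def alpha(self) -> float:
        return _interp(self.alpha_table, self.gel_pct)

    @property
    def beta(self) -> float:
        return _interp(self.beta_table, self.gel_pct)

    def at(self, gel_pct: float) -> "GelConfig":
        return GelConfig(gel_pct, self.voltage_gradient, self.band_sigma,
                         dict(self.alpha_table), dict(self.beta_table))


@dataclass(frozen=True)
class BandPattern:
    """Bands in one gel lane: (length bp, migration distance mm)."""

    lane_id: str
    bands: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        lengths = {}
        for length, dist in self.bands:
            if dist <= 0:
                raise ValueError("migration distance must be positive")
            if length in lengths and lengths[length] != dist:
                raise ValueError("same-length fragments must co-migrate")
            lengths[length] = dist


def migration_distance(length: int, cfg: GelConfig, time: float = DEFAULT_TIME_MIN) -> float:
    """Migration distance in mm of a fragment of ``length`` bp."""
    if length < MIN_LENGTH:
        raise ValueError(f"fragment of {length} bp is below the {MIN_LENGTH} bp floor")
    if time <= 0:
        raise ValueError("time must be positive")
    return time * cfg.voltage_gradient * math.exp(cfg.alpha - cfg.beta * math.log(length))


def separation(l1: int, l2: int, cfg: GelConfig, time: float = DEFAULT_TIME_MIN) -> str:
    """Band-pair state: "separated", "indistinct" or "comigrating"."""
    dd = abs(migration_distance(l1, cfg, time) - migration_distance(l2, cfg, time))
    if dd == 0.0:
        return "comigrating"
    if dd >= 2 * cfg.band_sigma:
        return "separated"
    return "indistinct"


def resolvable(l1: int, l2: int, cfg: GelConfig, time: float = DEFAULT_TIME_MIN) -> bool:
    """True iff the two fragments produce visibly separate bands."""
    return separation(l1, l2, cfg, time) == "separated"


def min_gel_percent(
    l1: int,
    l2: int,
    time: float = DEFAULT_TIME_MIN,
    cfg: GelConfig | None = None,
    candidates: Sequence[float] = STANDARD_GEL_PCTS,
) -> float | None:
    """Smallest standard gel percentage resolving the pair, or None."""
    base = cfg or GelConfig()
    for g in candidates:
        if resolvable(l1, l2, base.at(g), time):
            return g
    return None


def band_pattern(
    lane_id: str, lengths: Iterable[int], cfg: GelConfig, time: float = DEFAULT_TIME_MIN
) -> BandPattern:
    bands = tuple(
        (length, migration_distance(length, cfg, time)) for length in sorted(set(lengths), reverse=True)
    )
    return BandPattern(lane_id, bands)


LADDER_BP = (5000, 3000, 2000, 1500, 1000, 750, 500, 250, 100)


def render_gel(
    patterns: Sequence[BandPattern],
    cfg: GelConfig,
    time: float = DEFAULT_TIME_MIN,
    width: int = 9,
    depth_mm: float | None = None,
    resolution_mm: float = 1.0,
) -> str:
    """Deterministic ASCII lane plot with a ladder lane.

    Each text row is one ``resolution_mm`` slab of gel; bands are drawn as
    ``===`` bars at their migration depth.
    """
    ladder = [
        (bp, migration_distance(bp, cfg, time)) for bp in LADDER_BP if bp >= MIN_LENGTH
    ]
    lanes = [BandPattern("ladder", tuple(ladder)), *patterns]
    max_d = max((d for lane in lanes for _, d in lane.bands), default=1.0)
    depth = depth_mm if depth_mm is not None else max_d + 2 * resolution_mm
    n_rows = max(1, int(math.ceil(depth / resolution_mm)))
    header = "|".join(f"{lane.lane_id[:width]:^{width}}" for lane in lanes)
    rows = [header, "-" * len(header)]
    for r in range(n_rows):
        lo, hi = r * resolution_mm, (r + 1) * resolution_mm
        cells = []
        for lane in lanes:
            mark = " " * width
            for bp, d in lane.bands:
                if lo <= d < hi:
                    label = f"{bp}"
                    bar = f"={label}=" if len(label) + 2 <= width else "=" * width
                    mark = f"{bar:^{width}}"
                    break
            cells.append(mark)
        rows.append("|".join(cells))
    return "\n".join(rows) + "\n"


def config_to_yaml(cfg: GelConfig, path: str | Path | None = None) -> str:
    data = {
        "gel_pct": cfg.gel_pct,
        "voltage_gradient": cfg.voltage_gradient,
        "band_sigma": cfg.band_sigma,
        "alpha": {str(k): v for k, v in cfg.alpha_table.items()},
        "beta": {str(k): v for k, v in cfg.beta_table.items()},
    }
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(path: str | Path) -> GelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return GelConfig(
        gel_pct=float(data.get("gel_pct", 2.0)),
        voltage_gradient=float(data.get("voltage_gradient", 5.0)),
        band_sigma=float(data.get("band_sigma", 0.5)),
        alpha_table={float(k): float(v) for k, v in data["alpha"].items()},
        beta_table={float(k): float(v) for k, v in data["beta"].items()},
    )
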