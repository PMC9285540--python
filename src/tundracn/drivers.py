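"""Synthetic driver time series: vole cycles, spliced series, climate ramps.

Arctic small-mammal populations cycle with a 3-4 year period between trough
densities near 10 voles/ha and peak densities near 100 voles/ha, with a
long-run mean of 40 voles/ha.  The generator emulates only these summary
statistics — the within-cycle shape is a modeling choice: a 3-yr cycle is
[peak, trough, trough] and a 4-yr cycle [peak, trough, trough, shoulder],
with peak ~ U(90, 110), trough ~ U(8, 12) and shoulder ~ U(35, 45) so both
cycle lengths have an expected mean of 40 voles/ha.

Driver series are annual constants: year t's fluxes use year t's drivers.
A series covering a simulation horizon of H years has H + 1 entries
(years 0..H inclusive, so end-of-run driver values are defined).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VoleCycleSpec",
    "DriverSeries",
    "generate_vole_cycle",
    "splice_series",
    "climate_ramp",
    "constant_series",
]


@dataclass(frozen=True, slots=True)
class VoleCycleSpec:
    """Stochastic vole-cycle recipe (densities in voles/ha, horizon in years)."""

    n_years: int
    seed: int
    peak_range: tuple[float, float] = (90.0, 110.0)
    trough_range: tuple[float, float] = (8.0, 12.0)
    shoulder_range: tuple[float, float] = (35.0, 45.0)
    cycle_lengths: tuple[int, ...] = (3, 4)
    target_mean: float = 40.0
    #: max fractional adjustment of non-peak years when re-centering the mean
    mean_tolerance: float = 1.0
    max_rescale: float = 0.05

    def __post_init__(self) -> None:
        if self.n_years < min(self.cycle_lengths):
            raise ValueError("horizon shorter than one full cycle")
        if self.peak_range[0] <= self.trough_range[1]:
            raise ValueError("peak range must lie above trough range")
        if not self.trough_range[1] < self.target_mean < self.peak_range[0]:
            raise ValueError("target mean must lie between trough and peak ranges")


def generate_vole_cycle(spec: VoleCycleSpec) -> np.ndarray:
    """Generate a yearly vole-density series satisfying the cycle statistics.

    Peak years are spaced 3 or 4 years apart (uniform random choice); each
    cycle starts with its peak.  If the realized mean drifts outside
    ``target_mean +/- mean_tolerance``, non-peak years are rescaled by at
    most ``+/-max_rescale`` (troughs clamped back into their range) to
    re-center it.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    values: list[float] = []
    is_peak: list[bool] = []
    is_trough: list[bool] = []
    while len(values) < spec.n_years:
        length = int(rng.choice(spec.cycle_lengths))
        values.append(float(rng.uniform(*spec.peak_range)))
        is_peak.append(True)
        is_trough.append(False)
        for _ in range(2):
            values.append(float(rng.uniform(*spec.trough_range)))
            is_peak.append(False)
            is_trough.append(True)
        if length == 4:
            values.append(float(rng.uniform(*spec.shoulder_range)))
            is_peak.append(False)
            is_trough.append(False)
    v = np.asarray(values[: spec.n_years])
    peak = np.asarray(is_peak[: spec.n_years])
    trough = np.asarray(is_trough[: spec.n_years])

    mean = v.mean()
    if abs(mean - spec.target_mean) > spec.mean_tolerance and (~peak).any():
        nonpeak_sum = v[~peak].sum()
        want = spec.target_mean * len(v) - v[peak].sum()
        factor = np.clip(want / nonpeak_sum, 1 - spec.max_rescale, 1 + spec.max_rescale)
        v = v.copy()
        v[~peak] *= factor
        v[trough] = np.clip(v[trough], *spec.trough_range)
    return v


def splice_series(
    base: np.ndarray, switch_year: int, constant_value: float
) -> np.ndarray:
    """Copy of ``base`` held at ``constant_value`` from ``switch_year`` on.

    Emulates adding voles to (or removing them from) the ecosystem after an
    initial cycling period.
    """
    base = np.asarray(base, dtype=float)
    if not 0 <= switch_year <= len(base):
        raise ValueError("switch_year outside the series horizon")
    if constant_value < 0:
        raise ValueError("constant_value must be non-negative")
    out = base.copy()
    out[switch_year:] = constant_value
    return out


def climate_ramp(
    start_value: float, end_value: float, ramp_years: int, horizon: int
) -> np.ndarray:
    """Linear ramp over ``ramp_years``, held at ``end_value`` afterward.

    Returns ``horizon + 1`` yearly values (years 0..horizon); year 0 is the
    start value, year ``ramp_years`` exactly the end value.
    """
    if ramp_years > horizon:
        raise ValueError("ramp_years must not exceed the horizon")
    t = np.arange(horizon + 1, dtype=float)
    if ramp_years == 0:
        return np.full(horizon + 1, float(end_value))
    frac = np.minimum(t / ramp_years, 1.0)
    return start_value + (end_value - start_value) * frac


def constant_series(value: float, horizon: int) -> np.ndarray:
    """A constant yearly series over years 0..horizon."""
    return np.full(horizon + 1, float(value))


@dataclass(frozen=True, slots=True)
class DriverSeries:
    """Aligned yearly driver arrays over years 0..horizon (length horizon+1)."""

    Ca: np.ndarray
    T: np.ndarray
    Nin: np.ndarray
    V: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = {k: np.asarray(getattr(self, k), dtype=float) for k in ("Ca", "T", "Nin", "V")}
        n = {len(a) for a in arrays.values()}
        if len(n) != 1:
            raise ValueError("driver arrays must have equal length")
        if (arrays["V"] < 0).any():
            raise ValueError("vole density must be non-negative everywhere")
        for k, a in arrays.items():
            object.__setattr__(self, k, a)

    def __len__(self) -> int:
        return len(self.Ca)

    @property
    def horizon(self) -> int:
        return len(self) - 1

    def at(self, year: int):
        from .model_core import DriverState

        return DriverState(
            Ca=float(self.Ca[year]),
            T=float(self.T[year]),
            Nin=float(self.Nin[year]),
            V=float(self.V[year]),
        )

    @classmethod
    def constant(
        cls,
        horizon: int,
        Ca: float = 400.0,
        T: float = 10.0,
        Nin: float = 0.133,
        V: float = 0.0,
        provenance: dict | None = None,
    ) -> "DriverSeries":
        return cls(
            Ca=constant_series(Ca, horizon),
            T=constant_series(T, horizon),
            Nin=constant_series(Nin, horizon),
            V=constant_series(V, horizon),
            provenance=provenance or {"kind": "constant"},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(len(self)),
                "Ca": self.Ca,
                "T": self.T,
                "Nin": self.Nin,
                "V": self.V,
            }
        )

    def provenance_hash(self) -> str:
        digest = hashlib.sha256(
            json.dumps(self.provenance, sort_keys=True, default=str).encode()
        )
        return digest.hexdigest()[:12]

    def write(self, path) -> None:
        """Tabular text with a one-line provenance header."""
        header = json.dumps(self.provenance, sort_keys=True, default=str)
        with open(path, "w") as fh:
            fh.write(f"# provenance {self.provenance_hash()} {header}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "DriverSeries":
        with open(path) as fh:
            first = fh.readline()
            provenance = {}
            if first.startswith("#"):
                try:
                    provenance = json.loads(first.split(None, 3)[3])
                except (IndexError, json.JSONDecodeError):
                    provenance = {"raw_header": first.strip()}
                frame = pd.read_csv(fh)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh)
        return cls(
            Ca=frame["Ca"].to_numpy(),
            T=frame["T"].to_numpy(),
            Nin=frame["Nin"].to_numpy(),
            V=frame["V"].to_numpy(),
            provenance=provenance,
        )
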