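"""Free-energy-profile bookkeeping and transition-state-theory kinetics.

A :class:`FreeEnergyProfile` is the ordered list of stationary points
along a multi-step reaction — Michaelis complex, transition states,
intermediates, product complex — with cumulative Gibbs energies in
kcal/mol relative to the first point. From these the module derives
per-step barriers, the rate-determining barrier under the energetic
span convention (each TS measured from the lowest *preceding* minimum,
the profile-wide maximum of those spans), and Eyring rates

    k = (k_B T / h) · exp(−ΔG‡ / RT).

The energetic-span convention matters: a profile whose deepest early
minimum is the reactant state can have its rate-determining span at a
late TS even when an earlier TS has the largest single-step rise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL_MOL_K, eyring_prefactor

__all__ = [
    "FreeEnergyProfile",
    "KineticsContext",
    "StepBarrierTable",
    "step_barrier",
    "rate_determining_barrier",
    "tst_rate",
    "tst_barrier",
    "retardation_factor",
    "build_step_table",
    "compare_step_barriers",
    "load_profiles",
    "load_bundled_profiles",
    "load_bundled_step_reference",
]


@dataclass
class FreeEnergyProfile:
    """Ordered stationary points with cumulative ΔG (kcal/mol)."""

    points: list[tuple[str, str, float]]  # (label, kind: "min"|"ts", G)
    variant: str = ""
    subunit: str = ""

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("empty profile")
        labels = [p[0] for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate stationary-point labels")
        first_kind, first_g = self.points[0][1], self.points[0][2]
        if first_kind != "min" or first_g != 0.0:
            raise ValueError("profile must start at a minimum with G = 0")
        for i, (label, kind, g) in enumerate(self.points):
            if kind not in ("min", "ts"):
                raise ValueError(f"{label}: kind must be 'min' or 'ts'")
            expected = "min" if i % 2 == 0 else "ts"
            if kind != expected:
                raise ValueError(
                    f"{label}: labels must alternate minimum/TS (position {i} should be {expected})"
                )
            if not math.isfinite(g):
                raise ValueError(f"{label}: non-finite energy")

    def g(self, label: str) -> float:
        for lbl, _kind, g in self.points:
            if lbl == label:
                return g
        raise KeyError(f"no stationary point {label!r} in profile {self.subunit}/{self.variant}")

    def index(self, label: str) -> int:
        for i, (lbl, _k, _g) in enumerate(self.points):
            if lbl == label:
                return i
        raise KeyError(f"no stationary point {label!r}")

    @property
    def transition_states(self) -> list[str]:
        return [lbl for lbl, kind, _ in self.points if kind == "ts"]

    @property
    def minima(self) -> list[str]:
        return [lbl for lbl, kind, _ in self.points if kind == "min"]


@dataclass
class KineticsContext:
    """Temperature and the derived TST constants."""

    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        """R·T in kcal/mol."""
        return R_KCAL_MOL_K * self.temperature

    @property
    def prefactor(self) -> float:
        """Eyring prefactor k_B·T/h in s⁻¹."""
        return eyring_prefactor(self.temperature)


def step_barrier(profile: FreeEnergyProfile, ts_label: str, ref_label: str) -> float:
    """G(ts) − G(ref), kcal/mol. Also serves for stabilization energies
    (e.g. E-PC relative to E-I2, typically negative)."""
    return profile.g(ts_label) - profile.g(ref_label)


def rate_determining_barrier(profile: FreeEnergyProfile) -> tuple[float, str]:
    """Energetic-span rate-determining barrier: max over transition
    states of G(TS) − min{G(m): minima preceding TS}; ties go to the
    earliest TS."""
    if not profile.transition_states:
        raise ValueError("profile has no transition state")
    best: tuple[float, str] | None = None
    lowest_min = math.inf
    for lbl, kind, g in profile.points:
        if kind == "min":
            lowest_min = min(lowest_min, g)
        else:
            span = g - lowest_min
            if best is None or span > best[0] + 1e-12:
                best = (span, lbl)
    return best


def tst_rate(barrier_kcal: float, ctx: KineticsContext | None = None) -> float:
    """Eyring rate k = (k_B T/h)·exp(−ΔG‡/RT), s⁻¹."""
    ctx = ctx or KineticsContext()
    return ctx.prefactor * math.exp(-barrier_kcal / ctx.RT)


def tst_barrier(rate: float, ctx: KineticsContext | None = None) -> float:
    """Inverse of :func:`tst_rate`: ΔG‡ = RT·ln(k_B T/(h·k)), kcal/mol."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    ctx = ctx or KineticsContext()
    return ctx.RT * math.log(ctx.prefactor / rate)


def retardation_factor(
    barrier_fast: float, barrier_slow: float, ctx: KineticsContext | None = None
) -> tuple[float, int]:
    """Rate ratio k_fast/k_slow = exp(ΔΔG‡/RT) and its nearest power of ten.

    The headline comparison — full atrophy vs the intact field — gives
    a ratio of order 10³⁵ at 310 K.
    """
    ctx = ctx or KineticsContext()
    log10_factor = (barrier_slow - barrier_fast) / ctx.RT / math.log(10.0)
    factor = 10.0 ** log10_factor  # may overflow to inf for extreme ΔΔG; log10 is exact
    return factor, int(round(log10_factor))


@dataclass
class StepBarrierTable:
    """TS3 barriers and E-PC stabilizations relative to a reference minimum."""

    frame: pd.DataFrame  # columns: subunit, variant, point, value_kcal_mol
    ref_label: str = "E-I2"

    def value(self, subunit: str, variant: str, point: str) -> float:
        m = self.frame[
            (self.frame.subunit == subunit)
            & (self.frame.variant == variant)
            & (self.frame.point == point)
        ]
        if m.empty:
            raise KeyError(f"no entry for ({subunit}, {variant}, {point})")
        return float(m.value_kcal_mol.iloc[0])


def build_step_table(
    profiles: list[FreeEnergyProfile],
    ref_label: str = "E-I2",
    points: tuple[str, ...] = ("TS3", "E-PC"),
) -> StepBarrierTable:
    """Tabulate G(point) − G(ref) for each (subunit, variant) profile."""
    rows = []
    for p in profiles:
        for point in points:
            rows.append(
                {
                    "subunit": p.subunit,
                    "variant": p.variant,
                    "point": point,
                    "value_kcal_mol": step_barrier(p, point, ref_label),
                }
            )
    frame = pd.DataFrame(rows, columns=["subunit", "variant", "point", "value_kcal_mol"])
    return StepBarrierTable(frame=frame, ref_label=ref_label)


def compare_step_barriers(
    table: StepBarrierTable, subunit_a: str, subunit_b: str, point: str, variant: str
) -> float:
    """Signed difference value(a) − value(b) for one point and variant."""
    return table.value(subunit_a, variant, point) - table.value(subunit_b, variant, point)


# ---------------------------------------------------------------------------
# Profile I/O
# ---------------------------------------------------------------------------

def load_profiles(path: str | Path) -> list[FreeEnergyProfile]:
    """Load profiles from CSV with columns
    subunit, variant, label, kind(min|ts), G_kcal_mol."""
    df = pd.read_csv(path, comment="#")
    required = {"subunit", "variant", "label", "kind", "G_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    out = []
    for (subunit, variant), grp in df.groupby(["subunit", "variant"], sort=False):
        points = [(r.label, r.kind, float(r.G_kcal_mol)) for r in grp.itertuples()]
        out.append(FreeEnergyProfile(points=points, variant=variant, subunit=subunit))
    return out


_DATA = Path(__file__).parent / "data"


def load_bundled_profiles() -> list[FreeEnergyProfile]:
    """The transcribed proteasome–Salinosporamide A profiles shipped
    with the package (β5/β2/β1 × ON/OFF/D17)."""
    return load_profiles(_DATA / "sala_profiles.csv")


def load_bundled_step_reference() -> pd.DataFrame:
    """Published reference step-table values for cross-checking."""
    return pd.read_csv(_DATA / "sala_step_reference.csv", comment="#")
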