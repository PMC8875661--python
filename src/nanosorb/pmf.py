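"""Potential-of-mean-force post-processing.

Turns sampled free-energy profiles ``G(Z)`` — as produced by
adaptive-biasing-force MD along the vertical adsorbate–surface distance
``Z`` — into adsorption free energies ``ΔG_MD``, equilibrium constants
``K`` (mL/g) and ``logK``.

The physics is plain Boltzmann statistics: after normalizing ``G`` to
zero on the far plateau (14–15 Å, where the adsorbate no longer feels
the surface),

* ``ΔG_MD = G(Z_min) − G(Z_far) = min G``  (kcal/mol),
* ``K = S_A ∫ exp(−G(Z)/RT) dZ``          (mL/g),

with ``S_A`` the adsorbent's specific surface area (m²/g) and ``RT`` the
molar thermal energy.  The decadic-log relation
``logK = −ΔG/2.303RT + logC`` links the two; its slope at 300 K is the
theoretical −0.73 mol/kcal that :func:`theoretical_slope` returns.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "BOLTZMANN_K",
    "GAS_CONSTANT_R",
    "DECADIC_LOG",
    "PHASES",
    "ADSORBENTS",
    "AdsorbentSpec",
    "ThermoConstants",
    "PMFProfile",
    "AdsorptionRecord",
    "LogKRegression",
    "ProfileError",
    "PMFParseError",
    "DuplicateAbscissaError",
    "InsufficientDataError",
    "PlateauUnreachableError",
    "NotNormalizedError",
    "DegenerateRegressionError",
    "PlateauQualityWarning",
    "read_pmf_profile",
    "normalize_profile",
    "delta_g_md",
    "equilibrium_constant",
    "theoretical_slope",
    "regress_logk_on_deltag",
    "profile_to_record",
    "records_to_frame",
    "get_adsorbent",
]

#: Boltzmann constant, J/K.
BOLTZMANN_K = 1.381e-23
#: Molar gas constant, kcal mol⁻¹ K⁻¹.
GAS_CONSTANT_R = 1.9872e-3
#: Conventional ln(10) factor used in the decadic free-energy relation.
DECADIC_LOG = 2.303

PHASES = ("gaseous", "aqueous")


class ProfileError(ValueError):
    """Base class for malformed or mis-used PMF profiles."""


class PMFParseError(ProfileError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DuplicateAbscissaError(ProfileError):
    pass


class InsufficientDataError(ProfileError):
    pass


class PlateauUnreachableError(ProfileError):
    pass


class NotNormalizedError(RuntimeError):
    pass


class DegenerateRegressionError(ValueError):
    pass


class PlateauQualityWarning(UserWarning):
    """The far window is not flat enough to be trusted as a plateau."""


@dataclass(frozen=True)
class AdsorbentSpec:
    """An adsorbent identified by its theoretical specific surface area."""

    name: str
    specific_surface_area: float  # m²/g

    def __post_init__(self):
        if not self.specific_surface_area > 0:
            raise ValueError("specific_surface_area must be > 0")


#: Packaged defaults: layered black phosphorus and graphene.
ADSORBENTS = {
    "BP": AdsorbentSpec("BP", 2400.0),
    "graphene": AdsorbentSpec("graphene", 2630.0),
}


def get_adsorbent(name: str) -> AdsorbentSpec:
    try:
        return ADSORBENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown adsorbent {name!r}; known: {sorted(ADSORBENTS)}"
        ) from None


@dataclass(frozen=True)
class ThermoConstants:
    """Thermodynamic constants of the adsorption system.

    ``system_constant_c`` (mL/g) is the V/m constant of an experimental
    batch system entering ``logK = −ΔG/2.303RT + logC``; it is optional
    because the Boltzmann-integration route does not need it.
    """

    temperature: float = 300.0  # K
    gas_constant: float = GAS_CONSTANT_R  # kcal/(mol K)
    boltzmann_k: float = BOLTZMANN_K  # J/K
    system_constant_c: float | None = None  # mL/g

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")

    @property
    def rt(self) -> float:
        """Molar thermal energy R·T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class PMFProfile:
    """A sampled free-energy curve G(Z) for one adsorbate/phase/adsorbent.

    ``z_grid`` is strictly increasing in Å with approximately uniform
    spacing (canonically 0.05 Å bins); ``g_values`` are kcal/mol.
    """

    adsorbate_id: str
    phase: str
    adsorbent_id: str
    z_grid: np.ndarray
    g_values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        z = np.asarray(self.z_grid, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "g_values", g)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if z.ndim != 1 or g.ndim != 1 or len(z) != len(g):
            raise ProfileError("z_grid and g_values must be 1-D and equal length")
        if len(z) < 2:
            raise InsufficientDataError("profile needs at least 2 points")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise DuplicateAbscissaError("z_grid must be strictly increasing")
        ratio = dz.max() / dz.min()
        if ratio > 1.5 + 1e-9:
            raise ProfileError(
                f"grid spacing not approximately uniform (max/min ratio {ratio:.3g} > 1.5)"
            )

    def __len__(self) -> int:
        return len(self.z_grid)


@dataclass(frozen=True)
class AdsorptionRecord:
    """Per compound/phase adsorption summary derived from one PMF."""

    adsorbate_id: str
    phase: str
    delta_g_md: float  # kcal/mol
    K: float  # mL/g
    logK: float  # log10(mL/g)
    z_min: float  # Å
    e_ad: float | None = None  # kcal/mol, externally supplied DFT value


@dataclass(frozen=True)
class LogKRegression:
    slope: float
    intercept: float
    r: float
    n: int


def read_pmf_profile(
    source: str | Path | IO[str],
    *,
    adsorbate_id: str = "",
    phase: str = "aqueous",
    adsorbent_id: str = "BP",
) -> PMFProfile:
    """Parse a two-column whitespace-delimited PMF file into a profile.

    Column 1 is Z (Å), column 2 is G (kcal/mol); lines starting with
    ``#`` and blank lines are ignored.  Rows are sorted by Z; duplicate
    abscissae are rejected.  The returned profile is un-normalized.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_pmf_profile(
                fh, adsorbate_id=adsorbate_id, phase=phase, adsorbent_id=adsorbent_id
            )
    zs: list[float] = []
    gs: list[float] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PMFParseError(
                f"expected 2 columns, found {len(parts)}: {line!r}", lineno
            )
        try:
            z, g = float(parts[0]), float(parts[1])
        except ValueError:
            raise PMFParseError(f"non-numeric value in {line!r}", lineno) from None
        zs.append(z)
        gs.append(g)
    if len(zs) < 2:
        raise InsufficientDataError(f"need at least 2 data rows, found {len(zs)}")
    z_arr = np.asarray(zs)
    g_arr = np.asarray(gs)
    order = np.argsort(z_arr, kind="stable")
    z_arr, g_arr = z_arr[order], g_arr[order]
    if np.any(np.diff(z_arr) == 0):
        dup = z_arr[:-1][np.diff(z_arr) == 0][0]
        raise DuplicateAbscissaError(f"duplicate Z value {dup!r}")
    return PMFProfile(adsorbate_id, phase, adsorbent_id, z_arr, g_arr, normalized=False)


def write_pmf_profile(profile: PMFProfile, path: str | Path) -> None:
    """Write a profile in the same two-column text format read_pmf_profile reads."""
    header = (
        f"# adsorbate_id={profile.adsorbate_id} phase={profile.phase} "
        f"adsorbent_id={profile.adsorbent_id}\n# Z(A)  G(kcal/mol)\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for z, g in zip(profile.z_grid, profile.g_values):
            fh.write(f"{z:.6f} {g:.10f}\n")


def normalize_profile(
    profile: PMFProfile,
    far_window: tuple[float, float] = (14.0, 15.0),
    plateau_tol: float = 0.25,
) -> PMFProfile:
    """Shift G so its mean over ``far_window`` is zero.

    The far window is where the adsorbate no longer interacts with the
    surface; the shift is idempotent.  If the window's G standard
    deviation exceeds ``plateau_tol`` (kcal/mol) a
    :class:`PlateauQualityWarning` is emitted — the profile has not
    truly reached a plateau.
    """
    lo, hi = far_window
    mask = (profile.z_grid >= lo) & (profile.z_grid <= hi)
    n_in = int(mask.sum())
    if n_in < 3:
        raise PlateauUnreachableError(
            f"only {n_in} grid points inside far window [{lo}, {hi}] Å (need ≥ 3)"
        )
    window = profile.g_values[mask]
    if window.std() > plateau_tol:
        warnings.warn(
            f"far-window G std {window.std():.3g} kcal/mol exceeds plateau "
            f"tolerance {plateau_tol}; energies may not have reached a plateau",
            PlateauQualityWarning,
            stacklevel=2,
        )
    return replace(
        profile, g_values=profile.g_values - window.mean(), normalized=True
    )


def _require_normalized(profile: PMFProfile, op: str) -> None:
    if not profile.normalized:
        raise NotNormalizedError(
            f"{op} requires a normalized profile; call normalize_profile first"
        )


def delta_g_md(profile: PMFProfile) -> tuple[float, float]:
    """Adsorption free energy and minimum location.

    Returns ``(ΔG_MD, Z_min)`` where ``ΔG_MD = min G`` (the far plateau
    is zero by normalization).  Ties are broken toward the smallest Z.
    """
    _require_normalized(profile, "delta_g_md")
    idx = int(np.argmin(profile.g_values))  # argmin returns first minimum
    return float(profile.g_values[idx]), float(profile.z_grid[idx])


def _trapezoid_weights(z: np.ndarray) -> np.ndarray:
    dz = np.diff(z)
    w = np.empty_like(z)
    w[0] = dz[0] / 2.0
    w[-1] = dz[-1] / 2.0
    w[1:-1] = (dz[:-1] + dz[1:]) / 2.0
    return w


def equilibrium_constant(
    profile: PMFProfile,
    adsorbent: AdsorbentSpec,
    constants: ThermoConstants | None = None,
) -> tuple[float, float]:
    """Boltzmann-integrate a normalized profile into ``(K, logK)``.

    ``K = S_A ∫ exp(−G/RT) dZ`` with trapezoidal quadrature on the
    profile's own grid, evaluated in log-space so arbitrarily deep wells
    cannot overflow.  Units: S_A m²/g → ×10⁴ cm²/g, dZ Å → ×10⁻⁸ cm,
    hence K in cm³/g = mL/g.
    """
    _require_normalized(profile, "equilibrium_constant")
    constants = constants or ThermoConstants()
    rt = constants.rt
    w = _trapezoid_weights(profile.z_grid)
    # log ∫ exp(−G/RT) dZ  [Z in Å], accumulated as a log-sum-exp
    log_integral = float(logsumexp(-profile.g_values / rt + np.log(w)))
    # S_A [m²/g] × 1e4 [cm²/m²] × 1e-8 [cm/Å] = S_A × 1e-4 in cm·(cm²/g)/Å
    log10_k = (log_integral + math.log(adsorbent.specific_surface_area * 1e-4)) / math.log(10.0)
    return 10.0 ** log10_k, log10_k


def theoretical_slope(constants: ThermoConstants | None = None) -> float:
    """Theoretical slope −1/(2.303·RT) of logK versus ΔG, in mol/kcal.

    At 300 K this is −0.73 mol/kcal to two decimals.
    """
    constants = constants or ThermoConstants()
    return -1.0 / (DECADIC_LOG * constants.rt)


def regress_logk_on_deltag(records: Sequence[AdsorptionRecord]) -> LogKRegression:
    """OLS simple regression of logK on ΔG_MD across records.

    Used to check conformance of computed constants with the decadic
    free-energy relation (empirical slopes in the field are ≈ −0.7).
    """
    if len(records) < 3:
        raise DegenerateRegressionError(f"need at least 3 records, got {len(records)}")
    dg = np.array([r.delta_g_md for r in records], dtype=float)
    lk = np.array([r.logK for r in records], dtype=float)
    if np.ptp(dg) == 0:
        raise DegenerateRegressionError("zero variance in delta_g_md")
    res = stats.linregress(dg, lk)
    return LogKRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(records),
    )


def profile_to_record(
    profile: PMFProfile,
    adsorbent: AdsorbentSpec,
    constants: ThermoConstants | None = None,
    e_ad: float | None = None,
    far_window: tuple[float, float] = (14.0, 15.0),
) -> AdsorptionRecord:
    """Normalize (if needed) and reduce one profile to an AdsorptionRecord."""
    if not profile.normalized:
        profile = normalize_profile(profile, far_window=far_window)
    dg, z_min = delta_g_md(profile)
    k, logk = equilibrium_constant(profile, adsorbent, constants)
    return AdsorptionRecord(
        adsorbate_id=profile.adsorbate_id,
        phase=profile.phase,
        delta_g_md=dg,
        K=k,
        logK=logk,
        z_min=z_min,
        e_ad=e_ad,
    )


def records_to_frame(records: Iterable[AdsorptionRecord]) -> pd.DataFrame:
    """Tabulate records with the canonical column order."""
    rows = [
        {
            "adsorbate_id": r.adsorbate_id,
            "phase": r.phase,
            "z_min": r.z_min,
            "delta_g_md": r.delta_g_md,
            "K": r.K,
            "logK": r.logK,
            "e_ad": r.e_ad,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
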