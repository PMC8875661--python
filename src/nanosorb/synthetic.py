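"""Thermodynamically coherent synthetic study data.

The generator emulates the statistical structure a PMF/pp-LFER
adsorption study assumes, so every pipeline stage can be exercised and
checked against known ground truth:

* descriptor tables with realistic Abraham-descriptor ranges for small
  aliphatic/aromatic organics and the strong L–V collinearity real
  compounds exhibit (Gaussian-copula coupled uniforms);
* logK and |E_ad| endpoints with exact pp-LFER structure (defaulting to
  the packaged BP reference coefficients) plus Gaussian noise tuned so
  a refit attains R² ≈ 0.9;
* ΔG endpoints linked to logK through the decadic relation
  ``ΔG = (logK − logC)/slope`` with the theoretical slope
  −1/(2.303RT) and intercept −1.0, and the gaseous-vs-aqueous gap
  clipped into the 1.6–6.1 kcal/mol window (gaseous adsorption is
  always the more favorable);
* V-shaped PMF profiles (Gaussian well at Z = 4.4 Å plus an
  exponential repulsive wall) whose grid minimum is exactly the
  requested ΔG and whose far tail sits on a zero plateau.

Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .lfer import PPLFERModel, predict
from .pmf import PMFProfile, ThermoConstants, theoretical_slope

__all__ = [
    "DEFAULT_DESCRIPTOR_RANGES",
    "WellShape",
    "GeneratorConfig",
    "SyntheticDataset",
    "SyntheticStudy",
    "generate_descriptor_table",
    "generate_endpoints",
    "generate_pmf",
    "simulate_study",
    "write_study",
]

DEFAULT_DESCRIPTOR_RANGES = {
    "E": (0.0, 3.0),
    "S": (0.0, 2.0),
    "A": (0.0, 1.0),
    "B": (0.0, 1.2),
    "V": (0.3, 1.8),
    "L": (1.0, 10.0),
}


@dataclass(frozen=True)
class WellShape:
    """Geometry of the synthetic V-shaped free-energy well.

    ``thermal_width`` is the effective Boltzmann width
    ``w_eff = ∫ exp(−(G−G_min)/RT) dZ`` of the well in the harmonic
    approximation; it fixes the well curvature ``κ = 2π·RT/w_eff²`` so
    that wells of different depth stay congruent.  0.42 Å reproduces a
    theoretical logK-vs-ΔG intercept of log10(S_A·w_eff) ≈ −1.0 for
    S_A = 2400 m²/g.
    """

    center_z: float = 4.4  # Å
    thermal_width: float = 0.42  # Å
    z_lo: float = 3.0  # Å
    z_hi: float = 15.0  # Å
    dz: float = 0.05  # Å
    noise_sd: float = 0.05  # kcal/mol, i.i.d. on G
    wall_height: float = 25.0  # kcal/mol at z_lo
    wall_decay: float = 0.25  # Å

    def grid(self) -> np.ndarray:
        n = int(round((self.z_hi - self.z_lo) / self.dz)) + 1
        return self.z_lo + self.dz * np.arange(n)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    n_compounds: int = 41
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    lv_correlation: float = 0.8
    true_models: dict[str, PPLFERModel] | None = None  # None → packaged reference
    noise_sd: dict[str, float] | None = None  # None → tuned for target_r2
    target_r2: float = 0.9
    link_intercept: float = -1.0  # logC of the decadic relation
    temperature: float = 300.0  # K
    gap_bounds: tuple[float, float] = (1.6, 6.1)  # kcal/mol
    well: WellShape = field(default_factory=WellShape)

    def __post_init__(self):
        for name, (lo, hi) in self.descriptor_ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not abs(self.lv_correlation) < 1:
            raise ValueError("|lv_correlation| must be < 1")
        if self.noise_sd is not None and any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise sds must be ≥ 0")
        if not 0 < self.target_r2 <= 1:
            raise ValueError("target_r2 must be in (0, 1]")

    def resolved_models(self) -> dict[str, PPLFERModel]:
        if self.true_models is not None:
            return self.true_models
        from .fixtures import reference_models

        return reference_models()

    def resolved_noise_sd(self) -> dict[str, float]:
        """Endpoint noise, analytic: sd = √(var_signal·(1−R²)/R²).

        The signal variance of a linear model over independent uniform
        descriptors is Σ coef²·(hi−lo)²/12 (the L–V coupling does not
        enter because each model uses only one of V, L).
        """
        if self.noise_sd is not None:
            return self.noise_sd
        out = {}
        for key, model in self.resolved_models().items():
            var = sum(
                model.coefficients[d] ** 2
                * (self.descriptor_ranges[d][1] - self.descriptor_ranges[d][0]) ** 2
                / 12.0
                for d in model.descriptor_set
            )
            out[key] = math.sqrt(var * (1.0 - self.target_r2) / self.target_r2)
        return out


@dataclass
class SyntheticDataset:
    """Descriptor/endpoint table plus generating ground truth."""

    table: pd.DataFrame  # descriptors + endpoint columns, indexed by compound_id
    truth: pd.DataFrame  # noiseless endpoint predictions + implied t_delta_s
    n_clipped: int  # compounds whose ΔG gap was clipped into the window
    config: GeneratorConfig


@dataclass
class SyntheticStudy:
    dataset: SyntheticDataset
    profiles: dict[tuple[str, str], PMFProfile]  # (compound_id, phase) → PMF


def generate_descriptor_table(
    config: GeneratorConfig, seed: int = 0
) -> pd.DataFrame:
    """Draw a descriptor table: uniforms within ranges, L coupled to V.

    The L–V pair is drawn from a Gaussian copula; the normal correlation
    is set to ``2·sin(π·ρ/6)`` so the *uniform* marginals attain the
    configured Pearson correlation ρ.
    """
    rng = np.random.default_rng(seed)
    n = config.n_compounds
    ids = [f"C{i + 1:03d}" for i in range(n)]
    cols = {}
    for name in ("E", "S", "A", "B"):
        lo, hi = config.descriptor_ranges[name]
        cols[name] = rng.uniform(lo, hi, n)
    rho_normal = 2.0 * math.sin(math.pi * config.lv_correlation / 6.0)
    cov = [[1.0, rho_normal], [rho_normal, 1.0]]
    zz = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    uu = norm.cdf(zz)
    for name, u in zip(("V", "L"), uu.T):
        lo, hi = config.descriptor_ranges[name]
        cols[name] = lo + (hi - lo) * u
    df = pd.DataFrame(cols, index=pd.Index(ids, name="compound_id"))
    return df


def generate_endpoints(
    table: pd.DataFrame, config: GeneratorConfig, seed: int = 0
) -> SyntheticDataset:
    """Fill endpoint columns with pp-LFER structure plus tuned noise.

    logK and |E_ad| endpoints are exact linear predictions of the
    configured true models plus Gaussian noise.  ΔG endpoints invert
    the decadic relation from the logK columns; the per-compound
    gaseous-minus-aqueous advantage is clipped into ``gap_bounds`` (the
    ΔG columns only — the logK columns keep their linear structure).
    The implied entropic term TΔS = E_ad − ΔG_aq is stored as truth.
    """
    rng = np.random.default_rng(seed)
    models = config.resolved_models()
    noise = config.resolved_noise_sd()
    out = table.copy()
    truth = pd.DataFrame(index=table.index)
    for key in ("logK_gaseous", "logK_aqueous", "absEad_gaseous", "absEad_aqueous"):
        mu = np.asarray(predict(models[key], table), dtype=float)
        truth[key] = mu
        out[key] = mu + rng.normal(0.0, noise[key], len(table))

    slope = theoretical_slope(ThermoConstants(temperature=config.temperature))
    dg_aq = (out["logK_aqueous"] - config.link_intercept) / slope
    dg_gas = (out["logK_gaseous"] - config.link_intercept) / slope
    gap = dg_aq - dg_gas  # gaseous advantage, should be positive
    lo, hi = config.gap_bounds
    clipped = np.clip(gap, lo, hi)
    n_clipped = int((clipped != gap).sum())
    out["deltaG_aqueous"] = dg_aq
    out["deltaG_gaseous"] = dg_aq - clipped
    truth["t_delta_s"] = (-out["absEad_aqueous"]) - out["deltaG_aqueous"]
    return SyntheticDataset(table=out, truth=truth, n_clipped=n_clipped, config=config)


def generate_pmf(
    delta_g_target: float,
    well: WellShape | None = None,
    temperature: float = 300.0,
    rng: np.random.Generator | None = None,
) -> PMFProfile:
    """Build a V-shaped PMF whose grid minimum is exactly the target ΔG.

    The profile is a Gaussian well centered at ``well.center_z`` with
    curvature fixed by ``well.thermal_width`` plus an exponential
    repulsive wall at the low-Z edge; the depth is solved (scalar root
    find on the grid minimum) so that ``min G = delta_g_target`` before
    the optional i.i.d. Gaussian noise is added.  The far tail is a
    zero plateau, so normalization is a no-op up to noise.
    """
    if delta_g_target > 1e-12:
        raise ValueError(f"delta_g_target must be ≤ 0, got {delta_g_target}")
    well = well or WellShape()
    rt = ThermoConstants(temperature=temperature).rt
    z = well.grid()
    wall = well.wall_height * np.exp(-(z - well.z_lo) / well.wall_decay)
    kappa = 2.0 * math.pi * rt / well.thermal_width**2  # kcal/mol/Å²

    def profile_for(depth: float) -> np.ndarray:
        if depth == 0.0:
            return wall.copy()
        sigma = math.sqrt(-depth / kappa)
        return depth * np.exp(-((z - well.center_z) ** 2) / (2.0 * sigma**2)) + wall

    if delta_g_target == 0.0:
        g = wall.copy()
    else:

        def objective(depth: float) -> float:
            return float(profile_for(depth).min()) - delta_g_target

        d_lo = delta_g_target - well.wall_height - 1.0
        depth = brentq(objective, d_lo, 0.0, xtol=1e-13)
        g = profile_for(depth)

    if rng is not None and well.noise_sd > 0:
        g = g + rng.normal(0.0, well.noise_sd, len(z))
    return PMFProfile(
        adsorbate_id="",
        phase="aqueous",
        adsorbent_id="BP",
        z_grid=z,
        g_values=g,
        normalized=False,
    )


def simulate_study(config: GeneratorConfig, seed: int = 0) -> SyntheticStudy:
    """Generate a full coherent study: table, endpoints and PMF profiles.

    One PMF per compound and phase is built with the compound's ΔG
    endpoint as the well-depth target; profiles inherit the configured
    noise.  Deterministic per seed (profiles are drawn in sorted
    compound/phase order from a single stream).
    """
    table = generate_descriptor_table(config, seed)
    dataset = generate_endpoints(table, config, seed + 1)
    rng = np.random.default_rng(seed + 2)
    profiles: dict[tuple[str, str], PMFProfile] = {}
    for cid in dataset.table.index:
        for phase, col in (("gaseous", "deltaG_gaseous"), ("aqueous", "deltaG_aqueous")):
            target = min(0.0, float(dataset.table.loc[cid, col]))
            prof = generate_pmf(
                target, well=config.well, temperature=config.temperature, rng=rng
            )
            profiles[(cid, phase)] = replace(
                prof, adsorbate_id=cid, phase=phase
            )
    return SyntheticStudy(dataset=dataset, profiles=profiles)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write a study to disk in the formats the ingestion ops read.

    Emits ``descriptors.csv`` (descriptors + endpoints), one PMF text
    file per compound/phase under ``pmf/``, and ``manifest.csv`` mapping
    (adsorbate_id, phase, adsorbent_id) to the PMF path.  Returns the
    artifact paths.
    """
    from pathlib import Path

    from .pmf import write_pmf_profile

    outdir = Path(outdir)
    pmf_dir = outdir / "pmf"
    pmf_dir.mkdir(parents=True, exist_ok=True)
    desc_path = outdir / "descriptors.csv"
    study.dataset.table.to_csv(desc_path)
    rows = []
    for (cid, phase), prof in sorted(study.profiles.items()):
        path = pmf_dir / f"{cid}_{phase}.dat"
        write_pmf_profile(prof, path)
        rows.append(
            {
                "adsorbate_id": cid,
                "phase": phase,
                "adsorbent_id": prof.adsorbent_id,
                "path": str(path),
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return {"descriptors": str(desc_path), "manifest": str(manifest_path)}
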