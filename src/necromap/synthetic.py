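"""Synthetic alpine-grassland landscape with planted ground truth.

Emulates the inputs of a plateau-scale necromass survey: a point set of
sites split into alpine meadow (wetter, warmer, more productive, further
east) and alpine steppe (drier, colder) classes; environmental covariates
drawn from class-conditional Gaussians sharing a low-rank east-west
longitude trend; phylotype relative-abundance tables in which planted
"eco-cluster" members respond monotonically to known environmental drivers;
amino-sugar profiles back-solved so that the implied necromass carbon (MNC)
is a known linear function of cluster abundances, NDVI and soil texture plus
Gaussian noise; and a climate-perturbation helper for warming scenarios.

Every generator takes an explicit seed and is bit-reproducible. The planted
structure (cluster membership, driver responses, MNC weights, seed) is
returned as a :class:`GroundTruth` so downstream inference can be scored
against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ConversionCoefficients

__all__ = [
    "ENV_VARIABLES",
    "ClusterSpec",
    "GroundTruth",
    "GenerationInfeasibleError",
    "default_cluster_specs",
    "default_mnc_coefficients",
    "generate_environment",
    "generate_phylotypes",
    "generate_amino_sugars",
    "scenario_perturb",
    "aridity_index",
]

#: Environmental covariates carried by a site table (besides coordinates and class).
ENV_VARIABLES = (
    "MAT", "MAP", "AI", "NDVI", "NPP", "elevation",
    "SOC", "TN", "TP", "TK", "pH",
    "silt", "clay", "sand", "cf", "BD", "thickness", "cec",
)

# (meadow mean, steppe mean, within-class sd, loading on the shared
# standardized-longitude factor). Values are plausible alpine-grassland
# magnitudes: meadows sit in the wetter/warmer east, steppes in the
# drier/colder west.
_FIELD_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "MAT": (0.5, -2.5, 1.2, 0.8),        # degC
    "MAP": (500.0, 250.0, 70.0, 50.0),   # mm/yr
    "NDVI": (0.55, 0.25, 0.07, 0.04),    # [-1, 1]
    "NPP": (300.0, 120.0, 50.0, 30.0),   # gC/m2/yr
    "elevation": (3800.0, 4700.0, 280.0, -180.0),  # m
    "SOC": (45.0, 15.0, 9.0, 4.0),       # g/kg
    "TN": (3.5, 1.2, 0.7, 0.3),          # g/kg
    "TP": (0.7, 0.5, 0.12, 0.04),        # g/kg
    "TK": (18.0, 20.0, 2.5, 0.0),        # g/kg
    "pH": (6.8, 8.3, 0.35, -0.2),
    "cf": (10.0, 20.0, 4.0, -2.5),       # % gravel > 2 mm
    "BD": (1.0, 1.4, 0.12, -0.05),       # g/cm3
    "thickness": (50.0, 25.0, 8.0, 4.0),  # cm
    "cec": (20.0, 10.0, 3.5, 1.5),       # cmol/kg
}

# Texture composition targets (sand, silt, clay fractions) per class;
# drawn from a Dirichlet so the three always sum to 100%.
_TEXTURE_ALPHA = {
    "meadow": np.array([0.35, 0.45, 0.20]) * 40.0,
    "steppe": np.array([0.60, 0.28, 0.12]) * 40.0,
}

#: PET proxy: PET(mm/yr) = intercept + slope * MAT(degC), floored.
PET_INTERCEPT = 600.0
PET_SLOPE = 40.0
PET_FLOOR = 100.0


def aridity_index(map_mm: np.ndarray, mat_c: np.ndarray) -> np.ndarray:
    """AI = MAP / PET with a linear PET-in-MAT proxy, so AI responds to warming."""
    pet = np.maximum(PET_INTERCEPT + PET_SLOPE * np.asarray(mat_c, float), PET_FLOOR)
    return np.asarray(map_mm, float) / pet


class GenerationInfeasibleError(ValueError):
    """Planted MNC weights imply negative concentrations beyond clamp tolerance."""


@dataclass(frozen=True)
class ClusterSpec:
    """One planted eco-cluster: member count and environmental drivers.

    ``drivers`` is a sequence of ``(variable, sign, effect_size)`` where sign
    is +1/-1 and effect_size scales the response of member log-abundance to
    the standardized driver.
    """

    n_members: int
    drivers: tuple[tuple[str, int, float], ...]
    name: str | None = None

    def label(self) -> str:
        if self.name:
            return self.name
        parts = []
        for var, sign, _ in self.drivers:
            disp = "ele" if var == "elevation" else var
            parts.append(("H" if sign > 0 else "L") + disp)
        return "&".join(parts)


@dataclass
class GroundTruth:
    """Planted structure: who belongs where, what drives whom, and the MNC law."""

    cluster_membership: dict[str, str]  # phylotype -> cluster label or "background"
    driver_spec: dict[str, tuple[tuple[str, int, float], ...]]  # cluster -> drivers
    mnc_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0        # mg/g
    fb_ratio: float = 3.0        # fungal:bacterial necromass-C split
    seed: int = 0

    def cluster_names(self) -> list[str]:
        return list(self.driver_spec)

    def members(self, cluster: str) -> list[str]:
        return [p for p, c in self.cluster_membership.items() if c == cluster]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["driver_spec"] = {k: [list(t) for t in v] for k, v in d["driver_spec"].items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["driver_spec"] = {
            k: tuple((v0, int(v1), float(v2)) for v0, v1, v2 in v)
            for k, v in d["driver_spec"].items()
        }
        return cls(**d)


def default_cluster_specs() -> list[ClusterSpec]:
    """Two planted clusters mirroring common alpine habitat preferences:
    a wet-cold cluster (high MAP, low MAT) and a high-elevation cluster."""
    return [
        ClusterSpec(n_members=5, drivers=(("MAP", 1, 1.5), ("MAT", -1, 1.5))),
        ClusterSpec(n_members=5, drivers=(("elevation", 1, 1.5),)),
    ]


def default_mnc_coefficients(cluster_names: list[str]) -> dict[str, float]:
    """Linear MNC law: strong positive weight on the first cluster, weaker
    negative on the second, NDVI and silt terms, intercept in mg/g."""
    coef = {"intercept": 6.0, "NDVI": 12.0, "silt": 0.05}
    weights = [30.0, -6.0, 8.0, -4.0]
    for name, w in zip(cluster_names, weights):
        coef[name] = w
    return coef


def generate_environment(
    n_sites: int,
    seed: int,
    class_split: float = 0.48,
) -> pd.DataFrame:
    """Draw a site table of ``n_sites`` alpine-grassland points.

    ``class_split`` is the meadow fraction; meadow count = round(split * n).
    Meadow sites are drawn with higher MAP/NDVI/AI than steppe sites, and all
    fields share a low-rank standardized-longitude factor to mimic the
    east-west gradient. Deterministic for a fixed seed.
    """
    if n_sites < 4:
        raise ValueError(f"n_sites must be >= 4, got {n_sites}")
    rng = np.random.default_rng(seed)
    n_meadow = int(round(class_split * n_sites))
    n_meadow = min(max(n_meadow, 1), n_sites - 1)
    classes = np.array(["meadow"] * n_meadow + ["steppe"] * (n_sites - n_meadow))

    lon = np.where(
        classes == "meadow",
        rng.normal(97.0, 2.5, n_sites),
        rng.normal(85.0, 3.5, n_sites),
    )
    lat = rng.normal(32.5, 2.0, n_sites)
    g = (lon - lon.mean()) / max(lon.std(), 1e-9)  # shared east-west factor

    data: dict[str, np.ndarray] = {
        "site_id": np.array([f"S{i + 1:04d}" for i in range(n_sites)]),
        "lon": lon,
        "lat": lat,
        "grassland_class": classes,
    }
    is_meadow = classes == "meadow"
    for var, (mu_m, mu_s, sd, load) in _FIELD_PARAMS.items():
        mu = np.where(is_meadow, mu_m, mu_s)
        data[var] = mu + load * g + rng.normal(0.0, sd, n_sites)

    # texture: Dirichlet within class so sand+silt+clay == 100 exactly
    tex = np.empty((n_sites, 3))
    for cls in ("meadow", "steppe"):
        mask = classes == cls
        tex[mask] = rng.dirichlet(_TEXTURE_ALPHA[cls], size=int(mask.sum())) * 100.0
    data["sand"], data["silt"], data["clay"] = tex[:, 0], tex[:, 1], tex[:, 2]

    data["NDVI"] = np.clip(data["NDVI"], -1.0, 1.0)
    for var in ("MAP", "NPP", "SOC", "TN", "TP", "TK", "cf", "BD", "thickness", "cec"):
        data[var] = np.maximum(data[var], 0.01)
    data["pH"] = np.clip(data["pH"], 3.0, 10.5)
    data["AI"] = aridity_index(data["MAP"], data["MAT"])

    cols = ["site_id", "lon", "lat", "grassland_class", *ENV_VARIABLES]
    return pd.DataFrame({c: data[c] for c in cols})


def generate_phylotypes(
    env: pd.DataFrame,
    n_phylotypes: int,
    cluster_specs: list[ClusterSpec] | None = None,
    seed: int = 0,
    member_noise_sd: float = 0.4,
    background_dropout: float = 0.25,
    kingdom: str = "bacteria",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a samples x phylotypes relative-abundance table with planted
    eco-cluster structure.

    Members of a planted cluster share a monotone log-linear response to that
    cluster's standardized driver(s) and carry a dominance boost so they pass
    abundance filters; background phylotypes are driver-independent noise,
    and a fraction of their entries is zeroed to emulate patchy occupancy.
    Rows are renormalized to relative abundances summing to 1.
    """
    specs = cluster_specs if cluster_specs is not None else default_cluster_specs()
    for s in specs:
        if s.n_members < 2:
            raise ValueError(f"cluster {s.label()!r} needs >= 2 members, got {s.n_members}")
    n_planted = sum(s.n_members for s in specs)
    if n_planted > n_phylotypes:
        raise ValueError("n_phylotypes smaller than total planted members")

    rng = np.random.default_rng(seed)
    n_sites = len(env)
    prefix = "bOTU" if kingdom == "bacteria" else "fOTU"
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_phylotypes)]

    z = {}
    for var in ENV_VARIABLES:
        x = env[var].to_numpy(dtype=float)
        z[var] = (x - x.mean()) / max(x.std(), 1e-9)

    latent = np.empty((n_sites, n_phylotypes))
    membership: dict[str, str] = {}
    driver_spec: dict[str, tuple[tuple[str, int, float], ...]] = {}
    j = 0
    for spec in specs:
        label = spec.label()
        driver_spec[label] = tuple(spec.drivers)
        response = np.zeros(n_sites)
        for var, sign, effect in spec.drivers:
            response += effect * sign * z[var]
        for _ in range(spec.n_members):
            base = rng.normal(2.0, 0.3)
            latent[:, j] = base + response + rng.normal(0.0, member_noise_sd, n_sites)
            membership[ids[j]] = label
            j += 1
    for jj in range(j, n_phylotypes):
        base = rng.normal(0.0, 0.8)
        latent[:, jj] = base + rng.normal(0.0, 1.0, n_sites)
        membership[ids[jj]] = "background"

    abund = np.exp(latent)
    if j < n_phylotypes and background_dropout > 0:
        drop = rng.random((n_sites, n_phylotypes - j)) < background_dropout
        abund[:, j:][drop] = 0.0
    abund /= abund.sum(axis=1, keepdims=True)

    table = pd.DataFrame(abund, index=env["site_id"].to_numpy(), columns=ids)
    table.index.name = "site_id"
    truth = GroundTruth(
        cluster_membership=membership,
        driver_spec=driver_spec,
        seed=seed,
    )
    return table, truth


def generate_amino_sugars(
    env: pd.DataFrame,
    cluster_abund: pd.DataFrame,
    truth: GroundTruth,
    seed: int | None = None,
    coefficients: ConversionCoefficients | None = None,
    clamp_tol: float = 1e-6,
) -> pd.DataFrame:
    """Back-solve amino-sugar concentrations so the implied MNC follows the
    planted linear law ``truth.mnc_coefficients`` plus N(0, noise_sd) noise.

    The target MNC is split into fungal and bacterial pools at the fixed
    ``truth.fb_ratio``; MurA and GluN are then inverted through the standard
    conversion so the chemistry round-trips exactly. GalN and ManN are
    nuisance columns uncorrelated with MNC.
    """
    if len(cluster_abund) != len(env):
        raise ValueError("cluster_abund rows must align with env sites")
    coef = dict(truth.mnc_coefficients) or default_mnc_coefficients(
        truth.cluster_names())
    c = coefficients or ConversionCoefficients()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    mnc = np.full(len(env), coef.get("intercept", 0.0), dtype=float)
    for key, w in coef.items():
        if key == "intercept":
            continue
        if key in cluster_abund.columns:
            mnc += w * cluster_abund[key].to_numpy(dtype=float)
        elif key in env.columns:
            mnc += w * env[key].to_numpy(dtype=float)
        else:
            raise KeyError(f"MNC coefficient {key!r} matches no cluster or env column")
    # infeasibility is judged on the deterministic part: noise is clamped at 0
    if mnc.min() < -max(clamp_tol, 0.25):
        raise GenerationInfeasibleError(
            f"planted weights imply MNC as low as {mnc.min():.3g} mg/g; "
            "reduce negative weights or raise the intercept"
        )
    mnc = np.maximum(mnc, 0.0)
    if truth.noise_sd > 0:
        mnc = np.maximum(mnc + rng.normal(0.0, truth.noise_sd, len(env)), 0.0)

    r = truth.fb_ratio
    fungal = mnc * r / (1.0 + r)
    bacterial = mnc / (1.0 + r)
    mura = bacterial / c.bacterial_factor
    # invert fungal C = (GluN/mmG - 2 MurA/mmM) * mmG * f
    glun = fungal / c.fungal_factor + 2.0 * mura * c.glun_molar_mass / c.mura_molar_mass

    out = pd.DataFrame(
        {
            "site_id": env["site_id"].to_numpy(),
            "GluN": glun,
            "GalN": rng.lognormal(-1.0, 0.4, len(env)),
            "MurA": mura,
            "ManN": rng.lognormal(-2.5, 0.4, len(env)),
        }
    )
    return out


def scenario_perturb(
    env: pd.DataFrame,
    delta_mat: float = 0.0,
    delta_map_frac: float = 0.0,
    recompute_ai: bool = True,
) -> pd.DataFrame:
    """Return a copy of ``env`` under a climate perturbation.

    MAT is shifted by ``delta_mat`` degC, MAP multiplied by
    ``1 + delta_map_frac``; AI is recomputed from the perturbed climate by
    default (set ``recompute_ai=False`` to hold it at current values). All
    other columns are untouched, matching a projection in which soil
    properties are kept at their current values.
    """
    out = env.copy()
    out["MAT"] = out["MAT"] + delta_mat
    out["MAP"] = out["MAP"] * (1.0 + delta_map_frac)
    if recompute_ai:
        out["AI"] = aridity_index(out["MAP"].to_numpy(), out["MAT"].to_numpy())
    return out
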