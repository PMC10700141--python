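"""Synthetic global forcing and diversity series.

The generator stands in for palaeo-elevation and palaeo-runoff
reconstructions: continents come from band-limited spherical-harmonic
noise (degrees 2-8) thresholded to a target land fraction; ridge-like
orogens (peak heights 1-5 km) and crater-like closed depressions are
superimposed; runoff combines a zonal Hadley-like profile (wet tropics,
dry subtropics, mid-latitude storm tracks) with windward orographic
enhancement and weak noise, clamped non-negative.  Successive time slices
are smooth AR(1) perturbations of the previous one, so sequences have the
temporal coherence the downstream workflow assumes.

Diversity time series are drawn from the linear response structure the
analysis fits downstream: response = intercept + b_pvar*PVAR +
b_scov*SCOV + Gaussian noise, affinely rescaled to a count-like positive
range with the generating coefficients and the rescaling recorded in
metadata.

All randomness is driven by explicit integer seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .mesh import SphericalMesh, weighted_quantile


@dataclass
class TimeSliceForcing:
    """One reconstruction epoch on the mesh."""

    age: float  # Ma
    elevation: np.ndarray  # m, negative below sea level
    runoff: np.ndarray  # m/yr, >= 0
    sea_level: float = 0.0  # m

    def __post_init__(self):
        if np.any(self.runoff < 0):
            raise ValueError("runoff must be non-negative")

    @property
    def land_mask(self) -> np.ndarray:
        return self.elevation > self.sea_level

    def land_fraction(self, mesh: SphericalMesh) -> float:
        return float(mesh.cell_area[self.land_mask].sum() / mesh.cell_area.sum())


@dataclass
class DiversitySeries:
    """Diversity counts per group along a (strictly monotone) age axis."""

    age: np.ndarray  # Ma
    counts: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.diff(self.age)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ages must be strictly monotone")
        for g, c in self.counts.items():
            if np.any(np.asarray(c) < 0):
                raise ValueError(f"counts for group {g!r} must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, c in self.counts.items():
            rows.append(pd.DataFrame({"age_Ma": self.age, "group": g, "count": c}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def response(self, group: str) -> np.ndarray:
        """Invert the count rescaling back to the generating linear response."""
        meta = self.metadata[group]
        return (self.counts[group] - meta["count_offset"]) / meta["count_scale"]


# ---------------------------------------------------------------------------
# random fields on the sphere
# ---------------------------------------------------------------------------


def _harmonic_basis(mesh: SphericalMesh, lmin: int = 2, lmax: int = 8) -> np.ndarray:
    """Real spherical-harmonic basis columns evaluated at the nodes."""
    lon = np.radians(mesh.node_lonlat[:, 0])
    colat = np.radians(90.0 - mesh.node_lonlat[:, 1])
    cols = []
    for l in range(lmin, lmax + 1):
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, colat, lon)
            cols.append(y.real)
            if m > 0:
                cols.append(y.imag)
    return np.column_stack(cols)


def _basis_cache(mesh: SphericalMesh, lmin: int, lmax: int) -> np.ndarray:
    key = (lmin, lmax)
    cache = getattr(mesh, "_harm_cache", None)
    if cache is None:
        cache = {}
        mesh._harm_cache = cache
    if key not in cache:
        cache[key] = _harmonic_basis(mesh, lmin, lmax)
    return cache[key]


def _coef_spectrum(lmin: int, lmax: int, alpha: float = 1.5) -> np.ndarray:
    s = []
    for l in range(lmin, lmax + 1):
        n = 2 * l + 1
        s.extend([l ** (-alpha)] * n)
    return np.asarray(s)


def random_harmonic_field(
    mesh: SphericalMesh,
    rng: np.random.Generator,
    lmin: int = 2,
    lmax: int = 8,
    coeffs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited Gaussian random field; returns (field, coefficients)."""
    basis = _basis_cache(mesh, lmin, lmax)
    if coeffs is None:
        coeffs = rng.standard_normal(basis.shape[1]) * _coef_spectrum(lmin, lmax)
    f = basis @ coeffs
    w = mesh.cell_area / mesh.cell_area.sum()
    f = f - (w * f).sum()
    sd = np.sqrt((w * f**2).sum())
    return f / max(sd, 1e-30), coeffs


# ---------------------------------------------------------------------------
# forcing sequence
# ---------------------------------------------------------------------------

_GREAT_CIRCLE_SAMPLES = 48


def _angular_distance_to_arc(
    unit: np.ndarray, anchor: np.ndarray, tangent: np.ndarray, half_length: float
) -> np.ndarray:
    """Min angular distance (rad) from each unit vector to a great-circle arc."""
    s = np.linspace(-half_length, half_length, _GREAT_CIRCLE_SAMPLES)
    pts = np.outer(np.cos(s), anchor) + np.outer(np.sin(s), tangent)
    dots = np.clip(unit @ pts.T, -1.0, 1.0)
    return np.arccos(dots.max(axis=1))


def _random_land_point(rng, unit, land_score):
    idx = np.flatnonzero(land_score > np.quantile(land_score, 0.7))
    return unit[rng.choice(idx)]


def _zonal_runoff(lat_deg: np.ndarray, amplitude: float) -> np.ndarray:
    """Hadley-like zonal profile: wet tropics, dry subtropics, wet mid-lats."""
    lat = np.abs(lat_deg)
    return amplitude * (
        1.5 * np.exp(-((lat / 12.0) ** 2))
        + 0.7 * np.exp(-(((lat - 48.0) / 14.0) ** 2))
        + 0.08
    )


DEFAULT_FORCING_PARAMS = dict(
    n_slices=1,
    land_fraction_target=0.3,
    orogen_count=2,
    depression_count=2,
    runoff_zonal_amplitude=1.0,
    orographic_gain=20.0,  # m/yr of extra runoff per unit windward slope
    land_scale=800.0,  # m, sets the land hypsometry scale
    ocean_depth=4500.0,  # m
    ar_coherence=0.99,  # AR(1) coefficient linking successive slices
    age_start=100.0,  # Ma of the first slice
    age_step=5.0,  # Myr between slices
    runoff_noise=0.05,  # m/yr
)


def generate_forcing_sequence(params: dict | None = None, seed: int = 0) -> list:
    """Generate a temporally coherent sequence of TimeSliceForcing.

    See DEFAULT_FORCING_PARAMS for the tunables.  The same seed yields
    bit-identical output.  Requires a mesh under params["mesh"] or builds
    one at params["subdivision_level"] (default 6).
    """
    p = dict(DEFAULT_FORCING_PARAMS)
    if params:
        p.update(params)
    if not (0.05 < p["land_fraction_target"] < 0.6):
        raise ValueError("land_fraction_target must be in (0.05, 0.6)")
    if p["n_slices"] < 1:
        raise ValueError("n_slices must be >= 1")

    mesh: SphericalMesh = p.get("mesh")
    if mesh is None:
        from .mesh import build_icosphere

        mesh = build_icosphere(p.get("subdivision_level", 6))

    rng = np.random.default_rng(seed)
    unit = mesh.node_coords / mesh.radius
    lat = mesh.node_lonlat[:, 1]
    w = mesh.cell_area / mesh.cell_area.sum()

    base, coeffs = random_harmonic_field(mesh, rng)

    # fixed orogen and depression geometry for the whole sequence
    orogens = []
    for _ in range(int(p["orogen_count"])):
        anchor = _random_land_point(rng, unit, base)
        t = rng.standard_normal(3)
        t -= anchor * (t @ anchor)
        t /= np.linalg.norm(t)
        orogens.append(
            dict(
                anchor=anchor,
                tangent=t,
                half_length=np.radians(rng.uniform(10.0, 25.0)),
                width=np.radians(rng.uniform(2.0, 3.5)),
                height=rng.uniform(1000.0, 5000.0),
            )
        )
    # depression centers: on solid land, clear of the orogen belts and of
    # each other, so the constructed pit is a genuine closed local minimum
    depressions = []
    cand = np.flatnonzero(base > np.quantile(base, 0.75))
    cand = cand[rng.permutation(cand.size)]
    for c in cand:
        if len(depressions) >= int(p["depression_count"]):
            break
        pos = unit[c]
        rim_radius = np.radians(rng.uniform(3.0, 5.0))
        ok = True
        for o in orogens:
            d = _angular_distance_to_arc(pos[None, :], o["anchor"], o["tangent"],
                                         o["half_length"])[0]
            if d < 2.5 * o["width"] + rim_radius + np.radians(2.0):
                ok = False
                break
        for dep in depressions:
            sep = np.arccos(np.clip(pos @ dep["center"], -1, 1))
            if sep < 2.5 * (rim_radius + dep["rim_radius"]):
                ok = False
                break
        if not ok:
            continue
        depressions.append(
            dict(
                center=pos,
                rim_radius=rim_radius,
                rim_width=np.radians(1.2),
                rim_height=rng.uniform(600.0, 1000.0),
                pit_depth=rng.uniform(250.0, 450.0),
            )
        )
    if len(depressions) < int(p["depression_count"]):
        raise ValueError(
            f"could not place {p['depression_count']} depressions on land; "
            f"placed {len(depressions)} (raise land_fraction_target or lower counts)"
        )

    rho = float(p["ar_coherence"])
    spectrum = _coef_spectrum(2, 8)
    slices = []
    for k in range(int(p["n_slices"])):
        if k > 0:
            coeffs = rho * coeffs + np.sqrt(1 - rho**2) * (
                rng.standard_normal(coeffs.size) * spectrum
            )
        f, _ = random_harmonic_field(mesh, rng, coeffs=coeffs)

        thr = weighted_quantile(f, [1.0 - p["land_fraction_target"]], w)[0]
        land = f > thr
        achieved = float(w[land].sum())
        if abs(achieved - p["land_fraction_target"]) > 0.02:
            raise ValueError(
                f"land_fraction_target {p['land_fraction_target']} unreachable; "
                f"achieved {achieved:.3f}"
            )
        s_land = max((w[land] * (f[land] - thr)).sum() / max(w[land].sum(), 1e-12), 1e-6)
        s_oc = max((w[~land] * (thr - f[~land])).sum() / max(w[~land].sum(), 1e-12), 1e-6)
        z = np.where(
            land,
            p["land_scale"] * (f - thr) / s_land,
            -p["ocean_depth"] * (thr - f) / s_oc,
        )
        z = np.clip(z, -6500.0, None)

        land_taper = np.clip((f - thr) / (0.5 * s_land), 0.0, 1.0)
        for o in orogens:
            d = _angular_distance_to_arc(unit, o["anchor"], o["tangent"], o["half_length"])
            z += o["height"] * np.exp(-((d / o["width"]) ** 2)) * land_taper
        for dep in depressions:
            d = np.arccos(np.clip(unit @ dep["center"], -1.0, 1.0))
            r0 = dep["rim_radius"]
            rim = dep["rim_height"] * np.exp(-(((d - r0) / dep["rim_width"]) ** 2))
            pit = dep["pit_depth"] * np.exp(-((d / (0.45 * r0)) ** 2))
            z += rim - pit
            # enforce a closed pit: the crater floor must sit strictly below
            # the lowest point of the surrounding ring (still above sea level)
            inside = d < 0.4 * r0
            ring = (d >= 0.4 * r0) & (d < 1.2 * r0)
            if inside.any() and ring.any():
                ring_min = float(z[ring].min())
                ceiling = ring_min - 50.0 * (1.0 + (0.4 * r0 - d[inside]) / (0.4 * r0))
                z[inside] = np.minimum(z[inside], ceiling)
            # keep the floor above sea level without creating flats: smooth
            # softplus floor at +50 m preserves strict ordering
            bowl = d < 1.2 * r0
            if bowl.any():
                zi = z[bowl]
                z[bowl] = 50.0 + 25.0 * np.logaddexp(0.0, (zi - 50.0) / 25.0)

        noise, _ = random_harmonic_field(
            mesh, rng, lmin=4, lmax=8,
            coeffs=rng.standard_normal(_coef_spectrum(4, 8).size) * _coef_spectrum(4, 8),
        )
        runoff = _zonal_runoff(lat, p["runoff_zonal_amplitude"])
        gx, gy = mesh.tangent_gradient(z)
        wind_sign = np.where(np.abs(lat) < 30.0, -1.0, 1.0)  # easterlies / westerlies
        ascent = np.maximum(0.0, gx * wind_sign)
        runoff = runoff + p["orographic_gain"] * ascent + p["runoff_noise"] * noise
        runoff = np.maximum(runoff, 0.0)
        runoff[z <= 0.0] = 0.0

        slices.append(
            TimeSliceForcing(
                age=p["age_start"] - k * p["age_step"],
                elevation=z,
                runoff=runoff,
                sea_level=0.0,
            )
        )
    return slices


def save_forcing_sequence(slices, mesh: SphericalMesh, directory) -> list:
    """One netCDF file per slice, age in the filename and as an attribute."""
    from pathlib import Path

    from .mesh import mesh_fields_to_dataset

    paths = []
    for s in slices:
        ds = mesh_fields_to_dataset(mesh, {"elevation": s.elevation, "runoff": s.runoff})
        ds.attrs.update(age_Ma=s.age, sea_level_m=s.sea_level)
        path = Path(directory) / f"forcing_{s.age:07.2f}Ma.nc"
        ds.to_netcdf(path, engine="scipy")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# diversity series
# ---------------------------------------------------------------------------


def generate_diversity_series(
    pvar_series: np.ndarray,
    scov_series: np.ndarray,
    coefficients: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    ages: np.ndarray | None = None,
    group: str = "synthetic",
    count_scale: float = 1000.0,
    count_offset: float = 50.0,
) -> DiversitySeries:
    """Diversity counts from the linear response to P_VAR and S_COV.

    response = intercept + b_pvar*PVAR + b_scov*SCOV + N(0, noise_sd),
    then counts = count_offset + count_scale * response.  The generating
    coefficients and the rescaling are recorded in the series metadata so
    the regression stage can be checked for exact recovery.
    """
    coefficients = coefficients or {"intercept": 0.019, "b_pvar": 0.27, "b_scov": 0.61}
    pvar = np.asarray(pvar_series, float)
    scov = np.asarray(scov_series, float)
    if pvar.shape != scov.shape:
        raise ValueError("pvar_series and scov_series must have equal lengths")
    for name, arr in (("pvar_series", pvar), ("scov_series", scov)):
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError(f"{name} must be normalized to [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    response = (
        coefficients["intercept"]
        + coefficients["b_pvar"] * pvar
        + coefficients["b_scov"] * scov
    )
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=response.size)
    counts = count_offset + count_scale * response
    counts = np.maximum(counts, 0.0)
    if ages is None:
        ages = np.linspace(540.0, 0.0, pvar.size)
    meta = dict(coefficients)
    meta.update(count_scale=count_scale, count_offset=count_offset,
                noise_sd=noise_sd, seed=seed)
    return DiversitySeries(age=np.asarray(ages, float), counts={group: counts},
                           metadata={group: meta})


__all__ = [
    "TimeSliceForcing",
    "DiversitySeries",
    "DEFAULT_FORCING_PARAMS",
    "random_harmonic_field",
    "generate_forcing_sequence",
    "save_forcing_sequence",
    "generate_diversity_series",
]
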